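"""End-to-end orchestration: forge -> damage -> capture -> diagnostics -> report.

Each stage draws from a seed spawned deterministically from the run seed, so
a rerun with the same configuration reproduces every artifact byte for byte
(recorded as SHA-256 hashes in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .capture import amplify_and_sequence, partition
from .compare import assemble_report, fit_mixed_model
from .config import RunConfig
from .damage import damage_fragments, draw_fragments
from .diagnostics import compute_fraction_stats
from .genome import assign_methylome, build_reference
from .inference import (
    aggregate_ms,
    build_misincorporation_table,
    cpg_context_ratio,
    fit_damage_params,
    ms_track,
)
from .io import fragments_to_tsv, write_fastq, write_reference, write_sam

__all__ = ["run_pipeline", "simulate_run"]

log = logging.getLogger(__name__)


def _stage_rngs(seed: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_run(config: RunConfig) -> dict:
    """Run the simulation in memory; returns every intermediate object.

    Keys: ref, methylome, fragments, pools (MBD_plus/MBD_minus fragment
    lists), reads, stats, tables, fits, ratios, ms, report.
    """
    config.validate()
    rng_forge, rng_damage, rng_capture, rng_seq_p, rng_seq_m, *_ = _stage_rngs(config.seed)

    log.info("stage=forge seed=%s", config.seed)
    ref = build_reference(config.genome, seed=rng_forge)
    methylome = assign_methylome(ref, config.methylation)

    log.info("stage=damage n_fragments=%d", config.n_fragments)
    fragments = draw_fragments(
        ref,
        config.n_fragments,
        config.damage,
        endogenous_fraction=config.endogenous_fraction,
        mito_copy_boost=config.mito_copy_boost,
        seed=rng_damage,
    )
    damage_fragments(fragments, ref, config.damage, methylome, seed=rng_damage)

    log.info("stage=capture")
    plus, minus = partition(fragments, config.capture, seed=rng_capture)
    pools = {"MBD_plus": plus, "MBD_minus": minus}

    reads = {}
    for name, pool, rng in (
        ("MBD_plus", plus, rng_seq_p),
        ("MBD_minus", minus, rng_seq_m),
    ):
        log.info("stage=sequence fraction=%s pool=%d reads=%d", name, len(pool), config.n_reads)
        reads[name] = amplify_and_sequence(
            pool,
            ref,
            config.n_reads,
            amp_dispersion=config.amp_dispersion,
            gc_bias_slope=config.gc_bias_slope,
            fraction=name,
            seed=rng,
        )

    stats, tables, fits, ratios, ms = {}, {}, {}, {}, {}
    for name in ("MBD_plus", "MBD_minus"):
        log.info("stage=diagnose fraction=%s", name)
        stats[name] = compute_fraction_stats(reads[name], ref, fraction=name)
        tables[name] = build_misincorporation_table(reads[name], ref, d_max=config.d_max)
        fits[name] = fit_damage_params(tables[name])
        ratios[name] = cpg_context_ratio(tables[name])
        ms[name] = aggregate_ms(
            ms_track(reads[name], ref, window=config.ms_window, min_cov=config.ms_min_cov)
        )

    log.info("stage=compare")
    lengths = [
        (r.length, name, "s1")
        for name in ("MBD_plus", "MBD_minus")
        for r in reads[name]
        if not r.is_duplicate and r.mq_class == "MQ25" and r.origin_class != "microbial"
    ]
    mm = fit_mixed_model(
        [v for v, *_ in lengths],
        [f for _, f, _ in lengths],
        [s for *_, s in lengths],
    )
    report = assemble_report(
        stats["MBD_plus"],
        stats["MBD_minus"],
        fits["MBD_plus"],
        fits["MBD_minus"],
        ratio_plus=ratios["MBD_plus"],
        ratio_minus=ratios["MBD_minus"],
        ms_plus=ms["MBD_plus"],
        ms_minus=ms["MBD_minus"],
        mixed_models={"insert_length": mm},
    )
    return {
        "ref": ref,
        "methylome": methylome,
        "fragments": fragments,
        "pools": pools,
        "reads": reads,
        "stats": stats,
        "tables": tables,
        "fits": fits,
        "ratios": ratios,
        "ms": ms,
        "report": report,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run the full pipeline and write every artifact under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        result = simulate_run(config)
    except Exception as exc:  # tag the failing stage for the caller
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    ref, methylome = result["ref"], result["methylome"]
    write_reference(ref, methylome, out_dir)
    fragments_to_tsv(result["fragments"], out_dir / "fragments.tsv")
    for name in ("MBD_plus", "MBD_minus"):
        write_fastq(result["reads"][name], out_dir / f"{name}.fastq")
        write_sam(result["reads"][name], ref, out_dir / f"{name}.sam")
        with open(out_dir / f"{name}.stats.json", "w") as fh:
            json.dump(result["stats"][name].as_dict(), fh, indent=2)
        result["tables"][name].write_tsv(out_dir / f"{name}.misincorporation.tsv")
        with open(out_dir / f"{name}.damage_fit.json", "w") as fh:
            json.dump(result["fits"][name].as_dict(), fh, indent=2)
    with open(out_dir / "comparison_inputs.json", "w") as fh:
        json.dump(
            {
                "cpg_context_ratio": result["ratios"],
                "ms": result["ms"],
                "mixed_models": {
                    k: v for k, v in result["report"].mixed_models.items()
                },
            },
            fh,
            indent=2,
        )
    result["report"].to_json(out_dir / "report.json")
    (out_dir / "report.md").write_text(result["report"].to_markdown() + "\n")
    config.to_yaml(out_dir / "config.yaml")

    artifacts = sorted(
        p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "hashes": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir
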