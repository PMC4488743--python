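"""Deterministic canned inputs for unit tests and worked examples."""

from __future__ import annotations

import numpy as np

from .capture import amplify_and_sequence, partition
from .config import RunConfig
from .damage import DamageParams, SizeModel, damage_fragments, draw_fragments
from .genome import (
    GenomeConfig,
    MethylationProfile,
    ReferenceSet,
    assign_methylome,
    build_reference,
)
from .inference import MisincorporationTable

__all__ = ["make_fixture", "FIXTURES"]


def _toy_genome():
    config = GenomeConfig(
        nuclear_length=40_000,
        n_cgi=3,
        cgi_length=600,
        n_te_families=2,
        te_copies=2,
        te_length=500,
        mito_length=2_000,
        n_microbial=2,
        microbial_length=8_000,
    )
    ref = build_reference(config, seed=20150702)
    methylome = assign_methylome(ref, MethylationProfile())
    return ref, methylome


def _toy_reads():
    """Exactly 50 reads from a tiny end-to-end simulation."""
    ref, methylome = _toy_genome()
    params = DamageParams(size_model=SizeModel.lognormal(60), min_length=20)
    rng = np.random.default_rng(7)
    frags = draw_fragments(ref, 400, params, endogenous_fraction=0.5, seed=rng)
    damage_fragments(frags, ref, params, methylome, seed=rng)
    plus, minus = partition(frags, RunConfig().capture, seed=rng)
    pool = plus if len(plus) >= 20 else frags
    reads = amplify_and_sequence(pool, ref, 50, fraction="MBD_plus", seed=rng)
    return ref, methylome, reads


def _flat_damage_table():
    """A perfectly flat positional profile (p = 0.01 at huge counts)."""
    n = np.full(25, 1e8)
    return MisincorporationTable(d_max=25, c_sites=n, ct=0.01 * n, g_sites=n, ga=0.01 * n)


def _two_strata_methylome():
    """A reference whose left half is hypomethylated, right half methylated."""
    rng = np.random.default_rng(11)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, 60_000)].tobytes().decode()
    ref = ReferenceSet(
        contigs={"chr1": seq, "chrM": "A" * 500},
        contig_class={"chr1": "nuclear", "chrM": "mito"},
    )
    pos = ref.cpg_positions("chr1")
    prob = np.where(pos < 30_000, 0.1, 0.9)
    from .genome import MethylomeTrack

    track = MethylomeTrack(
        {
            "chr1": (pos, prob),
            "chrM": (ref.cpg_positions("chrM"), np.zeros(len(ref.cpg_positions("chrM")))),
        }
    )
    return ref, track


FIXTURES = {
    "toy-genome": _toy_genome,
    "toy-reads": _toy_reads,
    "flat-damage-table": _flat_damage_table,
    "two-strata-methylome": _two_strata_methylome,
}


def make_fixture(name: str):
    """Build a registered fixture; deterministic across calls."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}") from None
    return factory()
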