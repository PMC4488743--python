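"""MBD2-Fc capture of methylated fragments, PCR amplification and sequencing.

Capture follows a saturating affinity model: each intact methylated CpG on a
molecule independently fails to bind with probability ``1 - beta``, so the
molecule is retained with probability

    carryover + (1 - carryover) * (1 - escape) * (1 - (1 - beta)^k)

where ``k`` is the number of intact (methylated, non-deaminated) CpGs,
``carryover`` is nonspecific capture (the route by which microbial and other
unmethylated DNA enters the enriched fraction) and ``escape`` lumps wash and
elution losses.  Deaminated methyl-CpGs have become TpGs and no longer count
towards ``k`` -- the mechanism that biases the captured fraction against
damaged templates.

Sequencing is modelled as PCR resampling with per-molecule Gamma amplification
weights followed by draws with replacement; repeated draws of a molecule are
flagged as PCR duplicates.  Reads are emitted full length (fragment = insert =
read, i.e. collapsed reads) and are error-free apart from deamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .damage import Fragment, _as_rng, observed_sequence
from .genome import ReferenceSet

__all__ = [
    "CaptureParams",
    "ReadRecord",
    "count_intact_mcpg",
    "capture_probability",
    "partition",
    "amplify_and_sequence",
]


@dataclass(frozen=True)
class CaptureParams:
    beta: float = 0.6          # per-intact-mCpG binding probability
    carryover: float = 0.02    # nonspecific capture of any fragment
    escape: float = 0.05       # bindable fragment lost to the supernatant

    def validate(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 <= self.carryover < 1.0:
            raise ValueError("carryover must be in [0, 1)")
        if not 0.0 <= self.escape < 1.0:
            raise ValueError("escape must be in [0, 1)")


@dataclass
class ReadRecord:
    """A sequenced copy of a fragment; the unit all diagnostics consume."""

    read_id: str
    fragment_id: int
    contig: str
    start: int
    end: int
    sequence: str
    origin_class: str
    is_duplicate: bool
    mq_class: str  # MQ25 | MQ0_only
    fraction: str  # MBD_plus | MBD_minus

    @property
    def length(self) -> int:
        return self.end - self.start


def count_intact_mcpg(fragment: Fragment) -> int:
    """Methylated CpGs on this molecule whose C has not deaminated."""
    if fragment.meth_states is None:
        raise RuntimeError("fragment has no methylation states; deaminate it first")
    n = 0
    for pos, meth in fragment.meth_states.items():
        if meth and (pos - fragment.start, "+") not in fragment.deam_events:
            n += 1
    return n


def capture_probability(k: int, params: CaptureParams) -> float:
    """Probability a molecule with ``k`` intact mCpGs ends up in MBD+."""
    if k < 0:
        raise ValueError("k must be >= 0")
    params.validate()
    specific = (1.0 - params.escape) * (1.0 - (1.0 - params.beta) ** k)
    return params.carryover + (1.0 - params.carryover) * specific


def partition(
    fragments: list[Fragment],
    params: CaptureParams,
    seed=None,
) -> tuple[list[Fragment], list[Fragment]]:
    """Bernoulli-assign each deaminated fragment to (MBD+, MBD-)."""
    params.validate()
    rng = _as_rng(seed)
    plus: list[Fragment] = []
    minus: list[Fragment] = []
    u = rng.random(len(fragments))
    for f, ui in zip(fragments, u):
        if ui < capture_probability(count_intact_mcpg(f), params):
            plus.append(f)
        else:
            minus.append(f)
    return plus, minus


def amplify_and_sequence(
    pool: list[Fragment],
    ref: ReferenceSet,
    n_reads: int,
    amp_dispersion: float = 0.3,
    gc_bias_slope: float | None = None,
    fraction: str = "MBD_plus",
    seed=None,
) -> list[ReadRecord]:
    """PCR-amplify a captured pool and sample ``n_reads`` sequencing reads.

    Per-molecule amplification weights are Gamma(shape=1/amp_dispersion,
    mean=1); ``amp_dispersion=0`` gives uniform weights.  An optional
    exponential GC bias (``exp(gc_bias_slope * GC)``) emulates polymerase
    preference for GC-rich templates.  The first draw of each molecule is the
    non-duplicate representative; later draws are flagged duplicates, so
    smaller pools yield higher clonality at a fixed sequencing effort.
    """
    if n_reads == 0:
        return []
    if not pool:
        raise ValueError("cannot sequence from an empty pool")
    if amp_dispersion < 0:
        raise ValueError("amp_dispersion must be >= 0")
    rng = _as_rng(seed)
    m = len(pool)
    if amp_dispersion > 0:
        w = rng.gamma(1.0 / amp_dispersion, amp_dispersion, m)
    else:
        w = np.ones(m)
    if gc_bias_slope is not None:
        gc = np.array(
            [
                (seq.count("G") + seq.count("C")) / max(len(seq), 1)
                for seq in (ref.contigs[f.contig][f.start : f.end] for f in pool)
            ]
        )
        w = w * np.exp(gc_bias_slope * gc)
    w = w / w.sum()
    idx = rng.choice(m, size=n_reads, p=w)

    seq_cache: dict[int, str] = {}
    seen: set[int] = set()
    reads: list[ReadRecord] = []
    for r, i in enumerate(idx):
        i = int(i)
        f = pool[i]
        seq = seq_cache.get(i)
        if seq is None:
            seq = observed_sequence(f, ref)
            seq_cache[i] = seq
        reads.append(
            ReadRecord(
                read_id=f"{fraction}:{r}",
                fragment_id=i,
                contig=f.contig,
                start=f.start,
                end=f.end,
                sequence=seq,
                origin_class=f.origin_class,
                is_duplicate=i in seen,
                mq_class="MQ0_only" if f.origin_class == "repetitive" else "MQ25",
                fraction=fraction,
            )
        )
        seen.add(i)
    return reads
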