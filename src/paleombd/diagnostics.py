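"""Per-fraction composition, size, coverage and library-complexity statistics.

These are the read-level summaries used to contrast the captured (MBD+) and
supernatant (MBD-) fractions: endogenous content under permissive (MQ0-like)
and strict (MQ25-like) placement filters, PCR clonality, the mitochondrial
share of endogenous reads, insert sizes, GC / CpG / dinucleotide composition,
CpG-island and transposable-element coverage ratios, depth-of-coverage
histograms, and the Shannon diversity of the microbial background.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .capture import ReadRecord
from .genome import ReferenceSet

__all__ = [
    "FractionStats",
    "PAPER_SIZE_BINS",
    "endogenous_and_clonality",
    "interval_coverage_ratio",
    "composition_stats",
    "size_binned_cpg_fraction",
    "coverage_histogram",
    "shannon_index",
    "compute_fraction_stats",
    "microbial_abundances",
]

ENDOGENOUS_CLASSES = {"unique_nuclear", "repetitive", "mito"}
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

# size categories for the CpG-presence-by-length analysis; left-closed,
# right-open, "<30" meaning [2, 30)
PAPER_SIZE_BINS: tuple[tuple[int, float], ...] = (
    (2, 30),
    (30, 40),
    (40, 50),
    (50, 60),
    (60, 70),
    (70, 80),
    (80, 90),
    (90, 100),
    (100, 200),
    (200, 300),
    (300, math.inf),
)

# minimum data gates below which per-fraction statistics are unreliable
NUCLEAR_READ_GATE = 2_000
MITO_READ_GATE = 20


def endogenous_and_clonality(reads: list[ReadRecord]) -> tuple[float, float, float]:
    """(endogenous MQ0-analog, endogenous MQ25-analog, clonality).

    The MQ25 analog counts unique (non-duplicate), non-repetitive endogenous
    reads over all reads; the MQ0 analog additionally admits repetitive
    placements.  Clonality is the PCR-duplicate fraction among endogenous
    hits.  Empty input returns zeros.
    """
    total = len(reads)
    if total == 0:
        return 0.0, 0.0, 0.0
    endo = [r for r in reads if r.origin_class in ENDOGENOUS_CLASSES]
    uniq = [r for r in endo if not r.is_duplicate]
    endo_mq0 = len(uniq) / total
    endo_mq25 = sum(1 for r in uniq if r.origin_class != "repetitive") / total
    clonality = (sum(1 for r in endo if r.is_duplicate) / len(endo)) if endo else 0.0
    return endo_mq0, endo_mq25, clonality


def _depth_arrays(
    reads: list[ReadRecord],
    ref: ReferenceSet,
    contig_classes: tuple[str, ...] = ("nuclear",),
    include_duplicates: bool = False,
) -> dict[str, np.ndarray]:
    depth = {
        c: np.zeros(len(ref.contigs[c]), dtype=np.int32)
        for c, cls in ref.contig_class.items()
        if cls in contig_classes
    }
    for r in reads:
        if r.contig in depth and (include_duplicates or not r.is_duplicate):
            depth[r.contig][r.start : r.end] += 1
    return depth


def interval_coverage_ratio(
    reads: list[ReadRecord],
    intervals: list[tuple],
    ref: ReferenceSet,
) -> float:
    """Mean base-wise depth inside the intervals over mean depth outside.

    Computed over nuclear contigs from non-duplicate reads.  A zero outside
    depth yields a flagged infinity rather than an exception.
    """
    depth = _depth_arrays(reads, ref)
    total_in = total_out = 0.0
    n_in = n_out = 0
    for contig, arr in depth.items():
        mask = np.zeros(len(arr), dtype=bool)
        for iv in intervals:
            if iv[0] == contig:
                mask[iv[1] : iv[2]] = True
        total_in += float(arr[mask].sum())
        total_out += float(arr[~mask].sum())
        n_in += int(mask.sum())
        n_out += int((~mask).sum())
    if n_in == 0:
        raise ValueError("intervals cover no nuclear bases")
    mean_in = total_in / n_in
    mean_out = total_out / n_out if n_out else 0.0
    if mean_out == 0.0:
        return math.inf if mean_in > 0 else float("nan")
    return mean_in / mean_out


def composition_stats(
    reads: list[ReadRecord],
) -> tuple[float, float, dict[str, float], float]:
    """(mean GC, mean CpG per bp, dinucleotide frequencies, CpG-free fraction).

    GC and CpG density are per-read values averaged over reads; dinucleotide
    frequencies pool overlapping dimers within reads (never across reads) and
    sum to 1.  Reads shorter than 2 bp are excluded from dimer statistics.
    """
    if not reads:
        return float("nan"), float("nan"), {d: float("nan") for d in DINUCLEOTIDES}, float("nan")
    gc_vals = []
    cpg_vals = []
    cpg_free = 0
    dimer_counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for r in reads:
        seq = r.sequence
        L = len(seq)
        gc_vals.append((seq.count("G") + seq.count("C")) / L)
        n_cpg = seq.count("CG")
        cpg_vals.append(n_cpg / L)
        if n_cpg == 0:
            cpg_free += 1
        if L >= 2:
            for i in range(L - 1):
                dimer = seq[i : i + 2]
                if dimer in dimer_counts:
                    dimer_counts[dimer] += 1
    total = sum(dimer_counts.values())
    freqs = {d: (c / total if total else float("nan")) for d, c in dimer_counts.items()}
    return (
        float(np.mean(gc_vals)),
        float(np.mean(cpg_vals)),
        freqs,
        cpg_free / len(reads),
    )


def size_binned_cpg_fraction(
    reads: list[ReadRecord],
    bins: tuple[tuple[int, float], ...] = PAPER_SIZE_BINS,
) -> tuple[list[float | None], list[float | None]]:
    """Per size bin, the fraction of reads containing at least one CpG.

    Returns ``(plain, weighted)``: the plain per-bin fraction (primary) and a
    secondary variant additionally scaled by the bin's share of all reads
    considered.  Empty bins are reported as ``None``, not 0.
    """
    counts = [0] * len(bins)
    with_cpg = [0] * len(bins)
    considered = 0
    for r in reads:
        L = len(r.sequence)
        for i, (lo, hi) in enumerate(bins):
            if lo <= L < hi:
                counts[i] += 1
                considered += 1
                if "CG" in r.sequence:
                    with_cpg[i] += 1
                break
    plain: list[float | None] = []
    weighted: list[float | None] = []
    for i, n in enumerate(counts):
        if n == 0:
            plain.append(None)
            weighted.append(None)
        else:
            f = with_cpg[i] / n
            plain.append(f)
            weighted.append(f * (n / considered))
    return plain, weighted


def coverage_histogram(
    reads: list[ReadRecord],
    ref: ReferenceSet,
    include_duplicates: bool = False,
) -> dict[int, int]:
    """Base-wise depth histogram over nuclear contigs, depth >= 1 only."""
    hist: dict[int, int] = {}
    for arr in _depth_arrays(reads, ref, include_duplicates=include_duplicates).values():
        depths, counts = np.unique(arr[arr > 0], return_counts=True)
        for d, c in zip(depths.tolist(), counts.tolist()):
            hist[int(d)] = hist.get(int(d), 0) + int(c)
    return hist


def normalized_coverage(hist: dict[int, int]) -> dict[float, float]:
    """Depth histogram rescaled by the mean depth of covered bases."""
    total = sum(hist.values())
    if total == 0:
        return {}
    mean = sum(d * c for d, c in hist.items()) / total
    return {d / mean: c / total for d, c in hist.items()}


def shannon_index(abundances: Mapping[str, float], min_fraction: float = 0.01) -> float:
    """Shannon diversity -sum(p ln p) after discarding low-abundance taxa.

    Taxa below ``min_fraction`` of the total are disregarded and the
    remainder renormalised before the index is computed.
    """
    total = sum(abundances.values())
    if total <= 0:
        raise ValueError("abundances must have positive total")
    p = np.array([v / total for v in abundances.values()])
    p = p[p >= min_fraction]
    if len(p) == 0:
        raise ValueError("no taxa left after low-abundance filtering")
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def microbial_abundances(reads: list[ReadRecord], ref: ReferenceSet) -> dict[str, float]:
    """Read-count abundances of the synthetic microbial contigs (the 'taxa')."""
    counts: dict[str, int] = {}
    for r in reads:
        if ref.contig_class.get(r.contig) == "microbial" and not r.is_duplicate:
            counts[r.contig] = counts.get(r.contig, 0) + 1
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()} if total else {}


@dataclass
class FractionStats:
    """Paired summary of one library fraction (MBD+ or MBD-)."""

    fraction: str
    n_reads: int
    endogenous_mq0: float
    endogenous_mq25: float
    clonality: float
    mtdna_share_of_endogenous: float
    mean_insert: float
    median_insert: float
    mean_gc: float
    mean_cpg_per_bp: float
    dinucleotide_frequencies: dict[str, float]
    size_binned_cpg: list[float | None]
    size_binned_cpg_weighted: list[float | None]
    cpg_free_fraction: float
    coverage_histogram: dict[int, int]
    cgi_coverage_ratio: float
    te_coverage_ratio: float
    shannon: float | None
    n_nuclear: int = 0
    n_mito: int = 0
    reliable_nuclear: bool = field(default=True)
    reliable_mito: bool = field(default=True)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["coverage_histogram"] = {str(k): v for k, v in self.coverage_histogram.items()}
        return d


def compute_fraction_stats(
    reads: list[ReadRecord],
    ref: ReferenceSet,
    fraction: str | None = None,
) -> FractionStats:
    """Assemble the full per-fraction report from one read set.

    Composition and size statistics use unique (non-duplicate) endogenous
    reads under the strict placement filter; the TE coverage ratio admits
    repetitive reads (they are what TEs produce), while the CGI ratio uses
    strict-filter reads only.  Fractions with fewer than 2,000 nuclear or 20
    mitochondrial reads are flagged unreliable.
    """
    if fraction is None:
        fraction = reads[0].fraction if reads else "unknown"
    endo_mq0, endo_mq25, clonality = endogenous_and_clonality(reads)

    uniq_endo = [
        r for r in reads if not r.is_duplicate and r.origin_class in ENDOGENOUS_CLASSES
    ]
    uniq_mq25 = [r for r in uniq_endo if r.mq_class == "MQ25"]
    n_mito = sum(1 for r in uniq_mq25 if r.origin_class == "mito")
    n_nuclear = sum(1 for r in uniq_endo if r.origin_class != "mito")
    mt_share = n_mito / len(uniq_mq25) if uniq_mq25 else float("nan")

    lengths = [r.length for r in uniq_mq25] or [float("nan")]
    gc, cpg_bp, dimers, cpg_free = composition_stats(uniq_mq25)
    plain, weighted = size_binned_cpg_fraction(uniq_mq25)

    nuclear_mq25 = [r for r in uniq_mq25 if r.origin_class == "unique_nuclear"]
    nuclear_all = [r for r in uniq_endo if r.origin_class in ("unique_nuclear", "repetitive")]
    try:
        cgi_ratio = interval_coverage_ratio(nuclear_mq25, ref.cgi_intervals, ref)
    except ValueError:
        cgi_ratio = float("nan")
    try:
        te_ratio = interval_coverage_ratio(nuclear_all, ref.te_intervals, ref)
    except ValueError:
        te_ratio = float("nan")

    abund = microbial_abundances(reads, ref)
    shannon = shannon_index(abund) if abund else None

    return FractionStats(
        fraction=fraction,
        n_reads=len(reads),
        endogenous_mq0=endo_mq0,
        endogenous_mq25=endo_mq25,
        clonality=clonality,
        mtdna_share_of_endogenous=mt_share,
        mean_insert=float(np.mean(lengths)),
        median_insert=float(np.median(lengths)),
        mean_gc=gc,
        mean_cpg_per_bp=cpg_bp,
        dinucleotide_frequencies=dimers,
        size_binned_cpg=plain,
        size_binned_cpg_weighted=weighted,
        cpg_free_fraction=cpg_free,
        coverage_histogram=coverage_histogram(nuclear_mq25, ref),
        cgi_coverage_ratio=cgi_ratio,
        te_coverage_ratio=te_ratio,
        shannon=shannon,
        n_nuclear=n_nuclear,
        n_mito=n_mito,
        reliable_nuclear=n_nuclear >= NUCLEAR_READ_GATE,
        reliable_mito=n_mito >= MITO_READ_GATE,
    )
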