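"""Recovering damage and methylation signal from placed reads.

Three read-level statistics summarise post-mortem chemistry:

* the positional misincorporation table (C->T by distance from the 5' end,
  G->A mirrored from the 3' end, stratified by CpN dinucleotide context);
* a maximum-likelihood fit of the three-parameter damage model
  ``p(d) = delta_s*(1-lambda)^d + delta_d*(1-(1-lambda)^d)`` to the 5'
  profile, recovering single-strand / double-strand deamination rates and the
  overhang-length parameter;
* the CpG-context deamination ratio (per-site C->T rate at CpG sites over the
  rate at CpA/CpC/CpT sites) and the regional methylation proxy Ms
  (CpG->TpG mismatch frequency at read termini per genomic window), both of
  which read out methylation because methyl-C deaminates faster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .capture import ReadRecord
from .genome import ReferenceSet

__all__ = [
    "MisincorporationTable",
    "DamageFit",
    "MsWindow",
    "build_misincorporation_table",
    "fit_damage_params",
    "cpg_context_ratio",
    "ms_track",
    "aggregate_ms",
]

log = logging.getLogger(__name__)

CONTEXTS = ("CA", "CC", "CG", "CT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class MisincorporationTable:
    """Counts of substitution opportunities and events by end distance.

    Arrays are indexed ``d - 1`` for 1-based distance ``d``.  The 3' G->A
    signal (reverse-strand C->T) is kept separately so the 5' fit can use the
    3' side as a consistency check.  Context-stratified counts pool both ends
    on the reverse-complement-aware CpN context of the deaminating C.
    Counts are floats so analytically expected (noise-free) tables are valid.
    """

    d_max: int = 25
    c_sites: np.ndarray | None = None
    ct: np.ndarray | None = None
    g_sites: np.ndarray | None = None
    ga: np.ndarray | None = None
    context_sites: dict[str, np.ndarray] = field(default_factory=dict)
    context_events: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("c_sites", "ct", "g_sites", "ga"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.d_max))
        for ctx in CONTEXTS:
            self.context_sites.setdefault(ctx, np.zeros(self.d_max))
            self.context_events.setdefault(ctx, np.zeros(self.d_max))
        for name in ("c_sites", "ct", "g_sites", "ga"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != self.d_max:
                raise ValueError(f"{name} must have length d_max={self.d_max}")
            setattr(self, name, arr)
        if np.any(self.ct > self.c_sites) or np.any(self.ga > self.g_sites):
            raise ValueError("events exceed sites")

    def ct_frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.c_sites > 0, self.ct / self.c_sites, np.nan)

    def ga_frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.g_sites > 0, self.ga / self.g_sites, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "pos": np.arange(1, self.d_max + 1),
                "C": self.c_sites,
                "CtoT": self.ct,
                "G": self.g_sites,
                "GtoA": self.ga,
                "5pCtoT": self.ct_frequency(),
                "3pGtoA": self.ga_frequency(),
            }
        )
        for ctx in CONTEXTS:
            df[f"{ctx}_sites"] = self.context_sites[ctx]
            df[f"{ctx}_CtoT"] = self.context_events[ctx]
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MisincorporationTable":
        df = pd.read_csv(path, sep="\t")
        t = cls(
            d_max=len(df),
            c_sites=df["C"].to_numpy(float),
            ct=df["CtoT"].to_numpy(float),
            g_sites=df["G"].to_numpy(float),
            ga=df["GtoA"].to_numpy(float),
        )
        for ctx in CONTEXTS:
            t.context_sites[ctx] = df[f"{ctx}_sites"].to_numpy(float)
            t.context_events[ctx] = df[f"{ctx}_CtoT"].to_numpy(float)
        return t


def build_misincorporation_table(
    reads: list[ReadRecord],
    ref: ReferenceSet,
    d_max: int = 25,
    mq25_only: bool = True,
    endogenous_only: bool = True,
) -> MisincorporationTable:
    """Tally C->T / G->A opportunities and events by distance from read ends.

    Duplicates are always excluded; by default so are repetitive (MQ0-only)
    and non-endogenous reads, mirroring quality-filtered alignments against
    the endogenous reference.
    """
    table = MisincorporationTable(d_max=d_max)
    endo = {"unique_nuclear", "repetitive", "mito"}
    for read in reads:
        if read.is_duplicate:
            continue
        if mq25_only and read.mq_class != "MQ25":
            continue
        if endogenous_only and read.origin_class not in endo:
            continue
        contig = ref.contigs[read.contig]
        if read.start < 0 or read.end > len(contig):
            log.warning("read %s extends past contig %s; skipped", read.read_id, read.contig)
            continue
        refseq = contig[read.start : read.end]
        obs = read.sequence
        L = read.end - read.start
        span = min(d_max, L)
        for d in range(1, span + 1):
            # 5' side: forward-strand C
            i5 = d - 1
            if refseq[i5] == "C":
                table.c_sites[d - 1] += 1
                event = obs[i5] == "T"
                if event:
                    table.ct[d - 1] += 1
                nxt_pos = read.start + i5 + 1
                if nxt_pos < len(contig):
                    ctx = "C" + contig[nxt_pos]
                    if ctx in table.context_sites:
                        table.context_sites[ctx][d - 1] += 1
                        if event:
                            table.context_events[ctx][d - 1] += 1
            # 3' side: reference G = reverse-strand C
            i3 = L - d
            if refseq[i3] == "G":
                table.g_sites[d - 1] += 1
                event = obs[i3] == "A"
                if event:
                    table.ga[d - 1] += 1
                prv_pos = read.start + i3 - 1
                if prv_pos >= 0:
                    ctx = "C" + contig[prv_pos].translate(_COMPLEMENT)
                    if ctx in table.context_sites:
                        table.context_sites[ctx][d - 1] += 1
                        if event:
                            table.context_events[ctx][d - 1] += 1
    return table


@dataclass
class DamageFit:
    delta_s_hat: float
    delta_d_hat: float
    lambda_hat: float
    residual: float
    n_sites: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "delta_s": self.delta_s_hat,
            "delta_d": self.delta_d_hat,
            "lambda": self.lambda_hat,
            "residual": self.residual,
            "n_sites": self.n_sites,
            "degenerate": self.degenerate,
        }


_FIT_STARTS = (
    (0.30, 0.010, 0.30),
    (0.10, 0.050, 0.50),
    (0.50, 0.020, 0.20),
    (0.05, 0.005, 0.80),
)


def fit_damage_params(table: MisincorporationTable) -> DamageFit:
    """Bounded maximum-likelihood fit of (delta_s, delta_d, lambda).

    Maximises the binomial likelihood of the 5' C->T counts under
    ``p(d) = delta_s*(1-lambda)^d + delta_d*(1-(1-lambda)^d)`` over the box
    [0,1]^3, from a fixed grid of starts (deterministic).  A flat profile
    (delta_s ~ delta_d, or lambda ~ 1) is inherently non-identifiable in
    lambda and is flagged degenerate, as is an all-zero table.
    """
    n = table.c_sites.astype(float)
    k = table.ct.astype(float)
    use = n > 0
    if not use.any():
        raise ValueError("table has no nonzero site counts")
    if k[use].sum() == 0:
        return DamageFit(0.0, 0.0, 0.0, 0.0, float(n.sum()), degenerate=True)
    d = np.arange(1, table.d_max + 1, dtype=float)[use]
    n, k = n[use], k[use]

    def nll(theta: np.ndarray) -> float:
        ds, dd, lam = theta
        q = (1.0 - lam) ** d
        p = np.clip(ds * q + dd * (1.0 - q), 1e-12, 1.0 - 1e-12)
        return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())

    best = None
    bounds = [(1e-9, 1.0), (1e-9, 1.0), (1e-9, 1.0)]
    for x0 in _FIT_STARTS:
        res = minimize(nll, np.array(x0), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ds, dd, lam = (float(v) for v in best.x)
    q = (1.0 - lam) ** d
    p = ds * q + dd * (1.0 - q)
    residual = float(np.sqrt(np.mean((p - k / n) ** 2)))
    degenerate = abs(ds - dd) < 1e-4 or lam > 0.999
    return DamageFit(ds, dd, lam, residual, float(n.sum()), degenerate=degenerate)


def cpg_context_ratio(table: MisincorporationTable) -> float:
    """Per-site C->T rate at CpG sites over the rate at CpA/CpC/CpT sites.

    Normalising by context site counts separates chemistry from composition:
    the two fractions differ in how many CpGs they carry, not only in how
    fast those CpGs deaminate.  Returns a flagged infinity (with a warning)
    when no non-CpG events exist.
    """
    cpg_sites = table.context_sites["CG"].sum()
    cpg_events = table.context_events["CG"].sum()
    other_sites = sum(table.context_sites[c].sum() for c in ("CA", "CC", "CT"))
    other_events = sum(table.context_events[c].sum() for c in ("CA", "CC", "CT"))
    if cpg_sites == 0:
        raise ValueError("no CpG-context sites in table")
    if other_sites == 0 or other_events == 0:
        warnings.warn("no non-CpG C->T events; CpG-context ratio is undefined (inf)")
        return float("inf")
    return (cpg_events / cpg_sites) / (other_events / other_sites)


@dataclass(frozen=True)
class MsWindow:
    contig: str
    start: int  # window start on the tiling grid
    coverage: int  # terminal CpG observations
    mismatches: int  # terminal CpG->TpG observations
    ms: float


def ms_track(
    reads: list[ReadRecord],
    ref: ReferenceSet,
    window: int = 100,
    min_cov: int = 50,
    step: int | None = None,
    mq25_only: bool = True,
) -> list[MsWindow]:
    """Regional methylation proxy Ms per genomic window.

    For every reference CpG covered by the first aligned base of a read (the
    5' terminus; reverse-strand molecules contribute through the terminal
    G->A on the CpG's G), Ms is the fraction of those terminal observations
    that read TpG.  Windows tile the genome (``step`` defaults to ``window``)
    and are reported only when terminal CpG coverage reaches ``min_cov``.
    Duplicates and (by default) repetitive reads are excluded; only nuclear
    and mitochondrial contigs are scored.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if step is None:
        step = window
    cov: dict[tuple[str, int], int] = {}
    mm: dict[tuple[str, int], int] = {}
    scored = {c for c, cls in ref.contig_class.items() if cls in ("nuclear", "mito")}

    def bump(contig: str, site: int, is_mismatch: bool) -> None:
        # every window start w = k*step with w <= site < w + window
        k_lo = max(0, -(-(site - window + 1) // step))  # ceil division
        k_hi = site // step
        for k in range(k_lo, k_hi + 1):
            key = (contig, k * step)
            cov[key] = cov.get(key, 0) + 1
            if is_mismatch:
                mm[key] = mm.get(key, 0) + 1

    for read in reads:
        if read.is_duplicate or read.contig not in scored:
            continue
        if mq25_only and read.mq_class != "MQ25":
            continue
        contig = ref.contigs[read.contig]
        p5 = read.start
        if contig[p5] == "C" and p5 + 1 < len(contig) and contig[p5 + 1] == "G":
            bump(read.contig, p5, read.sequence[0] == "T")
        p3 = read.end - 1
        if contig[p3] == "G" and p3 >= 1 and contig[p3 - 1] == "C":
            bump(read.contig, p3 - 1, read.sequence[-1] == "A")

    out = []
    for (contig, w), c in sorted(cov.items()):
        if c >= min_cov:
            m = mm.get((contig, w), 0)
            out.append(MsWindow(contig, w, c, m, m / c))
    return out


def aggregate_ms(windows: list[MsWindow]) -> float:
    """Coverage-weighted mean Ms (= pooled mismatches / pooled coverage)."""
    cov = sum(w.coverage for w in windows)
    if cov == 0:
        return float("nan")
    return sum(w.mismatches for w in windows) / cov
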