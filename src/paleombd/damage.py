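"""Post-mortem DNA degradation: fragmentation, overhangs and deamination.

The model follows the standard ancient-DNA damage parameterisation: fragments
carry geometric single-stranded 5' overhangs at both ends (termination
parameter ``lambda_ov``); cytosines deaminate with probability ``delta_s`` in
single-stranded context and ``delta_d`` in double-stranded context, observed
as C->T at 5' read starts and, through the complementary strand, G->A at 3'
read ends.  Methylated CpG cytosines deaminate ``rho_meth``-fold faster
(5-methylcytosine hydrolyses to thymine directly); a deaminated methyl-C
destroys that CpG as a capture target.

The closed-form positional profile

    p(d) = rho * [delta_s * (1-lambda)^d + delta_d * (1 - (1-lambda)^d)]

(``d`` the 1-based distance from the 5' end, ``rho`` the methylation factor
where applicable, clipped to 1) is exposed in :func:`expected_ct_profile` and
serves as the oracle for the downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import MethylomeTrack, ReferenceSet

__all__ = [
    "SizeModel",
    "DamageParams",
    "Fragment",
    "draw_fragments",
    "apply_overhangs",
    "assign_methylation",
    "deaminate",
    "damage_fragments",
    "expected_ct_profile",
    "simulate_ct_profile",
]

_C = ord("C")
_G = ord("G")


@dataclass(frozen=True)
class SizeModel:
    """Fragment length distribution.

    ``lognormal`` matches the right-skewed size spectra of ancient extracts;
    ``per_base`` (every internucleotide bond breaks independently, geometric
    lengths) is provided for sensitivity analyses.
    """

    kind: str = "lognormal"
    mean_log: float = float(np.log(80.0))
    sd_log: float = 0.40
    p_break: float = 0.02

    @classmethod
    def lognormal(cls, median: float, sd_log: float = 0.40) -> "SizeModel":
        return cls(kind="lognormal", mean_log=float(np.log(median)), sd_log=sd_log)

    @classmethod
    def per_base(cls, p_break: float) -> "SizeModel":
        return cls(kind="per_base", p_break=p_break)

    @property
    def median(self) -> float:
        if self.kind == "lognormal":
            return float(np.exp(self.mean_log))
        return float(np.ceil(np.log(0.5) / np.log(1 - self.p_break)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "lognormal":
            return np.maximum(1, np.rint(rng.lognormal(self.mean_log, self.sd_log, n)).astype(int))
        if self.kind == "per_base":
            return rng.geometric(self.p_break, n)
        raise ValueError(f"unknown size model kind {self.kind!r}")


@dataclass(frozen=True)
class DamageParams:
    """Deamination and fragmentation parameters of the forward model."""

    delta_s: float = 0.25
    delta_d: float = 0.015
    lambda_ov: float = 0.35
    rho_meth: float = 4.0
    size_model: SizeModel = field(default_factory=SizeModel)
    min_length: int = 25

    def validate(self) -> None:
        for name in ("delta_s", "delta_d", "lambda_ov"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.rho_meth < 1.0:
            raise ValueError("rho_meth must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class Fragment:
    """A double-stranded ancient molecule with its damage history."""

    contig: str
    start: int
    end: int
    origin_class: str  # unique_nuclear | repetitive | mito | microbial
    overhang5: int | None = None
    overhang3: int | None = None
    meth_states: dict[int, bool] | None = None  # abs. forward C position -> methylated
    deam_events: set[tuple[int, str]] = field(default_factory=set)  # (offset, '+'|'-')

    @property
    def length(self) -> int:
        return self.end - self.start


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _te_midpoint_lookup(ref: ReferenceSet):
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in {t[0] for t in ref.te_intervals}:
        iv = sorted((s, e) for c, s, e, _ in ref.te_intervals if c == contig)
        by_contig[contig] = (
            np.array([s for s, _ in iv]),
            np.array([e for _, e in iv]),
        )

    def is_repetitive(contig: str, mid: int) -> bool:
        se = by_contig.get(contig)
        if se is None:
            return False
        starts, ends = se
        i = int(np.searchsorted(starts, mid, side="right")) - 1
        return i >= 0 and mid < ends[i]

    return is_repetitive


def draw_fragments(
    ref: ReferenceSet,
    n: int,
    params: DamageParams,
    endogenous_fraction: float = 0.35,
    mito_copy_boost: float = 3.0,
    seed=None,
) -> list[Fragment]:
    """Draw ``n`` fragments from the extract.

    Each fragment is endogenous (nuclear or mitochondrial) with probability
    ``endogenous_fraction``, otherwise microbial.  Within a category, contigs
    are chosen proportionally to length, the mitochondrial contig additionally
    weighted by ``mito_copy_boost`` (organellar copy number, calibrated for
    the scaled-down genome).  Start positions are uniform; lengths follow the
    configured size model, clipped to ``[min_length, contig length]`` by
    resampling.
    """
    params.validate()
    if n == 0:
        return []
    if not 0.0 < endogenous_fraction <= 1.0:
        raise ValueError("endogenous_fraction must be in (0, 1]")
    rng = _as_rng(seed)

    endo = ref.contigs_of_class("nuclear") + ref.contigs_of_class("mito")
    micro = ref.contigs_of_class("microbial")
    if not micro and endogenous_fraction < 1.0:
        endogenous_fraction = 1.0

    def weights(names: list[str]) -> np.ndarray:
        w = np.array(
            [
                len(ref.contigs[c]) * (mito_copy_boost if ref.contig_class[c] == "mito" else 1.0)
                for c in names
            ],
            dtype=float,
        )
        return w / w.sum()

    endo_w = weights(endo)
    micro_w = weights(micro) if micro else None

    is_endo = rng.random(n) < endogenous_fraction
    contig_idx = np.empty(n, dtype=int)
    contig_names: list[str] = [""] * n
    n_endo = int(is_endo.sum())
    endo_choice = rng.choice(len(endo), size=n_endo, p=endo_w)
    micro_choice = rng.choice(len(micro), size=n - n_endo, p=micro_w) if micro else np.empty(0, int)
    ei = mi = 0
    for i in range(n):
        if is_endo[i]:
            contig_names[i] = endo[endo_choice[ei]]
            ei += 1
        else:
            contig_names[i] = micro[micro_choice[mi]]
            mi += 1
    del contig_idx

    lengths = params.size_model.sample(rng, n)
    lengths = np.maximum(lengths, params.min_length)
    is_rep = _te_midpoint_lookup(ref)

    fragments: list[Fragment] = []
    for i in range(n):
        contig = contig_names[i]
        clen = len(ref.contigs[contig])
        L = int(lengths[i])
        while L > clen:  # fragment longer than contig -> resample
            L = max(int(params.size_model.sample(rng, 1)[0]), params.min_length)
        start = int(rng.integers(0, clen - L + 1))
        end = start + L
        cls = ref.contig_class[contig]
        if cls == "nuclear":
            origin = "repetitive" if is_rep(contig, (start + end) // 2) else "unique_nuclear"
        else:
            origin = cls
        fragments.append(Fragment(contig=contig, start=start, end=end, origin_class=origin))
    return fragments


def apply_overhangs(fragment: Fragment, lambda_ov: float, seed=None) -> Fragment:
    """Draw i.i.d. geometric 5' overhang lengths, P(L=l) = lambda*(1-lambda)^l."""
    if not 0.0 < lambda_ov <= 1.0:
        raise ValueError("lambda_ov must be in (0, 1]")
    rng = _as_rng(seed)
    oh = rng.geometric(lambda_ov, 2) - 1  # numpy geometric is on {1, 2, ...}
    fragment.overhang5 = int(oh[0])
    fragment.overhang3 = int(oh[1])
    return fragment


def assign_methylation(fragment: Fragment, methylome: MethylomeTrack, seed=None) -> Fragment:
    """Realise per-molecule methylation states from the track's probabilities.

    Methylation is Bernoulli per molecule (epialleles), so coverage-level
    methylation converges to the track value.  Only CpGs fully inside the
    fragment (C and G both within) are considered.
    """
    rng = _as_rng(seed)
    pos, prob = methylome.slice(fragment.contig, fragment.start, fragment.end - 1)
    states = rng.random(len(pos)) < prob
    fragment.meth_states = dict(zip(pos.tolist(), map(bool, states)))
    return fragment


def deaminate(
    fragment: Fragment,
    ref: ReferenceSet,
    params: DamageParams,
    methylome: MethylomeTrack | None = None,
    seed=None,
) -> Fragment:
    """Apply context-dependent cytosine deamination to one molecule.

    Forward-strand Cs within the 5' overhang (and, symmetrically,
    reverse-strand Cs, i.e. reference Gs, within the 3' overhang) deaminate
    with probability ``min(1, delta_s * rho)``; all other cytosines with
    ``min(1, delta_d * rho)``, where ``rho = rho_meth`` if the site is a
    methylated CpG on this molecule and 1 otherwise.  Events are observed as
    C->T (forward) and G->A (reverse-strand convention at the 3' end).
    """
    if fragment.overhang5 is None or fragment.overhang3 is None:
        raise RuntimeError("fragment has no overhangs; call apply_overhangs first")
    rng = _as_rng(seed)
    if fragment.meth_states is None:
        if methylome is None:
            raise RuntimeError("fragment has no methylation states and no methylome given")
        assign_methylation(fragment, methylome, rng)

    sb = ref.seq_bytes(fragment.contig)[fragment.start : fragment.end]
    L = fragment.length
    meth_pos = np.array(
        [p for p, m in fragment.meth_states.items() if m], dtype=np.int64
    )

    events: set[tuple[int, str]] = set()

    c_off = np.flatnonzero(sb == _C)
    if len(c_off):
        abs_pos = c_off + fragment.start
        meth = np.isin(abs_pos, meth_pos) if len(meth_pos) else np.zeros(len(c_off), bool)
        ss = c_off < fragment.overhang5
        p = np.where(ss, params.delta_s, params.delta_d) * np.where(meth, params.rho_meth, 1.0)
        hit = rng.random(len(c_off)) < np.minimum(p, 1.0)
        events.update((int(o), "+") for o in c_off[hit])

    g_off = np.flatnonzero(sb == _G)
    if len(g_off):
        # reference G = reverse-strand C; its CpG partner C sits one base left
        abs_pos = g_off + fragment.start
        meth = np.isin(abs_pos - 1, meth_pos) if len(meth_pos) else np.zeros(len(g_off), bool)
        ss = (L - 1 - g_off) < fragment.overhang3
        p = np.where(ss, params.delta_s, params.delta_d) * np.where(meth, params.rho_meth, 1.0)
        hit = rng.random(len(g_off)) < np.minimum(p, 1.0)
        events.update((int(o), "-") for o in g_off[hit])

    fragment.deam_events = events
    return fragment


def damage_fragments(
    fragments: list[Fragment],
    ref: ReferenceSet,
    params: DamageParams,
    methylome: MethylomeTrack,
    seed=None,
) -> list[Fragment]:
    """Overhangs + methylation states + deamination for a whole pool."""
    rng = _as_rng(seed)
    for f in fragments:
        apply_overhangs(f, params.lambda_ov, rng)
        deaminate(f, ref, params, methylome, rng)
    return fragments


def observed_sequence(fragment: Fragment, ref: ReferenceSet) -> str:
    """The sequence a (error-free) sequencer reports for this molecule."""
    b = bytearray(ref.seq_bytes(fragment.contig)[fragment.start : fragment.end].tobytes())
    for off, strand in fragment.deam_events:
        b[off] = ord("T") if strand == "+" else ord("A")
    return b.decode()


def expected_ct_profile(params: DamageParams, d: int, methylated: bool = False) -> float:
    """Closed-form C->T probability at 1-based distance ``d`` from the 5' end."""
    if d < 1:
        raise ValueError("distance d must be >= 1")
    q = (1.0 - params.lambda_ov) ** d
    rho = params.rho_meth if methylated else 1.0
    return min(1.0, rho * (params.delta_s * q + params.delta_d * (1.0 - q)))


def simulate_ct_profile(
    params: DamageParams,
    n_fragments: int,
    length: int = 64,
    d_max: int = 25,
    seed=None,
) -> dict[str, np.ndarray]:
    """Monte-Carlo calibration of the positional profile on an all-C template.

    Simulates ``n_fragments`` molecules on a synthetic all-cytosine contig
    through the real overhang and deamination machinery and tallies C->T
    events by distance from the 5' end.  Also accumulates, per distance, the
    per-molecule conditional event probability given the drawn overhangs
    (a Rao-Blackwellised estimate of the same frequency with strictly smaller
    Monte-Carlo variance), which is what calibration checks compare against
    :func:`expected_ct_profile`.

    Returns arrays indexed by d-1: ``events`` (observed C->T counts),
    ``sites`` (= n_fragments at every d), ``conditional`` (summed conditional
    probabilities).
    """
    if length <= d_max:
        raise ValueError("template length must exceed d_max")
    ref = ReferenceSet(
        contigs={"calib": "C" * length, "calibM": "A" * 10},
        contig_class={"calib": "nuclear", "calibM": "mito"},
    )
    empty = MethylomeTrack({})
    rng = _as_rng(seed)
    d = np.arange(1, d_max + 1)
    events = np.zeros(d_max)
    conditional = np.zeros(d_max)
    for _ in range(n_fragments):
        f = Fragment("calib", 0, length, "unique_nuclear")
        apply_overhangs(f, params.lambda_ov, rng)
        deaminate(f, ref, params, empty, rng)
        ss = d <= f.overhang5
        conditional += np.where(ss, params.delta_s, params.delta_d)
        for off, strand in f.deam_events:
            if strand == "+" and off < d_max:
                events[off] += 1
    return {
        "d": d,
        "events": events,
        "sites": np.full(d_max, float(n_fragments)),
        "conditional": conditional,
    }
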