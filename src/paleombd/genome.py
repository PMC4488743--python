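"""Synthetic reference genomes with the regulatory structure MBD enrichment sees.

The simulator needs a reference world that reproduces, at desk scale, the
methylation strata of a vertebrate genome: a largely methylated nuclear
background, hypomethylated CpG islands (CGIs), hypermethylated multi-copy
transposable elements (TEs), an unmethylated mitochondrial contig, and
unmethylated microbial background contigs.  Everything downstream
(fragmentation, deamination, capture, diagnostics) is scored against this
ground truth.

Coordinates are 0-based half-open (BED convention).  A CpG site is indexed by
the forward-strand position of its C; the paired G on the reverse strand is
implied, never stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeConfig",
    "MethylationProfile",
    "ReferenceSet",
    "MethylomeTrack",
    "PlacementError",
    "build_reference",
    "assign_methylome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """Raised when annotation intervals cannot be placed without overlap."""


@dataclass(frozen=True)
class GenomeConfig:
    """Sizes and composition of the synthetic reference.

    Defaults give a ~1.5 Mb world: 1 Mb nuclear contig, 16.5 kb mitochondrial
    contig and 0.5 Mb of microbial background, small enough for desk-scale
    simulation while keeping thousands of CpG sites per stratum.
    """

    nuclear_length: int = 1_000_000
    nuclear_gc: float = 0.42
    n_cgi: int = 30
    cgi_length: int = 1_500
    cgi_gc: float = 0.65
    cgi_cpg_rate: float = 0.06  # per-step probability of emitting a CG dimer
    n_te_families: int = 6
    te_copies: int = 4
    te_length: int = 1_200
    te_gc: float = 0.45
    mito_length: int = 16_500
    mito_gc: float = 0.40
    n_microbial: int = 4
    microbial_length: int = 125_000
    microbial_gc: float = 0.50
    max_placement_tries: int = 1_000

    def validate(self) -> None:
        if self.te_copies < 2 and self.n_te_families > 0:
            raise ValueError("TE families need >= 2 copies to be repetitive")
        for name in ("nuclear_gc", "cgi_gc", "te_gc", "mito_gc", "microbial_gc"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.nuclear_length <= 0 or self.mito_length <= 0:
            raise ValueError("contig lengths must be positive")


@dataclass(frozen=True)
class MethylationProfile:
    """Per-stratum CpG methylation probabilities.

    ``background`` applies to nuclear CpGs outside any annotation; vertebrate
    genomes are globally methylated so the default is high.  CGIs are
    hypomethylated, TEs are silenced (hypermethylated), and the mitochondrial
    genome carries no CpG methylation regardless of the value given here.
    """

    background: float = 0.78
    cgi: float = 0.05
    te: float = 0.95
    mito: float = 0.0

    def validate(self) -> None:
        for name in ("background", "cgi", "te", "mito"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"methylation probability {name}={v} outside [0, 1]")


@dataclass
class ReferenceSet:
    """Contigs plus CGI/TE annotations; the simulation's ground truth."""

    contigs: dict[str, str]
    contig_class: dict[str, str]  # nuclear | mito | microbial
    cgi_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    te_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    te_family_count: dict[str, int] = field(default_factory=dict)

    _seq_bytes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _cpg_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    def seq_bytes(self, contig: str) -> np.ndarray:
        arr = self._seq_bytes.get(contig)
        if arr is None:
            arr = np.frombuffer(self.contigs[contig].encode(), dtype=np.uint8)
            self._seq_bytes[contig] = arr
        return arr

    def cpg_positions(self, contig: str) -> np.ndarray:
        """Forward-strand positions of every CG dimer in ``contig``."""
        pos = self._cpg_cache.get(contig)
        if pos is None:
            b = self.seq_bytes(contig)
            pos = np.flatnonzero((b[:-1] == ord("C")) & (b[1:] == ord("G")))
            self._cpg_cache[contig] = pos
        return pos

    def contigs_of_class(self, cls: str) -> list[str]:
        return [n for n, c in self.contig_class.items() if c == cls]

    @property
    def mito_contig(self) -> str:
        (name,) = self.contigs_of_class("mito")
        return name

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if set(self.contigs) != set(self.contig_class):
            raise ValueError("contigs and contig_class disagree")
        if len(self.contigs_of_class("mito")) != 1:
            raise ValueError("exactly one mitochondrial contig required")
        for contig, start, end, *_ in [*self.cgi_intervals, *self.te_intervals]:
            if self.contig_class.get(contig) != "nuclear":
                raise ValueError("CGI/TE annotations must be nuclear")
            if not 0 <= start < end <= len(self.contigs[contig]):
                raise ValueError(f"interval ({contig},{start},{end}) exceeds contig bounds")
        for fam, n in self.te_family_count.items():
            if n < 2:
                raise ValueError(f"TE family {fam} has {n} < 2 copies")


class MethylomeTrack:
    """Methylation probability for every CpG of the nuclear + mito contigs.

    Stored as per-contig sorted position/probability arrays; microbial contigs
    have no entries (their methylation is non-CpG and irrelevant to MBD).
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._data = {
            c: (np.asarray(p, dtype=np.int64), np.asarray(q, dtype=float))
            for c, (p, q) in data.items()
        }
        for c, (p, q) in self._data.items():
            if len(p) != len(q):
                raise ValueError(f"{c}: positions and probabilities differ in length")
            if len(q) and (q.min() < 0 or q.max() > 1):
                raise ValueError("methylation probability outside [0, 1]")

    def contigs(self) -> list[str]:
        return list(self._data)

    def sites(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        return self._data.get(contig, (np.empty(0, dtype=np.int64), np.empty(0)))

    def slice(self, contig: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Sites with ``start <= pos < end`` (position of the C)."""
        pos, prob = self.sites(contig)
        i, j = np.searchsorted(pos, [start, end])
        return pos[i:j], prob[i:j]

    def probability(self, contig: str, position: int) -> float:
        pos, prob = self.sites(contig)
        i = np.searchsorted(pos, position)
        if i == len(pos) or pos[i] != position:
            raise KeyError((contig, position))
        return float(prob[i])

    def __len__(self) -> int:
        return sum(len(p) for p, _ in self._data.values())

    def items(self):
        for c, (pos, prob) in self._data.items():
            for p, q in zip(pos.tolist(), prob.tolist()):
                yield (c, p), q


# ---------------------------------------------------------------------------
# sequence generation


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _cgi_seq(rng: np.random.Generator, length: int, gc: float, cpg_rate: float) -> np.ndarray:
    # Emit CG dimers at an elevated rate so islands are CpG-dense as well as
    # GC-rich, the property that actually matters for MBD (many CpG targets,
    # none of them methylated).
    out = np.empty(length + 1, dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    i = 0
    steps = rng.random(length)
    singles = _BASES[rng.choice(4, size=length, p=p)]
    for k in range(length):
        if i >= length:
            break
        if steps[k] < cpg_rate and i + 1 < length:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            out[i] = singles[k]
            i += 1
    return out[:length]


def _place_intervals(
    rng: np.random.Generator,
    contig_length: int,
    lengths: list[int],
    occupied: list[tuple[int, int]],
    max_tries: int,
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    for L in lengths:
        if L > contig_length:
            raise PlacementError(f"interval of length {L} exceeds contig ({contig_length})")
        for _ in range(max_tries):
            s = int(rng.integers(0, contig_length - L + 1))
            e = s + L
            if all(e <= a or s >= b for a, b in taken):
                placed.append((s, e))
                taken.append((s, e))
                break
        else:
            raise PlacementError(
                f"could not place interval of length {L} after {max_tries} tries"
            )
    return placed


def build_reference(config: GenomeConfig, seed: int) -> ReferenceSet:
    """Generate the synthetic reference world; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)

    contigs: dict[str, str] = {}
    contig_class: dict[str, str] = {}

    nuc = _random_seq(rng, config.nuclear_length, config.nuclear_gc)

    # CGIs first, then TEs, all disjoint so each base has one stratum on disk
    # (methylation precedence is handled separately in assign_methylome).
    cgi_iv = _place_intervals(
        rng, config.nuclear_length, [config.cgi_length] * config.n_cgi, [], config.max_placement_tries
    )
    for s, e in cgi_iv:
        nuc[s:e] = _cgi_seq(rng, e - s, config.cgi_gc, config.cgi_cpg_rate)

    te_intervals: list[tuple[str, int, int, str]] = []
    te_family_count: dict[str, int] = {}
    occupied = list(cgi_iv)
    for fam_idx in range(config.n_te_families):
        fam = f"TE{fam_idx + 1}"
        fam_seq = _random_seq(rng, config.te_length, config.te_gc)
        spots = _place_intervals(
            rng,
            config.nuclear_length,
            [config.te_length] * config.te_copies,
            occupied,
            config.max_placement_tries,
        )
        for s, e in spots:
            nuc[s:e] = fam_seq  # exact duplicates -> reads from them are ambiguous
            te_intervals.append(("chr1", s, e, fam))
        occupied.extend(spots)
        te_family_count[fam] = config.te_copies

    contigs["chr1"] = nuc.tobytes().decode()
    contig_class["chr1"] = "nuclear"

    contigs["chrM"] = _random_seq(rng, config.mito_length, config.mito_gc).tobytes().decode()
    contig_class["chrM"] = "mito"

    for i in range(config.n_microbial):
        name = f"microbe_{i + 1}"
        contigs[name] = (
            _random_seq(rng, config.microbial_length, config.microbial_gc).tobytes().decode()
        )
        contig_class[name] = "microbial"

    return ReferenceSet(
        contigs=contigs,
        contig_class=contig_class,
        cgi_intervals=[("chr1", s, e) for s, e in cgi_iv],
        te_intervals=sorted(te_intervals, key=lambda t: t[1]),
        te_family_count=te_family_count,
    )


def assign_methylome(ref: ReferenceSet, profile: MethylationProfile) -> MethylomeTrack:
    """Assign each CpG the methylation probability of its stratum.

    Precedence on overlap is TE > CGI > background: TE silencing is the
    mechanism behind TE over-representation in the captured fraction, so it
    wins.  Mitochondrial sites are forced to zero regardless of the profile.
    """
    profile.validate()
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, cls in ref.contig_class.items():
        if cls == "microbial":
            continue
        pos = ref.cpg_positions(contig)
        if cls == "mito":
            data[contig] = (pos, np.zeros(len(pos)))
            continue
        prob = np.full(len(pos), profile.background)
        for c, s, e in ref.cgi_intervals:
            if c == contig:
                prob[(pos >= s) & (pos < e)] = profile.cgi
        for c, s, e, _fam in ref.te_intervals:
            if c == contig:
                prob[(pos >= s) & (pos < e)] = profile.te
        data[contig] = (pos, prob)
    return MethylomeTrack(data)


def scan_cpg(sequence: str) -> list[int]:
    """Regex-based CG scan; used as an independent oracle in tests."""
    return [m.start() for m in re.finditer("CG", sequence)]
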