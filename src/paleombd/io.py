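"""Readers and writers for the standard formats the pipeline exchanges.

FASTA/FASTQ go through Biopython, SAM through pysam; BED, bedGraph and the
tab-separated truth tables are plain text.  Every reader round-trips its
writer.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .capture import ReadRecord
from .damage import Fragment
from .genome import MethylomeTrack, ReferenceSet

__all__ = [
    "write_reference",
    "read_reference",
    "write_fastq",
    "write_sam",
    "read_sam",
    "fragments_to_tsv",
    "fragments_from_tsv",
]


# ---------------------------------------------------------------------------
# reference world


def write_reference(ref: ReferenceSet, methylome: MethylomeTrack | None, out_dir) -> dict[str, Path]:
    """Emit FASTA + CGI/TE BED + bedGraph methylome; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "reference.fasta",
        "cgi_bed": out_dir / "cgi.bed",
        "te_bed": out_dir / "te.bed",
        "methylome": out_dir / "methylome.bedgraph",
    }
    records = [
        SeqRecord(Seq(seq), id=name, description=f"class={ref.contig_class[name]}")
        for name, seq in ref.contigs.items()
    ]
    SeqIO.write(records, paths["fasta"], "fasta")  # wraps at 60 columns

    with open(paths["cgi_bed"], "w") as fh:
        for contig, s, e in ref.cgi_intervals:
            fh.write(f"{contig}\t{s}\t{e}\n")
    with open(paths["te_bed"], "w") as fh:
        for contig, s, e, fam in ref.te_intervals:
            fh.write(f"{contig}\t{s}\t{e}\t{fam}\n")

    with open(paths["methylome"], "w") as fh:
        if methylome is not None:
            for contig in methylome.contigs():
                pos, prob = methylome.sites(contig)
                for p, q in zip(pos.tolist(), prob.tolist()):
                    fh.write(f"{contig}\t{p}\t{p + 1}\t{q:g}\n")
    return paths


def read_reference(in_dir) -> tuple[ReferenceSet, MethylomeTrack]:
    in_dir = Path(in_dir)
    contigs: dict[str, str] = {}
    contig_class: dict[str, str] = {}
    for rec in SeqIO.parse(in_dir / "reference.fasta", "fasta"):
        contigs[rec.id] = str(rec.seq)
        cls = "nuclear"
        for tok in rec.description.split():
            if tok.startswith("class="):
                cls = tok.split("=", 1)[1]
        contig_class[rec.id] = cls

    cgi = []
    p = in_dir / "cgi.bed"
    if p.exists():
        for line in p.read_text().splitlines():
            c, s, e = line.split("\t")[:3]
            cgi.append((c, int(s), int(e)))
    te = []
    fam_count: dict[str, int] = {}
    p = in_dir / "te.bed"
    if p.exists():
        for line in p.read_text().splitlines():
            c, s, e, fam = line.split("\t")[:4]
            te.append((c, int(s), int(e), fam))
            fam_count[fam] = fam_count.get(fam, 0) + 1

    ref = ReferenceSet(
        contigs=contigs,
        contig_class=contig_class,
        cgi_intervals=cgi,
        te_intervals=te,
        te_family_count=fam_count,
    )

    data: dict[str, tuple[list[int], list[float]]] = {}
    p = in_dir / "methylome.bedgraph"
    if p.exists():
        for line in p.read_text().splitlines():
            c, s, _e, q = line.split("\t")
            data.setdefault(c, ([], []))[0].append(int(s))
            data[c][1].append(float(q))
    track = MethylomeTrack({c: (ps, qs) for c, (ps, qs) in data.items()})
    return ref, track


# ---------------------------------------------------------------------------
# reads


def write_fastq(reads: list[ReadRecord], path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.read_id,
            description="",
            letter_annotations={"phred_quality": [40] * len(r.sequence)},
        )
        for r in reads
    ]
    SeqIO.write(records, path, "fastq")


def _sam_header(ref: ReferenceSet) -> dict:
    names = list(ref.contigs)
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(ref.contigs[n])} for n in names],
    }


def write_sam(reads: list[ReadRecord], ref: ReferenceSet, path) -> None:
    """Minimal SAM with true placements.

    MAPQ encodes the placement-quality dichotomy (0 for repetitive origin, 60
    otherwise); duplicates carry flag 0x400; tags: XI fragment id, XO origin
    class, XF fraction.
    """
    header = pysam.AlignmentHeader.from_dict(_sam_header(ref))
    tid = {n: i for i, n in enumerate(ref.contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 0x400 if r.is_duplicate else 0
            a.reference_id = tid[r.contig]
            a.reference_start = r.start
            a.mapping_quality = 0 if r.mq_class == "MQ0_only" else 60
            a.cigarstring = f"{len(r.sequence)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
            a.set_tag("XI", r.fragment_id)
            a.set_tag("XO", r.origin_class)
            a.set_tag("XF", r.fraction)
            fh.write(a)


def read_sam(path) -> list[ReadRecord]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            origin = a.get_tag("XO")
            reads.append(
                ReadRecord(
                    read_id=a.query_name,
                    fragment_id=int(a.get_tag("XI")),
                    contig=a.reference_name,
                    start=a.reference_start,
                    end=a.reference_start + len(a.query_sequence),
                    sequence=a.query_sequence,
                    origin_class=origin,
                    is_duplicate=bool(a.flag & 0x400),
                    mq_class="MQ0_only" if a.mapping_quality == 0 else "MQ25",
                    fraction=a.get_tag("XF"),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# fragment truth tables


def fragments_to_tsv(fragments: list[Fragment], path) -> None:
    rows = []
    for i, f in enumerate(fragments):
        meth = ";".join(
            f"{p}:{int(m)}" for p, m in sorted((f.meth_states or {}).items())
        )
        deam = ";".join(f"{o}{s}" for o, s in sorted(f.deam_events))
        rows.append(
            {
                "fragment_id": i,
                "contig": f.contig,
                "start": f.start,
                "end": f.end,
                "overhang5": f.overhang5 if f.overhang5 is not None else -1,
                "overhang3": f.overhang3 if f.overhang3 is not None else -1,
                "origin_class": f.origin_class,
                "meth_states": meth,
                "deam_events": deam,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "fragment_id",
            "contig",
            "start",
            "end",
            "overhang5",
            "overhang3",
            "origin_class",
            "meth_states",
            "deam_events",
        ],
    ).to_csv(path, sep="\t", index=False)


def fragments_from_tsv(path) -> list[Fragment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    fragments = []
    for row in df.itertuples(index=False):
        meth: dict[int, bool] | None = None
        if row.meth_states != "":
            meth = {}
            for tok in str(row.meth_states).split(";"):
                p, m = tok.split(":")
                meth[int(p)] = bool(int(m))
        elif row.overhang5 != -1:
            meth = {}
        deam = set()
        if row.deam_events != "":
            for tok in str(row.deam_events).split(";"):
                deam.add((int(tok[:-1]), tok[-1]))
        fragments.append(
            Fragment(
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                origin_class=row.origin_class,
                overhang5=None if row.overhang5 == -1 else int(row.overhang5),
                overhang3=None if row.overhang3 == -1 else int(row.overhang3),
                meth_states=meth,
                deam_events=deam,
            )
        )
    return fragments
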