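"""Readers and writers for the pipeline's external formats, plus read-level QC.

External formats handled here:

* FASTA (reference genome) and FASTQ (raw reads), via Biopython;
* tab-delimited per-cytosine site tables (one per sample);
* BED intervals (CpG islands, repeats) and GTF gene models.

Coordinate conventions: everything in memory is 0-based, half-open.  Site
tables store 1-based positions (matching common methylation-extractor
dialects), GTF is 1-based inclusive, BED is 0-based half-open; the readers
and writers perform the shifts so the rest of the package never has to.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class MalformedReadError(ValueError):
    """A sequencing read whose base and quality strings disagree."""


class SiteTableError(ValueError):
    """A per-site methylation table that violates its own invariants."""


class GeneModelError(ValueError):
    """A gene model whose exons fall outside the gene span."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequencingRead:
    """One read: id, bases over {A,C,G,T,N}, and per-base PHRED scores."""

    id: str
    bases: str
    quals: Sequence[int]

    def validate(self) -> None:
        if len(self.bases) != len(self.quals):
            raise MalformedReadError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 for q in self.quals):
            raise MalformedReadError(f"read {self.id!r}: negative PHRED score")


@dataclass
class ReadQcReport:
    """Per-rule removal counts and base-composition stats of the survivors.

    ``q20``/``q30`` are the fractions of surviving bases with PHRED >= 20/30;
    ``gc`` is the G+C fraction among surviving non-N bases.
    """

    n_input: int
    n_adapter_removed: int
    n_n_removed: int
    n_lowqual_removed: int
    q20: float
    q30: float
    gc: float

    @property
    def n_clean(self) -> int:
        return (self.n_input - self.n_adapter_removed - self.n_n_removed
                - self.n_lowqual_removed)

    def as_keyvalue(self) -> str:
        keys = ("n_input", "n_adapter_removed", "n_n_removed",
                "n_lowqual_removed", "q20", "q30", "gc")
        lines = [f"{k}={getattr(self, k)}" for k in keys]
        lines.append(f"n_clean={self.n_clean}")
        return "\n".join(lines)


@dataclass(frozen=True)
class GenomicInterval:
    """A BED-style interval: 0-based half-open, optional strand and label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class GeneModel:
    """Strand-aware gene structure; promoter and introns are derived.

    ``span`` and ``exons`` are 0-based half-open.  The TSS is ``start`` on
    the plus strand and ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise GeneModelError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside span "
                    f"[{self.start},{self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive sorted exons."""
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out

    def promoter(self, length: int = 2000) -> GenomicInterval:
        """The ``length`` bp immediately upstream of the TSS (strand-aware)."""
        if self.strand == "+":
            s = max(0, self.start - length)
            return GenomicInterval(self.chrom, s, max(s + 1, self.start),
                                   self.strand, f"{self.gene_id}_promoter")
        return GenomicInterval(self.chrom, self.end, self.end + length,
                               self.strand, f"{self.gene_id}_promoter")


# ---------------------------------------------------------------------------
# Read-level QC
# ---------------------------------------------------------------------------

def filter_reads(reads: Iterable[SequencingRead],
                 adapter: str,
                 max_n_frac: float = 0.10,
                 lowqual_phred: int = 5,
                 lowqual_frac: float = 0.50,
                 ) -> tuple[list[SequencingRead], ReadQcReport]:
    """Apply the three whole-read removal rules and summarize the survivors.

    Rules, in order: (1) reads containing the 3' adapter sequence are
    removed; (2) reads whose N fraction exceeds ``max_n_frac`` are removed;
    (3) reads where >= ``lowqual_frac`` of bases have PHRED <= ``lowqual_phred``
    are removed.  Removal is whole-read; survivors are untouched.  Q20, Q30
    and GC content are computed over the surviving bases only.
    """
    if not 0 <= max_n_frac <= 1 or not 0 <= lowqual_frac <= 1:
        raise ValueError("fraction thresholds must be in [0, 1]")

    survivors: list[SequencingRead] = []
    n_input = n_adapter = n_ncut = n_lowq = 0
    for read in reads:
        read.validate()
        n_input += 1
        if adapter and adapter in read.bases:
            n_adapter += 1
            continue
        n = len(read.bases)
        if n and read.bases.count("N") / n > max_n_frac:
            n_ncut += 1
            continue
        if n and sum(q <= lowqual_phred for q in read.quals) / n >= lowqual_frac:
            n_lowq += 1
            continue
        survivors.append(read)

    n_bases = sum(len(r.bases) for r in survivors)
    if n_bases:
        q20 = sum(q >= 20 for r in survivors for q in r.quals) / n_bases
        q30 = sum(q >= 30 for r in survivors for q in r.quals) / n_bases
        acgt = sum(len(r.bases) - r.bases.count("N") for r in survivors)
        gc_n = sum(r.bases.count("G") + r.bases.count("C") for r in survivors)
        gc = gc_n / acgt if acgt else 0.0
    else:
        q20 = q30 = gc = 0.0
    report = ReadQcReport(n_input, n_adapter, n_ncut, n_lowq, q20, q30, gc)
    return survivors, report


def mark_duplicates(alignments: Sequence[tuple[str, int, str]]) -> list[int]:
    """Indices of reads to keep: one per (chrom, start, strand) key.

    Reads mapping to the same position on the same strand are treated as
    PCR/optical duplicates; the first-encountered read of each key is kept.
    """
    seen: set[tuple[str, int, str]] = set()
    kept = []
    for i, key in enumerate(alignments):
        k = (key[0], key[1], key[2])
        if k not in seen:
            seen.add(k)
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# Per-site methylation tables
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read one sample's per-cytosine table.

    File columns (tab-delimited, with header): chrom, pos (1-based), strand,
    context, meth_count, total_count.  The returned frame uses 0-based
    positions.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str,
                                            "context": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise SiteTableError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["meth_count"] > df["total_count"]]
    if len(bad):
        # +2: header line plus 1-based line numbering
        raise SiteTableError(
            f"{path}: meth_count > total_count at line {bad[0] + 2}")
    if (df["total_count"] < 0).any() or (df["meth_count"] < 0).any():
        raise SiteTableError(f"{path}: negative counts")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    return df[SITE_COLUMNS]


def write_site_table(df: pd.DataFrame, path: str | Path) -> None:
    """Exact inverse of :func:`read_site_table` (positions back to 1-based)."""
    out = df[SITE_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, label: str | None = None
                   ) -> list[GenomicInterval]:
    """Read a BED file (3+ columns) into 0-based half-open intervals.

    ``label`` overrides the name column when given (e.g. tagging a whole
    file of repeats as "repeat").
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = label if label is not None else (f[3] if len(f) > 3 else "")
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]),
                                       strand, name))
    return out


def write_intervals(intervals: Iterable[GenomicInterval],
                    path: str | Path) -> None:
    """Write intervals as BED6 (name=label, score=0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t"
                     f"{iv.strand}\n")


def cgi_shores(cgis: Sequence[GenomicInterval], width: int = 2000
               ) -> list[GenomicInterval]:
    """The ``width`` bp flanking each CpG island, minus any island overlap.

    Shores on both sides of every island are computed, then any part that
    falls inside another island is cut away; abutting shore fragments are
    not merged across islands.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in cgis:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    shores = []
    for cgi in cgis:
        islands = by_chrom[cgi.chrom]
        for s, e in ((max(0, cgi.start - width), cgi.start),
                     (cgi.end, cgi.end + width)):
            segs = [(s, e)] if s < e else []
            for is_, ie in islands:
                segs = [piece
                        for a, b in segs
                        for piece in ((a, min(b, is_)), (max(a, ie), b))
                        if piece[0] < piece[1]]
            for a, b in segs:
                shores.append(GenomicInterval(cgi.chrom, a, b, ".",
                                              "CGI_shore"))
    return shores


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def _parse_gtf_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip('"')
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene and exon features from a GTF file (1-based inclusive)."""
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand = f[:7]
            gid = _parse_gtf_attrs(f[8])["gene_id"]
            s, e = int(start) - 1, int(end)
            if feature == "gene":
                genes[gid] = GeneModel(gid, chrom, strand, s, e, [])
                order.append(gid)
            elif feature == "exon":
                exons.setdefault(gid, []).append((s, e))
    out = []
    for gid in order:
        g = genes[gid]
        g.exons = sorted(exons.get(gid, []))
        for s, e in g.exons:
            if s < g.start or e > g.end:
                raise GeneModelError(
                    f"gene {gid}: exon [{s},{e}) outside span "
                    f"[{g.start},{g.end})")
        out.append(g)
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path,
                      source: str = "hairmeth") -> None:
    """Write gene models as GTF; exact inverse of :func:`read_gene_models`."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ / expression tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[SequencingRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(SequencingRead(rec.id, str(rec.seq).upper(),
                                  rec.letter_annotations["phred_quality"]))
    return out


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression results: TSV with columns gene_id, log_fc, q_value."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log_fc", "q_value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "log_fc", "q_value"]].to_csv(path, sep="\t", index=False)


def bisulfite_convert(seq: str) -> tuple[str, str]:
    """C->T and G->A converted versions of a sequence, for three-letter
    alignment indexes."""
    return seq.replace("C", "T"), seq.replace("G", "A")
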