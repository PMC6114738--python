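"""Methylome-transcriptome integration.

DMRs are annotated against gene models (a gene is hit when a DMR overlaps
its promoter or span by at least one base; feature precedence within a gene
is promoter > exon > intron), aggregated into hyper-/hypo-methylated gene
(DMG) sets, and intersected with differentially expressed genes (DEGs)
filtered from an external expression results table at Q <= 0.05 and
|log2 fold change| > 1.  Sign conventions line up: positive log_fc and
"hyper" both mean telogen-higher.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .dmrcall import Dmr
from .io_formats import GeneModel, GenomicInterval, cgi_shores
from .methcore import ANAGEN, TELOGEN, MethylomeMatrix


@dataclass
class DmrAnnotation:
    """Gene and CpG-island context of one DMR."""

    dmr: Dmr
    gene_hits: list[tuple[str, str]]   # (gene_id, feature class)
    in_cgi: bool
    in_shore: bool

    @property
    def intergenic(self) -> bool:
        return not self.gene_hits


@dataclass
class DmgRecord:
    """One differentially methylated gene with its supporting DMRs."""

    gene_id: str
    directions: set[str] = field(default_factory=set)
    dmr_ids: list[int] = field(default_factory=list)
    feature_hits: list[str] = field(default_factory=list)

    @property
    def ambivalent(self) -> bool:
        return len(self.directions) == 2


class GeneIndex:
    """Interval indices over gene promoters/spans/exons and CGIs/shores."""

    def __init__(self, genes: Sequence[GeneModel],
                 cgis: Sequence[GenomicInterval],
                 promoter_length: int = 2000,
                 include_promoter: bool = True):
        self.genes = {g.gene_id: g for g in genes}
        self.promoter_length = promoter_length
        self.include_promoter = include_promoter
        self._gene_trees: dict[str, IntervalTree] = {}
        self._cgi_trees: dict[str, IntervalTree] = {}
        self._shore_trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._gene_trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end, g.gene_id)
            if include_promoter:
                p = g.promoter(promoter_length)
                tree.addi(p.start, p.end, g.gene_id)
        for c in cgis:
            self._cgi_trees.setdefault(c.chrom, IntervalTree()
                                       ).addi(c.start, c.end, c.label)
        for s in cgi_shores(cgis, width=2000):
            self._shore_trees.setdefault(s.chrom, IntervalTree()
                                         ).addi(s.start, s.end, s.label)

    def gene_ids_overlapping(self, chrom: str, start: int, end: int
                             ) -> set[str]:
        tree = self._gene_trees.get(chrom)
        return {iv.data for iv in tree.overlap(start, end)} if tree else set()

    def overlaps(self, trees, chrom, start, end) -> bool:
        tree = trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree else False


def _feature_class(dmr: Dmr, gene: GeneModel, index: GeneIndex) -> str | None:
    """Highest-precedence feature of ``gene`` the DMR overlaps."""
    hits = []
    if index.include_promoter:
        p = gene.promoter(index.promoter_length)
        if p.start < dmr.end and dmr.start < p.end:
            hits.append("promoter")
    for s, e in gene.exons:
        if s < dmr.end and dmr.start < e:
            hits.append("exon")
            break
    for s, e in gene.introns():
        if s < dmr.end and dmr.start < e:
            hits.append("intron")
            break
    if not hits and gene.start < dmr.end and dmr.start < gene.end:
        # overlap with the span but neither exon nor derived intron
        # (single-exon genes have no introns): class by exon/intron absence
        hits.append("exon" if not gene.exons else "intron")
    for cls in ("promoter", "exon", "intron"):
        if cls in hits:
            return cls
    return None


def annotate_dmr(dmr: Dmr, index: GeneIndex) -> DmrAnnotation:
    """Annotate one DMR against prebuilt gene/CGI indices."""
    gene_hits = []
    for gid in sorted(index.gene_ids_overlapping(dmr.chrom, dmr.start,
                                                 dmr.end)):
        cls = _feature_class(dmr, index.genes[gid], index)
        if cls is not None:
            gene_hits.append((gid, cls))
    return DmrAnnotation(
        dmr=dmr,
        gene_hits=gene_hits,
        in_cgi=index.overlaps(index._cgi_trees, dmr.chrom, dmr.start,
                              dmr.end),
        in_shore=index.overlaps(index._shore_trees, dmr.chrom, dmr.start,
                                dmr.end))


def annotate_dmrs(dmrs: Sequence[Dmr],
                  genes: Sequence[GeneModel],
                  cgis: Sequence[GenomicInterval],
                  promoter_length: int = 2000,
                  include_promoter: bool = True) -> list[DmrAnnotation]:
    index = GeneIndex(genes, cgis, promoter_length, include_promoter)
    return [annotate_dmr(d, index) for d in dmrs]


def build_dmg_sets(annotations: Sequence[DmrAnnotation]
                   ) -> tuple[set[str], set[str], dict[str, DmgRecord]]:
    """Hyper and hypo DMG sets (a gene may be in both → ambivalent)."""
    records: dict[str, DmgRecord] = {}
    for i, ann in enumerate(annotations):
        for gid, cls in ann.gene_hits:
            rec = records.setdefault(gid, DmgRecord(gid))
            rec.directions.add(ann.dmr.direction)
            rec.dmr_ids.append(i)
            rec.feature_hits.append(cls)
    hyper = {g for g, r in records.items() if "hyper" in r.directions}
    hypo = {g for g, r in records.items() if "hypo" in r.directions}
    return hyper, hypo, records


def filter_degs(table: pd.DataFrame,
                max_q: float = 0.05,
                min_abs_lfc: float = 1.0
                ) -> tuple[list[str], list[str], int]:
    """DEG filter: kept iff q <= max_q and |log_fc| > min_abs_lfc.

    Returns (up-regulated ids, down-regulated ids, n records skipped for a
    missing q).  The q boundary is inclusive, the fold-change boundary
    strict.
    """
    missing = table["q_value"].isna()
    n_skipped = int(missing.sum())
    t = table[~missing]
    kept = t[(t["q_value"] <= max_q) & (t["log_fc"].abs() > min_abs_lfc)]
    up = kept.loc[kept["log_fc"] > 0, "gene_id"].tolist()
    down = kept.loc[kept["log_fc"] < 0, "gene_id"].tolist()
    return up, down, n_skipped


def overlap_dmg_deg(dmg_records: dict[str, DmgRecord],
                    deg_up: Sequence[str],
                    deg_down: Sequence[str]) -> pd.DataFrame:
    """Genes both differentially methylated and differentially expressed.

    One row per overlap gene with its methylation direction(s) and
    expression sign, for concordance reporting.
    """
    expr = {g: "up" for g in deg_up}
    expr.update({g: "down" for g in deg_down})
    rows = []
    for gid in sorted(set(dmg_records) & set(expr)):
        rec = dmg_records[gid]
        rows.append((gid, "/".join(sorted(rec.directions)), expr[gid],
                     len(rec.dmr_ids)))
    return pd.DataFrame(rows, columns=["gene_id", "meth_direction",
                                       "expr_sign", "n_dmrs"])


def gene_meth_profile(gene: GeneModel, matrix: MethylomeMatrix,
                      flank: int = 2000) -> pd.DataFrame:
    """Per-position pooled group levels across a gene +- ``flank``.

    Genomic (browser-view) orientation, restricted to covered sites; an
    empty frame means the gene has no covered sites.
    """
    lo = max(0, gene.start - flank)
    hi = gene.end + flank
    mask = ((matrix.sites["chrom"] == gene.chrom)
            & (matrix.sites["pos"] >= lo)
            & (matrix.sites["pos"] < hi)).to_numpy()
    sub = matrix.subset(mask)
    ma, ta = sub.group_pooled(ANAGEN)
    mt, tt = sub.group_pooled(TELOGEN)
    covered = (ta > 0) | (tt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return pd.DataFrame({
            "pos": sub.sites["pos"].to_numpy()[covered],
            "anagen": np.where(ta > 0, ma / np.where(ta > 0, ta, 1),
                               np.nan)[covered],
            "telogen": np.where(tt > 0, mt / np.where(tt > 0, tt, 1),
                                np.nan)[covered],
        })
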