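"""Descriptive methylome statistics: window densities, feature meta-profiles,
CpG observed/expected ratios, and correlation analyses.

All level summaries are coverage-weighted (pooled counts, sum m / sum t),
computed per sequence context and per stage group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel, GenomicInterval
from .methcore import MethylomeMatrix

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class FeatureProfile:
    """Binned pooled methylation over one feature class.

    ``values`` has one row per bin and a (group, context) MultiIndex on
    columns; entries are pooled levels (NaN where a bin has no coverage).
    Bin 0 is always the 5'/upstream end for strand-aware classes.
    """

    feature_class: str
    values: pd.DataFrame
    n_features: int
    n_short: int = 0


@dataclass
class ChromSummary:
    """Per-chromosome covariates for the methylation-vs-feature correlations."""

    chrom: str
    length: int
    mean_level: float
    cpg_count: int
    cpg_oe: float
    gene_count: int
    repeat_count: int


# ---------------------------------------------------------------------------
# Window densities
# ---------------------------------------------------------------------------

def window_density(matrix: MethylomeMatrix, window: int = 300_000
                   ) -> pd.DataFrame:
    """Pooled methylation level in non-overlapping tiling windows.

    Returns a tidy frame (chrom, start, end, group, context, meth_sum,
    total_sum, level); windows with no covered sites for a combination are
    absent.  Window boundaries are [k*window, (k+1)*window) per chromosome.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    groups = sorted(set(matrix.groups.values()))
    rows = []
    for chrom, sub in _iter_chroms(matrix):
        pos = sub.sites["pos"].to_numpy()
        widx = pos // window
        n_win = int(widx.max()) + 1 if len(widx) else 0
        ctx = sub.sites["context"].to_numpy()
        for g in groups:
            mg, tg = sub.group_pooled(g)
            for c in CONTEXTS:
                cmask = ctx == c
                if not cmask.any():
                    continue
                msum = np.bincount(widx[cmask], weights=mg[cmask],
                                   minlength=n_win)
                tsum = np.bincount(widx[cmask], weights=tg[cmask],
                                   minlength=n_win)
                for k in np.flatnonzero(tsum > 0):
                    rows.append((chrom, int(k) * window,
                                 (int(k) + 1) * window, g, c,
                                 int(msum[k]), int(tsum[k]),
                                 msum[k] / tsum[k]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "group",
                                       "context", "meth_sum", "total_sum",
                                       "level"])


def _iter_chroms(matrix: MethylomeMatrix):
    for chrom in matrix.sites["chrom"].unique():
        yield chrom, matrix.for_chrom(chrom)


# ---------------------------------------------------------------------------
# Feature meta-profiles
# ---------------------------------------------------------------------------

def _accumulate(meth_acc, tot_acc, bins, ctx_code, meth_g, tot_g):
    np.add.at(meth_acc, (bins, ctx_code), meth_g)
    np.add.at(tot_acc, (bins, ctx_code), tot_g)


def metaprofile(matrix: MethylomeMatrix,
                genes: Sequence[GeneModel],
                cgis: Sequence[GenomicInterval],
                n_bins: int = 50,
                flank: int = 2000,
                flank_bin: int = 100,
                promoter_length: int = 2000,
                ) -> dict[str, FeatureProfile]:
    """Pooled methylation meta-profiles over genomic feature classes.

    Gene-linked classes (promoter, exon, intron, gene_body_flank) are
    oriented so bin 0 is 5'/upstream; minus-strand genes are flipped.
    Bodies, exons, introns and CpG islands are length-scaled to ``n_bins``;
    promoters, flanks and island shores use fixed ``flank_bin``-bp bins
    (shore bin 0 abuts the island).  ``gene_body_flank`` concatenates
    upstream flank, scaled body and downstream flank.  Genes shorter than
    ``n_bins`` bp are kept (fractional binning) and counted in ``n_short``.
    """
    groups = sorted(set(matrix.groups.values()))
    ctx_of = {c: i for i, c in enumerate(CONTEXTS)}

    n_pbins = promoter_length // flank_bin
    n_fbins = flank // flank_bin
    sizes = {"promoter": n_pbins, "exon": n_bins, "intron": n_bins,
             "CGI": n_bins, "CGI_shore": n_fbins,
             "gene_body_flank": 2 * n_fbins + n_bins}
    acc = {cls: {g: (np.zeros((nb, len(CONTEXTS))),
                     np.zeros((nb, len(CONTEXTS))))
                 for g in groups}
           for cls, nb in sizes.items()}
    counts = {cls: 0 for cls in sizes}
    n_short = 0

    # pooled per-group counts, chromosome by chromosome
    for chrom, sub in _iter_chroms(matrix):
        pos = sub.sites["pos"].to_numpy()
        ctx_code = sub.sites["context"].map(ctx_of).to_numpy()
        pooled = {g: sub.group_pooled(g) for g in groups}
        chrom_genes = [g for g in genes if g.chrom == chrom]
        chrom_cgis = [c for c in cgis if c.chrom == chrom]

        in_island = _interval_mask(pos, [(c.start, c.end) for c in chrom_cgis])

        def add(cls, lo, hi, bin_fn, extra_mask=None):
            i0, i1 = np.searchsorted(pos, [lo, hi])
            if i0 == i1:
                return
            sl = slice(i0, i1)
            idx = np.arange(i0, i1)
            if extra_mask is not None:
                idx = idx[extra_mask[sl]]
                if len(idx) == 0:
                    return
            bins = bin_fn(pos[idx])
            ok = (bins >= 0) & (bins < sizes[cls])
            idx, bins = idx[ok], bins[ok]
            for g in groups:
                mg, tg = pooled[g]
                _accumulate(*acc[cls][g], bins, ctx_code[idx],
                            mg[idx], tg[idx])

        for gene in chrom_genes:
            counts["promoter"] += 1
            counts["gene_body_flank"] += 1
            glen = gene.end - gene.start
            if glen < n_bins:
                n_short += 1
            if gene.strand == "+":
                ps, pe = gene.start - promoter_length, gene.start
                add("promoter", max(0, ps), pe,
                    lambda p, ps=ps: (p - ps) // flank_bin)
                add("gene_body_flank", max(0, gene.start - flank), gene.end + flank,
                    lambda p, g=gene: _body_flank_bins(
                        p, g.start, g.end, False, n_bins, n_fbins, flank_bin,
                        flank))
            else:
                ps, pe = gene.end, gene.end + promoter_length
                add("promoter", ps, pe,
                    lambda p, pe=pe: (pe - 1 - p) // flank_bin)
                add("gene_body_flank", max(0, gene.start - flank), gene.end + flank,
                    lambda p, g=gene: _body_flank_bins(
                        p, g.start, g.end, True, n_bins, n_fbins, flank_bin,
                        flank))
            for s, e in gene.exons:
                counts["exon"] += 1
                if gene.strand == "+":
                    add("exon", s, e,
                        lambda p, s=s, e=e: (p - s) * n_bins // (e - s))
                else:
                    add("exon", s, e,
                        lambda p, s=s, e=e: n_bins - 1 -
                        (p - s) * n_bins // (e - s))
            for s, e in gene.introns():
                counts["intron"] += 1
                if gene.strand == "+":
                    add("intron", s, e,
                        lambda p, s=s, e=e: (p - s) * n_bins // (e - s))
                else:
                    add("intron", s, e,
                        lambda p, s=s, e=e: n_bins - 1 -
                        (p - s) * n_bins // (e - s))

        for cgi in chrom_cgis:
            counts["CGI"] += 1
            add("CGI", cgi.start, cgi.end,
                lambda p, c=cgi: (p - c.start) * n_bins // (c.end - c.start))
            counts["CGI_shore"] += 1
            not_island = ~in_island
            add("CGI_shore", max(0, cgi.start - flank), cgi.start,
                lambda p, c=cgi: (c.start - 1 - p) // flank_bin,
                extra_mask=not_island)
            add("CGI_shore", cgi.end, cgi.end + flank,
                lambda p, c=cgi: (p - c.end) // flank_bin,
                extra_mask=not_island)

    out = {}
    for cls, nb in sizes.items():
        cols = {}
        for g in groups:
            m, t = acc[cls][g]
            with np.errstate(divide="ignore", invalid="ignore"):
                lv = np.where(t > 0, m / np.where(t > 0, t, 1), np.nan)
            for ci, c in enumerate(CONTEXTS):
                cols[(g, c)] = lv[:, ci]
        values = pd.DataFrame(cols)
        values.columns = pd.MultiIndex.from_tuples(values.columns,
                                                   names=["group", "context"])
        out[cls] = FeatureProfile(cls, values, counts[cls],
                                  n_short if cls == "gene_body_flank" else 0)
    return out


def _body_flank_bins(p, start, end, minus, n_bins, n_fbins, flank_bin, flank):
    """Bin index in the flank+body+flank layout, 5'->3'."""
    bins = np.empty(len(p), dtype=np.int64)
    up = p < start
    dn = p >= end
    body = ~up & ~dn
    bins[body] = n_fbins + (p[body] - start) * n_bins // (end - start)
    bins[up] = -((start - p[up] - 1) // flank_bin) + n_fbins - 1
    bins[dn] = n_fbins + n_bins + (p[dn] - end) // flank_bin
    if minus:
        total = 2 * n_fbins + n_bins
        bins = total - 1 - bins
    return bins


def _interval_mask(pos: np.ndarray,
                   intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for s, e in intervals:
        i0, i1 = np.searchsorted(pos, [s, e])
        mask[i0:i1] = True
    return mask


# ---------------------------------------------------------------------------
# CpG observed/expected
# ---------------------------------------------------------------------------

def cpg_oe(seq: str) -> float:
    """CpG observed/expected ratio, (N_CG * L) / (N_C * N_G).

    Returns 0 when the sequence lacks C or G (no CpG is then possible).
    """
    if len(seq) < 2:
        raise ValueError("sequence too short for dinucleotide counting")
    seq = seq.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = seq.count("CG")
    return n_cg * len(seq) / (n_c * n_g)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def summarize_chromosomes(matrix: MethylomeMatrix,
                          seqs: Mapping[str, str],
                          genes: Sequence[GeneModel],
                          repeats: Sequence[GenomicInterval],
                          context: str = "CG",
                          group: str | None = None,
                          ) -> list[ChromSummary]:
    """One ChromSummary per chromosome present in ``seqs``.

    ``mean_level`` is the pooled level of ``context`` sites over all samples
    (or one group's samples when ``group`` is given).
    """
    sub = matrix.for_context(context)
    out = []
    for chrom, seq in seqs.items():
        csub = sub.for_chrom(chrom)
        if group is None:
            m, t = csub.meth.sum(), csub.total.sum()
        else:
            mg, tg = csub.group_pooled(group)
            m, t = mg.sum(), tg.sum()
        level = m / t if t > 0 else float("nan")
        out.append(ChromSummary(
            chrom=chrom, length=len(seq), mean_level=float(level),
            cpg_count=seq.count("CG"), cpg_oe=cpg_oe(seq),
            gene_count=sum(g.chrom == chrom for g in genes),
            repeat_count=sum(r.chrom == chrom for r in repeats)))
    return out


def chrom_feature_correlations(summaries: Sequence[ChromSummary]
                               ) -> pd.DataFrame:
    """Pearson r (and p) of per-chromosome mean level vs genomic covariates.

    Zero-variance covariates give NaN sentinels.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 chromosomes for correlation")
    y = np.array([s.mean_level for s in summaries], float)
    rows = []
    for name in ("length", "cpg_count", "cpg_oe", "gene_count",
                 "repeat_count"):
        x = np.array([getattr(s, name) for s in summaries], float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((name, float("nan"), float("nan")))
        else:
            r, p = stats.pearsonr(x, y)
            rows.append((name, float(r), float(p)))
    return pd.DataFrame(rows, columns=["feature", "r", "p"]
                        ).set_index("feature")


def sample_correlation(matrix: MethylomeMatrix,
                       context: str = "CG",
                       min_total: int = 4) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-site levels between samples.

    For each pair only sites covered >= ``min_total`` in both samples enter;
    the matrix is symmetric with a unit diagonal, NaN where a pair shares no
    qualifying sites.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples")
    sub = matrix.for_context(context)
    lv = sub.levels(min_total=min_total)
    n = len(sub.samples)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            ok = ~np.isnan(lv[:, i]) & ~np.isnan(lv[:, j])
            if ok.sum() >= 2 and lv[ok, i].std() > 0 and lv[ok, j].std() > 0:
                r, _ = stats.pearsonr(lv[ok, i], lv[ok, j])
                out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=sub.samples, columns=sub.samples)
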