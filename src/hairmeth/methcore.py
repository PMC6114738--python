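"""Per-site methylation layer: context classification, methylated-cytosine
calling, bisulfite conversion-rate estimation, and level computation.

Bisulfite sequencing converts unmethylated cytosines to thymine; a read
supporting "methylated" at a site is a retained C.  The per-site unit is a
strand-resolved cytosine with a sequence context (CG, CHG or CHH, read
3'-ward on the cytosine's own strand, H in {A, C, T}).  An unmethylated
lambda-phage spike-in measures the conversion failure rate, which in turn
parameterizes the binomial test used to call a site methylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ANAGEN = "anagen"
TELOGEN = "telogen"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class NotACytosine(ValueError):
    """Raised when the queried base is not a cytosine on the given strand."""


# ---------------------------------------------------------------------------
# Context classification
# ---------------------------------------------------------------------------

def classify_context(seq: str, pos: int, strand: str) -> str:
    """Sequence context of the cytosine at ``pos`` on ``strand``.

    On "+" the base at ``pos`` must be C and the context is read rightward;
    on "-" it must be G (a cytosine on the reverse complement) and the
    context is read leftward, complemented.  Sites within 2 bp of the
    sequence end with insufficient context are classified CHH.
    """
    if strand == "+":
        if seq[pos] != "C":
            raise NotACytosine(f"base at +{pos} is {seq[pos]}, not C")
        n1 = seq[pos + 1] if pos + 1 < len(seq) else None
        n2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        if seq[pos] != "G":
            raise NotACytosine(f"base at -{pos} is {seq[pos]}, not G")
        n1 = seq[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else None
        n2 = seq[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if n1 == "G":
        return "CG"
    if n2 == "G" and n1 is not None:
        return "CHG"
    return "CHH"


def genome_cytosines(seq: str, chrom: str) -> pd.DataFrame:
    """All cytosines of a sequence on both strands, with contexts.

    Vectorized scan; returns a frame with columns chrom, pos, strand,
    context sorted by (pos, strand).  Ns never count as G, so contexts
    containing N fall through to CHG/CHH exactly as in
    :func:`classify_context`.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    is_c = arr == b"C"
    is_g = arr == b"G"

    g1 = np.zeros(n, bool)
    g1[:-1] = is_g[1:]
    g2 = np.zeros(n, bool)
    g2[:-2] = is_g[2:]
    plus_pos = np.flatnonzero(is_c)
    plus_ctx = np.where(g1[plus_pos], "CG",
                        np.where(g2[plus_pos], "CHG", "CHH"))

    c1 = np.zeros(n, bool)
    c1[1:] = is_c[:-1]
    c2 = np.zeros(n, bool)
    c2[2:] = is_c[:-2]
    minus_pos = np.flatnonzero(is_g)
    minus_ctx = np.where(c1[minus_pos], "CG",
                         np.where(c2[minus_pos], "CHG", "CHH"))

    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.concatenate([plus_pos, minus_pos]),
        "strand": np.concatenate([np.repeat("+", len(plus_pos)),
                                  np.repeat("-", len(minus_pos))]),
        "context": np.concatenate([plus_ctx, minus_ctx]),
    })
    return df.sort_values(["pos", "strand"], kind="stable",
                          ignore_index=True)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineSite:
    """One strand-resolved cytosine with counts for a single sample."""

    chrom: str
    pos: int
    strand: str
    context: str
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError(
                f"{self.chrom}:{self.pos}: meth {self.meth_count} / "
                f"total {self.total_count}")
        if self.context not in ("CG", "CHG", "CHH"):
            raise ValueError(f"bad context {self.context!r}")


@dataclass
class ConversionEstimate:
    """Bisulfite conversion rate from an unmethylated spike-in."""

    rate: float
    error: float
    n_sites: int


@dataclass
class MethylomeMatrix:
    """Sites x samples count matrix — the pipeline's central table.

    ``sites`` holds the shared coordinates (chrom, pos, strand, context),
    sorted by (chrom, pos, strand); ``meth``/``total`` are integer arrays of
    shape (n_sites, n_samples); ``groups`` maps each sample name to its
    stage label ("anagen" or "telogen").
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.meth.shape != self.total.shape:
            raise ValueError("meth/total shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count matrix shape does not match sites/samples")
        for s in self.samples:
            if s not in self.groups:
                raise ValueError(f"sample {s!r} has no group label")
        if (self.meth > self.total).any() or (self.meth < 0).any():
            raise ValueError("counts violate 0 <= meth <= total")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_site_tables(cls, tables: Mapping[str, pd.DataFrame],
                         groups: Mapping[str, str]) -> "MethylomeMatrix":
        """Outer-join per-sample site tables on (chrom, pos, strand, context).

        Sites absent from a sample get zero counts there.
        """
        samples = list(tables)
        keys = ["chrom", "pos", "strand", "context"]
        merged: pd.DataFrame | None = None
        for name in samples:
            t = tables[name][keys + ["meth_count", "total_count"]].rename(
                columns={"meth_count": f"m_{name}", "total_count": f"t_{name}"})
            merged = t if merged is None else merged.merge(
                t, on=keys, how="outer")
        assert merged is not None
        merged = merged.sort_values(["chrom", "pos", "strand"],
                                    kind="stable", ignore_index=True)
        meth = merged[[f"m_{s}" for s in samples]].fillna(0).to_numpy(np.int64)
        total = merged[[f"t_{s}" for s in samples]].fillna(0).to_numpy(np.int64)
        return cls(merged[keys].copy(), meth, total, samples, dict(groups))

    # -- views -------------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_samples(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.samples)
                if self.groups[s] == group]

    def subset(self, mask: np.ndarray) -> "MethylomeMatrix":
        return MethylomeMatrix(self.sites.loc[mask].reset_index(drop=True),
                               self.meth[mask], self.total[mask],
                               list(self.samples), dict(self.groups))

    def for_context(self, context: str) -> "MethylomeMatrix":
        return self.subset((self.sites["context"] == context).to_numpy())

    def for_chrom(self, chrom: str) -> "MethylomeMatrix":
        return self.subset((self.sites["chrom"] == chrom).to_numpy())

    def drop_chrom(self, chrom: str) -> "MethylomeMatrix":
        return self.subset((self.sites["chrom"] != chrom).to_numpy())

    def levels(self, min_total: int = 1) -> np.ndarray:
        """Per-site per-sample levels; NaN where total < ``min_total``."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = self.meth / self.total
        lv[self.total < max(1, min_total)] = np.nan
        return lv

    def group_pooled(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Counts summed over the group's samples: (meth, total) per site."""
        idx = self.group_samples(group)
        return self.meth[:, idx].sum(axis=1), self.total[:, idx].sum(axis=1)


# ---------------------------------------------------------------------------
# Conversion rate
# ---------------------------------------------------------------------------

def estimate_conversion(meth: np.ndarray | Sequence[int],
                        total: np.ndarray | Sequence[int]
                        ) -> ConversionEstimate:
    """Conversion rate from spike-in counts: 1 - sum(meth)/sum(total).

    All cytosines of the spike-in are unmethylated, so every retained C is a
    conversion failure.
    """
    m = int(np.sum(meth))
    t = int(np.sum(total))
    if t == 0:
        raise ValueError("no covered spike-in sites; conversion rate undefined")
    rate = 1.0 - m / t
    return ConversionEstimate(rate, 1.0 - rate, int(np.sum(np.asarray(total) > 0)))


def estimate_conversion_from_matrix(matrix: MethylomeMatrix,
                                    lambda_contig: str) -> ConversionEstimate:
    """Conversion rate pooled over all samples from the spike-in contig."""
    mask = (matrix.sites["chrom"] == lambda_contig).to_numpy()
    if not mask.any():
        raise ValueError(f"no sites on spike-in contig {lambda_contig!r}")
    return estimate_conversion(matrix.meth[mask].sum(axis=1),
                               matrix.total[mask].sum(axis=1))


# ---------------------------------------------------------------------------
# Methylated-cytosine calling
# ---------------------------------------------------------------------------

def binomial_meth_pvalues(meth: np.ndarray, total: np.ndarray,
                          conversion_error: float) -> np.ndarray:
    """One-sided binomial tail P(X >= meth | n=total, p=error) per site."""
    return stats.binom.sf(np.asarray(meth) - 1, np.asarray(total),
                          conversion_error)

def call_methylated(meth: np.ndarray, total: np.ndarray,
                    conversion_error: float,
                    alpha: float = 0.05) -> np.ndarray:
    """Boolean mC calls for one sample's count vectors.

    A site is called methylated when the one-sided binomial tail probability
    of seeing >= ``meth`` unconverted reads out of ``total`` under the
    conversion-error rate survives Benjamini-Hochberg correction over all
    tested (covered) sites at ``alpha``.
    """
    if not 0 < conversion_error < 1:
        raise ValueError("conversion_error must be in (0, 1)")
    meth = np.asarray(meth)
    total = np.asarray(total)
    called = np.zeros(meth.shape, dtype=bool)
    tested = total >= 1
    if not tested.any():
        return called
    p = binomial_meth_pvalues(meth[tested], total[tested], conversion_error)
    rej, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    called[tested] = rej & (meth[tested] > 0)
    return called


def call_site(site: CytosineSite, conversion_error: float,
              alpha: float = 0.05) -> bool:
    """Single-site convenience wrapper (no multiplicity correction possible
    for one site; the raw tail probability is compared with ``alpha``)."""
    if site.total_count < 1:
        return False
    p = float(binomial_meth_pvalues(np.array([site.meth_count]),
                                    np.array([site.total_count]),
                                    conversion_error)[0])
    return p < alpha and site.meth_count > 0


def call_matrix(matrix: MethylomeMatrix, conversion_error: float,
                alpha: float = 0.05) -> np.ndarray:
    """Per-sample mC calls over the whole matrix (BH within each sample)."""
    out = np.zeros(matrix.meth.shape, dtype=bool)
    for j in range(len(matrix.samples)):
        out[:, j] = call_methylated(matrix.meth[:, j], matrix.total[:, j],
                                    conversion_error, alpha)
    return out


# ---------------------------------------------------------------------------
# Levels
# ---------------------------------------------------------------------------

def site_level(meth: int, total: int) -> float:
    if total < 1:
        raise ValueError("site level undefined without coverage")
    return meth / total


def region_level(meth: np.ndarray | Sequence[int],
                 total: np.ndarray | Sequence[int]) -> float:
    """Coverage-weighted region level: pooled counts sum(m)/sum(t).

    Returns NaN (missing-value sentinel) for a region with no coverage.
    """
    t = int(np.sum(total))
    if t == 0:
        return float("nan")
    return float(np.sum(meth) / t)


def mc_proportions(matrix: MethylomeMatrix, calls: np.ndarray
                   ) -> dict[str, dict[str, float]]:
    """Proportions of called mCs by context (CG/CHG/CHH) within each group.

    Counted over (site, sample) pairs: each sample's calls contribute to its
    group's tally.  The three fractions sum to 1 within a group.
    """
    ctx = matrix.sites["context"].to_numpy()
    out: dict[str, dict[str, float]] = {}
    for group in sorted(set(matrix.groups.values())):
        idx = matrix.group_samples(group)
        grp_calls = calls[:, idx]
        n_total = int(grp_calls.sum())
        if n_total == 0:
            raise ValueError(f"no called mCs in group {group!r}")
        out[group] = {
            c: int(grp_calls[ctx == c].sum()) / n_total
            for c in ("CG", "CHG", "CHH")
        }
    return out
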