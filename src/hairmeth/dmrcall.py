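"""Differentially methylated region (DMR) detection.

The procedure, in running order:

1.  **Smoothing** — each sample's CpG levels are smoothed along the
    chromosome with coverage-weighted tricube local regression (local
    likelihood in the BSmooth spirit), borrowing strength across
    neighbouring sites before any testing.
2.  **Sliding-window testing** — 1000-bp windows advanced in 100-bp steps;
    within a window each sample is summarized by its mean smoothed level and
    the two stage groups are compared with a Welch t-test; window p-values
    are Benjamini-Hochberg corrected.
3.  **Site flagging** — a cytosine is differential when it lies in at least
    one window with q < 0.05 and its own pooled between-group level
    difference exceeds 0.25 in absolute value.
4.  **Merging** — runs of same-sign flagged sites with consecutive gaps
    <= 300 bp and at least 3 sites become DMRs; hyper means telogen-higher.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methcore import ANAGEN, TELOGEN, MethylomeMatrix

# Default procedure parameters; the 1000/100 window/step, 0.25 difference,
# 3-site minimum, 300-bp gap and 0.05 FDR are the published cut-offs.
HALF_WINDOW = 500
SMOOTH_MIN_SITES = 10
WINDOW = 1000
STEP = 100
MIN_WINDOW_SITES = 3
FDR = 0.05
MIN_DIFF = 0.25
MAX_GAP = 300
MIN_SITES = 3
COVERAGE_FLOOR = 4


@dataclass
class Dmr:
    """A merged differentially methylated region.

    ``mean_diff`` is the pooled telogen minus anagen level over the region's
    supporting sites; direction is "hyper" (telogen-higher) iff it is
    positive.  The half-open span runs from the first to one past the last
    supporting cytosine.
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    mean_diff: float
    direction: str
    q_value: float
    site_indices: np.ndarray = field(repr=False, default=None)


class DmrResult(NamedTuple):
    dmrs: list[Dmr]
    windows: pd.DataFrame
    flagged: pd.DataFrame
    smoothed: np.ndarray


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth(matrix: MethylomeMatrix,
           half_window: int = HALF_WINDOW,
           min_sites: int = SMOOTH_MIN_SITES,
           degree: int = 1) -> np.ndarray:
    """Coverage-weighted tricube local-regression smoothing per sample.

    For each site, sites within +-``half_window`` bp on the same chromosome
    (the window widens to the ``min_sites`` nearest sites where sparse) are
    fit with a degree-``degree`` weighted polynomial; weights are
    tricube(distance) * coverage.  Returns an (n_sites, n_samples) array in
    [0, 1], NaN where a sample has no coverage in the window.  Smoothing
    never crosses chromosome boundaries.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1")
    out = np.full(matrix.meth.shape, np.nan)
    chroms = matrix.sites["chrom"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        pos = positions[sel].astype(np.int64)
        if not np.all(np.diff(pos) >= 0):
            raise ValueError("sites must be sorted by (chrom, pos)")
        meth = matrix.meth[sel].astype(float)
        tot = matrix.total[sel].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = np.where(tot > 0, meth / np.where(tot > 0, tot, 1), 0.0)
        out[sel] = _smooth_chrom(pos, lvl, tot, half_window, min_sites,
                                 degree)
    return out


def _smooth_chrom(pos, lvl, tot, h, min_sites, degree):
    m, s = lvl.shape
    lo = np.searchsorted(pos, pos - h, side="left")
    hi = np.searchsorted(pos, pos + h, side="right")
    res = np.full((m, s), np.nan)
    for i in range(m):
        l, r = lo[i], hi[i]
        # widen to the nearest min_sites sites when the window is sparse
        while r - l < min_sites and (l > 0 or r < m):
            d_left = pos[i] - pos[l - 1] if l > 0 else np.inf
            d_right = pos[r] - pos[i] if r < m else np.inf
            if d_left <= d_right:
                l -= 1
            else:
                r += 1
        x = (pos[l:r] - pos[i]).astype(float)
        span = max(h, np.abs(x).max() + 1)
        w = (1.0 - (np.abs(x) / span) ** 3) ** 3
        wt = w[:, None] * tot[l:r]          # (k, s)
        sw = wt.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            if degree == 0:
                val = (wt * lvl[l:r]).sum(axis=0) / sw
            else:
                swx = (wt * x[:, None]).sum(axis=0)
                swx2 = (wt * (x ** 2)[:, None]).sum(axis=0)
                swy = (wt * lvl[l:r]).sum(axis=0)
                swxy = (wt * x[:, None] * lvl[l:r]).sum(axis=0)
                denom = sw * swx2 - swx ** 2
                flat = denom <= 1e-12 * np.maximum(sw * swx2, 1e-300)
                val = np.where(flat, swy / sw,
                               (swx2 * swy - swx * swxy)
                               / np.where(flat, 1.0, denom))
        val[sw == 0] = np.nan
        res[i] = val
    return np.clip(res, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Sliding-window testing
# ---------------------------------------------------------------------------

def scan_windows(matrix: MethylomeMatrix,
                 smoothed: np.ndarray,
                 window: int = WINDOW,
                 step: int = STEP,
                 min_window_sites: int = MIN_WINDOW_SITES) -> pd.DataFrame:
    """Welch t-test of group mean smoothed levels in sliding windows.

    Windows are [k*step, k*step + window) per chromosome.  Each sample's
    window summary is its mean smoothed level over covered sites; windows
    with fewer than ``min_window_sites`` sites, or where either group has
    fewer than two sample summaries, are skipped.  Benjamini-Hochberg
    q-values are computed over all tested windows genome-wide.
    """
    a_idx = matrix.group_samples(ANAGEN)
    t_idx = matrix.group_samples(TELOGEN)
    if len(a_idx) < 2 or len(t_idx) < 2:
        raise ValueError("need >= 2 samples per group")

    frames = []
    chroms = matrix.sites["chrom"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        pos = positions[sel].astype(np.int64)
        sm = smoothed[sel]
        starts = np.arange(0, int(pos.max()) + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        n_in = hi - lo
        keep = n_in >= min_window_sites
        if not keep.any():
            continue
        starts, lo, hi, n_in = starts[keep], lo[keep], hi[keep], n_in[keep]

        # NaN-aware prefix sums for per-sample window means
        filled = np.nan_to_num(sm, nan=0.0)
        csum = np.vstack([np.zeros(sm.shape[1]), np.cumsum(filled, axis=0)])
        ccnt = np.vstack([np.zeros(sm.shape[1]),
                          np.cumsum(~np.isnan(sm), axis=0)])
        sums = csum[hi] - csum[lo]
        cnts = ccnt[hi] - ccnt[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(cnts > 0, sums / np.where(cnts > 0, cnts, 1),
                             np.nan)

        ta = _group_stats(means[:, a_idx])
        tt = _group_stats(means[:, t_idx])
        ok = (ta.n >= 2) & (tt.n >= 2)
        if not ok.any():
            continue
        t_stat, p_val = _welch(ta, tt)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts[ok],
            "end": starts[ok] + window,
            "n_sites": n_in[ok],
            "mean_anagen": ta.mean[ok],
            "mean_telogen": tt.mean[ok],
            "t_stat": t_stat[ok],
            "p_value": p_val[ok],
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                     "mean_anagen", "mean_telogen", "t_stat",
                                     "p_value", "q_value"])
    df = pd.concat(frames, ignore_index=True)
    _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = q
    return df


class _GroupStats(NamedTuple):
    n: np.ndarray
    mean: np.ndarray
    var: np.ndarray


def _group_stats(x: np.ndarray) -> _GroupStats:
    n = (~np.isnan(x)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=1)
        var = np.where(n >= 2, np.nanvar(x, axis=1, ddof=1), np.nan)
    return _GroupStats(n, mean, var)


def _welch(a: _GroupStats, b: _GroupStats) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = a.var / a.n + b.var / b.n
        diff = b.mean - a.mean
        t = np.where(se2 > 0, diff / np.sqrt(np.where(se2 > 0, se2, 1)),
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        df = np.where(se2 > 0,
                      se2 ** 2 / ((a.var / a.n) ** 2 / (a.n - 1)
                                  + (b.var / b.n) ** 2 / (b.n - 1)),
                      1.0)
        p = np.where(np.isfinite(t),
                     2 * stats.t.sf(np.abs(t), df),
                     0.0)
        p = np.where((se2 == 0) & (diff == 0), 1.0, p)
    return t, p


# ---------------------------------------------------------------------------
# Site flagging
# ---------------------------------------------------------------------------

def differential_sites(matrix: MethylomeMatrix,
                       windows: pd.DataFrame,
                       min_diff: float = MIN_DIFF,
                       fdr: float = FDR,
                       coverage_floor: int = COVERAGE_FLOOR) -> pd.DataFrame:
    """Flag sites inside significant windows with a large pooled difference.

    A site is differential iff (a) it lies in >= 1 window with q < ``fdr``
    and (b) its pooled telogen-anagen level difference exceeds ``min_diff``
    in absolute value, with both groups pooled-covered >= ``coverage_floor``.
    Returns the flagged sites with signed differences and the minimum q of
    any covering significant window.
    """
    ma, ta = matrix.group_pooled(ANAGEN)
    mt, tt = matrix.group_pooled(TELOGEN)
    covered = (ta >= coverage_floor) & (tt >= coverage_floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.where(covered,
                        mt / np.where(tt > 0, tt, 1)
                        - ma / np.where(ta > 0, ta, 1), np.nan)

    min_q = np.full(matrix.n_sites, np.inf)
    chroms = matrix.sites["chrom"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()
    sig = windows[windows["q_value"] < fdr]
    for chrom, grp in sig.groupby("chrom", sort=False):
        sel = np.flatnonzero(chroms == chrom)
        pos = positions[sel]
        for start, end, q in zip(grp["start"], grp["end"], grp["q_value"]):
            i0, i1 = np.searchsorted(pos, [start, end])
            np.minimum.at(min_q, sel[i0:i1], q)

    flag = covered & (min_q < np.inf) & (np.abs(diff) > min_diff)
    idx = np.flatnonzero(flag)
    return pd.DataFrame({
        "site_idx": idx,
        "chrom": chroms[idx],
        "pos": positions[idx],
        "diff": diff[idx],
        "min_q": min_q[idx],
    })


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_dmrs(flagged: pd.DataFrame,
               max_gap: int = MAX_GAP,
               min_sites: int = MIN_SITES) -> list[Dmr]:
    """Merge flagged sites into DMRs.

    Consecutive same-sign flagged sites with gaps <= ``max_gap`` form a run;
    runs with >= ``min_sites`` sites become DMRs spanning first to one past
    the last site.  Opposite-sign sites never co-merge; a sign change or a
    larger gap splits the run.  ``mean_diff`` here is provisional (the mean
    of site differences); :func:`label_direction` replaces it with the
    pooled region difference.
    """
    dmrs: list[Dmr] = []
    for chrom, grp in flagged.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        diff = grp["diff"].to_numpy()
        qs = grp["min_q"].to_numpy()
        sidx = grp["site_idx"].to_numpy()
        run: list[int] = []
        for i in range(len(grp)):
            if run and (pos[i] - pos[run[-1]] > max_gap
                        or np.sign(diff[i]) != np.sign(diff[run[-1]])):
                _emit(dmrs, chrom, run, pos, diff, qs, sidx, min_sites)
                run = []
            run.append(i)
        _emit(dmrs, chrom, run, pos, diff, qs, sidx, min_sites)
    return dmrs


def _emit(dmrs, chrom, run, pos, diff, qs, sidx, min_sites):
    if len(run) < min_sites:
        return
    r = np.asarray(run)
    md = float(diff[r].mean())
    dmrs.append(Dmr(chrom=chrom, start=int(pos[r[0]]),
                    end=int(pos[r[-1]]) + 1, n_sites=len(r),
                    mean_diff=md,
                    direction="hyper" if md > 0 else "hypo",
                    q_value=float(qs[r].min()),
                    site_indices=sidx[r]))


def label_direction(dmrs: Sequence[Dmr], matrix: MethylomeMatrix
                    ) -> list[Dmr]:
    """Recompute each DMR's pooled telogen-anagen difference and direction.

    Because a DMR is a same-sign run, the pooled difference cannot be
    exactly zero; this is asserted.
    """
    ma, ta = matrix.group_pooled(ANAGEN)
    mt, tt = matrix.group_pooled(TELOGEN)
    out = []
    for d in dmrs:
        idx = d.site_indices
        diff = mt[idx].sum() / tt[idx].sum() - ma[idx].sum() / ta[idx].sum()
        assert diff != 0, "same-sign run with zero pooled difference"
        out.append(Dmr(d.chrom, d.start, d.end, d.n_sites, float(diff),
                       "hyper" if diff > 0 else "hypo", d.q_value,
                       d.site_indices))
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def call_dmrs(matrix: MethylomeMatrix,
              context: str | None = "CG",
              half_window: int = HALF_WINDOW,
              smooth_min_sites: int = SMOOTH_MIN_SITES,
              degree: int = 1,
              window: int = WINDOW,
              step: int = STEP,
              min_window_sites: int = MIN_WINDOW_SITES,
              fdr: float = FDR,
              min_diff: float = MIN_DIFF,
              max_gap: int = MAX_GAP,
              min_sites: int = MIN_SITES,
              coverage_floor: int = COVERAGE_FLOOR) -> DmrResult:
    """Run the full DMR procedure on one context (CG by default)."""
    sub = matrix.for_context(context) if context else matrix
    smoothed = smooth(sub, half_window, smooth_min_sites, degree)
    windows = scan_windows(sub, smoothed, window, step, min_window_sites)
    flagged = differential_sites(sub, windows, min_diff, fdr, coverage_floor)
    dmrs = label_direction(merge_dmrs(flagged, max_gap, min_sites), sub)
    return DmrResult(dmrs, windows, flagged, smoothed)


def dmrs_to_bed(dmrs: Sequence[Dmr]) -> str:
    """BED6+ text for a DMR list (name=direction, score=1000*|mean_diff|)."""
    lines = []
    for d in dmrs:
        score = int(round(1000 * abs(d.mean_diff)))
        lines.append(f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}\t"
                     f"{score}\t.")
    return "\n".join(lines) + ("\n" if lines else "")


def dmrs_to_frame(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.chrom, d.start, d.end, d.n_sites, d.mean_diff, d.direction,
          d.q_value) for d in dmrs],
        columns=["chrom", "start", "end", "n_sites", "mean_diff",
                 "direction", "q_value"])
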