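"""Calling ChIP-enriched regions from replicated tiling-array log-ratios.

The procedure mirrors a Ringo/limma-style analysis: variance-stabilizing
normalization (asinh glog here), per-probe one-sample moderated t tests
with Benjamini-Hochberg adjustment, sliding-window quantile smoothing of
the replicate-mean signal (winHalfSize 100 bp, 0.75 quantile), a null
upper bound from the symmetric part of the smoothed-score distribution
(0.99 quantile), and assembly of enriched regions as runs of >=4
above-threshold probes spaced <=200 bp, gated on probe-wise adjusted
p < 0.02 and a minimum total probe coverage of 8.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ProbeTrack:
    """Ordered tiling probes with per-replicate log-ratios.

    ``probes`` holds probe_id, chrom, start, end plus one column per
    replicate (r1..rk); ``smoothed``/``pvalue``/``adj_pvalue`` columns are
    added by the pipeline steps.
    """

    probes: pd.DataFrame

    def __post_init__(self):
        self.probes = self.probes.sort_values(["chrom", "start"], kind="mergesort")
        self.probes = self.probes.reset_index(drop=True)

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.probes.columns
                if c not in ("probe_id", "chrom", "start", "end",
                             "smoothed", "pvalue", "adj_pvalue", "flagged")]

    @property
    def centers(self) -> np.ndarray:
        return ((self.probes["start"] + self.probes["end"]) // 2).to_numpy()

    @property
    def replicate_matrix(self) -> np.ndarray:
        return self.probes[self.replicate_columns].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, text: str) -> "ProbeTrack":
        return cls(pd.read_csv(io.StringIO(text), sep="\t"))

    def to_tsv(self) -> str:
        return self.probes.to_csv(sep="\t", index=False)

    def apply_blocklist(self, blocklist) -> "ProbeTrack":
        """Drop probes overlapping any (chrom, start, end) blocklist interval
        (stands in for repetitive / multi-mapping probe exclusion)."""
        keep = np.ones(len(self.probes), dtype=bool)
        for chrom, bstart, bend in blocklist:
            keep &= ~((self.probes["chrom"] == chrom)
                      & (self.probes["start"] < bend)
                      & (self.probes["end"] > bstart)).to_numpy()
        return ProbeTrack(self.probes[keep].copy())


@dataclass
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    n_probes: int
    best_adj_p: float
    max_smoothed: float
    rank: int = 0
    total_probes: int = 0


def normalize_track(track: ProbeTrack, method: str = "glog") -> ProbeTrack:
    """Normalize replicate columns.

    ``glog`` (default, variance-stabilizing stand-in): x -> asinh(x / s_r)
    with s_r the per-replicate median absolute deviation, then median
    centering.  ``quantile`` makes replicate distributions identical;
    ``none`` is the identity.
    """
    if method == "none":
        return track
    df = track.probes.copy()
    cols = track.replicate_columns
    if len(cols) < 2:
        raise ValueError("need >=2 replicates to normalize")
    X = df[cols].to_numpy(dtype=float)
    if method == "glog":
        for j in range(X.shape[1]):
            col = X[:, j]
            mad = np.nanmedian(np.abs(col - np.nanmedian(col)))
            if mad == 0:
                warnings.warn(f"replicate {cols[j]} is (near-)constant; centering only")
                X[:, j] = col - np.nanmedian(col)
            else:
                t = np.arcsinh(col / mad)
                X[:, j] = t - np.nanmedian(t)
    elif method == "quantile":
        order = np.argsort(X, axis=0)
        ranks = np.empty_like(order)
        for j in range(X.shape[1]):
            ranks[order[:, j], j] = np.arange(X.shape[0])
        mean_sorted = np.sort(X, axis=0).mean(axis=1)
        X = mean_sorted[ranks]
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    df[cols] = X
    return ProbeTrack(df)


def _fit_prior_df(s2: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2) on log s^2."""
    ok = (s2 > 0) & (d > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[d > 0])) if np.any(d > 0) else 1.0
    z = np.log(s2[ok])
    dd = d[ok]
    e = z - special.digamma(dd / 2) + np.log(dd / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, dd / 2))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    # invert trigamma(d0/2) = evar by Newton iteration
    x = 0.5 + 1.0 / evar
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1 - tri / evar) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10:
            break
    d0 = 2 * x
    s0_sq = float(np.exp(emean + special.digamma(x) - np.log(x)))
    return float(d0), s0_sq


def probe_statistics(track: ProbeTrack, shrink: bool = True) -> ProbeTrack:
    """One-sample t tests of replicate log-ratios against 0 per probe.

    With ``shrink`` the per-probe variances are shrunk toward a prior
    variance s0^2 with prior df d0 fitted by moments on log s^2
    (posterior s~^2 = (d0 s0^2 + d s^2)/(d0 + d), t referred to a
    t distribution with d0 + d df).  P values are two-sided and BH
    adjusted across probes; probes with <2 non-null replicates get p = 1
    and a flag.
    """
    df = track.probes.copy()
    X = track.replicate_matrix
    n = np.sum(~np.isnan(X), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=1)
        s2 = np.nanvar(X, axis=1, ddof=1)
    mean = np.nan_to_num(mean)
    s2 = np.nan_to_num(s2)
    d = np.maximum(n - 1, 0).astype(float)
    flagged = n < 2

    if shrink:
        d0, s0_sq = _fit_prior_df(s2[~flagged], d[~flagged])
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.full_like(d, 1e9)
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
    else:
        s2_post = s2
        df_total = d
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / np.sqrt(s2_post / np.maximum(n, 1))
    tstat = np.where((mean == 0), 0.0, tstat)
    p = np.ones_like(tstat)
    valid = ~flagged & (df_total > 0) & np.isfinite(tstat)
    p[valid] = 2 * stats.t.sf(np.abs(tstat[valid]), df_total[valid])
    p[valid & (np.abs(tstat) > 1e15)] = 0.0
    df["pvalue"] = p
    df["adj_pvalue"] = benjamini_hochberg(p)
    df["flagged"] = flagged
    return ProbeTrack(df)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p values (monotone, capped at 1)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def smooth_signal(track: ProbeTrack, winHalfSize: int = 100, quant: float = 0.75) -> ProbeTrack:
    """Sliding-window quantile smoothing of the replicate-mean signal.

    Each probe's smoothed level is the ``quant`` quantile (linear
    interpolation) of replicate-mean values of all same-chromosome probes
    whose center lies within +/- winHalfSize of its own center.
    """
    df = track.probes.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        level = np.nanmean(track.replicate_matrix, axis=1)
    level = np.nan_to_num(level)
    centers = track.centers
    smoothed = np.empty(len(df))
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        c = centers[idx]
        lo = np.searchsorted(c, c - winHalfSize, side="left")
        hi = np.searchsorted(c, c + winHalfSize, side="right")
        vals = level[idx]
        for k in range(len(idx)):
            smoothed[idx[k]] = np.quantile(vals[lo[k]:hi[k]], quant)
    df["smoothed"] = smoothed
    return ProbeTrack(df)


def _kde_mode(values: np.ndarray) -> float:
    """Mode of the value distribution via a Gaussian KDE on a grid."""
    lo, hi = np.quantile(values, [0.005, 0.995])
    if lo == hi:
        return float(lo)
    grid = np.linspace(lo, hi, 512)
    dens = stats.gaussian_kde(values)(grid)
    # center of the near-maximal plateau: steadier than a bare argmax
    top = dens >= 0.995 * dens.max()
    return float(np.average(grid[top], weights=dens[top]))


def null_threshold(track: ProbeTrack, q: float = 0.99, method: str = "mode-reflect") -> float:
    """Upper bound of the null smoothed-signal distribution.

    ``mode-reflect`` (default) estimates the null as the left-of-mode half
    of the smoothed-value distribution reflected around its mode, so a
    minority of strongly positive (bound) probes barely moves the bound;
    ``empirical`` simply takes the q quantile of all values.
    """
    values = track.probes["smoothed"].to_numpy(dtype=float)
    if np.all(values == values[0]):
        warnings.warn("all smoothed values identical; threshold equals that value")
        return float(values[0])
    if method == "empirical":
        return float(np.quantile(values, q))
    if method != "mode-reflect":
        raise ValueError(f"unknown null method {method!r}")
    mode = _kde_mode(values)
    left = values[values <= mode]
    null = np.concatenate([left, 2 * mode - left])
    return float(np.quantile(null, q))


def call_regions(track: ProbeTrack, threshold: float, distCutOff: int = 200,
                 minProbesInRow: int = 4, p_gate: float = 0.02,
                 min_total_probes: int = 8) -> list[EnrichedRegion]:
    """Assemble enriched regions from above-threshold probes.

    Above-threshold probes on the same chromosome whose centers are
    <= distCutOff apart form a run; runs are kept when they hold >=
    minProbesInRow probes, at least one probe with adjusted p < p_gate,
    and >= min_total_probes track probes counting the run plus flanking
    probes within distCutOff of its ends.  Regions are ranked by best
    adjusted p, then by maximal smoothed level.
    """
    df = track.probes
    smoothed = df["smoothed"].to_numpy(dtype=float)
    adj_p = df["adj_pvalue"].to_numpy(dtype=float) if "adj_pvalue" in df else np.ones(len(df))
    centers = track.centers
    regions: list[EnrichedRegion] = []
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        above = idx[smoothed[idx] > threshold]
        if above.size == 0:
            continue
        runs, cur = [], [above[0]]
        for i in above[1:]:
            if centers[i] - centers[cur[-1]] <= distCutOff:
                cur.append(i)
            else:
                runs.append(cur)
                cur = [i]
        runs.append(cur)
        for run in runs:
            if len(run) < minProbesInRow:
                continue
            best_p = float(np.min(adj_p[run]))
            if not best_p < p_gate:
                continue
            lo_c = centers[run[0]] - distCutOff
            hi_c = centers[run[-1]] + distCutOff
            flank = idx[(centers[idx] >= lo_c) & (centers[idx] <= hi_c)]
            total = int(flank.size)
            if total < min_total_probes:
                logger.info("run on %s dropped: only %d total probes", chrom, total)
                continue
            regions.append(EnrichedRegion(
                chrom=chrom,
                start=int(df["start"].iloc[run[0]]),
                end=int(df["end"].iloc[run[-1]]),
                n_probes=len(run),
                best_adj_p=best_p,
                max_smoothed=float(np.max(smoothed[run])),
                total_probes=total,
            ))
    regions.sort(key=lambda r: (r.best_adj_p, -r.max_smoothed))
    for k, r in enumerate(regions, start=1):
        r.rank = k
    return regions


def regions_to_bed(regions: list[EnrichedRegion]) -> str:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\tcher_{r.rank}\t{r.n_probes}\t+"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def regions_to_tsv(regions: list[EnrichedRegion]) -> str:
    lines = ["rank\tchrom\tstart\tend\tn_probes\ttotal_probes\tbest_adj_p\tmax_smoothed"]
    for r in regions:
        lines.append(
            f"{r.rank}\t{r.chrom}\t{r.start}\t{r.end}\t{r.n_probes}"
            f"\t{r.total_probes}\t{r.best_adj_p:.6g}\t{r.max_smoothed:.6g}"
        )
    return "\n".join(lines) + "\n"
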