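"""Linkage disequilibrium: pairwise genotype r², decay distance, pruning.

r² here is the squared Pearson correlation between alternate-allele dosage
vectors at two sites, over jointly called samples — the composite
(genotype) LD appropriate to unphased diploid data.  The decay distance is
where a cubic smoothing spline fitted to (log10 distance, r²) first drops
below a background threshold (default r² < 0.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from domscan.genotypes import MISSING, GenotypeMatrix
from domscan.tracks import WindowTrack

logger = logging.getLogger("domscan")

PAIR_COLUMNS = ["chrom", "pos1", "pos2", "distance", "r2"]


def pairwise_r2(
    gm: GenotypeMatrix, group="all", max_dist_bp: int = 1_000_000
) -> pd.DataFrame:
    """Genotype r² for all same-chromosome site pairs within a distance cap.

    Returns a DataFrame (chrom, pos1, pos2, distance, r2) with
    0 < distance <= ``max_dist_bp``.  Pairs where either site has zero
    dosage variance over the jointly called samples are skipped.
    """
    idx = gm.group_indices(group)
    if len(idx) < 4:
        logger.warning("pairwise_r2: group has %d < 4 samples", len(idx))
    calls = gm.calls[idx].astype(np.float64)
    calls[calls == MISSING] = np.nan
    out = []
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        loc = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        X = calls[:, loc]
        nm = np.isfinite(X)
        for i in range(len(loc) - 1):
            j_hi = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
            if j_hi <= i + 1:
                continue
            x = X[:, i]
            Y = X[:, i + 1 : j_hi]
            joint = nm[:, i][:, None] & nm[:, i + 1 : j_hi]
            n = joint.sum(axis=0).astype(float)
            xm = np.where(joint, x[:, None], 0.0)
            ym = np.where(joint, Y, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sx, sy = xm.sum(axis=0), ym.sum(axis=0)
                sxx, syy = (xm**2).sum(axis=0), (ym**2).sum(axis=0)
                sxy = (xm * ym).sum(axis=0)
                cov = sxy - sx * sy / n
                vx = sxx - sx**2 / n
                vy = syy - sy**2 / n
                r2 = cov**2 / (vx * vy)
            valid = (n >= 2) & (vx > 0) & (vy > 0)
            jj = np.flatnonzero(valid)
            for j in jj:
                out.append(
                    (
                        chrom,
                        int(pos[i]),
                        int(pos[i + 1 + j]),
                        int(pos[i + 1 + j] - pos[i]),
                        float(min(r2[j], 1.0)),
                    )
                )
    return pd.DataFrame(out, columns=PAIR_COLUMNS)


@dataclass
class DecayFit:
    """Smoothing-spline fit of r² against log10 distance."""

    spline: UnivariateSpline
    smoothing: float
    threshold: float
    decay_distance_bp: float  # NaN when censored
    censored: bool
    log10_range: tuple[float, float]

    def predict(self, distance_bp):
        return self.spline(np.log10(np.asarray(distance_bp, dtype=float)))


def decay_distance(
    pairs: pd.DataFrame, threshold: float = 0.2, smoothing: float | None = None
) -> DecayFit:
    """LD decay distance from pairwise r² via a cubic smoothing spline.

    Distances are log10-transformed; r² values sharing a distance are
    averaged (weight sqrt(count)) before fitting.  When ``smoothing`` is
    None the spline's residual budget is set from a first-difference
    estimate of the local noise variance — a GCV-like default exposed for
    override.  The decay distance is the smallest distance in the observed
    range at which the fitted curve falls below ``threshold``; if the curve
    never crosses, the fit is censored (distance NaN).
    """
    if len(pairs) < 50:
        raise ValueError("need >= 50 pairs to fit LD decay")
    d = pairs["distance"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    x = np.log10(d)
    if x.max() - x.min() < 1.0:
        raise ValueError("pairs must span at least one decade of distance")
    order = np.argsort(x, kind="stable")
    x, r2 = x[order], r2[order]
    xu, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    ybar = np.bincount(inv, weights=r2) / counts
    if len(xu) < 10:
        raise ValueError("degenerate distance range: fewer than 10 distinct distances")
    if smoothing is None:
        # local-noise estimate: half the mean squared successive difference
        noise = 0.5 * np.mean(np.diff(ybar) ** 2)
        smoothing = len(xu) * max(noise, 1e-6)
    w = np.sqrt(counts.astype(float))
    spl = UnivariateSpline(xu, ybar, w=w / w.mean(), k=3, s=smoothing)
    grid = np.linspace(xu[0], xu[-1], 4000)
    fit = spl(grid)
    below = fit < threshold
    if below.any():
        dist = float(10 ** grid[int(np.argmax(below))])
        censored = False
    else:
        dist, censored = float("nan"), True
    return DecayFit(
        spline=spl,
        smoothing=float(smoothing),
        threshold=threshold,
        decay_distance_bp=dist,
        censored=censored,
        log10_range=(float(xu[0]), float(xu[-1])),
    )


def ld_prune(
    gm: GenotypeMatrix,
    window_bp: int = 50_000,
    step_bp: int = 1_000,
    r2_max: float = 0.25,
    group="all",
) -> GenotypeMatrix:
    """Greedy LD pruning: drop the lower-MAF site of correlated pairs.

    Scanning left to right within each chromosome, any pair of retained
    sites within ``window_bp`` of each other with r² > ``r2_max`` loses its
    lower-MAF member (ties: the later position is removed).  Since windows
    advance by ``step_bp`` <= ``window_bp``, every such pair co-occurs in
    some window; the scan therefore visits pairs directly, ordered by left
    site.  The retained submatrix is returned and the count logged.
    """
    if not (0 < r2_max <= 1) or window_bp < 1 or step_bp < 1:
        raise ValueError("invalid pruning parameters")
    idx = gm.group_indices(group)
    calls = gm.calls[idx].astype(np.float64)
    calls[calls == MISSING] = np.nan
    nm = np.isfinite(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.nansum(calls, axis=0) / (2.0 * nm.sum(axis=0))
    maf = np.minimum(af, 1 - af)
    keep = np.ones(gm.n_sites, dtype=bool)
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        loc = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        for ii, i in enumerate(loc):
            if not keep[i]:
                continue
            j_hi = np.searchsorted(pos, pos[ii] + window_bp, side="right")
            for jj in range(ii + 1, j_hi):
                j = loc[jj]
                if not keep[i]:
                    break
                if not keep[j]:
                    continue
                r2 = _pair_r2(calls[:, i], calls[:, j])
                if r2 is not None and r2 > r2_max:
                    if maf[i] < maf[j]:
                        keep[i] = False
                    else:  # tie -> later position removed
                        keep[j] = False
    logger.info("ld_prune: retained %d/%d sites", int(keep.sum()), gm.n_sites)
    return gm.take_sites(keep)


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    joint = np.isfinite(x) & np.isfinite(y)
    if joint.sum() < 2:
        return None
    xs, ys = x[joint], y[joint]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return None
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def local_ld_track(pairs: pd.DataFrame, window_bp: int = 1_000_000) -> WindowTrack:
    """Mean r² of pairs binned by pair midpoint into physical windows."""
    rows = []
    if len(pairs):
        mid = (pairs["pos1"].to_numpy() + pairs["pos2"].to_numpy()) / 2.0 - 1.0
        for chrom in pairs["chrom"].unique():
            sel = pairs["chrom"].to_numpy() == chrom
            b = (mid[sel] // window_bp).astype(int)
            r2 = pairs["r2"].to_numpy()[sel]
            counts = np.bincount(b)
            sums = np.bincount(b, weights=r2)
            for k in np.flatnonzero(counts):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(k * window_bp),
                        "end": int((k + 1) * window_bp),
                        "n_sites": int(counts[k]),
                        "value": float(sums[k] / counts[k]),
                    }
                )
    return WindowTrack(
        df=pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "value"]),
        statistic="local_ld",
        meta={"window_bp": window_bp, "assignment": "pair midpoint, mean r2 per window"},
    )
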