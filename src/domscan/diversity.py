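"""Nucleotide diversity (pi) and the reduction-of-diversity ratio (ROD).

Per-site pi is Nei's mean pairwise difference between alleles,
sum_ij x_i x_j pi_ij, in its unbiased sample form: with m non-missing
alleles at a site (two per called diploid) and alternate-allele frequency
p, pi = 2 p (1-p) m / (m-1).  Windows are marker-count windows (default
10 markers, 5-marker step) whose physical span runs from the first to the
last contained marker, so they can be intersected with physical tracks.

ROD contrasts a focal group against a reference: per shared window,
ROD = pi_focal / pi_reference.  Windows with ROD < 1 indicate reduced
diversity in the focal group (candidate domestication footprints); windows
with ROD > 1 are "increase of diversity" (IOD) windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from domscan.genotypes import MISSING, GenotypeMatrix
from domscan.tracks import WindowTrack, pos_to_bed

logger = logging.getLogger("domscan")


@dataclass
class PiEstimate:
    pi: float
    m: int  # non-missing allele count used


def site_pi(calls_at_site) -> PiEstimate:
    """Unbiased per-site nucleotide diversity from a dosage vector.

    Equals the exhaustive mean pairwise difference over all m(m-1)/2
    allele pairs at the site.  Requires >= 2 non-missing calls.
    """
    calls = np.asarray(calls_at_site)
    nm = calls != MISSING
    n = int(nm.sum())
    if n < 2:
        raise ValueError("site_pi needs >= 2 non-missing calls")
    m = 2 * n
    p = calls[nm].sum() / m
    return PiEstimate(pi=2.0 * p * (1.0 - p) * m / (m - 1.0), m=m)


def _sitewise_pi(calls: np.ndarray) -> np.ndarray:
    """Vectorised site pi for a (samples x sites) dosage block.

    Sites with < 2 non-missing calls get NaN (skipped downstream).
    """
    nm = calls != MISSING
    n = nm.sum(axis=0)
    m = 2.0 * n
    alt = np.where(nm, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / m
        pi = 2.0 * p * (1.0 - p) * m / (m - 1.0)
    return np.where(n >= 2, pi, np.nan)


def _window_starts(n_sites: int, window_sites: int, step_sites: int) -> list[tuple[int, int]]:
    """(first, last) site-index pairs, inclusive, for marker-count windows."""
    if n_sites <= window_sites:
        return [(0, n_sites - 1)]
    out = []
    s = 0
    while s + window_sites <= n_sites:
        out.append((s, s + window_sites - 1))
        s += step_sites
    # trailing partial window so the final markers are covered
    if out[-1][1] < n_sites - 1:
        out.append((n_sites - window_sites, n_sites - 1))
    return out


def windowed_pi(
    gm: GenotypeMatrix,
    group,
    window_sites: int = 10,
    step_sites: int = 5,
    unbiased: bool = True,
) -> WindowTrack:
    """Mean per-site pi in sliding marker-count windows for one group.

    Windowing restarts on each chromosome; a chromosome with fewer sites
    than ``window_sites`` yields a single truncated window (flagged in the
    log).  Window span is [first marker pos - 1, last marker pos) in BED
    coordinates.  ``unbiased=False`` switches to the plug-in 2p(1-p)
    estimator for sensitivity checks.
    """
    if not (window_sites >= step_sites >= 1):
        raise ValueError("need window_sites >= step_sites >= 1")
    idx = gm.group_indices(group)
    if len(idx) < 2:
        raise ValueError("group needs >= 2 samples")
    pi = _sitewise_pi(gm.calls[idx])
    if not unbiased:
        nm = gm.calls[idx] != MISSING
        m = 2.0 * nm.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = pi * (m - 1.0) / m
    rows = []
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        loc = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if len(loc) < window_sites:
            logger.info(
                "windowed_pi: chromosome %s has %d < %d sites; truncated window",
                chrom, len(loc), window_sites,
            )
        for a, b in _window_starts(len(loc), window_sites, step_sites):
            vals = pi[loc[a : b + 1]]
            defined = vals[np.isfinite(vals)]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos_to_bed(pos[a])),
                    "end": int(pos[b]),
                    "n_sites": b - a + 1,
                    "value": float(defined.mean()) if len(defined) else np.nan,
                }
            )
    return WindowTrack(
        df=pd.DataFrame(rows),
        statistic="pi",
        meta={"group": str(group), "window_sites": window_sites, "step_sites": step_sites},
    )


def rod_track(pi_focal: WindowTrack, pi_reference: WindowTrack) -> WindowTrack:
    """Per-window ratio of focal to reference diversity.

    Both tracks must share the identical window grid (same sites).  Windows
    where the reference pi is zero or either pi is undefined emit NaN and
    are excluded from percentile extraction.  The genome-wide ratio
    sum(pi_focal)/sum(pi_reference) is stored in ``meta['genome_wide_rod']``.
    """
    if not pi_focal.same_grid(pi_reference):
        raise ValueError("ROD requires identical window grids")
    f = pi_focal.df["value"].to_numpy(dtype=float)
    r = pi_reference.df["value"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rod = np.where(np.isfinite(f) & np.isfinite(r) & (r > 0), f / r, np.nan)
    both = np.isfinite(f) & np.isfinite(r)
    genome_wide = float(f[both].sum() / r[both].sum()) if r[both].sum() > 0 else np.nan
    df = pi_focal.df.copy()
    df["value"] = rod
    return WindowTrack(
        df=df,
        statistic="rod",
        meta={
            "genome_wide_rod": genome_wide,
            "focal": pi_focal.meta.get("group"),
            "reference": pi_reference.meta.get("group"),
        },
    )
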