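"""Weir & Cockerham (1984) fixation index between two subpopulations.

Per site, the estimator decomposes allele-frequency variance into three
components: a (among populations), b (among individuals within
populations) and c (within individuals, i.e. heterozygosity).  The site
estimate is theta_hat = a / (a + b + c).  Windowed and pooled values are
the *ratio of sums* sum(a) / sum(a+b+c) over the contributing sites —
never the mean of per-site ratios — which is the standard weighted
("Weir and Cockerham weighted") estimator.  Negative per-site components
are retained in the sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from domscan.genotypes import MISSING, GenotypeMatrix
from domscan.tracks import WindowTrack

logger = logging.getLogger("domscan")


@dataclass
class FstComponents:
    """Per-site variance components; arrays are aligned with the site axis."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    usable: np.ndarray  # both pops called at >= 2 alleles and site polymorphic overall

    @property
    def fst(self) -> np.ndarray:
        """Per-site a/(a+b+c); NaN where unusable or denominator is zero."""
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.usable & (denom != 0), self.a / denom, np.nan)
        return f


def _pop_stats(calls: np.ndarray):
    """(n diploids called, alt freq, observed het fraction) per site."""
    nm = calls != MISSING
    n = nm.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nm, calls, 0).sum(axis=0) / (2.0 * n)
        h = (calls == 1).sum(axis=0) / n
    return n, p, h


def wc_fst_site(calls_a: np.ndarray, calls_b: np.ndarray) -> FstComponents:
    """Weir-Cockerham variance components for two populations, per site.

    ``calls_a`` and ``calls_b`` are (samples x sites) dosage blocks for the
    two populations (1-D input is treated as a single site).  Sites where
    either population has fewer than two called diploids, or which are
    monomorphic overall, are flagged unusable.
    """
    calls_a = np.atleast_2d(np.asarray(calls_a, dtype=np.int8))
    calls_b = np.atleast_2d(np.asarray(calls_b, dtype=np.int8))
    if calls_a.ndim != 2 or calls_b.ndim != 2:
        raise ValueError("expected 2-D (samples x sites) blocks")
    n1, p1, h1 = _pop_stats(calls_a)
    n2, p2, h2 = _pop_stats(calls_b)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    usable = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return FstComponents(a=a, b=b, c=c, usable=usable)


def _components_for_groups(gm: GenotypeMatrix, group_a, group_b) -> FstComponents:
    ia, ib = gm.group_indices(group_a), gm.group_indices(group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need >= 2 samples")
    return wc_fst_site(gm.calls[ia], gm.calls[ib])


def pooled_fst(gm: GenotypeMatrix, group_a, group_b) -> float:
    """Genome-wide weighted Fst, sum(a)/sum(a+b+c) over all usable sites."""
    comp = _components_for_groups(gm, group_a, group_b)
    denom = (comp.a + comp.b + comp.c)[comp.usable].sum()
    if not comp.usable.any() or denom == 0:
        raise ValueError("no usable polymorphic sites for pooled Fst")
    return float(comp.a[comp.usable].sum() / denom)


def fst_windowed(
    gm: GenotypeMatrix,
    focal,
    others,
    window_bp: int = 1_000_000,
    step_bp: int = 1_000,
) -> WindowTrack:
    """Weighted Fst in overlapping physical windows along each chromosome.

    Windows are anchored at multiples of ``step_bp`` from position 0
    (BED coordinates) and span ``window_bp``; the last window starts at or
    before the final site.  Windows containing no usable site emit NaN.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window_bp >= step_bp >= 1")
    comp = _components_for_groups(gm, focal, others)
    num = np.where(comp.usable, comp.a, 0.0)
    den = np.where(comp.usable, comp.a + comp.b + comp.c, 0.0)
    rows = []
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        loc = sub.index.to_numpy()
        pos0 = sub["pos"].to_numpy() - 1  # 0-based site coordinates
        cnum = np.concatenate([[0.0], np.cumsum(num[loc])])
        cden = np.concatenate([[0.0], np.cumsum(den[loc])])
        cuse = np.concatenate([[0], np.cumsum(comp.usable[loc].astype(int))])
        last_start = (pos0[-1] // step_bp) * step_bp
        starts = np.arange(0, last_start + 1, step_bp)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, starts + window_bp, side="left")
        wnum = cnum[hi] - cnum[lo]
        wden = cden[hi] - cden[lo]
        wuse = cuse[hi] - cuse[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where((wuse > 0) & (wden != 0), wnum / wden, np.nan)
        n_sites = hi - lo
        keep = n_sites > 0
        for s, ns, v in zip(starts[keep], n_sites[keep], val[keep]):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(s + window_bp),
                    "n_sites": int(ns),
                    "value": float(v) if np.isfinite(v) else np.nan,
                }
            )
    return WindowTrack(
        df=pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "value"]),
        statistic="fst",
        meta={
            "focal": str(focal),
            "others": str(others),
            "window_bp": window_bp,
            "step_bp": step_bp,
        },
    )
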