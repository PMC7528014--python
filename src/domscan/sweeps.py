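"""Composite-likelihood-ratio (CLR) selective-sweep scan.

SweepFinder-class model on a folded site-frequency spectrum (SFS).  The
genome-wide folded SFS is the null; near a swept locus the spectrum is
distorted by lineage escape: at distance d from the sweep, each sampled
lineage escapes with probability p_esc = 1 - exp(-alpha * d).  Escaped
lineages retain background variation; non-escaping lineages coalesce into
the single swept lineage and all carry its allele.  For n sampled alleles
with e escapees this is a draw of e+1 lineages from the background
spectrum, with one of them (the swept ancestor) expanded to n - e copies.

At each point of a fixed physical grid,

    Lambda = 2 * max_alpha sum_sites [ log P_sweep(k | alpha, d) - log P0(k) ]

maximised over a log-spaced alpha grid that nests the null (p_esc -> 1
recovers the background exactly, so Lambda >= 0).  Sites only contribute
within the distance where p_esc < 1 - 1e-6; beyond it their likelihood
ratio is 1.  Distances are discretised into bands of constant
alpha*distance, which makes the whole scan a handful of prefix-sum lookups
per grid point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from domscan.genotypes import MISSING, GenotypeMatrix
from domscan.regions import Region

logger = logging.getLogger("domscan")

#: alpha*d beyond which a site's likelihood ratio is treated as 1
#: (escape probability within 1e-6 of certain).
_U_MAX = -np.log(1e-6)

#: floor applied to SFS class probabilities before taking logs, so empty
#: empirical classes cannot produce infinite log-ratios.
_PROB_FLOOR = 1e-8


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum for a fixed allele count n.

    probs[k-1] is the probability of minor-allele count k, k = 1..n//2,
    over polymorphic sites only (invariant sites are unavailable in a
    SNP-only matrix).
    """

    n: int
    probs: np.ndarray
    n_sites: int = 0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != self.n // 2:
            raise ValueError("probs must have n//2 folded classes")
        if (self.probs < 0).any():
            raise ValueError("negative SFS probability")
        s = self.probs.sum()
        if not np.isclose(s, 1.0, atol=1e-8):
            raise ValueError("SFS probabilities must sum to 1")


def _site_class_weights(calls: np.ndarray, n: int):
    """Project each site onto folded classes of a common allele count.

    For a site with n_s >= n called alleles and alt count j, the projected
    minor-count distribution is hypergeometric; mass on monomorphic
    subsamples is dropped and the site renormalised.  Returns
    (weights matrix n_kept x n//2, site index of kept sites).
    """
    nm = calls != MISSING
    ns = 2 * nm.sum(axis=0)
    alt = np.where(nm, calls, 0).sum(axis=0)
    kept, weights = [], []
    kmax = n // 2
    i_all = np.arange(n + 1)
    for s in range(calls.shape[1]):
        if ns[s] < n or alt[s] == 0 or alt[s] == ns[s]:
            continue
        pm = hypergeom.pmf(i_all, ns[s], alt[s], n)
        w = np.zeros(kmax)
        for i in range(1, n):
            w[min(i, n - i) - 1] += pm[i]
        tot = w.sum()
        if tot <= 0:
            continue
        kept.append(s)
        weights.append(w / tot)
    if not kept:
        return np.zeros((0, kmax)), np.array([], dtype=int)
    return np.array(weights), np.array(kept, dtype=int)


def folded_sfs(gm: GenotypeMatrix, group) -> FoldedSFS:
    """Empirical folded SFS for a group, projected to the modal allele count.

    Sites with fewer called alleles than the modal count, or monomorphic
    within the group, are dropped.
    """
    idx = gm.group_indices(group)
    if len(idx) < 2:
        raise ValueError("group needs >= 2 samples")
    calls = gm.calls[idx]
    nm = calls != MISSING
    ns = 2 * nm.sum(axis=0)
    alt = np.where(nm, calls, 0).sum(axis=0)
    poly = (alt > 0) & (alt < ns) & (ns >= 2)
    if not poly.any():
        raise ValueError("no polymorphic sites in group")
    vals, counts = np.unique(ns[poly], return_counts=True)
    n = int(vals[np.argmax(counts)])
    weights, kept = _site_class_weights(calls, n)
    if len(kept) == 0:
        raise ValueError("no sites projectable to the modal allele count")
    probs = weights.sum(axis=0)
    probs /= probs.sum()
    return FoldedSFS(n=n, probs=probs, n_sites=len(kept))


# ---------------------------------------------------------------------------
# sweep-distorted spectrum


def _unfold(sfs: FoldedSFS) -> np.ndarray:
    """Symmetric unfolded spectrum p_j over j = 0..n (monomorphic mass 0)."""
    n = sfs.n
    p = np.zeros(n + 1)
    for k in range(1, n // 2 + 1):
        if k == n - k:
            p[k] = sfs.probs[k - 1]
        else:
            p[k] = sfs.probs[k - 1] / 2.0
            p[n - k] = sfs.probs[k - 1] / 2.0
    return p


def _projection_tables(p_bg: np.ndarray, n: int) -> list[np.ndarray]:
    """proj[m][i] = P(i derived in a subsample of m | background), m=1..n."""
    j = np.arange(n + 1)
    tables = [None]  # index by m
    for m in range(1, n + 1):
        i = np.arange(m + 1)
        # hypergeom.pmf broadcast: rows i, cols j
        pm = hypergeom.pmf(i[:, None], n, j[None, :], m)
        tables.append(pm @ p_bg)
    return tables


def sweep_spectrum(background: FoldedSFS, p_esc: float) -> np.ndarray:
    """Folded spectrum under the sweep model at escape probability p_esc.

    Conditional on the site remaining polymorphic in the sample; sums to 1
    over the n//2 folded classes.
    """
    return _sweep_spectra(background, np.array([p_esc]))[0]


def _sweep_spectra(background: FoldedSFS, p_esc: np.ndarray) -> np.ndarray:
    """Rows of folded sweep spectra, one per escape probability."""
    n = background.n
    p_bg = _unfold(background)
    proj = _projection_tables(p_bg, n)
    out = np.zeros((len(p_esc), n // 2))
    e_all = np.arange(n + 1)
    for r, pe in enumerate(p_esc):
        we = binom.pmf(e_all, n, pe)
        unfolded = np.zeros(n + 1)
        # e = n: everything escaped, background recovered exactly
        unfolded += we[n] * p_bg
        for e in range(n):
            if we[e] < 1e-12:
                continue
            m = e + 1
            q = proj[m]  # length m+1, includes monomorphic subsamples
            i = np.arange(m + 1)
            frac_derived = i / m
            b_derived = i - 1 + (n - e)  # swept ancestor carries derived
            b_ancestral = i  # swept ancestor carries ancestral
            np.add.at(unfolded, b_derived, we[e] * q * frac_derived)
            np.add.at(unfolded, b_ancestral, we[e] * q * (1 - frac_derived))
        folded = np.zeros(n // 2)
        for bcls in range(1, n):
            folded[min(bcls, n - bcls) - 1] += unfolded[bcls]
        tot = folded.sum()
        if tot <= 0:
            # fully swept and nothing escaped: no polymorphism possible;
            # treat as the least-favourable spectrum (uniform floor)
            folded[:] = 1.0 / len(folded)
        else:
            folded /= tot
        out[r] = folded
    return out


# ---------------------------------------------------------------------------
# the scan


@dataclass
class SweepGrid:
    """Per-grid-point CLR values Lambda and fitted sweep intensity alpha."""

    df: pd.DataFrame  # chrom, pos, Lambda, alpha_hat
    grid_bp: int
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("# statistic=clr\n")
            for k, v in self.meta.items():
                fh.write(f"# {k}={v}\n")
            self.df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def default_alpha_grid() -> np.ndarray:
    """Log-spaced sweep intensities, 1e-8 .. 1e-2 per bp."""
    return np.logspace(-8, -2, 13)


def clr_scan(
    gm: GenotypeMatrix,
    group,
    background: FoldedSFS | None = None,
    grid_bp: int = 1_000,
    alpha_grid: np.ndarray | None = None,
    n_esc_bins: int = 48,
) -> SweepGrid:
    """CLR sweep scan on a fixed physical grid along each chromosome.

    ``background`` defaults to the group's own genome-wide folded SFS.
    Chromosomes with fewer than 2 projectable polymorphic sites emit no
    grid.  Lambda >= 0 everywhere because the null (background) is always
    in the maximisation; alpha_hat is NaN where the null wins.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    if background is None:
        background = folded_sfs(gm, group)
    n = background.n
    idx = gm.group_indices(group)
    calls = gm.calls[idx]

    # escape-probability bands, uniform in u = alpha * distance
    edges = np.linspace(0.0, _U_MAX, n_esc_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pe_centers = 1.0 - np.exp(-centers)
    spectra = _sweep_spectra(background, pe_centers)  # (bins, n//2)
    spectra = np.maximum(spectra, _PROB_FLOOR)
    spectra /= spectra.sum(axis=1, keepdims=True)
    bg = np.maximum(background.probs, _PROB_FLOOR)
    bg = bg / bg.sum()

    frames = []
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        loc = sub.index.to_numpy()
        pos = sub["pos"].to_numpy().astype(np.int64)
        weights, kept = _site_class_weights(calls[:, loc], n)
        if len(kept) < 2:
            logger.info("clr_scan: chromosome %s has <2 usable sites; skipped", chrom)
            continue
        spos = pos[kept].astype(float)
        lbg = np.log(weights @ bg)
        # log-likelihood-ratio of each site under each escape band
        llr = np.log(weights @ spectra.T) - lbg[:, None]  # (sites, bins)
        csum = np.zeros((n_esc_bins, len(kept) + 1))
        csum[:, 1:] = np.cumsum(llr.T, axis=1)

        grid = np.arange(pos[0], pos[-1] + 1, grid_bp, dtype=float)
        best = np.full(len(grid), -np.inf)
        best_alpha = np.full(len(grid), np.nan)
        for alpha in alpha_grid:
            d_edges = edges / alpha
            total = np.zeros(len(grid))
            left_cap = np.searchsorted(spos, grid, side="left")
            for b in range(n_esc_bins):
                lo_r = np.searchsorted(spos, grid + d_edges[b], side="left")
                hi_r = np.searchsorted(spos, grid + d_edges[b + 1], side="left")
                lo_l = np.searchsorted(spos, grid - d_edges[b + 1], side="right")
                hi_l = np.searchsorted(spos, grid - d_edges[b], side="right")
                hi_l = np.minimum(hi_l, left_cap)  # keep pos == g on the right side
                lo_l = np.minimum(lo_l, hi_l)
                total += csum[b, hi_r] - csum[b, lo_r]
                total += csum[b, hi_l] - csum[b, lo_l]
            better = total > best
            best[better] = total[better]
            best_alpha[better] = alpha
        lam = 2.0 * np.maximum(best, 0.0)
        best_alpha[best <= 0] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": grid.astype(np.int64),
                    "Lambda": lam,
                    "alpha_hat": best_alpha,
                }
            )
        )
    if not frames:
        raise ValueError("no chromosome had enough usable sites for the scan")
    return SweepGrid(
        df=pd.concat(frames, ignore_index=True),
        grid_bp=grid_bp,
        meta={
            "group": str(group),
            "n_alleles": n,
            "grid_bp": grid_bp,
            "alpha_min": float(alpha_grid.min()),
            "alpha_max": float(alpha_grid.max()),
        },
    )


def sweep_intervals(grid: SweepGrid, percentile: float = 99.0) -> list[Region]:
    """Maximal runs of grid points with Lambda above the percentile cutoff.

    The cutoff is strict (ties at the cutoff are excluded, so a flat scan
    yields nothing).  Each run becomes one interval covering its grid
    points, [first_pos - 1, last_pos - 1 + grid_bp) in BED coordinates.
    """
    df = grid.df
    if not len(df):
        raise ValueError("empty sweep grid")
    cutoff = float(np.percentile(df["Lambda"], percentile))
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        lam = sub["Lambda"].to_numpy()
        above = lam > cutoff
        if not above.any():
            continue
        breaks = np.flatnonzero(np.diff(above.astype(int)))
        bounds = np.concatenate([[-1], breaks, [len(above) - 1]])
        for s, e in zip(bounds[:-1] + 1, bounds[1:] + 1):
            if not above[s]:
                continue
            out.append(
                Region(
                    chrom=str(chrom),
                    start=int(pos[s] - 1),
                    end=int(pos[e - 1] - 1 + grid.grid_bp),
                    label="SWEEP",
                    score=float(lam[s:e].max()),
                    provenance="clr_scan",
                )
            )
    return out
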