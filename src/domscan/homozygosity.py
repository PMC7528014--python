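"""Runs of homozygosity (ROH): detection, concordance grouping, pooling.

A run is detected per sample by sliding a physical window (default 1 Mbp)
site by site along a chromosome and classifying each window homozygous if
it contains at most ``max_het`` heterozygous (dosage 1) and ``max_missing``
missing calls.  Maximal unions of consecutive homozygous windows, trimmed
to their outermost homozygous called sites and at least ``min_length_bp``
long, are emitted.  Missing calls never break a run but count toward the
allowance.  Overlapping segments from different samples whose genotypes
agree at >= 99% of jointly called homozygous sites are clustered into
groups by single linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from domscan.genotypes import MISSING, GenotypeMatrix
from domscan.tracks import WindowTrack

logger = logging.getLogger("domscan")


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_sites: int
    n_het: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.end - self.start


def roh_scan(
    gm: GenotypeMatrix,
    sample: str,
    window_bp: int = 1_000_000,
    max_het: int = 1,
    max_missing: int = 5,
    min_length_bp: int = 1_000_000,
    max_gap_bp: int = 1_000_000,
    step_sites: int = 1,
) -> list[ROHSegment]:
    """Detect runs of homozygosity for one sample.

    Windows of ``window_bp`` anchored at every ``step_sites``-th site are
    classified by the het/missing allowances; runs are maximal stretches of
    *consecutive* homozygous windows (their unioned site coverage), with
    the tail past the last supporting window cut at the first heterozygous
    call.  Runs are split where consecutive sites are more than
    ``max_gap_bp`` apart, trimmed to outermost called homozygous sites,
    kept if their span reaches ``min_length_bp``, and deduplicated so one
    sample never reports overlapping segments.
    """
    if min(window_bp, min_length_bp, max_gap_bp, step_sites) < 1 or min(max_het, max_missing) < 0:
        raise ValueError("invalid ROH parameters")
    try:
        row = gm.sample_ids.index(sample)
    except ValueError:
        raise KeyError(f"unknown sample {sample!r}") from None
    segments: list[ROHSegment] = []
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        loc = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        g = gm.calls[row, loc]
        het = (g == 1).astype(int)
        mis = (g == MISSING).astype(int)
        chet = np.concatenate([[0], np.cumsum(het)])
        cmis = np.concatenate([[0], np.cumsum(mis)])
        anchors = np.arange(0, len(loc), step_sites)
        win_end = np.searchsorted(pos, pos[anchors] + window_bp, side="left")
        hom = (chet[win_end] - chet[anchors] <= max_het) & (
            cmis[win_end] - cmis[anchors] <= max_missing
        )
        if not hom.any():
            continue
        # runs of *consecutive* homozygous windows; a non-homozygous window
        # in between always breaks the run
        hom_idx = np.flatnonzero(hom)
        anchor_breaks = np.flatnonzero(np.diff(hom_idx) > 1)
        run_starts = np.concatenate([[0], anchor_breaks + 1])
        run_ends = np.concatenate([anchor_breaks, [len(hom_idx) - 1]])
        runs = []
        for s, e in zip(run_starts, run_ends):
            a_last = anchors[hom_idx[e]]
            b2 = win_end[hom_idx[e]]
            # past the last supporting anchor the run extends only while
            # contiguously homozygous: a het there has no window of its own
            tail_het = np.flatnonzero(het[a_last + 1 : b2])
            if len(tail_het):
                b2 = a_last + 1 + tail_het[0]
            span = np.arange(anchors[hom_idx[s]], b2)
            # split where consecutive sites are too far apart
            gap_break = np.flatnonzero(np.diff(pos[span]) > max_gap_bp)
            bounds = np.concatenate([[0], gap_break + 1, [len(span)]])
            runs.extend(
                span[bounds[i] : bounds[i + 1]]
                for i in range(len(bounds) - 1)
                if bounds[i + 1] > bounds[i]
            )
        chrom_segments: list[ROHSegment] = []
        for run in runs:
            called_hom = np.flatnonzero((g[run] != 1) & (g[run] != MISSING))
            if len(called_hom) == 0:
                continue
            # trim to outermost homozygous sites
            run = run[called_hom[0] : called_hom[-1] + 1]
            start_bp = int(pos[run[0]] - 1)
            end_bp = int(pos[run[-1]])
            if end_bp - start_bp < min_length_bp:
                continue
            chrom_segments.append(
                ROHSegment(
                    sample=sample,
                    chrom=str(chrom),
                    start=start_bp,
                    end=end_bp,
                    n_sites=len(run),
                    n_het=int(het[run].sum()),
                    n_missing=int(mis[run].sum()),
                )
            )
        # window support can fragment at run boundaries into overlapping
        # spans; keep the longest segment of each overlapping set
        kept: list[ROHSegment] = []
        for seg in sorted(chrom_segments, key=lambda s: -s.n_sites):
            if all(s.end <= seg.start or s.start >= seg.end for s in kept):
                kept.append(seg)
        segments.extend(sorted(kept, key=lambda s: s.start))
    return segments


def roh_scan_all(gm: GenotypeMatrix, group="all", **kwargs) -> list[ROHSegment]:
    """Run :func:`roh_scan` for every sample of a group."""
    idx = gm.group_indices(group)
    out = []
    for i in idx:
        out.extend(roh_scan(gm, gm.sample_ids[i], **kwargs))
    return out


@dataclass
class ROHGroup:
    """Overlapping, allelically concordant segments across samples."""

    segments: list[ROHSegment]
    chrom: str = field(init=False)
    consensus_start: int = field(init=False)
    consensus_end: int = field(init=False)

    def __post_init__(self):
        self.chrom = self.segments[0].chrom
        self.consensus_start = min(s.start for s in self.segments)
        self.consensus_end = max(s.end for s in self.segments)

    @property
    def samples(self) -> list[str]:
        return sorted({s.sample for s in self.segments})


def _segment_concordance(gm, row_a, row_b, chrom, start, end):
    """Fraction of jointly called homozygous sites with identical dosage
    over [start, end); None when no comparable site exists."""
    sub = gm.sites[(gm.sites["chrom"] == chrom)]
    loc = sub.index.to_numpy()
    pos = sub["pos"].to_numpy()
    inside = (pos - 1 >= start) & (pos - 1 < end)
    loc = loc[inside]
    a = gm.calls[row_a, loc]
    b = gm.calls[row_b, loc]
    comp = (a != MISSING) & (b != MISSING) & (a != 1) & (b != 1)
    if not comp.any():
        return None
    return float((a[comp] == b[comp]).mean())


def roh_group(
    segments: list[ROHSegment], gm: GenotypeMatrix, min_concordance: float = 0.99
) -> list[ROHGroup]:
    """Cluster segments by single linkage on overlap + allelic concordance.

    Two segments are linked when they overlap on the same chromosome and
    their samples' genotypes agree at a fraction >= ``min_concordance`` of
    jointly called homozygous sites inside the overlap.  Pairs with no
    comparable site are not linked.  Order-invariant by construction.
    """
    segs = sorted(segments, key=lambda s: (s.chrom, s.start, s.end, s.sample))
    n = len(segs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows = {sid: i for i, sid in enumerate(gm.sample_ids)}
    for i in range(n):
        for j in range(i + 1, n):
            if segs[j].chrom != segs[i].chrom:
                continue
            lo = max(segs[i].start, segs[j].start)
            hi = min(segs[i].end, segs[j].end)
            if lo >= hi:
                continue
            conc = _segment_concordance(
                gm, rows[segs[i].sample], rows[segs[j].sample], segs[i].chrom, lo, hi
            )
            if conc is not None and conc >= min_concordance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[ROHSegment]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(segs[i])
    groups = [ROHGroup(segments=members) for members in clusters.values()]
    groups.sort(key=lambda grp: (grp.chrom, grp.consensus_start, grp.consensus_end))
    return groups


def pooled_roh_track(groups: list[ROHGroup], bin_bp: int = 1_000_000) -> WindowTrack:
    """Per bin, count of distinct samples with an overlapping ROH segment."""
    segs = [s for grp in groups for s in grp.segments]
    rows = []
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        members = by_chrom[chrom]
        last_bin = max(s.end - 1 for s in members) // bin_bp
        counts = np.zeros(last_bin + 1, dtype=int)
        for k in range(last_bin + 1):
            lo, hi = k * bin_bp, (k + 1) * bin_bp
            counts[k] = len(
                {s.sample for s in members if s.start < hi and s.end > lo}
            )
        for k, c in enumerate(counts):
            rows.append(
                {
                    "chrom": chrom,
                    "start": k * bin_bp,
                    "end": (k + 1) * bin_bp,
                    "n_sites": int(c),
                    "value": float(c),
                }
            )
    return WindowTrack(
        df=pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "value"]),
        statistic="pooled_roh",
        meta={"bin_bp": bin_bp},
    )


def segments_to_bed(segments: list[ROHSegment], path):
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda x: (x.chrom, x.start, x.end, x.sample)):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sample}\t{s.n_sites}\n")
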