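"""Interval layer: top-percentile extraction, merging, annotation overlap
and multi-signal collocation.

Every scan track funnels into labelled genomic intervals here.  Labels
come from a closed vocabulary (FST, ROD, IOD, SWEEP, LD, ROH, SNPLIST);
regions only ever merge within a label, and "feature-rich" super-intervals
are the places where several labels co-occur.  All coordinates are
0-based half-open (BED semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from domscan.tracks import WindowTrack

logger = logging.getLogger("domscan")

LABELS = frozenset({"FST", "ROD", "IOD", "SWEEP", "LD", "ROH", "SNPLIST"})


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    label: str
    score: float = float("nan")
    provenance: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if self.label not in LABELS:
            raise ValueError(f"unknown region label {self.label!r}")

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def top_percentile_regions(
    track: WindowTrack, percentile: float = 99.0, tail: str = "upper", label: str = "FST"
) -> list[Region]:
    """Windows beyond the percentile cutoff, unioned where they overlap.

    ``tail="upper"`` selects windows with value strictly above the
    ``percentile``-th percentile of the defined windows; ``tail="lower"``
    selects strictly below the (100 - percentile)-th.  An all-identical
    track selects nothing (with a warning).  Undefined (NaN) windows never
    participate.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    defined = track.defined
    if len(defined) < 100:
        logger.warning(
            "top_percentile_regions: only %d defined windows (<100)", len(defined)
        )
    vals = defined["value"].to_numpy()
    if len(vals) == 0:
        return []
    if tail == "upper":
        cutoff = np.percentile(vals, percentile)
        sel = defined[defined["value"] > cutoff]
    else:
        cutoff = np.percentile(vals, 100.0 - percentile)
        sel = defined[defined["value"] < cutoff]
    if len(sel) == 0:
        logger.warning("top_percentile_regions: empty selection (flat track?)")
        return []
    out = []
    for chrom, sub in sel.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        cur_s, cur_e, cur_v = None, None, -np.inf
        for _, row in sub.iterrows():
            if cur_s is None:
                cur_s, cur_e, cur_v = row["start"], row["end"], row["value"]
            elif row["start"] < cur_e:  # overlapping selected windows union
                cur_e = max(cur_e, row["end"])
                cur_v = max(cur_v, row["value"]) if tail == "upper" else min(cur_v, row["value"])
            else:
                out.append(Region(str(chrom), int(cur_s), int(cur_e), label, float(cur_v), track.statistic))
                cur_s, cur_e, cur_v = row["start"], row["end"], row["value"]
        out.append(Region(str(chrom), int(cur_s), int(cur_e), label, float(cur_v), track.statistic))
    return out


def merge_regions(regions: list[Region], max_gap_bp: int = 1_000_000) -> list[Region]:
    """Union same-chromosome same-label regions separated by < ``max_gap_bp``.

    The gap rule is strict: a gap exactly equal to ``max_gap_bp`` does not
    merge.  Scores combine by max; output is sorted and non-overlapping
    per label.  Idempotent and input-order invariant.
    """
    out = []
    by_key: dict[tuple, list[Region]] = {}
    for r in regions:
        by_key.setdefault((r.chrom, r.label), []).append(r)
    for (chrom, label), rs in sorted(by_key.items()):
        rs = sorted(rs, key=lambda r: (r.start, r.end))
        cur = rs[0]
        for r in rs[1:]:
            if r.start - cur.end < max_gap_bp:
                scores = [s for s in (cur.score, r.score) if np.isfinite(s)]
                cur = Region(
                    chrom,
                    cur.start,
                    max(cur.end, r.end),
                    label,
                    max(scores) if scores else float("nan"),
                    cur.provenance or r.provenance,
                )
            else:
                out.append(cur)
                cur = r
        out.append(cur)
    out.sort(key=lambda r: (r.chrom, r.start, r.end, r.label))
    return out


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path) -> pd.DataFrame:
    """Read gene intervals from GFF3 or BED into (chrom, start, end, gene).

    GFF3: features of type ``gene`` (fallback: every feature) with the ID
    attribute as name; 1-based closed coordinates converted to BED.
    BED: first four columns, already 0-based half-open.
    """
    path = str(path)
    rows = []
    if path.endswith((".gff", ".gff3")):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{f[3]}"
                rows.append((f[0], int(f[3]) - 1, int(f[4]), name, f[2]))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "type"])
        genes = df[df["type"] == "gene"]
        if len(genes):
            df = genes
        return df[["chrom", "start", "end", "gene"]].reset_index(drop=True)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            rows.append((f[0], int(f[1]), int(f[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def intersect_annotation(
    regions: list[Region], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Genes overlapping each region by >= 1 bp (half-open intervals).

    Raises when the annotation and the regions share no chromosome names
    (assembly naming mismatch).  Returns one row per (region, gene) hit
    plus per-region counts accessible by grouping.
    """
    region_chroms = {r.chrom for r in regions}
    anno_chroms = set(annotation["chrom"].astype(str))
    if regions is not None and region_chroms and not (region_chroms & anno_chroms):
        raise ValueError(
            f"no shared chromosome names between regions {sorted(region_chroms)} "
            f"and annotation {sorted(anno_chroms)[:9]}"
        )
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annotation.groupby("chrom", sort=False):
        t = IntervalTree()
        for _, row in sub.iterrows():
            if row["end"] > row["start"]:
                t.addi(int(row["start"]), int(row["end"]), row["gene"])
        trees[str(chrom)] = t
    rows = []
    for r in regions:
        hits = trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end)
        for h in sorted(hits):
            rows.append(
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "label": r.label,
                    "gene": h.data,
                    "gene_start": h.begin,
                    "gene_end": h.end,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "label", "gene", "gene_start", "gene_end"],
    )


# ---------------------------------------------------------------------------
# collocation


def snp_list_regions(snp_list: pd.DataFrame, label: str = "SNPLIST") -> list[Region]:
    """Externally supplied SNPs (chrom, pos 1-based) as 1-bp point regions."""
    return [
        Region(str(r["chrom"]), int(r["pos"]) - 1, int(r["pos"]), label)
        for _, r in snp_list.iterrows()
    ]


def collocate(
    all_regions: dict[str, list[Region]],
    snp_lists: pd.DataFrame | None = None,
    min_labels: int = 3,
    max_gap_bp: int = 1_000_000,
    min_overlap_fraction: float = 0.0,
) -> pd.DataFrame:
    """Cross-label overlap report and multi-signal super-intervals.

    Per-label regions are merged first (gap < ``max_gap_bp``), then the
    union of all labels is flattened into super-intervals (>= 1 bp overlap
    chains them); super-intervals carrying at least ``min_labels`` distinct
    labels are reported with member labels, per-label counts and spans.
    ``snp_lists`` adds point features under the SNPLIST label.
    A ``min_overlap_fraction`` > 0 additionally requires each member to
    overlap the super-interval by that fraction of the member's length.
    """
    if len(all_regions) < 2 and snp_lists is None:
        raise ValueError("collocation needs at least two labels")
    merged: list[Region] = []
    for label, regs in all_regions.items():
        merged.extend(merge_regions(list(regs), max_gap_bp=max_gap_bp))
    if snp_lists is not None and len(snp_lists):
        merged.extend(snp_list_regions(snp_lists))
    rows = []
    by_chrom: dict[str, list[Region]] = {}
    for r in merged:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cluster: list[Region] = []
        hi = -1
        for r in rs + [None]:
            if r is not None and (not cluster or r.start < hi):
                cluster.append(r)
                hi = max(hi, r.end)
                continue
            if cluster:
                lo = min(m.start for m in cluster)
                chi = max(m.end for m in cluster)
                members = [
                    m
                    for m in cluster
                    if min_overlap_fraction <= 0
                    or (min(m.end, chi) - max(m.start, lo)) / (m.end - m.start)
                    >= min_overlap_fraction
                ]
                labels = sorted({m.label for m in members})
                rows.append(
                    {
                        "chrom": chrom,
                        "start": lo,
                        "end": chi,
                        "n_labels": len(labels),
                        "labels": ",".join(labels),
                        "label_counts": ";".join(
                            f"{lab}={sum(m.label == lab for m in members)}"
                            for lab in labels
                        ),
                    }
                )
            if r is None:
                break
            cluster = [r]
            hi = r.end
    report = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_labels", "labels", "label_counts"]
    )
    return report[report["n_labels"] >= min_labels].reset_index(drop=True)


def regions_to_bed(regions: list[Region], path):
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda x: (x.chrom, x.start, x.end, x.label)):
            score = 0.0 if not np.isfinite(r.score) else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{score:.6g}\n")


def regions_from_bed(path, label=None) -> list[Region]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                Region(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    label or (f[3] if len(f) > 3 else "FST"),
                    float(f[4]) if len(f) > 4 else float("nan"),
                )
            )
    return out
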