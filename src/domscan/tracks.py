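"""Per-window statistic tracks with genomic coordinates.

A :class:`WindowTrack` is the common currency between the scan modules
(pi, ROD, Fst, local LD, CLR, pooled ROH) and the interval layer in
:mod:`domscan.regions`.  Coordinates are 0-based half-open throughout;
VCF 1-based positions are converted exactly once, at window construction,
via :func:`pos_to_bed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["chrom", "start", "end", "n_sites", "value"]


def pos_to_bed(pos):
    """Convert a 1-based VCF position to the 0-based BED start of that base.

    The single place in the package where the two coordinate conventions
    meet: base at VCF position p occupies the BED interval [p-1, p).
    """
    return np.asarray(pos) - 1


@dataclass
class WindowTrack:
    """Sorted per-window values of one statistic.

    df columns: chrom, start, end (0-based half-open), n_sites, value.
    Windows with an undefined statistic carry NaN and are excluded from
    percentile extraction downstream.
    """

    df: pd.DataFrame
    statistic: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"WindowTrack missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if len(df):
            if not (df["start"] < df["end"]).all():
                raise ValueError("window start must be < end")
            order = df.sort_values(["chrom", "start", "end"], kind="stable").index
            if not np.array_equal(order.to_numpy(), np.arange(len(df))):
                df = df.loc[order].reset_index(drop=True)
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def defined(self) -> pd.DataFrame:
        """Windows where the statistic has a value."""
        return self.df[np.isfinite(self.df["value"])]

    def same_grid(self, other: "WindowTrack") -> bool:
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        return (
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and np.array_equal(a["start"].to_numpy(), b["start"].to_numpy())
            and np.array_equal(a["end"].to_numpy(), b["end"].to_numpy())
        )

    def to_tsv(self, path, extra_header: dict | None = None):
        header = dict(self.meta)
        if extra_header:
            header.update(extra_header)
        with open(path, "w") as fh:
            fh.write(f"# statistic={self.statistic}\n")
            for k, v in header.items():
                fh.write(f"# {k}={v}\n")
            self.df.to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, statistic: str | None = None) -> "WindowTrack":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", na_values=["NA"])
        stat = statistic or meta.pop("statistic", "value")
        return cls(df=df, statistic=stat, meta=meta)
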