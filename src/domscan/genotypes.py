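"""SNP genotype cohort: loading, filtering, summaries and relatedness.

The central container is :class:`GenotypeMatrix` — a samples x sites matrix
of alternate-allele dosages (0/1/2, missing encoded as -1) with per-site
records (chromosome, 1-based position, ref/alt base) and per-sample records
(id, subpopulation label).  Every statistic in the package operates on it
with sitewise/pairwise deletion of missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from domscan.tracks import WindowTrack, pos_to_bed

logger = logging.getLogger("domscan")

#: Sentinel for a missing diploid call, distinct from the dosages {0, 1, 2}.
MISSING = -1

#: Subpopulation label for samples without an assignment.
UNASSIGNED = "unassigned"

_BASES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix with site and sample metadata.

    Parameters
    ----------
    calls
        int8 array of shape (S samples, L sites); values 0, 1, 2 or
        :data:`MISSING`.
    sites
        DataFrame with columns chrom, pos (1-based), ref, alt; positions
        strictly increasing within each chromosome.
    samples
        DataFrame with columns sample, subpop.
    """

    calls: np.ndarray
    sites: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self):
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x sites)")
        S, L = self.calls.shape
        if L < 1:
            raise ValueError("at least one site required")
        if len(self.sites) != L or len(self.samples) != S:
            raise ValueError("metadata shape mismatch with calls")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid call values {bad}")
        if self.samples["sample"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ValueError("ref == alt at some site")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample"].tolist()

    @property
    def subpop_labels(self) -> list[str]:
        """Distinct assigned subpopulation labels, in order of appearance."""
        labels = self.samples["subpop"]
        return [s for s in labels.unique() if s != UNASSIGNED]

    def group_indices(self, group) -> np.ndarray:
        """Sample row indices for a group selector.

        ``group`` may be ``"all"``, a subpopulation label, an iterable of
        labels, or ``("rest", focal_label)`` for every *assigned* sample
        outside the focal subpopulation.
        """
        labels = self.samples["subpop"].to_numpy()
        if isinstance(group, str):
            if group == "all":
                return np.arange(self.n_samples)
            if group not in set(labels):
                raise KeyError(f"unknown subpopulation label {group!r}")
            return np.flatnonzero(labels == group)
        group = tuple(group)
        if len(group) == 2 and group[0] == "rest":
            focal = group[1]
            if focal not in set(labels):
                raise KeyError(f"unknown subpopulation label {focal!r}")
            return np.flatnonzero((labels != focal) & (labels != UNASSIGNED))
        known = set(labels)
        for g in group:
            if g not in known:
                raise KeyError(f"unknown subpopulation label {g!r}")
        return np.flatnonzero(np.isin(labels, group))

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            calls=self.calls[:, index],
            sites=self.sites.iloc[index],
            samples=self.samples,
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            calls=self.calls[index],
            sites=self.sites,
            samples=self.samples.iloc[index],
        )

    def site_ids(self) -> pd.Index:
        return pd.Index(
            self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)
        )


# ---------------------------------------------------------------------------
# loading


def read_subpop_map(path) -> pd.DataFrame:
    """Read a two-column sample -> subpopulation TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError("subpop map needs two columns: sample, subpop")
    df = df.iloc[:, :2]
    df.columns = ["sample", "subpop"]
    if df.iloc[0]["sample"].lower() == "sample":
        df = df.iloc[1:].reset_index(drop=True)
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in subpop map")
    return df


def load_vcf(path, subpop_map=None) -> GenotypeMatrix:
    """Load a multi-sample diploid VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records (single-base A/C/G/T ref and alt) are
    retained; indels and multiallelic records are dropped and counted.
    Genotypes are encoded as alternate-allele dosage from the GT field.

    Parameters
    ----------
    path
        VCF v4.2 file, plain or bgzipped.
    subpop_map
        Optional path to a sample -> subpopulation TSV.  Samples named in
        the map but absent from the VCF raise; VCF samples absent from the
        map are labelled :data:`UNASSIGNED`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in VCF")

    chroms, positions, refs, alts, rows = [], [], [], [], []
    n_dropped = 0
    for v in vcf:
        alt = v.ALT
        if (
            len(alt) != 1
            or v.REF not in _BASES
            or alt[0] not in _BASES
            or v.REF == alt[0]
        ):
            n_dropped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(alt[0])
    vcf.close()
    if n_dropped:
        logger.info("load_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")

    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": refs, "alt": alts})
    calls = np.stack(rows, axis=1)

    dup = sites.duplicated(subset=["chrom", "pos"])
    if dup.any():
        logger.warning("load_vcf: dropped %d duplicate-position records", dup.sum())
        keep = ~dup.to_numpy()
        sites, calls = sites[keep], calls[:, keep]

    subpops = pd.Series(UNASSIGNED, index=sample_ids, dtype=object)
    if subpop_map is not None:
        mapping = read_subpop_map(subpop_map)
        unknown = set(mapping["sample"]) - set(sample_ids)
        if unknown:
            raise ValueError(f"subpop map names samples not in VCF: {sorted(unknown)}")
        subpops.loc[mapping["sample"]] = mapping["subpop"].to_numpy()
    samples = pd.DataFrame({"sample": sample_ids, "subpop": subpops.to_numpy()})

    return GenotypeMatrix(calls=calls, sites=sites, samples=samples)


# ---------------------------------------------------------------------------
# per-site summaries and filtering


def _allele_stats(calls: np.ndarray):
    """Return (n_non_missing, alt_freq, het_fraction, missingness) per site.

    alt_freq / het are NaN for sites with no non-missing call.
    """
    nm = calls != MISSING
    n_nm = nm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(nm, calls, 0).sum(axis=0)
        af = np.where(n_nm > 0, alt / (2.0 * n_nm), np.nan)
        het = np.where(n_nm > 0, (calls == 1).sum(axis=0) / n_nm, np.nan)
    missingness = 1.0 - n_nm / calls.shape[0]
    return n_nm, af, het, missingness


def site_summaries(gm: GenotypeMatrix, group="all") -> pd.DataFrame:
    """Per-site missingness, heterozygosity and minor allele frequency.

    MAF is computed from allele counts among non-missing calls; for a site
    with every call missing, heterozygosity and maf are NaN (undefined) and
    missingness is 1.  Pass a subpopulation label as ``group`` to stratify.
    """
    idx = gm.group_indices(group)
    n_nm, af, het, missingness = _allele_stats(gm.calls[idx])
    maf = np.minimum(af, 1.0 - af)
    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "missingness": missingness,
            "heterozygosity": het,
            "maf": maf,
            "n_non_missing": n_nm,
        }
    )


def filter_sites(
    gm: GenotypeMatrix, max_missing: float = 0.10, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Retain sites with missingness <= ``max_missing`` and MAF >= ``min_maf``.

    Site order is preserved and removal counts per criterion are logged.
    Raises if no site survives.
    """
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must be in [0, 1]")
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    _, af, _, missingness = _allele_stats(gm.calls)
    maf = np.minimum(af, 1.0 - af)
    miss_ok = missingness <= max_missing
    with np.errstate(invalid="ignore"):
        maf_ok = maf >= min_maf  # NaN maf (all-missing site) fails
    keep = miss_ok & np.where(np.isnan(maf), False, maf_ok)
    logger.info(
        "filter_sites: removed %d by missingness > %g, %d by maf < %g; retained %d/%d",
        int((~miss_ok).sum()),
        max_missing,
        int((miss_ok & ~np.where(np.isnan(maf), False, maf_ok)).sum()),
        min_maf,
        int(keep.sum()),
        gm.n_sites,
    )
    if not keep.any():
        raise ValueError(
            f"all sites removed (max_missing={max_missing}, min_maf={min_maf})"
        )
    return gm.take_sites(keep)


# ---------------------------------------------------------------------------
# identity by state


@dataclass
class IBSMatrix:
    """Pairwise identity-by-state probabilities.

    values[i, j] is the mean per-locus allele-sharing score over loci where
    both samples are called: identical homozygotes score 1, opposite
    homozygotes 0, and any pairing involving a heterozygote 0.5 per
    differing dosage step — score = (2 - |dosage_i - dosage_j|) / 2.
    Pairs with no jointly called locus are NaN.
    """

    values: np.ndarray
    n_loci: np.ndarray
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")


def ibs_matrix(gm: GenotypeMatrix) -> IBSMatrix:
    """Pairwise IBS similarity over all jointly non-missing loci.

    The per-locus score (2 - |d_i - d_j|)/2 reproduces the three diploid
    anchor cases: hom/same-hom = 1, hom/opposite-hom = 0, hom/het = 0.5
    (and het/het = 1, the distance-matrix convention for unphased dosages).
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = gm.calls
    onehot = [(calls == d) for d in (0, 1, 2)]
    # C[a][b][i, j] = number of loci where sample i has dosage a and j has b
    num = np.zeros((gm.n_samples, gm.n_samples))
    den = np.zeros_like(num)
    for a in range(3):
        Aa = onehot[a].astype(np.float64)
        for b in range(3):
            C = Aa @ onehot[b].astype(np.float64).T
            num += (2 - abs(a - b)) / 2.0 * C
            den += C
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    n_zero = int((den[np.triu_indices_from(den, k=1)] == 0).sum())
    if n_zero:
        logger.warning("ibs_matrix: %d pairs share no called locus", n_zero)
    return IBSMatrix(values=values, n_loci=den.astype(np.int64), sample_ids=gm.sample_ids)


# ---------------------------------------------------------------------------
# subpopulation allele partitioning, base composition, density


@dataclass
class AllelePartition:
    """Per-subpopulation polymorphic-site sets and their set arithmetic."""

    sets: dict  # label -> frozenset of site ids
    n_samples: dict  # label -> accession count
    shared_all: int = field(init=False)
    pairwise: pd.DataFrame = field(init=False)
    unique_per_accession: dict = field(init=False)

    def __post_init__(self):
        labels = list(self.sets)
        common = set.intersection(*(set(s) for s in self.sets.values())) if labels else set()
        self.shared_all = len(common)
        rows = []
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                A, B = self.sets[a], self.sets[b]
                rows.append(
                    {
                        "a": a,
                        "b": b,
                        "union": len(A | B),
                        "intersection": len(A & B),
                        "a_minus_b": len(A - B),
                        "b_minus_a": len(B - A),
                    }
                )
        self.pairwise = pd.DataFrame(
            rows, columns=["a", "b", "union", "intersection", "a_minus_b", "b_minus_a"]
        )
        self.unique_per_accession = {}
        for a in labels:
            others = set().union(*(self.sets[b] for b in labels if b != a))
            private = len(self.sets[a] - others)
            self.unique_per_accession[a] = private / self.n_samples[a]


def allele_partition(
    gm: GenotypeMatrix, per_subpop_min_maf: float = 0.05, subpops=None
) -> AllelePartition:
    """Partition polymorphic sites by subpopulation.

    For each subpopulation, sites polymorphic at within-group
    MAF > ``per_subpop_min_maf`` (strict, per the usual "MAF > 5%" rule)
    form its set; union/intersection/difference counts and the count of
    private sites per accession are derived.
    """
    labels = subpops if subpops is not None else gm.subpop_labels
    sets, n_samples = {}, {}
    ids = gm.site_ids()
    for label in labels:
        idx = gm.group_indices(label)
        if len(idx) < 2:
            raise ValueError(f"subpopulation {label!r} has fewer than 2 samples")
        _, af, _, _ = _allele_stats(gm.calls[idx])
        maf = np.minimum(af, 1.0 - af)
        with np.errstate(invalid="ignore"):
            poly = np.where(np.isnan(maf), False, maf > per_subpop_min_maf)
        sets[label] = frozenset(ids[poly])
        n_samples[label] = len(idx)
    return AllelePartition(sets=sets, n_samples=n_samples)


def at_composition(gm: GenotypeMatrix, by_subpop: bool = True, weighted: bool = True):
    """A/T base-composition share of each group's polymorphic sites.

    Default mode weights each site's ref and alt allele by its within-group
    frequency, averaging the A/T share across polymorphic sites; the
    unweighted mode counts each allele of each polymorphic site once.
    Groups with no polymorphic site get NaN with a warning.
    """
    groups = gm.subpop_labels if by_subpop else ["all"]
    is_at_ref = gm.sites["ref"].isin(["A", "T"]).to_numpy(dtype=float)
    is_at_alt = gm.sites["alt"].isin(["A", "T"]).to_numpy(dtype=float)
    out = {}
    for label in groups:
        idx = gm.group_indices(label)
        _, af, _, _ = _allele_stats(gm.calls[idx])
        with np.errstate(invalid="ignore"):
            poly = np.where(np.isnan(af), False, (af > 0) & (af < 1))
        if not poly.any():
            logger.warning("at_composition: group %r has no polymorphic sites", label)
            out[label] = np.nan
            continue
        if weighted:
            share = (1 - af[poly]) * is_at_ref[poly] + af[poly] * is_at_alt[poly]
        else:
            share = 0.5 * (is_at_ref[poly] + is_at_alt[poly])
        out[label] = float(np.mean(share))
    return out


def snp_density(gm: GenotypeMatrix, bin_bp: int = 1_000_000) -> WindowTrack:
    """Marker count per non-overlapping ``bin_bp`` bin along each chromosome.

    Bins are half-open [k*bin_bp, (k+1)*bin_bp) in 0-based coordinates;
    bins from zero through the last occupied bin are emitted (interior
    empty bins count 0); chromosomes without sites emit nothing.
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    rows = []
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        b = pos_to_bed(sub["pos"].to_numpy()) // bin_bp
        counts = np.bincount(b)
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
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "value"])
    return WindowTrack(df=df, statistic="snp_density", meta={"bin_bp": bin_bp})
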