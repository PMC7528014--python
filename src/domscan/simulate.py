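"""Synthetic GBS-style cohort generator.

The generator emulates the statistical structure the scan modules assume,
at the scale of a real genotyping-by-sequencing crop panel:

* subpopulations diverging from shared ancestral allele frequencies under
  the Balding-Nichols model (subpopulation frequency ~ Beta with mean p
  and variance F p (1-p)), which gives direct control of the expected Fst;
* within-subpopulation inbreeding F_IS, so sample heterozygosity at a
  site with subpopulation frequency q is 2 q (1-q) (1-F_IS);
* distance-decaying linkage disequilibrium from a latent first-order
  autoregressive Gaussian per haplotype, with site-to-site correlation
  exp(-delta_bp / d0);
* planted features: selective sweeps (focal-subpopulation frequencies
  pushed to near fixation inside an interval) and per-sample homozygous
  tracts; and
* independent site/sample missingness, applied last.

Default rates mirror the cohort the pipeline targets: four
subpopulations, ~3% missingness and ~16% heterozygosity, SNP density of
about 65 markers per Mbp.  Everything is reproducible from the seed;
the same config yields a byte-identical VCF.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from domscan.genotypes import MISSING, UNASSIGNED, GenotypeMatrix

_ANCESTRAL_LO, _ANCESTRAL_HI = 0.05, 0.95


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic cohort.

    Planted sweeps are (subpop, chrom, start, end, strength) with 0-based
    half-open bp intervals; ``strength`` is how close to fixation the
    focal frequencies are pushed (0.02 leaves frequencies within 2% of 0
    or 1).  Planted ROH are (sample, chrom, start, end) and overwrite the
    sample's calls with the subpopulation-major homozygote.
    """

    subpopulations: list = field(
        default_factory=lambda: [
            ("calabrese_hybrid", 30),
            ("calabrese_landrace", 40),
            ("sprouting", 25),
            ("violet_cauliflower", 14),
        ]
    )
    chromosomes: dict = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000}
    )
    sites_per_mbp: float = 65.0
    fst: float | dict = 0.2
    f_is: float | dict = 0.45
    missing_rate: float = 0.03
    ld_decay_bp: float = 500.0
    sweeps: list = field(default_factory=list)  # (subpop, chrom, start, end, strength)
    roh: list = field(default_factory=list)  # (sample, chrom, start, end)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must be in [0, 1]")
        for f in self._per_subpop(self.fst).values():
            if not (0 < f < 1):
                raise ValueError("fst must be in (0, 1)")
        for f in self._per_subpop(self.f_is).values():
            if not (0 <= f <= 1):
                raise ValueError("f_is must be in [0, 1]")
        for sp, chrom, start, end, strength in self.sweeps:
            self._check_interval(chrom, start, end)
            if not (0 < strength <= 1):
                raise ValueError("sweep strength must be in (0, 1]")
        for sample, chrom, start, end in self.roh:
            self._check_interval(chrom, start, end)

    def _check_interval(self, chrom, start, end):
        if chrom not in self.chromosomes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.chromosomes[chrom]):
            raise ValueError(f"interval {chrom}:{start}-{end} outside chromosome")

    def _per_subpop(self, value) -> dict:
        labels = [lab for lab, _ in self.subpopulations]
        if isinstance(value, dict):
            return {lab: float(value.get(lab, 0.2)) for lab in labels}
        return {lab: float(value) for lab in labels}

    @property
    def sample_table(self) -> pd.DataFrame:
        rows = []
        for lab, n in self.subpopulations:
            for i in range(n):
                rows.append({"sample": f"{lab}_{i:03d}", "subpop": lab})
        return pd.DataFrame(rows)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("subpopulations", "sweeps", "roh"):
            if key in raw and raw[key]:
                raw[key] = [tuple(x) for x in raw[key]]
        return cls(**raw)


def simulate_cohort(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a full cohort from a :class:`SimConfig`.

    Order of operations: ancestral frequencies -> Balding-Nichols
    subpopulation frequencies -> sweep planting (on frequencies) ->
    correlated haplotype draws with inbreeding -> ROH planting (on calls)
    -> missingness masking.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_table
    fst = cfg._per_subpop(cfg.fst)
    f_is = cfg._per_subpop(cfg.f_is)
    sample_rows = {s: i for i, s in enumerate(samples["sample"])}

    all_sites, call_blocks = [], []
    for chrom in sorted(cfg.chromosomes):
        length = cfg.chromosomes[chrom]
        n_sites = max(2, int(round(cfg.sites_per_mbp * length / 1e6)))
        pos = np.sort(
            rng.choice(np.int64(length), size=n_sites, replace=False).astype(np.int64)
        ) + 1
        p_anc = rng.uniform(_ANCESTRAL_LO, _ANCESTRAL_HI, n_sites)
        ref_alt = np.array(
            [rng.permutation(["A", "C", "G", "T"])[:2] for _ in range(n_sites)]
        )
        all_sites.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": ref_alt[:, 0], "alt": ref_alt[:, 1]}
            )
        )
        # latent AR(1) site-to-site correlation
        rho = np.exp(-np.diff(pos) / cfg.ld_decay_bp)

        chrom_calls = np.empty((len(samples), n_sites), dtype=np.int8)
        row = 0
        for lab, n_samp in cfg.subpopulations:
            F = fst[lab]
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            q = rng.beta(a, b)
            q = np.clip(q, 1e-6, 1 - 1e-6)
            # plant sweeps: push focal frequencies to near fixation
            for sp, s_chrom, s_start, s_end, strength in cfg.sweeps:
                if sp != lab or s_chrom != chrom:
                    continue
                inside = (pos - 1 >= s_start) & (pos - 1 < s_end)
                u = rng.uniform(0, strength, inside.sum())
                q[inside] = np.where(q[inside] >= 0.5, 1 - u, u)
            thresh = norm.ppf(q)
            z = _ar1_chains(rng, rho, n_sites, 2 * n_samp)
            alleles = (z < thresh[None, :]).astype(np.int8)
            a1, a2 = alleles[:n_samp], alleles[n_samp:]
            ibd = rng.random((n_samp, n_sites)) < f_is[lab]
            chrom_calls[row : row + n_samp] = a1 + np.where(ibd, a1, a2)
            row += n_samp
        # plant ROH: overwrite with the subpopulation-major homozygote
        for sample, r_chrom, r_start, r_end in cfg.roh:
            if r_chrom != chrom:
                continue
            r = sample_rows[sample]
            inside = (pos - 1 >= r_start) & (pos - 1 < r_end)
            major = (p_anc[inside] >= 0.5).astype(np.int8) * 2
            chrom_calls[r, inside] = major
        call_blocks.append(chrom_calls)

    calls = np.concatenate(call_blocks, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    sites = pd.concat(all_sites, ignore_index=True)
    return GenotypeMatrix(calls=calls, sites=sites, samples=samples)


def _ar1_chains(rng, rho: np.ndarray, n_sites: int, n_chains: int) -> np.ndarray:
    """Stationary AR(1) latent chains, one row per haplotype."""
    eps = rng.standard_normal((n_chains, n_sites))
    z = np.empty((n_chains, n_sites))
    z[:, 0] = eps[:, 0]
    innov = np.sqrt(1.0 - rho**2)
    for i in range(1, n_sites):
        z[:, i] = rho[i - 1] * z[:, i - 1] + innov[i - 1] * eps[:, i]
    return z


def expected_statistics(cfg: SimConfig) -> dict:
    """Closed-form expectations implied by a config (test oracles).

    * heterozygosity per subpop: 2 E[p(1-p)] (1-F) (1-F_IS) with
      E[p(1-p)] from the Uniform(0.05, 0.95) ancestral draw;
    * pooled Fst between subpops ~ F (equal F per subpop);
    * per-subpop pi ~ 2 E[p(1-p)] (1-F) (unaffected by F_IS, which only
      redistributes alleles within individuals);
    * r2(d) ~ exp(-2 d / d0), the squared latent AR correlation — an
      approximation for thresholded Gaussians, validated by simulation.
    """
    lo, hi = _ANCESTRAL_LO, _ANCESTRAL_HI
    var = (hi - lo) ** 2 / 12.0
    e_p1p = 0.25 - var  # E[p] = 0.5 for the symmetric uniform
    fst = cfg._per_subpop(cfg.fst)
    f_is = cfg._per_subpop(cfg.f_is)
    het = {lab: 2 * e_p1p * (1 - fst[lab]) * (1 - f_is[lab]) for lab in fst}
    pi = {lab: 2 * e_p1p * (1 - fst[lab]) for lab in fst}

    def r2(d):
        return np.exp(-2.0 * np.asarray(d, dtype=float) / cfg.ld_decay_bp)

    return {
        "heterozygosity": het,
        "pi": pi,
        "fst": dict(fst),
        "r2_curve": r2,
        "missing_rate": cfg.missing_rate,
    }


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(gm: GenotypeMatrix, path):
    """Write a minimal GT-only VCF v4.2; round-trips through load_vcf.

    Output is deterministic for a given matrix (no timestamps), so the
    same simulation seed yields a byte-identical file.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in gm.sites["chrom"].unique():
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
        + "\n"
    )
    sites = gm.sites
    for j in range(gm.n_sites):
        gts = "\t".join(gt_str[int(g)] for g in gm.calls[:, j])
        buf.write(
            f"{sites['chrom'].iat[j]}\t{sites['pos'].iat[j]}\t.\t"
            f"{sites['ref'].iat[j]}\t{sites['alt'].iat[j]}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_subpop_map(gm: GenotypeMatrix, path):
    gm.samples.to_csv(path, sep="\t", index=False)


def write_truth_bed(cfg: SimConfig, path):
    """BED of planted features (sweeps and ROH) for recovery checks."""
    with open(path, "w") as fh:
        for sp, chrom, start, end, strength in cfg.sweeps:
            fh.write(f"{chrom}\t{start}\t{end}\tSWEEP:{sp}\t{strength}\n")
        for sample, chrom, start, end in cfg.roh:
            fh.write(f"{chrom}\t{start}\t{end}\tROH:{sample}\t.\n")
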