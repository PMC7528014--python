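# Methods

This note documents the models behind each scan, the defaults and why
they are set where they are, what the synthetic cohorts do and do not
emulate, and the numerical choices made where the design was open.

## Genotype model and missing data

All statistics operate on a samples × sites matrix of alternate-allele
dosages (0/1/2) with a single missing sentinel. Missing calls are handled
by sitewise or pairwise deletion everywhere — a pair's IBS average, a
site's allele frequencies, an r² correlation and the F_ST components each
use only the calls actually observed for that computation. No imputation
or phasing is performed; every statistic is defined on unphased genotypes.

Coordinates: VCF positions are 1-based; every exported interval (window
tracks, BED, regions) is 0-based half-open. The conversion lives in one
function (`tracks.pos_to_bed`) so the two conventions meet exactly once.

## Nucleotide diversity and ROD

Per-site π is the mean pairwise difference between the m non-missing
alleles at the site (two per called diploid): with alternate frequency p,
π = 2p(1−p)·m/(m−1). This is the unbiased sample form of Nei's
Σ xᵢxⱼ πᵢⱼ and equals exhaustive enumeration over all m(m−1)/2 allele
pairs (tested to 1e−12). A plug-in 2p(1−p) mode exists behind a flag for
sensitivity checks.

Windows are marker-count windows (default 10 markers, step 5) restarted
per chromosome; a chromosome with fewer markers than the window yields a
single truncated window. When the final markers would otherwise be
uncovered, one trailing full-size window anchored at the chromosome end is
added. The window's physical span runs from the first to the last
contained marker so marker-count windows can be intersected with physical
tracks downstream.

ROD = π_focal/π_reference per window (undefined where the reference is
zero), plus the genome-wide ratio Σπ_focal/Σπ_reference. Both tails of the
window distribution are extracted: the bottom percentile as ROD
(reduction) regions and the top percentile as IOD (enrichment) regions.
The reference group selector is explicit — "all other assigned samples" by
default, but any group expression works — because which samples belong in
the reference pool is a study-design decision, not a package decision.

## Weir–Cockerham F_ST

Per site the two-population variance components a (among populations),
b (among individuals within populations) and c (within individuals) follow
Weir & Cockerham (1984), computed from per-population sample sizes, allele
frequencies and observed heterozygosities. Windowed and pooled estimates
are always the ratio of sums Σa/Σ(a+b+c) — never the mean of per-site
ratios, which is biased by low-information sites; a dedicated test
distinguishes the two on an asymmetric example. Negative per-site
components are retained in the sums (standard for ratio-of-sums
estimators) and only clamped in displayed per-site tables. Windows are
physical (default 1 Mbp span, 1 kbp step) anchored at step multiples from
position zero of each chromosome. Only two-population comparisons are
exposed; the scan contrasts the focal subpopulation against the rest, and
pooled values are reported for every subpopulation pair.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors over jointly
called samples — composite (genotype) LD, the correct notion for unphased
data. Pairs are restricted to the same chromosome within 1 Mbp.

The decay distance fits a cubic smoothing spline to (log₁₀ distance, r²):
values sharing a distance are averaged with weight √count, and the default
smoothing budget is set from a first-difference estimate of the local
noise variance (half the mean squared successive difference of the
per-distance means, times the number of distinct distances). This is a
GCV-like default; the parameter is exposed because the R notion of
`spar` does not port. The decay distance is the smallest distance in the
observed range at which the fitted curve drops below the threshold
(default r² = 0.2); a curve that never crosses is reported censored. By
construction the estimate is monotone in the threshold.

Pruning follows the "indep-pairwise" convention with window 50 kbp /
step 1 kbp / r² > 0.25 — note the window ≥ step orientation; tool
write-ups sometimes print the two numbers swapped. Because the step
divides the window, every same-window pair is visited by a simple greedy
left-to-right scan: the lower-MAF member of an offending pair is removed,
ties dropping the later position. The local LD track assigns each pair to
the 1 Mbp window containing its midpoint (an arbitrary but documented
choice) and reports mean r².

## CLR sweep scan

The scan implements the SweepFinder model class on the folded SFS, not a
byte-level clone of any particular tool. The genome-wide folded spectrum
of the scanned group is the null. At distance d from a putative sweep with
intensity α, each sampled lineage escapes the sweep with probability
p_esc = 1 − exp(−αd); escaped lineages carry background variation while
all non-escaping lineages coalesce into the single swept lineage. For a
sample of n alleles with e escapees this is a draw of e + 1 lineages from
the background spectrum (hypergeometric projection), with the swept
ancestor expanded to n − e copies; the resulting unfolded spectrum is
folded and conditioned on remaining polymorphic. Because the matrix is
SNP-only, invariant sites are unavailable and the background is
polymorphic-sites-only throughout, so the conditioning is consistent
between null and alternative.

Λ(grid point) = 2·max_α Σ_sites [log P_sweep(k|α,d) − log P₀(k)] on a
1 kbp grid, with α on a log grid spanning 1e−8 to 1e−2 per bp. The null
is nested exactly: as p_esc → 1 the sweep spectrum is the background, and
the maximisation floors at zero, so Λ ≥ 0 everywhere. Sites beyond the
distance where p_esc > 1 − 1e−6 contribute a likelihood ratio of 1 and
are skipped. For tractability the continuous p_esc axis is discretised
into 48 bands uniform in αd; per-site log-ratios per band are prefix-summed
along each chromosome so each grid point costs a few binary searches
rather than a pass over all sites. Empirical SFS classes are floored at
1e−8 before logs so empty classes cannot produce infinite ratios. Sites
with fewer called alleles than the modal count are dropped (projection
down to the modal count handles the rest); the fitted α̂ is reported per
grid point, NaN where the null wins.

Sweep intervals are maximal runs of grid points with Λ strictly above the
chosen percentile cutoff (default top 1%); a flat scan therefore yields
nothing. What counts as "high likelihood" is ultimately a calibration
question, which is why the cutoff is a parameter rather than a constant.

## Runs of homozygosity

Per sample and chromosome, 1 Mbp windows anchored at every site are
classified homozygous when they contain at most 1 heterozygous and at most
5 missing calls. Runs are maximal stretches of consecutive homozygous
windows; their unioned site coverage forms the segment, except that past
the last supporting window anchor the run extends only until the first
heterozygous call (a het out there has no window of its own vouching for
it). Runs split where consecutive markers are more than 1 Mbp apart
(sparse GBS coverage should not bridge assembly gaps), are trimmed to
their outermost called homozygous sites, kept at ≥1 Mbp, and deduplicated
so a sample never reports overlapping segments (window support can
fragment at run boundaries; the longest fragment wins). There is no
SNP-density floor — GBS marker density is low and roughly uniform, so a
density guard tuned for array data would reject everything.

Grouping is single linkage over the predicate "segments overlap and their
samples agree at ≥99% of jointly called homozygous sites inside the
overlap" — genotypic identity, stated in output metadata since allelic
matching conventions differ between tools. Pairs with no comparable site
are not linked. The pooled track counts distinct samples with a segment
overlapping each 1 Mbp bin.

## Identity by state

Per locus the score is (2 − |dᵢ − dⱼ|)/2, reproducing the three diploid
anchors (identical homozygotes 1, opposite homozygotes 0, homozygote vs
heterozygote 0.5) and scoring het–het as 1, the standard distance-matrix
convention for unphased dosages. The matrix averages over jointly called
loci; pairs sharing none are flagged undefined.

## Cohort summaries

MAF is always the minor (second most common) allele frequency among
non-missing calls, hence ≤ 0.5. The subpopulation allele partition takes,
per subpopulation, the sites with within-group MAF strictly above 5%, and
reports shared/union/intersection/difference counts and private sites per
accession. The within-group MAF filter is applied alone; the missingness
filter is not re-applied per group. A/T base composition has no single
standard definition, so two modes are provided and named in the output:
the default weights each polymorphic site's ref and alt allele by its
within-group frequency; the unweighted mode counts each allele once.

## The simulator

`simulate_cohort` draws ancestral frequencies p ~ Uniform(0.05, 0.95),
then per-subpopulation frequencies from the Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F), giving direct control of expected F_ST.
Haplotypes are thresholded latent Gaussian AR(1) chains with site-to-site
correlation exp(−Δbp/d₀), which induces distance-decaying LD;
within-individual inbreeding F_IS is a per-site identity-by-descent coin
that copies the first haplotype's allele, so heterozygosity at
subpopulation frequency q is 2q(1−q)(1−F_IS). Sweeps are planted by
pushing focal-subpopulation frequencies to within `strength` of fixation
inside the interval; homozygous tracts by overwriting a sample's calls
with the major-allele homozygote; missingness is independent masking,
applied last. Everything derives from one seed, and the same config writes
a byte-identical VCF.

Defaults describe the kind of cohort the pipeline targets: four
subpopulations of a ~109-accession panel, ~65 markers/Mbp, 3% missingness,
and F = 0.2 with F_IS = 0.45, which together give ~16% heterozygosity
(2·E[p(1−p)]·(1−F)·(1−F_IS) ≈ 0.365·0.8·0.55 ≈ 0.16). `expected_statistics`
returns the closed-form expectations (heterozygosity, π, F_ST ≈ F, and the
approximate r²(d) ≈ exp(−2d/d₀) implied by the latent AR construction) for
use as recovery-test oracles.

What the simulator does not emulate: genealogies (sweeps act on
frequencies, not haplotype trees, so haplotype-based detectors would see
nothing), demography and migration, reference-bias or allele-calling
error, and the empirical GBS site-frequency distribution (ancestral
frequencies are uniform, so simulated MAF runs higher than a real
GBS panel's). Passing recovery tests therefore demonstrate correctness of
the estimators under their own model assumptions, not field performance.

## Region layer

"Adjacent regions separated by less than 1 Mbp" merge — strictly less, so
a gap of exactly 1 Mbp stays split. Labels never merge across types.
Top-percentile extraction uses a strict inequality against the percentile
of defined windows, so an all-tied track selects nothing. Collocation
first merges per label, then chains ≥1 bp overlaps across labels into
super-intervals and reports those carrying at least `min_labels` (default
3) distinct labels; a minimum-overlap-fraction parameter (default 0)
can require more than token overlap. Externally computed SNP lists (e.g.
ordination loadings, which this package does not compute) enter as 1 bp
point features under the SNPLIST label. Annotation intersection counts
≥1 bp overlap against gene intervals read from GFF3 (gene features, ID
attribute) or BED, and raises on a chromosome-naming mismatch rather than
silently reporting zero overlap.

## Problem sizes in the test suite

The bundled tests and the acceptance checks run on simulated cohorts of
25–50 samples per group and 1,300–10,000 sites on 10–20 Mbp chromosomes —
large enough for the estimators' sampling errors to be well inside the
stated tolerances (e.g. pooled F_ST within ±0.03 of the generating F at
10,000 sites), while keeping the full suite around a minute of compute.

## Known limitations

Two-population F_ST only; no haplotype statistics (D′, EM r², iHS,
XP-EHH); no Watterson's θ or Tajima's D; physical distance only (no
recombination map); the CLR scan's escape-probability discretisation
trades a sub-percent Λ approximation for a ~100× speedup; and the ROH
scanner's forward-anchored windows locate the segment end less precisely
than its start (boundary error bounded by one window).
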