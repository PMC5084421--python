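# Methods

`sweepaxes` re-implements, as a tested pipeline, a comparison-and-summary
workflow for selection-signature scans on phased multi-population
haplotypes: nine per-SNP statistics from three families, a varimax factor
summarization into three canonical axes, and empirical-outlier candidate
regions. This note documents the models, the defaults and why they are
what they are, the synthetic data generator, and the numerical choices.

## Scan statistics

All statistics operate on a binary haplotype matrix (0 = ancestral,
1 = derived where the ancestral state is known; otherwise REF-based coding
flagged as unpolarized) aligned to one SNP map. Sliding windows are
100 SNPs with step 1, each window's value assigned to its central SNP
(element `window//2`); the first and last `window//2` SNPs of a chromosome
carry no value. Per-SNP missing values are NaN throughout.

**Site-frequency-spectrum family** (oriented *low is evidence*):

* Tajima's D: `(θπ − θW) / sqrt(e1·S + e2·S(S−1))` with the full 1989
  constants from the haplotype count n. θπ is the mean pairwise
  difference, `θW = S/a1`. Windows with `S = 0` are missing. The
  normalizing constants vanish identically for n < 4 (where the numerator
  is also identically zero); those cases return 0.
* Fay & Wu's H: `θπ − θH`, unstandardized, both terms restricted to sites
  with a known ancestral state so unpolarizable sites cannot bias the
  difference; `θH = Σ 2i²/(n(n−1))` over derived counts i.
* Fu & Li's D*: the within-sample variant standardizing
  `n/(n−1)·S − a1·ηs` with the published 1993 constants (u_D*, v_D* in the
  libsequence/DnaSP form), where ηs counts *any-allele* singletons —
  alleles carried by exactly one haplotype — since no outgroup
  polarization is assumed. A polarized-singleton variant would only
  change which sites enter ηs.

θ estimators are per-window, not per-site: only genome-wide ranks are
consumed downstream, and the window size is constant.

**Haplotype-length family**:

* EHH from a core SNP is the fraction of carrier pairs of the core allele
  that remain identical over the span from the core to each offset;
  extension stops below a truncation value (0.05), at an inter-SNP gap
  above 200 kb, or at the chromosome edge (curves there are flagged and
  kept — dropping them is a config option; keeping maximizes SNP coverage
  for the factor analysis).
* iHH integrates EHH over genetic distance by trapezoids, interpolating
  the final segment down to the truncation value. |iHS| is
  `|z(ln(iHH_anc/iHH_der))|`, z-scored within 50 equal-width
  derived-frequency bins genome-wide (bins under 20 cores merged with a
  neighbour). Cores require a known ancestral allele, ≥ 2 carriers per
  class and derived frequency within [0.05, 0.95]. Truncation, gap, MAF
  bound and bin count are the scanning conventions popularized by the
  selscan tool, exposed as parameters. Without a genetic map, 1 cM/Mb is
  assumed (logged).
* |nSL| replaces genetic distance by segregating-site counts: the
  statistic is the log-ratio of mean pairwise identity run lengths
  (core included, capped at 200 segregating sites per direction),
  standardized like iHS. The scan runs on the population's segregating
  sites only, so distances are counted in the statistic's own units.
* H12 treats window haplotypes as exact 100-SNP strings and sums squared
  frequencies with the top two classes pooled:
  `(p1+p2)² + Σ_{j>2} pj²` (*high is evidence*).
* XP-EHH compares whole populations: at each core, EHH is computed over
  all haplotypes of each population (no allele split) while the *pooled*
  two-population EHH controls truncation at 0.05; the statistic
  `ln(IHH_A/IHH_B)` is z-scored genome-wide per pair and each
  population's track is the mean of its pairwise tracks with the focal
  population in the numerator (*abs is evidence*). Signed pairwise values
  are averaged; absolute values are taken only at the transform stage.

**Differentiation family** (*high is evidence*):

* FST per SNP per pair is Wright's `(H_T − H_S)/H_T` on haplotype
  frequencies, `H = 2p(1−p)`, with H_T from the count-pooled frequency and
  H_S the unweighted mean of the two within-population heterozygosities.
  Pooled-monomorphic SNPs are missing. Window means (missing skipped) are
  assigned to central SNPs; a population's track is the mean over its
  pairs. An inverted `(H_S − H_T)/H_T` orientation is available behind
  the `convention="printed"` flag for exactness experiments; the default
  is the orientation in which larger means more differentiated.
* VarLD: per window and pair, the signed Pearson correlation matrices of
  SNP columns (zero-variance SNPs contribute zero correlations and a unit
  diagonal, preserving the trace) are eigendecomposed; the raw score is
  `Σ_i |λ_A,(i) − λ_B,(i)|` over descending eigenvalues. Raw scores are
  z-scored genome-wide per pair and averaged per population — the
  z-scoring mirrors the VarLD program's practice; the per-population
  averaging follows the same convention as FST/XP-EHH.

SelEstim-like selection coefficients and XP-CLR composite-likelihood
scores are *not* computed internally; they enter as external per-SNP
score-track TSVs through the same reader as native tracks.

## Axis summarization

Each track is mapped to a common scale in two steps. First an evidence
value v: the raw score for *high is evidence* tracks, its negative for the
SFS tests, the absolute value for XP-EHH. Then the signed log transform
`sign(v)·ln(1+|v|)`, which is monotone in evidence and defined for the
negative values SFS tests produce (a plain `ln` is available for strictly
positive tracks, and is exactly scale-free after column z-scoring).

Rows of the score matrix are (population, SNP) pairs stacked over
populations; columns are tests; each column is z-scored over complete
rows. Rows with any missing entry are excluded from the correlation
matrix and the factor fit (complete case — the missingness is structural:
window edges, MAF bounds, fixed cores — not informative), and their axis
scores are missing. One factor model is fitted on the pooled rows so that
axes are comparable across populations, which the cross-population axis
correlations require; scores are then computed per population.

The factor analysis is principal-component extraction (top-3 eigenpairs
of the test correlation matrix; unrotated loading column j is
`eigvec_j · sqrt(eigval_j)`), followed by classical pairwise varimax with
Kaiser row normalization, swept until the criterion improvement is below
1e-10 *and* remaining rotation angles are below 1e-9 rad (max 1000
sweeps). Axes are ordered by explained variance and sign-fixed so the
largest-|loading| entry of each axis is positive. Score weights are the
regression coefficients `R⁻¹Λ`; per-row scores are rescaled to unit
variance over complete rows. Communalities (row sums of squared
loadings) are invariant under the rotation and are reported ×100 as
"% variance" per test.

Axis labels ("SFS", "haplotype-length", "differentiation") are assigned
post hoc by which test family loads highest — a report annotation, never
an algorithmic step. A sklearn-style transformer (`FactorSummarizer`,
fit/transform) wraps this stage, since it is the one genuinely
transform-shaped component of the pipeline; the scans themselves are
plain functions over haplotypes.

## Region calling

The genome-wide empirical distribution of each axis-score track is its
own null; thresholds are per population and axis. The strict rule tiles
each chromosome into fixed 1-Mb bins from position 1 and calls bins with
at least 25 SNPs above the top-0.1% quantile (linear-interpolation
quantile; strictly greater), merging adjacent called bins — a fixed
tiling is the simplest construction consistent with "1-Mb regions", and
merging avoids splitting a signal at a bin edge. The relaxed rule merges
top-5% SNPs within 1 Mb of each other into regions (single-SNP regions
allowed) for enrichment hand-off. Genes overlap a region when their
intervals intersect by ≥ 1 bp; outputs are a per-region mapping and a
deduplicated gene universe.

## Synthetic data

A forward Wright–Fisher simulator replaces the (undeposited) genotype
data. Forward time was chosen over the coalescent for direct control of
selection and splits and trivially verifiable update rules. Populations
hold `2·N_e` haplotypes paired into diploids; each generation children
pick parent diploids (fitness-weighted under selection: genotype
viabilities 1, 1+s/2, 1+s per derived copy at a sweep site) and recombine
the parental pair with Poisson crossovers placed uniformly in genetic
distance. Mutation is infinite-sites-style onto a fixed grid of
pre-allocated SNP slots shared by all populations (new mutations enter
slots currently empty everywhere, so tracks align across populations
without position matching). The ancestral population starts from the
neutral equilibrium SFS (`E[η_i] = θ/i` assigned independently per slot)
and a 4·N_e-generation burn-in builds the genealogical correlation (LD)
that the haplotype statistics probe. Sweep alleles enter as single copies
at a configured generation; with `rescue` on, a lost allele is re-seeded
(up to 100 attempts), otherwise the loss is recorded in the truth object.

**Preset scale.** The presets are a λ = 10 diffusion rescaling of a
cattle-like scenario (N_e = 2000, μ = 1e-8 /bp/gen, r = 1 cM/Mb,
s = 0.05): N_e = 200, μ = 1e-7, r = 10 cM/Mb, s = 0.5, run for 20k SNP
slots over 20 Mb. The rescaling preserves 4·N_e·μ, 4·N_e·r per bp and
2·N_e·s — the compound parameters the statistics respond to. The neutral
preset splits two populations 150 generations (λ-scaled: 1500) before
sampling 50 haplotypes per population, giving breed-scale pairwise FST of
roughly 0.1–0.2. The sweep preset adds one single-copy (hard) sweep at
the midpoint SNP of one population starting 35 generations before
sampling, so the swept allele is typically at intermediate-to-high
frequency — the regime where haplotype-length tests are informative. A
standing-variant start was deliberately avoided: several independent
founder copies make a soft sweep, which iHS/nSL cannot see by
construction. The expected one-sided hitchhiking footprint at these
parameters is s/(2·ln 2N_e s) ≈ 4.7 cM ≈ 470 kb, which is the scale on
which end-to-end checks look for the signal. The seven-population preset
mirrors a star radiation of 7 breeds sampled at 48 haplotypes each on a
smaller 5-Mb genome.

**What the generator does and does not emulate.** It produces phased
haplotypes with known ancestral states, drift-structured LD, population
splits and hitchhiking — the statistical structure the tests assume. It
does not emulate chip ascertainment bias, variable recombination maps,
trio structure, gene conversion, or bovine demography beyond a star
split; passing tests therefore demonstrate correctness and qualitative
power of the machinery at desk scale, not calibrated power on real
cattle data. Two desk-scale artifacts deserve note: (i) the genome is
20 Mb, so the genome-wide empirical null rests on far fewer independent
LD blocks than a 2.5-Gb genome — top-quantile outliers are accordingly
clumpier under neutrality, and the strict 25-SNP/1-Mb region rule is not
expected to separate sweep from neutral at this scale (0.1% of ~10k
scored SNPs is ~10 SNPs genome-wide); (ii) sample-polymorphic SNP grids
(monomorphic slots dropped) mimic chip-like data but shift window-θ
scales, which the rank-based downstream stages absorb.

## Numerical choices and degenerate inputs

* Tajima/Fu–Li constants vanish for n < 4; the statistics return 0 there
  (their numerators are identically 0) rather than NaN.
* Quantiles use linear interpolation; outliers are strictly above the
  threshold.
* iHS/nSL/XP-EHH cores with a non-positive integral on either side are
  missing; frequency bins under 20 cores merge left-to-right.
* Zero-variance SNPs in VarLD windows: correlation 0 off-diagonal, 1 on
  the diagonal, so eigenvalue sums always equal the window size.
* Varimax starts from the unrotated principal axes; ties in axis ordering
  cannot occur in float; sign fixing uses the largest-|loading| row.
* The pipeline derives all stage randomness from one seed; artifacts are
  SHA-256-checksummed into a manifest, and identical config + inputs
  reproduce identical checksums.

## Problem sizes in the test-suite and acceptance runs

Oracle-equivalence suites run on ≤ 8 haplotypes × ≤ 20 SNPs (hundreds to
a thousand random fixtures — exhaustive pair enumeration is exact there).
End-to-end checks run the 20k-slot presets with 10 replicate seeds per
arm; simulator calibration uses 200 single-locus replicates
(heterozygosity decay, frequency martingale) and small multi-locus
genomes for split-time monotonicity. These sizes keep the full suite in
the tens of minutes on one CPU while leaving every assertion
statistically meaningful.

## Known limitations

* Complete-case factor analysis discards SNPs missing any one test —
  near-fixed sweeps lose exactly their most extreme neighbourhood from
  the axis scores (iHS/nSL cores there are undefined). An imputation or
  per-family fallback would recover them at the cost of a more opaque
  contract.
* H12 windows require exact string identity; a mismatch-tolerant variant
  would be more robust to genotyping error in real data.
* The strict region rule at desk scale is descriptive only (see above).
* Single-chromosome presets; the code paths for multiple chromosomes are
  exercised by unit tests but not by the presets.
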