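# sweepaxes

Selection-signature scans on phased multi-population haplotypes, varimax
factor summarization into canonical axes, and empirical-outlier candidate
regions.

Genome scans for positive selection disagree with each other, because
different statistics see sweeps of different ages: site-frequency-spectrum
tests (Tajima's D, Fay & Wu's H, Fu & Li's D*) retain old signals,
population-differentiation tests (FST, VarLD, and imported tracks such as
SelEstim or XP-CLR scores) see events around breed formation, and
haplotype-length tests (iHS, nSL, H12, XP-EHH) see only recent, incomplete
sweeps. `sweepaxes` is for population geneticists who run several of these
scans on the same phased SNP data (e.g. livestock breeds genotyped on a
dense chip) and want a principled summary instead of eleven disagreeing
Manhattan plots: it computes nine statistics per SNP and population, maps
them onto a common evidence scale with a signed log transform, fits a
three-axis principal-factor model with varimax rotation to the test
correlation matrix, scores every SNP on each axis, and calls candidate
regions from the genome-wide empirical distribution of the axis scores
(fixed 1-Mb bins holding ≥ 25 SNPs above the top-0.1% quantile, plus a
relaxed top-5% rule for enrichment hand-off).

The core model: with per-SNP transformed scores z (one column per test,
columns standardized), the correlation matrix **R** is decomposed as
**R ≈ ΛΛᵀ** with Λ the tests × 3 loading matrix from the top three
eigenpairs, rotated by an orthogonal varimax **T** (Λ* = ΛT); per-test
communality h² = Σⱼ Λ*²ᵢⱼ is the share of that test's variance the axes
capture, and per-SNP axis scores are **z R⁻¹ Λ\***, rescaled to unit
variance. Axes are labelled post hoc by the test family loading highest.

A forward Wright–Fisher simulator (`sweepaxes.simulate`) provides the test
substrate: multiple populations splitting from a common ancestor, known
ancestral alleles, recombination, and optional selective sweeps, with
presets that are a λ = 10 diffusion rescaling of a cattle-like scenario.

## Worked example

```python
import numpy as np
from sweepaxes import axes
from sweepaxes.pipeline import TEST_FAMILIES, compute_tracks
from sweepaxes.simulate import preset_sweep, simulate

haps, snp_map, truth = simulate(preset_sweep(seed=7))
tracks = compute_tracks(haps)                      # 9 tests x 2 populations
mat = axes.build_score_matrix(tracks)
corr, order = axes.correlation_matrix(mat)
model = axes.factor_analysis(corr, 3, mat.test_names)
print(axes.label_axes(model, TEST_FAMILIES))
for name, load, h2 in zip(model.test_names, model.loadings,
                          model.communalities):
    print(f"{name:8s} {np.round(load, 2)}  {100 * h2:3.0f}%")
```

prints (seed 7):

```
{1: 'haplotype_length', 2: 'sfs', 3: 'differentiation'}
TajimaD  [0.02 0.9  0.05]   82%
FayWuH   [0.06 0.3  0.61]   46%
FuLiD    [-0.01  0.86  0.01]   75%
IHS      [ 0.95 -0.    0.03]   91%
NSL      [0.96 0.02 0.04]   92%
H12      [ 0.27 -0.01  0.54]   37%
FST      [ 0.08 -0.    0.75]   58%
XPEHH    [-0.04  0.07  0.48]   23%
VarLD    [-0.08 -0.13  0.38]   17%
```

The three test families separate onto the three rotated axes — iHS/nSL on
one, the SFS tests on another, the differentiation-family tests (with H12
and XP-EHH leaning the same way) on the third — and the "% variance"
column is the communality of each test. Region calling then runs per axis
and population:

```python
at = axes.axis_score_tracks(mat, model, snp_map)
from sweepaxes.regions import call_relaxed_regions
regions = call_relaxed_regions(at[(1, "pop1")], axis=1, population="pop1")
```

The same flow is available from the shell
(`sweepaxes simulate | sfs | haplen | diff | summarize | run`);
`summarize` fits the factor model to a directory of per-test track TSVs
(including externally computed ones), and `run` executes every stage
from one YAML file and writes a SHA-256 manifest so reruns are
verifiably identical.

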