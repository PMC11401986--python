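# Methods

## Data model

A genotyping batch is four artifacts: a SNP **manifest** (marker names,
chromosome tokens, positions, intensity-only flags), a **cluster file**
(population AA/AB/BB cluster statistics per SNP in the MA plane), a user
**sample sheet** (sample → GTC path, individual and family metadata), and
one **GTC** file per sample (called genotype, GenCall score, raw
two-channel intensities, affine normalization transforms). Everything
downstream operates on a long-format table with one row per
(sample, SNP) and the column names `Chr`, `Name`, `gtype`, `score`,
`x_raw`, `y_raw`, `x`, `y`, later `m_raw`, `a_raw`, `m`, `a` and
`rfgda_score`.

The GTC codec implements the public little-endian table-of-contents
container layout, restricted to the entries this pipeline consumes. Two
deliberate departures from vendor packing — float64 call scores and an
explicit per-record transform index — make write→read round trips
bit-exact, which the fixture round-trip tests rely on. Manifest and
cluster files are supported in an equivalent TSV dialect (what the
simulator emits) and a compact binary subset; the full vendor BPM/EGT
layouts are out of scope.

## Normalization

Raw intensities are mapped to normalized space by a six-parameter affine
transform applied in four stages: subtract the channel offsets
(offset_x, offset_y), rotate by theta, remove shear from the first
coordinate, divide by the per-axis scales (scale_x, scale_y > 0).
Negative results are clamped to zero so the subsequent log transform is
defined; the algebraic inverse (used by the simulator) is exact for
points nothing clamped. Stage order follows the vendor's published
reference implementation.

## MA features

m = log2(x+ε) − log2(y+ε) and a = (log2(x+ε)+log2(y+ε))/2, computed on
raw and normalized intensities (four appended columns). Base 2 is the
microarray convention and makes the homozygous ridges sit at m = ±4 for
a 16:1 channel ratio. The pseudo-count ε defaults to 1 raw-intensity
unit (configurable) so zero intensities stay finite. No-call rows keep
their features; they are needed for rescoring diagnostics.

## QC contracts

* `filter_informative` keeps rows with chromosome token ≠ "0", SNP name
  not containing the substring "cnv" (case-sensitive), and manifest
  intensity-only flag false. Idempotent; empty results allowed.
* `callrate` reports per-group genotype-class proportions over **all**
  records including NC (the four classes sum to 1).
* `heterozygosity` reports the AB share among **called** genotypes only —
  a no-call carries no zygosity information. Groups with zero called
  genotypes report NaN, never 0. For haploid batches this statistic is a
  direct ADI estimate.
* `genotype_pca` uses only SNPs called in every sample (complete case, no
  imputation), coded as B-allele dosage (AA=0, AB=1, BB=2); columns are
  centred but not variance-scaled (dosages are already commensurate).
  Dosage coding over one-hot is a deliberate choice — it is the standard
  genetics convention and keeps per-SNP weight comparable. The
  decomposition uses a full SVD so results are deterministic; per-
  chromosome mode repeats it independently per chromosome token.

## RF-GDA scoring

First layer: a random forest (default 100 trees, depth ≤ 12, fixed seed,
single-threaded for determinism) over the feature list
(m, a, m_raw, a_raw), trained on calls whose correctness is known —
labels come from the simulator's truth tables (a call is correct when
the called genotype equals the template genotype and is not NC).

Second layer: per individual, calls with forest probability ≥ p_hi
(default 0.9) form the positive seed set and ≤ p_lo (default 0.15) the
negative one; each class gets a maximum-likelihood full-covariance
Gaussian (divide-by-n covariance), regularized as Σ + ridge·I
(ridge = 1e-6), with priors from the seed counts. The confident-call
seeding is what lets the second layer adapt to an *unlabelled* batch.
The two-class (correct vs error) formulation is this package's
documented choice; a per-genotype mixture (3–6 Gaussians) would be a
drop-in alternative behind the same interface. Individuals with fewer
than 200 seed calls in either class (min_count) fall back to a pooled
layer fitted on all individuals together, recorded in the model's
provenance. The reported `rfgda_score` is the posterior probability of
the correct class, computed in log space with log-sum-exp; it obeys the
complement identity to machine precision and never converts an NC back
into a called genotype.

Deployment refits the Gaussian layers on each new batch
(`refit_gda`) while reusing the trained forest: the forest generalizes
across batches, the per-individual layers should always describe the
batch being scored.

Model files are a magic + version byte + pickle payload; loading a
mismatched version or corrupted payload raises an explicit error rather
than returning a garbage model.

## Thresholding

`set_threshold` no-calls records with score **strictly below** the
threshold (so a grid starting at 0.0 begins with a no-op) and keeps the
original genotype in a `gtype_prethreshold` shadow column. Pre-existing
no-calls stay NC at every threshold and remain in the call-rate
denominator. The sweep evaluates each (score column, threshold) pair,
pivots the genotype classes wide, and adds callrate = AA + AB + BB; the
summary reports mean and SEM (sample SD/√n, NaN for a single
individual) across individuals.

## Simulator

The generator emulates the study conditions the package targets: a batch
of 23 haploid (sperm) single cells from two families, WGA-amplified,
with heavy drop-in noise. Defaults: 20,000 SNPs, families of 12 + 11,
ado_rate 0.20, adi_rate 0.10, nc_rate 0.03, intensity_only_fraction
0.02. Per family, a B-allele frequency profile is drawn once
(Uniform(0.05, 0.95) per SNP); haploid genotypes are Bernoulli draws
from it, diploid genotypes Hardy–Weinberg. Error generation:

* true AB loses an allele with probability ado_rate (ADO; AA/BB chosen
  evenly). Haploid templates have no AB, so there `ado_rate` models
  amplification failure of the single allele and surfaces as a no-call —
  the realized haploid no-call burden is ≈ 1 − (1−ado)(1−nc) ≈ 22%.
* a still-correct homozygote becomes AB with probability adi_rate (ADI).
* a baseline nc_rate no-calls any record; intensity-only probes are
  always NC.

Observed calls draw (m, a) from per-genotype Gaussians — AA at (+4, 10),
AB at (0, 10), BB at (−4, 10), the ADI cloud at (0, 7) with inflated
spread, no-calls from a broad low-a cloud at (0, 6) — then
back-transform to normalized intensities and through the *inverse* of a
randomly drawn per-sample affine transform to raw intensities (quantized
to uint16), so the normalization code path is exercised non-trivially.
GenCall-like scores come from Beta distributions: correct Beta(9, 3)
(mode 0.8), errors Beta(5.5, 6.5) (mode 0.45), no-calls Beta(2, 10) —
discriminative but deliberately imperfect, giving the baseline scorer
something genuine to compare against. All sub-streams derive from one
master seed; identical seeds give byte-identical fixture sets.

What the simulator does **not** model: genome-positional correlation of
drop-out, copy-number/aneuploidy signal, per-SNP cluster heterogeneity
(all SNPs share the cluster geometry), and any realistic joint
distribution of GenCall score and error class (the Beta model is a
configuration choice, isolated behind `SimulationConfig.score_model`).
Passing tests therefore demonstrate the pipeline's correctness and the
scorer's behaviour under a clean generative model, not its error rates
on real arrays, where cluster geometry varies per SNP and noise is more
structured.

## Evaluation conventions

`evaluate_against_truth` calls a record *retained* when it is non-NC
after thresholding and *correct* when the originally called genotype
equals the template; precision is over retained calls, recall relative
to the correct calls in the unthresholded called set (threshold 0 →
recall 1). Matched-call-rate comparisons use retention quantiles of the
*called* genotypes (`ab_fraction_at_retention`): a batch with a ~22%
baseline no-call burden cannot reach an absolute call rate of 0.99, but
each scorer can be asked to keep the best 99/95/90% of the calls it was
given, which is the comparison that matters.

## Problem sizes

The test suite and acceptance script run the two-scorer comparison at
the full study scale (23 samples × 20,000 SNPs, trained on an
independent batch of the same size), GDA parameter recovery over 20
replicates of 20,000 calls per individual, the codec round trip over
1,000 generated record sets, and the numeric identities over 10,000+
random draws. Determinism is verified end-to-end at 8 samples ×
3,000 SNPs, a size chosen to keep two full pipeline runs cheap while
exercising every stage.

## Known limitations

* IDAT parsing and vendor BPM/EGT binary layouts are out of scope; GTC
  (in the documented dialect) is the entry format.
* The first layer ships only as a random forest; the scoring interface
  is plug-in shaped (any object with `predict_proba` over the feature
  matrix would serve) but no alternative is bundled.
* Cluster-file statistics are carried and validated but not used by the
  scorer, which estimates its own Gaussians per batch.
* The GDA layer assumes the feature clouds are adequately Gaussian;
  strongly multimodal within-class structure (e.g. mixed diploid
  genotype clusters in the positive class) is absorbed into wide
  covariances rather than modelled.
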