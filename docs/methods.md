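# Methods

This note records the models implemented in `olfsel`, their assumptions, the
defaults and why, and the numerical and design choices that were genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Liability-threshold selection model

A fly's two-choice behavior is modelled by a latent liability
z ~ N(μ_t, σ_P²); the fly chooses the odor arm iff z > 0.  This is the
minimal quantitative-genetics link between a continuous heritable trait and
a binary assay outcome, and it yields closed forms: the expected preference
index is PI_t = 2Φ(μ_t/σ_P) − 1, and selecting all flies of one arm is sharp
truncation at 0, so the selection differential follows the truncated-normal
mean identities (S = σφ/Φ upward, S = −σφ/(1 − Φ) downward).

Transmission uses the breeder's equation μ_{t+1} = μ_t + h²S_t with constant
h² (infinitesimal model, non-overlapping generations, no mutation or
linkage).  Transmission itself is deterministic; all Monte-Carlo noise comes
from the finite assay (n_flies draws per generation).  Two consequences
worth knowing:

- On the liability scale, R_t = h²S_t holds *exactly* per line, so the
  realized-h² regression recovers the generating h² to machine precision.
  Real data adds segregation variance and measurement error that this
  simulator deliberately omits; passing recovery tests therefore validates
  the estimator's algebra, not its robustness to transmission noise.
- With a non-indifferent base (μ0 ≠ 0) the two selection directions are
  asymmetric: the direction selecting the *rarer* arm has the larger |S|
  (φ/Φ vs φ/(1−Φ)).  An initially averse base (μ0 < 0) responds more
  strongly to upward selection.  This is the structural source of
  direction-asymmetric response in the model.

Control lines keep the flies of one uniformly random arm (no odor present),
so their expected differential is zero.  If the selected arm is empty the
assay is re-drawn (the protocol's "tested until enough parents" rule), with
a bounded retry count; the realized S of the successful draw enters the
records, with no imputation.

Defaults: σ_P = 1 (the liability unit), μ0 = 0, n_flies = 30 per assay and
30 generations with 3 replicate lines per direction — the experimental
design shape.  The paper-scale parent count ("minimum of 25 + 25") is not
fixed; n_flies is a free parameter because the census contributing parents
was not a constant in the protocol.

## Realized heritability

ĥ² is the through-origin OLS slope of cumulative response on cumulative
selection differential; zero cumulative selection must imply zero expected
cumulative response, which is why the origin constraint is the default (an
`intercept=True` variant is exposed).  SE and the two-sided p use the
through-origin formulas with df = T − 1.  The OLS SE treats the cumulative
residuals as independent, which they are not in general (they accumulate);
in this package's simulator the residuals are ~0 on the liability scale so
the issue is moot there, but PI-scale SEs should be read as descriptive.

PI-scale inputs pin the selected group's PI at ±1 (all parents sit on one
arm by construction).  This is a convention, not an estimate; it makes the
PI-scale ĥ² smaller than the liability h² (the example script shows ~0.13
vs 0.25) and monotone in it — the property the tests check.

## Biphasic dose-response and the valence crossover

The data motivating the form are dose-response curves that switch from
attraction at low concentration to aversion at high concentration.  No
mechanistic model is claimed; the difference of two Hill terms

PI(c) = a·c^{h_a}/(c^{h_a} + k_a^{h_a}) − b·c^{h_b}/(c^{h_b} + k_b^{h_b})

is the simplest form with saturating attraction, later-recruited aversion
and a well-defined sign crossover.  Fitting: bounded nonlinear least squares
(amplitudes in [0, 2], Hill slopes in [0.2, 8], midpoints on the log10 axis
within ±3 decades of the observed range), ≥ 5 starts with the attractive
midpoint initialised toward low and the aversive toward high concentrations
plus seeded jitter.  Cost ties (within 1e−10 relative) break toward the
smaller aversive amplitude so that a monotone attractive curve does not
acquire a phantom aversive term hidden beyond the observed range — without
this tie-break b is unidentifiable on such data.  The crossover is the first
sign change of the fitted curve between the smallest and largest observed
concentration, bisected on the log axis to |PI| < 1e−10, and is reported
absent when the curve does not change sign there.  Concentrations are v/v
fractions; the crossover co-scales exactly with a common rescaling of
concentrations and midpoints.

## Odor-space distance and generalization

The descriptor matrix is user-supplied (any set of physicochemical
properties); each column is z-scored over the loaded odorant set with the
sample SD (n − 1), zero-variance columns are dropped with a warning, and
distance is Euclidean in the standardized space.  This is an openly stated
approximation of fixed-normalization descriptor metrics: standardization is
*set-relative*, so adding an odorant changes existing distances — distances
are always recomputed, never cached, and a test pins this behavior.
Generalization is OLS of ΔPI on distance *with* intercept (the observed
regressions have nonzero intercepts); the ΔPI sign convention folds the
selection direction so that generalization appears as a negative slope for
both line types.

## Expression divergence

The engine starts from a count matrix; read processing and alignment are
upstream and out of scope.  Choices, in pipeline order:

- **Filter**: CPM ≥ 1 in at least half the samples, with "half" read as
  qualifying-count ≥ S/2 (for even S, exactly half suffices — the laxer
  reading; `min_fraction` is configurable).  The filter is idempotent.
- **TMM**: reference = sample whose upper-quartile relative abundance is
  closest to the mean; M/A over genes nonzero in both sample and reference;
  two-tail trims of 30% on M and 5% on A by rank; precision weights from
  the binomial delta-method variances; factors rescaled to geometric mean 1.
  Fewer than 5 usable genes after trimming falls back to factor 1 with a
  warning.  The factor is exactly 1 for identical or integer-scaled
  two-sample columns; for multi-sample matrices an integer rescaling of one
  sample perturbs only the count-level precision weights (sub-percent
  effect), which a test documents.
- **Dispersion**: a single common NB dispersion — the median across genes of
  df-weighted within-group moment estimates (v − m)/m² on counts scaled to
  a common effective library size, clipped at 0.  Sample variances are
  multiplied by the chi-square median-bias factor 1/(1 − 2/(9·df))³ with df
  the combined within-group degrees of freedom, so the *median* across genes
  is centred on the truth at small group sizes (an uncorrected median sits
  ~7% low at 6 + 6 samples and makes the exact test conservative).  This is
  a deliberate simplification of likelihood-based tagwise machinery; the
  package does not promise to reproduce gene counts obtained with
  empirical-Bayes dispersion estimation.
- **Exact test**: group sums of pseudo-counts (scaled to the geometric-mean
  effective library size and rounded) are NB with size n_g/φ; conditioning
  on the total gives a distribution free of the mean (binomial when φ = 0).
  The two-sided p sums the probabilities of all splits as or less likely
  than the observed one, ties included.  log2 fold changes use group-mean
  pseudo-counts with a 0.5 offset to avoid infinite ratios.
- **FDR**: Benjamini–Hochberg step-up (via statsmodels) at q ≤ 0.1, the
  threshold used throughout.
- **Contrasts**: replicate lines are pooled within treatments; the filter,
  TMM factors and the common dispersion are computed once per regime (using
  all three treatment groups — one consistent null model) and shared by the
  three contrasts.
- **Venn valence labels**: positive-valence = (A∩B)∪(A∩B∩C), negative =
  (B∩C)∪(A∩B∩C), generalized = A∩B∩C, over A = PI+ vs control,
  B = PI+ vs PI−, C = PI− vs control.
- **Enrichment**: one-sided hypergeometric upper tail per term (equivalent
  to Fisher's exact on the 2×2 table), BH across terms; annotation gene sets
  are intersected with the universe first.

## Synthetic-data generators

`gen_counts` draws relative abundances from a log-normal (log2 mean 5,
SD 2 — a realistic bulk dynamic range), library sizes uniform in
0.8–1.2 × 10⁶ (the study-scale ~36M-read libraries scaled down to keep
simulation studies fast; the conditional exact test enumerates totals, so
runtime scales with library size), and NB counts at the planted
fold-changes; dispersion 0.1 is a typical bulk-RNA-seq value.  Planted DE
defaults to alternating up/down signs so the TMM assumption (most genes
non-DE, symmetric) holds.  What the generator does *not* emulate: GC/length
bias, sample-specific quality, correlated genes, outlier libraries — so
passing calibration tests bounds only sampling-noise behavior, not
robustness to those artifacts.  `gen_selection_experiment`,
`gen_generalization` and `gen_annotation` similarly mirror the design
shapes (9 lines; 12 test odorants + 1 selection odorant; GMT terms with one
planted enrichment) and are bit-reproducible under a fixed seed.

## Validation design and known limitations

Monte-Carlo validation compares 500 simulated lines of 1000 flies against
the closed-form recursion.  The liability mean is held to 3 MC standard
errors at every generation (its deviations are random-walk-correlated, so
this family is effectively small).  The PI trajectories contribute 124
near-independent comparisons across four heritabilities; a fixed 3σ rule
would false-alarm on a correct simulator with ~30% probability, so that
family uses the Šidák-style simultaneous threshold with the same overall
3σ error rate.  DE calibration checks that the null fraction of p ≤ 0.05
lies in the binomial 95% band around 0.05 at 2000 genes and that BH at
q ≤ 0.1 rejects ≤ 1%; planted-truth recovery requires recall and precision
≥ 0.8 for 100 genes at log2FC = 2 in a 6 vs 6 design.

Known limitations: no segregation/drift variance in transmission (see
above); a single common dispersion rather than tagwise shrinkage; the
conditional exact test rounds pseudo-counts (negligible at the default
library sizes, visible for counts near zero); descriptor distances are
set-relative; the biphasic dose-response form is a phenomenological choice
and its parameters are only jointly identifiable when the data span both
limbs of the curve.
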