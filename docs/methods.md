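# Methods

This note records the model, the procedure parameters, the scope of the
synthetic generator, the numerical choices, and the known limitations of
`convscreen`. Everything here is implemented in `src/convscreen/`; nothing
below is an empirical claim unless it names the code path that computes it.

## Encoding

Each alignment column is mapped to a single ordinal integer feature. The
per-column key assigns code 0 to the most frequent character, code 1 to the
next, and so on, with ties broken alphabetically; the gap character `-`
participates like any other state. Keys are stored with the encoded matrix
and are invertible (`decode_matrix`).

`permute_keys` produces deliberately relabelled keys for robustness probes:
`"swap-binary"` swaps the two codes of every two-state column, and
`"full-shuffle"` applies a seeded random permutation to every column's
codes. For a two-state column the swap is the affine map `x ↦ 1 − x`, and
because every model fit standardizes each feature, binary-column swaps leave
all fitted models and all selections exactly invariant (up to floating-point
round-off). Relabelling a column with three or more states (or with gaps)
is **not** affine, so model output can genuinely change; see Limitations.

## Classifier and objective

All models are L2-regularized logistic regression with an unpenalized
intercept, `C = 1.0` (i.e. the scikit-learn parameterization: minimize
`½‖w‖² + C·Σ log(1 + exp(−yᵢ(w·xᵢ + b)))`). Features are standardized to
zero mean and unit variance using **training-fold statistics only**, with
the biased (divide-by-n) standard deviation and a variance floor of 1e-12
for constant columns. Optimization uses L-BFGS-B on an analytically
differentiated objective; all splits of a CV run are solved jointly as one
block-separable problem (`_engine.py`), which is numerically cross-checked
against per-split scikit-learn fits in the test suite (coefficient agreement
at ~1e-6).

## Cross-validation

Model quality is estimated by repeated random subsampling: `n_iterations`
(default 500) independent random 70:30 train:test splits, stratification-free
but rejected and redrawn if either fold lacks a class. Reported metrics are
per-split held-out accuracy and AUROC, summarized by their mean and standard
deviation across splits. Splits depend only on the master seed, the seed
context, and the number of samples — never on the feature matrix — so every
gene of a panel is evaluated on identical splits.

### Seeding

All randomness flows from one master seed through
`numpy.random.SeedSequence([master_seed, *context])` with fixed integer
context tags per stage (v1 CV, v2, RFE, permutation null, complex
combiner). Derived integer seeds are taken below 2³¹. Reruns with the same
seed reproduce every report file byte for byte (`write_reports` formats
floats as `%.6f` and orders rows deterministically).

## Feature selection

- **v2 (strongest-k):** one fit on the full standardized dataset; the ten
  features with the largest |coefficient| (ties broken toward lower column
  index) form the gene's strongest set.
- **v3 (RFE-CV):** starting from all columns, each step runs the full CV on
  the active set and eliminates the feature with the smallest mean
  |standardized coefficient| across the step's fits (ties broken toward the
  higher alignment position), down to two features. All steps share one
  splits block (one seed context per gene) and warm-start from the previous
  step's solution. The **optimal subset** is the step with the highest mean
  accuracy among steps with at most ten features; ties go to the smaller
  set, then to the higher mean AUROC. `in_zone` flags optima with mean
  accuracy ≥ 0.9.

Sharing one set of splits across all RFE steps is a deliberate choice: it
makes step scores comparable (differences reflect the feature set, not split
luck) and keeps the path deterministic, at the cost of the optimal step's
score being mildly optimistic for that split set.

## Complexes

A complex is screened by concatenating, per subunit, the ten strongest
features (all features for subunits shorter than ten columns) — a combined
width of Σₛ min(10, pₛ) — and running RFE-CV on the concatenation under the
complex seed context. The optimal cross-subunit set is reported with
`gene:position` feature labels.

## Permutation null and significance

The null battery re-runs the identical CV for each gene with **a fresh
seeded label permutation per CV iteration**. A single fixed permutation is
not an adequate null: any one permuted labeling has its own
dataset-specific achievable accuracy, and a t-test across hundreds of CV
iterations will resolve that offset as spurious "significance" in either
direction. Averaging over per-iteration permutations estimates the chance
distribution itself; on label-independent features its mean sits at the
majority-class fraction as expected.

True-label vs null comparisons use Welch-free two-sample Student's t-tests
(equal-variance, scipy `ttest_ind`) that are **one-sided ("greater")** in
the battery: the screening claim is directional — a gene classifies *better*
than chance — and a below-chance excursion is a non-finding, not evidence.
P-values are Bonferroni-adjusted across the genes of a battery. The
general-purpose `compare_metric_distributions` defaults to two-sided.

**Caveat (pseudo-replication):** the t-test's units are CV iterations of a
single dataset, which are not independent replicates; with hundreds of
iterations the test is anticonservative, and a noise gene whose true-label
CV lands ~0.04 above its null by dataset luck can reach adjusted
significance at some seeds. Battery p-values rank evidence within a panel;
they are not calibrated error rates over independent datasets.

## Diversity

Mean pairwise distance (MPD) is the average Hamming distance (number of
differing columns, gaps counted as states) over all unordered sequence
pairs, computed by default on one class subset (the ancestral class) so that
phenotype-linked variation is excluded. `diversity_report` correlates
per-gene MPD, alignment length, and MPD per 100 columns with optimal-model
accuracy (Pearson r).

## Synthetic generator — scope

The generator produces label-conditional alignments with planted
convergent-like signal: the derived class is partitioned into lineages, a
signal column carries a derived-state residue in each "signal lineage"
member independently with probability `penetrance`, with `leakage` giving
the same state in the ancestral class; background columns draw i.i.d. from a
shared categorical alphabet with a gap fraction. It is a calibration and
testing instrument, **not** a phylogenetic simulator: there is no tree, no
substitution model, no rate variation, and background columns are
independent across sites and samples. `verify_truth` recomputes planted
per-class state frequencies exactly and chi-square-screens background
columns for accidental label association. `default_screen_spec()` fixes a
desk-scale condition (58 + 76 samples, 16 lineages, one strong gene with six
planted columns at penetrance 0.85 in 12 lineages, one moderate gene, eight
noise genes).

## Numerical choices

- L-BFGS-B with gradient tolerance `pgtol = 1e-5` and tight `factr`;
  warm starts along the RFE path.
- Biased standard deviation (ddof = 0) for standardization; variance floor
  1e-12.
- AUROC by the Mann–Whitney tie-corrected rank statistic on the held-out
  fold; folds with a single class are redrawn at split time, so the metric
  is always defined.
- Bonferroni correction clamps adjusted p-values at 1.
- All report floats serialized at six decimals; JSON keys sorted.

## Limitations

- **Encoding sensitivity for multistate columns.** Only binary-column code
  swaps are affine; permuting codes of columns with ≥3 states (or gaps)
  changes the geometry the linear model sees. In practice the strongly
  informative (planted) columns survive key permutation, but weak
  "passenger" columns in an optimal set can be replaced by different
  passengers. Position-level conclusions should be read from the stable
  core, not from the full optimal set.
- **Pseudo-replication** in the null battery t-tests (see above).
- **Winner's curse in exhaustive comparisons.** The maximum score over all
  feature pairs evaluated on one split set is upward-biased; RFE-selected
  pairs scoring slightly below an exhaustive "best pair" on the same splits
  is expected behavior, not an RFE failure.
- Repeated random subsampling reuses samples across splits; the standard
  deviation across splits understates sampling variability of the mean.
- The generator's i.i.d. background cannot produce lineage-structured
  correlation among noise columns, so real-data false-positive behavior may
  be less benign than the synthetic battery suggests.
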