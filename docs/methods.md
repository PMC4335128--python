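# Methods

## The modeling problem

`pcmlearn` implements proteochemometric (PCM) regression: one model is fitted
over compound–target *pairs*, with each design row the concatenation of a
compound descriptor block and a target descriptor block, and the response the
pair's pIC50 (−log10 of the IC50 in molar units). Because chemical and target
information enter one model, the approach can interpolate and extrapolate in
both spaces — in particular it can predict the potency of a compound on an
isoform it was never measured against, which is the question that matters for
selectivity-driven series such as cyclooxygenase inhibitors.

## Data curation

Raw IC50 exports are filtered to records with an exact-equality activity
relationship, assay score confidence ≥ 8 and nanomolar units; replicate
measurements of one (compound, target) pair are averaged (arithmetic mean;
replicate SDs are retained as a diagnostic, and medians would only be
preferable under heavy outlier contamination, which public replicate data do
not show). pIC50 = 9 − log10(IC50/nM), i.e. the molar convention — typical
inhibitor potencies then land in the 4–10 range. Structures are standardized
by stripping to the largest carbon-containing fragment; fragments with no
carbon are rejected as inorganic. No element, halogen or mass restrictions
are applied.

## Descriptors

**Compounds — keyed circular substructure counts.** Every atom environment of
radius 0, 1 or 2 bonds (maximal diameter four bonds) observed in the training
set becomes a column of its own. Identifiers are canonical rooted fragment
SMILES prefixed with the radius (e.g. `r1|C(c)(F)(F)F` for an aryl-attached
CF3 carbon), not hash integers, so vocabularies are portable and every model
coefficient names a depictable substructure. Counting is closed-world: a
prediction-time environment absent from the training vocabulary is dropped.
An atom whose environment stops growing (the molecule ends within the
radius) emits no duplicate higher-radius environment.

**Targets — z-scales over binding-site positions.** Each selected alignment
column contributes the five extended z-scale values of the residue at that
position (z1 lipophilicity, z2 steric bulk, z3 polarity, z4/z5 electronic
character); a target is the concatenation over the selected columns
(5·|columns| values). Gap characters map to five zeros, which keeps
dimensions fixed and is distinguishable from every residue. The alignment
and the column selection are inputs; computing them is out of scope.

**Preprocessing.** Fitted on training rows only and frozen: (1) a
near-zero-variance filter removes constant columns and columns whose most
common value outnumbers the second most common by more than 30:1 (strict
inequality); (2) centering to zero mean and scaling to unit variance with
the sample SD (n−1 denominator).

## Cross-validation discipline and the model library

The data are split once into six folds by stratified sampling of the
response (ten quantile bins; within each bin a seeded shuffle is dealt
round-robin to folds, with the dealing pointer carried across bins, so fold
sizes differ by at most the number of bins). Fold 6 is the held-out test set
by default and never touches preprocessing statistics, hyperparameter search
or fitting. Hyperparameters are chosen by grid search over the five training
folds (five fits per combination, each holding out one fold; lowest mean
held-out RMSE wins, ties broken by grid order).

A *model library* is a list of regressors — gradient-boosted trees, random
forests, linear/radial SVR, elastic net, ordinary linear, delegated to
scikit-learn — trained on the same folds. Each member is fitted per-fold so
that every training datapoint has exactly one out-of-fold (OOF) prediction,
then refitted on all five training folds for test-time use. The OOF matrix
(rows = training datapoints, columns = members) is the common currency of
the ensemble methods. The shipped default grid has 27 members ("test" size)
or a few hundred ("full").

## Ensembles

**Greedy weight optimization** (Caruana-style ensemble selection with
replacement): integer member weights start at zero; at each of n iterations
(default 1000) the single-weight increment whose normalized weighted OOF
average has the lowest RMSE is applied. The *reported* ensemble is the best
normalized weight vector seen along the walk, so the RMSE trace is
non-increasing by construction while the forced walk keeps exploring finer
weight resolutions; on small libraries this reaches the exhaustive optimum
over the integer-weight simplex (verified against brute force in the tests).
A keep-only-if-improving variant was rejected because it deadlocks at
coarse-denominator grid points (e.g. stuck at weights (1,1) when the optimum
is 23/42). Final weights are normalized to sum to one.

**Model stacking**: a meta-learner (linear, elastic net, linear/radial SVR
or random forest) is fitted with the OOF matrix as features. Meta
hyperparameters are tuned by cross-validation over the library's own folds —
reusing the same split avoids optimistically leaking the fold structure.
Coefficient-exposing meta families report a member-weight vector.

Homo-ensembles (members of one algorithm family) and hetero-ensembles
(≥ 2 families) are realized by filtering the member list before fitting.

## Validation metrics

For observed y and predicted ỹ (N points, ȳ the mean of the evaluated set):

- RMSE = √(Σ(y−ỹ)²/N)
- q² = 1 − Σ(y−ỹ)² / Σ(y−ȳ)²
- R²₀ = 1 − Σ(y−sỹ)² / Σ(y−ȳ)², with slope s = Σyỹ / Σỹ² — the regression of
  observed on predicted forced through the origin; asymmetric in its
  arguments and possibly negative; invariant to positive rescaling of ỹ.
- CCC (Lin) = 2·cov(y,ỹ) / (var y + var ỹ + (ȳ−mean ỹ)²), population
  moments; |CCC| ≤ |Pearson r|.

Soundness thresholds: q²_internal > 0.5 and q²_test, R²₀_test > 0.6, strict
inequalities, configurable. Metric uncertainties come from paired bootstrap
resampling (mean ± SD over replicates, default 1000).

**Noise-bounded maximum performance.** Public IC50 measurements carry an
average SD of ~0.68 pIC50 units across laboratories. The achievable metric
range given that uncertainty is estimated by simulation: per replicate, draw
a test-set-sized sample A from the pIC50 pool without replacement, set
A_noisy = A + N(0, σ) with σ = 0.68, and compute the metrics of A (truth)
against A_noisy (prediction) — the orientation matters for R²₀. The mean of
the minimum-RMSE distribution converges to σ (0.68 at two decimals for
sample size 823); a model reporting test metrics beyond these bounds is
fitting noise. The default sample size is ⌈pool/6⌉, the test-fold share.

**y-scrambling.** For each fraction f, a seeded random f-share of *training*
responses is permuted among themselves (preserving the marginal), the model
refitted, and test metrics recorded; fraction 0 reproduces the unscrambled
model bit-for-bit, and with genuine signal the metrics collapse as f → 1.

## Applicability domain

The ensemble standard deviation E_std of a datapoint is the unweighted
sample SD (n−1) of the member predictions for it — zero-weight members
included, since disagreement is informative regardless of weight. Intervals
are ỹ ± β·E_std (β > 0); the boundary counts as inside. The coverage curve
(share of observations inside their interval, per β over a default grid of
0.1…4.0 in steps of 0.1) is non-decreasing in β, and
`beta_for_confidence(curve, level)` returns the smallest grid β reaching a
requested confidence level. Cross-validation and test coverage are reported
separately; neither is assumed larger.

## Substructure attribution

**Predictive (model-based) method.** A substructure is "virtually removed"
from each compound containing it by zeroing its raw count — before the
frozen preprocessing transform is re-applied — and the drop in predicted
pIC50 recorded: Δᵢ = ŷ(original) − ŷ(zeroed). The reported contribution is
the count-weighted mean Σcᵢ Δᵢ / Σcᵢ with an unweighted SD (the SD flags
context dependence). Positive = beneficial, negative = deleterious. Zeroing
touches only the named column.

*Identifiability and the sparse attribution model.* Multi-radius keyed
counts satisfy exact linear identities — every environment's count equals
the sum of its radius+1 refinements present in the vocabulary — so an
L2-penalized or plain least-squares fit spreads an effect arbitrarily across
a substructure's relatives and count-zeroing then sees only a fraction of
it. The package therefore provides `SparseLinearRegressor`, an L1 selection
stage followed by an unpenalized refit on the selected support (relaxed
lasso): representing a signal on the column that carries it costs the least
L1 mass, so the effect concentrates on the planted substructure, and the
refit removes shrinkage bias. Tree/kernel models remain available for
attribution but inherit the ambiguity.

**Student's (model-free) method.** Within one bioactivity set (one target),
the pIC50 distribution of compounds containing a substructure (A) is
compared with that of compounds lacking it (B). Both groups must have ≥ 3
members and pass a Shapiro–Wilk normality gate at α = 0.05; failing either
yields "not assessed" (no silent nonparametric fallback). Otherwise a
two-tailed Welch t-test at α = 0.05 decides significance (pooled-variance
variant available), and the sign of mean(A) − mean(B) labels the
substructure beneficial or deleterious. No multiple-testing correction is
applied by default; a Benjamini–Hochberg switch exists for large
vocabularies. Substructures significant on two isoform sets are binned as
{increase, decrease} × {set 1 only, set 2 only, both}; significant with
opposite signs is reported as "opposite" rather than forced into a bin.

The two methods answer different questions and can legitimately disagree: a
passenger substructure that co-occurs with a potency-driving one is inert to
the predictive method but significant to the distribution comparison,
because the passenger-free population is diluted with inactive compounds.
`method_disagreement_scenario` constructs exactly this case (passenger S1
riding on driver S2, three compound groups, effect 0.8 and noise 0.6 chosen
so both groups still pass the normality gate) and the tests assert the
disagreement.

## Synthetic data generator

The generator emulates the statistical shape of a public bioactivity panel,
not its chemistry. Compounds are seeded decorations of ~15 scaffold
templates (aryl, pyrrole, pyrazole, thiazole, oxazole, pyridine, furanone,
sulfone, anilide cores) with substituents including sulfonamide, CF3,
acetyl, nitrile, nitro and halogens. Four *marker motifs* (CF3, sulfonamide,
acetyl, nitrile) are drawn with boosted frequency and occasionally attached
through a methylene so each marker occurs in more than one immediate
context; without that variation every environment of a marker is an exact
rescaled copy of every other and no effect could be attributed to one of
them specifically. Targets are two "isoform clusters" of aligned binding-site
sequences: cluster B differs from cluster A at a controlled fraction of
positions (default divergence 0.5 of 25 positions), with within-cluster
variation defaulting to 0.15·divergence so zero divergence yields identical
sequences.

Bioactivities follow an additive ground truth

    pIC50(i,j) = base + Σ_s effect(s, cluster(j))·count_i(s) + offset(j)
                + interaction(i,j) + noise(i,j)

with base 6.5 (mid-range potency), per-target offsets N(0, 0.5), a small
pairwise interaction term N(0, 0.1), Gaussian noise of SD 0.68 (the public
IC50 uncertainty) and a retained completeness fraction of 0.14 by default —
the sparsity regime of real panels. Planted effect substructures are chosen
from the compounds' own vocabulary under identifiability constraints:
prevalence 10–85%, at most ~once per containing compound (Σc²/Σc ≤ 1.1), no
exact rescaled duplicate column, and pairwise correlation < 0.5 between
chosen effects. Effects alternate ±effect_size; `flip=True` negates cluster
B's effects (an isoform-selectivity signal). Everything regenerates
bit-identically from one seed.

What the generator does *not* emulate: real structure–activity landscapes
(the truth is additive and low-dimensional), assay heterogeneity, activity
cliffs, correlated measurement error, or the value distribution of any real
database. Passing tests on this data demonstrate that the machinery is
correct and that planted signal of realistic magnitude is recovered under
realistic noise and sparsity — not that any particular real dataset is
predictable.

## Problem sizes used by the test suite

Scaled-down study conditions keep the default runs compact: the benchmark
library uses 250 compounds × 8 targets at completeness 0.5 (≈1000
datapoints) with the 27-member grid; attribution recovery uses 250 compounds
× 6 targets at noise SD 0.3; distribution-comparison checks use 500
compounds on one target at full completeness so present/absent groups exceed
50. The Student's-method recovery checks plant one effect per generated
dataset: with several ±1 effects in one compound population, each
present/absent group is a mixture of shifted modes and the Shapiro–Wilk gate
(correctly) refuses to assess it — single-effect designs are the regime the
gate admits.

## Numerical choices and edge cases

- Ties: greedy increments break toward the lowest member index; grid search
  toward earlier grid entries; vocabulary order is lexicographic in the
  environment identifier.
- `q²` and CCC raise on constant vectors, R²₀ on all-zero predictions, the
  scaler on zero training SDs (precluded by the variance filter), the
  spread on libraries of fewer than two members.
- Noise simulation draws without replacement by default; with-replacement
  is explicit opt-in.
- Scrambling a fraction amounting to fewer than two points is the identity.
- All stochastic routines take explicit integer seeds and are reproducible
  bit-for-bit from them.

## Known limitations

- The attribution guarantees hold for the additive synthetic truth; on real
  data with correlated substructure effects the predictive method reports
  the model's view, and its SD (context dependence) should be read alongside
  the mean.
- The full-scale benchmark (hundreds of members on thousands of datapoints)
  is supported (`default_library_specs("full")`) but not exercised by the
  default test run.
- The Student's method inherits the usual sample-size sensitivity of
  t-tests: tiny mean differences become significant on large sets.
- Selected binding-site columns are trusted input; no structure-based site
  extraction is performed.
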