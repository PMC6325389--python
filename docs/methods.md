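# Methods

## Scope and assumptions

`refpop` implements single-generation, infinitesimal-model selection theory
for genomic reference populations:

* The selection criterion (EBV), the true breeding value G and the GEBV
  are jointly normal; genetic variance is standardized to 1.
* Preselection is one round of truncation on EBV. The variance of the
  criterion among the survivors shrinks by k = i(i − x); the genetic
  variance by k·r²_EBV. No iterated (Bulmer-equilibrium) reduction and no
  multi-generation persistence of accuracy is modelled.
* Prediction errors of EBV and GEBV are uncorrelated, so
  corr(EBV, GEBV) = r_EBV·r_GEBV. This assumption is hard-coded.
* The unselected GEBV reliability is the deterministic prediction
  λr²/(λr² + 1) with λ = n_P/n_G and n_G = 2·N_E·L. Marker density, LD
  decay, genomic relationships and genetic correlations below 1 between
  bull and cow trait expressions are outside scope.
* Bulls contribute progeny-test information (daughter phenotypes), cows
  their own records. Adjusted reliabilities of the two groups combine via
  a two-source selection index with P = [[a, ac], [ac, c]], g = [a, c],
  i.e. r²_combined = (a + c − 2ac)/(1 − ac).

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| N_E | historical effective population size | 100 | typical for intensively selected dairy populations; n_G scales linearly in it |
| L | genome length (Morgans) | 30 | cattle autosomal map length |
| n_G | effective chromosome segments | 2·N_E·L = 6000 | derived |
| h² | heritability | scenario grid {0.1, 0.3, 0.5} | spans fitness-like to production traits |
| N | daughters per progeny-tested bull | 50 or 100 | the two standard progeny-test sizes |
| n_P | reference-population size | {5000, 10000, 20000, 40000} | realistic national reference populations |
| p (bulls) | preselection percentage | {5, 30, 100} | intense male selection |
| p (cows) | preselection percentage | {70, 80, 90, 100} | mild female selection |
| sire_daughters (cow index) | daughters behind the sire EBV inside the cow's PA/index | 50 | see conventions below |

Percentages cross the API boundary on the 0–100 scale and are converted to
fractions internally. λ is kept real-valued; reference sizes are never
rounded to integers inside the math.

## Reconstructed combining rules

Two formulas the deterministic pipeline needs are not standard-form inputs
and were reconstructed and verified against the reference reliability
table (exact to 3 decimals at all three heritabilities, asserted in the
test suite):

* parent average: r²_PA = (r²_sire + r²_dam)/4 with r²_dam = h² (dam's own
  record);
* cow EBV (preselection on own record): selection index of PA and the own
  record with Var(PA) = Cov(PA, G) = Cov(PA, record) = r²_PA,
  Var(record) = 1/h², Cov(record, G) = 1 on the σ²_G = 1 scale.

## Numerical choices

* Normal quantile/density delegate to scipy (`|Δx| < 1e−9`); k = i(i − x)
  is validated against 1 − Var(Z | Z > x) by direct numeric integration to
  1e−8 across p ∈ {0.01, …, 0.99}.
* p = 1 (no selection) bypasses the truncation math exactly: k = 0, i = 0,
  x reported as −inf.
* Forward/backward transforms (preselection adjust ↔ de-select,
  reliability ↔ required size) are exact algebraic inverses; property
  tests hold them to 1e−12 over the realistic domain (the size↔reliability
  round trip degrades near reliability 1 − 1e−8, where the subtraction
  1 − r² cancels in double precision).
* Table comparisons use round-half-up at the printed precision, applied as
  a display step separate from the full-precision computation.

## Truncation-constant conventions

Regenerating the published scenario tables exposed two internally
consistent precision regimes in the source. Inverting every printed cell
of the bull tables for the k it implies gives k(5%) ≈ 0.86234 and
k(30%) ≈ 0.73597 — exactly the values obtained from x and i rounded to
three decimals, the precision of classical textbook selection-intensity
tables — while the cow tables imply full-precision constants. The package
therefore:

* defaults to exact constants everywhere in the library API;
* offers `constants="textbook"` (x, i rounded to 3 decimals) on
  `variance_reduction`, and uses it for the bull side of the
  publication-reproduction grids (tables 1, 4 and the bull column of table 7),
  exact constants for the cow side.

## Known discrepancies in the reference tables

After adopting those conventions, 20 of 369 transcribed cells still differ
from recomputation. Nineteen differ by exactly one unit in the last
printed decimal (isolated rounding slips; one of them, the unselected cow
reliability 0.4546 at h² = 0.5/n_P = 10,000, is a double-rounding of
0.45455). One is an outright misprint: the combined reliability printed as
0.670 for h² = 0.3, 20,000 cows, 5–100%, is inconsistent with the same
row's printed per-group values (0.524, 0.500), which give 0.678. All 20
carry a `note` in the packaged CSVs, are excluded from hard equality
assertions, and are soft-reported with a 1-ulp bound (10-ulp for the
misprint).

Two structural issues are reported rather than asserted:

* **Cow-table block labels.** The printed preselected-on-PA block of the
  cow reliability table holds the *lower* values, although selecting on
  the less reliable PA must cost the least reliability (the bias table and
  the equivalence table obey this ordering). The computational assignment
  reproduces all cells; `table2_label_swap_report()` quantifies the swap
  (9 vs 74 mismatching cells under the two assignments).
* **Bulls-per-cow inside the mixed population.** The literal
  back-conversion pipeline (reliability gain → unselected scale →
  equivalent bulls → per cow) does not reduce to the collapsed
  equal-reliability ratio: 0.0410 vs 0.1688 for the benchmark mixed
  scenario. Both routes are implemented and exposed; no equality is
  asserted. The mixed-table "– 70" cow rows only reproduce when the cow
  index uses a 100-daughter sire, although the cows-only convention is 50;
  `cow_ebv_reliability(h2, sire_daughters)` therefore takes the daughter
  count as a parameter and the mixed-table grid sets 100.

## Monte-Carlo validator

The validator draws (G, EBV, GEBV) from the implied covariance
(Var(EBV) = Cov(EBV, G) = r²_EBV, Var(GEBV) = Cov(GEBV, G) = r²_GEBV,
Cov(EBV, GEBV) = r²_EBV·r²_GEBV on the σ²_G = 1 scale) via a symmetric
eigen square root, selects the exact top-p fraction by rank (order
statistics, avoiding threshold discreteness), and estimates the selected-
set criterion-variance ratio, squared correlation of G and GEBV, and
regression slope of G on GEBV, each with a 200-resample nonparametric
bootstrap SE. Because truncation of one margin of a multivariate normal
obeys Pearson's selection formulas exactly, empirical and analytic values
must agree up to Monte-Carlo noise; the acceptance suite checks 12
scenarios spanning h² ∈ {0.1, 0.3, 0.5} and p ∈ {0.05, 0.3, 0.7} at 10⁶
draws against a 3-SE band. Generators are numpy PCG64 streams; scenario
seeds are spawned deterministically from the user seed and recorded in the
report. The simulator validates the selection algebra only — it simulates
no genotypes, markers or pedigrees, so agreement says nothing about how
well λr²/(λr² + 1) describes a real genotyped population.

## Problem sizes

Everything analytic runs in milliseconds (the full seven-table regeneration
is bounded at 5 s in the tests and takes well under 1 s). The Monte-Carlo
acceptance check uses 10⁶ draws × 12 scenarios with 200 bootstrap
resamples, about half a minute on one CPU; unit tests use 2×10⁴–2×10⁵
draws.

## Limitations

* Single generation, single trait, two groups at most in the mixed index.
* No finite-population corrections to selection intensity; criteria are
  exactly normal.
* The deterministic reliability formula ignores genomic relationships
  between reference and candidate animals; observed validation accuracies
  on real data are not directly comparable.
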