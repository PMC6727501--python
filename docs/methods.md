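# Methods

## The problem

Hospitals reimbursed under diagnosis-related groups (DRGs) are paid a
bundled rate for cases with similar clinical characteristics and
resource consumption. Up-coding — inflating individual fee items so a
case reimburses more than its resource use warrants — is traditionally
caught by peer review of the full expenditure list, after which the
insurer *deducts* the offending items. `drgrasch` implements a
model-based screen: within one DRG, a reference ("norm") group of clean
claims calibrates what each fee item typically costs relative to the
case total; a new discharge case is then scored item by item, and items
claimed far above their model expectation are flagged as probable
deductions before the insurer ever audits them.

## Model

Each case *n* in a DRG has fees on up to *I* items. A fee of zero (or
an absent row) means no expenditure on that item and is treated as
missing everywhere: such cells never enter normalization bounds,
calibration, or residuals. Observed fees are min–max normalized
against the norm group of the same DRG,

    O_ni = (fee_ni − min_i) / (max_i − min_i),

clamped symmetrically to [ε, 1 − ε] with ε = 0.005. The raw transform
attains exactly 0 and 1 at the group extremes, which makes logistic
score contributions unbounded; the clamp is the usual extreme-score
adjustment and is configurable. Bounds come from the norm group only —
it is the reference standard — and experimental fees outside the norm
range clamp to the ends.

The normalized fee is modeled by the continuous-response Rasch form

    E_ni = exp(θ_n − δ_i) / (1 + exp(θ_n − δ_i)),
    Var_ni = E_ni (1 − E_ni),

where θ_n (case ability, logits) is the case's overall fee level within
its DRG and δ_i (item difficulty, logits) is high for items that are
systematically small or rare relative to the case total — on this scale
a high fee is an "easy" item. The quasi-binomial variance E(1 − E) is
taken literally from the score equations; no parametric density beyond
the mean/variance structure is assumed.

### Estimation

Ability for a case with observed item set I_n solves the score
condition Σ_{i∈I_n} (O_ni − E_ni) = 0 by Newton–Raphson:

    θ ← θ + Σ(O − E) / Σ Var,

starting at 0, each step capped at 1.0 logit (the variance in the
denominator vanishes in the logistic tails, so uncapped steps can
overshoot from poor starts), stopping when the step falls below the
tolerance (default 1e-4, max 100 iterations). With a single observed
item this reduces to the one-cell update and has the closed form
θ = δ + logit(O). The standard error is 1/√(Σ Var) at the estimate.
Only observed items contribute — cases missing most fees are scored on
what they have, in the spirit of adaptive testing.

Item difficulties are calibrated jointly (JMLE-style alternation): (a)
a full ability solve for every norm case given current δ, (b) one
mirrored Newton step per item, δ ← δ − Σ_n(O − E)/Σ_n Var over the
cases observing it, (c) re-centering δ to mean zero (the logit scale's
location is otherwise unidentified; θ is shifted by the same constant
so θ − δ is invariant across sweeps). Convergence is declared when the
largest difficulty update in a sweep is below tolerance. Items observed
by fewer than two cases, zero-variance (degenerate) items, and item
blocks sharing no case with the rest are rejected up front with the
offending items named. The procedure is deterministic given input
order; case-order permutations move estimates only within tolerance.

### Residual detection

For each observed cell of a scored case,

    Z_ni = (O_ni − E_ni) / √Var_ni.

An item with Z > 2.0 (strict inequality; roughly the one-tailed 5%
criterion for small samples) is flagged as probably up-coded. The
upper side is the default because deductions target inflated fees; a
two-sided mode (|Z| > 2) is available for reporting items *under*
expectation. Outfit MNSQ — the unweighted mean of Z² over the case's
observed cells — is reported as a person-fit summary but is not used
for flagging. Ability is deliberately estimated from *all* observed
items including a potentially up-coded one, matching the operational
setting where the contaminated claim is all there is.

A structural property worth knowing: given E, the largest attainable Z
is (1 − ε − E)/√(E(1 − E)), which is below 2.0 whenever E ≳ 0.17. A
one-sided Z > 2 flag can therefore only fire on cells whose expected
normalized fee is low — a "hard" item claimed near the norm maximum.
That is exactly the canonical up-coding signature (a rarely-billed item
suddenly claimed at a high amount), but it means additive mid-scale
inflation is detectable by ranking (AUC) long before it is flaggable at
the 2.0 criterion.

## Evaluation

Flags are compared against the insurer's per-item deduction labels.
Two per-case correctness notions are implemented and surfaced in
configuration: **matched** (some actually-deducted item was flagged;
cases with no deduction are not evaluable and are excluded with a
count) and **any** (the case was flagged at all). Year-stratified
correct/incorrect counts are tested for homogeneity with the Pearson
chi-square **without** continuity correction — the uncorrected statistic
reproduces the published audit tables' p-values (0.19 for the year
table; Yates correction would give ≈ 0.24), which pins the convention.
When one outcome column is empty the statistic is defined as 0 (p = 1).
Per-category tables count a case correct when "any item in the
category flagged" agrees with "any item in the category deducted", so
every labeled case is evaluable in every category.

ROC analysis uses the Mann–Whitney rank formulation of the AUC
(midranks for ties, so AUC = (concordant + ½·ties)/(n₊·n₋)) with the
Hanley–McNeil exponential-approximation standard error and a two-sided
normal test against the chance value 0.5. The case-level unit of
analysis per category takes the maximum Z over the category's observed
items as the score and "any deduction in the category" as the label;
an item-level ROC over all residual cells is also provided and is what
the acceptance run reports. DeLong comparisons between two AUCs and
multiple-testing corrections are out of scope.

## Synthetic data

The generator emulates the study design the detector targets: one DRG
with 300 norm cases and 194 audited cases on a 17-item schema, each
audited case up-coded on one item. Difficulties and abilities are
N(0, 1); each observed cell draws its normalized fee from a Beta with
mean E_ni and precision m (shapes E·m and (1−E)·m, default m = 9);
cells go missing independently with probability 0.1; fees are the
normalized value times a fixed per-item currency scale (default
25 000, an arbitrary unit). Up-coding adds Δ = 0.4 on the normalized
scale, capped below 1 − ε, and exports the injected pairs as the
"deducted" labels. Each purpose (difficulties, abilities, noise,
missingness, injection) uses its own RNG stream spawned from the master
seed, so toggling injection never perturbs the base data.

The Beta family respects the (0, 1) support the normalization imposes,
but its variance E(1−E)/(1+m) is deliberately *smaller* than the
model's nominal E(1−E): a normalized fee is one bounded measurement,
not a binomial proportion. Null residuals are therefore
under-dispersed (per-cell sd of Z ≈ 1/√(1+m) ≈ 0.32 at the default
precision) and the z > 2 false-flag rate is conservative — far below
the nominal 2.5%. Tests rely on these conservative bounds, not on
nominal calibration of Z as a standard normal.

Consequences for interpreting the synthetic results: with a moderate
additive shift of 0.4, injected cells separate cleanly from clean
cells by rank (item-level AUC ≈ 0.95 at defaults) but rarely cross the
absolute Z > 2 criterion, because of the attainable-Z ceiling described
above. Matched-mode accuracy on synthetic data is therefore near zero
even while detection power is high — the published ≈ 0.82 correct rate
arose from real audited claims whose deducted items were extreme
relative to the norm, a regime the generator reproduces only when the
up-coded item is a hard (low-E) one. The generator makes no attempt to
imitate real Taiwanese fee distributions, DRG weights, or hospital
case mix, and passing tests accordingly validate the machinery and its
statistical behavior, not field performance.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| ε (clamp) | 0.005 | normalized-score clamp; keeps likelihood finite |
| tol | 1e-4 | max parameter update at convergence (logits) |
| max_iter | 100 | Newton iterations / JMLE sweeps |
| step cap | 1.0 | max logit change per Newton step |
| threshold | 2.0 | Z flag criterion, strict, upper-sided |
| m | 9 | Beta precision of synthetic noise |
| Δ | 0.4 | injected up-coding shift (normalized scale) |
| p_miss | 0.1 | per-cell missingness in synthetic data |

Ties at the flag threshold are resolved by the strict inequality
(measure-zero in continuous data; the convention is fixed). Degenerate
inputs fail loudly and early: empty observation sets, observations at
0/1, disconnected designs, zero-variance items, single-case norm
groups.

## Problem sizes

The test suite and the acceptance run use the design sizes themselves
(300 × 17 calibration, 194 scored cases), with 5 replicates for the
stochastic checks (difficulty recovery, AUC monotonicity in Δ); the
vectorized calibration makes a full study a sub-second computation, so
no down-scaling was needed.

## Known limitations

- Supports the plain one-parameter continuous Rasch form only: no
  discrimination/guessing parameters, no polytomous models, no Bayesian
  estimation.
- JMLE difficulty estimates carry the usual finite-sample bias; with
  300 cases per DRG the recovery correlation exceeds 0.99 in
  simulation, so no bias correction is applied.
- The Z statistic treats the calibrated difficulties as known; the
  calibration uncertainty (SE of δ) is reported and drawn as bubble
  size in the dashboard payload but not propagated into Z.
- The attainable-Z ceiling means upper-sided flags cannot fire on
  items the case is expected to use heavily, whatever the inflation.
- One hospital-style norm group per DRG is assumed exchangeable; if
  DRGs do not share a fee structure across institutions the calibrated
  model does not transfer.
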