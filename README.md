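# drgrasch

Screening of DRG hospital claims for probable reimbursement deductions
with a continuous-response Rasch model.

Hospitals paid under diagnosis-related groups (DRGs) sometimes up-code:
individual fee items are claimed far above what the case's resource use
warrants, and the insurer later deducts them after audit. `drgrasch`
flags such items *before* audit. For each DRG, a norm group of clean
claims calibrates item difficulties; new discharge cases are then
scored item by item and outliers are flagged. The intended users are
hospital claims/quality departments and payer-side auditors.

## Model

Within a DRG, each observed fee is min–max normalized to
O ∈ (0, 1) against the norm group, and modeled by

    E_ni = exp(θ_n − δ_i) / (1 + exp(θ_n − δ_i)),   Var_ni = E_ni(1 − E_ni),

where θ_n is the case's overall fee level (ability, logits) and δ_i is
the item difficulty (high δ = item typically cheap/rare; a high fee is
an "easy" item). Abilities solve Σ(O − E) = 0 by Newton–Raphson over
the observed items only — zero fees are missing data and are ignored;
difficulties are jointly calibrated on the norm group with a mean-zero
centering. Each cell's standardized residual

    Z_ni = (O_ni − E_ni) / √Var_ni

flags the item as a probable deduction when Z > 2.0. Outfit MNSQ
(mean Z² per case) summarizes person fit. Flags are evaluated against
per-item audit labels with correct-rate tables, uncorrected Pearson
chi-square year comparisons, and Mann–Whitney ROC AUC with a
Hanley–McNeil test against 0.5. See `docs/methods.md` for assumptions,
defaults, and limitations.

## Worked example

```python
from drgrasch import (SimConfig, simulate_study, fit_norm_model, score_claimset,
                      labels_from_claimset, item_level_roc)

cfg = SimConfig(seed=42)           # 300 norm + 194 audited cases, 17 items
norm, _, exp, _ = simulate_study(cfg)

model = fit_norm_model(norm, cfg.drg_code)
print(f"calibrated {len(model.items)} items in "
      f"{model.convergence.iterations} sweeps")

result = score_claimset(exp, {cfg.drg_code: model})
worst = max(result.scored(), key=lambda s: s.max_z())
print(f"case {worst.case_id}: ability {worst.ability.theta:.2f} logits, "
      f"outfit MNSQ {worst.outfit_mnsq:.2f}, max Z {worst.max_z():.2f}, "
      f"flagged {sorted(worst.flagged_items)}")

roc = item_level_roc(result.scored(), labels_from_claimset(exp))
print(f"item-level AUC {roc.auc:.3f} (p vs 0.5: {roc.p_vs_half:.2e}, "
      f"{roc.n_pos} deducted / {roc.n_neg} clean cells)")
```

prints

```
calibrated 17 items in 6 sweeps
case E0026: ability -1.06 logits, outfit MNSQ 0.31, max Z 1.93, flagged []
item-level AUC 0.954 (p vs 0.5: 0.00e+00, 194 deducted / 2767 clean cells)
```

The synthetic study injects one up-coded item into every audited case
(an additive shift of 0.4 on the normalized fee scale). The AUC of
0.954 says the Z-score ranks the 194 deducted cells far above the 2 767
clean ones; the most aberrant case here still sits below the absolute
Z > 2 flag because its inflated item is one the model expects to be
mid-range — see `docs/methods.md` on the attainable-Z ceiling.

## Command line

The same workflow runs from files alone:

```sh
drgrasch simulate  --out sim --seed 42
drgrasch calibrate --claims sim/norm.csv --out model.json
drgrasch score     --claims sim/experimental.csv --model model.json --out scores.json
drgrasch evaluate  --scores scores.json --claims sim/experimental.csv --out eval
drgrasch report    --scores scores.json --model model.json --out dashboard
```

`report` writes one bubble-chart payload per case (item difficulty on
Y, residual Z on X, bubble size = difficulty SE, the case's ability as
a distinct bubble, threshold line at Z = 2) as deterministic JSON plus
a static HTML view.

Claims travel as long-format CSV — `case_id,drg,year,item,fee[,deducted]`,
one row per case-item, zero/absent fee = no expenditure (missing).

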