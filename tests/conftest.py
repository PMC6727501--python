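import pytest

from drgrasch import (
    SimConfig,
    fit_norm_model,
    labels_from_claimset,
    score_claimset,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study at default conditions: 300 norm cases,
    194 experimental cases, 17 items, one up-coded item per case."""
    cfg = SimConfig(seed=42)
    norm_set, norm_truth, exp_set, exp_truth = simulate_study(cfg)
    model = fit_norm_model(norm_set, cfg.drg_code)
    result = score_claimset(exp_set, {cfg.drg_code: model})
    return {
        "config": cfg,
        "norm_set": norm_set,
        "norm_truth": norm_truth,
        "exp_set": exp_set,
        "exp_truth": exp_truth,
        "model": model,
        "result": result,
        "labels": labels_from_claimset(exp_set),
    }


@pytest.fixture(scope="session")
def small_study():
    """A miniature study for fast I/O and CLI round trips."""
    cfg = SimConfig(seed=7, n_norm=40, n_exp=12, n_items=6, p_miss=0.05)
    norm_set, norm_truth, exp_set, exp_truth = simulate_study(cfg)
    model = fit_norm_model(norm_set, cfg.drg_code)
    result = score_claimset(exp_set, {cfg.drg_code: model})
    return {
        "config": cfg,
        "norm_set": norm_set,
        "exp_set": exp_set,
        "exp_truth": exp_truth,
        "model": model,
        "result": result,
        "labels": labels_from_claimset(exp_set),
    }
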