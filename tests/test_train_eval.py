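"""Training protocol: splits, RMSE, CV folds, reports, determinism."""

import math

import numpy as np
import pytest

import molgat as mg
from molgat.train_eval import (TrainConfig, _largest_remainder_sizes,
                               ablation_run, descriptor_table, kfold_cv,
                               node_position_report, rf_baseline, rmse,
                               split_dataset, train)


def small_dataset(mode="constant", n=60, noise=0.0, seed=0):
    spec = mg.SyntheticSpec(n_molecules=n, grammar="mixed", target_mode=mode,
                            noise_sd=noise, seed=seed)
    return mg.make_dataset(spec)


FAST = dict(epochs=150, early_stop_patience=40)


# --- splitting -------------------------------------------------------------

def test_split_exact_division():
    tr, va, te = split_dataset(list(range(100)), (0.8, 0.1, 0.1), seed=0)
    assert (len(tr), len(va), len(te)) == (80, 10, 10)


def test_split_covers_and_disjoint_odd_n():
    items = list(range(101))
    parts = split_dataset(items, (0.8, 0.1, 0.1), seed=1)
    joined = [x for p in parts for x in p]
    assert sorted(joined) == items
    assert sum(map(len, parts)) == 101


def test_split_deterministic():
    a = split_dataset(list(range(50)), seed=3)
    b = split_dataset(list(range(50)), seed=3)
    assert a == b
    assert a != split_dataset(list(range(50)), seed=4)


def test_split_rejects_bad_fractions():
    with pytest.raises(ValueError):
        split_dataset(list(range(10)), (0.5, 0.2, 0.2), seed=0)


def test_largest_remainder_rounding():
    assert _largest_remainder_sizes(10, (0.8, 0.1, 0.1)) == [8, 1, 1]
    assert sum(_largest_remainder_sizes(13, (0.8, 0.1, 0.1))) == 13


# --- rmse ------------------------------------------------------------------

def test_rmse_zero_and_hand_value():
    assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(
        math.sqrt(12.5), abs=1e-6)


def test_rmse_homogeneity(rng):
    p, t = rng.normal(size=20), rng.normal(size=20)
    assert rmse(3.5 * p, 3.5 * t) == pytest.approx(3.5 * rmse(p, t))


def test_rmse_matches_two_pass_oracle(rng):
    p, t = rng.normal(size=101), rng.normal(size=101)
    acc = 0.0
    for a, b in zip(p, t):  # brute-force two-pass accumulation
        acc += (a - b) ** 2
    assert rmse(p, t) == pytest.approx(math.sqrt(acc / 101), abs=1e-10)


def test_rmse_length_mismatch():
    with pytest.raises(ValueError):
        rmse([1.0], [1.0, 2.0])


# --- training --------------------------------------------------------------

def test_constant_target_fit():
    """The model can drive a constant-target RMSE to ~0."""
    records = small_dataset("constant")
    tc = TrainConfig(seed=0, **FAST)
    tr, va, te = split_dataset(records, tc.split, 0)
    model, hist = train(tr, va, mg.ModelConfig(seed=0), tc)
    assert hist["best_val_rmse"] < 0.05


def test_training_deterministic():
    records = small_dataset("constant")
    tc = TrainConfig(seed=2, epochs=30, early_stop_patience=30)
    tr, va, _ = split_dataset(records, tc.split, 2)
    m1, h1 = train(tr, va, mg.ModelConfig(seed=2), tc)
    m2, h2 = train(tr, va, mg.ModelConfig(seed=2), tc)
    for k in m1.params:
        assert np.array_equal(m1.params[k].data, m2.params[k].data)
    assert h1["train_rmse"] == h2["train_rmse"]


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        train([], [], mg.ModelConfig(), TrainConfig())


# --- k-fold CV -------------------------------------------------------------

def test_kfold_fold_arithmetic_and_constant_targets():
    records = small_dataset("constant", n=50)
    tc = TrainConfig(seed=0, k_folds=5, epochs=60, early_stop_patience=60)
    report = kfold_cv(records, mg.ModelConfig(seed=0), tc)
    assert len(report.fold_rmses) == 5
    assert report.fold_mean < 0.1
    assert report.n_evaluated == len(records)


def test_kfold_rejects_too_few_records():
    with pytest.raises(ValueError):
        kfold_cv(small_dataset(n=3), mg.ModelConfig(),
                 TrainConfig(k_folds=5))


# --- node-position report --------------------------------------------------

def test_report_has_all_ten_strategies_and_exclusion_count():
    records = small_dataset("constant", n=40, seed=3)
    model = mg.build_model(mg.ModelConfig(seed=0))
    report = node_position_report(model, records)
    assert set(report.per_strategy) == set(mg.READOUT_KINDS)
    n_small = sum(
        1 for r in records if mg.parse_smiles(r.smiles).GetNumAtoms() < 5
    )
    assert report.n_excluded_small == n_small
    assert all(v >= 0 for v in report.per_strategy.values())


def test_constant_output_model_gives_equal_rmse_everywhere():
    # an untrained model with zeroed final layer predicts 0 for every node
    records = small_dataset("constant", n=30, seed=4)
    model = mg.build_model(mg.ModelConfig(seed=0))
    last = model.config.n_layers - 1
    for k, p in model.params.items():
        if k.startswith(f"layer{last}."):
            p.data[:] = 0.0
    report = node_position_report(model, records)
    vals = list(report.per_strategy.values())
    assert max(vals) - min(vals) < 1e-12


def test_report_rejects_empty_test_set():
    model = mg.build_model(mg.ModelConfig())
    with pytest.raises(ValueError):
        node_position_report(model, [])


# --- ablation --------------------------------------------------------------

def test_identity_mask_equals_default_and_duplicates_identical():
    records = small_dataset("constant", n=40, seed=5)
    tc = TrainConfig(seed=1, epochs=40, early_stop_patience=40)
    mc = mg.ModelConfig(seed=1)
    rows = ablation_run(
        records,
        [(mc, None), (mc, np.ones(35, dtype=bool)), (mc, list(range(35)))],
        tc,
    )
    assert rows[0]["test_rmse"] == rows[1]["test_rmse"] == rows[2]["test_rmse"]


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        ablation_run(small_dataset(n=20),
                     [(mg.ModelConfig(), np.zeros(35, dtype=bool))],
                     TrainConfig(epochs=5))


# --- random forest ---------------------------------------------------------

def test_rf_constant_targets_and_determinism():
    records = small_dataset("constant", n=50, seed=6)
    a = rf_baseline(records, n_trees=20, seed=0)
    b = rf_baseline(records, n_trees=20, seed=0)
    assert a == b
    assert a < 0.05


def test_descriptor_table_is_finite():
    records = small_dataset("constant", n=15, seed=7)
    X, y, kept = descriptor_table(records)
    assert np.all(np.isfinite(X))
    assert X.shape[0] == len(y) == len(kept)
    assert X.shape[1] > 21  # globals plus the standard descriptor set


# --- grid search and fold export -------------------------------------------

def test_grid_search_picks_best_validation_lr():
    records = small_dataset("constant", n=40, seed=8)
    tc = TrainConfig(seed=0, epochs=25, early_stop_patience=25)
    from molgat.train_eval import grid_search_lr
    best, scores = grid_search_lr(records, mg.ModelConfig(seed=0), tc,
                                  grid=(1e-2, 1e-3))
    assert set(scores) == {1e-2, 1e-3}
    assert scores[best] == min(scores.values())


def test_kfold_exports_disjoint_covering_folds():
    records = small_dataset("constant", n=40, seed=9)
    tc = TrainConfig(seed=3, k_folds=4, epochs=20, early_stop_patience=20)
    report = kfold_cv(records, mg.ModelConfig(seed=3), tc)
    flat = sorted(i for fold in report.fold_indices for i in fold)
    assert flat == list(range(40))
    assert len(report.fold_indices) == 4


def test_named_feature_subsets_have_expected_widths():
    from molgat.train_eval import FEATURE_SUBSETS
    widths = {k: int(v.sum()) for k, v in FEATURE_SUBSETS.items()}
    assert widths["full"] == 35
    assert widths["atomic_only"] == 14
    assert widths["no_geometry"] == 29          # atomic + 15 chemical
    assert widths["geometry_extent"] == 32      # + width/length/height
    # every subset keeps the atomic block
    for mask in FEATURE_SUBSETS.values():
        assert mask[:14].all()


def test_ablation_supports_named_subsets_and_layer_swaps():
    from molgat.train_eval import FEATURE_SUBSETS
    records = small_dataset("constant", n=30, seed=11)
    tc = TrainConfig(seed=0, epochs=15, early_stop_patience=15)
    variants = [
        (mg.ModelConfig(seed=0), FEATURE_SUBSETS["no_geometry"]),
        (mg.ModelConfig(seed=0, layer_type="gcn"), None),
        (mg.ModelConfig(seed=0, layer_type="gatv2"), None),
    ]
    rows = ablation_run(records, variants, tc)
    assert [r["layer_type"] for r in rows] == ["gat", "gcn", "gatv2"]
    assert rows[0]["n_features"] == 29
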