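"""Luciferase normalization, one-sample tests, proportions, morphometry."""
import numpy as np
import pandas as pd
import pytest

from clipfunnel.reporter import (normalize_luciferase, one_sample_tests,
                                 paired_morphometry, proportion_test)
from clipfunnel.simulate import simulate_luciferase_wells


def wells_frame(records):
    return pd.DataFrame(records, columns=["construct_id", "condition",
                                          "biological_replicate",
                                          "technical_replicate", "firefly", "renilla"])


def uniform_wells(constructs=("empty", "utrA"), n_bio=2, n_tech=4,
                  firefly=2000.0, renilla=1000.0):
    recs = []
    for c in constructs:
        for cond in ("effector", "control_effector"):
            for b in range(n_bio):
                for t in range(n_tech):
                    recs.append((c, cond, f"b{b}", f"t{t}", firefly, renilla))
    return wells_frame(recs)


def test_identical_wells_normalize_to_zero():
    acts = normalize_luciferase(uniform_wells(), control_construct="empty")
    assert np.allclose(acts["log2_activity"], 0.0)


def test_doubled_firefly_in_one_construct_gives_plus_one():
    wells = uniform_wells()
    mask = (wells["construct_id"] == "utrA") & (wells["condition"] == "effector")
    wells.loc[mask, "firefly"] *= 2.0
    acts = normalize_luciferase(wells, control_construct="empty")
    by = acts.groupby("construct_id")["log2_activity"].mean()
    assert by["utrA"] == pytest.approx(1.0)
    assert by["empty"] == pytest.approx(0.0)


def test_normalization_invariant_under_per_replicate_firefly_rescale():
    wells = simulate_luciferase_wells({"utrA": -0.5, "utrB": 0.3}, seed=4)
    base = normalize_luciferase(wells, control_construct="empty")
    scaled = wells.copy()
    for i, b in enumerate(sorted(scaled["biological_replicate"].unique())):
        scaled.loc[scaled["biological_replicate"] == b, "firefly"] *= 3.7 * (i + 1)
    rescaled = normalize_luciferase(scaled, control_construct="empty")
    np.testing.assert_allclose(base["log2_activity"], rescaled["log2_activity"],
                               atol=1e-12)


def test_planted_effect_recovered():
    wells = simulate_luciferase_wells({"utrA": -0.5}, n_bio=6, n_tech=4,
                                      sigma=0.05, seed=8)
    acts = normalize_luciferase(wells, control_construct="empty")
    mean = acts.loc[acts["construct_id"] == "utrA", "log2_activity"].mean()
    assert mean == pytest.approx(-0.5, abs=0.05)


def test_without_effector_norm_uses_control_construct_only():
    wells = uniform_wells()
    mask = (wells["construct_id"] == "utrA") & (wells["condition"] == "effector")
    wells.loc[mask, "firefly"] *= 4.0
    acts = normalize_luciferase(wells, control_construct="empty",
                                with_effector_norm=False)
    by = acts.groupby("construct_id")["log2_activity"].mean()
    assert by["utrA"] == pytest.approx(2.0)


def test_missing_control_pairing_and_zero_renilla_error():
    wells = uniform_wells(constructs=("utrA",))
    with pytest.raises(ValueError):
        normalize_luciferase(wells, control_construct="empty")
    bad = uniform_wells()
    bad.loc[0, "renilla"] = 0.0
    with pytest.raises(ValueError):
        normalize_luciferase(bad, control_construct="empty")


# --- one-sample tests ----------------------------------------------------


def activities(construct_to_values):
    rows = [(c, f"b{i}", v) for c, vals in construct_to_values.items()
            for i, v in enumerate(vals)]
    return pd.DataFrame(rows, columns=["construct_id", "biological_replicate",
                                       "log2_activity"])


def test_single_construct_padj_equals_p():
    out = one_sample_tests(activities({"a": [-0.4, -0.6, -0.5, -0.45]}))
    assert out.loc[0, "padj"] == pytest.approx(out.loc[0, "p"])


def test_padj_matches_hand_applied_bh_step_up():
    rng = np.random.default_rng(5)
    acts = activities({f"c{i}": rng.normal(0.2 * i, 0.3, 5).tolist() for i in range(6)})
    out = one_sample_tests(acts).sort_values("p", ignore_index=True)
    p = out["p"].to_numpy()
    m = len(p)
    # independent BH: step-up from the largest p
    expected = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[i] * m / (i + 1))
        expected[i] = running
    np.testing.assert_allclose(out["padj"].to_numpy(), expected, atol=1e-10)
    assert (np.diff(out["padj"]) >= -1e-12).all() and (out["padj"] <= 1).all()


def test_bh_worked_example_all_equal():
    from statsmodels.stats.multitest import multipletests
    padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    np.testing.assert_allclose(padj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_zero_variance_and_small_n_paths():
    with pytest.warns(UserWarning):
        out = one_sample_tests(activities({"flat": [0.5, 0.5, 0.5], "tiny": [0.1]}))
    assert list(out["construct_id"]) == ["flat"]
    assert out.loc[0, "p"] == 1.0 and bool(out.loc[0, "zero_variance"])


def test_type_one_error_calibrated_under_null():
    """1000 null constructs (true mean 0, n = 6): rejection rate at alpha=0.05
    stays within binomial tolerance."""
    rng = np.random.default_rng(6)
    acts = activities({f"n{i:04d}": rng.normal(0, 1, 6).tolist() for i in range(1000)})
    out = one_sample_tests(acts)
    rate = (out["p"] < 0.05).mean()
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000) + 0.005


# --- proportion test -----------------------------------------------------


def test_proportion_equal_rates_chi2_zero():
    res = proportion_test(30, 70, 15, 35)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)


def test_proportion_matches_closed_form():
    res = proportion_test(70, 30, 5, 95)
    obs = np.array([[70, 30], [5, 95]], dtype=float)
    row, col, tot = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True), obs.sum()
    exp = row @ col / tot
    assert res.chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-10)


def test_proportion_zero_margin_errors():
    with pytest.raises(ValueError):
        proportion_test(0, 100, 0, 50)


# --- paired morphometry --------------------------------------------------


def measurements(n_larvae, lens_shrink=0.7, noise=0.0, seed=0, unpaired=False):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_larvae):
        for side in ("control", "injected"):
            scale = lens_shrink if side == "injected" else 1.0
            for structure, minor, major in (("eye", 30.0, 40.0), ("lens", 10.0, 12.0)):
                s = scale if structure == "lens" else 1.0
                rows.append((f"L{i}", side, structure,
                             s * minor * (1 + rng.normal(0, noise)),
                             s * major * (1 + rng.normal(0, noise)), 5.0))
        if unpaired and i == 0:
            rows = [r for r in rows if not (r[0] == "L0" and r[1] == "injected")]
    return pd.DataFrame(rows, columns=["larva_id", "side", "structure",
                                       "minor_diameter", "major_diameter",
                                       "cornea_thickness"])


def test_area_is_product_of_diameters():
    df = pd.DataFrame([("L0", "control", "eye", 2.0, 3.0, None),
                       ("L0", "injected", "eye", 2.0, 3.0, None),
                       ("L0", "control", "lens", 1.0, 1.0, None),
                       ("L0", "injected", "lens", 1.0, 1.0, None)],
                      columns=["larva_id", "side", "structure", "minor_diameter",
                               "major_diameter", "cornea_thickness"])
    records, _, _ = paired_morphometry(df)
    assert set(records.loc[records["structure"] == "eye", "area"]) == {6.0}


def test_identical_sides_give_p_one_with_flag():
    df = measurements(5, lens_shrink=1.0, noise=0.0)
    with pytest.warns(UserWarning):
        _, _, tests = paired_morphometry(df)
    assert (tests["p"] == 1.0).all() and tests["zero_variance"].all()


def test_lens_reduction_detected_in_most_seeds():
    """30% paired lens-area reduction with 5% measurement noise, n=8 larvae:
    the paired t test detects it (p < 0.05) in at least 90% of seeds."""
    detected = 0
    n_seeds = 20
    for seed in range(n_seeds):
        df = measurements(8, lens_shrink=np.sqrt(0.7), noise=0.05, seed=seed)
        _, _, tests = paired_morphometry(df)
        p = tests.set_index("endpoint").loc["lens_area", "p"]
        detected += p < 0.05
    assert detected >= 0.9 * n_seeds


def test_unpaired_larva_dropped_with_warning():
    df = measurements(6, noise=0.05, seed=1, unpaired=True)
    with pytest.warns(UserWarning, match="unpaired"):
        _, _, tests = paired_morphometry(df)
    assert (tests["n_pairs"] == 5).all()


def test_invariance_to_order_and_unit_rescale():
    df = measurements(8, noise=0.05, seed=2)
    _, _, base = paired_morphometry(df)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    _, _, reordered = paired_morphometry(shuffled)
    scaled = df.copy()
    scaled[["minor_diameter", "major_diameter"]] *= 1000.0  # mm -> um
    _, _, rescaled = paired_morphometry(scaled)
    for other in (reordered, rescaled):
        np.testing.assert_allclose(base["p"].to_numpy(), other["p"].to_numpy(),
                                   atol=1e-9)
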