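"""Analysis-group construction, Stage-1 bootstrap pairs, and the Stage-2
logit-linear mixed-effects scaling model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from cptscale.scaling import (
    PersistenceScaling,
    PersistenceScalingResults,
    build_analysis_groups,
    clipped_logit,
    stage1_pairs,
    summarize_studies,
)
from cptscale.simulate import (
    MetaSimConfig,
    ScalingTruth,
    default_group_cells,
    simulate_meta_dataset,
    simulate_scaling_pairs,
)
from cptscale.trials import records_to_frame


def study_row(study, site, state="WY", habitat="grassland", region="R6",
              n_raptor=10, n_gamebird=10):
    return {"study_id": study, "site_id": site, "state": state,
            "region": region, "habitat": habitat, "n_raptor": n_raptor,
            "n_gamebird": n_gamebird, "seasons": {"fall"}}


# --- analysis groups ------------------------------------------------------


def test_same_site_studies_merge_until_adequate():
    studies = pd.DataFrame([
        study_row("y1", "siteA", n_raptor=5, n_gamebird=9),
        study_row("y2", "siteA", n_raptor=6, n_gamebird=9),
    ])
    groups = build_analysis_groups(studies)
    assert len(groups) == 1
    assert groups[0].n_raptor == 11 and groups[0].n_gamebird == 18
    assert sorted(groups[0].member_studies) == ["y1", "y2"]


def test_no_cross_state_merge_both_excluded():
    studies = pd.DataFrame([
        study_row("a", "siteA", state="WY", n_raptor=6),
        study_row("b", "siteB", state="CO", n_raptor=6),
    ])
    assert build_analysis_groups(studies) == []


def test_same_state_same_habitat_merge():
    studies = pd.DataFrame([
        study_row("a", "siteA", n_raptor=5),
        study_row("b", "siteB", n_raptor=5),
    ])
    groups = build_analysis_groups(studies)
    assert len(groups) == 1 and groups[0].n_raptor == 10
    assert groups[0].state == "WY"


def test_deficient_leftover_folds_into_adequate_same_cell():
    studies = pd.DataFrame([
        study_row("big", "siteA", n_raptor=20),
        study_row("tiny", "siteB", n_raptor=3),
    ])
    groups = build_analysis_groups(studies)
    assert len(groups) == 1 and groups[0].n_raptor == 23


def test_groups_never_deficient_nor_cross_state():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(25):
        rows.append(study_row(
            f"s{i:02d}", f"site{i % 12:02d}",
            state=["WY", "CO", "NE"][i % 3],
            habitat=["grassland", "cropland"][i % 2],
            n_raptor=int(rng.integers(2, 15)),
            n_gamebird=int(rng.integers(2, 15)),
        ))
    groups = build_analysis_groups(pd.DataFrame(rows))
    for g in groups:
        assert g.n_raptor >= 8 and g.n_gamebird >= 8
        assert len({g.state}) == 1


# --- stage 1 --------------------------------------------------------------


@pytest.fixture(scope="module")
def small_pipeline():
    truth = ScalingTruth(slope=4.0, re_sd_intercept=0.3, re_sd_slope=1.0,
                         resid_sd=0.2)
    cells = default_group_cells(n_groups=4, n_per_cell=30, seed=7)
    records, truth_ledger = simulate_meta_dataset(
        MetaSimConfig(cells=cells, scaling_truth=truth, seed=3)
    )
    df = records_to_frame(records)
    groups = build_analysis_groups(summarize_studies(df))
    data = stage1_pairs(groups, df, intervals=(14, 30, 60, 90), B=50, seed=5)
    return groups, data


def test_stage1_row_counts_and_pairing(small_pipeline):
    groups, data = small_pipeline
    cells = data.draws[["group_id", "season", "interval"]].drop_duplicates()
    # exactly B replicates per (group, season, interval) cell
    assert len(data.draws) == len(cells) * 50
    counts = data.draws.groupby(["group_id", "season", "interval"])["replicate"].agg(
        ["count", "min", "max"]
    )
    assert (counts["count"] == 50).all()
    assert (counts["min"] == 1).all() and (counts["max"] == 50).all()
    # one point-estimate row per cell
    assert len(data.points) == len(cells)


def test_stage1_probabilities_clipped_open_interval(small_pipeline):
    _, data = small_pipeline
    for col in ("gamebird_r", "raptor_r"):
        assert (data.draws[col] > 0).all() and (data.draws[col] < 1).all()


def test_logit_round_trip():
    p = np.array([1e-6, 0.01, 0.5, 0.99, 1 - 1e-6])
    np.testing.assert_allclose(expit(clipped_logit(p)), p, atol=1e-12)


# --- stage 2 --------------------------------------------------------------


def test_fit_scaling_recovers_generating_slope():
    truth = ScalingTruth(intercept=-0.7, slope=4.0, re_sd_intercept=0.3,
                         re_sd_slope=1.0, resid_sd=0.2)
    df = simulate_scaling_pairs(truth, n_groups=30, B=100, seed=12)
    res = PersistenceScaling(df).fit(candidate_fixed=[()])
    slope = res.fixed["gamebird_r"]
    se = res.fixed_se["gamebird_r"]
    assert abs(slope - 4.0) < 3 * se
    assert abs(res.fixed["intercept"] + 0.7) < 3 * res.fixed_se["intercept"]
    assert res.resid_sd == pytest.approx(0.2, abs=0.05)
    assert 0.0 <= res.icc <= 1.0


def test_null_covariates_usually_excluded_by_selection():
    """With no true season/region/habitat offsets, the parsimony rule should
    keep the covariate-free model in most replicates."""
    labels = [{"region": ["R1", "R2"][g % 2], "habitat": ["cropland", "grassland"][g // 2 % 2],
               "season": "fall"} for g in range(16)]
    truth = ScalingTruth(slope=4.0, re_sd_intercept=0.3, re_sd_slope=1.0, resid_sd=0.2)
    hits = 0
    for rep in range(5):
        df = simulate_scaling_pairs(truth, n_groups=16, B=60,
                                    group_labels=labels, seed=100 + rep)
        res = PersistenceScaling(df).fit()
        hits += res.covariates == ()
    assert hits >= 4


def test_true_covariate_offsets_detected():
    labels = [{"region": ["R1", "R6"][g % 2], "habitat": "cropland",
               "season": "fall"} for g in range(20)]
    truth = ScalingTruth(slope=4.0, fixed_offsets={"region[R6]": 2.0},
                         re_sd_intercept=0.2, re_sd_slope=0.5, resid_sd=0.2)
    df = simulate_scaling_pairs(truth, n_groups=20, B=80, group_labels=labels,
                                seed=33)
    res = PersistenceScaling(df).fit()
    assert "region" in res.covariates
    assert abs(res.fixed["region[R6]"] - 2.0) < 3 * res.fixed_se["region[R6]"]


def test_requires_two_groups():
    df = simulate_scaling_pairs(ScalingTruth(), n_groups=1, B=10, seed=0)
    with pytest.raises(ValueError, match="2 analysis groups"):
        PersistenceScaling(df)


# --- prediction -----------------------------------------------------------


def test_zero_coefficients_predict_one_half():
    m = PersistenceScalingResults.from_coefficients(
        {"intercept": 0.0, "gamebird_r": 0.0}
    )
    assert m.predict(0.31) == pytest.approx(0.5)
    assert m.predict(0.9) == pytest.approx(0.5)


def test_known_group_with_zero_blups_equals_new_group_prediction():
    m = PersistenceScalingResults.from_coefficients(
        {"intercept": -0.5, "gamebird_r": 4.0}, blups={"G1": (0.0, 0.0)}
    )
    assert m.predict(0.4, group_id="G1") == m.predict(0.4, group_id=None)
    m2 = PersistenceScalingResults.from_coefficients(
        {"intercept": -0.5, "gamebird_r": 4.0}, blups={"G1": (0.3, 0.5)}
    )
    assert m2.predict(0.4, group_id="G1") > m2.predict(0.4, group_id=None)


def test_prediction_strictly_increasing_in_gamebird_r():
    m = PersistenceScalingResults.from_coefficients(
        {"intercept": -0.66, "gamebird_r": 4.19, "region[R3]": 0.33}
    )
    xs = np.linspace(0.01, 0.99, 50)
    ys = [m.predict(x, region="R3") for x in xs]
    assert np.all(np.diff(ys) > 0)


def test_unfitted_level_and_bad_inputs_rejected():
    m = PersistenceScalingResults.from_coefficients(
        {"intercept": -0.66, "gamebird_r": 4.19, "region[R3]": 0.33}
    )
    with pytest.raises(ValueError, match="R7"):
        m.predict(0.3, region="R7")
    with pytest.raises(ValueError, match="strictly between"):
        m.predict(0.0)


def test_prediction_interval_contains_point():
    truth = ScalingTruth(slope=4.0, re_sd_intercept=0.3, re_sd_slope=1.0,
                         resid_sd=0.2)
    df = simulate_scaling_pairs(truth, n_groups=12, B=50, seed=21)
    res = PersistenceScaling(df).fit(candidate_fixed=[()])
    point, (lo, hi) = res.predict(0.4, with_interval=True, seed=0)
    assert lo <= point <= hi
    assert 0.0 < lo < hi < 1.0


def test_json_round_trip(tmp_path):
    truth = ScalingTruth(slope=4.0, re_sd_intercept=0.3, re_sd_slope=1.0,
                         resid_sd=0.2)
    df = simulate_scaling_pairs(truth, n_groups=10, B=40, seed=8)
    res = PersistenceScaling(df).fit(candidate_fixed=[()])
    path = tmp_path / "model.json"
    res.to_json(path)
    back = PersistenceScalingResults.from_json(path)
    assert back.predict(0.37) == pytest.approx(res.predict(0.37), abs=1e-12)
    g = next(iter(res.blups))
    assert back.predict(0.37, group_id=g) == pytest.approx(
        res.predict(0.37, group_id=g), abs=1e-12
    )
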