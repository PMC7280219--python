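"""Standardization, PCA severity model, orientation, correlation, separation."""

import json

import numpy as np
import pandas as pd
import pytest

from dermaflim.exceptions import (
    ConfigurationError,
    DegenerateFeatureError,
    InsufficientDataError,
    SchemaMismatchError,
    UndefinedValueError,
    ValidationError,
)
from dermaflim.severity import (
    SeverityModel,
    SeverityResults,
    group_separation,
    pearson_r,
    standardize,
)


def random_table(n=10, k=8, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, k)) * rng.uniform(0.5, 3.0, size=k)
        + rng.normal(0, 5, size=k),
        columns=[f"f{i}" for i in range(k)],
    )


# --------------------------------------------------------------- standardize
def test_standardize_hand_example_population_sd():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 9.0]})
    scaled, means, stds = standardize(table)
    assert scaled["a"].tolist() == pytest.approx(
        [-1.224744871, 0.0, 1.224744871]
    )
    assert means["a"] == 2.0
    assert stds["a"] == pytest.approx(np.sqrt(2.0 / 3.0))


def test_standardize_is_idempotent():
    scaled, *_ = standardize(random_table())
    rescaled, *_ = standardize(scaled)
    assert np.allclose(scaled.to_numpy(), rescaled.to_numpy(), atol=1e-12)
    assert np.allclose(rescaled.mean(), 0.0, atol=1e-10)
    assert np.allclose(rescaled.var(ddof=0), 1.0, atol=1e-10)


def test_standardize_names_degenerate_column():
    table = random_table()
    table["flat"] = 5.0
    with pytest.raises(DegenerateFeatureError, match="flat"):
        standardize(table)


# ---------------------------------------------------------------------- PCA
def test_bivariate_correlation_closed_form():
    """For standardized bivariate data with rho, PC1 ratio -> (1+rho)/2."""
    rng = np.random.default_rng(7)
    rho = 0.8
    cov = [[1.0, rho], [rho, 1.0]]
    x = rng.multivariate_normal([0, 0], cov, size=20000)
    table = pd.DataFrame(x, columns=["u", "v"])
    res = SeverityModel(table, orient=None, n_components=2).fit()
    assert res.explained_variance_ratio[0] == pytest.approx(0.9, abs=0.01)


def test_identical_columns_are_rank_one():
    rng = np.random.default_rng(8)
    col = rng.normal(size=50)
    table = pd.DataFrame({"a": col, "b": col.copy()})
    res = SeverityModel(table, orient=None).fit()
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)


def test_loadings_orthonormal_and_ratios_sum_to_one():
    res = SeverityModel(random_table(30, 6), orient=None, n_components=6).fit()
    gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
    assert np.allclose(gram, np.eye(6), atol=1e-8)
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)
    assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()


def test_pca_matches_covariance_eigendecomposition():
    """SVD route equals a brute-force correlation-matrix eigensolve."""
    table = random_table(10, 8, seed=3)
    res = SeverityModel(table, orient=None, n_components=8).fit()
    scaled, *_ = standardize(table)
    x = scaled.to_numpy()
    cov = (x - x.mean(axis=0)).T @ (x - x.mean(axis=0)) / len(x)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    assert np.allclose(
        evals / evals.sum(), res.explained_variance_ratio, atol=1e-8
    )
    for j in range(8):
        a = res.loadings.to_numpy()[:, j]
        b = evecs[:, j]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


def test_component_count_validation():
    with pytest.raises(ConfigurationError):
        SeverityModel(random_table(5, 3), n_components=4)
    with pytest.raises(ValidationError):
        SeverityModel(random_table(2, 3))


# -------------------------------------------------------------- orientation
def grouped_table(seed=0, n=20, shift=3.0):
    rng = np.random.default_rng(seed)
    control = rng.normal(0, 1, size=(n, 4))
    pso = rng.normal(shift, 1, size=(n, 4))
    table = pd.DataFrame(
        np.vstack([control, pso]), columns=list("abcd")
    )
    groups = pd.Series(["control"] * n + ["psoriasis"] * n)
    return table, groups


def test_oriented_pc1_puts_psoriasis_high():
    table, groups = grouped_table()
    res = SeverityModel(table, groups=groups).fit()
    scores = res.severity_scores()
    assert scores[groups.values == "psoriasis"].mean() > scores[
        groups.values == "control"
    ].mean()


def test_orientation_is_a_pure_sign_gauge():
    table, groups = grouped_table(seed=5)
    res = SeverityModel(table, groups=groups).fit()
    flipped = SeverityModel(-table, groups=groups).fit()
    # negating every feature flips the raw SVD axis; orientation undoes it
    assert np.allclose(
        res.severity_scores().to_numpy(),
        flipped.severity_scores().to_numpy(),
        atol=1e-8,
    )


def test_single_group_orientation_warns_and_keeps_plus_one():
    table, _ = grouped_table()
    with pytest.warns(UserWarning, match="orientation"):
        res = SeverityModel(
            table, groups=pd.Series(["control"] * len(table))
        ).fit()
    assert res.pc1_sign == 1


def test_feature_orientation_mode():
    table, _ = grouped_table()
    res = SeverityModel(table, orient=("feature", "a")).fit()
    assert res.loadings.loc["a", "PC1"] >= 0


# ------------------------------------------------------------------ project
def test_projecting_the_training_mean_scores_zero():
    table = random_table(15, 5)
    res = SeverityModel(table, orient=None).fit()
    mean_row = table.mean().to_frame().T
    assert np.allclose(res.project(mean_row).to_numpy(), 0.0, atol=1e-10)


def test_reprojected_training_rows_match_fit_scores():
    table = random_table(15, 5, seed=9)
    res = SeverityModel(table, orient=None).fit()
    assert np.allclose(
        res.project(table).to_numpy(), res.scores.to_numpy(), atol=1e-8
    )


def test_projection_schema_mismatch():
    res = SeverityModel(random_table(10, 4), orient=None).fit()
    bad = random_table(3, 4).rename(columns={"f0": "other"})
    with pytest.raises(SchemaMismatchError, match="f0"):
        res.project(bad)


def test_scale_invariant_ranking():
    """Pre-standardization feature rescaling cannot change the ranking."""
    table = random_table(12, 5, seed=4)
    res = SeverityModel(table, orient=None).fit()
    res_scaled = SeverityModel(table * 37.5, orient=None).fit()
    r1 = res.scores["PC1"].rank()
    r2 = res_scaled.scores["PC1"].rank()
    # sign gauge may flip without orientation labels; accept either order
    assert (r1 == r2).all() or (r1 == len(r1) + 1 - r2).all()


# ----------------------------------------------------------------- pearson_r
@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
        ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
        ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
    ],
)
def test_pearson_values(x, y, expected):
    assert pearson_r(np.array(x, float), np.array(y, float)) == pytest.approx(
        expected
    )


def test_pearson_degenerate_inputs():
    with pytest.raises(UndefinedValueError):
        pearson_r(np.ones(5), np.arange(5.0))
    with pytest.raises(InsufficientDataError):
        pearson_r(np.arange(2.0), np.arange(2.0))


# --------------------------------------------------------- group separation
def test_well_separated_groups_have_high_silhouette():
    rng = np.random.default_rng(0)
    scores = pd.DataFrame(
        np.vstack(
            [rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))]
        ),
        columns=["PC1", "PC2"],
    )
    labels = pd.Series(["a"] * 20 + ["b"] * 20)
    sep = group_separation(scores, labels)
    assert sep["silhouette"] > 0.5
    assert sep["pc1_gaps"]["a_vs_b"] == pytest.approx(5.0, abs=0.5)


def test_identical_groups_have_no_structure():
    rng = np.random.default_rng(1)
    scores = pd.DataFrame(rng.normal(size=(40, 2)), columns=["PC1", "PC2"])
    labels = pd.Series(["a", "b"] * 20)
    assert abs(group_separation(scores, labels)["silhouette"]) < 0.15


def test_singleton_groups_are_excluded_with_warning():
    rng = np.random.default_rng(2)
    scores = pd.DataFrame(rng.normal(size=(5, 2)), columns=["PC1", "PC2"])
    labels = pd.Series(["a", "a", "b", "b", "c"])
    with pytest.warns(UserWarning, match="singleton"):
        sep = group_separation(scores, labels)
    assert set(sep["pc1_group_means"]) == {"a", "b"}


# ------------------------------------------------------- results object API
def test_summary_and_json_round_trip(tmp_path):
    table, groups = grouped_table(seed=11)
    res = SeverityModel(table, groups=groups).fit()
    text = res.summary()
    assert "Explained variance ratio" in text and "PC1 loadings" in text
    path = tmp_path / "model.json"
    res.to_json(path)
    loaded = SeverityResults.from_json(path)
    assert loaded.feature_names == res.feature_names
    assert np.allclose(
        loaded.project(table).to_numpy(), res.project(table).to_numpy()
    )
    payload = json.loads(path.read_text())
    assert payload["pc1_sign"] in (-1, 1)


def test_plot_scores_writes_figure(tmp_path):
    table, groups = grouped_table(seed=12)
    res = SeverityModel(table, groups=groups).fit()
    out = tmp_path / "scores.png"
    res.plot_scores(path=out)
    assert out.stat().st_size > 0
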