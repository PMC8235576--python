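"""Empirical-Bayes harmonization, variance partition, bootstrap regression."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import proteonet as pn
from proteonet.batch import DesignError, HarmonizationStep, eb_batch_adjust


def _two_batch_fixture(shift=2.0, noise=0.5, n_p=30, n_per=10, seed=0, group_effect=0.0):
    rng = np.random.default_rng(seed)
    cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    base = rng.normal(0, 1, (n_p, 1))
    Y = base + rng.normal(0, noise, (n_p, 2 * n_per))
    Y[:, n_per:] += shift
    meta = pd.DataFrame(
        {
            "batch": [0] * n_per + [1] * n_per,
            "group": (["x", "y"] * n_per)[: 2 * n_per],
        },
        index=cols,
    )
    if group_effect:
        Y[:, meta["group"].to_numpy() == "y"] += group_effect
    return pd.DataFrame(Y, columns=cols), meta


def test_single_batch_returns_input():
    ab, meta = _two_batch_fixture()
    meta["batch"] = 0
    out, _ = eb_batch_adjust(ab, meta, "batch")
    assert np.allclose(out.to_numpy(), ab.to_numpy(), atol=1e-9)


def test_pure_additive_shift_removed_exactly_noiseless():
    ab, meta = _two_batch_fixture(shift=2.0, noise=0.0)
    out, _ = eb_batch_adjust(ab, meta, "batch")
    diff = out[meta.index[meta["batch"] == 0]].mean(axis=1) - out[
        meta.index[meta["batch"] == 1]
    ].mean(axis=1)
    assert np.abs(diff).max() < 1e-6


def test_protected_group_effect_preserved():
    """Orthogonal batch/group assignment: planted group difference
    survives batch adjustment within 2%."""
    ab, meta = _two_batch_fixture(shift=1.5, noise=0.05, n_p=200, group_effect=2.0, seed=3)
    out, _ = eb_batch_adjust(ab, meta, "batch", ("group",))
    gdiff = out[meta.index[meta["group"] == "y"]].mean(axis=1) - out[
        meta.index[meta["group"] == "x"]
    ].mean(axis=1)
    assert abs(gdiff.mean() - 2.0) / 2.0 < 0.02


def test_confounded_batch_and_protected_factor_raise():
    ab, meta = _two_batch_fixture()
    meta["group"] = np.where(meta["batch"] == 0, "x", "y")  # aliased
    with pytest.raises(DesignError, match="confounded"):
        eb_batch_adjust(ab, meta, "batch", ("group",))


def test_small_batch_raises():
    ab, meta = _two_batch_fixture()
    meta.loc[meta.index[0], "batch"] = 7
    with pytest.raises(DesignError, match="fewer than 2"):
        eb_batch_adjust(ab, meta, "batch")


@settings(deadline=None, max_examples=10, derandomize=True)
@given(st.floats(min_value=-50, max_value=50))
def test_shift_equivariance(c):
    ab, meta = _two_batch_fixture(seed=4)
    out1, _ = eb_batch_adjust(ab, meta, "batch")
    out2, _ = eb_batch_adjust(ab + c, meta, "batch")
    assert np.allclose(out2.to_numpy(), out1.to_numpy() + c, atol=1e-9)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_eb_adjust_matches_sva_combat(tmp_path):
    """Independent oracle: the parametric EB adjustment reproduces the
    reference R implementation (sva::ComBat) to numerical precision."""
    rng = np.random.default_rng(42)
    n_p, n_per = 40, 8
    batch = np.repeat([1, 2, 3], n_per)
    group = np.tile(["a", "b"], 3 * n_per // 2)
    Y = rng.normal(0, 1, (n_p, 3 * n_per))
    Y += np.where(group == "b", 1.0, 0.0)[None, :] * rng.normal(0.5, 0.2, (n_p, 1))
    Y += rng.normal(0, 0.8, (n_p, 3))[:, batch - 1]
    ab = pd.DataFrame(Y, columns=[f"s{i}" for i in range(3 * n_per)])
    meta = pd.DataFrame({"batch": batch, "group": group}, index=ab.columns)
    ab.to_csv(tmp_path / "y.csv")
    meta.to_csv(tmp_path / "meta.csv")
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(sva))\n'
        f'y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1))\n'
        f'meta <- read.csv("{tmp_path}/meta.csv", row.names=1)\n'
        "mod <- model.matrix(~group, data=meta)\n"
        "out <- ComBat(dat=y, batch=meta$batch, mod=mod, par.prior=TRUE)\n"
        f'write.csv(out, "{tmp_path}/r.csv")\n'
    )
    res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
    if res.returncode != 0:
        pytest.skip(f"sva unavailable: {res.stderr[-200:]}")
    r = pd.read_csv(tmp_path / "r.csv", index_col=0)
    r.columns = ab.columns
    mine, _ = eb_batch_adjust(ab, meta, "batch", ("group",))
    assert np.abs(mine.to_numpy() - r.to_numpy()).max() < 1e-8


def test_empty_plan_returns_biological_samples_unchanged(prepped):
    ab, meta, _ = prepped
    out = pn.run_harmonization_plan(ab, meta, plan=[])
    bio = meta.index[~meta["is_gis"]]
    assert list(out.columns) == [c for c in ab.columns if c in set(bio)]
    assert np.allclose(out.to_numpy(), ab[out.columns].to_numpy())


def test_unknown_plan_factor_raises(prepped):
    ab, meta, _ = prepped
    with pytest.raises(KeyError, match="flowcell"):
        pn.run_harmonization_plan(ab, meta, plan=[HarmonizationStep("flowcell")])


def test_plan_reordering_is_stable_on_orthogonal_design():
    """With a fully crossed batch x region design the pass order does
    not change the result appreciably."""
    rng = np.random.default_rng(5)
    n_p = 60
    cols = [f"s{i}" for i in range(24)]
    meta = pd.DataFrame(
        {
            "batch": np.repeat([0, 1], 12),
            "region": np.tile(["frontal", "temporal"], 12),
            "group": np.tile(["x", "x", "y", "y"], 6),
            "sex": "M",
            "is_gis": False,
        },
        index=cols,
    )
    Y = rng.normal(0, 1e-5, (n_p, 24))  # near-noiseless: EB shrinkage residue vanishes
    Y[:, meta["batch"].to_numpy() == 1] += 1.0
    Y[:, (meta["region"] == "temporal").to_numpy()] += 0.5
    Y[:, (meta["group"] == "y").to_numpy()] += 2.0
    ab = pd.DataFrame(Y, columns=cols)
    p1 = [HarmonizationStep("batch", ("group", "region")), HarmonizationStep("region", ("group",))]
    p2 = [HarmonizationStep("region", ("group",)), HarmonizationStep("batch", ("group", "region"))]
    o1 = pn.run_harmonization_plan(ab, meta, p1)
    o2 = pn.run_harmonization_plan(ab, meta, p2)
    g1 = o1.T.groupby(meta["group"]).mean()
    g2 = o2.T.groupby(meta["group"]).mean()
    assert np.abs((g1 - g2).to_numpy()).max() < 1e-6


def test_variance_partition_pure_factor_and_mixture():
    rng = np.random.default_rng(6)
    cols = [f"s{i}" for i in range(80)]
    meta = pd.DataFrame({"batch": np.repeat([0, 1], 40)}, index=cols)
    indicator = np.where(meta["batch"] == 1, 1.0, 0.0)
    noise = rng.normal(0, 1, 80)
    noise = (noise - noise.mean()) / noise.std()
    half = indicator - indicator.mean()
    half = half / half.std()
    ab = pd.DataFrame(
        {c: v for c, v in zip(cols, np.vstack([indicator, half + noise]).T)},
        index=["pure", "mix"],
    )
    vp = pn.variance_partition(ab, meta, ["batch"])
    assert vp.loc["pure", "batch"] == pytest.approx(1.0, abs=1e-9)
    assert vp.loc["mix", "batch"] == pytest.approx(0.5, abs=0.1)
    assert np.allclose(vp.sum(axis=1), 1.0, atol=1e-9)


def test_variance_partition_null_factor_near_chance_level():
    """A pure-noise protein's factor fraction stays within 3x the
    permutation-null mean (df/(n-1))."""
    rng = np.random.default_rng(7)
    cols = [f"s{i}" for i in range(90)]
    meta = pd.DataFrame({"batch": np.repeat(np.arange(10), 9)}, index=cols)
    ab = pd.DataFrame(rng.normal(0, 1, (300, 90)), columns=cols)
    vp = pn.variance_partition(ab, meta, ["batch"])
    null_mean = 9.0 / 89.0
    assert vp["batch"].mean() < 3 * null_mean
    # excess mode removes most of the chance floor (E[max(0, chi2_9 - 9)]
    # leaves ~2% residue for a 9-df factor on random data)
    vpe = pn.variance_partition(ab, meta, ["batch"], method="excess")
    assert vpe["batch"].mean() < vp["batch"].mean() / 3
    assert vpe["batch"].mean() < 0.03


def test_variance_partition_aliased_factor():
    cols = [f"s{i}" for i in range(12)]
    meta = pd.DataFrame(
        {"batch": np.repeat([0, 1, 2, 3], 3), "platform": np.repeat([1, 1, 2, 2], 3)}, index=cols
    )
    ab = pd.DataFrame(np.random.default_rng(8).normal(0, 1, (5, 12)), columns=cols)
    vp = pn.variance_partition(ab, meta, ["batch", "platform"])
    assert (vp["platform"] == 0).all()
    with pytest.raises(DesignError, match="aliased"):
        pn.variance_partition(ab, meta, ["batch", "platform"], on_aliased="raise")


def _covariate_fixture(slope_age=0.0, noise=0.3, n_p=80, seed=9):
    rng = np.random.default_rng(seed)
    cols = [f"s{i}" for i in range(60)]
    meta = pd.DataFrame(
        {
            "group": np.repeat(["control", "disease"], 30),
            "age": rng.uniform(50, 90, 60),
            "pmi": rng.uniform(2, 30, 60),
        },
        index=cols,
    )
    Y = rng.normal(0, noise, (n_p, 60)) if noise > 0 else np.zeros((n_p, 60))
    Y += slope_age * (meta["age"].to_numpy() - meta["age"].mean())[None, :]
    Y[:, meta["group"].to_numpy() == "disease"] += 1.0
    return pd.DataFrame(Y, columns=cols), meta


def test_bootstrap_single_full_sample_fit_equals_least_squares():
    ab, meta = _covariate_fixture(slope_age=0.05)
    boot = pn.regress_covariates_bootstrap(ab, meta, n_boot=1, seed=0, resample=False)
    # least-squares oracle
    G = pd.get_dummies(meta["group"], drop_first=True).to_numpy(float)
    Z = meta[["age", "pmi"]].to_numpy()
    Zc = Z - Z.mean(axis=0)
    X = np.hstack([np.ones((60, 1)), G, Zc])
    coef, *_ = np.linalg.lstsq(X, ab.to_numpy().T, rcond=None)
    expected = ab.to_numpy() - (Zc @ coef[-2:]).T
    assert np.allclose(boot.to_numpy(), expected, atol=1e-9)


def _refit_age_slope(out, meta):
    """Oracle: re-fit the protected model and read the age coefficient."""
    G = pd.get_dummies(meta["group"], drop_first=True).to_numpy(float)
    Z = meta[["age", "pmi"]].to_numpy()
    X = np.hstack([np.ones((len(meta), 1)), G, Z - Z.mean(axis=0)])
    coef, *_ = np.linalg.lstsq(X, out.to_numpy().T, rcond=None)
    return coef[-2]


def test_planted_age_slope_removed():
    ab, meta = _covariate_fixture(slope_age=0.1, noise=0.0)
    out = pn.regress_covariates_bootstrap(ab, meta, n_boot=200, seed=1)
    assert np.abs(_refit_age_slope(out, meta)).max() < 1e-3


def test_null_covariates_perturb_at_sampling_noise_level():
    """With no true slopes the change is pure coefficient sampling
    noise, mean |delta| ~ 0.8 sqrt(2) sigma/sqrt(n); the estimator must
    not exceed 1.5x that analytic level (no added bias)."""
    ab, meta = _covariate_fixture(slope_age=0.0, noise=0.3)
    out = pn.regress_covariates_bootstrap(ab, meta, n_boot=100, seed=2)
    expected = 0.8 * np.sqrt(2) * 0.3 / np.sqrt(len(meta))
    assert np.abs(out.to_numpy() - ab.to_numpy()).mean() < 1.5 * expected


def test_group_difference_preserved_through_regression():
    ab, meta = _covariate_fixture(slope_age=0.1, noise=0.1)
    out = pn.regress_covariates_bootstrap(ab, meta, n_boot=100, seed=3)
    gdiff = (
        out[meta.index[meta["group"] == "disease"]].mean(axis=1)
        - out[meta.index[meta["group"] == "control"]].mean(axis=1)
    )
    assert abs(gdiff.mean() - 1.0) < 0.02


def test_bootstrap_errors():
    ab, meta = _covariate_fixture()
    with pytest.raises(ValueError, match="n_boot"):
        pn.regress_covariates_bootstrap(ab, meta, n_boot=0)
    meta2 = meta.copy()
    meta2.loc[meta2.index[0], "group"] = "singleton"
    with pytest.raises(ValueError, match="single sample"):
        pn.regress_covariates_bootstrap(ab, meta2, n_boot=10)
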