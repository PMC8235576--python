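"""Network construction: bicor, adjacency, TOM, tree cutting, eigenproteins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import proteonet as pn
from proteonet import network as nw


# ---------------------------------------------------------------------------
# biweight midcorrelation


def _bicor_direct(x, y):
    """Independent direct-formula evaluation (no shared code paths)."""
    def tr(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        d = (v - med) * w
        return d / np.sqrt(np.sum(d**2))

    return float(np.dot(tr(np.asarray(x, float)), tr(np.asarray(y, float))))


def test_bicor_perfect_and_anti_correlation():
    x = np.array([1.0, 2.0, 4.0, 3.5, 5.0])
    assert nw.bicor(x, x) == pytest.approx(1.0, abs=1e-12)
    assert nw.bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)


def test_bicor_downweights_outlier_versus_pearson():
    x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = nw.bicor(x, y)
    assert b == pytest.approx(_bicor_direct(x, y), abs=1e-12)
    pearson = np.corrcoef(x, y)[0, 1]
    assert abs(b - pearson) > 0.05


def test_bicor_constant_vector_raises():
    with pytest.raises(ValueError):
        nw.bicor(np.ones(5), np.arange(5.0))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    arrays(float, (2, 8), elements=st.floats(-100, 100, allow_nan=False)).filter(
        lambda a: np.ptp(a[0]) > 1e-6 and np.ptp(a[1]) > 1e-6
    )
)
def test_bicor_bounded_and_symmetric(a):
    b1 = nw.bicor(a[0], a[1])
    b2 = nw.bicor(a[1], a[0])
    assert -1.0 <= b1 <= 1.0
    assert b1 == pytest.approx(b2, abs=1e-12)


def test_bicor_matrix_agrees_with_pairwise():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (6, 20))
    C = nw.bicor_matrix(X)
    for i in range(6):
        for j in range(i + 1, 6):
            assert C[i, j] == pytest.approx(nw.bicor(X[i], X[j]), abs=1e-12)


# ---------------------------------------------------------------------------
# adjacency and TOM


def test_signed_adjacency_forced_arithmetic():
    cor = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, 1.0], [-1.0, 1.0, 1.0]])
    A = nw.signed_adjacency(cor, beta=7.0)
    assert A[0, 1] == pytest.approx(0.5**7)
    assert A[0, 1] == pytest.approx(0.0078125)
    assert A[0, 2] == 0.0
    assert A[1, 2] == 1.0
    assert np.all(np.diag(A) == 1.0)


def _tom_triple_loop(A, denom):
    """Brute-force triple-loop oracle for the TOM dissimilarity."""
    n = A.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            f = (ki + kj) / 2 if denom == "mean" else min(ki, kj)
            out[i, j] = 1 - (l + A[i, j]) / (f + 1 - A[i, j])
    return out


@pytest.mark.parametrize("denom", ["mean", "min"])
@pytest.mark.parametrize("n", [5, 6, 7, 8])
def test_tom_matches_triple_loop_oracle(n, denom):
    rng = np.random.default_rng(n)
    A = rng.uniform(0, 1, (n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    assert np.abs(nw.topological_overlap(A, denom) - _tom_triple_loop(A, denom)).max() < 1e-12


def test_tom_complete_and_empty_graphs():
    A = np.ones((4, 4))
    d = nw.topological_overlap(A)
    assert np.allclose(d, 0.0)
    A0 = np.eye(4)
    d0 = nw.topological_overlap(A0)
    off = ~np.eye(4, dtype=bool)
    assert np.allclose(d0[off], 1.0)  # TOM 0 off diagonal


def test_tom_rejects_asymmetric():
    A = np.eye(3)
    A[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        nw.topological_overlap(A)


# ---------------------------------------------------------------------------
# soft threshold


def test_soft_threshold_on_scale_free_fixture():
    """Hub-structured expression (one dominant factor with a continuum
    of loadings gives pairwise correlation rho_i rho_j, whose signed
    soft-thresholded connectivity follows an approximate power law)
    reaches the scale-free fit target."""
    rng = np.random.default_rng(3)
    n_p, n_s = 400, 150
    f = rng.normal(0, 1, n_s)
    rho = rng.uniform(0.05, 1.0, n_p)
    X = rho[:, None] * f + np.sqrt(1 - rho**2)[:, None] * rng.normal(0, 1, (n_p, n_s))
    ab = pd.DataFrame(X, columns=[f"s{i}" for i in range(n_s)])
    power, table = nw.pick_soft_threshold(ab, cor_kind="pearson", target_mean_k=n_p / 10)
    assert table["meets_target"].any()
    assert table.loc[table["power"] == power, "signed_r2"].iloc[0] > 0.8


def test_soft_threshold_needs_enough_proteins():
    ab = pd.DataFrame(np.random.default_rng(0).normal(0, 1, (2, 10)))
    with pytest.raises(ValueError, match="50 proteins"):
        nw.pick_soft_threshold(ab)


# ---------------------------------------------------------------------------
# tree cutting


def _block_data(sizes, within=0.8, n_s=60, seed=0, noise_between=0.0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(sizes):
        f = rng.normal(0, 1, n_s)
        noise_sd = np.sqrt(1 / within - 1)
        rows.append(f[None, :] + rng.normal(0, noise_sd, (size, n_s)))
        labels += [b] * size
    return np.vstack(rows), np.array(labels)


def test_two_planted_blocks_recovered_exactly():
    X, truth = _block_data([40, 30], seed=1)
    C = np.corrcoef(X)
    diss = nw.topological_overlap(nw.signed_adjacency(C, 7.0))
    labels = nw.cut_dendrogram(diss)
    assert adjusted_rand_score(truth, labels) >= 0.95
    assert len(set(labels) - {0}) == 2


def test_block_below_minimum_size_is_unassigned():
    X, truth = _block_data([40, 10], seed=2)
    C = np.corrcoef(X)
    diss = nw.topological_overlap(nw.signed_adjacency(C, 7.0))
    labels = nw.cut_dendrogram(diss, nw.NetworkParams(min_module_size=17))
    small = labels[truth == 1]
    assert (small == 0).all()


def test_cut_is_deterministic():
    X, _ = _block_data([30, 25, 20], seed=3)
    diss = nw.topological_overlap(nw.signed_adjacency(np.corrcoef(X), 7.0))
    l1 = nw.cut_dendrogram(diss)
    l2 = nw.cut_dendrogram(diss)
    assert np.array_equal(l1, l2)


def test_tiny_input_all_unassigned():
    diss = 1 - np.eye(5)
    with pytest.warns(UserWarning):
        labels = nw.cut_dendrogram(diss, nw.NetworkParams(min_module_size=17))
    assert (labels == 0).all()


# ---------------------------------------------------------------------------
# eigenproteins / kME


def test_eigenprotein_of_identical_profiles():
    rng = np.random.default_rng(4)
    prof = rng.normal(0, 2, 30)
    ab = pd.DataFrame(np.tile(prof, (10, 1)), index=[f"P{i}" for i in range(10)])
    assign = pd.Series("m1", index=ab.index)
    eig, pve = pn.module_eigenproteins(ab, assign)
    z = (prof - prof.mean()) / prof.std(ddof=1)
    assert np.allclose(eig["m1"], z, atol=1e-9)
    assert pve["m1"] == pytest.approx(1.0)


def test_eigenprotein_orientation_with_sign_flipped_members():
    rng = np.random.default_rng(5)
    f = rng.normal(0, 1, 40)
    members = np.vstack([f + rng.normal(0, 0.1, 40) for _ in range(6)]
                        + [-f + rng.normal(0, 0.1, 40) for _ in range(3)])
    ab = pd.DataFrame(members, index=[f"P{i}" for i in range(9)])
    assign = pd.Series("m1", index=ab.index)
    eig, _ = pn.module_eigenproteins(ab, assign)
    zmean = ((members - members.mean(1, keepdims=True)) / members.std(1, ddof=1, keepdims=True)).mean(0)
    assert np.corrcoef(eig["m1"], zmean)[0, 1] > 0


def test_single_member_module_raises():
    ab = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)), index=["a", "b"])
    with pytest.raises(ValueError, match="fewer than 2"):
        pn.module_eigenproteins(ab, pd.Series({"a": "m1", "b": "m2"}))


def test_kme_identity_orthogonal_and_hub_ranking():
    rng = np.random.default_rng(6)
    f = rng.normal(0, 1, 50)
    f = (f - f.mean()) / f.std(ddof=1)
    g = rng.normal(0, 1, 50)
    g = g - g.mean()
    g -= (g @ f) / (f @ f) * f  # orthogonalize
    loadings = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5]
    rows = {f"P{i}": l * f + (1 - l) * 0.6 * g for i, l in enumerate(loadings)}
    rows["self"] = f
    ab = pd.DataFrame(rows).T
    eig = pd.DataFrame({"m1": f / f.std(ddof=1)}, index=range(50))
    eig.index = ab.columns
    kme = pn.kme_table(ab, eig)
    assert kme.loc["self", "m1"] == pytest.approx(1.0, abs=1e-9)
    ab.loc["orth"] = g
    kme = pn.kme_table(ab, eig)
    assert kme.loc["orth", "m1"] == pytest.approx(0.0, abs=1e-9)
    ranked = kme.loc[[f"P{i}" for i in range(6)], "m1"].sort_values(ascending=False)
    assert list(ranked.index) == [f"P{i}" for i in range(6)]
    hubs = nw.hub_proteins(kme, pd.Series("m1", index=ab.index), "m1", n=3)
    assert set(hubs[:2]) == {"self", "P0"}  # both carry kME 1 (pure factor)


# ---------------------------------------------------------------------------
# merging and reassignment


def _merge_fixture(cor_between, seed=7, sizes=(20, 20)):
    rng = np.random.default_rng(seed)
    n_s = 200
    f1 = rng.normal(0, 1, n_s)
    f2 = cor_between * f1 + np.sqrt(1 - cor_between**2) * rng.normal(0, 1, n_s)
    rows, labels = [], []
    for f, size, name in zip((f1, f2), sizes, ("a", "b")):
        rows.append(f[None, :] + rng.normal(0, 0.05, (size, n_s)))
        labels += [name] * size
    ab = pd.DataFrame(np.vstack(rows), index=[f"P{i}" for i in range(sum(sizes))])
    return ab, pd.Series(labels, index=ab.index)


def test_highly_correlated_modules_merge_below_cut():
    ab, assign = _merge_fixture(0.96)
    merged = pn.network.merge_close_modules(ab, assign, merge_cut_height=0.07)
    assert merged.nunique() == 1


def test_distinct_modules_stay_unmerged():
    ab, assign = _merge_fixture(0.5)
    merged = pn.network.merge_close_modules(ab, assign, merge_cut_height=0.07)
    assert merged.nunique() == 2


def test_merging_is_order_independent_on_three_modules():
    """Iterated pairwise merging reaches the same partition as every
    exhaustive merge order on a 3-module fixture."""
    rng = np.random.default_rng(8)
    n_s = 150
    f1 = rng.normal(0, 1, n_s)
    f2 = 0.97 * f1 + np.sqrt(1 - 0.97**2) * rng.normal(0, 1, n_s)
    f3 = rng.normal(0, 1, n_s)
    rows, labels = [], []
    for f, name in zip((f1, f2, f3), ("a", "b", "c")):
        rows.append(f[None, :] + rng.normal(0, 0.05, (15, n_s)))
        labels += [name] * 15
    ab = pd.DataFrame(np.vstack(rows), index=[f"P{i}" for i in range(45)])
    for order in (["a", "b", "c"], ["c", "b", "a"], ["b", "a", "c"]):
        relabeled = pd.Series(labels, index=ab.index)
        merged = pn.network.merge_close_modules(ab, relabeled, 0.07)
        parts = {frozenset(merged.index[merged == m]) for m in merged.unique()}
        if order == ["a", "b", "c"]:
            reference = parts
        assert parts == reference
    # a+b merged, c separate
    assert len(reference) == 2


def test_reassignment_moves_mislabeled_protein_and_threshold_zero_freezes():
    rng = np.random.default_rng(9)
    n_s = 100
    fa, fb = rng.normal(0, 1, n_s), rng.normal(0, 1, n_s)
    rows, labels = [], []
    for i in range(15):
        rows.append(fa + rng.normal(0, 0.2, n_s)); labels.append("a")
    for i in range(15):
        rows.append(fb + rng.normal(0, 0.2, n_s)); labels.append("b")
    rows.append(fb + rng.normal(0, 0.2, n_s)); labels.append("a")  # mislabeled
    ab = pd.DataFrame(np.vstack(rows), index=[f"P{i}" for i in range(31)])
    assign = pd.Series(labels, index=ab.index)
    out = pn.network.reassign_members(ab, assign, threshold=0.05)
    assert out["P30"] == "b"
    assert (out[:-1] == assign[:-1]).all()  # well-placed members stay
    frozen = pn.network.reassign_members(ab, assign, threshold=0.0)
    assert (frozen == assign).all()


# ---------------------------------------------------------------------------
# estimator surface


def test_network_estimator_sklearn_contract(regressed):
    ab, _, _ = regressed
    net = pn.CoexpressionNetwork(min_module_size=10)
    params = net.get_params()
    assert params["beta"] == 7.0 and params["min_module_size"] == 10
    net.set_params(min_module_size=17)
    net.fit(ab.T)
    assert hasattr(net, "labels_") and hasattr(net, "eigenproteins_")
    assert set(net.labels_.unique()) - {"grey"} == set(net.eigenproteins_.columns)
    assert (net.kme_.to_numpy() <= 1.0 + 1e-12).all()
    # eigenprotein sign convention
    for m in net.eigenproteins_.columns:
        members = net.labels_[net.labels_ == m].index
        X = ab.loc[members].to_numpy()
        z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        assert np.corrcoef(net.eigenproteins_[m], z.mean(0))[0, 1] > 0


def test_network_refuses_missing_cells():
    ab = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 30)))
    ab.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        pn.CoexpressionNetwork().fit(ab)
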