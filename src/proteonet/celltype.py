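"""Cell-type marker enrichment, deconvolution, and gene-set tests.

Modules are tested for marker enrichment by one-sided Fisher exact
tests over the analysis universe with Benjamini-Hochberg correction.
Per-sample cell-type weights are estimated marker-based on the linear
scale: signatures are built from the marker-mean profiles of the most
marker-extreme samples per type and weights fitted by nonnegative
least squares, then normalized to the simplex (or z-scored). Generic
gene-set over-representation uses the hypergeometric tail with BH FDR
and a normal-approximation Z-score accept flag (Z > 1.96).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import fisher_exact, hypergeom
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .network import UNASSIGNED
from .stats import module_trait_significance


def map_orthologs(symbols, mapping_table: dict[str, str]) -> list[str]:
    """Apply a foreign -> local symbol mapping; unmapped symbols drop.

    Many-to-one collisions are resolved upstream (first occurrence per
    foreign symbol, see the mapping-table reader). Duplicated local
    symbols after mapping are deduplicated preserving order.
    """
    if not mapping_table:
        raise ValueError("empty mapping table")
    out, seen = [], set()
    for s in symbols:
        if s in mapping_table:
            t = mapping_table[s]
            if t not in seen:
                seen.add(t)
                out.append(t)
    return out


def module_marker_enrichment(
    assignment: pd.Series,
    markers: dict[str, list[str]],
    universe: pd.Index | None = None,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of marker sets in each module.

    The 2x2 is module membership x marker membership over the universe
    (default: all assigned + unassigned proteins in the assignment);
    BH correction runs across the full module x cell-type grid. Marker
    sets empty after restriction to the universe are skipped and
    reported with NaN p.
    """
    if universe is None:
        universe = assignment.index
    assignment = assignment.loc[assignment.index.intersection(universe)]
    N = len(assignment)
    modules = [m for m in pd.unique(assignment) if m != UNASSIGNED]
    rows = []
    for t, syms in markers.items():
        marker_set = set(syms) & set(assignment.index)
        if not marker_set:
            rows.extend(
                dict(module=m, cell_type=t, k=0, p=np.nan, skipped=True) for m in modules
            )
            continue
        for m in modules:
            members = set(assignment.index[assignment == m])
            k = len(members & marker_set)
            table = [
                [k, len(members) - k],
                [len(marker_set) - k, N - len(members) - len(marker_set) + k],
            ]
            _, p = fisher_exact(table, alternative="greater")
            rows.append(dict(module=m, cell_type=t, k=k, p=float(p), skipped=False))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


class MarkerDeconvolver(BaseEstimator, TransformerMixin):
    """Marker-based cell-type weight estimation (digital-sorting style).

    With type-exclusive markers, a sample's mean marker abundance for
    cell type ``t`` (linear scale) is proportional to that type's
    proportion: ``A_ts ~= c_t w_ts``. The default ``method="LM"``
    estimates the per-type scale ``c_t`` by a nonnegative linear model
    enforcing that proportions sum to one across the fitted samples
    (regress 1 on the marker-mean matrix), then recovers weights as
    ``A_ts / c_t``. ``method="signature"`` instead builds per-type
    signature profiles from the most marker-extreme fitted samples (top
    ``signature_quantile``) — or an explicit ``signatures`` table — and
    solves a nonnegative least-squares fit of every sample's marker
    profile on that basis.

    Input is samples x proteins on the log2 scale by default
    (``input_scale="linear"`` to skip the 2**x conversion);
    proportions mix linearly, so deconvolution always runs on the
    linear scale.
    """

    def __init__(
        self,
        markers: dict[str, list[str]] | None = None,
        method: str = "LM",  # {LM, signature}
        normalize: str = "simplex",  # {simplex, zscore, none}
        input_scale: str = "log2",
        signature_quantile: float = 0.9,
        signatures: pd.DataFrame | None = None,
    ):
        self.markers = markers
        self.method = method
        self.normalize = normalize
        self.input_scale = input_scale
        self.signature_quantile = signature_quantile
        self.signatures = signatures

    def _linear(self, X: pd.DataFrame) -> pd.DataFrame:
        return 2.0**X if self.input_scale == "log2" else X

    def _marker_means(self, lin: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {t: lin[cols].mean(axis=1) for t, cols in self.present_.items()}
        )

    def fit(self, X: pd.DataFrame, y=None):
        if self.markers is None:
            raise ValueError("markers are required")
        lin = self._linear(X)
        present: dict[str, list[str]] = {}
        for t, syms in self.markers.items():
            cols = [s for s in syms if s in lin.columns]
            if len(cols) < 2:
                raise ValueError(f"cell type {t!r} has fewer than 2 markers in the matrix")
            present[t] = cols
        self.present_ = present
        self.marker_rows_ = sorted({s for cols in present.values() for s in cols})
        if self.method == "LM":
            A = self._marker_means(lin).to_numpy(float)  # samples x types
            # scales c_t from sum-to-one: 1 ~= sum_t A_ts / c_t, b_t = 1/c_t >= 0
            b, _ = nnls(A, np.ones(len(A)))
            self.inv_scale_ = pd.Series(b, index=list(present))
            return self
        if self.signatures is not None:
            self.signatures_ = self.signatures.loc[self.marker_rows_]
            return self
        sig = {}
        for t, cols in present.items():
            score = lin[cols].mean(axis=1)
            top = score[score >= score.quantile(self.signature_quantile)].index
            sig[t] = lin.loc[top, self.marker_rows_].mean(axis=0)
        self.signatures_ = pd.DataFrame(sig)  # marker rows x types
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        lin = self._linear(X)
        types = list(self.present_)
        if self.method == "LM":
            A = self._marker_means(lin)
            weights = A * self.inv_scale_
        else:
            S = self.signatures_.to_numpy(float)
            types = list(self.signatures_.columns)
            W = np.zeros((len(lin), len(types)))
            M = lin[self.marker_rows_].to_numpy(float)
            for i in range(len(lin)):
                W[i], _ = nnls(S, M[i])
            weights = pd.DataFrame(W, index=lin.index, columns=types)
        if self.normalize == "simplex":
            total = weights.sum(axis=1).replace(0.0, np.nan)
            weights = weights.div(total, axis=0).fillna(0.0)
        elif self.normalize == "zscore":
            weights = (weights - weights.mean()) / weights.std(ddof=1)
        return weights


def estimate_celltype_weights(
    ab: pd.DataFrame,
    markers: dict[str, list[str]],
    meta: pd.DataFrame | None = None,
    method: str = "LM",
    normalize: str = "simplex",
    input_scale: str = "log2",
    signatures: pd.DataFrame | None = None,
    covariates: tuple[str, ...] = ("age", "sex", "pmi"),
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample cell-type weights from a proteins x samples matrix.

    Returns ``(weights, significance)``; the significance table (group
    F/p per cell type, adjusted for the covariates) is computed when
    ``meta`` is given, else None.
    """
    est = MarkerDeconvolver(
        markers=markers,
        method=method,
        normalize=normalize,
        input_scale=input_scale,
        signatures=signatures,
    )
    weights = est.fit(ab.T).transform(ab.T)
    sig = None
    if meta is not None:
        sig = module_trait_significance(weights, meta, covariates=covariates)
    return weights, sig


def zscore_across_datasets(weights_a: pd.DataFrame, weights_b: pd.DataFrame) -> pd.DataFrame:
    """Z-score each dataset's weights per cell type, then concatenate.

    Normalizing within dataset makes relative abundances comparable
    side by side across cohorts.
    """
    if list(weights_a.columns) != list(weights_b.columns):
        raise ValueError("datasets must share the same cell types")
    za = (weights_a - weights_a.mean()) / weights_a.std(ddof=1)
    zb = (weights_b - weights_b.mean()) / weights_b.std(ddof=1)
    za = za.assign(dataset="A")
    zb = zb.assign(dataset="B")
    return pd.concat([za, zb], axis=0)


def geneset_overrepresentation(
    query: set,
    collection: dict[str, list[str]],
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in a collection.

    Per set: tail p = P(X >= k), BH q across the collection, and the
    normal-approximation Z ``(k - nK/N) / sqrt(nK/N (1-K/N) (N-n)/(N-1))``
    with sets accepted at Z > 1.96. Sets with no member in the universe
    are skipped with a report row. A query equal to the universe is
    flagged degenerate.
    """
    universe = set(universe)
    query = set(query) & universe
    N, n = len(universe), len(query)
    degenerate = n == N
    rows = []
    for name, members in collection.items():
        K = len(set(members) & universe)
        if K == 0:
            rows.append(dict(set=name, K=0, k=0, p=np.nan, z=np.nan, skipped=True))
            continue
        k = len(set(members) & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        mean = n * K / N
        var = mean * (1 - K / N) * (N - n) / max(N - 1, 1)
        z = (k - mean) / np.sqrt(var) if var > 0 else 0.0
        rows.append(dict(set=name, K=K, k=k, p=p, z=float(z), skipped=False))
    out = pd.DataFrame(rows).set_index("set")
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["accepted"] = (out["z"] > 1.96) & ~out["skipped"]
    out["degenerate"] = degenerate
    return out
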