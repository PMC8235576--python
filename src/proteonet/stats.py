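"""Differential abundance and module/trait significance statistics.

Per-protein differences are disease-group mean minus control mean (log2
scale), tested by one-way ANOVA with Tukey's honestly-significant-
difference post hoc (Tukey-Kramer standard errors for unbalanced
groups). Module-level significance is a covariate-adjusted group F test
(type-II sum of squares) on the eigenprotein or cell-type weight, with
a plain Kruskal-Wallis p reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class DEResult:
    """Per-protein differential abundance results.

    ``diffs``/``tukey_p``: proteins x contrasts (``"<group>"`` read as
    group minus control); ``pairwise_p``: proteins x all ``"a|b"``
    pairs; ``anova``: per-protein F and p.
    """

    control: str
    groups: list[str]
    anova: pd.DataFrame
    diffs: pd.DataFrame
    tukey_p: pd.DataFrame
    pairwise_p: pd.DataFrame

    def volcano(self, contrast: str) -> pd.DataFrame:
        """Volcano-ready table: log2 difference vs -log10 Tukey p."""
        p = self.tukey_p[contrast].clip(lower=1e-300)
        return pd.DataFrame(
            {"log2_diff": self.diffs[contrast], "neg_log10_p": -np.log10(p)},
            index=self.diffs.index,
        )


def anova_tukey(
    ab: pd.DataFrame,
    meta: pd.DataFrame,
    groups: list[str],
    control: str | None = None,
    group_col: str = "group",
) -> DEResult:
    """One-way ANOVA + Tukey HSD across ``groups``, vectorized over proteins.

    The studentized-range p uses Tukey-Kramer standard errors
    ``sqrt(MSE/2 (1/n_i + 1/n_j))`` so unbalanced designs are handled.
    With exactly two groups the Tukey p equals the two-sided pooled t
    test p (``q = t sqrt(2)``).
    """
    if control is None:
        control = groups[0]
    meta = meta.loc[ab.columns]
    idx = {g: meta.index[meta[group_col] == g] for g in groups}
    for g, members in idx.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if ab.isna().any().any():
        raise ValueError("missing cells are not supported")

    k = len(groups)
    ns = np.array([len(idx[g]) for g in groups])
    n_tot = ns.sum()
    means = np.column_stack([ab[idx[g]].mean(axis=1).to_numpy() for g in groups])  # p x k
    sse = np.zeros(ab.shape[0])
    for j, g in enumerate(groups):
        X = ab[idx[g]].to_numpy(float)
        sse += ((X - means[:, [j]]) ** 2).sum(axis=1)
    df_w = n_tot - k
    mse = sse / df_w
    grand = (means * ns[None, :]).sum(axis=1) / n_tot
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where((mse == 0) & (msb == 0), 0.0, msb / np.where(mse == 0, np.nan, mse))
    F = np.where(np.isnan(F), np.inf, F)
    p = np.where(np.isinf(F), 0.0, sps.f.sf(np.where(np.isinf(F), 1.0, F), k - 1, df_w))
    p = np.where(F == 0.0, 1.0, p)
    anova = pd.DataFrame({"F": F, "p": p}, index=ab.index)

    pairwise = {}
    for i, j in combinations(range(k), 2):
        se = np.sqrt(np.maximum(mse, 0.0) / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(means[:, i] - means[:, j]) / se
        q = np.where(np.isnan(q), 0.0, q)  # 0/0: identical constant groups
        pq = np.where(np.isinf(q), 0.0, sps.studentized_range.sf(np.where(np.isinf(q), 1.0, q), k, df_w))
        pairwise[f"{groups[i]}|{groups[j]}"] = np.clip(pq, 0.0, 1.0)
    pairwise_p = pd.DataFrame(pairwise, index=ab.index)

    disease = [g for g in groups if g != control]
    ctrl_j = groups.index(control)
    diffs = pd.DataFrame(
        {g: means[:, groups.index(g)] - means[:, ctrl_j] for g in disease}, index=ab.index
    )
    tukey_p = pd.DataFrame(
        {
            g: pairwise_p[
                f"{control}|{g}" if f"{control}|{g}" in pairwise_p else f"{g}|{control}"
            ]
            for g in disease
        },
        index=ab.index,
    )
    return DEResult(
        control=control,
        groups=list(groups),
        anova=anova,
        diffs=diffs,
        tukey_p=tukey_p,
        pairwise_p=pairwise_p,
    )


def count_significant(
    de: DEResult, contrast: str, alpha: float = 0.05, mode: str = "tukey"
) -> int:
    """Number of proteins significant for a disease-vs-control contrast.

    ``mode="tukey"`` (default) counts Tukey pairwise p < alpha;
    ``mode="anova"`` counts overall ANOVA p < alpha (contrast-independent
    gate).
    """
    if contrast not in de.tukey_p.columns:
        raise KeyError(f"unknown contrast {contrast!r}; have {list(de.tukey_p.columns)}")
    if mode == "tukey":
        return int((de.tukey_p[contrast] < alpha).sum())
    if mode == "anova":
        return int((de.anova["p"] < alpha).sum())
    raise ValueError("mode must be 'tukey' or 'anova'")


def overlap_sets(sets: dict[str, set]) -> dict:
    """All Venn-partition region counts plus every k-way intersection.

    Returns ``{"regions": DataFrame, "intersections": {tuple: count}}``
    where regions has one boolean column per set and a ``count``
    column, and intersections maps every subset of >= 1 set names (in
    input order) to its intersection cardinality.
    """
    names = list(sets)
    sets = {k: set(v) for k, v in sets.items()}
    universe = set().union(*sets.values()) if sets else set()
    rows = []
    for pattern in product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        inside = [n for n, b in zip(names, pattern) if b]
        outside = [n for n, b in zip(names, pattern) if not b]
        region = set.intersection(*(sets[n] for n in inside)) if inside else universe
        for n in outside:
            region = region - sets[n]
        rows.append({**dict(zip(names, pattern)), "count": len(region)})
    regions = pd.DataFrame(rows)
    inter = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter[combo] = len(set.intersection(*(sets[n] for n in combo)))
    return {"regions": regions, "intersections": inter}


def module_trait_significance(
    profiles: pd.DataFrame,
    meta: pd.DataFrame,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age", "sex", "pmi"),
) -> pd.DataFrame:
    """Covariate-adjusted group significance per module/weight column.

    Fits ``response = group + covariates`` and reports the type-II F
    statistic for the group term with its F-distribution p-value (the
    module p-value), plus a plain rank-based Kruskal-Wallis p for
    comparison.
    """
    meta = meta.loc[profiles.index]
    groups = meta[group_col].astype(str)
    G = pd.get_dummies(groups, drop_first=True).to_numpy(float)
    blocks = [np.ones((len(meta), 1))]
    for c in covariates:
        v = meta[c]
        if pd.api.types.is_numeric_dtype(v):
            blocks.append((v.to_numpy(float) - v.to_numpy(float).mean())[:, None])
        else:
            blocks.append(pd.get_dummies(v.astype(str), drop_first=True).to_numpy(float))
    reduced = np.hstack(blocks)
    full = np.hstack([reduced, G])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("collinear covariates / group design")
    df1 = G.shape[1]
    df2 = len(meta) - full.shape[1]
    out = []
    labels = groups.to_numpy()
    for col in profiles.columns:
        y = profiles[col].to_numpy(float)
        rss_r = _rss(reduced, y)
        rss_f = _rss(full, y)
        F = ((rss_r - rss_f) / df1) / (rss_f / df2) if rss_f > 0 else np.inf
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        if np.ptp(y) == 0:
            p_kw = 1.0  # constant response: no rank information
        else:
            p_kw = float(sps.kruskal(*(y[labels == g] for g in pd.unique(labels))).pvalue)
        out.append({"module": col, "F": F, "p": p, "p_kruskal": p_kw})
    return pd.DataFrame(out).set_index("module")


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)
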