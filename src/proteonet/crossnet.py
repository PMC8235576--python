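"""Cross-network comparison: module overlap, synthetic eigengene projection,
and protein-level differential-expression correlation.

Overlap between two module assignments is scored by hypergeometric
enrichment/depletion over the shared protein universe with
Benjamini-Hochberg correction per direction. A source network's module
can also be projected into a target dataset as a "synthetic" eigengene:
its top-decile-kME members present in the target (at least 4 of them)
are summarized by the usual eigenprotein machinery in the target's
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr
from statsmodels.stats.multitest import multipletests

from .network import UNASSIGNED, module_eigenproteins


@dataclass
class OverlapResult:
    """Module-pair overlap statistics (rows: net A modules, cols: net B)."""

    counts: pd.DataFrame
    p_enrich: pd.DataFrame
    p_deplete: pd.DataFrame
    q_enrich: pd.DataFrame
    q_deplete: pd.DataFrame
    signed_neglog10: pd.DataFrame
    universe_size: int


def module_overlap(
    assign_a: pd.Series,
    assign_b: pd.Series,
    universe: pd.Index | None = None,
    include_unassigned: bool = False,
) -> OverlapResult:
    """Hypergeometric overlap of two module assignments.

    For each pair the enrichment p is the upper tail P(X >= k) of
    observing the shared-member count ``k`` given the module sizes and
    the shared universe; the depletion p is the lower tail P(X <= k).
    BH correction is applied across the full pair grid per direction.
    Unassigned proteins are excluded from the universe by default.
    """
    if universe is None:
        universe = assign_a.index.intersection(assign_b.index)
    a = assign_a.loc[assign_a.index.intersection(universe)]
    b = assign_b.loc[assign_b.index.intersection(universe)]
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    if not include_unassigned:
        keep = (a != UNASSIGNED) & (b != UNASSIGNED)
        a, b = a[keep], b[keep]
    N = len(a)
    if N == 0:
        raise ValueError("empty shared protein universe")
    mods_a = list(pd.unique(a))
    mods_b = list(pd.unique(b))
    counts = pd.DataFrame(0, index=mods_a, columns=mods_b)
    pe = pd.DataFrame(1.0, index=mods_a, columns=mods_b)
    pdep = pd.DataFrame(1.0, index=mods_a, columns=mods_b)
    for ma in mods_a:
        in_a = a == ma
        K = int(in_a.sum())
        for mb in mods_b:
            in_b = b == mb
            n = int(in_b.sum())
            k = int((in_a & in_b).sum())
            counts.loc[ma, mb] = k
            pe.loc[ma, mb] = float(hypergeom.sf(k - 1, N, K, n))
            pdep.loc[ma, mb] = float(hypergeom.cdf(k, N, K, n))
    qe = pe.copy()
    qd = pdep.copy()
    qe[:] = multipletests(pe.to_numpy().ravel(), method="fdr_bh")[1].reshape(pe.shape)
    qd[:] = multipletests(pdep.to_numpy().ravel(), method="fdr_bh")[1].reshape(pdep.shape)
    expected = pd.DataFrame(
        np.outer([(a == m).sum() for m in mods_a], [(b == m).sum() for m in mods_b]) / N,
        index=mods_a,
        columns=mods_b,
    )
    enriched = counts >= expected
    signed = np.where(
        enriched,
        -np.log10(pe.clip(lower=1e-300)),
        np.log10(pdep.clip(lower=1e-300)),
    )
    return OverlapResult(
        counts=counts,
        p_enrich=pe,
        p_deplete=pdep,
        q_enrich=qe,
        q_deplete=qd,
        signed_neglog10=pd.DataFrame(signed, index=mods_a, columns=mods_b),
        universe_size=N,
    )


def project_synthetic_eigengene(
    source_kme: pd.DataFrame,
    source_assign: pd.Series,
    target_ab: pd.DataFrame,
    top_quantile: float = 0.9,
    min_members: int = 4,
    within_module: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project source modules into a target dataset as synthetic eigengenes.

    Members with own-module kME at or above the ``top_quantile``
    percentile (computed within each source module by default, globally
    when ``within_module=False``) are intersected with the target's
    proteins; when at least ``min_members`` remain their eigenprotein
    is computed in the target samples. Returns ``(eigengenes, report)``
    where the report lists every source module with its member counts
    and an exclusion reason where applicable.
    """
    eig = {}
    rows = []
    if not within_module:
        own = pd.Series(
            {p: source_kme.loc[p, m] for p, m in source_assign.items() if m in source_kme.columns}
        )
        global_thresh = own.quantile(top_quantile)
    for m in [m for m in pd.unique(source_assign) if m != UNASSIGNED]:
        members = source_assign.index[source_assign == m]
        members = members.intersection(source_kme.index)
        kme_own = source_kme.loc[members, m]
        thresh = kme_own.quantile(top_quantile) if within_module else global_thresh
        top = kme_own.index[kme_own >= thresh]
        present = top.intersection(target_ab.index)
        row = dict(module=m, n_top=len(top), n_in_target=len(present), reason="")
        if len(present) < min_members:
            row["reason"] = f"fewer than {min_members} members in target"
            rows.append(row)
            continue
        sub_assign = pd.Series(m, index=present)
        e, _ = module_eigenproteins(target_ab.loc[present], sub_assign)
        eig[m] = e[m]
        rows.append(row)
    report = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    eigengenes = pd.DataFrame(eig, index=target_ab.columns)
    return eigengenes, report


def cross_disease_correlation(
    de_a,
    de_b,
    contrast_a: str,
    contrast_b: str,
    coloring: pd.Series | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of two contrasts' log2 differences.

    Returns ``(r, p, table)`` over the shared proteins; the table
    carries each protein's module color for plotting when given.
    """
    da = de_a.diffs[contrast_a]
    db = de_b.diffs[contrast_b]
    shared = da.index.intersection(db.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared proteins (< 10)")
    x, y = da.loc[shared], db.loc[shared]
    r, p = pearsonr(x, y)
    table = pd.DataFrame({"diff_a": x, "diff_b": y})
    if coloring is not None:
        table["module"] = coloring.reindex(shared).fillna(UNASSIGNED)
    return float(r), float(p), table
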