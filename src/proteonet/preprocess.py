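"""Reference-channel normalization, completeness filtering, outlier removal.

Estimators follow sklearn conventions (samples x proteins orientation,
``fit``/``transform``, fitted attributes with trailing underscores); the
module-level functions keep the proteins x samples disk orientation and
are thin wrappers over them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


def _require_meta(X: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    missing = [s for s in X.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    return meta.loc[X.index]


class GISNormalizer(BaseEstimator, TransformerMixin):
    """Subtract each batch's pooled-reference (GIS) channel mean.

    For every protein and batch, the mean log2 abundance of that batch's
    GIS channels is subtracted from all channels of the batch, anchoring
    abundances to the shared pooled standard. GIS channels are retained:
    they are cross-batch technical replicates and anchor the later
    empirical-Bayes passes.
    """

    def __init__(self, batch_col: str = "batch", gis_col: str = "is_gis"):
        self.batch_col = batch_col
        self.gis_col = gis_col

    def fit(self, X: pd.DataFrame, y=None, meta: pd.DataFrame | None = None):
        if meta is None:
            raise ValueError("meta is required")
        meta = _require_meta(X, meta)
        offsets = {}
        for b, rows in meta.groupby(self.batch_col, sort=False):
            gis = rows.index[rows[self.gis_col].astype(bool)]
            if len(gis) == 0:
                raise ValueError(f"batch {b!r} has no GIS channel")
            offsets[b] = X.loc[gis].mean(axis=0, skipna=True)
        self.offsets_ = pd.DataFrame(offsets).T  # batch x protein
        return self

    def transform(self, X: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        if meta is None:
            raise ValueError("meta is required")
        meta = _require_meta(X, meta)
        out = X.copy()
        for b, rows in meta.groupby(self.batch_col, sort=False):
            out.loc[rows.index] = X.loc[rows.index] - self.offsets_.loc[b]
        return out


class CompleteCaseFilter(BaseEstimator, TransformerMixin):
    """Keep only proteins observed in every channel of every batch.

    The completeness rule is defined at batch level: a single missing
    cell anywhere disqualifies the protein, mirroring a
    no-missingness-across-batches inclusion criterion. Column (protein)
    order is preserved.
    """

    def fit(self, X: pd.DataFrame, y=None, meta: pd.DataFrame | None = None):
        self.keep_ = X.notna().all(axis=0)
        if not self.keep_.any():
            warnings.warn("no protein passes the completeness filter", stacklevel=2)
        return self

    def transform(self, X: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        return X.loc[:, self.keep_[self.keep_].index.intersection(X.columns)]


class ConnectivityOutlierFilter(BaseEstimator, TransformerMixin):
    """Drop samples whose network connectivity is an outlier.

    Per-sample connectivity over sample-sample Pearson correlations of
    protein profiles::

        k_i = sum_{j != i} (1 + cor(i, j)) / 2

    standardized to Z.k within each stratum (instrument platform when
    ``per_platform``); samples with ``|Z.k| > z_cut`` are removed in a
    single pass. A stratum with zero connectivity spread has no
    outliers.
    """

    def __init__(self, z_cut: float = 2.0, per_platform: bool = True, platform_col: str = "platform"):
        self.z_cut = z_cut
        self.per_platform = per_platform
        self.platform_col = platform_col

    def fit(self, X: pd.DataFrame, y=None, meta: pd.DataFrame | None = None):
        if self.per_platform and meta is None:
            raise ValueError("meta is required for per-platform stratification")
        strata = (
            _require_meta(X, meta)[self.platform_col]
            if self.per_platform
            else pd.Series("all", index=X.index)
        )
        records = []
        for stratum, samples in strata.groupby(strata, sort=False):
            ids = samples.index
            if len(ids) < 3:
                raise ValueError(f"stratum {stratum!r} has fewer than 3 samples")
            cor = np.corrcoef(X.loc[ids].to_numpy())
            k = ((1.0 + cor) / 2.0).sum(axis=1) - 1.0  # exclude self term
            sd = k.std(ddof=1)
            z = (k - k.mean()) / sd if sd > 0 else np.zeros_like(k)
            for s, ki, zi in zip(ids, k, z):
                records.append((s, stratum, ki, zi))
        self.report_ = pd.DataFrame(
            records, columns=["sample_id", "stratum", "k", "z_k"]
        ).set_index("sample_id")
        self.removed_ = list(self.report_.index[self.report_["z_k"].abs() > self.z_cut])
        return self

    def transform(self, X: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        return X.drop(index=[s for s in self.removed_ if s in X.index])


# ---------------------------------------------------------------------------
# proteins x samples functional wrappers


def normalize_to_gis(ab: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """GIS-anchor a proteins x samples log2 matrix (see :class:`GISNormalizer`)."""
    norm = GISNormalizer().fit(ab.T, meta=meta)
    return norm.transform(ab.T, meta=meta).T


def filter_complete_proteins(ab: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Restrict to proteins with zero missing cells in every batch."""
    f = CompleteCaseFilter().fit(ab.T)
    return f.transform(ab.T).T


def remove_connectivity_outliers(
    ab: pd.DataFrame,
    meta: pd.DataFrame,
    z_cut: float = 2.0,
    per_platform: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass |Z.k| outlier removal; returns (matrix, removal report)."""
    f = ConnectivityOutlierFilter(z_cut=z_cut, per_platform=per_platform).fit(ab.T, meta=meta)
    report = f.report_.loc[f.removed_] if f.removed_ else f.report_.iloc[0:0]
    return f.transform(ab.T).T, report
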