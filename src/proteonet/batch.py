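"""Empirical-Bayes batch harmonization and covariate regression.

The corrector implements the parametric location/scale empirical-Bayes
adjustment (the ComBat model): per protein, a linear model with batch
offsets and protected biological covariates is fitted; residuals are
standardized by the pooled variance; per-batch location and scale
estimates are shrunk toward moment-matched normal / inverse-gamma
priors by the standard iterative update; and the data are reconstructed
with batch terms removed and protected terms restored.

Multi-pass orchestration (``run_harmonization_plan``) encodes the
staged-cohort recipe: per-platform labeling-batch passes protecting
diagnosis and region, a cross-platform pass, removal of the pooled
reference (GIS) channels, and a final region pass protecting sex.

``regress_covariates_bootstrap`` then removes age/PMI covariance by
nonparametric (case-resampling) bootstrap regression with diagnosis
protected in every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

_ZERO_VAR = 1e-12


class DesignError(ValueError):
    """Rank-deficient or confounded design matrix."""


def _dummies(meta: pd.DataFrame, cols: tuple[str, ...] | list[str]) -> np.ndarray:
    """Design block: centered values for float covariates (age, PMI),
    drop-first dummies for everything else (factors stay factors even
    when integer-coded, e.g. batch or platform ids)."""
    blocks = []
    for c in cols:
        v = meta[c]
        if pd.api.types.is_float_dtype(v):
            blocks.append((v.to_numpy(float) - v.to_numpy(float).mean())[:, None])
        else:
            d = pd.get_dummies(v.astype(str), drop_first=True).to_numpy(float)
            blocks.append(d)
    if not blocks:
        return np.empty((len(meta), 0))
    return np.hstack(blocks)


@dataclass
class EBAdjustment:
    """Fitted empirical-Bayes adjustment (one pass)."""

    batch_levels: list
    grand_mean: np.ndarray  # per protein
    beta_protected: np.ndarray  # q x proteins
    pooled_var: np.ndarray  # per protein
    gamma_star: pd.DataFrame  # batch x protein, shrunk locations
    delta_star: pd.DataFrame  # batch x protein, shrunk scales (>0)
    hyper: dict = field(default_factory=dict)  # per batch: gamma_bar, tau2, lambda, theta


class EmpiricalBayesBatchCorrector(BaseEstimator, TransformerMixin):
    """Parametric location/scale empirical-Bayes batch correction.

    sklearn-style, transductive: ``fit`` estimates the adjustment on the
    samples it is given and ``transform`` applies it to those same
    samples. Protected covariates (diagnosis, region, ...) are modeled
    explicitly and restored untouched. With a single batch the data are
    returned unchanged.

    Parameters
    ----------
    batch_col : metadata column naming the factor to remove.
    protected_cols : metadata columns whose effects must be preserved.
    tol : convergence tolerance of the iterative EB update.
    """

    def __init__(
        self,
        batch_col: str = "batch",
        protected_cols: tuple[str, ...] = (),
        tol: float = 1e-4,
        max_iter: int = 500,
    ):
        self.batch_col = batch_col
        self.protected_cols = protected_cols
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None, meta: pd.DataFrame | None = None):
        if meta is None:
            raise ValueError("meta is required")
        meta = meta.loc[X.index]
        if X.isna().any().any():
            raise ValueError("missing cells: run the completeness filter first")
        batches = meta[self.batch_col]
        levels = list(pd.unique(batches))
        counts = batches.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise DesignError(f"batch level(s) {small} have fewer than 2 samples")

        B = pd.get_dummies(batches.astype(str), drop_first=False)[
            [str(level) for level in levels]
        ].to_numpy(float)
        C = _dummies(meta, self.protected_cols)
        if C.shape[1] and np.linalg.matrix_rank(np.hstack([np.ones((len(meta), 1)), C])) < C.shape[1] + 1:
            raise DesignError("protected design is rank deficient")
        design = np.hstack([B, C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise DesignError(
                f"batch factor {self.batch_col!r} is confounded with protected "
                f"terms {tuple(self.protected_cols)!r} (aliased design columns)"
            )

        self.samples_ = X.index
        self.batches_ = batches
        if len(levels) == 1:
            self.identity_ = True
            self.adjustment_ = None
            return self
        self.identity_ = False

        Y = X.to_numpy(float)  # n x p
        n, p = Y.shape
        n_b = B.sum(axis=0)

        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        batch_coef = coef[: len(levels)]  # nb x p
        beta = coef[len(levels):]  # q x p
        grand_mean = (n_b / n) @ batch_coef
        resid = Y - design @ coef
        pooled_var = (resid**2).mean(axis=0)
        ok = pooled_var > _ZERO_VAR
        scale = np.sqrt(np.where(ok, pooled_var, 1.0))

        stand_mean = grand_mean[None, :] + (C @ beta if C.shape[1] else 0.0)
        Z = np.where(ok[None, :], (Y - stand_mean) / scale[None, :], 0.0)

        gamma_star = np.zeros((len(levels), p))
        delta_star = np.ones((len(levels), p))
        hyper = {}
        for bi, level in enumerate(levels):
            rows = B[:, bi].astype(bool)
            Zb = Z[rows]
            nb = int(n_b[bi])
            g_hat = Zb.mean(axis=0)
            d_hat = Zb.var(axis=0, ddof=1)
            g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
            m, s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
            if s2 > _ZERO_VAR and t2 > _ZERO_VAR:
                lam = (2.0 * s2 + m**2) / s2
                theta = (m * s2 + m**3) / s2
                g_star, d_star = _it_solve(
                    Zb, g_hat, d_hat, g_bar, t2, lam, theta, self.tol, self.max_iter
                )
            else:
                # degenerate priors (e.g. noiseless fixtures): use direct estimates
                lam, theta = np.nan, np.nan
                g_star, d_star = g_hat, np.maximum(d_hat, _ZERO_VAR)
            gamma_star[bi] = g_star
            delta_star[bi] = np.maximum(d_star, _ZERO_VAR)
            hyper[level] = dict(gamma_bar=g_bar, tau2=t2, lam=lam, theta=theta, n=nb)

        bayes = np.where(
            ok[None, :],
            (Z - B @ gamma_star) / np.sqrt(B @ delta_star) * scale[None, :] + stand_mean,
            stand_mean if np.ndim(stand_mean) else Y,
        )
        self.adjusted_ = pd.DataFrame(bayes, index=X.index, columns=X.columns)
        self.adjustment_ = EBAdjustment(
            batch_levels=levels,
            grand_mean=grand_mean,
            beta_protected=beta,
            pooled_var=pooled_var,
            gamma_star=pd.DataFrame(gamma_star, index=levels, columns=X.columns),
            delta_star=pd.DataFrame(delta_star, index=levels, columns=X.columns),
            hyper=hyper,
        )
        return self

    def transform(self, X: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        if self.identity_:
            return X.copy()
        if not X.index.equals(self.samples_):
            raise ValueError("transductive corrector: transform expects the fitted samples")
        return self.adjusted_.copy()


def _it_solve(Zb, g_hat, d_hat, g_bar, t2, lam, theta, tol, max_iter):
    """Iterative EB shrinkage updates to convergence (parametric priors)."""
    nb = Zb.shape[0]
    g_star, d_star = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (nb * t2 * g_hat + d_star * g_bar) / (nb * t2 + d_star)
        sum2 = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (theta + 0.5 * sum2) / (nb / 2.0 + lam - 1.0)
        change = max(
            np.abs(g_new - g_star).max() / max(np.abs(g_star).max(), 1e-30),
            np.abs(d_new - d_star).max() / max(np.abs(d_star).max(), 1e-30),
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


# ---------------------------------------------------------------------------
# functional surface (proteins x samples)


def eb_batch_adjust(
    ab: pd.DataFrame,
    meta: pd.DataFrame,
    batch_factor: str,
    protected: tuple[str, ...] = (),
    tol: float = 1e-4,
) -> tuple[pd.DataFrame, EBAdjustment | None]:
    """Empirical-Bayes adjust a proteins x samples matrix (one pass)."""
    est = EmpiricalBayesBatchCorrector(batch_col=batch_factor, protected_cols=protected, tol=tol)
    est.fit(ab.T, meta=meta)
    return est.transform(ab.T, meta=meta).T, est.adjustment_


@dataclass
class HarmonizationStep:
    """One pass: remove ``batch_factor`` protecting ``protected``.

    ``within``: run the pass separately inside each level of that
    metadata column (e.g. per instrument platform). ``drop_gis``: drop
    pooled-reference channels *before* this pass runs (``None`` batch
    factor means the step only drops them).
    """

    batch_factor: str | None
    protected: tuple[str, ...] = ()
    within: str | None = None
    drop_gis: bool = False


def default_plan() -> list[HarmonizationStep]:
    """The four-pass staged-cohort recipe.

    (1) within each platform, remove labeling-batch effects protecting
    diagnosis and region; (2) across the merged matrix, remove platform
    protecting diagnosis and region; (3) drop GIS channels; (4) remove
    region protecting sex, yielding region-agnostic profiles.
    """
    return [
        HarmonizationStep("batch", ("group", "region"), within="platform"),
        HarmonizationStep("platform", ("group", "region")),
        HarmonizationStep("region", ("sex",), drop_gis=True),
    ]


def run_harmonization_plan(
    ab: pd.DataFrame,
    meta: pd.DataFrame,
    plan: list[HarmonizationStep] | None = None,
    gis_col: str = "is_gis",
) -> pd.DataFrame:
    """Run an ordered list of EB passes; returns biological samples only.

    An empty plan returns the biological samples of the input unchanged.
    """
    if plan is None:
        plan = default_plan()
    out = ab.copy()
    meta = meta.loc[out.columns]
    for step in plan:
        if step.drop_gis and gis_col in meta.columns:
            keep = meta.index[~meta[gis_col].astype(bool)]
            out = out[keep]
            meta = meta.loc[keep]
        if step.batch_factor is None:
            continue
        if step.batch_factor not in meta.columns:
            raise KeyError(f"plan references unknown factor {step.batch_factor!r}")
        if step.within is not None:
            parts = []
            for _, rows in meta.groupby(step.within, sort=False):
                sub, _ = eb_batch_adjust(
                    out[rows.index], meta.loc[rows.index], step.batch_factor, step.protected
                )
                parts.append(sub)
            out = pd.concat(parts, axis=1)[out.columns]
        else:
            out, _ = eb_batch_adjust(out, meta, step.batch_factor, step.protected)
    if gis_col in meta.columns:
        keep = meta.index[~meta[gis_col].astype(bool)]
        out = out[[c for c in out.columns if c in set(keep)]]
    return out


def variance_partition(
    ab: pd.DataFrame,
    meta: pd.DataFrame,
    factors: list[str],
    on_aliased: str = "zero",
    method: str = "seq",
) -> pd.DataFrame:
    """Per-protein variance fractions from sequential sums of squares.

    Factors enter a fixed-effects linear model in the given order; each
    factor's fraction is its incremental reduction in residual sum of
    squares over the total (centered) sum of squares, so shared
    variance is credited to the earlier factor. Fractions plus the
    residual sum to 1 (``method="seq"``, default).

    ``method="excess"`` subtracts each factor's chance expectation
    (its degrees of freedom times the residual mean square, the
    method-of-moments null) and clips at zero — a k-degree-of-freedom
    factor absorbs ~k/(n-1) of pure noise by chance, so the raw
    sequential fraction has a noise floor that this mode removes; use
    it to ask whether any *real* factor variance remains. Excess
    fractions do not sum to 1.

    A factor fully aliased by its predecessors (e.g. platform when every
    labeling batch runs on one platform and batch precedes it) adds no
    dimension and scores 0 when ``on_aliased="zero"`` (default);
    ``on_aliased="raise"`` turns any aliasing into :class:`DesignError`.
    """
    if method not in ("seq", "excess"):
        raise ValueError("method must be 'seq' or 'excess'")
    meta = meta.loc[ab.columns]
    for f in factors:
        if f not in meta.columns:
            raise KeyError(f"factor {f!r} not in metadata")
    n = ab.shape[1]
    Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis so far (intercept)
    Y = ab.to_numpy(float).T  # n x p
    Yc = Y - Y.mean(axis=0, keepdims=True)
    tss = (Yc**2).sum(axis=0)
    tss_safe = np.where(tss > _ZERO_VAR, tss, np.nan)
    fracs = {}
    dfs = {}
    explained = np.zeros(ab.shape[0])
    for f in factors:
        blk = _dummies(meta, [f])
        # residualize against the accumulated basis, keep new directions
        R = blk - Q @ (Q.T @ blk)
        Qf, Rf = np.linalg.qr(R)
        keep = np.abs(np.diag(Rf)) > 1e-8 * max(1.0, np.abs(Rf).max())
        if not keep.any():
            if on_aliased == "raise":
                raise DesignError(f"factor {f!r} is aliased by preceding factors")
            fracs[f] = np.zeros(ab.shape[0])
            dfs[f] = 0
            continue
        Qf = Qf[:, keep]
        T = Qf.T @ Y
        ss = (T**2).sum(axis=0)
        fracs[f] = ss / tss_safe
        dfs[f] = Qf.shape[1]
        explained += ss
        Q = np.hstack([Q, Qf])
    rss = tss - explained
    if method == "excess":
        df_resid = max(n - Q.shape[1], 1)
        ms_resid = rss / df_resid
        for f in factors:
            fracs[f] = np.maximum(fracs[f] - dfs[f] * ms_resid / tss_safe, 0.0)
    fracs["residual"] = rss / tss_safe
    return pd.DataFrame(fracs, index=ab.index).fillna(0.0)


class BootstrapCovariateRegressor(BaseEstimator, TransformerMixin):
    """Remove nuisance covariates by bootstrap-stabilized regression.

    Per protein the model ``value = intercept + group + b_age*age +
    b_pmi*pmi`` is fitted on ``n_boot`` case-resampled datasets
    (resampling within the protected group, so diagnosis is represented
    in every fit); nuisance slopes are aggregated by the mean and the
    centered nuisance contribution subtracted. Group structure is
    untouched. With ``n_boot=1`` and ``resample=False`` this is exactly
    plain least-squares removal.
    """

    def __init__(
        self,
        nuisance: tuple[str, ...] = ("age", "pmi"),
        protected: str = "group",
        n_boot: int = 1000,
        seed: int = 0,
        resample: bool = True,
    ):
        self.nuisance = nuisance
        self.protected = protected
        self.n_boot = n_boot
        self.seed = seed
        self.resample = resample

    def fit(self, X: pd.DataFrame, y=None, meta: pd.DataFrame | None = None):
        if meta is None:
            raise ValueError("meta is required")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        meta = meta.loc[X.index]
        if X.isna().any().any():
            raise ValueError("missing cells are not supported")
        groups = meta[self.protected].astype(str)
        counts = groups.value_counts()
        if self.resample and (counts < 2).any():
            raise ValueError(
                f"group(s) {counts[counts < 2].index.tolist()} have a single sample; "
                "within-group resampling impossible"
            )
        G = pd.get_dummies(groups, drop_first=True).to_numpy(float)
        Z = meta[list(self.nuisance)].to_numpy(float)
        Zc = Z - Z.mean(axis=0, keepdims=True)
        design = np.hstack([np.ones((len(meta), 1)), G, Zc])
        nz = len(self.nuisance)
        Y = X.to_numpy(float)

        rng = np.random.default_rng(self.seed)
        group_pos = {g: np.flatnonzero(groups.to_numpy() == g) for g in counts.index}
        slopes = np.zeros((nz, Y.shape[1]))
        for _ in range(self.n_boot):
            if self.resample:
                idx = np.concatenate(
                    [rng.choice(pos, size=len(pos), replace=True) for pos in group_pos.values()]
                )
            else:
                idx = np.arange(len(meta))
            coef, *_ = np.linalg.lstsq(design[idx], Y[idx], rcond=None)
            slopes += coef[-nz:]
        slopes /= self.n_boot

        self.slopes_ = pd.DataFrame(slopes, index=list(self.nuisance), columns=X.columns)
        self.nuisance_means_ = Z.mean(axis=0)
        return self

    def transform(self, X: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        if meta is None:
            raise ValueError("meta is required")
        meta = meta.loc[X.index]
        Zc = meta[list(self.nuisance)].to_numpy(float) - self.nuisance_means_[None, :]
        return X - Zc @ self.slopes_.to_numpy()


def regress_covariates_bootstrap(
    ab: pd.DataFrame,
    meta: pd.DataFrame,
    nuisance: tuple[str, ...] = ("age", "pmi"),
    protected: str = "group",
    n_boot: int = 1000,
    seed: int = 0,
    resample: bool = True,
) -> pd.DataFrame:
    """Functional wrapper over :class:`BootstrapCovariateRegressor` (proteins x samples)."""
    est = BootstrapCovariateRegressor(
        nuisance=nuisance, protected=protected, n_boot=n_boot, seed=seed, resample=resample
    )
    est.fit(ab.T, meta=meta)
    return est.transform(ab.T, meta=meta).T
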