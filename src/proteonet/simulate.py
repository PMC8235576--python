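"""Synthetic multi-batch labeled-proteomics datasets with ground truth.

The generator emulates the statistical structure of a staged
neurodegeneration cohort profiled by isobaric labeling: ~10 labeling
batches of 9 biological samples flanked by 2 pooled-reference (GIS)
channels, two instrument platforms, two brain regions, diagnosis groups
on an ordered severity continuum (control, four disease stages, and an
exaggerated-phenotype endpoint), planted correlated-protein modules with
stage-dependent eigenprotein trajectories, additive/multiplicative batch
effects, age/PMI covariate effects, and whole-batch missingness.

Everything downstream (GIS normalization, empirical-Bayes harmonization,
covariate regression, network construction, deconvolution) can be scored
against the emitted :class:`SyntheticTruth`.

Abundances are generated directly on the log2 scale; linear-scale input
data must be log-transformed at ingestion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical severity ordering used for trajectory construction (0..5)
DEFAULT_GROUPS = ("control", "stage1", "stage2", "stage3", "stage4", "exaggerated")

#: trajectory archetypes as unit patterns over severity levels 0..5.
#: The effect size (in factor-SD units) scales these.
TRAJECTORY_SHAPES: Mapping[str, np.ndarray] = {
    "flat": np.zeros(6),
    "decreasing": np.array([0.0, -0.2, -0.4, -0.6, -0.8, -1.0]),
    "increasing": np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0]),
    "peak_mid": np.array([0.0, 0.2, 1.0, 0.6, 0.4, 0.3]),
    "early_plateau": np.array([0.0, 0.8, 1.0, 1.0, 1.0, 1.2]),
}

DEFAULT_CELLTYPES = ("neuron", "astrocyte", "microglia", "oligodendrocyte", "endothelial")


class ConfigError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the desk-scale study conditions used throughout the
    test suite: 90 biological samples in 10 batches of 9 (+2 GIS each),
    ~1500 proteins of which five planted modules (sizes 30-60) carry
    stage-dependent trajectories at 2 SD effect against 0.5 SD noise.
    """

    n_proteins: int = 1500
    module_sizes: Sequence[int] = (60, 50, 45, 40, 30)
    trajectory_per_module: Sequence[str] = (
        "decreasing",
        "increasing",
        "peak_mid",
        "early_plateau",
        "flat",
    )
    effect_sd: float = 2.0
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "control": 25,
            "stage1": 7,
            "stage2": 12,
            "stage3": 13,
            "stage4": 16,
            "exaggerated": 17,
        }
    )
    n_batches: int = 10
    samples_per_batch: int = 9
    gis_per_batch: int = 2
    platform_of_batch: Mapping[int, int] | None = None
    batch_shift_sd: float = 0.4
    batch_scale_sd: float = 0.2
    platform_shift_sd: float = 0.3
    region_shift_sd: float = 0.25
    covariate_fraction: float = 0.2
    age_slope_sd: float = 0.01
    pmi_slope_sd: float = 0.01
    missing_batch_fraction: float = 0.12
    noise_sd: float = 0.5
    gis_noise_sd: float = 0.0
    n_celltypes: int = 5
    markers_per_type: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if sum(self.module_sizes) > self.n_proteins:
            raise ConfigError(
                f"sum of module sizes {sum(self.module_sizes)} exceeds n_proteins {self.n_proteins}"
            )
        if len(self.module_sizes) != len(self.trajectory_per_module):
            raise ConfigError("module_sizes and trajectory_per_module lengths differ")
        for t in self.trajectory_per_module:
            if t not in TRAJECTORY_SHAPES:
                raise ConfigError(f"unknown trajectory {t!r}")
        if not self.group_sizes:
            raise ConfigError("group_sizes is empty")
        unknown = set(self.group_sizes) - set(DEFAULT_GROUPS)
        if unknown:
            raise ConfigError(f"unknown severity groups: {sorted(unknown)}")
        n_bio = self.n_batches * self.samples_per_batch
        if sum(self.group_sizes.values()) != n_bio:
            raise ConfigError(
                f"group sizes sum to {sum(self.group_sizes.values())} but "
                f"{self.n_batches} batches x {self.samples_per_batch} = {n_bio} biological samples"
            )
        if self.gis_per_batch < 0:
            raise ConfigError("gis_per_batch must be >= 0")
        if self.noise_sd < 0 or self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ConfigError("effect standard deviations must be nonnegative")
        if not 0 <= self.missing_batch_fraction < 1:
            raise ConfigError("missing_batch_fraction must lie in [0, 1)")
        if self.n_celltypes > 0 and self.n_celltypes * self.markers_per_type > self.n_proteins:
            raise ConfigError("marker sets do not fit in n_proteins")

    def platforms(self) -> dict[int, int]:
        """Batch -> platform map; default assigns the first half to platform 1."""
        if self.platform_of_batch is not None:
            return dict(self.platform_of_batch)
        half = (self.n_batches + 1) // 2
        return {b: (1 if b < half else 2) for b in range(self.n_batches)}


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset.

    ``module_of_protein`` labels background proteins ``"background"``.
    ``eigen_trajectory`` holds the planted group-mean level of each
    module's latent factor (log2 units). ``celltype_fraction`` rows lie
    on the simplex; ``marker_sets`` are disjoint across cell types.
    """

    module_of_protein: pd.Series
    eigen_trajectory: pd.DataFrame  # module x group
    batch_additive: pd.DataFrame  # batch x protein
    batch_scale: pd.DataFrame  # batch x protein (noise-scale factors)
    platform_shift: pd.Series  # per protein, added to platform-2 samples
    region_shift: pd.Series  # per protein, added to temporal samples
    covariate_slopes: pd.DataFrame  # protein x {age, pmi}
    loading: pd.Series  # per-protein factor loading (module members)
    module_factor: pd.DataFrame  # module x biological sample latent scores
    celltype_fraction: pd.DataFrame  # sample x cell type, simplex rows
    marker_sets: dict[str, list[str]]
    celltype_signatures: pd.DataFrame  # protein x cell type, linear scale
    mixture_weights: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of_protein": self.module_of_protein.to_dict(),
            "eigen_trajectory": self.eigen_trajectory.to_dict(),
            "covariate_slopes": self.covariate_slopes.to_dict(),
            "marker_sets": self.marker_sets,
            "celltype_fraction": self.celltype_fraction.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _sample_metadata(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Randomize biological samples into batches and attach traits."""
    groups: list[str] = []
    for g, n in config.group_sizes.items():
        groups.extend([g] * n)
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]

    platforms = config.platforms()
    rows = []
    idx = 0
    for b in range(config.n_batches):
        n_ch = config.samples_per_batch + config.gis_per_batch
        # GIS channels flank the biological samples in each batch
        gis_channels = set()
        if config.gis_per_batch >= 1:
            gis_channels.add(1)
        if config.gis_per_batch >= 2:
            gis_channels.add(n_ch)
        gis_channels.update(range(2, config.gis_per_batch))  # any extras
        gis_seen = 0
        for ch in range(1, n_ch + 1):
            if ch in gis_channels:
                region = "frontal" if gis_seen == 0 else "temporal"
                rows.append(
                    dict(
                        sample_id=f"B{b + 1:02d}.GIS{gis_seen + 1}",
                        group="GIS",
                        age=np.nan,
                        sex="M",
                        pmi=np.nan,
                        region=region,
                        batch=b,
                        channel=ch,
                        platform=platforms[b],
                        is_gis=True,
                    )
                )
                gis_seen += 1
            else:
                g = groups[idx]
                rows.append(
                    dict(
                        sample_id=f"S{idx + 1:03d}",
                        group=g,
                        age=float(np.clip(rng.normal(66.0, 9.0), 40.0, 95.0)),
                        sex=("M" if rng.random() < 0.8 else "F"),
                        pmi=float(np.clip(rng.normal(14.0, 5.0), 2.0, 40.0)),
                        region=("frontal" if rng.random() < 0.5 else "temporal"),
                        batch=b,
                        channel=ch,
                        platform=platforms[b],
                        is_gis=False,
                    )
                )
                idx += 1
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a synthetic cohort.

    Returns ``(abundance, meta, truth)`` where ``abundance`` is a
    proteins x samples log2 DataFrame (NaN for whole-batch missingness),
    ``meta`` the per-sample metadata table, and ``truth`` the planted
    structure. The generative model per biological sample ``s`` and
    protein ``p`` is::

        y[p, s] = baseline[p] + loading[p] * factor[module(p), s]
                  + batch_additive[batch(s), p]
                  + platform_shift[p] * 1[platform(s) == 2]
                  + region_shift[p] * 1[region(s) == temporal]
                  + b_age[p] * (age - mean age) + b_pmi[p] * (pmi - mean pmi)
                  + batch_scale[batch(s), p] * eps,   eps ~ N(0, noise_sd^2)

    GIS channels carry the pooled mean of the clean biological signal
    plus the same batch/platform/region technical terms, so they anchor
    cross-batch harmonization. Identical config (including seed) yields
    bit-identical output.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    meta = _sample_metadata(config, rng)
    bio = meta.index[~meta["is_gis"]]
    severity = {g: i for i, g in enumerate(DEFAULT_GROUPS)}

    n_p = config.n_proteins
    proteins = pd.Index([f"P{i + 1:05d}" for i in range(n_p)], name="protein")

    # planted module memberships: first proteins in order, rest background
    module_names = [f"sim{m + 1}" for m in range(len(config.module_sizes))]
    labels = np.array(["background"] * n_p, dtype=object)
    pos = 0
    for name, size in zip(module_names, config.module_sizes):
        labels[pos : pos + size] = name
        pos += size
    module_of_protein = pd.Series(labels, index=proteins, name="module")

    baseline = rng.normal(0.0, 0.5, size=n_p)
    loading = rng.uniform(0.7, 1.0, size=n_p)

    # latent module factors per biological sample: planted group mean + unit jitter
    traj = pd.DataFrame(
        {
            g: [
                config.effect_sd * TRAJECTORY_SHAPES[t][severity[g]]
                for t in config.trajectory_per_module
            ]
            for g in DEFAULT_GROUPS
            if g in config.group_sizes
        },
        index=module_names,
    )
    factor = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(module_names), len(bio))),
        index=module_names,
        columns=bio,
    )
    for s in bio:
        g = meta.loc[s, "group"]
        factor[s] += traj[g].to_numpy()

    signal = np.tile(baseline[:, None], (1, len(bio)))
    for m_i, name in enumerate(module_names):
        members = module_of_protein.to_numpy() == name
        signal[members, :] += np.outer(loading[members], factor.loc[name].to_numpy())

    # covariate effects on a random protein subset
    slopes = np.zeros((n_p, 2))
    n_cov = int(round(config.covariate_fraction * n_p))
    cov_idx = rng.choice(n_p, size=n_cov, replace=False)
    slopes[cov_idx, 0] = rng.normal(0.0, config.age_slope_sd, size=n_cov)
    slopes[cov_idx, 1] = rng.normal(0.0, config.pmi_slope_sd, size=n_cov)
    age = meta.loc[bio, "age"].to_numpy()
    pmi = meta.loc[bio, "pmi"].to_numpy()
    signal += np.outer(slopes[:, 0], age - age.mean()) + np.outer(slopes[:, 1], pmi - pmi.mean())

    # technical effects
    batch_add = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, n_p))
    batch_scale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=(config.n_batches, n_p)))
    platform_shift = rng.normal(0.0, config.platform_shift_sd, size=n_p)
    region_shift = rng.normal(0.0, config.region_shift_sd, size=n_p)

    pooled = signal.mean(axis=1)  # clean pooled biological signal, per protein

    values = np.empty((n_p, len(meta)))
    for j, s in enumerate(meta.index):
        b = int(meta.loc[s, "batch"])
        is_gis = bool(meta.loc[s, "is_gis"])
        clean = pooled if is_gis else signal[:, bio.get_loc(s)]
        tech = batch_add[b].copy()
        if meta.loc[s, "platform"] == 2:
            tech += platform_shift
        if meta.loc[s, "region"] == "temporal":
            tech += region_shift
        # GIS channels are noise-free by default so they differ across
        # batches only by the planted technical effects (exact anchors)
        sd = config.gis_noise_sd if is_gis else config.noise_sd
        eps = rng.normal(0.0, 1.0, size=n_p)
        values[:, j] = clean + tech + batch_scale[b] * sd * eps

    abundance = pd.DataFrame(values, index=proteins, columns=meta.index)

    # whole-batch missingness: chosen proteins absent in every channel of a batch
    n_miss = int(round(config.missing_batch_fraction * n_p))
    miss_idx = rng.choice(n_p, size=n_miss, replace=False)
    for p_i in miss_idx:
        b = int(rng.integers(config.n_batches))
        cols = meta.index[meta["batch"] == b]
        abundance.loc[proteins[p_i], cols] = np.nan

    # cell-type structure for deconvolution tests (independent of abundance)
    celltypes = list(DEFAULT_CELLTYPES[: config.n_celltypes])
    marker_sets: dict[str, list[str]] = {}
    sig = pd.DataFrame(
        rng.lognormal(2.0, 0.4, size=(n_p, len(celltypes))), index=proteins, columns=celltypes
    )
    taken = rng.permutation(n_p)
    k = 0
    for t in celltypes:
        members = [proteins[i] for i in taken[k : k + config.markers_per_type]]
        k += config.markers_per_type
        marker_sets[t] = [str(p) for p in members]
        sig.loc[members, :] *= 0.1
        sig.loc[members, t] *= 80.0  # markers dominate their own type

    # per-sample fractions: astrocyte share doubled in the exaggerated group
    alpha = np.ones(len(celltypes))
    frac_rows = []
    for s in bio:
        a = alpha.copy()
        if meta.loc[s, "group"] == "exaggerated" and "astrocyte" in celltypes:
            a[celltypes.index("astrocyte")] = 2.0
        frac_rows.append(rng.dirichlet(a * 4.0))
    celltype_fraction = pd.DataFrame(frac_rows, index=bio, columns=celltypes)

    truth = SyntheticTruth(
        module_of_protein=module_of_protein,
        eigen_trajectory=traj,
        batch_additive=pd.DataFrame(batch_add, columns=proteins),
        batch_scale=pd.DataFrame(batch_scale, columns=proteins),
        platform_shift=pd.Series(platform_shift, index=proteins),
        region_shift=pd.Series(region_shift, index=proteins),
        covariate_slopes=pd.DataFrame(slopes, index=proteins, columns=["age", "pmi"]),
        loading=pd.Series(loading, index=proteins),
        module_factor=factor,
        celltype_fraction=celltype_fraction,
        marker_sets=marker_sets,
        celltype_signatures=sig,
    )
    return abundance, meta, truth


def generate_mixture_samples(
    truth: SyntheticTruth,
    n_samples: int,
    seed: int,
    weights: np.ndarray | None = None,
    noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convex mixtures of cell-type signature profiles (linear scale).

    Each sample is ``signatures @ w`` for simplex weights ``w`` (drawn
    Dirichlet(1) unless given), with multiplicative log-normal noise of
    scale ``noise_sd`` (zero noise reproduces the combination exactly).
    Returns ``(abundance, weights)`` and records the weights on
    ``truth.mixture_weights``.
    """
    rng = np.random.default_rng(seed)
    sig = truth.celltype_signatures
    types = list(sig.columns)
    if weights is None:
        weights = rng.dirichlet(np.ones(len(types)), size=n_samples)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.ndim == 1:
            weights = weights[None, :]
        if weights.shape != (n_samples, len(types)):
            raise ValueError("weights shape does not match (n_samples, n_celltypes)")
        if np.any(weights < -1e-12) or np.any(np.abs(weights.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("mixture weights must lie on the simplex")
    names = [f"MIX{i + 1:03d}" for i in range(n_samples)]
    clean = sig.to_numpy() @ weights.T
    if noise_sd > 0:
        clean = clean * np.exp(rng.normal(0.0, noise_sd, size=clean.shape))
    ab = pd.DataFrame(clean, index=sig.index, columns=names)
    w = pd.DataFrame(weights, index=names, columns=types)
    truth.mixture_weights = w
    return ab, w


def write_dataset(
    outdir: str | Path,
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> dict[str, Path]:
    """Write abundance/metadata TSVs (and truth JSON) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.tsv",
        "meta": outdir / "samples.tsv",
    }
    abundance.to_csv(paths["abundance"], sep="\t", na_rep="NA")
    meta.to_csv(paths["meta"], sep="\t")
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    return paths
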