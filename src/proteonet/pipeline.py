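"""Config-driven orchestration of the full analysis with a run manifest.

A run config (YAML) either points at input tables (abundance, metadata,
markers, gene sets, ortholog map) or requests a synthetic cohort, and
sets the harmonization plan, network parameters, contrasts, output
directory, and seed. ``run_pipeline`` executes the stages in order —
simulate/load, prep (GIS normalization, completeness filter, outlier
removal), harmonize (EB passes), regress (bootstrap covariates),
network, diffstats, crossnet (self-projection export), celltype — and
writes every intermediate as TSV plus a JSON manifest with content
hashes so a rerun with the same config and seed is verifiable.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .batch import HarmonizationStep, regress_covariates_bootstrap, run_harmonization_plan, variance_partition
from .celltype import estimate_celltype_weights, module_marker_enrichment
from .crossnet import project_synthetic_eigengene
from .network import CoexpressionNetwork
from .preprocess import filter_complete_proteins, normalize_to_gis, remove_connectivity_outliers
from .simulate import SyntheticConfig, generate_dataset
from .stats import anova_tukey, module_trait_significance


class ConfigValidationError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "proteonet_run",
    "synthetic": None,  # SyntheticConfig kwargs, or None when inputs given
    "inputs": None,  # {abundance, metadata, markers?}
    "z_cut": 2.0,
    "plan": "default",  # or list of {batch_factor, protected, within, drop_gis}
    "n_boot": 200,
    "network": {},  # CoexpressionNetwork kwargs
    "contrasts": {"groups": None, "control": "control"},
}


def load_config(path: str | Path) -> dict:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigValidationError(f"malformed config: {e}") from None
    cfg = {**DEFAULT_CONFIG, **(raw or {})}
    return cfg


def validate_config(path: str | Path) -> dict:
    """Schema and cross-field checks; returns {errors: [...], warnings: [...]}."""
    errors: list[str] = []
    warnings_: list[str] = []
    try:
        cfg = load_config(path)
    except ConfigValidationError as e:
        return {"errors": [str(e)], "warnings": []}
    if cfg["synthetic"] is None and cfg["inputs"] is None:
        errors.append("config needs either 'synthetic' or 'inputs'")
    if cfg["inputs"] is not None:
        for key in ("abundance", "metadata"):
            p = cfg["inputs"].get(key)
            if p is None:
                errors.append(f"inputs.{key} is required")
            elif not Path(p).exists():
                errors.append(f"inputs.{key} path {p!r} does not exist")
    if cfg["synthetic"] is not None:
        try:
            SyntheticConfig(**cfg["synthetic"]).validate()
        except (TypeError, ValueError) as e:
            errors.append(f"synthetic: {e}")
    beta = cfg.get("network", {}).get("beta", 7.0)
    if not 1 <= beta <= 30:
        warnings_.append(f"soft power beta={beta} outside the usual 1-30 range")
    if isinstance(cfg["plan"], list):
        meta_cols = {"batch", "platform", "region", "group", "sex", "age", "pmi"}
        if cfg["inputs"] is not None and cfg["inputs"].get("metadata") and Path(cfg["inputs"]["metadata"]).exists():
            meta_cols = set(pio.read_sample_meta(cfg["inputs"]["metadata"]).columns)
        for step in cfg["plan"]:
            f = step.get("batch_factor")
            if f is not None and f not in meta_cols:
                errors.append(f"plan references absent factor {f!r}")
    return {"errors": errors, "warnings": warnings_}


def _plan_from_config(cfg: dict) -> list[HarmonizationStep] | None:
    if cfg["plan"] == "default" or cfg["plan"] is None:
        return None
    return [
        HarmonizationStep(
            batch_factor=s.get("batch_factor"),
            protected=tuple(s.get("protected", ())),
            within=s.get("within"),
            drop_gis=bool(s.get("drop_gis", False)),
        )
        for s in cfg["plan"]
    ]


def _hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def run_pipeline(cfg: dict | str | Path) -> dict:
    """Execute the staged pipeline; returns (and writes) the run manifest."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    else:
        cfg = {**DEFAULT_CONFIG, **cfg}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, t0: float, outputs: dict[str, Path], in_hash: str, **params):
        manifest.append(
            dict(
                stage=stage,
                input_hash=in_hash,
                outputs={k: str(v) for k, v in outputs.items()},
                params=params,
                seconds=round(time.time() - t0, 3),
            )
        )

    # --- stage 1: simulate / load -----------------------------------------
    t0 = time.time()
    if cfg["synthetic"] is not None:
        sim_cfg = SyntheticConfig(**{**cfg["synthetic"], "seed": cfg["synthetic"].get("seed", cfg["seed"])})
        ab, meta, truth = generate_dataset(sim_cfg)
        truth_path = outdir / "truth.json"
        truth.to_json(truth_path)
        markers = truth.marker_sets
    else:
        ab = pio.read_abundance(cfg["inputs"]["abundance"])
        meta = pio.read_sample_meta(cfg["inputs"]["metadata"])
        pio.check_matrix_meta(ab, meta)
        markers = (
            pio.read_markers(cfg["inputs"]["markers"]) if cfg["inputs"].get("markers") else None
        )
        truth = None
    pio.write_abundance(ab, outdir / "00_input_abundance.tsv")
    meta.to_csv(outdir / "00_samples.tsv", sep="\t")
    record("simulate" if truth is not None else "load", t0, {"abundance": outdir / "00_input_abundance.tsv"}, _hash(ab), seed=cfg["seed"])

    # --- stage 2: prep ------------------------------------------------------
    t0 = time.time()
    in_hash = _hash(ab)
    ab = normalize_to_gis(ab, meta)
    ab = filter_complete_proteins(ab, meta)
    ab, removed = remove_connectivity_outliers(ab, meta, z_cut=cfg["z_cut"])
    meta = meta.loc[ab.columns]
    pio.write_abundance(ab, outdir / "01_prepped.tsv")
    removed.to_csv(outdir / "01_removed_samples.tsv", sep="\t")
    record("prep", t0, {"abundance": outdir / "01_prepped.tsv"}, in_hash, z_cut=cfg["z_cut"])

    # --- stage 3: harmonize -------------------------------------------------
    t0 = time.time()
    in_hash = _hash(ab)
    plan = _plan_from_config(cfg)
    harmonized = run_harmonization_plan(ab, meta, plan)
    meta_bio = meta.loc[harmonized.columns]
    factors = [f for f in ("batch", "platform", "region", "group") if f in meta_bio.columns]
    vp = variance_partition(harmonized, meta_bio, factors)
    pio.write_abundance(harmonized, outdir / "02_harmonized.tsv")
    vp.to_csv(outdir / "02_variance_partition.tsv", sep="\t")
    record("harmonize", t0, {"abundance": outdir / "02_harmonized.tsv"}, in_hash, plan="default" if plan is None else "custom")

    # --- stage 4: regress ---------------------------------------------------
    t0 = time.time()
    in_hash = _hash(harmonized)
    nuisance = tuple(c for c in ("age", "pmi") if c in meta_bio.columns)
    regressed = regress_covariates_bootstrap(
        harmonized, meta_bio, nuisance=nuisance, n_boot=cfg["n_boot"], seed=cfg["seed"]
    )
    pio.write_abundance(regressed, outdir / "03_regressed.tsv")
    record("regress", t0, {"abundance": outdir / "03_regressed.tsv"}, in_hash, n_boot=cfg["n_boot"])

    # --- stage 5: network ---------------------------------------------------
    t0 = time.time()
    in_hash = _hash(regressed)
    net = CoexpressionNetwork(**cfg.get("network", {})).fit(regressed.T)
    assign = pd.DataFrame(
        {
            "module": net.labels_,
            "alias": net.labels_.map(lambda c: net.aliases_.get(c, "M0")),
            "kme_own": [
                net.kme_.loc[p, m] if m in net.kme_.columns else np.nan
                for p, m in net.labels_.items()
            ],
        }
    )
    assign.to_csv(outdir / "04_modules.tsv", sep="\t")
    net.eigenproteins_.to_csv(outdir / "04_eigenproteins.tsv", sep="\t")
    net.kme_.to_csv(outdir / "04_kme.tsv", sep="\t")
    record("network", t0, {"modules": outdir / "04_modules.tsv"}, in_hash, **cfg.get("network", {}))

    # --- stage 6: diffstats -------------------------------------------------
    t0 = time.time()
    groups = cfg["contrasts"].get("groups") or [
        g for g in meta_bio["group"].unique() if g != "GIS"
    ]
    control = cfg["contrasts"].get("control", "control")
    groups = [control] + [g for g in groups if g != control]
    de = anova_tukey(regressed, meta_bio, groups, control=control)
    de_table = pd.concat(
        [de.anova, de.diffs.add_prefix("diff_"), de.tukey_p.add_prefix("tukey_p_")], axis=1
    )
    de_table.to_csv(outdir / "05_differential.tsv", sep="\t")
    if not net.eigenproteins_.empty:
        mts = module_trait_significance(net.eigenproteins_, meta_bio)
        mts.to_csv(outdir / "05_module_significance.tsv", sep="\t")
    record("diffstats", t0, {"de": outdir / "05_differential.tsv"}, _hash(regressed), groups=groups)

    # --- stage 7: crossnet (self-projection export) -------------------------
    t0 = time.time()
    if not net.eigenproteins_.empty:
        syn, rep = project_synthetic_eigengene(net.kme_, net.labels_, regressed)
        syn.to_csv(outdir / "06_synthetic_eigengenes.tsv", sep="\t")
        rep.to_csv(outdir / "06_projection_report.tsv", sep="\t")
    record("crossnet", t0, {"synthetic": outdir / "06_synthetic_eigengenes.tsv"}, _hash(regressed))

    # --- stage 8: celltype --------------------------------------------------
    t0 = time.time()
    if markers:
        weights, sig = estimate_celltype_weights(regressed, markers, meta=meta_bio)
        weights.to_csv(outdir / "07_celltype_weights.tsv", sep="\t")
        if sig is not None:
            sig.to_csv(outdir / "07_celltype_significance.tsv", sep="\t")
        enr = module_marker_enrichment(net.labels_, markers)
        enr.to_csv(outdir / "07_marker_enrichment.tsv", sep="\t", index=False)
    record("celltype", t0, {"weights": outdir / "07_celltype_weights.tsv"}, _hash(regressed))

    run_manifest = {
        "config": {k: v for k, v in cfg.items() if not isinstance(v, (pd.DataFrame,))},
        "stages": manifest,
    }
    (outdir / "manifest.json").write_text(json.dumps(run_manifest, indent=1, default=str))
    return run_manifest
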