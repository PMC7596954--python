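"""Configuration-driven orchestration of the full SBM analysis.

Runs the stages ``simulate -> qc -> decompose -> glm -> voxelglm -> cca``
in dependency order on a phantom or on user-supplied maps, writing all
tables as TSV, maps as NIfTI and summaries as JSON under one output
directory, stamped with a hash of the semantically meaningful
configuration fields.  A stage failure halts downstream stages; partial
outputs are retained next to a ``FAILED`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cca as cca_mod
from . import glm as glm_mod
from . import ica as ica_mod
from . import phantom as phantom_mod
from . import preproc, tables, voxel
from .dataset import GMDataset, load_dataset, save_nifti

log = logging.getLogger("sbmtools")

STAGES = ("simulate", "qc", "decompose", "glm", "voxelglm", "cca")

#: The two first-class symptom batteries entering the CCA analyses.
BATTERIES = {
    "examiner_rated": list(phantom_mod.EXAMINER_BATTERY),
    "parent_rated": list(phantom_mod.PARENT_BATTERY),
}


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclass
class RunConfig:
    """All knobs of one pipeline run; loadable from YAML."""

    output_dir: str = "sbm_run"
    maps_dir: str | None = None  # None -> the simulate stage provides them
    phenotype_path: str | None = None
    smooth_fwhm_mm: float = 4.0
    qc_sd_mult: float = 3.0
    ica_order: int | str = "auto"  # integer or 'auto' (Laplace evidence)
    ica_restarts: int = 5
    ica_seed: int = 0
    glm_terms: dict = field(
        default_factory=lambda: {
            "main": list(glm_mod.DEFAULT_TERMS),
            "adhd": list(glm_mod.ADHD_TERMS),
        }
    )
    glm_fdr_q: float = 0.05
    iq_subset_min_fsiq: float | None = 75.0  # IQ-subset sensitivity variant
    voxel_n_perm: int = 500
    tfce: dict = field(default_factory=dict)
    cca_batteries: dict = field(default_factory=lambda: dict(BATTERIES))
    cca_n_perm: int = 1000
    cca_seed: int = 0
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def semantic_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d.pop("output_dir")  # where outputs land is not semantically meaningful
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _phantom_spec(config: RunConfig) -> phantom_mod.PhantomSpec:
    overrides = dict(config.phantom)
    if "covariate_effects" in overrides:
        overrides["covariate_effects"] = phantom_mod.CovariateEffects(
            **overrides["covariate_effects"]
        )
    for key in ("grid_shape", "group_effect", "behavior_sources"):
        if key in overrides:
            val = overrides[key]
            overrides[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
    return phantom_mod.PhantomSpec(**overrides)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage '{stage}' requires missing artifact {path}")
    return path


def _load_inputs(out: Path, config: RunConfig, stage: str) -> tuple[GMDataset, pd.DataFrame]:
    if config.maps_dir is not None:
        maps_dir = Path(config.maps_dir)
        pheno_path = Path(config.phenotype_path)
    else:
        maps_dir = _require(out / "simulate", stage)
        pheno_path = _require(out / "simulate" / "phenotype.tsv", stage)
    mask = _require(next(iter(sorted(maps_dir.glob("mask.nii*"))), maps_dir / "mask.nii.gz"), stage)
    paths = sorted(p for p in maps_dir.glob("*_gmdensity.nii*"))
    if not paths:
        raise DependencyError(f"stage '{stage}' found no *_gmdensity.nii* in {maps_dir}")
    dataset = load_dataset(paths, mask)
    phenotype = pd.read_csv(pheno_path, sep="\t")
    order = {sid: i for i, sid in enumerate(phenotype["subject_id"])}
    idx = np.argsort([order[s] for s in dataset.subject_ids])
    dataset = GMDataset(
        dataset.data[idx], dataset.mask, dataset.affine,
        [dataset.subject_ids[i] for i in idx],
    )
    return dataset, phenotype


def _smoothed(dataset: GMDataset, config: RunConfig) -> GMDataset:
    return preproc.smooth_fwhm(dataset, config.smooth_fwhm_mm)


def run(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order; return the report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    report: dict = {"config_hash": config.config_hash(), "stages": {}}
    requested = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    try:
        for stage in requested:
            log.info("stage %s starting", stage)
            report["stages"][stage] = _run_stage(stage, out, config)
            log.info("stage %s done", stage)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        report["failed"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _run_stage(stage: str, out: Path, config: RunConfig) -> dict:
    if stage == "simulate":
        spec = _phantom_spec(config)
        dataset, truth = phantom_mod.generate_phantom(spec)
        paths = phantom_mod.write_phantom(dataset, truth, out / "simulate")
        return {"n_subjects": dataset.n_subjects, "n_voxels": dataset.n_voxels,
                "seed": spec.seed, "phenotype": str(paths["phenotype"])}

    if stage == "qc":
        dataset, _ = _load_inputs(out, config, stage)
        qc = preproc.homogeneity_qc(_smoothed(dataset, config), config.qc_sd_mult)
        (out / "qc").mkdir(exist_ok=True)
        qc.to_csv(out / "qc" / "qc_report.tsv", sep="\t", index=False)
        return {"n_flagged": int(qc["flagged"].sum())}

    if stage == "decompose":
        dataset, _ = _load_inputs(out, config, stage)
        sm = _smoothed(dataset, config)
        if config.ica_order == "auto":
            # estimated on unsmoothed maps: the Laplace evidence assumes
            # spatially white residual noise, which smoothing destroys
            order = ica_mod.estimate_order(dataset, method="laplace")
        else:
            order = int(config.ica_order)
        dec = ica_mod.decompose(sm, order, n_restarts=config.ica_restarts,
                                seed=config.ica_seed)
        ica_dir = out / "ica"
        ica_dir.mkdir(exist_ok=True)
        four_d = np.stack([dataset.unmask(s) for s in dec.sources], axis=-1)
        save_nifti(four_d, dataset.affine, ica_dir / "sources.nii.gz")
        loadings = pd.DataFrame(
            dec.loadings,
            columns=[f"IC{i + 1:02d}" for i in range(order)],
        )
        loadings.insert(0, "subject_id", dataset.subject_ids)
        loadings.to_csv(ica_dir / "loadings.tsv", sep="\t", index=False)
        (ica_dir / "convergence.json").write_text(
            json.dumps({"order": order, "seed": config.ica_seed,
                        "explained_variance": dec.explained_variance,
                        "restarts": dec.convergence}, indent=2)
        )
        return {"order": order, "explained_variance": dec.explained_variance}

    if stage == "glm":
        _, phenotype = _load_inputs(out, config, stage)
        loadings = _read_loadings(out, stage)
        glm_dir = out / "glm"
        glm_dir.mkdir(exist_ok=True)
        summary = {}
        variants = dict(config.glm_terms)
        for name, terms in variants.items():
            fit, n_used = _fit_variant(phenotype, loadings, terms, config.glm_fdr_q)
            fit.to_frame().to_csv(glm_dir / f"results_{name}.tsv", sep="\t", index=False)
            (glm_dir / f"results_{name}.json").write_text(json.dumps(
                {"terms": list(terms), "n_used": n_used, "fdr_q": config.glm_fdr_q,
                 "fdr_threshold": fit.fdr_threshold}, indent=2))
            summary[name] = {"n_used": n_used,
                             "n_fdr_significant": int(fit.fdr_significant.sum())}
        if config.iq_subset_min_fsiq is not None:
            sub = phenotype[phenotype["fsiq"] >= config.iq_subset_min_fsiq]
            fit, n_used = _fit_variant(sub.reset_index(drop=True),
                                       loadings.loc[sub.index],
                                       config.glm_terms.get("main", glm_mod.DEFAULT_TERMS),
                                       config.glm_fdr_q)
            fit.to_frame().to_csv(glm_dir / "results_iq_subset.tsv", sep="\t", index=False)
            summary["iq_subset"] = {"n_used": n_used,
                                    "n_fdr_significant": int(fit.fdr_significant.sum())}
        return summary

    if stage == "voxelglm":
        dataset, phenotype = _load_inputs(out, config, stage)
        sm = _smoothed(dataset, config)
        design = glm_mod.build_design(phenotype, glm_mod.DEFAULT_TERMS)
        params = voxel.TFCEParams(**config.tfce)
        inf = voxel.permutation_glm(sm, design, n_perm=config.voxel_n_perm,
                                    params=params, seed=config.ica_seed)
        vdir = out / "voxel"
        vdir.mkdir(exist_ok=True)
        save_nifti(dataset.unmask(inf.stat_map), dataset.affine, vdir / "tstat.nii.gz")
        save_nifti(dataset.unmask(inf.tfce_map), dataset.affine, vdir / "tfce.nii.gz")
        save_nifti(dataset.unmask(1.0 - inf.fwe_p_map), dataset.affine,
                   vdir / "tfce_1mfwep.nii.gz")
        pd.DataFrame({"null_max_tfce": inf.null_max}).to_csv(
            vdir / "null_max.tsv", sep="\t", index=False)
        return {"n_perm": inf.n_permutations,
                "min_fwe_p": float(inf.fwe_p_map.min()),
                "n_sig_voxels": int((inf.fwe_p_map < 0.05).sum())}

    if stage == "cca":
        _, phenotype = _load_inputs(out, config, stage)
        loadings = _read_loadings(out, stage)
        cdir = out / "cca"
        cdir.mkdir(exist_ok=True)
        summary = {}
        aut = phenotype["diagnosis"] == "autism"
        for name, cols in config.cca_batteries.items():
            behav = phenotype.loc[aut, cols]
            x = loadings.loc[aut.to_numpy()].drop(columns="subject_id")
            complete = ~behav.isna().any(axis=1).to_numpy()
            res = cca_mod.fit_cca(x[complete], behav[complete])
            p, null = cca_mod.permutation_test(
                x[complete], behav[complete],
                n_perm=config.cca_n_perm, seed=config.cca_seed)
            bdir = cdir / name
            bdir.mkdir(exist_ok=True)
            (bdir / "mode.json").write_text(json.dumps(
                {"r": float(res.correlations[0]), "perm_p": p,
                 "n": res.n_samples, "n_modes": res.n_modes,
                 "bonferroni_alpha": res.bonferroni_alpha,
                 "significant": p < res.bonferroni_alpha,
                 "n_perm": config.cca_n_perm}, indent=2))
            pd.DataFrame({"variable": res.x_columns,
                          "raw_weight": res.x_weights[:, 0],
                          "corrected": res.x_corrected[:, 0]}).to_csv(
                bdir / "brain_weights.tsv", sep="\t", index=False)
            pd.DataFrame({"variable": res.y_columns,
                          "raw_weight": res.y_weights[:, 0],
                          "corrected": res.y_corrected[:, 0]}).to_csv(
                bdir / "behavior_weights.tsv", sep="\t", index=False)
            scatter = pd.DataFrame({
                "brain_variate": res.x_variates[:, 0],
                "behavior_variate": res.y_variates[:, 0],
            })
            # color covariate: the behavior score loading most on the mode
            top = int(np.argmax(np.abs(res.y_corrected[:, 0])))
            scatter["color_score"] = behav[complete].iloc[:, top].to_numpy()
            scatter.to_csv(bdir / "main_mode_scatter.tsv", sep="\t", index=False)
            pd.DataFrame({"null_r1": null}).to_csv(bdir / "null_r1.tsv",
                                                   sep="\t", index=False)
            summary[name] = {"r": float(res.correlations[0]), "perm_p": p,
                             "n_complete": res.n_samples,
                             "bonferroni_alpha": res.bonferroni_alpha}
        return summary

    raise ValueError(f"unknown stage {stage!r}")


def _read_loadings(out: Path, stage: str) -> pd.DataFrame:
    path = _require(out / "ica" / "loadings.tsv", stage)
    return pd.read_csv(path, sep="\t")


def _fit_variant(phenotype, loadings, terms, q):
    design = glm_mod.build_design(phenotype, terms)
    L = loadings.drop(columns="subject_id").to_numpy(float)
    Lz = (L - L.mean(axis=0)) / L.std(axis=0, ddof=1)
    fit = glm_mod.fit_loading_glm(Lz[design.row_index], design, q=q)
    return fit, design.n


def demographics_report(phenotype: pd.DataFrame) -> pd.DataFrame:
    """Convenience wrapper for the Table-1-style statistics."""
    return tables.demographics_table(phenotype)
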