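"""Synthetic structural-covariation phantoms with known ground truth.

The phantom emulates the generative structure that source-based
morphometry assumes: each participant's gray-matter density map is a
linear mixture of a small number of smooth spatial sources, weighted by
per-participant loadings, plus voxel noise.  On top of the mixture the
generator plants

* a diagnostic group effect: a standardized mean shift on designated
  sources' loadings between the autism and typically-developing groups;
* covariate effects: age, sex, IQ and acquisition-site contributions to
  every loading, so downstream models have something real to adjust for;
* one canonical brain-behavior mode: symptom scores generated linearly
  from a designated subset of loadings plus independent noise, tuned so
  the population canonical correlation equals a requested value.

Everything is deterministic given the spec seed, and the emitted truth
record (:class:`PhantomTruth`) is the recovery oracle for every
downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import GMDataset, save_nifti

#: Behavior score columns, in battery order: five examiner-rated
#: (ADI/ADOS subscales) then three parent-rated totals (SRS/RBS/SSP).
BEHAVIOR_COLUMNS = (
    "adi_social",
    "adi_communication",
    "adi_rrb",
    "ados_social_affect",
    "ados_rrb",
    "srs_total",
    "rbs_total",
    "ssp_total",
)
EXAMINER_BATTERY = BEHAVIOR_COLUMNS[:5]
PARENT_BATTERY = BEHAVIOR_COLUMNS[5:]

COVARIATE_COLUMNS = ("diagnosis", "age", "sex", "fsiq", "site", "adhd")


@dataclass(frozen=True)
class CovariateEffects:
    """Standardized slopes of covariates on every loading column."""

    age: float = 0.10
    sex: float = 0.10
    iq: float = 0.10
    site: float = 0.10


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions the pipeline is designed for: a
    two-group cohort with five acquisition sites, male-skewed autism
    group, small negative group shifts on two sources, and one planted
    canonical mode of correlation 0.7 between a subset of loadings and
    the eight symptom scores.
    """

    grid_shape: tuple[int, int, int] = (20, 24, 20)
    n_subjects: int = 200
    n_sources: int = 5
    source_radius_vox: float = 2.5  # Gaussian sigma of each blob, voxels
    source_amplitude: float = 1.0
    noise_sd: float = 0.25
    baseline: float = 1.0  # mean GM density added before clipping
    clip_negative: bool = True
    group_effect: tuple[tuple[int, float], ...] = ((0, -0.36), (1, -0.32))
    autism_fraction: float = 347.0 / 599.0
    behavior_sources: tuple[int, ...] | None = None  # None -> last min(3, K)
    planted_r: float = 0.7
    behavior_noise_sd: float = 1.0
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    site_count: int = 5
    voxel_size_mm: float = 2.0
    seed: int = 0
    max_source_abs_corr: float = 0.2  # rejection-sampling overlap bound

    def validate(self) -> None:
        if self.n_sources >= self.n_subjects:
            raise ValueError("n_sources must be < n_subjects")
        if self.noise_sd < 0 or self.behavior_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if not 0 < self.planted_r <= 1:
            raise ValueError("planted_r must lie in (0, 1]")
        if any(k >= self.n_sources or k < 0 for k, _ in self.group_effect):
            raise ValueError("group_effect source index out of range")
        if self.behavior_sources is not None and any(
            k >= self.n_sources or k < 0 for k in self.behavior_sources
        ):
            raise ValueError("behavior_sources index out of range")
        if self.site_count < 1:
            raise ValueError("site_count must be >= 1")
        diameter = 2.0 * self.source_radius_vox
        if any(dim < diameter for dim in self.grid_shape):
            raise ValueError(
                f"grid {self.grid_shape} is degenerate: every dimension must "
                f"be at least one blob diameter ({diameter:.1f} voxels)"
            )


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom — the recovery oracle."""

    sources: np.ndarray  # (K, V) spatial sources, masked/vectorized
    loadings: np.ndarray  # (N, K) final loadings incl. planted effects
    phenotype: pd.DataFrame  # per-subject covariates + behavior scores
    brain_weights: np.ndarray  # (K,) planted canonical weights over sources
    behavior_weights: np.ndarray  # (Q,) planted canonical weights over scores
    planted_r: float  # population canonical correlation of the mode
    group_effect: tuple[tuple[int, float], ...]
    spec: PhantomSpec

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        spec_dict = asdict(self.spec)
        record = {
            "spec": spec_dict,
            "planted_mode": {
                "brain_weights": self.brain_weights.tolist(),
                "behavior_weights": self.behavior_weights.tolist(),
                "canonical_r": self.planted_r,
            },
            "group_effect": [list(ge) for ge in self.group_effect],
            "sources": self.sources.tolist(),
            "loadings": self.loadings.tolist(),
        }
        path.write_text(json.dumps(record))
        return path


def _gaussian_blob(grid_shape, center, sigma) -> np.ndarray:
    axes = [np.arange(n, dtype=float) for n in grid_shape]
    sq = 0.0
    for ax, c, grid_axis in zip(np.ix_(*axes), center, range(3)):
        sq = sq + (ax - c) ** 2
    return np.exp(-sq / (2.0 * sigma**2))


def _sample_sources(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """K smooth blobs with pairwise |spatial correlation| below the bound."""
    shape = spec.grid_shape
    sigma = spec.source_radius_vox
    margin = sigma  # keep blob peaks away from the box edge
    flat: list[np.ndarray] = []
    tries = 0
    while len(flat) < spec.n_sources:
        tries += 1
        if tries > 2000 * spec.n_sources:
            raise RuntimeError(
                "could not place non-overlapping sources; grid too small for "
                f"{spec.n_sources} blobs of sigma {sigma}"
            )
        center = [rng.uniform(margin, dim - 1 - margin) for dim in shape]
        cand = (spec.source_amplitude * _gaussian_blob(shape, center, sigma)).ravel()
        cc = cand - cand.mean()
        ok = True
        for prev in flat:
            pc = prev - prev.mean()
            r = float(pc @ cc / (np.linalg.norm(pc) * np.linalg.norm(cc)))
            if abs(r) >= spec.max_source_abs_corr:
                ok = False
                break
        if ok:
            flat.append(cand)
    return np.vstack(flat)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _sample_phenotype(spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_subjects
    n_aut = int(round(spec.autism_fraction * n))
    diagnosis = np.array(["autism"] * n_aut + ["td"] * (n - n_aut))
    # Table-1-like marginals: wide age range, male-skewed autism group,
    # slightly lower IQ in autism, ADHD comorbidity concentrated in autism.
    age = rng.uniform(6.0, 30.0, size=n)
    p_male = np.where(diagnosis == "autism", 0.729, 0.647)
    sex = np.where(rng.uniform(size=n) < p_male, "male", "female")
    fsiq = np.where(
        diagnosis == "autism",
        rng.normal(99.4, 18.9, size=n),
        rng.normal(104.9, 18.3, size=n),
    )
    site = np.array([f"site{j + 1:02d}" for j in rng.integers(spec.site_count, size=n)])
    p_adhd = np.where(diagnosis == "autism", 0.465, 0.104)
    adhd = (rng.uniform(size=n) < p_adhd).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "diagnosis": diagnosis,
            "age": age,
            "sex": sex,
            "fsiq": fsiq,
            "site": site,
            "adhd": adhd,
        }
    )


def generate_phantom(spec: PhantomSpec) -> tuple[GMDataset, PhantomTruth]:
    """Generate a phantom dataset and its ground-truth record.

    Loadings are unit-variance Laplace (super-Gaussian, so the mixture is
    identifiable by ICA), shifted by the planted group effect and tilted
    by the covariate slopes.  Maps are ``baseline + loadings @ sources +
    noise``, clipped at zero when ``clip_negative`` is set.  Behavior
    scores are generated from the designated loading subset so that the
    population canonical correlation with the loadings equals
    ``planted_r``.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, spec.n_sources

    sources = _sample_sources(spec, rng)  # (K, V)
    phenotype = _sample_phenotype(spec, rng)

    loadings = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n, k))  # unit variance
    is_aut = (phenotype["diagnosis"] == "autism").to_numpy()
    for idx, shift in spec.group_effect:
        loadings[is_aut, idx] += shift

    ce = spec.covariate_effects
    z_age = _standardize(phenotype["age"].to_numpy())
    z_iq = _standardize(phenotype["fsiq"].to_numpy())
    z_sex = _standardize((phenotype["sex"] == "male").to_numpy(float))
    site_codes = pd.Categorical(phenotype["site"]).codes
    site_offsets = rng.normal(0.0, 1.0, size=spec.site_count)
    z_site = _standardize(site_offsets[site_codes])
    covar_term = ce.age * z_age + ce.sex * z_sex + ce.iq * z_iq + ce.site * z_site
    loadings += covar_term[:, None]

    # Planted canonical mode: u = normalized combination of the designated
    # loadings; each behavior score is a*u + noise with a chosen so the
    # population first canonical correlation over all Q scores is planted_r.
    q = len(BEHAVIOR_COLUMNS)
    behavior_sources = (
        spec.behavior_sources
        if spec.behavior_sources is not None
        else tuple(range(max(0, k - 3), k))
    )
    w_brain = np.zeros(k)
    w_brain[list(behavior_sources)] = 1.0 / np.sqrt(len(behavior_sources))
    u = loadings @ w_brain
    u = _standardize(u)
    t = spec.planted_r**2 / (1.0 - spec.planted_r**2) if spec.planted_r < 1 else np.inf
    if np.isfinite(t):
        a = spec.behavior_noise_sd * np.sqrt(t / q)
        behavior = u[:, None] * a + rng.normal(
            0.0, spec.behavior_noise_sd, size=(n, q)
        )
        w_behavior = np.full(q, 1.0 / np.sqrt(q))
    else:
        behavior = np.tile(u[:, None], (1, q))
        w_behavior = np.full(q, 1.0 / np.sqrt(q))
    for j, col in enumerate(BEHAVIOR_COLUMNS):
        phenotype[col] = behavior[:, j]

    maps = spec.baseline + loadings @ sources
    if spec.noise_sd > 0:
        maps = maps + rng.normal(0.0, spec.noise_sd, size=maps.shape)
    if spec.clip_negative:
        np.clip(maps, 0.0, None, out=maps)

    mask = np.ones(spec.grid_shape, dtype=bool)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    dataset = GMDataset(
        data=maps,
        mask=mask,
        affine=affine,
        subject_ids=list(phenotype["subject_id"]),
    )
    truth = PhantomTruth(
        sources=sources,
        loadings=loadings,
        phenotype=phenotype,
        brain_weights=w_brain,
        behavior_weights=w_behavior,
        planted_r=spec.planted_r,
        group_effect=spec.group_effect,
        spec=spec,
    )
    return dataset, truth


def generate_missingness(
    table: pd.DataFrame,
    fraction: float,
    seed: int,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mask a fraction of behavior rows missing completely at random.

    ``floor(fraction * n)`` rows get NaN in the behavior columns (rounding
    toward completeness); diagnosis and covariates are never masked.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must satisfy 0 <= fraction < 1")
    out = table.copy()
    if fraction == 0:
        return out
    cols = [c for c in (columns or BEHAVIOR_COLUMNS) if c in out.columns]
    if set(cols) & set(COVARIATE_COLUMNS):
        raise ValueError("covariate columns cannot be masked")
    n = len(out)
    n_missing = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    rows = rng.choice(n, size=n_missing, replace=False)
    out.iloc[rows, [out.columns.get_loc(c) for c in cols]] = np.nan
    return out


def write_phantom(
    dataset: GMDataset, truth: PhantomTruth, outdir: str | Path, gzipped: bool = True
) -> dict:
    """Write maps, mask, phenotype TSV and truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    map_paths = dataset.write(outdir, gzipped=gzipped)
    pheno_path = outdir / "phenotype.tsv"
    truth.phenotype.to_csv(pheno_path, sep="\t", index=False)
    truth_path = truth.write(outdir / "truth.json")
    ext = ".nii.gz" if gzipped else ".nii"
    return {
        "maps": map_paths,
        "mask": outdir / f"mask{ext}",
        "phenotype": pheno_path,
        "truth": truth_path,
    }
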