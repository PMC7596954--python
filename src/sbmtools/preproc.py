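"""Smoothing and sample-homogeneity quality control for GM density maps.

Mirrors the minimal preprocessing applied to already-segmented,
already-registered VBM maps: isotropic Gaussian smoothing at a given
FWHM, and a homogeneity check flagging participants whose maps correlate
unusually poorly with the rest of the sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataset import GMDataset

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # = 2.3548...


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: np.ndarray) -> np.ndarray:
    """Per-axis Gaussian sigma in voxels for an isotropic FWHM in mm."""
    return float(fwhm_mm) / (FWHM_TO_SIGMA * np.asarray(voxel_size_mm, dtype=float))


def smooth_fwhm(dataset: GMDataset, fwhm_mm: float) -> GMDataset:
    """Smooth each subject's volume with an isotropic Gaussian kernel.

    sigma_vox = fwhm_mm / (2*sqrt(2 ln 2) * voxel_size).  Smoothing is
    applied to the unmasked volume with reflective boundary handling,
    then re-masked and re-vectorized.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return dataset.copy_with(dataset.data.copy())
    sigma = fwhm_to_sigma_vox(fwhm_mm, dataset.voxel_size_mm)
    out = np.empty_like(dataset.data)
    for i in range(dataset.n_subjects):
        vol = dataset.unmask(dataset.data[i])
        sm = ndimage.gaussian_filter(vol, sigma=sigma, mode="reflect")
        out[i] = sm[dataset.mask]
    return dataset.copy_with(out)


def homogeneity_qc(
    dataset: GMDataset,
    sd_mult: float = 3.0,
) -> pd.DataFrame:
    """Flag subjects whose mean correlation with the sample is an outlier.

    For each subject the mean Pearson correlation of their masked map
    with every other subject's map is computed; subjects falling below
    ``sample mean - sd_mult * sample sd`` are flagged.  Subjects with a
    constant (zero-variance) map have undefined correlations and are
    flagged distinctly (``note == 'zero-variance map'``).

    Returns a DataFrame with columns subject_id, mean_correlation,
    flagged, note.
    """
    n = dataset.n_subjects
    if n < 3:
        raise ValueError("homogeneity QC requires at least 3 subjects")
    X = dataset.data
    sds = X.std(axis=1)
    degenerate = sds == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    Z = Xc / safe[:, None]
    C = Z @ Z.T  # pairwise Pearson correlations
    np.fill_diagonal(C, np.nan)
    C[degenerate, :] = np.nan
    C[:, degenerate] = np.nan
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean_corr = np.nanmean(C, axis=1)
    mean_corr[degenerate] = np.nan
    valid = ~degenerate
    mu = float(np.mean(mean_corr[valid])) if valid.any() else np.nan
    sd = float(np.std(mean_corr[valid], ddof=1)) if valid.sum() > 1 else 0.0
    cutoff = mu - sd_mult * sd
    flagged = np.zeros(n, dtype=bool)
    flagged[valid] = mean_corr[valid] < cutoff
    flagged[degenerate] = True
    note = np.where(degenerate, "zero-variance map", "")
    return pd.DataFrame(
        {
            "subject_id": dataset.subject_ids,
            "mean_correlation": mean_corr,
            "flagged": flagged,
            "note": note,
        }
    )
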