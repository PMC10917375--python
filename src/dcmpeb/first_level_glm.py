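"""Event-related GLM, condition contrasts, and ROI definition/extraction.

This stage mirrors a standard task-fMRI first level: condition onsets
convolved with the canonical double-gamma hemodynamic response, run
intercepts and optional motion confounds, a discrete-cosine high-pass
basis (cutoff 128 s by default), ordinary-least-squares fitting, and a
NoGo > Go contrast.  ROI handling runs on small synthetic voxel grids:
an individual peak is located inside an atlas mask near a group peak,
and the region's summary signal is the first principal eigenvariate of
its voxel time series.  Whole-brain random-field inference is out of
scope; multiple comparisons on toy grids use Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GLMDesign",
    "ContrastResult",
    "ROIDefinition",
    "canonical_hrf",
    "cosine_basis",
    "build_design",
    "fit_contrast",
    "second_level_onesample",
    "second_level_twosample",
    "define_roi",
    "extract_timeseries",
]


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds."""
    try:
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf
        return spm_hrf(dt, oversampling=1, time_length=duration)
    except ImportError:  # pragma: no cover - nilearn is a hard dependency
        t = np.arange(0, duration, dt)
        peak = stats.gamma.pdf(t, 6)
        under = stats.gamma.pdf(t, 16)
        h = peak - under / 6.0
        return h / h.sum()


def cosine_basis(n_volumes: int, TR: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete cosine high-pass basis (constant term excluded).

    The number of columns is floor(2 * duration / cutoff) + 1, the
    standard drift-model order for the given cutoff period.
    """
    duration = n_volumes * TR
    order = int(np.floor(2.0 * duration / cutoff)) + 1
    t = (np.arange(n_volumes) + 0.5) / n_volumes
    return np.column_stack([np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * t)
                            for k in range(1, order + 1)])


@dataclass
class GLMDesign:
    """Design matrix for one session (possibly several concatenated runs)."""

    X: np.ndarray
    names: tuple
    condition_columns: dict      # condition name -> column index
    confound_columns: tuple
    TR: float
    high_pass_cutoff: float

    def __post_init__(self):
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient after filtering")

    def contrast_vector(self, positive, negative=()) -> np.ndarray:
        c = np.zeros(self.X.shape[1])
        for name in np.atleast_1d(positive):
            c[self.condition_columns[name]] = 1.0
        for name in np.atleast_1d(negative):
            c[self.condition_columns[name]] = -1.0
        return c


def build_design(events: pd.DataFrame, TR: float, n_volumes: int,
                 confounds: np.ndarray | None = None,
                 high_pass_cutoff: float = 128.0,
                 oversampling: int = 16) -> GLMDesign:
    """HRF-convolved condition regressors plus drift and confound columns.

    ``events`` needs columns ``onset`` (s), ``duration`` (s) and
    ``trial_type``; an optional ``run`` column splits the session into
    concatenated runs, each with its own intercept and cosine drift
    basis.  ``n_volumes`` is per run.  Confounds (e.g. six motion
    parameters) are appended as given.
    """
    events = events.copy()
    if "run" not in events:
        events["run"] = 0
    runs = sorted(events["run"].unique())
    n_runs = len(runs)
    conditions = sorted(events["trial_type"].unique())
    dt = TR / oversampling
    n_micro = n_volumes * oversampling
    hrf = canonical_hrf(dt)

    total = n_runs * n_volumes
    cond_cols = {}
    cols, names = [], []
    for c in conditions:
        reg = np.zeros(total)
        for ri, run in enumerate(runs):
            sel = events[(events.trial_type == c) & (events.run == run)]
            u = np.zeros(n_micro)
            for onset, dur in zip(sel["onset"], sel["duration"]):
                i0 = int(round(onset / dt))
                if not 0 <= i0 < n_micro:
                    raise ValueError(f"event onset {onset} s outside the scan")
                i1 = max(i0 + 1, int(round((onset + dur) / dt)))
                u[i0:i1] = 1.0
            conv = np.convolve(u, hrf)[:n_micro]
            reg[ri * n_volumes:(ri + 1) * n_volumes] = conv[::oversampling]
        cond_cols[c] = len(cols)
        cols.append(reg)
        names.append(c)

    confound_idx = []
    for ri, run in enumerate(runs):
        drift = cosine_basis(n_volumes, TR, high_pass_cutoff)
        for k in range(drift.shape[1]):
            col = np.zeros(total)
            col[ri * n_volumes:(ri + 1) * n_volumes] = drift[:, k]
            confound_idx.append(len(cols))
            cols.append(col)
            names.append(f"drift_run{run}_{k + 1}")
        inter = np.zeros(total)
        inter[ri * n_volumes:(ri + 1) * n_volumes] = 1.0
        confound_idx.append(len(cols))
        cols.append(inter)
        names.append(f"intercept_run{run}")
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != total:
            raise ValueError("confound rows must match total volumes")
        for k in range(confounds.shape[1]):
            confound_idx.append(len(cols))
            cols.append(confounds[:, k])
            names.append(f"confound_{k + 1}")

    return GLMDesign(np.column_stack(cols), tuple(names), cond_cols,
                     tuple(confound_idx), TR, high_pass_cutoff)


@dataclass
class ContrastResult:
    """Per-series contrast estimates with t statistics.

    ``peak_table`` lists the series (voxels) ordered by decreasing t;
    coordinates are 0-based voxel indices when a grid shape is given.
    """

    effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    dof: int
    degenerate: np.ndarray
    peak_table: pd.DataFrame


def fit_contrast(data: np.ndarray, design: GLMDesign,
                 contrast: np.ndarray,
                 grid_shape: tuple | None = None) -> ContrastResult:
    """Ordinary least squares per series with a t test on ``contrast``.

    ``data`` is volumes x series.  Series with (numerically) zero
    residual variance are flagged degenerate rather than reported with
    an unbounded t.  Two-sided p values.
    """
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError("data volumes do not match design rows")
    c = np.asarray(contrast, dtype=float)
    if c.shape != (X.shape[1],):
        raise ValueError("contrast length must match design columns")
    if np.all(c == 0):
        raise ValueError("degenerate contrast: all weights zero")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    effect = c @ beta
    var_c = float(c @ XtX_inv @ c)
    scale = np.max(np.abs(Y), axis=0) + 1.0
    degenerate = sigma2 <= (1e-12 * scale) ** 2
    se = np.sqrt(np.maximum(sigma2, 1e-300) * var_c)
    t = np.where(degenerate, np.inf * np.sign(effect), effect / se)
    p = np.where(degenerate, 0.0, 2.0 * stats.t.sf(np.abs(t), dof))

    order = np.argsort(-t)
    table = {"series": order, "t": t[order], "effect": effect[order],
             "p": p[order]}
    if grid_shape is not None:
        coords = np.array(np.unravel_index(order, grid_shape)).T
        for d in range(coords.shape[1]):
            table[f"i{d}"] = coords[:, d]
    return ContrastResult(effect=effect, t=t, p=p, dof=int(dof),
                          degenerate=degenerate,
                          peak_table=pd.DataFrame(table))


def second_level_onesample(contrast_maps: np.ndarray):
    """One-sample t-test over subjects (rows) per voxel/series."""
    return stats.ttest_1samp(np.atleast_2d(contrast_maps), 0.0, axis=0)


def second_level_twosample(maps_a: np.ndarray, maps_b: np.ndarray):
    """Two-sample t-test (e.g. sex difference) per voxel/series."""
    return stats.ttest_ind(np.atleast_2d(maps_a), np.atleast_2d(maps_b),
                           axis=0)


@dataclass
class ROIDefinition:
    """An individual-specific region of interest on a voxel grid."""

    label: str
    mask_id: str
    group_peak: tuple
    individual_peak: tuple
    radius: float
    voxels: np.ndarray           # (n_voxels, ndim) indices inside the ROI
    fallback_to_group: bool = False
    extraction: str = "first_eigenvariate"


def define_roi(stat_map: np.ndarray, atlas_mask: np.ndarray,
               group_peak: tuple, radius: float = 2.0,
               label: str = "", mask_id: str = "",
               threshold: float | None = None) -> ROIDefinition:
    """Locate an individual activation peak near the group peak.

    The individual peak is the argmax of the statistic inside
    ``atlas_mask`` intersected with a sphere of ``radius`` voxels around
    ``group_peak``; exact ties resolve to the lexicographically smallest
    coordinate.  If a ``threshold`` is given and no voxel exceeds it,
    the group peak is used and flagged.
    """
    mask = np.asarray(atlas_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty atlas mask")
    stat = np.asarray(stat_map, dtype=float)
    if stat.shape != mask.shape:
        raise ValueError("stat map and mask shapes differ")
    coords = np.argwhere(mask)
    d2 = np.sum((coords - np.asarray(group_peak)) ** 2, axis=1)
    inside = coords[d2 <= radius ** 2]
    if inside.size == 0:
        inside = coords[[int(np.argmin(d2))]]
    values = stat[tuple(inside.T)]
    fallback = False
    if threshold is not None and not np.any(values > threshold):
        peak = tuple(int(v) for v in group_peak)
        fallback = True
    else:
        best = values.max()
        ties = inside[values == best]
        ties = ties[np.lexsort(ties.T[::-1])]
        peak = tuple(int(v) for v in ties[0])
    d2p = np.sum((coords - np.asarray(peak)) ** 2, axis=1)
    roi_voxels = coords[d2p <= radius ** 2]
    return ROIDefinition(label=label, mask_id=mask_id,
                         group_peak=tuple(group_peak),
                         individual_peak=peak, radius=radius,
                         voxels=roi_voxels, fallback_to_group=fallback)


def extract_timeseries(voxel_data: np.ndarray) -> np.ndarray:
    """First principal eigenvariate of a (volumes x voxels) matrix.

    The component is scaled by its singular value over sqrt(n_voxels)
    (preserving mean amplitude) and sign-aligned with the ROI mean
    signal.  Constant (zero-variance) data is rejected.
    """
    Y = np.atleast_2d(np.asarray(voxel_data, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.allclose(Y.std(axis=0), 0.0):
        raise ValueError("constant ROI data: zero-variance signal")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    y = U[:, 0] * s[0] / np.sqrt(Y.shape[1])
    mean = Y.mean(axis=1)
    if np.dot(y, mean) < 0:
        y = -y
    return y


def load_nifti_roi(data_path, mask_path) -> np.ndarray:
    """Voxel time series (volumes x voxels) from a 4-D NIfTI plus a
    binary mask volume — convenience entry point for real ROI data."""
    import nibabel as nib

    img = nib.load(str(data_path))
    mask = nib.load(str(mask_path)).get_fdata() > 0
    data = img.get_fdata()
    return data[mask].T
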