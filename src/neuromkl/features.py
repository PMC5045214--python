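"""Regional feature channels from volumetric data.

Four per-subject feature vectors are computed on an atlas parcellation:

* **ALFF** - amplitude of low-frequency fluctuations: the mean in-band
  (default 0.01-0.08 Hz) amplitude-spectrum value of each voxel's time
  series, scaled by the subject's global mean and averaged per ROI.
* **ReHo** - regional homogeneity: Kendall's coefficient of concordance
  W of each voxel with its 3x3x3 neighbourhood, scaled by the global
  mean and averaged per ROI.
* **RFCS** - regional functional correlation strength: the mean absolute
  Pearson correlation of an ROI's mean time series with every other
  ROI's, S(i) = (1/(N-1)) * sum_{j != i} |R_ij|.
* **GM** - regional mean of the structural (gray-matter) map.

All temporal operations assume time on the last axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .atlas import AtlasParcellation
from .synthetic import CHANNELS, Cohort


class DegenerateMapError(ValueError):
    """Raised when a map's global mean is zero and cannot be scaled."""


class EmptyRegionError(ValueError):
    """Raised when an atlas ROI contains no voxels of the data grid."""


@dataclass(frozen=True)
class VoxelMap:
    """A 3-D scalar map with a validity mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside the mask")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N Pearson correlation matrix over ROIs."""

    r: np.ndarray
    roi_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        n = len(self.roi_ids)
        if r.shape != (n, n):
            raise ValueError("matrix shape inconsistent with roi_ids")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(r)) > 1.0 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x ROIs feature matrix for one channel."""

    matrix: np.ndarray
    channel: str
    roi_ids: tuple[int, ...]
    subject_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.subject_ids), len(self.roi_ids)):
            raise ValueError("matrix shape inconsistent with ids")
        if not np.all(np.isfinite(m)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.labels) != len(self.subject_ids):
            raise ValueError("labels and subject_ids lengths differ")
        object.__setattr__(self, "matrix", m)

    @property
    def y(self) -> np.ndarray:
        """Numeric class coding: patient = -1, control = +1."""
        return np.array([-1 if l == "patient" else 1 for l in self.labels])


def bandpass(ts: np.ndarray, tr: float, low: float, high: float) -> np.ndarray:
    """Ideal (DFT-mask) band-pass filter along the last axis.

    The series is demeaned and frequency bins outside ``[low, high]`` Hz
    are zeroed, giving exact band edges with no filter-order choice.
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[-1]
    if T < 8:
        raise ValueError("need at least 8 time points to band-pass")
    nyq = 0.5 / tr
    if not (0.0 <= low < high):
        raise ValueError(f"invalid band ({low}, {high})")
    if high > nyq + 1e-12:
        raise ValueError(f"band upper edge {high} Hz exceeds Nyquist {nyq} Hz")
    spec = np.fft.rfft(ts, axis=-1)
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=-1)


def compute_alff(functional: np.ndarray, tr: float,
                 band: tuple[float, float] = (0.01, 0.08),
                 mask: np.ndarray | None = None) -> VoxelMap:
    """Per-voxel mean in-band amplitude-spectrum value.

    With the one-sided amplitude spectrum A_k = 2|X_k|/T of the demeaned
    series, ALFF is the mean of A_k over bins whose frequency lies inside
    ``band``.  Nonnegative, and linear: scaling a series by c > 0 scales
    its ALFF by c.  A constant series has ALFF 0.
    """
    functional = np.asarray(functional, dtype=float)
    T = functional.shape[-1]
    if T < 32:
        raise ValueError("need at least 32 time points for ALFF")
    low, high = band
    nyq = 0.5 / tr
    if not (0.0 <= low < high <= nyq + 1e-12):
        raise ValueError(f"invalid band {band} for TR={tr}")
    if mask is None:
        mask = np.ones(functional.shape[:-1], dtype=bool)
    data = functional[mask] - functional[mask].mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(data, axis=-1))
    freqs = np.fft.rfftfreq(T, d=tr)
    inband = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not inband.any():
        raise ValueError("no frequency bins inside the band")
    alff = (2.0 / T) * spec[:, inband].mean(axis=-1)
    values = np.zeros(functional.shape[:-1])
    values[mask] = alff
    return VoxelMap(values=values, mask=mask)


def global_mean_scale(vmap: VoxelMap) -> VoxelMap:
    """Divide a map by its global (within-mask) mean; output mean is 1."""
    gmean = vmap.values[vmap.mask].mean()
    if abs(gmean) < 1e-300:
        raise DegenerateMapError("global mean is zero; cannot scale map")
    values = np.zeros_like(vmap.values)
    values[vmap.mask] = vmap.values[vmap.mask] / gmean
    return VoxelMap(values=values, mask=vmap.mask)


_NEIGHBOURHOODS = {7: 1, 19: 2, 27: 3}


def _neighbourhood_offsets(size: int) -> np.ndarray:
    if size not in _NEIGHBOURHOODS:
        raise ValueError(f"neighbourhood must be one of {sorted(_NEIGHBOURHOODS)}")
    max_manhattan = _NEIGHBOURHOODS[size]
    offs = [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if abs(dx) + abs(dy) + abs(dz) <= max_manhattan]
    assert len(offs) == size
    return np.array(offs)


def compute_reho(functional: np.ndarray, mask: np.ndarray | None = None,
                 neighborhood: int = 27) -> VoxelMap:
    """Kendall's coefficient of concordance over voxel neighbourhoods.

    For each voxel whose full K-voxel neighbourhood lies inside the
    volume (and mask), W = 12 * sum_t (R_t - Rbar)^2 / (K^2 (T^3 - T)),
    where R_t is the sum over the K series of the within-series rank of
    time point t (midranks for ties).  W is in [0, 1]; voxels lacking a
    full neighbourhood, or whose neighbourhood is entirely constant, are
    excluded from the output mask.
    """
    functional = np.asarray(functional, dtype=float)
    if functional.ndim != 4:
        raise ValueError("functional must be 4-D (x, y, z, t)")
    shape, T = functional.shape[:-1], functional.shape[-1]
    if T < 8:
        raise ValueError("need at least 8 time points for ReHo")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    offsets = _neighbourhood_offsets(neighborhood)
    K = len(offsets)

    ranks = stats.rankdata(functional, axis=-1, method="average")
    constant = functional.std(axis=-1) == 0

    rank_sum = np.zeros(shape + (T,))
    valid = np.ones(shape, dtype=bool)
    n_const = np.zeros(shape, dtype=int)
    for dx, dy, dz in offsets:
        shifted = np.full(shape + (T,), np.nan)
        sc = np.full(shape, True)
        cc = np.full(shape, True)
        src = tuple(slice(max(0, -d), min(s, s - d)) for d, s in zip((dx, dy, dz), shape))
        dst = tuple(slice(max(0, d), min(s, s + d)) for d, s in zip((dx, dy, dz), shape))
        shifted[dst] = ranks[src]
        sc[dst] = ~mask[src]
        cc[dst] = constant[src]
        rank_sum += np.nan_to_num(shifted)
        valid &= ~sc & ~np.isnan(shifted[..., 0])
        n_const += np.where(cc, 1, 0)
    valid &= mask
    all_const = valid & (n_const == K)
    if all_const.any():
        warnings.warn("ReHo undefined for fully constant neighbourhoods; masked out",
                      stacklevel=2)
        valid &= ~all_const

    rbar = K * (T + 1) / 2.0
    ss = ((rank_sum - rbar) ** 2).sum(axis=-1)
    w = 12.0 * ss / (K ** 2 * (T ** 3 - T))
    values = np.zeros(shape)
    values[valid] = w[valid]
    if not valid.any():
        raise ValueError("no voxel has a full in-mask neighbourhood")
    return VoxelMap(values=values, mask=valid)


def regress_nuisance(ts_matrix: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS-residualize each row series against covariate series.

    ``ts_matrix`` is (n_series, T) and ``covariates`` (n_cov, T); an
    intercept is always included.  Residuals are orthogonal to every
    covariate.
    """
    Y = np.atleast_2d(np.asarray(ts_matrix, dtype=float))
    Cv = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Y.shape[-1] != Cv.shape[-1]:
        raise ValueError("series and covariates differ in length")
    X = np.column_stack([np.ones(Cv.shape[-1]), Cv.T])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient (with intercept)")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def roi_timeseries(functional: np.ndarray, atlas: AtlasParcellation) -> np.ndarray:
    """N x T matrix of voxel-average time series per ROI (roi_ids order)."""
    functional = np.asarray(functional, dtype=float)
    if functional.shape[:-1] != atlas.shape:
        raise ValueError("functional grid does not match the atlas")
    out = np.empty((atlas.n_rois, functional.shape[-1]))
    for i, rid in enumerate(atlas.roi_ids):
        vox = atlas.roi_mask(rid)
        if not vox.any():
            raise EmptyRegionError(f"ROI {rid} has no voxels on this grid")
        out[i] = functional[vox].mean(axis=0)
    return out


def connectivity(roi_ts: np.ndarray, roi_ids: tuple[int, ...]) -> ConnectivityMatrix:
    """Pearson correlation matrix between all ROI mean time series."""
    sds = roi_ts.std(axis=-1)
    if np.any(sds == 0):
        bad = [roi_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant ROI time series (ROIs {bad}); correlation undefined")
    r = np.corrcoef(roi_ts)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r=r, roi_ids=tuple(roi_ids))


def compute_rfcs(conn: ConnectivityMatrix) -> np.ndarray:
    """S(i) = mean absolute off-diagonal correlation of ROI i."""
    n = len(conn.roi_ids)
    if n < 2:
        raise ValueError("RFCS undefined for fewer than 2 ROIs")
    a = np.abs(conn.r)
    return (a.sum(axis=1) - np.diag(a)) / (n - 1)


def regional_means(vmap: VoxelMap, atlas: AtlasParcellation) -> np.ndarray:
    """Mean map value over each ROI's in-mask voxels; NaN if fully masked."""
    if vmap.values.shape != atlas.shape:
        raise ValueError("map grid does not match the atlas")
    out = np.empty(atlas.n_rois)
    for i, rid in enumerate(atlas.roi_ids):
        vox = atlas.roi_mask(rid) & vmap.mask
        out[i] = vmap.values[vox].mean() if vox.any() else np.nan
    return out


def gaussian_smooth(volume: np.ndarray, fwhm_vox: float) -> np.ndarray:
    """Isotropic Gaussian smoothing with FWHM given in voxels."""
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings: band edges in Hz, optional smoothing (voxels),
    and optional per-subject nuisance covariates (n_cov x T arrays)."""

    band: tuple[float, float] = (0.01, 0.08)
    smooth_fwhm_vox: float | None = None
    gm_smooth_fwhm_vox: float | None = None
    reho_neighborhood: int = 27
    nuisance: dict[str, np.ndarray] | None = None


def extract_features(cohort: Cohort, atlas: AtlasParcellation | None = None,
                     config: FeatureConfig | None = None) -> dict[str, FeatureTable]:
    """Compute the four regional feature tables for a cohort.

    Pipeline per subject: band-pass -> ALFF map -> global-mean scale ->
    regional means; band-pass -> ReHo map -> global-mean scale ->
    regional means; band-pass (+ nuisance regression) -> ROI series ->
    correlation -> RFCS; structural map -> regional means.  ROIs whose
    ReHo regional mean is undefined for any subject (no interior voxel)
    are dropped from the ReHo table only.
    """
    if atlas is None:
        atlas = cohort.atlas
    if config is None:
        config = FeatureConfig()
    cfg = cohort.config
    rows: dict[str, list[np.ndarray]] = {ch: [] for ch in CHANNELS}
    for subj in cohort.subjects:
        func = subj.functional
        if config.smooth_fwhm_vox:
            func = np.stack([gaussian_smooth(func[..., t], config.smooth_fwhm_vox)
                             for t in range(func.shape[-1])], axis=-1)
        filt = bandpass(func, cfg.tr, *config.band)

        alff = global_mean_scale(compute_alff(func, cfg.tr, config.band))
        rows["ALFF"].append(regional_means(alff, atlas))

        reho = global_mean_scale(compute_reho(filt, neighborhood=config.reho_neighborhood))
        rows["ReHo"].append(regional_means(reho, atlas))

        ts = roi_timeseries(filt, atlas)
        if config.nuisance and subj.subject_id in config.nuisance:
            ts = regress_nuisance(ts, config.nuisance[subj.subject_id])
        rows["RFCS"].append(compute_rfcs(connectivity(ts, atlas.roi_ids)))

        struct = subj.structural
        if config.gm_smooth_fwhm_vox:
            struct = gaussian_smooth(struct, config.gm_smooth_fwhm_vox)
        gm_map = VoxelMap(values=np.asarray(struct, dtype=float),
                          mask=atlas.brain_mask())
        rows["GM"].append(regional_means(gm_map, atlas))

    tables = {}
    for ch in CHANNELS:
        mat = np.vstack(rows[ch])
        keep = np.all(np.isfinite(mat), axis=0)
        if not keep.all():
            dropped = [atlas.roi_ids[i] for i in np.flatnonzero(~keep)]
            warnings.warn(f"{ch}: dropping ROIs without valid voxels: {dropped[:8]}"
                          f"{'...' if len(dropped) > 8 else ''}", stacklevel=2)
        tables[ch] = FeatureTable(
            matrix=mat[:, keep], channel=ch,
            roi_ids=tuple(atlas.roi_ids[i] for i in np.flatnonzero(keep)),
            subject_ids=tuple(cohort.subject_ids), labels=tuple(cohort.labels))
    return tables
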