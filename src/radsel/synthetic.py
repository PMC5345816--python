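"""Synthetic inputs: PET-like tumor phantoms and cohort feature tables.

The phantom generator produces an ellipsoidal lesion on a scanner-like
grid (default voxels 4 x 4 x 2 mm): a uniform base uptake plus a
spatially correlated Gaussian heterogeneity field, smoothed with a
Gaussian kernel matching the scanner's reconstruction filter (default
5 mm FWHM) and clipped at zero. The smoothing is applied to the
heterogeneity component only, so the mask boundary stays crisp and a
zero-amplitude phantom is genuinely uniform; reconstruction physics
(Poisson sinogram noise, edge spill-over) is deliberately not modeled.

The cohort generator emulates the study population the selection and
evaluation stages expect: 65 patients, 61 features drawn from a
multivariate normal with block-constant within-block correlation
(features inside a block are redundant, blocks are mutually
independent), a binary response label at 63%/37% prevalence with
class-conditional mean shifts on the informative features, and
exponential survival times whose log-hazard is linear in standardized
features, with independent uniform censoring calibrated to a target
censoring fraction. The default block preset mirrors the 9-group
redundancy structure reported for the original 65-patient cohort,
leaving 28 of 61 features uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ParameterError
from .io import BinaryMask, FeatureTable, SUVolume
from .names import ALL_FEATURES

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: block sizes of the default cohort preset: 9 correlated groups covering 42
#: of 61 features, leaving 19 singletons -> 9 + 19 = 28 uncorrelated.
DEFAULT_BLOCK_SIZES = (2, 3, 2, 2, 2, 4, 12, 12, 3)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture of a synthetic ellipsoidal lesion."""

    semi_axes: tuple[float, float, float] = (15.0, 15.0, 20.0)  # mm
    base_suv: float = 8.0
    heterogeneity: float = 2.0  # SUV amplitude of the correlated field
    correlation_length: float = 6.0  # mm
    background_suv: float = 1.0
    spacing: tuple[float, float, float] = (4.0, 4.0, 2.0)  # mm
    smoothing_fwhm: float = 5.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ParameterError("semi-axes must be positive")
        if not self.base_suv > self.background_suv >= 0:
            raise ParameterError("need base SUV > background SUV >= 0")
        if self.heterogeneity < 0 or self.correlation_length <= 0:
            raise ParameterError("invalid heterogeneity parameters")


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic patient cohort."""

    n_patients: int = 65
    n_features: int = 61
    blocks: tuple[tuple[int, float], ...] = tuple(
        (s, 0.95) for s in DEFAULT_BLOCK_SIZES
    )
    informative: tuple[tuple[str, float], ...] = ()  # (feature, shift in SD)
    prevalence: float = 0.63
    baseline_median_months: float = 23.0
    hazard_coefficients: tuple[tuple[str, float], ...] = ()  # (feature, log HR / SD)
    censoring_fraction: float = 0.37
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(s for s, _ in self.blocks) > self.n_features:
            raise ConfigurationError("block sizes exceed the feature count")
        if any(s < 2 or not -1 < r < 1 for s, r in self.blocks):
            raise ConfigurationError("blocks need size >= 2 and |rho| < 1")
        if not 0 < self.prevalence < 1:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if not 0 <= self.censoring_fraction < 1:
            raise ConfigurationError("censoring fraction must be in [0, 1)")

    def feature_names(self) -> list[str]:
        if self.n_features == len(ALL_FEATURES):
            return list(ALL_FEATURES)
        return [f"f{k:03d}" for k in range(1, self.n_features + 1)]

    def block_members(self) -> list[list[str]]:
        """Feature names of each correlated block, assigned in order."""
        names = self.feature_names()
        out, start = [], 0
        for size, _ in self.blocks:
            out.append(names[start:start + size])
            start += size
        return out


def make_phantom(spec: PhantomSpec) -> tuple[SUVolume, BinaryMask]:
    """Generate an ellipsoidal SUV phantom and its binary mask."""
    spacing = spec.spacing
    # grid with a 1.5x margin around the ellipsoid
    half_extent = [1.5 * a for a in spec.semi_axes]
    shape = tuple(
        max(3, int(np.ceil(2 * h / s)) | 1) for h, s in zip(half_extent, spacing)
    )
    coords = np.indices(shape).astype(float)
    for ax in range(3):
        coords[ax] = (coords[ax] - (shape[ax] - 1) / 2.0) * spacing[ax]
    r2 = sum(
        (coords[ax] / spec.semi_axes[ax]) ** 2 for ax in range(3)
    )
    mask = r2 <= 1.0
    if mask.sum() < 2:
        raise ParameterError("semi-axes smaller than one voxel: degenerate phantom")

    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(shape)
    sigma_corr = [spec.correlation_length * FWHM_TO_SIGMA / s for s in spacing]
    fieldv = ndimage.gaussian_filter(noise, sigma_corr)
    sd = fieldv.std()
    if sd > 0:
        fieldv /= sd  # unit-variance correlated field
    sigma_rec = [spec.smoothing_fwhm * FWHM_TO_SIGMA / s for s in spacing]
    texture = ndimage.gaussian_filter(spec.heterogeneity * fieldv, sigma_rec)

    values = np.where(mask, spec.base_suv + texture, spec.background_suv)
    values = np.clip(values, 0.0, None)
    return SUVolume(values, spacing), BinaryMask(mask, spacing)


def _block_correlation(spec: CohortSpec) -> np.ndarray:
    corr = np.eye(spec.n_features)
    start = 0
    for size, rho in spec.blocks:
        corr[start:start + size, start:start + size] = rho
        np.fill_diagonal(corr[start:start + size, start:start + size], 1.0)
        start += size
    return corr


def _calibrate_censoring(times: np.ndarray, fraction: float) -> float:
    """Upper bound b of Uniform(0, b) censoring hitting the target fraction.

    Solves mean(min(t_i / b, 1)) = fraction on the drawn event times by
    bisection; the expected censored share under C ~ U(0, b) given T = t
    is P(C < t) = min(t/b, 1).
    """
    lo, hi = 1e-9, float(times.max()) * 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        cens = float(np.mean(np.minimum(times / mid, 1.0)))
        if cens > fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw a cohort feature table with response and survival outcomes."""
    rng = np.random.default_rng(spec.seed)
    names = spec.feature_names()
    name_set = set(names)
    for feat, _ in tuple(spec.informative) + tuple(spec.hazard_coefficients):
        if feat not in name_set:
            raise ConfigurationError(f"unknown feature in spec: {feat!r}")

    chol = np.linalg.cholesky(_block_correlation(spec))
    z = rng.standard_normal((spec.n_patients, spec.n_features)) @ chol.T

    response = (rng.random(spec.n_patients) < spec.prevalence).astype(float)
    col = {n: k for k, n in enumerate(names)}
    values = z.copy()
    for feat, shift in spec.informative:
        values[:, col[feat]] += shift * response

    # survival: exponential with log-hazard linear in the standardized draws
    lam0 = np.log(2.0) / spec.baseline_median_months
    log_hr = np.zeros(spec.n_patients)
    for feat, beta in spec.hazard_coefficients:
        log_hr += beta * z[:, col[feat]]
    hazard = lam0 * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_fraction > 0:
        b = _calibrate_censoring(t_event, spec.censoring_fraction)
        c = rng.uniform(0.0, b, spec.n_patients)
        event = (t_event <= c).astype(float)
        time = np.minimum(t_event, c)
    else:
        event = np.ones(spec.n_patients)
        time = t_event

    return FeatureTable(
        patient_ids=[f"P{k:03d}" for k in range(1, spec.n_patients + 1)],
        feature_names=names,
        values=values,
        response=response,
        time=time,
        event=event,
    )
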