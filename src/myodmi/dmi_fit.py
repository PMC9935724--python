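"""Per-voxel compartment-fraction estimation from two-shell DWI.

The three fractions (``v_intra``, ``v_extra``, ``v_iso``) are
orientation-invariant, so estimation works on *spherical means*: the average
signal over gradient directions at fixed b, which for each compartment equals
a closed-form kernel independent of fiber orientation and dispersion. With a
b0 volume and two diffusion shells the normalized shell means give two
equations; with the sum-to-one constraint the three fractions are exactly
determined, which yields a deterministic linear oracle
(:func:`fit_fractions_linear`).

The production estimator (:func:`fit_fractions_bayes`) is a simulated-prior
Bayesian posterior-mean regression: draw parameter sets from the prior
(fractions uniform on the simplex, orientations uniform on the sphere),
simulate their signals on the actual acquisition scheme with matched Rician
noise, reduce to shell-mean features, and fit a polynomial least-squares
regression from features to true fractions. Least squares onto the simulated
prior approximates the posterior mean under that prior, and training on noisy
magnitudes lets the estimator absorb the Rician bias instead of correcting it
analytically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from scipy.special import erf

from .errors import ConfigurationError, DegenerateModelError, ValidationError
from .io_formats import AcquisitionScheme, DWIStack
from .model import (
    TissueParams,
    add_rician,
    mixture_signal,
    project_simplex,
    sample_simplex,
    sample_sphere,
)

#: voxels whose mean b0 signal falls below this multiple of the estimated
#: noise sigma are treated as background and excluded from the valid mask
BACKGROUND_SIGMA_FACTOR = 5.0


@dataclass
class ShellMeans:
    """Spherical-mean reduction of a batch of voxel signals.

    ``m0`` is the mean b0 signal; ``m`` holds, per nonzero shell (ascending
    b), the direction-averaged signal divided by ``m0``. Voxels with
    ``m0 <= 0`` are flagged invalid rather than raising. Normalized means
    slightly above 1 can occur under noise and are tolerated up to 1.5.
    """

    shells: np.ndarray  # (k,)
    m0: np.ndarray  # (...,)
    m: np.ndarray  # (..., k)
    valid: np.ndarray  # (...,) bool


@dataclass(frozen=True)
class PriorConfig:
    """Configuration of the simulated-prior regression.

    ``n_samples`` draws from the prior (floor 10,000), polynomial feature
    ``degree`` (with interaction terms), and training ``snr`` — the b0
    signal-to-noise ratio at which Rician noise is applied to the simulated
    training signals; ``None`` trains noiseless.
    """

    n_samples: int = 100_000
    degree: int = 3
    snr: float | None = 40.0

    def __post_init__(self) -> None:
        if self.n_samples < 10_000:
            raise ConfigurationError(
                f"n_samples={self.n_samples} below the 10,000 floor; the "
                "regression needs a dense prior sample"
            )
        if self.degree < 1:
            raise ConfigurationError("polynomial degree must be >= 1")
        if self.snr is not None and not self.snr > 0:
            raise ConfigurationError("snr must be positive or None")


@dataclass
class CompartmentMap:
    """Per-voxel volume-fraction maps on the unit simplex."""

    v_intra: np.ndarray
    v_extra: np.ndarray
    v_iso: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("v_intra", "v_extra", "v_iso"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            vals = arr[self.valid_mask]
            if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
                raise ValidationError(f"{name} outside [0, 1] at valid voxels")
        total = (self.v_intra + self.v_extra + self.v_iso)[self.valid_mask]
        if total.size and np.max(np.abs(total - 1.0)) > 1e-6:
            raise ValidationError("fractions do not sum to 1 at valid voxels")

    def stacked(self) -> np.ndarray:
        """(..., 3) view in (v_intra, v_extra, v_iso) order."""
        return np.stack([self.v_intra, self.v_extra, self.v_iso], axis=-1)


def shell_spherical_mean(signals, scheme: AcquisitionScheme) -> ShellMeans:
    """Direction-average signals per shell, normalized by the b0 mean.

    ``signals`` may be a single voxel ``(n_vol,)`` or a batch ``(..., n_vol)``.
    Requires at least one b0 volume and >= 6 directions per nonzero shell.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != len(scheme):
        raise ValidationError(
            f"signal length {signals.shape[-1]} does not match scheme "
            f"length {len(scheme)}"
        )
    shells = scheme.shells
    if shells.size == 0:
        raise ValidationError("scheme has no nonzero shell")
    for b in shells:
        if np.sum(scheme.shell_mask(b)) < 6:
            raise ValidationError(
                f"shell b={b:g} has fewer than 6 directions; spherical means "
                "would be orientation-biased"
            )
    m0 = signals[..., scheme.b0_mask].mean(axis=-1)
    valid = m0 > 0
    safe_m0 = np.where(valid, m0, 1.0)
    m = np.stack(
        [signals[..., scheme.shell_mask(b)].mean(axis=-1) / safe_m0 for b in shells],
        axis=-1,
    )
    m = np.where(valid[..., None], m, np.nan)
    return ShellMeans(shells=shells, m0=m0, m=m, valid=valid)


def forward_shell_means(fractions, tissue: TissueParams, shells) -> ShellMeans:
    """Model-implied shell means for given fractions (the exact quadrature
    limit): ``m_b = v . K(b)``. Useful as the noiseless input of the linear
    oracle, which then inverts it exactly."""
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    shells = np.asarray(shells, dtype=float)
    K = np.stack(kernel_spherical_means(tissue, shells), axis=-1)  # (k, 3)
    m = fractions @ K.T
    m0 = np.ones(fractions.shape[:-1])
    return ShellMeans(shells=shells, m0=m0, m=m, valid=np.ones_like(m0, dtype=bool))


def _sqrtpi_erf_term(x: np.ndarray) -> np.ndarray:
    """sqrt(pi/(4x)) * erf(sqrt(x)), with the x -> 0 limit of 1.

    This is the orientation average of exp(-x cos^2 theta) over the sphere.
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x > 0
    sx = np.sqrt(x[nz])
    out[nz] = np.sqrt(np.pi) / (2.0 * sx) * erf(sx)
    return out


def kernel_spherical_means(tissue: TissueParams, b) -> tuple:
    """Closed-form spherical-mean kernels (K_intra, K_extra, K_iso) at b.

    K_intra(b)  = sqrt(pi/(4 b D_a)) erf(sqrt(b D_a))
    K_extra(b)  = exp(-b D_r) sqrt(pi/(4 b (D_a-D_r))) erf(sqrt(b (D_a-D_r)))
    K_iso(b)    = exp(-b D_iso)

    All three equal 1 at b = 0 (handled analytically). Accepts scalar or
    array b (s/mm^2).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValidationError("b must be >= 0")
    k_intra = _sqrtpi_erf_term(b * tissue.d_a)
    k_extra = np.exp(-b * tissue.d_r) * _sqrtpi_erf_term(b * (tissue.d_a - tissue.d_r))
    k_iso = np.exp(-b * tissue.d_iso)
    if b.ndim == 0:
        return float(k_intra), float(k_extra), float(k_iso)
    return k_intra, k_extra, k_iso


def kernel_matrix(tissue: TissueParams, shells) -> np.ndarray:
    """(k+1, 3) system matrix: one kernel row per shell plus the sum row."""
    shells = np.asarray(shells, dtype=float)
    rows = np.stack(kernel_spherical_means(tissue, shells), axis=-1)
    return np.vstack([rows, np.ones(3)])


def fit_fractions_linear(
    means: ShellMeans,
    tissue: TissueParams,
    cond_threshold: float = 1e8,
) -> np.ndarray:
    """Deterministic constrained least-squares oracle for the fractions.

    Solves ``m_b = v_intra K_intra(b) + v_extra K_extra(b) + v_iso K_iso(b)``
    jointly over the shells together with the sum-to-one row, then projects
    onto the simplex if the solution leaves it. Needs >= 2 distinct nonzero
    shells; with exactly two the system is square and the inversion exact.

    Returns an (..., 3) array; invalid voxels (no b0 signal) come back NaN.
    """
    if means.shells.size < 2:
        raise ValidationError(
            f"need >= 2 distinct nonzero shells, got {means.shells.size}"
        )
    A = kernel_matrix(tissue, means.shells)
    cond = np.linalg.cond(A)
    if cond > cond_threshold:
        raise DegenerateModelError(
            f"kernel matrix condition number {cond:.3g} exceeds "
            f"{cond_threshold:.3g}: shells or diffusivities collapse "
            "compartments"
        )
    rhs = np.concatenate(
        [means.m, np.ones(means.m.shape[:-1] + (1,))], axis=-1
    )
    pinv = np.linalg.pinv(A)
    flat = np.nan_to_num(rhs.reshape(-1, rhs.shape[-1]))
    sol = flat @ pinv.T
    off = (np.any(sol < -1e-9, axis=-1)) | (np.abs(sol.sum(-1) - 1) > 1e-9)
    sol[off] = project_simplex(sol[off])
    sol = sol.reshape(rhs.shape[:-1] + (3,))
    sol[~means.valid] = np.nan
    return sol


def _poly_design(features: np.ndarray, degree: int) -> np.ndarray:
    """Full polynomial design (all monomials up to total degree, incl. 1)."""
    features = np.atleast_2d(features)
    n, k = features.shape
    cols = [np.ones(n)]
    for d in range(1, degree + 1):
        for combo in combinations_with_replacement(range(k), d):
            cols.append(np.prod(features[:, combo], axis=1))
    return np.stack(cols, axis=1)


@dataclass
class PosteriorRegressor:
    """Trained feature -> fraction polynomial map (approximate posterior mean)."""

    coef: np.ndarray  # (n_terms, 3)
    degree: int
    shells: np.ndarray
    tissue: TissueParams

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Map (..., k) shell-mean features to simplex fractions (..., 3)."""
        features = np.asarray(features, dtype=float)
        shape = features.shape[:-1]
        phi = _poly_design(features.reshape(-1, features.shape[-1]), self.degree)
        pred = phi @ self.coef
        pred = np.clip(pred, 0.0, 1.0)
        total = pred.sum(axis=-1, keepdims=True)
        pred = np.where(total > 0, pred / np.where(total > 0, total, 1.0), 1.0 / 3.0)
        return pred.reshape(shape + (3,))


def train_posterior_regressor(
    scheme: AcquisitionScheme,
    tissue: TissueParams,
    prior_config: PriorConfig,
    seed: int,
) -> PosteriorRegressor:
    """Simulate the prior on the actual scheme and fit the regression."""
    rng = np.random.default_rng(seed)
    m = prior_config.n_samples
    fractions = sample_simplex(m, rng)
    orientations = sample_sphere(m, rng)
    signals = mixture_signal(
        scheme.effective_bvals, scheme.bvecs, fractions, orientations, tissue
    )
    if prior_config.snr is not None and np.isfinite(prior_config.snr):
        signals = add_rician(signals, 1.0 / prior_config.snr, rng)
    means = shell_spherical_mean(signals, scheme)
    phi = _poly_design(means.m, prior_config.degree)
    coef, *_ = np.linalg.lstsq(phi, fractions, rcond=None)
    return PosteriorRegressor(
        coef=coef, degree=prior_config.degree, shells=means.shells, tissue=tissue
    )


def estimate_background_sigma(dwi: DWIStack) -> float:
    """Noise sigma from the darkest decile of the mean-b0 image.

    Background magnitude voxels are Rician with zero underlying signal, whose
    mean is sigma * sqrt(pi/2); the darkest decile approximates background.
    Returns 0 for noise-free synthetic data.
    """
    b0 = dwi.data[..., dwi.scheme.b0_mask].mean(axis=-1)
    dark = b0[b0 <= np.quantile(b0, 0.10)]
    if dark.size == 0:
        return 0.0
    return float(dark.mean() / np.sqrt(np.pi / 2.0))


def fit_fractions_bayes(
    dwi: DWIStack,
    tissue: TissueParams | None = None,
    prior_config: PriorConfig | None = None,
    seed: int = 0,
    regressor: PosteriorRegressor | None = None,
    sigma: float | None = None,
) -> CompartmentMap:
    """Estimate a :class:`CompartmentMap` with the simulated-prior regression.

    A pre-trained ``regressor`` (from :func:`train_posterior_regressor` on the
    same scheme) can be supplied to amortize training across subjects;
    otherwise one is trained here. ``sigma`` overrides the background noise
    estimate used for masking.
    """
    tissue = tissue or TissueParams()
    prior_config = prior_config or PriorConfig()
    if regressor is None:
        regressor = train_posterior_regressor(dwi.scheme, tissue, prior_config, seed)
    means = shell_spherical_mean(dwi.data, dwi.scheme)
    if sigma is None:
        sigma = estimate_background_sigma(dwi)
    valid = means.valid & (means.m0 > BACKGROUND_SIGMA_FACTOR * sigma) & (means.m0 > 0)
    feats = np.nan_to_num(means.m)
    fracs = regressor.predict(feats)
    fracs[~valid] = np.nan
    return CompartmentMap(
        v_intra=fracs[..., 0],
        v_extra=fracs[..., 1],
        v_iso=fracs[..., 2],
        valid_mask=valid,
    )


__all__ = [
    "ShellMeans",
    "PriorConfig",
    "CompartmentMap",
    "PosteriorRegressor",
    "shell_spherical_mean",
    "forward_shell_means",
    "kernel_spherical_means",
    "kernel_matrix",
    "fit_fractions_linear",
    "train_posterior_regressor",
    "estimate_background_sigma",
    "fit_fractions_bayes",
    "BACKGROUND_SIGMA_FACTOR",
]
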