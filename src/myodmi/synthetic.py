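"""Synthetic shoulder phantoms and cohorts for end-to-end testing.

No subject data accompany the study this package operationalizes, so this
module generates (i) voxel-level DWI signals from the three-compartment
forward model, (ii) whole "subject" phantoms — a two-shell DWI stack, a
two-point Dixon echo pair, a three-muscle label mask, and the ground-truth
fraction/FF maps — and (iii) tabular cohorts whose per-sex compartment
fractions, strength tests, and demographics reproduce the published summary
statistics (11 males + 11 females; male subscapularis v_intra 0.42 +/- 0.04
vs female 0.29 +/- 0.05, etc.), with strength coupled positively to the
tested muscle's v_intra.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dixon import FatFractionMap
from .dmi_fit import CompartmentMap
from .errors import GenerationError, ValidationError
from .io_formats import AcquisitionScheme, DWIStack, MuscleMask, ScalarMap
from .model import TissueParams, add_rician, mixture_signal, validate_fractions
from .voi import derive_ratios

MUSCLES = ("SSP", "ISP", "SSC")
MUSCLE_LABELS = {"SSP": 1, "ISP": 2, "SSC": 3}

#: strength test -> the rotator-cuff muscle it loads
TEST_MUSCLE = {
    "internal_rotation": "SSC",
    "external_rotation": "ISP",
    "jobe": "SSP",
    "starter": "SSP",
}

# Published cohort summary statistics (mean, SD) by sex. The male
# supraspinatus V-ISO is stored as its simplex-consistent value 0.28
# (the printed 0.53 is inconsistent with the fractions summing to one and
# with V-ISO being lower in males).
FRACTION_STATS = {
    "SSC": {"M": (0.42, 0.04, 0.32, 0.04), "F": (0.29, 0.05, 0.44, 0.05)},
    "ISP": {"M": (0.28, 0.05, 0.42, 0.04), "F": (0.21, 0.05, 0.49, 0.08)},
    "SSP": {"M": (0.45, 0.07, 0.28, 0.06), "F": (0.38, 0.06, 0.34, 0.05)},
}

FF_STATS = {
    "SSC": {"M": (2.17, 0.51), "F": (9.29, 15.50)},
    "ISP": {"M": (5.00, 8.97), "F": (6.62, 12.50)},
    "SSP": {"M": (14.70, 14.00), "F": (21.60, 23.80)},
}

STRENGTH_STATS = {  # test -> sex -> (mean_of_mean, sd_of_mean, mean_of_max, sd_of_max)
    "internal_rotation": {"M": (11.40, 1.28, 12.80, 1.61), "F": (6.53, 0.93, 7.90, 1.05)},
    "external_rotation": {"M": (10.40, 1.90, 11.90, 1.67), "F": (5.58, 1.19, 6.37, 1.18)},
    "jobe": {"M": (11.30, 2.43, 12.80, 3.31), "F": (7.23, 1.21, 8.18, 1.39)},
    "starter": {"M": (11.10, 2.84, 12.30, 2.71), "F": (6.82, 1.45, 7.80, 1.56)},
}

DEMOGRAPHICS = {  # variable -> sex -> (mean, sd)
    "age": {"M": (26.30, 2.76), "F": (27.10, 3.45)},
    "weight_kg": {"M": (78.70, 5.08), "F": (63.20, 4.92)},
    "height_m": {"M": (1.83, 0.06), "F": (1.71, 0.04)},
}


# 12 gradient directions from electrostatic-repulsion optimization on the
# projective sphere (minimal 1/r^2 energy over antipodal pairs), the design
# family clinical dMRI protocols use. Their 12-point spherical-mean
# quadrature error is an order of magnitude below a generic point set's.
_DIRS_12 = np.array([
    (-0.97218968, -0.18027734, 0.14949018),
    (-0.84181760, 0.53965204, 0.01090002),
    (-0.63016854, -0.08145286, 0.77217423),
    (-0.51364040, 0.56205485, 0.64828071),
    (-0.45289399, -0.71299106, 0.53528570),
    (-0.14885439, 0.96584932, 0.21207892),
    (0.04582948, -0.20517508, 0.97765170),
    (0.17615550, 0.51474988, 0.83904815),
    (0.23279107, -0.84884738, 0.47462243),
    (0.53683902, 0.82998643, 0.15141463),
    (0.67311916, -0.33966251, 0.65691702),
    (0.78963065, 0.30382737, 0.53307821),
])


def fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform hemisphere directions (deterministic Fibonacci spiral)."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    dirs = []
    for i in range(n):
        z = (i + 0.5) / n
        r = math.sqrt(max(0.0, 1.0 - z * z))
        phi = i * golden
        dirs.append((r * math.cos(phi), r * math.sin(phi), z))
    return np.asarray(dirs)


def default_scheme(n_b0: int = 1, bvalues=(600.0, 1000.0), n_dirs: int = 12
                   ) -> AcquisitionScheme:
    """Two-shell scheme mirroring the acquisition: ``n_dirs`` directions at
    each b-value plus ``n_b0`` b = 0 volumes.

    For the default 12 directions a frozen electrostatically optimized set is
    used (shared across shells); other counts fall back to a Fibonacci
    spiral, adequate for quadrature-convergence studies at large n.
    """
    dirs = _DIRS_12 if n_dirs == 12 else fibonacci_directions(n_dirs)
    bvals = [0.0] * n_b0
    bvecs = [(0.0, 0.0, 0.0)] * n_b0
    for b in bvalues:
        bvals.extend([b] * n_dirs)
        bvecs.extend(dirs.tolist())
    return AcquisitionScheme(bvals=np.asarray(bvals), bvecs=np.asarray(bvecs))


@dataclass(frozen=True)
class GroundTruthVoxel:
    """One voxel's true parameters for signal simulation."""

    v_intra: float
    v_extra: float
    v_iso: float
    orientation: tuple = (0.0, 0.0, 1.0)
    s0: float = 1.0
    ff: float = 0.0

    def __post_init__(self) -> None:
        validate_fractions(np.array([self.v_intra, self.v_extra, self.v_iso]))
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValidationError(f"orientation norm {n} != 1")
        if not 0.0 <= self.ff <= 100.0:
            raise ValidationError("ff must be in [0, 100]")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.v_intra, self.v_extra, self.v_iso])


def simulate_voxel_signal(
    scheme: AcquisitionScheme,
    truth: GroundTruthVoxel,
    tissue: TissueParams | None = None,
    snr: float = np.inf,
    seed: int = 0,
) -> np.ndarray:
    """Forward-simulate one voxel's signal vector on ``scheme``.

    Rician noise of scale ``s0 / snr`` is applied for finite ``snr``;
    ``snr = inf`` is noiseless. Deterministic for fixed seed.
    """
    if not snr > 0:
        raise ValidationError("snr must be positive (use inf for noiseless)")
    tissue = tissue or TissueParams()
    sig = mixture_signal(
        scheme.effective_bvals,
        scheme.bvecs,
        truth.fractions[None, :],
        np.asarray(truth.orientation, dtype=float)[None, :],
        tissue,
        s0=truth.s0,
    )[0]
    if np.isfinite(snr):
        sig = add_rician(sig, truth.s0 / snr, np.random.default_rng(seed))
    return sig


@dataclass
class SubjectPhantom:
    """Complete synthetic dataset for one subject."""

    dwi: DWIStack
    dixon_in_phase: ScalarMap
    dixon_opposed_phase: ScalarMap
    mask: MuscleMask
    truth_fractions: CompartmentMap
    truth_ff: FatFractionMap


def _ellipsoid_mask(shape, center_frac, semi_frac) -> np.ndarray:
    shape = np.asarray(shape)
    idx = np.indices(shape).astype(float) + 0.5
    c = np.asarray(center_frac) * shape
    a = np.asarray(semi_frac) * shape
    d = sum(((idx[k] - c[k]) / a[k]) ** 2 for k in range(3))
    return d <= 1.0


# fractional (center, semi-axes) of the three muscle ellipsoids on the grid
_VOI_GEOMETRY = {
    "SSP": ((0.27, 0.28, 0.50), (0.15, 0.16, 0.30)),
    "ISP": ((0.73, 0.28, 0.50), (0.15, 0.16, 0.30)),
    "SSC": ((0.50, 0.74, 0.50), (0.17, 0.15, 0.30)),
}


def make_phantom_mask(grid_shape) -> MuscleMask:
    """Three disjoint ellipsoidal muscle VOIs on the given grid.

    The geometry is fractional, so the same anatomy can be rendered on any
    grid (e.g. before and after isotropic upsampling).
    """
    shape = tuple(int(s) for s in grid_shape)
    labels = np.zeros(shape, dtype=np.int16)
    for muscle in MUSCLES:
        center, semi = _VOI_GEOMETRY[muscle]
        voi = _ellipsoid_mask(shape, center, semi)
        if not voi.any():
            raise GenerationError(f"grid {shape} too small to contain the {muscle} VOI")
        if np.any(labels[voi] != 0):
            raise GenerationError("muscle VOIs overlap on this grid")
        labels[voi] = MUSCLE_LABELS[muscle]
    return MuscleMask(labels=labels)


def _orientation_field(shape) -> np.ndarray:
    """Smoothly varying unit fiber directions over the grid."""
    idx = np.indices(shape).astype(float)
    nx, ny, _ = shape
    vx = 0.35 * np.sin(2 * np.pi * idx[0] / max(nx, 1))
    vy = 0.35 * np.cos(2 * np.pi * idx[1] / max(ny, 1))
    vz = np.ones(shape)
    vec = np.stack([vx, vy, vz], axis=-1)
    return vec / np.linalg.norm(vec, axis=-1, keepdims=True)


def generate_subject_phantom(
    subject_truth: dict,
    scheme: AcquisitionScheme | None = None,
    grid_shape=(24, 24, 12),
    tissue: TissueParams | None = None,
    snr: float = 40.0,
    seed: int = 0,
    jitter_sd: float = 0.01,
    voxel_size=(2.0, 2.0, 4.0),
    dixon_total: float = 100.0,
    dixon_snr: float | None = None,
) -> SubjectPhantom:
    """Build a phantom shoulder dataset for one subject.

    ``subject_truth`` maps muscle name -> ``{"v_intra", "v_extra", "v_iso",
    "ff"}``. Inside each of three disjoint ellipsoidal muscle VOIs, voxels
    carry the subject's muscle fractions plus Gaussian within-muscle jitter
    (re-projected to the simplex), a smoothly varying fiber orientation, and
    the muscle's fat fraction. The Dixon pair is in-phase = water + fat,
    opposed-phase = |water - fat|, with Gaussian noise of scale
    ``dixon_total / dixon_snr`` (defaults to the DWI ``snr``). Background is
    zero signal plus noise. ``snr = inf`` (and jitter 0) is fully noiseless.
    """
    scheme = scheme or default_scheme()
    tissue = tissue or TissueParams()
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in grid_shape)
    missing = [m for m in MUSCLES if m not in subject_truth]
    if missing:
        raise GenerationError(f"subject_truth missing muscles {missing}")

    mask = make_phantom_mask(shape)
    labels = mask.labels

    fracs = np.zeros(shape + (3,))
    ff = np.full(shape, np.nan)
    orient = _orientation_field(shape)
    for muscle in MUSCLES:
        sel = labels == MUSCLE_LABELS[muscle]
        t = subject_truth[muscle]
        base = np.array([t["v_intra"], t["v_extra"], t["v_iso"]])
        validate_fractions(base, atol=1e-6)
        n = int(sel.sum())
        vi = base[0] + (rng.normal(0.0, jitter_sd, n) if jitter_sd > 0 else 0.0)
        vs = base[2] + (rng.normal(0.0, jitter_sd, n) if jitter_sd > 0 else 0.0)
        trio = np.stack([vi, 1.0 - vi - vs, vs], axis=-1) if n else np.empty((0, 3))
        bad = (trio < 0).any(axis=-1) | (trio > 1).any(axis=-1)
        if bad.any():
            from .model import project_simplex

            trio[bad] = project_simplex(trio[bad])
        fracs[sel] = trio
        ff[sel] = float(t.get("ff", 0.0))

    tissue_sel = labels > 0
    signals = np.zeros(shape + (len(scheme),))
    signals[tissue_sel] = mixture_signal(
        scheme.effective_bvals,
        scheme.bvecs,
        fracs[tissue_sel],
        orient[tissue_sel],
        tissue,
        s0=1.0,
    )
    if np.isfinite(snr):
        signals = add_rician(signals, 1.0 / snr, rng)
    dwi = DWIStack(
        data=signals, voxel_size=np.asarray(voxel_size, dtype=float), scheme=scheme
    )

    fat = np.where(tissue_sel, np.nan_to_num(ff) / 100.0 * dixon_total, 0.0)
    water = np.where(tissue_sel, dixon_total - fat, 0.0)
    ip = water + fat
    op = np.abs(water - fat)
    if dixon_snr is None:
        dixon_snr = snr
    if dixon_snr is not None and np.isfinite(dixon_snr):
        ip = np.clip(ip + rng.normal(0.0, dixon_total / dixon_snr, shape), 0, None)
        op = np.clip(op + rng.normal(0.0, dixon_total / dixon_snr, shape), 0, None)
    vs = np.asarray(voxel_size, dtype=float)

    truth_map = CompartmentMap(
        v_intra=np.where(tissue_sel, fracs[..., 0], np.nan),
        v_extra=np.where(tissue_sel, fracs[..., 1], np.nan),
        v_iso=np.where(tissue_sel, fracs[..., 2], np.nan),
        valid_mask=tissue_sel,
    )
    truth_ff = FatFractionMap(ff=ff, valid_mask=tissue_sel)
    return SubjectPhantom(
        dwi=dwi,
        dixon_in_phase=ScalarMap(data=ip, voxel_size=vs),
        dixon_opposed_phase=ScalarMap(data=op, voxel_size=vs),
        mask=mask,
        truth_fractions=truth_map,
        truth_ff=truth_ff,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-generator configuration, defaulted to the published cohort.

    ``beta_strength`` (kg per unit v_intra) couples each strength test to the
    tested muscle's intracellular fraction within sex; the sex-specific
    intercepts and residual noise are chosen so group means and SDs match the
    published table. ``gamma_noise_sd`` perturbs the max/mean strength ratio.
    """

    n_male: int = 11
    n_female: int = 11
    fraction_stats: dict = field(default_factory=lambda: FRACTION_STATS)
    ff_stats: dict = field(default_factory=lambda: FF_STATS)
    strength_stats: dict = field(default_factory=lambda: STRENGTH_STATS)
    demographics: dict = field(default_factory=lambda: DEMOGRAPHICS)
    beta_strength: float = 8.0
    gamma_noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 2 or self.n_female < 2:
            raise ValidationError("need >= 2 subjects per sex for statistics")
        for muscle in MUSCLES:
            for sex in ("M", "F"):
                stats = self.fraction_stats[muscle][sex]
                if stats[1] < 0 or stats[3] < 0:
                    raise ValidationError("fraction SDs must be >= 0")


def _draw_simplex_fractions(mean_i, sd_i, mean_s, sd_s, n, rng, max_tries=1000):
    """Sex/muscle fractions: draw (v_intra, v_iso) normal, v_extra = remainder,
    redraw off-simplex triples."""
    out = np.empty((n, 3))
    filled = 0
    for _ in range(max_tries):
        need = n - filled
        if need == 0:
            break
        vi = rng.normal(mean_i, sd_i, need)
        vs = rng.normal(mean_s, sd_s, need)
        trio = np.stack([vi, 1.0 - vi - vs, vs], axis=-1)
        ok = (trio >= 0).all(axis=-1) & (trio <= 1).all(axis=-1)
        take = trio[ok]
        out[filled : filled + len(take)] = take
        filled += len(take)
    if filled < n:
        raise GenerationError("could not draw on-simplex fractions; SDs too large")
    return out


def _lognormal_params(mean, sd):
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None
                    ) -> pd.DataFrame:
    """Generate a cohort table with per-subject ground truth.

    Per subject: sex, demographics, per-muscle compartment fractions drawn
    from the sex-specific normals (projected to the simplex by construction),
    lognormal fat fractions, strength tests linear in the tested muscle's
    v_intra, and the derived ER/IR and ISP/SSC ratios. Deterministic per
    seed (``seed`` overrides ``config.seed``).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    sid = 0
    for sex, n in (("M", config.n_male), ("F", config.n_female)):
        fracs = {
            muscle: _draw_simplex_fractions(*config.fraction_stats[muscle][sex], n, rng)
            for muscle in MUSCLES
        }
        ffs = {}
        for muscle in MUSCLES:
            mu, sg = _lognormal_params(*config.ff_stats[muscle][sex])
            ffs[muscle] = rng.lognormal(mu, sg, n)
        demo = {
            var: rng.normal(m, s, n)
            for var, (m, s) in ((v, config.demographics[v][sex]) for v in config.demographics)
        }
        strength = {}
        for test, muscle in TEST_MUSCLE.items():
            mean_m, sd_m, mean_x, sd_x = config.strength_stats[test][sex]
            mean_i, sd_i = config.fraction_stats[muscle][sex][:2]
            slope_var = (config.beta_strength * sd_i) ** 2
            eps_sd = math.sqrt(max(sd_m**2 - slope_var, 0.01))
            vals = (
                mean_m
                + config.beta_strength * (fracs[muscle][:, 0] - mean_i)
                + rng.normal(0.0, eps_sd, n)
            )
            gamma = mean_x / mean_m
            maxima = vals * (gamma + rng.normal(0.0, config.gamma_noise_sd, n))
            # strengths are physical forces; redraw residuals that go nonpositive
            for arr in (vals, maxima):
                while np.any(arr <= 0):
                    bad = arr <= 0
                    arr[bad] = mean_m + rng.normal(0.0, eps_sd, bad.sum())
            strength[test] = (vals, maxima)
        for i in range(n):
            sid += 1
            row = {
                "subject_id": f"S{sid:03d}",
                "sex": sex,
                "age": demo["age"][i],
                "height_m": demo["height_m"][i],
                "weight_kg": demo["weight_kg"][i],
            }
            row["bmi"] = row["weight_kg"] / row["height_m"] ** 2
            for muscle in MUSCLES:
                key = muscle.lower()
                row[f"{key}_v_intra"] = fracs[muscle][i, 0]
                row[f"{key}_v_extra"] = fracs[muscle][i, 1]
                row[f"{key}_v_iso"] = fracs[muscle][i, 2]
                row[f"{key}_ff"] = ffs[muscle][i]
            for test in TEST_MUSCLE:
                row[f"{test}_mean_kg"] = strength[test][0][i]
                row[f"{test}_max_kg"] = strength[test][1][i]
            rows.append(derive_ratios(row))
    return pd.DataFrame(rows)


def subject_truth_from_row(row) -> dict:
    """Extract the phantom ground truth for one cohort-table row."""
    return {
        muscle: {
            "v_intra": float(row[f"{muscle.lower()}_v_intra"]),
            "v_extra": float(row[f"{muscle.lower()}_v_extra"]),
            "v_iso": float(row[f"{muscle.lower()}_v_iso"]),
            "ff": float(row[f"{muscle.lower()}_ff"]),
        }
        for muscle in MUSCLES
    }


__all__ = [
    "MUSCLES",
    "MUSCLE_LABELS",
    "TEST_MUSCLE",
    "FRACTION_STATS",
    "FF_STATS",
    "STRENGTH_STATS",
    "DEMOGRAPHICS",
    "default_scheme",
    "fibonacci_directions",
    "GroundTruthVoxel",
    "simulate_voxel_signal",
    "SubjectPhantom",
    "make_phantom_mask",
    "generate_subject_phantom",
    "CohortConfig",
    "generate_cohort",
    "subject_truth_from_row",
]
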