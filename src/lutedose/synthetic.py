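"""Synthetic test inputs with exact ground truth.

Desk-scale generators for everything the dosimetry chain consumes:
multi-exponential time-activity curves with multiplicative noise,
population samples of effective decay constants, blurred-sphere phantoms
for recovery-curve measurement, and conjugate-view slab projections.
Every generator returns the exact underlying truth next to the degraded
observable, so each downstream estimator has a closed-loop recovery test,
and all randomness is seed-controlled.

These fixtures emulate the arithmetic structure of real data (exponential
kinetics, resolution blur, exponential slab attenuation), not its physics:
there is no projector, scatter, septal penetration, or anatomical texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .kinetics import TimeActivityCurve
from .quantify import ConjugateViewPair

__all__ = [
    "TacModelSpec",
    "PhantomSpec",
    "make_tac",
    "sample_population_lambdas",
    "make_sphere_phantom",
    "make_conjugate_views",
]


@dataclass(frozen=True)
class TacModelSpec:
    """Sum-of-exponentials TAC model with multiplicative noise.

    ``phases`` are (amplitude MBq, rate 1/h) pairs; a negative amplitude
    models an uptake phase (net activity must stay non-negative).  The
    noise is Gaussian with coefficient of variation ``noise_cv``,
    multiplicative and truncated at zero, matching the roughly constant
    relative error of count-derived activity estimates.
    """

    phases: tuple[tuple[float, float], ...]
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("at least one phase required")
        for amp, rate in self.phases:
            if rate <= 0:
                raise ValueError(f"rates must be > 0, got {rate}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def true_activity(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for amp, rate in self.phases:
            out += amp * np.exp(-rate * t)
        return out

    @property
    def true_tia_MBq_h(self) -> float:
        """Closed-form integral over [0, ∞): Σ amplitude/rate."""
        return sum(amp / rate for amp, rate in self.phases)


def make_tac(
    spec: TacModelSpec, times_h: Sequence[float], region: str = "synthetic"
) -> tuple[TimeActivityCurve, float]:
    """Sample the model at the given times; return (TAC, exact TIA)."""
    t = np.asarray(times_h, dtype=float)
    truth = spec.true_activity(t)
    if np.any(truth < 0):
        raise ValueError("spec yields negative activity at a sample time")
    if np.any(spec.true_activity(np.linspace(0, max(t.max(), 1.0), 257)) < 0):
        raise ValueError("spec yields negative activity on [0, t_max]")
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = truth * (1.0 + spec.noise_cv * rng.standard_normal(t.size))
        noisy = np.maximum(noisy, 0.0)
    else:
        noisy = truth
    sig = tuple(spec.noise_cv * truth) if spec.noise_cv > 0 else None
    return (
        TimeActivityCurve(region, tuple(t), tuple(noisy), sig),
        spec.true_tia_MBq_h,
    )


def sample_population_lambdas(
    mean_per_h: float, cv: float, n: int, seed: int = 0
) -> np.ndarray:
    """Draw effective decay constants from a log-normal population.

    The log-normal is parameterised to the requested arithmetic mean and
    coefficient of variation (σ² = ln(1+CV²), μ = ln(mean) − σ²/2), giving
    a strictly positive, right-skewed distribution like observed patient
    washout-rate histograms.
    """
    if mean_per_h <= 0:
        raise ValueError("mean must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv == 0:
        return np.full(n, mean_per_h)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean_per_h) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


@dataclass(frozen=True)
class PhantomSpec:
    """Sphere-insert phantom on a uniform background.

    Spheres of the given volumes are placed (non-overlapping) in a 3-D grid
    at a fixed activity concentration; the background holds the
    concentration times ``background_ratio``.  Isotropic Gaussian smoothing
    of width ``blur_fwhm_mm`` stands in for the system resolution.
    """

    sphere_volumes_cm3: tuple[float, ...]
    background_ratio: float = 0.0
    blur_fwhm_mm: float = 10.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sphere_volumes_cm3:
            raise ValueError("at least one sphere volume required")
        if any(v <= 0 for v in self.sphere_volumes_cm3):
            raise ValueError("sphere volumes must be > 0")
        if not 0 <= self.background_ratio < 1:
            raise ValueError("background_ratio must be in [0, 1)")
        if self.blur_fwhm_mm < 0:
            raise ValueError("blur width must be >= 0")


def _sphere_radii_mm(volumes_cm3: Sequence[float]) -> list[float]:
    return [(3.0 * v * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0) for v in volumes_cm3]


def make_sphere_phantom(
    spec: PhantomSpec, concentration_MBq_per_mL: float = 1.0
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Build (truth map, blurred map, sphere metadata).

    Maps are activity concentration in MBq/mL on the phantom grid.  The
    Gaussian blur conserves total activity (reflective boundaries); sphere
    metadata records centre, radius, true volume and true activity so
    recovery coefficients can be measured against ground truth.
    """
    if concentration_MBq_per_mL <= 0:
        raise ValueError("concentration must be > 0")
    nx, ny, nz = spec.grid_shape
    vox = spec.voxel_size_mm
    radii = _sphere_radii_mm(spec.sphere_volumes_cm3)

    # Place sphere centres along x with padding; refuse overlap/overflow.
    centres = []
    x = 0.0
    gap = 4.0 * vox
    for r in radii:
        x += r + gap
        centres.append(x)
        x += r
    total_extent = x + gap
    if total_extent > nx * vox:
        raise ValueError(
            f"spheres (extent {total_extent:.0f} mm) do not fit the grid "
            f"({nx * vox:.0f} mm along x); enlarge the grid or shrink volumes"
        )
    # Overlap check (line placement guarantees it, but user subclassing may not).
    for (c1, r1), (c2, r2) in zip(
        zip(centres, radii), list(zip(centres, radii))[1:]
    ):
        if c2 - c1 < r1 + r2:
            raise ValueError("spheres overlap")

    xs = (np.arange(nx) + 0.5) * vox
    ys = (np.arange(ny) + 0.5) * vox
    zs = (np.arange(nz) + 0.5) * vox
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    truth = np.full(spec.grid_shape, spec.background_ratio * concentration_MBq_per_mL)
    meta = []
    yc, zc = ny * vox / 2.0, nz * vox / 2.0
    for cx, r, vol in zip(centres, radii, spec.sphere_volumes_cm3):
        inside = (X - cx) ** 2 + (Y - yc) ** 2 + (Z - zc) ** 2 <= r * r
        truth[inside] = concentration_MBq_per_mL
        voxel_ml = (vox / 10.0) ** 3
        meta.append(
            {
                "centre_mm": (cx, yc, zc),
                "radius_mm": r,
                "volume_cm3": vol,
                "voxel_volume_cm3": float(inside.sum()) * voxel_ml,
                "true_activity_MBq": concentration_MBq_per_mL * inside.sum() * voxel_ml,
                "mask": inside,
            }
        )
    if spec.blur_fwhm_mm > 0:
        sigma_vox = spec.blur_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / vox
        blurred = gaussian_filter(truth, sigma=sigma_vox, mode="reflect")
    else:
        blurred = truth.copy()
    return truth, blurred, meta


def make_conjugate_views(
    activity_MBq: float,
    depth_cm: float,
    thickness_cm: float,
    mu_per_cm: float,
    q_pl_cps_per_MBq: float,
) -> ConjugateViewPair:
    """Forward-model a point source at depth d in a uniform slab.

    Anterior view attenuated through d, posterior through L − d:
    C_A = Q_pl·A·e^{−μd}, C_P = Q_pl·A·e^{−μ(L−d)}.  The geometric mean of
    the two views times e^{μL/2} recovers A exactly for every depth — the
    identity the conjugate-view method rests on.
    """
    if not 0 <= depth_cm <= thickness_cm:
        raise ValueError(
            f"depth {depth_cm} cm outside slab [0, {thickness_cm}] cm"
        )
    if activity_MBq < 0 or mu_per_cm < 0 or q_pl_cps_per_MBq <= 0:
        raise ValueError("invalid forward-model inputs")
    c_ant = q_pl_cps_per_MBq * activity_MBq * math.exp(-mu_per_cm * depth_cm)
    c_post = q_pl_cps_per_MBq * activity_MBq * math.exp(-mu_per_cm * (thickness_cm - depth_cm))
    return ConjugateViewPair(
        c_ant_cps=c_ant,
        c_post_cps=c_post,
        thickness_cm=thickness_cm,
        mu_per_cm=mu_per_cm,
    )
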