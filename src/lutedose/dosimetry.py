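"""Absorbed dose assembly: the MIRD sum, organ schemes, and voxel dosimetry.

The mean absorbed dose to a target region over the dose-integration period
is the sum over source regions of time-integrated activity × S-value,

    D(r_T) = Σ_{r_S} Ã(r_S) · S(r_T ← r_S),

with the integration period taken to infinity.  On top of that sum this
module implements the organ-specific procedures used clinically for
177Lu-labelled SSTR- and PSMA-targeting therapy: two equivalent kidney
schemes (activity-based with mass-scaled S-values, and concentration-based
with local energy deposition), blood-based red-marrow and blood dosimetry,
gland dosimetry with a mass range, an extravasation estimate, and
voxel-level LED dose-rate maps with dose-volume histograms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import FitResult, TimeActivityCurve, fit_exponential
from .nuclide import ICRP107, NuclideDataset, decay_constant, delta_to_energy_per_tia
from .svalues import SValueRecord, SValueTable, led_self_svalue, scale_svalue

__all__ = [
    "DoseReport",
    "KidneyDoseResult",
    "BloodKinetics",
    "GlandDose",
    "VoxelDoseRateMap",
    "DVH",
    "VoxelDoseResult",
    "KIDNEY_DENSITY_G_PER_CM3",
    "BLOOD_SELF_SVALUE_GY_PER_GBQ_H_PER_ML",
    "TOTAL_BODY_GAMMA_SVALUE_GY_PER_GBQ_H",
    "mean_dose",
    "kidney_scheme1",
    "kidney_scheme2",
    "red_marrow_dose",
    "blood_dose",
    "gland_dose",
    "extravasation_dose",
    "voxel_dose_rate",
    "voxel_tia_and_dvh",
    "compute_dvh",
]

#: Soft-tissue density used to convert kidney volume to mass, g/cm³.
KIDNEY_DENSITY_G_PER_CM3 = 1.05
#: LED-derived self-dose S-value for 1 mL of blood, Gy per GBq·h/mL.
BLOOD_SELF_SVALUE_GY_PER_GBQ_H_PER_ML = 85.3
#: Photon total-body S-value for 177Lu, Gy per GBq·h; scaled by the
#: patient/reference body-mass ratio to the 2/3 power when applied to blood.
TOTAL_BODY_GAMMA_SVALUE_GY_PER_GBQ_H = 0.00185


@dataclass
class Contribution:
    """One source-region term of the MIRD sum."""

    source: str
    tia_MBq_h: float
    svalue_mGy_per_MBq_h: float

    @property
    def dose_mGy(self) -> float:
        return self.tia_MBq_h * self.svalue_mGy_per_MBq_h


@dataclass
class DoseReport:
    """Per-region absorbed dose with its contribution breakdown."""

    target: str
    contributions: list[Contribution] = field(default_factory=list)
    mass_used_g: float | None = None
    cycle: int = 1
    assumptions: list[str] = field(default_factory=list)

    @property
    def mean_dose_mGy(self) -> float:
        return sum(c.dose_mGy for c in self.contributions)

    @property
    def mean_dose_Gy(self) -> float:
        return self.mean_dose_mGy / 1000.0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "target": self.target,
            "mean_dose_mGy": self.mean_dose_mGy,
            "mass_used_g": self.mass_used_g,
            "cycle": self.cycle,
            "assumptions": self.assumptions,
            "contributions": [
                {
                    "source": c.source,
                    "tia_MBq_h": c.tia_MBq_h,
                    "svalue_mGy_per_MBq_h": c.svalue_mGy_per_MBq_h,
                    "dose_mGy": c.dose_mGy,
                }
                for c in self.contributions
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        """Flat CSV, one row per contribution."""
        pd.DataFrame(
            {
                "target": self.target,
                "cycle": self.cycle,
                "source": [c.source for c in self.contributions],
                "tia_MBq_h": [c.tia_MBq_h for c in self.contributions],
                "svalue_mGy_per_MBq_h": [c.svalue_mGy_per_MBq_h for c in self.contributions],
                "dose_mGy": [c.dose_mGy for c in self.contributions],
            }
        ).to_csv(path, index=False)


def mean_dose(
    tias_MBq_h: Mapping[str, float],
    svalues: SValueTable,
    target: str,
    phantom: str,
) -> DoseReport:
    """MIRD sum over source regions for one target.

    Every source region in ``tias_MBq_h`` must have a matching
    (source → target) record in the table for the given phantom; a missing
    pair is a configuration error, never silently dropped.
    """
    report = DoseReport(target=target)
    missing = []
    for source, tia in tias_MBq_h.items():
        try:
            rec = svalues.lookup(source, target, phantom)
        except LookupError:
            missing.append(source)
            continue
        report.contributions.append(Contribution(source, tia, rec.value))
    if missing:
        raise LookupError(
            f"no S-value for source(s) {missing} → target {target!r} "
            f"(phantom {phantom!r}); every supplied TIA must be matched"
        )
    return report


# ---------------------------------------------------------------------------
# Kidney schemes
# ---------------------------------------------------------------------------

def _tia_from_tac(
    tac: TimeActivityCurve,
    carried_lambda_per_h: float | None,
    min_cycle1_samples: int = 3,
) -> tuple[float, float, FitResult | None]:
    """TIA and effective λ, by monoexp fit (cycle 1) or carried half-life.

    With a carried λ the sample(s) are back-extrapolated through a
    mono-exponential at that rate; with several samples the implied
    amplitudes are averaged.
    """
    if carried_lambda_per_h is None:
        if len(tac) < min_cycle1_samples:
            raise ValueError(
                f"cycle-1 fitting needs >= {min_cycle1_samples} samples "
                f"(got {len(tac)}); later cycles need the cycle-1 half-life"
            )
        fit = fit_exponential(tac, model="monoexp")
        return fit.tia_MBq_h, fit.params["lambda"], fit
    if carried_lambda_per_h <= 0:
        raise ValueError("carried decay constant must be > 0")
    if len(tac) < 1:
        raise ValueError("need at least one sample on a follow-up cycle")
    amplitudes = tac.a * np.exp(carried_lambda_per_h * tac.t)
    a0 = float(np.mean(amplitudes))
    return a0 / carried_lambda_per_h, carried_lambda_per_h, None


@dataclass
class KidneyDoseResult:
    """Left/right kidney dose reports with combined summaries."""

    left: DoseReport
    right: DoseReport
    total_tia_MBq_h: float
    effective_halflives_h: tuple[float, float]
    svalue_pat: SValueRecord | None = None

    @property
    def combined_mass_weighted_Gy(self) -> float:
        """Mass-weighted mean of the per-kidney doses (the default summary)."""
        ml, mr = self.left.mass_used_g, self.right.mass_used_g
        return (
            (self.left.mean_dose_Gy * ml + self.right.mean_dose_Gy * mr) / (ml + mr)
        )

    @property
    def combined_plain_mean_Gy(self) -> float:
        return 0.5 * (self.left.mean_dose_Gy + self.right.mean_dose_Gy)


def kidney_scheme1(
    left_tac: TimeActivityCurve,
    right_tac: TimeActivityCurve,
    kidney_masses_g: tuple[float, float],
    svalue: SValueRecord,
    cycle1_halflives_h: tuple[float, float] | None = None,
    cycle: int = 1,
) -> KidneyDoseResult:
    """Activity-based kidney dosimetry (reference S-value route).

    At cycle 1 a mono-exponential is fitted to each kidney's activity TAC
    (>= 3 samples); on later cycles a single measurement is combined with
    the carried cycle-1 effective half-life.  The reference self-dose
    S-value is mass-scaled to the combined patient kidney mass, and each
    kidney's dose uses its own TIA with the S-value scaled to that kidney's
    own mass, so the mass-weighted mean of the two doses equals the
    combined-mass calculation applied to the summed TIA.
    """
    ml, mr = kidney_masses_g
    if ml <= 0 or mr <= 0:
        raise ValueError("kidney masses must be > 0")
    lambdas: list[float | None] = [None, None]
    if cycle1_halflives_h is not None:
        lambdas = [math.log(2.0) / t for t in cycle1_halflives_h]
    elif cycle > 1:
        raise ValueError("follow-up cycles require cycle1_halflives_h")

    reports = []
    tias = []
    halflives = []
    for tac, mass, lam in zip((left_tac, right_tac), (ml, mr), lambdas):
        tia, lam_eff, _ = _tia_from_tac(tac, lam)
        s_own = scale_svalue(svalue, mass)
        rep = DoseReport(
            target=tac.region,
            contributions=[Contribution(tac.region, tia, s_own.value)],
            mass_used_g=mass,
            cycle=cycle,
            assumptions=["self-dose only (rest-of-body contribution ~2% omitted)"],
        )
        if lam is not None:
            rep.assumptions.append(
                "effective half-life carried from cycle 1; re-assess if renal "
                "function or tumour burden changed"
            )
        reports.append(rep)
        tias.append(tia)
        halflives.append(math.log(2.0) / lam_eff)

    s_pat = scale_svalue(svalue, ml + mr)
    return KidneyDoseResult(
        left=reports[0],
        right=reports[1],
        total_tia_MBq_h=sum(tias),
        effective_halflives_h=(halflives[0], halflives[1]),
        svalue_pat=s_pat,
    )


def kidney_scheme2(
    left_conc_tac: TimeActivityCurve,
    right_conc_tac: TimeActivityCurve,
    recovery: float,
    nuclide: NuclideDataset = ICRP107,
    density_g_per_cm3: float = KIDNEY_DENSITY_G_PER_CM3,
    cycle1_halflives_h: tuple[float, float] | None = None,
    volumes_ml: tuple[float, float] | None = None,
    cycle: int = 1,
) -> KidneyDoseResult:
    """Concentration-based kidney dosimetry (local-energy-deposition route).

    The recovery-corrected activity concentration (MBq/mL) is converted to
    an absorbed dose rate Δ_e·[A]/ρ, a mono-exponential is fitted to the
    dose-rate curve (cycle 1) or a carried half-life applied, and the dose
    is the analytic time integral.  ``volumes_ml`` provides the weights for
    the mass-weighted combined dose; equal weights when omitted.
    """
    if not 0 < recovery <= 1.2:
        raise ValueError("recovery must be in (0, 1.2]")
    if density_g_per_cm3 <= 0:
        raise ValueError("density must be > 0")
    # mJ/(MBq·h) × (MBq/cm³)/(g/cm³) = mJ/(g·h) = Gy/h → mGy/h
    rate_factor = delta_to_energy_per_tia(nuclide.delta_e_keV) / density_g_per_cm3 * 1000.0

    lambdas: list[float | None] = [None, None]
    if cycle1_halflives_h is not None:
        lambdas = [math.log(2.0) / t for t in cycle1_halflives_h]
    elif cycle > 1:
        raise ValueError("follow-up cycles require cycle1_halflives_h")

    if volumes_ml is None:
        weights = (1.0, 1.0)
        masses: tuple[float | None, float | None] = (None, None)
    else:
        weights = volumes_ml
        masses = tuple(v * density_g_per_cm3 for v in volumes_ml)

    reports = []
    doses_mGy = []
    halflives = []
    for tac, lam, mass in zip((left_conc_tac, right_conc_tac), lambdas, masses):
        rate_tac = TimeActivityCurve(
            tac.region, tac.times_h, tuple(a / recovery * rate_factor for a in tac.a)
        )
        dose_mGy, lam_eff, _ = _tia_from_tac(rate_tac, lam)  # mGy/h integrated → mGy
        rep = DoseReport(
            target=tac.region,
            contributions=[Contribution(tac.region, dose_mGy, 1.0)],
            mass_used_g=mass,
            cycle=cycle,
            assumptions=[
                "local energy deposition (electron self-dose only)",
                f"mass density {density_g_per_cm3} g/cm3",
            ],
        )
        reports.append(rep)
        doses_mGy.append(dose_mGy)
        halflives.append(math.log(2.0) / lam_eff)

    result = KidneyDoseResult(
        left=reports[0],
        right=reports[1],
        total_tia_MBq_h=float("nan"),  # concentration route has no activity TIA
        effective_halflives_h=(halflives[0], halflives[1]),
    )
    # Weighted combination for the concentration route (volumes as weights).
    wl, wr = weights
    result.left.mass_used_g = masses[0] if masses[0] is not None else wl
    result.right.mass_used_g = masses[1] if masses[1] is not None else wr
    return result


# ---------------------------------------------------------------------------
# Red marrow and blood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BloodKinetics:
    """Blood and total-body time-integrated activity summary.

    ``tia_conc_blood_MBq_h_per_mL`` is the integral of the blood
    activity-concentration curve; ``rmblr`` is the red-marrow-to-blood
    activity concentration ratio (≈1 for both SSTR- and PSMA-targeting
    compounds when there is no specific marrow binding).
    """

    tia_conc_blood_MBq_h_per_mL: float
    tia_total_body_MBq_h: float = 0.0
    body_mass_kg: float | None = None
    rmblr: float = 1.0

    def __post_init__(self) -> None:
        if self.tia_conc_blood_MBq_h_per_mL < 0 or self.tia_total_body_MBq_h < 0:
            raise ValueError("TIA values must be >= 0")
        if self.rmblr < 0:
            raise ValueError("rmblr must be >= 0")


def red_marrow_dose(
    blood: BloodKinetics,
    rm_svalue: SValueRecord,
    image_contributions: Mapping[str, tuple[float, float]] | None = None,
) -> DoseReport:
    """Blood-based red-marrow dose, optionally with image-based cross terms.

    The self term takes the marrow TIA concentration as RMBLR times the
    blood TIA concentration, scaled to the reference-phantom marrow mass
    (mL ≈ g): Ã_RM = [Ã_BL]·RMBLR·m_RM,ref, dosed with the reference
    self-dose S-value.  Cross terms (bone, high-uptake organs, remainder of
    body) are supplied as ``{source: (tia_MBq_h, svalue_mGy_per_MBq_h)}``
    from image-based quantification; omitted terms are recorded in the
    assumptions.
    """
    if not rm_svalue.is_self:
        raise ValueError("rm_svalue must be a self-dose record")
    tia_rm = blood.tia_conc_blood_MBq_h_per_mL * blood.rmblr * rm_svalue.ref_mass_g
    report = DoseReport(
        target=rm_svalue.target,
        contributions=[Contribution("red marrow (blood-derived)", tia_rm, rm_svalue.value)],
        mass_used_g=rm_svalue.ref_mass_g,
        assumptions=[
            f"RMBLR = {blood.rmblr} (no specific marrow binding)",
            "marrow TIA from blood concentration at reference marrow mass",
        ],
    )
    provided = set()
    if image_contributions:
        for source, (tia, sval) in image_contributions.items():
            if tia < 0 or sval < 0:
                raise ValueError("cross-term TIA and S-value must be >= 0")
            report.contributions.append(Contribution(source, tia, sval))
            provided.add(source)
    for term in ("bone", "remainder of body"):
        if term not in provided:
            report.assumptions.append(f"cross term omitted: {term}")
    return report


def blood_dose(blood: BloodKinetics) -> float:
    """Absorbed dose to blood, Gy: self (electron) + total-body photon term.

    D = [Ã_BL]·S(BL←BL) + Ã_TB·S_γ(TB←TB)/M^(2/3), with the blood TIA
    concentration in GBq·h/mL and total-body TIA in GBq·h.
    """
    conc_gbq = blood.tia_conc_blood_MBq_h_per_mL / 1000.0
    dose = conc_gbq * BLOOD_SELF_SVALUE_GY_PER_GBQ_H_PER_ML
    if blood.tia_total_body_MBq_h > 0:
        if blood.body_mass_kg is None or blood.body_mass_kg <= 0:
            raise ValueError("body mass required for the total-body photon term")
        tb_gbq = blood.tia_total_body_MBq_h / 1000.0
        dose += tb_gbq * TOTAL_BODY_GAMMA_SVALUE_GY_PER_GBQ_H / blood.body_mass_kg ** (2.0 / 3.0)
    return dose


# ---------------------------------------------------------------------------
# Glands, extravasation
# ---------------------------------------------------------------------------

@dataclass
class GlandDose:
    """Gland dose at the central mass with bounds from the mass range."""

    report: DoseReport
    dose_low_mGy: float | None = None
    dose_high_mGy: float | None = None


def gland_dose(
    tac: TimeActivityCurve | float,
    mass_g: float | tuple[float, float, float],
    dataset: NuclideDataset = ICRP107,
    svalue: SValueRecord | None = None,
) -> GlandDose:
    """Self-dose for a small gland (salivary, lacrimal, pituitary).

    ``tac`` may be a sampled TAC (mono-exponential fit, >= 2 samples) or a
    precomputed TIA in MBq·h.  With a reference ``svalue`` the dose uses the
    mass-scaled S-value; otherwise the LED approximation Δ_e/m (the only
    option for the lacrimal glands, where no phantom value exists).  A
    ``(low, mid, high)`` mass range yields the dose at the central mass plus
    bounds — dose scales as 1/m, so the low mass gives the high bound.
    """
    if isinstance(tac, TimeActivityCurve):
        fit = fit_exponential(tac, model="monoexp")
        tia = fit.tia_MBq_h
    else:
        tia = float(tac)
        if tia < 0:
            raise ValueError("TIA must be >= 0")

    if isinstance(mass_g, tuple):
        low, mid, high = mass_g
        if not 0 < low <= mid <= high:
            raise ValueError("mass range must satisfy 0 < low <= mid <= high")
    else:
        low = mid = high = float(mass_g)
        if mid <= 0:
            raise ValueError("mass must be > 0")

    def s_at(mass: float) -> float:
        if svalue is not None:
            return scale_svalue(svalue, mass).value
        return led_self_svalue(mass, dataset)

    method = "mass-scaled reference S-value" if svalue is not None else "LED (Δ_e/m)"
    report = DoseReport(
        target="gland",
        contributions=[Contribution("gland", tia, s_at(mid))],
        mass_used_g=mid,
        assumptions=[method, "self-dose only"],
    )
    low_dose = high_dose = None
    if high > low:
        high_dose = tia * s_at(low)   # smallest mass → highest dose
        low_dose = tia * s_at(high)
    return GlandDose(report, dose_low_mGy=low_dose, dose_high_mGy=high_dose)


def extravasation_dose(
    activity_MBq: float,
    volume_cm3: float,
    clearance_halflife_h: float | None = None,
    nuclide: NuclideDataset = ICRP107,
    density_g_per_cm3: float = 1.0,
) -> float:
    """Absorbed dose (Gy) to an extravasation volume at the injection site.

    The infiltrated activity is assumed uniformly distributed in
    ``volume_cm3`` and removed at the effective rate λ_phys + λ_bio (λ_bio
    from the lymphatic clearance half-life; zero when no clearance).  The
    dose uses local energy deposition: TIA × Δ_e / mass.
    """
    if activity_MBq < 0:
        raise ValueError("activity must be >= 0")
    if volume_cm3 <= 0:
        raise ValueError("volume must be > 0")
    if density_g_per_cm3 <= 0:
        raise ValueError("density must be > 0")
    lam = decay_constant(nuclide)
    if clearance_halflife_h is not None:
        if clearance_halflife_h <= 0:
            raise ValueError("clearance half-life must be > 0")
        lam += math.log(2.0) / clearance_halflife_h
    tia = activity_MBq / lam  # MBq·h
    mass_kg = volume_cm3 * density_g_per_cm3 / 1000.0
    energy_mJ = tia * delta_to_energy_per_tia(nuclide.delta_e_keV)
    return energy_mJ / mass_kg / 1000.0  # mJ/kg = mGy → Gy


# ---------------------------------------------------------------------------
# Voxel-level dosimetry
# ---------------------------------------------------------------------------

@dataclass
class VoxelDoseRateMap:
    """3-D absorbed dose-rate map, mGy/h, at one time point."""

    values_mGy_per_h: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    density_g_per_cm3: float | np.ndarray = 1.0
    time_h: float = 0.0

    def __post_init__(self) -> None:
        self.values_mGy_per_h = np.asarray(self.values_mGy_per_h, dtype=float)
        if np.any(self.values_mGy_per_h < 0):
            raise ValueError("dose rates must be >= 0")


def voxel_dose_rate(
    conc_map_MBq_per_mL: np.ndarray,
    density_g_per_cm3: float | np.ndarray = 1.0,
    dataset: NuclideDataset = ICRP107,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    time_h: float = 0.0,
) -> VoxelDoseRateMap:
    """Element-wise LED dose rate Ḋ_k = Δ_e·[A]_k/ρ_k, mGy/h.

    A uniform soft-tissue density is usually sufficient; a density array of
    the same shape can be supplied for bone or lung.
    """
    conc = np.asarray(conc_map_MBq_per_mL, dtype=float)
    rho = np.asarray(density_g_per_cm3, dtype=float)
    if rho.ndim and rho.shape != conc.shape:
        raise ValueError(
            f"density shape {rho.shape} does not match map shape {conc.shape}"
        )
    if np.any(rho <= 0):
        raise ValueError("density must be > 0 everywhere")
    rate = delta_to_energy_per_tia(dataset.delta_e_keV) * conc / rho * 1000.0
    return VoxelDoseRateMap(rate, voxel_size_mm, density_g_per_cm3, time_h)


@dataclass
class DVH:
    """Cumulative dose-volume histogram over a masked volume."""

    dose_mGy: np.ndarray
    volume_fraction: np.ndarray

    def at(self, dose_mGy: float) -> float:
        """Fraction of the masked volume receiving at least ``dose_mGy``."""
        return float(np.interp(dose_mGy, self.dose_mGy, self.volume_fraction))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"dose_mGy": self.dose_mGy, "volume_fraction": self.volume_fraction}
        ).to_csv(path, index=False)


def compute_dvh(
    dose_map_mGy: np.ndarray, mask: np.ndarray, n_bins: int = 200
) -> DVH:
    """Cumulative DVH: volume fraction with dose >= each bin edge.

    DVH(0) is 1 by construction and the curve is non-increasing.
    """
    doses = np.asarray(dose_map_mGy, dtype=float)[np.asarray(mask, dtype=bool)]
    if doses.size == 0:
        raise ValueError("mask selects no voxels")
    edges = np.linspace(0.0, float(doses.max()), n_bins + 1)
    frac = np.array([(doses >= d).mean() if d > 0 else 1.0 for d in edges])
    return DVH(edges, frac)


@dataclass
class VoxelDoseResult:
    """Voxel-level absorbed dose with DVH and fit diagnostics."""

    dose_map_mGy: np.ndarray | None
    voi_dose_mGy: float
    dvh: DVH | None
    n_fallback_voxels: int = 0


def voxel_tia_and_dvh(
    maps: Sequence[VoxelDoseRateMap],
    voi_mask: np.ndarray,
    method: Literal["voxelwise_fit", "voi_mean_fit"] = "voxelwise_fit",
    nuclide: NuclideDataset = ICRP107,
) -> VoxelDoseResult:
    """Integrate a time series of dose-rate maps into absorbed dose.

    ``voxelwise_fit`` fits a mono-exponential to every masked voxel's
    dose-rate history (log-linear least squares) and integrates to
    infinity, producing a dose map and its cumulative DVH; voxels whose
    rates are not decreasing fall back to trapezoid integration with a
    physical-decay tail and are counted in the diagnostics.
    ``voi_mean_fit`` fits the VOI-mean dose rate instead and returns a
    scalar dose.  All maps must share one grid.
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 time points for fitting")
    shape = maps[0].values_mGy_per_h.shape
    for m in maps[1:]:
        if m.values_mGy_per_h.shape != shape:
            raise ValueError("all maps must be co-registered on one grid")
    mask = np.asarray(voi_mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match the maps")
    times = np.array([m.time_h for m in maps], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("map times must be strictly increasing")
    rates = np.stack([m.values_mGy_per_h for m in maps])  # (T, ...) mGy/h

    if method == "voi_mean_fit":
        mean_rates = rates[:, mask].mean(axis=1)
        tac = TimeActivityCurve("VOI mean dose rate", tuple(times), tuple(mean_rates))
        fit = fit_exponential(tac, model="monoexp")
        return VoxelDoseResult(None, fit.tia_MBq_h, None, 0)
    if method != "voxelwise_fit":
        raise ValueError(f"unknown method {method!r}")

    flat = rates[:, mask]  # (T, N)
    n_vox = flat.shape[1]
    dose = np.zeros(n_vox)
    # Log-linear fit per voxel where every rate is positive and decaying.
    positive = np.all(flat > 0, axis=0)
    logr = np.where(flat > 0, np.log(np.maximum(flat, 1e-300)), 0.0)
    t_mean = times.mean()
    t_var = ((times - t_mean) ** 2).sum()
    slope = ((times - t_mean)[:, None] * logr).sum(axis=0) / t_var
    intercept = logr.mean(axis=0) - slope * t_mean
    lam = -slope
    # A voxel qualifies for the monoexp route only if its rates actually
    # decrease; flat voxels otherwise fit λ ≈ float noise and blow up 1/λ.
    decreasing = flat[-1] < flat[0]
    fit_ok = positive & (lam > 0) & decreasing
    dose[fit_ok] = np.exp(intercept[fit_ok]) / lam[fit_ok]
    # Fallback: trapezoid over the samples plus physical-decay tail.
    fb = ~fit_ok
    if fb.any():
        lam_phys = decay_constant(nuclide)
        area = np.trapezoid(flat[:, fb], times, axis=0)
        area += 0.5 * flat[0, fb] * times[0]
        dose[fb] = area + flat[-1, fb] / lam_phys

    dose_map = np.zeros(shape)
    dose_map[mask] = dose
    dvh = compute_dvh(dose_map, mask)
    voi_dose = float(dose.mean())
    return VoxelDoseResult(dose_map, voi_dose, dvh, int(fb.sum()))
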