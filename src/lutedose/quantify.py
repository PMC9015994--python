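"""Gamma-camera counts to activity: calibration, recovery, planar methods.

Converts measured counts into activity (MBq) for SPECT and planar imaging:

* SPECT calibration factor Q_sp (cps per MBq) from a phantom of known
  activity concentration, and the recovery coefficient R(v) that captures
  the partial-volume loss for an object of volume v;
* VOI activity A = C / (Q_sp · R(v));
* conjugate-view planar quantification from the geometric mean of anterior
  and posterior count rates with broad-beam attenuation correction
  exp(μL/2), with optional background subtraction (the 177Lu source
  self-attenuation factor is near unity and omitted);
* triple-energy-window (TEW) scatter correction;
* hybrid planar–SPECT rescaling of a relative planar TAC to an absolute
  SPECT anchor point;
* inversion of a measured count-rate response curve (dead-time correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .kinetics import TimeActivityCurve

__all__ = [
    "SpectCalibration",
    "PlanarCalibration",
    "RecoveryCurve",
    "Recovery",
    "VOIMeasurement",
    "ConjugateViewPair",
    "DeadTimeResponse",
    "TewResult",
    "spect_calibration",
    "recovery_coefficient",
    "activity_from_voi",
    "conjugate_view_activity",
    "tew_scatter_correct",
    "hybrid_rescale",
    "deadtime_correct",
    "MU_EFF_208KEV_PER_CM",
]

#: Default broad-beam (effective) attenuation coefficient for the 208 keV
#: photopeak of 177Lu in soft tissue, 1/cm.  Override per patient or with a
#: transmission measurement.
MU_EFF_208KEV_PER_CM = 0.12


@dataclass(frozen=True)
class SpectCalibration:
    """SPECT system sensitivity Q_sp, counts per second per MBq."""

    q_sp_cps_per_MBq: float
    acquisition_notes: str = ""

    def __post_init__(self) -> None:
        if self.q_sp_cps_per_MBq <= 0:
            raise ValueError("q_sp must be > 0")


@dataclass(frozen=True)
class PlanarCalibration:
    """Planar (in-air) sensitivity Q_pl, counts per second per MBq."""

    q_pl_cps_per_MBq: float

    def __post_init__(self) -> None:
        if self.q_pl_cps_per_MBq <= 0:
            raise ValueError("q_pl must be > 0")


def spect_calibration(
    counts: float,
    duration_s: float,
    activity_conc_MBq_per_cm3: float,
    voi_volume_cm3: float,
    acquisition_notes: str = "",
) -> SpectCalibration:
    """Q_sp = (counts / duration) / (activity concentration × VOI volume)."""
    if counts <= 0 or duration_s <= 0:
        raise ValueError("counts and duration must be > 0")
    if activity_conc_MBq_per_cm3 <= 0 or voi_volume_cm3 <= 0:
        raise ValueError("activity concentration and VOI volume must be > 0")
    q = (counts / duration_s) / (activity_conc_MBq_per_cm3 * voi_volume_cm3)
    return SpectCalibration(q, acquisition_notes)


def recovery_coefficient(
    count_rate_cps: float, q_sp_cps_per_MBq: float, true_activity_MBq: float
) -> float:
    """R = C / (Q_sp × A) for a phantom insert of known activity."""
    if q_sp_cps_per_MBq <= 0 or true_activity_MBq <= 0:
        raise ValueError("q_sp and true activity must be > 0")
    if count_rate_cps < 0:
        raise ValueError("count rate must be >= 0")
    return count_rate_cps / (q_sp_cps_per_MBq * true_activity_MBq)


class Recovery(NamedTuple):
    """Interpolated recovery coefficient with a support flag."""

    value: float
    clamped: bool


@dataclass(frozen=True)
class RecoveryCurve:
    """Recovery coefficient versus object volume.

    Nodes are (volume cm³, recovery) pairs with strictly increasing
    volumes; recoveries must lie in (0, 1.2] (mild over-recovery from noise
    or spill-in is tolerated).  Monotonicity in volume is not enforced —
    measured curves are noisy — but interpolation is done in log-volume
    where real recovery curves are close to piecewise linear.
    """

    volumes_cm3: tuple[float, ...]
    recoveries: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_cm3, dtype=float)
        r = np.asarray(self.recoveries, dtype=float)
        if v.size == 0:
            raise ValueError("recovery curve must have at least one node")
        if v.size != r.size:
            raise ValueError("volumes and recoveries must have equal length")
        if np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise ValueError("volumes must be positive and strictly increasing")
        if np.any(r <= 0) or np.any(r > 1.2):
            raise ValueError("recoveries must lie in (0, 1.2]")

    def recovery_at(self, volume_cm3: float) -> Recovery:
        """Piecewise-linear interpolation in log-volume, clamped at the ends."""
        if volume_cm3 <= 0:
            raise ValueError("volume must be > 0")
        v = np.asarray(self.volumes_cm3)
        r = np.asarray(self.recoveries)
        if volume_cm3 < v[0]:
            return Recovery(float(r[0]), True)
        if volume_cm3 > v[-1]:
            return Recovery(float(r[-1]), True)
        return Recovery(float(np.interp(math.log(volume_cm3), np.log(v), r)), False)

    def monotone_fit(self) -> "RecoveryCurve":
        """A view with recoveries replaced by their running maximum.

        Useful when a noisy measured curve must be forced non-decreasing
        with volume before clinical use.
        """
        return RecoveryCurve(
            self.volumes_cm3, tuple(np.maximum.accumulate(self.recoveries))
        )


@dataclass(frozen=True)
class VOIMeasurement:
    """Counts in a VOI over a source region at one time point."""

    counts: float
    duration_s: float
    volume_cm3: float
    time_post_admin_h: float

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise ValueError("counts must be >= 0")
        if self.duration_s <= 0 or self.volume_cm3 <= 0:
            raise ValueError("duration and volume must be > 0")

    @property
    def count_rate_cps(self) -> float:
        return self.counts / self.duration_s


def activity_from_voi(
    m: VOIMeasurement, cal: SpectCalibration, curve: RecoveryCurve
) -> float:
    """A = C / (Q_sp × R(v)) in MBq, with R interpolated at the VOI volume."""
    rec = curve.recovery_at(m.volume_cm3)
    if rec.value <= 0:
        raise ValueError("recovery must be > 0")
    return m.count_rate_cps / (cal.q_sp_cps_per_MBq * rec.value)


@dataclass(frozen=True)
class ConjugateViewPair:
    """Anterior/posterior count rates over a source region.

    ``thickness_cm`` is the patient thickness L at the source location and
    ``mu_per_cm`` the (effective) attenuation coefficient; optional
    background rates are subtracted before quantification.
    """

    c_ant_cps: float
    c_post_cps: float
    thickness_cm: float
    mu_per_cm: float = MU_EFF_208KEV_PER_CM
    background_ant_cps: float = 0.0
    background_post_cps: float = 0.0

    def __post_init__(self) -> None:
        if self.c_ant_cps < 0 or self.c_post_cps < 0:
            raise ValueError("count rates must be >= 0")
        if self.thickness_cm < 0 or self.mu_per_cm < 0:
            raise ValueError("thickness and mu must be >= 0")


def conjugate_view_activity(pair: ConjugateViewPair, cal: PlanarCalibration) -> float:
    """Geometric-mean planar activity A = √(C_A·C_P) · e^{μL/2} / Q_pl.

    Backgrounds, when present, are subtracted from each view first; a
    negative net rate is an error naming the offending view.  The source
    self-attenuation factor is near unity for 177Lu and omitted.
    """
    ant = pair.c_ant_cps - pair.background_ant_cps
    post = pair.c_post_cps - pair.background_post_cps
    if ant < 0:
        raise ValueError("anterior count rate negative after background subtraction")
    if post < 0:
        raise ValueError("posterior count rate negative after background subtraction")
    geo = math.sqrt(ant * post)
    atten = math.exp(pair.mu_per_cm * pair.thickness_cm / 2.0)
    return geo * atten / cal.q_pl_cps_per_MBq


class TewResult(NamedTuple):
    """TEW-corrected photopeak rate with a floor flag."""

    corrected_cps: float
    clipped: bool


def tew_scatter_correct(
    peak_counts_cps: float,
    lower_counts_cps: float,
    upper_counts_cps: float,
    peak_width_keV: float,
    lower_width_keV: float,
    upper_width_keV: float,
) -> TewResult:
    """Triple-energy-window scatter correction.

    The scatter inside the photopeak window is estimated by the trapezoid
    spanned by the two flanking narrow windows:
    ``scatter = (C_low/w_low + C_up/w_up) × w_peak / 2``.  The corrected
    rate is floored at zero (``clipped=True`` when the floor engaged).
    Window widths are acquisition settings and must be supplied.
    """
    for w in (peak_width_keV, lower_width_keV, upper_width_keV):
        if w <= 0:
            raise ValueError("window widths must be > 0")
    for c in (peak_counts_cps, lower_counts_cps, upper_counts_cps):
        if c < 0:
            raise ValueError("counts must be >= 0")
    scatter = (
        lower_counts_cps / lower_width_keV + upper_counts_cps / upper_width_keV
    ) * peak_width_keV / 2.0
    corrected = peak_counts_cps - scatter
    if corrected < 0:
        return TewResult(0.0, True)
    return TewResult(corrected, False)


def hybrid_rescale(
    planar_tac: TimeActivityCurve,
    anchor_time_h: float,
    anchor_activity_MBq: float,
) -> TimeActivityCurve:
    """Rescale a relative planar TAC to an absolute SPECT anchor.

    The planar curve supplies the shape; the SPECT measurement at
    ``anchor_time_h`` supplies the amplitude.  Ratios between time points
    are preserved exactly.  An anchor between samples uses log-linear
    interpolation of the planar value (exact for exponential washout).
    """
    if anchor_activity_MBq <= 0:
        raise ValueError("anchor activity must be > 0")
    t, a = planar_tac.t, planar_tac.a
    if not (t[0] <= anchor_time_h <= t[-1]):
        raise ValueError(
            f"anchor time {anchor_time_h} h outside planar sampling "
            f"[{t[0]}, {t[-1]}] h"
        )
    idx = np.searchsorted(t, anchor_time_h)
    if idx < t.size and t[idx] == anchor_time_h:
        planar_value = a[idx]
    else:
        lo, hi = idx - 1, idx
        if a[lo] <= 0 or a[hi] <= 0:
            raise ValueError("log-linear interpolation requires positive samples")
        frac = (anchor_time_h - t[lo]) / (t[hi] - t[lo])
        planar_value = math.exp(
            (1 - frac) * math.log(a[lo]) + frac * math.log(a[hi])
        )
    if planar_value <= 0:
        raise ValueError("planar value at anchor must be > 0")
    return planar_tac.scaled(anchor_activity_MBq / planar_value)


@dataclass(frozen=True)
class DeadTimeResponse:
    """Measured count-rate response: true rate → observed rate.

    No parametric (e.g. paralyzable) model is assumed; the measured curve is
    inverted by monotone interpolation.  Observed rates outside the
    characterised range are refused rather than extrapolated.
    """

    true_rates_cps: tuple[float, ...]
    observed_rates_cps: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.true_rates_cps, dtype=float)
        o = np.asarray(self.observed_rates_cps, dtype=float)
        if t.size != o.size or t.size < 2:
            raise ValueError("response needs >= 2 (true, observed) pairs")
        if np.any(np.diff(t) <= 0) or np.any(np.diff(o) <= 0):
            raise ValueError("response must be strictly increasing")

    def correct(self, observed_rate_cps: float) -> float:
        """Invert the response: observed → true count rate."""
        o = np.asarray(self.observed_rates_cps)
        t = np.asarray(self.true_rates_cps)
        if not (o[0] <= observed_rate_cps <= o[-1]):
            raise ValueError(
                f"observed rate {observed_rate_cps} cps outside characterised "
                f"range [{o[0]}, {o[-1]}] cps; no extrapolation"
            )
        return float(np.interp(observed_rate_cps, o, t))


def deadtime_correct(
    observed_rate_cps: float, response: DeadTimeResponse | None = None
) -> float:
    """Dead-time-correct an observed rate; identity when no response given."""
    if observed_rate_cps < 0:
        raise ValueError("observed rate must be >= 0")
    if response is None:
        return observed_rate_cps
    return response.correct(observed_rate_cps)
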