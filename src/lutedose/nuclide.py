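"""Radionuclide constants and decay arithmetic for 177Lu dosimetry.

The quantities that matter for absorbed-dose work with a beta/gamma emitter
such as 177Lu are the physical half-life and the mean energy emitted per
decay, split into an electron channel (beta particles, conversion and Auger
electrons; deposited locally on the organ scale) and a photon channel
(gamma rays and X-rays; largely escaping small regions).  Different
evaluated nuclear-data compilations disagree at the half-percent level, so
datasets carry a provenance label and several compilations are packaged.

Canonical units throughout the package: hours, MBq, gram, mGy, mJ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml

__all__ = [
    "NuclideDataset",
    "LU177_HALF_LIFE_H",
    "KEV_PER_DECAY_TO_MJ_PER_MBQ_H",
    "ICRP107",
    "OLINDA",
    "NUDAT2",
    "get_dataset",
    "register_dataset",
    "available_datasets",
    "decay_constant",
    "delta_to_energy_per_tia",
    "dataset_ratio",
]

#: 177Lu physical half-life, hours (6.647 days).
LU177_HALF_LIFE_H = 6.647 * 24.0

#: Exact SI conversion: 1 keV = 1.602176634e-16 J = 1.602176634e-13 mJ.
_KEV_TO_MJ = 1.602176634e-13
#: Decays per MBq·h: 1e6 decays/s per MBq times 3600 s.
_DECAYS_PER_MBQ_H = 3.6e9
#: Combined factor: keV per decay -> mJ per MBq·h of time-integrated activity.
KEV_PER_DECAY_TO_MJ_PER_MBQ_H = _KEV_TO_MJ * _DECAYS_PER_MBQ_H


@dataclass(frozen=True)
class NuclideDataset:
    """One radionuclide data compilation.

    Parameters
    ----------
    name:
        Provenance label, e.g. ``"ICRP107"`` or ``"NuDat2"``.
    half_life_h:
        Physical half-life in hours.
    delta_e_keV:
        Mean electron (beta + conversion + Auger) energy per decay, keV.
    delta_ph_keV:
        Mean photon (gamma + X-ray) energy per decay, keV.
    """

    name: str
    half_life_h: float
    delta_e_keV: float
    delta_ph_keV: float

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError(f"half_life_h must be > 0, got {self.half_life_h}")
        if self.delta_e_keV <= 0:
            raise ValueError(f"delta_e_keV must be > 0, got {self.delta_e_keV}")
        if self.delta_ph_keV <= 0:
            raise ValueError(f"delta_ph_keV must be > 0, got {self.delta_ph_keV}")

    @property
    def delta_e_mJ_per_MBq_h(self) -> float:
        """Electron energy per unit TIA, mJ MBq^-1 h^-1."""
        return delta_to_energy_per_tia(self.delta_e_keV)

    @property
    def delta_ph_mJ_per_MBq_h(self) -> float:
        """Photon energy per unit TIA, mJ MBq^-1 h^-1."""
        return delta_to_energy_per_tia(self.delta_ph_keV)

    def to_config(self, path: str | Path) -> None:
        """Write the dataset to a flat key-value YAML file."""
        data = {
            "name": self.name,
            "half_life_h": float(self.half_life_h),
            "delta_e_keV": float(self.delta_e_keV),
            "delta_ph_keV": float(self.delta_ph_keV),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_config(cls, path: str | Path) -> "NuclideDataset":
        """Read a dataset from a flat key-value YAML file."""
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            name=str(data["name"]),
            half_life_h=float(data["half_life_h"]),
            delta_e_keV=float(data["delta_e_keV"]),
            delta_ph_keV=float(data["delta_ph_keV"]),
        )


# Packaged 177Lu compilations.  Electron/photon energies per decay as printed
# by the respective sources; all share the 6.647 d half-life.
ICRP107 = NuclideDataset("ICRP107", LU177_HALF_LIFE_H, 147.9, 35.1)
OLINDA = NuclideDataset("Olinda", LU177_HALF_LIFE_H, 147.2, 35.1)
NUDAT2 = NuclideDataset("NuDat2", LU177_HALF_LIFE_H, 147.1, 33.4)

_REGISTRY: dict[str, NuclideDataset] = {
    d.name: d for d in (ICRP107, OLINDA, NUDAT2)
}


def get_dataset(name: str) -> NuclideDataset:
    """Look up a registered dataset by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown nuclide dataset {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def register_dataset(dataset: NuclideDataset) -> None:
    """Register a user-supplied dataset (overwrites an existing name)."""
    _REGISTRY[dataset.name] = dataset


def available_datasets() -> list[str]:
    return sorted(_REGISTRY)


def decay_constant(dataset: NuclideDataset) -> float:
    """Physical decay constant, 1/h: ln(2) / half-life."""
    if dataset.half_life_h <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / dataset.half_life_h


def delta_to_energy_per_tia(delta_keV: float) -> float:
    """Convert mean energy per decay (keV) to energy per unit TIA.

    Returns mJ MBq^-1 h^-1.  The conversion is linear:
    ``delta × 1.602176634e-13 mJ/keV × 3.6e9 decays/(MBq·h)``.
    """
    if delta_keV < 0:
        raise ValueError(f"delta must be >= 0, got {delta_keV}")
    return delta_keV * KEV_PER_DECAY_TO_MJ_PER_MBQ_H


def dataset_ratio(
    a: NuclideDataset,
    b: NuclideDataset,
    channel: Literal["electron", "photon"],
) -> float:
    """Percent difference of dataset *a* relative to *b* in one channel.

    Returns ``100 × (value_a − value_b) / value_b``.
    """
    if channel == "electron":
        va, vb = a.delta_e_keV, b.delta_e_keV
    elif channel == "photon":
        va, vb = a.delta_ph_keV, b.delta_ph_keV
    else:
        raise ValueError(f"channel must be 'electron' or 'photon', got {channel!r}")
    if vb == 0:
        raise ValueError("reference dataset has zero value in this channel")
    return 100.0 * (va - vb) / vb
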