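"""Kinetic rate constants of the PD-1/TCR/CD28 signaling model.

The model carries 36 constants: 14 second-order rate constants in
(nM s)^-1 (kinase/phosphatase catalysis modeled as mass action, plus
association steps), 16 first-order rate constants in s^-1
(auto-phosphorylation, dissociation, and the Michaelis-Menten catalytic
rates), 5 Michaelis constants in nM, and one dimensionless constant used
in the saturation correction for PD-1 phosphorylation.

Parameter names flatten the conventional subscript notation, e.g. the
rate of dephosphorylation of Y394 from doubly phosphorylated Lck is
``k_dpa_yiya``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "PARAMETER_NAMES",
    "RateParameters",
    "load_parameters",
    "save_parameters",
]


@dataclass(frozen=True)
class RateParameters:
    """The 36 kinetic constants of the signaling model.

    Defaults are the calibrated values of the model. All constants must
    be strictly positive; perturbation switches produce modified copies
    with selected constants zeroed (see :func:`pd1tcr.scenarios.apply_flags`),
    which is the one sanctioned exception to positivity.
    """

    # -- second-order rate constants, (nM s)^-1 -------------------------
    k_dpa_yiya: float = 2.4e-5  # CP removes pY394 from Lck_yiya
    k_dpi_yi: float = 2.4e-5    # CP removes pY505 from Lck_yi
    k_dpi_yiya: float = 1.2e-5  # CP removes pY505 from Lck_yiya
    k_dpa_ya: float = 6e-6      # CP removes pY394 from Lck_ya
    k_dpa_pi: float = 1.2e-7    # CP removes pY394 from Lck_pi
    k_a_zap: float = 7e-5       # Zap70 binding to phospho-CD3zeta
    k_p1_zap: float = 2e-6      # Lck phosphorylates Zap70 Y315
    k_p2_zap: float = 3e-5      # Lck phosphorylates Zap70 Y493
    k_p_lat: float = 1e-3       # active Zap70 phosphorylates LAT
    k_a_slp: float = 1.5e-2     # Slp76 binding to LAT-Gads
    k_p_slp: float = 3e-3       # active Zap70 phosphorylates bound Slp76
    k_a_gads: float = 5e-4      # Gads binding to phospho-LAT
    k_a_pi3k: float = 1.4e-6    # PI3K binding to phospho-CD28
    k_a_shp: float = 6.5e-3     # Shp2 binding to phospho-PD-1

    # -- first-order rate constants, s^-1 -------------------------------
    k_pi_i: float = 6e-7        # auto-phosphorylation of Y505 on Lck_i
    k_pi_ya: float = 6e-5       # auto-phosphorylation of Y505 on Lck_ya
    k_pa_i: float = 1e-6        # auto-phosphorylation of Y394 on Lck_i
    k_pa_yi: float = 7.5e-4     # auto-phosphorylation of Y394 on Lck_yi
    k_p_cd3: float = 3.29       # Lck on CD3zeta (MM catalytic rate)
    k_dp_cd3: float = 5.0       # CP on phospho-CD3zeta (MM catalytic rate)
    k_d_zap: float = 1e-3       # Zap70 dissociation from CD3zeta
    k_d_slp: float = 0.12       # Slp76 dissociation from LAT-Gads
    k_d_gads: float = 1.5       # Gads dissociation from LAT
    k_p_cd28: float = 1.0       # Lck on CD28 (MM catalytic rate)
    k_dp_cd28: float = 5.0      # CP on phospho-CD28 (MM catalytic rate)
    k_d_pi3k: float = 9e-4      # PI3K dissociation from CD28
    k_p_pd1: float = 7.5        # Lck on PD-1 (MM catalytic rate)
    k_d1_shp: float = 10.0      # CP1/CP2 dissociation (intact PD-1 phosphosite)
    k_dp_cp2: float = 5e-8      # CP2 self-dephosphorylation to CP1
    k_d2_shp: float = 1.0       # CP dissociation via self-dephosphorylation

    # -- Michaelis constants, nM ----------------------------------------
    KM_p_cd3: float = 80.0
    KM_dp_cd3: float = 150.0
    KM_p_cd28: float = 1000.0
    KM_dp_cd28: float = 500.0
    KM_p_pd1: float = 1000.0

    # -- dimensionless ---------------------------------------------------
    k_corr: float = 41.0        # constant of the PD-1 phosphorylation correction

    def __post_init__(self) -> None:
        for name, value in self.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")

    # -- mapping-style access -------------------------------------------
    def items(self) -> Iterator[tuple[str, float]]:
        for name in PARAMETER_NAMES:
            yield name, getattr(self, name)

    def __getitem__(self, name: str) -> float:
        if name not in PARAMETER_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def replace(self, **changes: float) -> "RateParameters":
        """Return a copy with the given constants replaced."""
        return dataclasses.replace(self, **changes)

    def to_array(self) -> np.ndarray:
        """Pack constants into a float64 vector in canonical order."""
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "RateParameters":
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(PARAMETER_NAMES),):
            raise ValueError(f"expected {len(PARAMETER_NAMES)} values, got shape {values.shape}")
        return cls(**dict(zip(PARAMETER_NAMES, values.tolist())))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "RateParameters":
        unknown = set(mapping) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


PARAMETER_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(RateParameters)
)


def load_parameters(path: str | Path | None = None) -> RateParameters:
    """Read a parameter set from a flat key-value YAML file.

    With ``path=None`` the packaged default set is loaded; it is identical
    to the in-code defaults and ships so that parameter files can be
    derived from it by editing.
    """
    if path is None:
        text = resources.files("pd1tcr.data").joinpath("default_parameters.yaml").read_text()
    else:
        text = Path(path).read_text()
    mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise ValueError("parameter file must be a flat key-value mapping")
    return RateParameters.from_mapping(mapping)


def save_parameters(params: RateParameters, path: str | Path) -> None:
    """Write a parameter set as a flat key-value YAML file."""
    with open(path, "w") as fh:
        for name, value in params.items():
            fh.write(f"{name}: {value!r}\n")
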