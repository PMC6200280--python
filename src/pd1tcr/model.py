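"""State, pools, perturbation switches and the ODE right-hand side.

The model tracks 20 time-varying species (nM) of the proximal T-cell
signaling network downstream of already-ligated TCR/CD3zeta, CD28 and
PD-1 cytoplasmic domains:

* receptor tails: phosphorylated CD3zeta (``cd3a``) and CD28 (``cd28a``);
* the PD-1/Shp2 axis: ligated PD-1 in un-, singly and doubly
  phosphorylated form, free Shp2, and the catalytically active
  Shp2-PD-1 complexes CP1 and CP2;
* five phosphoforms of the kinase Lck distinguished by the order of
  phosphorylation of its activating (Y394) and inhibitory (Y505)
  tyrosines — only ``lck_ya`` and ``lck_yiya`` are catalytically active;
* the Zap70 activation ladder on CD3zeta (bound, pY315, pY315+pY493);
* the LAT/Gads/Slp76 adaptor cascade and CD28-bound PI3K.

Unphosphorylated/unbound pools are not integrated; they are eliminated
through conservation relations, so the corresponding totals are
conserved exactly by construction. Receptor (de)phosphorylation follows
Michaelis-Menten kinetics, everything else mass action. Dephosphorylation
is catalysed exclusively by PD-1-bound Shp2 (CP1 + CP2); free Shp2 is
catalytically inert.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _kernel
from .parameters import RateParameters

__all__ = [
    "SPECIES_NAMES",
    "POOL_NAMES",
    "READOUT_NAMES",
    "SpeciesState",
    "TotalPools",
    "PerturbationFlags",
    "DerivedReadouts",
    "correction_factor",
    "rhs",
    "readouts",
]

SPECIES_NAMES: tuple[str, ...] = (
    "cd3a", "cd28a", "pd1", "pd1p1", "pd1p2", "shp2_free", "cp1", "cp2",
    "lck_yiya", "lck_yi", "lck_ya", "lck_pi",
    "zap70i", "zap70a1", "zap70a2",
    "lata", "slp76i", "slp76a", "gadsa", "pi3kb",
)

POOL_NAMES: tuple[str, ...] = (
    "cd3T", "cd28T", "zap70T", "pi3kT", "lckT",
    "latT", "gadsT", "slp76T", "shp2T", "pd1T",
)

# Undershoot below this magnitude is treated as zero; anything more
# negative indicates a genuinely invalid state.
NEGATIVITY_TOLERANCE = 1e-9


def _vector_dataclass_array(obj, names: tuple[str, ...]) -> np.ndarray:
    return np.array([getattr(obj, n) for n in names], dtype=np.float64)


@dataclass(frozen=True)
class TotalPools:
    """Conserved total concentrations (nM) of the eight protein pools
    plus the implied PD-1 and Shp2 totals fixed by initial conditions."""

    cd3T: float = 0.0
    cd28T: float = 0.0
    zap70T: float = 0.0
    pi3kT: float = 0.0
    lckT: float = 0.0
    latT: float = 0.0
    gadsT: float = 0.0
    slp76T: float = 0.0
    shp2T: float = 0.0
    pd1T: float = 0.0

    def __post_init__(self) -> None:
        for name in POOL_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"pool {name} must be finite and >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return _vector_dataclass_array(self, POOL_NAMES)

    def replace(self, **changes: float) -> "TotalPools":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (nM) of the 20 integrated species."""

    cd3a: float = 0.0
    cd28a: float = 0.0
    pd1: float = 0.0
    pd1p1: float = 0.0
    pd1p2: float = 0.0
    shp2_free: float = 0.0
    cp1: float = 0.0
    cp2: float = 0.0
    lck_yiya: float = 0.0
    lck_yi: float = 0.0
    lck_ya: float = 0.0
    lck_pi: float = 0.0
    zap70i: float = 0.0
    zap70a1: float = 0.0
    zap70a2: float = 0.0
    lata: float = 0.0
    slp76i: float = 0.0
    slp76a: float = 0.0
    gadsa: float = 0.0
    pi3kb: float = 0.0

    def to_array(self) -> np.ndarray:
        return _vector_dataclass_array(self, SPECIES_NAMES)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "SpeciesState":
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(SPECIES_NAMES),):
            raise ValueError(f"expected {len(SPECIES_NAMES)} species, got {values.shape}")
        return cls(**dict(zip(SPECIES_NAMES, values.tolist())))

    def replace(self, **changes: float) -> "SpeciesState":
        return dataclasses.replace(self, **changes)

    def validate(self, pools: TotalPools | None = None, tol: float = 1e-6) -> None:
        """Raise ``ValueError`` on negative fields or pool-bound breaches."""
        arr = self.to_array()
        if np.any(arr < -NEGATIVITY_TOLERANCE):
            bad = [n for n, v in zip(SPECIES_NAMES, arr) if v < -NEGATIVITY_TOLERANCE]
            raise ValueError(f"negative species concentration(s): {bad}")
        if pools is None:
            return
        bounds = {
            "cd3T": self.cd3a + self.zap70i + self.zap70a1 + self.zap70a2,
            "cd28T": self.cd28a + self.pi3kb,
            "zap70T": self.zap70i + self.zap70a1 + self.zap70a2,
            "pi3kT": self.pi3kb,
            "lckT": self.lck_yiya + self.lck_yi + self.lck_ya + self.lck_pi,
            "latT": self.lata + self.gadsa + self.slp76i + self.slp76a,
            "gadsT": self.gadsa + self.slp76i + self.slp76a,
            "slp76T": self.slp76i + self.slp76a,
        }
        for pool_name, used in bounds.items():
            total = getattr(pools, pool_name)
            if used > total + tol:
                raise ValueError(
                    f"species bound to pool {pool_name} exceed its total: {used} > {total}"
                )


@dataclass(frozen=True)
class PerturbationFlags:
    """Switches reproducing the model's knockout/reconstitution protocols.

    Each boolean enables one catalytic route; switching it off zeroes the
    corresponding rate constants (see :func:`pd1tcr.scenarios.apply_flags`):

    * ``shp2_receptor_catalysis`` — CP dephosphorylation of CD3zeta/CD28;
    * ``shp2_lck_catalysis`` — all five CP-mediated Lck dephosphorylations;
    * ``pd1_self_dephosphorylation`` — CP self-dephosphorylation routes;
    * ``pd1_phosphorylation`` — Lck phosphorylation of PD-1.

    ``clamp_cp2`` (nM, optional) freezes CP2 at a constant value with its
    exchange fluxes disabled, emulating a membrane-tethered Shp2 pool.
    """

    shp2_receptor_catalysis: bool = True
    shp2_lck_catalysis: bool = True
    pd1_self_dephosphorylation: bool = True
    pd1_phosphorylation: bool = True
    clamp_cp2: float | None = None

    def __post_init__(self) -> None:
        if self.clamp_cp2 is not None and self.clamp_cp2 < 0:
            raise ValueError("clamp_cp2 must be >= 0 when set")


READOUT_NAMES: tuple[str, ...] = (
    "lck_active", "cp_active", "phospho_cd3", "phospho_cd28",
    "zap70_pY315", "zap70_pY493", "lck_pY505", "lck_pY394",
    "phospho_lat", "phospho_slp76",
    "pct_bound_shp2", "pct_bound_pi3k", "pct_bound_zap70", "pct_active_lck",
)


@dataclass(frozen=True)
class DerivedReadouts:
    """Aggregate observables derived from one state.

    The phospho-aggregates are the sums reported by the reconstitution
    assays (e.g. phosphorylated CD3zeta counts every species built on a
    phosphorylated CD3zeta tail). Percentages are relative to the
    corresponding total pool; they are NaN when that pool is empty and
    :meth:`require` turns NaN into an explicit error.
    """

    lck_active: float
    cp_active: float
    phospho_cd3: float
    phospho_cd28: float
    zap70_pY315: float
    zap70_pY493: float
    lck_pY505: float
    lck_pY394: float
    phospho_lat: float
    phospho_slp76: float
    pct_bound_shp2: float
    pct_bound_pi3k: float
    pct_bound_zap70: float
    pct_active_lck: float

    def __getitem__(self, name: str) -> float:
        if name not in READOUT_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def require(self, name: str) -> float:
        """Return a readout, raising if it is undefined (empty pool)."""
        value = self[name]
        if np.isnan(value):
            raise ValueError(f"readout {name} is undefined: its total pool is zero")
        return value

    def as_dict(self) -> Mapping[str, float]:
        return {n: getattr(self, n) for n in READOUT_NAMES}


def correction_factor(pd1p1: float, pd1p2: float, lckT: float, k_corr: float) -> float:
    """Saturation correction for the first PD-1 phosphorylation step.

    Shp2 recruitment to PD-1 saturates at high PD-1 dose; the model
    captures this phenomenologically by scaling the phosphorylation flux
    of unphosphorylated PD-1 with ``1 - (PD1p1 + PD1p2) / (lckT * k)``,
    clamped at zero from below so the flux can never turn negative. The
    factor applies only to the PD1 -> PD1p1 step, not to PD1p1 -> PD1p2.
    """
    if pd1p1 < 0 or pd1p2 < 0:
        raise ValueError("phosphorylated PD-1 concentrations must be >= 0")
    if k_corr <= 0:
        raise ValueError("k_corr must be > 0")
    if lckT <= 0:
        raise ValueError(
            "correction factor undefined for lckT = 0; with no Lck the "
            "PD-1 phosphorylation flux is identically zero"
        )
    return max(0.0, 1.0 - (pd1p1 + pd1p2) / (lckT * k_corr))


def rhs(
    state: SpeciesState,
    pools: TotalPools,
    params: RateParameters,
    flags: PerturbationFlags | None = None,
) -> SpeciesState:
    """Evaluate the 20 time derivatives (nM/s) at one state.

    Perturbation switches are honoured by zeroing the corresponding rate
    constants before evaluation; ``clamp_cp2`` is forwarded to the kernel.
    Raises on negative state fields (beyond integrator undershoot) and on
    non-finite derivatives.
    """
    from .scenarios import apply_flags  # deferred: scenarios imports model

    state.validate()
    if flags is not None:
        params = apply_flags(params, flags)
        clamp = flags.clamp_cp2 is not None
        clamp_value = flags.clamp_cp2 if clamp else 0.0
    else:
        clamp, clamp_value = False, 0.0
    out = np.empty(len(SPECIES_NAMES))
    _kernel.rhs_kernel(
        state.to_array(), pools.to_array(), params.to_array(), clamp, clamp_value, out
    )
    if not np.all(np.isfinite(out)):
        bad = [n for n, v in zip(SPECIES_NAMES, out) if not np.isfinite(v)]
        raise ArithmeticError(f"non-finite derivative(s) in equation(s) for: {bad}")
    return SpeciesState.from_array(out)


def readouts(state: SpeciesState, pools: TotalPools) -> DerivedReadouts:
    """Compute all aggregate observables for one state."""
    state.validate()

    def pct(part: float, total: float) -> float:
        return 100.0 * part / total if total > 0 else float("nan")

    lck_active = state.lck_yiya + state.lck_ya
    return DerivedReadouts(
        lck_active=lck_active,
        cp_active=state.cp1 + state.cp2,
        phospho_cd3=state.cd3a + state.zap70i + state.zap70a1 + state.zap70a2,
        phospho_cd28=state.cd28a + state.pi3kb,
        zap70_pY315=state.zap70a1 + state.zap70a2,
        zap70_pY493=state.zap70a2,
        lck_pY505=state.lck_yi + state.lck_yiya + state.lck_pi,
        lck_pY394=state.lck_ya + state.lck_yiya + state.lck_pi,
        phospho_lat=state.lata + state.gadsa + state.slp76i + state.slp76a,
        phospho_slp76=state.slp76a,
        pct_bound_shp2=pct(state.cp1 + state.cp2, pools.shp2T),
        pct_bound_pi3k=pct(state.pi3kb, pools.pi3kT),
        pct_bound_zap70=pct(state.zap70i + state.zap70a1 + state.zap70a2, pools.zap70T),
        pct_active_lck=pct(lck_active, pools.lckT),
    )
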