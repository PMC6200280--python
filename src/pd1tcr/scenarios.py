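"""Runnable experiment definitions and the built-in protocol catalogue.

A :class:`Scenario` bundles everything needed to integrate the model
once: total pools, rate parameters, perturbation switches, the initial
Lck phosphoform split and the simulation duration. The catalogue encodes
the liposome-reconstitution protocols the model was benchmarked against
(time-course and dose-response experiments with the cytoplasmic domains
of CD3zeta, CD28 and PD-1 tethered to vesicles), plus the perturbation
variants used to dissect Shp2 dissociation from PD-1.

Conventions for initial conditions: ligated PD-1 starts unphosphorylated
(``pd1 = pd1T``), Shp2 starts free (``shp2_free = shp2T``), Lck starts
distributed over its phosphoforms by ``lck_split`` (default 25% each of
unphosphorylated, pY394, pY505 and sequentially doubly phosphorylated
active form, none of the closed doubly phosphorylated form, matching the
proportions measured in Jurkat T cells), and everything else starts at
zero unless the protocol pre-loads a complex (``initial_overrides``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import POOL_NAMES, SPECIES_NAMES, PerturbationFlags, SpeciesState, TotalPools
from .parameters import RateParameters

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "builtin_scenario",
    "random_scenario",
    "apply_flags",
]

#: fractions of lckT assigned at t=0 to (lck_i, lck_ya, lck_yi, lck_yiya, lck_pi)
DEFAULT_LCK_SPLIT: tuple[float, float, float, float, float] = (0.25, 0.25, 0.25, 0.25, 0.0)


@dataclass(frozen=True)
class Scenario:
    """A complete, runnable in-silico experiment."""

    label: str
    pools: TotalPools
    params: RateParameters = field(default_factory=RateParameters)
    flags: PerturbationFlags = field(default_factory=PerturbationFlags)
    duration: float = 1800.0
    lck_split: tuple[float, float, float, float, float] = DEFAULT_LCK_SPLIT
    initial_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if abs(sum(self.lck_split) - 1.0) > 1e-12:
            raise ValueError("lck_split fractions must sum to 1")
        if any(f < 0 for f in self.lck_split):
            raise ValueError("lck_split fractions must be >= 0")
        unknown = set(self.initial_overrides) - set(SPECIES_NAMES)
        if unknown:
            raise KeyError(f"unknown species in initial_overrides: {sorted(unknown)}")

    @property
    def initial_state(self) -> SpeciesState:
        """Initial species concentrations implied by pools and overrides."""
        f_i, f_ya, f_yi, f_yiya, f_pi = self.lck_split
        del f_i  # unphosphorylated Lck is a conserved remainder, not integrated
        values = dict.fromkeys(SPECIES_NAMES, 0.0)
        values["pd1"] = self.pools.pd1T
        values["shp2_free"] = self.pools.shp2T
        values["lck_ya"] = f_ya * self.pools.lckT
        values["lck_yi"] = f_yi * self.pools.lckT
        values["lck_yiya"] = f_yiya * self.pools.lckT
        values["lck_pi"] = f_pi * self.pools.lckT
        values.update(self.initial_overrides)
        if self.flags.clamp_cp2 is not None:
            values["cp2"] = self.flags.clamp_cp2
        state = SpeciesState(**values)
        state.validate(self.pools)
        return state

    def replace(self, **changes) -> "Scenario":
        return dataclasses.replace(self, **changes)

    def with_pools(self, **pool_changes: float) -> "Scenario":
        """Copy with pool totals replaced (initial state follows)."""
        return self.replace(pools=self.pools.replace(**pool_changes))


def apply_flags(params: RateParameters, flags: PerturbationFlags) -> RateParameters:
    """Return a copy of ``params`` with switched-off routes zeroed.

    * ``shp2_lck_catalysis`` off: the five CP-mediated Lck
      dephosphorylation constants become 0;
    * ``pd1_self_dephosphorylation`` off: ``k_dp_cp2`` and ``k_d2_shp``
      become 0 (CP complexes no longer self-dephosphorylate PD-1);
    * ``shp2_receptor_catalysis`` off: ``k_dp_cd3`` and ``k_dp_cd28``
      become 0;
    * ``pd1_phosphorylation`` off: ``k_p_pd1`` becomes 0.
    """
    changes: dict[str, float] = {}
    if not flags.shp2_lck_catalysis:
        changes.update(
            k_dpa_yiya=0.0, k_dpi_yi=0.0, k_dpi_yiya=0.0, k_dpa_ya=0.0, k_dpa_pi=0.0
        )
    if not flags.pd1_self_dephosphorylation:
        changes.update(k_dp_cp2=0.0, k_d2_shp=0.0)
    if not flags.shp2_receptor_catalysis:
        changes.update(k_dp_cd3=0.0, k_dp_cd28=0.0)
    if not flags.pd1_phosphorylation:
        changes.update(k_p_pd1=0.0)
    if not changes:
        return params
    return dataclasses.replace(params, **changes)


def _fig3_pools(**overrides: float) -> TotalPools:
    base = dict(
        cd3T=100.0, lckT=100.0, pi3kT=200.0,
        cd28T=300.0, zap70T=300.0, shp2T=300.0,
        latT=300.0, gadsT=300.0, slp76T=300.0,
        pd1T=0.0,
    )
    base.update(overrides)
    return TotalPools(**base)


def _catalogue() -> dict[str, Scenario]:
    # Binding-domain-only Shp2: association/dissociation without any
    # catalysis; PD-1 dose is the scanned variable (default 100 nM).
    fig2a = Scenario(
        label="fig2a",
        pools=TotalPools(lckT=7.2, shp2T=100.0, pd1T=100.0),
        flags=PerturbationFlags(
            shp2_receptor_catalysis=False,
            shp2_lck_catalysis=False,
            pd1_self_dephosphorylation=False,
        ),
    )
    # Full-length Shp2, all catalysis active; Lck is the scanned variable.
    fig2b = Scenario(
        label="fig2b",
        pools=TotalPools(lckT=100.0, shp2T=50.0, pd1T=300.0),
    )
    # Zap70 vs PI3K recruitment kinetics without PD-1.
    fig2c = Scenario(
        label="fig2c",
        pools=TotalPools(
            cd3T=800.0, cd28T=800.0, zap70T=300.0, pi3kT=300.0, lckT=100.0
        ),
    )
    # Disengagement kinetics: receptors start fully phosphorylated and
    # occupied, no Lck, membrane-tethered Shp2 modeled as clamped CP2.
    fig2d = Scenario(
        label="fig2d",
        pools=TotalPools(
            cd3T=300.0, cd28T=300.0, zap70T=300.0, pi3kT=300.0,
            shp2T=200.0, pd1T=200.0,
        ),
        flags=PerturbationFlags(clamp_cp2=200.0),
        initial_overrides={
            "cd3a": 0.0, "cd28a": 0.0, "zap70i": 300.0, "pi3kb": 300.0,
            "shp2_free": 0.0, "pd1": 0.0,
        },
    )
    # Effect of PD-1 on PI3K / Zap70 recruitment kinetics.
    fig2ef = Scenario(
        label="fig2ef",
        pools=TotalPools(
            cd3T=50.0, zap70T=300.0, cd28T=250.0, pi3kT=500.0,
            lckT=300.0, pd1T=100.0, shp2T=100.0,
        ),
    )
    # Dose-response base: PD-1 is scanned starting from 0.
    fig3_base = Scenario(label="fig3_base", pools=_fig3_pools())
    # 2-D Lck x PD-1 scan of Shp2 recruitment, 300 nM Shp2.
    fig4 = Scenario(label="fig4", pools=_fig3_pools(shp2T=300.0, pd1T=300.0))
    # 300 nM PD-1 and Shp2; Lck x substrate scans.
    fig5 = Scenario(label="fig5", pools=_fig3_pools(shp2T=300.0, pd1T=300.0))
    # PD-1 x substrate scans with 300 nM Shp2 and 100 nM Lck.
    fig6 = Scenario(label="fig6", pools=_fig3_pools(shp2T=300.0, lckT=100.0, pd1T=300.0))
    # Active/inactive Lck balance with 300 nM PD-1.
    fig7 = Scenario(label="fig7", pools=_fig3_pools(pd1T=300.0))
    # Shp2 dissociation dissection: no CP-mediated Lck dephosphorylation.
    fig8a = Scenario(
        label="fig8a",
        pools=_fig3_pools(lckT=100.0, shp2T=300.0, pd1T=300.0),
        flags=PerturbationFlags(shp2_lck_catalysis=False),
    )
    # Shp2 dissociation dissection: no PD-1 self-dephosphorylation.
    fig8b = Scenario(
        label="fig8b",
        pools=_fig3_pools(lckT=100.0, shp2T=300.0, pd1T=300.0),
        flags=PerturbationFlags(pd1_self_dephosphorylation=False),
    )
    return {
        s.label: s
        for s in (
            fig2a, fig2b, fig2c, fig2d, fig2ef, fig3_base,
            fig4, fig5, fig6, fig7, fig8a, fig8b,
        )
    }


_CATALOGUE = _catalogue()
SCENARIO_NAMES: tuple[str, ...] = tuple(_CATALOGUE)


def builtin_scenario(name: str, overrides: Mapping[str, object] | None = None) -> Scenario:
    """Fetch a catalogue scenario, optionally overriding concentrations/flags.

    ``overrides`` may contain pool names (``pd1T=300``), perturbation flag
    names (``shp2_lck_catalysis=False``, ``clamp_cp2=200``), ``duration``
    or ``lck_split``.
    """
    try:
        scenario = _CATALOGUE[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        ) from None
    if not overrides:
        return scenario
    pool_changes = {k: float(v) for k, v in overrides.items() if k in POOL_NAMES}
    flag_names = {f.name for f in dataclasses.fields(PerturbationFlags)}
    flag_changes = {k: v for k, v in overrides.items() if k in flag_names}
    rest = {
        k: v for k, v in overrides.items()
        if k not in POOL_NAMES and k not in flag_names
    }
    allowed_rest = {"duration", "lck_split", "params", "initial_overrides", "label"}
    unknown = set(rest) - allowed_rest
    if unknown:
        raise KeyError(f"unknown override keys: {sorted(unknown)}")
    if pool_changes:
        scenario = scenario.with_pools(**pool_changes)
    if flag_changes:
        scenario = scenario.replace(flags=dataclasses.replace(scenario.flags, **flag_changes))
    if rest:
        scenario = scenario.replace(**rest)
    return scenario


def random_scenario(
    seed: int,
    concentration_ranges: Mapping[str, tuple[float, float]] | None = None,
    duration: float = 1800.0,
) -> Scenario:
    """Draw a randomized scenario for testing, deterministic per seed.

    Each pool total is drawn uniformly within its ``(low, high)`` range;
    unlisted pools default to the 0-500 nM band typical of the
    reconstitution experiments. Parameters and flags stay at defaults.
    """
    default_range = (0.0, 500.0)
    ranges = dict.fromkeys(POOL_NAMES, default_range)
    if concentration_ranges:
        unknown = set(concentration_ranges) - set(POOL_NAMES)
        if unknown:
            raise KeyError(f"unknown pool names: {sorted(unknown)}")
        ranges.update(concentration_ranges)
    for name, (lo, hi) in ranges.items():
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    pools = TotalPools(
        **{name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    )
    return Scenario(label=f"random-{seed}", pools=pools, duration=duration)
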