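"""PD-1 dose-response scans, Hill fitting and 2-D concentration scans.

The dose-response protocol mirrors the reconstitution experiments: at
each PD-1 dose the full model is run for 30 minutes, the phospho-state
aggregate of each signaling molecule is recorded and normalized to its
value in the absence of PD-1. The inhibition fraction
``1 - normalized`` is then fit with the Hill function

    f(x) = k * x**n / (IC50**n + x**n)

against PD-1 surface density x (molecules/um^2, nM times 2.9), so that
IC50 is the dose of half-maximal dephosphorylation and k the maximum
inhibition reached. Fitting uses bounded nonlinear least squares with
multi-start over log-spaced IC50 initial guesses, which avoids boundary
traps on shallow curves that saturate well below 100% inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import READOUT_NAMES
from .parameters import RateParameters
from .scenarios import Scenario, builtin_scenario
from .simulate import endpoint

__all__ = [
    "NOMINAL_NM_TO_DENSITY",
    "DOSE_RESPONSE_READOUTS",
    "TABLE3_ROWS",
    "DoseResponseTable",
    "HillFitResult",
    "scan_pd1",
    "fit_hill",
    "table3",
    "scan_2d",
    "default_dose_grid",
]

#: conventional nM -> molecules/um^2 factor of the reconstitution assays
NOMINAL_NM_TO_DENSITY = 2.9

#: the eight phospho-aggregates tracked in the dose-response analysis
DOSE_RESPONSE_READOUTS: tuple[str, ...] = (
    "phospho_cd3", "phospho_cd28", "lck_pY505", "lck_pY394",
    "zap70_pY315", "zap70_pY493", "phospho_lat", "phospho_slp76",
)

#: display name per readout, in canonical reporting order
TABLE3_ROWS: tuple[tuple[str, str], ...] = (
    ("CD3zeta", "phospho_cd3"),
    ("CD28", "phospho_cd28"),
    ("Lck(Y505)", "lck_pY505"),
    ("Lck(Y394)", "lck_pY394"),
    ("Zap70(Y315)", "zap70_pY315"),
    ("Zap70(Y493)", "zap70_pY493"),
    ("LAT", "phospho_lat"),
    ("SLP76", "phospho_slp76"),
)


def default_dose_grid(n_log: int = 30, lo: float = 1.0, hi: float = 1e4) -> np.ndarray:
    """Zero plus ``n_log`` log-spaced PD-1 doses (nM) on [lo, hi].

    The upper end of 10^4 nM (~2.9e4 molecules/um^2) comfortably
    brackets the least PD-1-sensitive readouts.
    """
    return np.concatenate([[0.0], np.logspace(np.log10(lo), np.log10(hi), n_log)])


@dataclass(frozen=True)
class DoseResponseTable:
    """One readout's 30-minute response across a PD-1 dose scan."""

    readout_name: str
    doses_nM: np.ndarray
    doses_density: np.ndarray  # molecules/um^2
    raw_values: np.ndarray     # nM at the reporting time
    normalized_values: np.ndarray  # % of the zero-PD-1 value
    inhibition_values: np.ndarray  # 100 - normalized, %

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_nM": self.doses_nM,
                "dose_molecules_per_um2": self.doses_density,
                "raw_nM": self.raw_values,
                "normalized_pct": self.normalized_values,
                "inhibition_pct": self.inhibition_values,
            }
        )


@dataclass(frozen=True)
class HillFitResult:
    """Hill-function fit of one inhibition curve."""

    k_max: float     # maximum inhibition, fraction of the zero-dose signal
    n_hill: float    # steepness exponent
    ic50: float      # PD-1 molecules/um^2 at half-maximal inhibition
    residual_norm: float
    converged: bool


def scan_pd1(
    base: Scenario,
    doses_nM,
    *,
    t_end: float = 1800.0,
    readout_names: tuple[str, ...] = DOSE_RESPONSE_READOUTS,
) -> dict[str, DoseResponseTable]:
    """Run the 30-minute PD-1 dose scan and normalize each readout.

    ``doses_nM`` must include 0; the zero-dose run defines the
    normalization denominator of every curve.
    """
    doses = np.asarray(doses_nM, dtype=np.float64)
    if doses.ndim != 1 or doses.size < 2:
        raise ValueError("doses must be a 1-D sequence with at least two entries")
    if not np.any(doses == 0.0):
        raise ValueError("doses must include 0 (the normalization reference)")
    if base.pools.shp2T <= 0:
        raise ValueError("the base scenario must provide Shp2 (shp2T > 0)")
    unknown = set(readout_names) - set(READOUT_NAMES)
    if unknown:
        raise KeyError(f"unknown readouts: {sorted(unknown)}")

    values = np.empty((doses.size, len(readout_names)))
    for i, dose in enumerate(doses):
        obs = endpoint(base.with_pools(pd1T=float(dose)), t_end=t_end)
        values[i] = [getattr(obs, n) for n in readout_names]

    zero_idx = int(np.flatnonzero(doses == 0.0)[0])
    tables: dict[str, DoseResponseTable] = {}
    for j, name in enumerate(readout_names):
        denom = values[zero_idx, j]
        if denom <= 0:
            raise ValueError(f"zero-dose value of {name} is not positive; cannot normalize")
        normalized = 100.0 * values[:, j] / denom
        tables[name] = DoseResponseTable(
            readout_name=name,
            doses_nM=doses.copy(),
            doses_density=doses * NOMINAL_NM_TO_DENSITY,
            raw_values=values[:, j].copy(),
            normalized_values=normalized,
            inhibition_values=100.0 - normalized,
        )
    return tables


def _hill(x: np.ndarray, k: float, n: float, ic50: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        xn = np.where(x > 0, np.exp(n * np.log(np.maximum(x, 1e-300))), 0.0)
    return k * xn / (ic50**n + xn)


def fit_hill(doses_density, inhibition) -> HillFitResult:
    """Fit ``k * x^n / (IC50^n + x^n)`` to an inhibition-fraction curve.

    ``inhibition`` is a fraction in [0, ~1]. Requires at least four dose
    points spanning a decade. An all-zero curve is flagged as
    non-identifiable (``converged=False``) rather than raising.
    """
    x = np.asarray(doses_density, dtype=np.float64)
    y = np.asarray(inhibition, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and inhibition must be 1-D arrays of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 dose points")
    positive = x[x > 0]
    if positive.size < 2 or positive.max() / positive.min() < 10.0:
        raise ValueError("doses must span at least one decade")
    if np.any(y < -1e-9):
        raise ValueError("inhibition values must be >= 0")

    if np.all(np.abs(y) < 1e-12):
        return HillFitResult(
            k_max=0.0, n_hill=1.0, ic50=float("nan"), residual_norm=0.0, converged=False
        )

    k0 = float(np.clip(np.max(y), 1e-3, 1.2))
    lb = np.array([1e-6, 1e-6, 1.0])
    ub = np.array([1.2, 10.0, 1e5])
    best = None
    for ic50_guess in np.logspace(
        np.log10(max(positive.min(), lb[2])), np.log10(min(positive.max(), ub[2])), 5
    ):
        p0 = np.clip(np.array([k0, 1.0, ic50_guess]), lb, ub)
        res = least_squares(
            lambda p: _hill(x, *p) - y, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    k, n, ic50 = best.x
    return HillFitResult(
        k_max=float(k),
        n_hill=float(n),
        ic50=float(ic50),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
    )


def table3(
    params: RateParameters | None = None,
    *,
    base: Scenario | None = None,
    doses_nM=None,
) -> pd.DataFrame:
    """Hill coefficients and IC50s of the eight PD-1 dose-response curves.

    Runs the standard dose scan on the benchmark concentration set
    (100 nM Lck and CD3zeta; 200 nM PI3K; 300 nM CD28, Zap70, Shp2, LAT,
    Gads, SLP76), fits each inhibition curve, and reports IC50 in PD-1
    molecules/um^2. Returns a DataFrame with columns ``molecule``,
    ``hill_coefficient``, ``ic50_molecules_per_um2``, ``max_inhibition``,
    ``converged`` in canonical row order.
    """
    if base is None:
        base = builtin_scenario("fig3_base")
    if params is not None:
        base = base.replace(params=params)
    if doses_nM is None:
        doses_nM = default_dose_grid()
    tables = scan_pd1(base, doses_nM)
    rows = []
    for display, readout in TABLE3_ROWS:
        tab = tables[readout]
        fit = fit_hill(tab.doses_density, tab.inhibition_values / 100.0)
        rows.append(
            {
                "molecule": display,
                "hill_coefficient": fit.n_hill,
                "ic50_molecules_per_um2": fit.ic50,
                "max_inhibition": fit.k_max,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def scan_2d(
    base: Scenario,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    readout: str,
    *,
    t_end: float = 1800.0,
) -> np.ndarray:
    """Grid of 30-minute readouts over two total-pool axes.

    Returns an array of shape ``(len(values1), len(values2))`` where
    entry ``[i, j]`` is the endpoint readout with ``axis1``'s pool set to
    ``values1[i]`` and ``axis2``'s to ``values2[j]``.
    """
    from .model import POOL_NAMES

    (name1, values1), (name2, values2) = axis1, axis2
    for pool in (name1, name2):
        if pool not in POOL_NAMES:
            raise KeyError(f"unknown pool {pool!r}")
    if readout not in READOUT_NAMES:
        raise KeyError(f"unknown readout {readout!r}")
    values1 = np.atleast_1d(np.asarray(values1, dtype=np.float64))
    values2 = np.atleast_1d(np.asarray(values2, dtype=np.float64))
    grid = np.empty((values1.size, values2.size))
    for i, v1 in enumerate(values1):
        for j, v2 in enumerate(values2):
            obs = endpoint(base.with_pools(**{name1: float(v1), name2: float(v2)}), t_end=t_end)
            grid[i, j] = getattr(obs, readout)
    return grid
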