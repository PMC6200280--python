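"""Multi-parametric sensitivity analysis with K-S scoring.

The procedure varies many rate constants simultaneously: each varied
parameter is sampled by Latin hypercube within +/-50% of its default,
samples are permuted independently per parameter and combined into
parameter sets. For every set the model is run at 11 PD-1 doses (0 nM
plus 10 log-spaced between 1 and 1000 nM) and the chosen percentage
readout is recorded at 10 time points; the overall error of a set is the
sum of squared deviations from the default-parameter reference over all
doses and time points. Sets with error below the ensemble mean are
"acceptable". A parameter's sensitivity is the two-sample
Kolmogorov-Smirnov distance between its marginal distributions in the
acceptable and unacceptable classes: insensitive parameters have nearly
identical marginals (K-S near the sampling-noise floor), influential
ones separate the classes.

Three modular analyses are predefined, each varying only the parameters
upstream of its readout while holding the rest at defaults:

* ``shp2_recruitment`` (15 parameters, % of bound Shp2),
* ``pi3k_recruitment`` (21 parameters, % of bound PI3K),
* ``slp76_activation`` (29 parameters, % of active Slp76; the CD28/PI3K
  branch and the PD-1 saturation constant are held fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from . import _kernel, simulate
from .parameters import PARAMETER_NAMES, RateParameters
from .scenarios import Scenario, builtin_scenario

__all__ = [
    "MODULE_PARAMETERS",
    "MpsaModuleSpec",
    "MpsaResult",
    "module_spec",
    "lhs_sample",
    "overall_error",
    "classify",
    "ks_statistic",
    "run_mpsa",
    "default_pd1_doses",
    "default_time_points",
]

# Integration tolerances for the ensemble runs. The classification
# signal is driven by +/-50% parameter changes, orders of magnitude
# above integration error at these settings.
MPSA_RTOL = 1e-6
MPSA_ATOL = 1e-8

_SHP2_PARAMS: tuple[str, ...] = (
    # PD-1 phosphorylation and CP1/CP2 formation/turnover
    "k_p_pd1", "KM_p_pd1", "k_a_shp", "k_d1_shp", "k_d2_shp", "k_dp_cp2",
    # Lck dephosphorylation by CP and auto-phosphorylation
    "k_dpa_yiya", "k_dpi_yi", "k_dpi_yiya", "k_dpa_ya", "k_dpa_pi",
    "k_pi_i", "k_pi_ya", "k_pa_i", "k_pa_yi",
)
_CD28_PI3K_PARAMS: tuple[str, ...] = (
    "k_p_cd28", "KM_p_cd28", "k_dp_cd28", "KM_dp_cd28", "k_a_pi3k", "k_d_pi3k",
)

MODULE_PARAMETERS: dict[str, tuple[str, ...]] = {
    "shp2_recruitment": _SHP2_PARAMS,
    "pi3k_recruitment": _SHP2_PARAMS + _CD28_PI3K_PARAMS,
    "slp76_activation": tuple(
        n for n in PARAMETER_NAMES if n not in _CD28_PI3K_PARAMS and n != "k_corr"
    ),
}

_MODULE_READOUTS: dict[str, str] = {
    "shp2_recruitment": "pct_bound_shp2",
    "pi3k_recruitment": "pct_bound_pi3k",
    "slp76_activation": "pct_active_slp76",
}

_SPECIES_IDX = {name: i for i, name in enumerate(
    ("cd3a", "cd28a", "pd1", "pd1p1", "pd1p2", "shp2_free", "cp1", "cp2",
     "lck_yiya", "lck_yi", "lck_ya", "lck_pi", "zap70i", "zap70a1", "zap70a2",
     "lata", "slp76i", "slp76a", "gadsa", "pi3kb")
)}


def default_pd1_doses() -> np.ndarray:
    """0 nM plus 10 log-spaced doses between 1 and 1000 nM."""
    return np.concatenate([[0.0], np.logspace(0.0, 3.0, 10)])


def default_time_points() -> np.ndarray:
    """Ten instants evenly spaced at 180 s over (0, 1800 s].

    t = 0 is excluded: every readout is at its initial value there for
    all parameter sets, so it carries no information.
    """
    return np.linspace(180.0, 1800.0, 10)


@dataclass(frozen=True)
class MpsaModuleSpec:
    """Complete specification of one modular sensitivity analysis."""

    name: str
    varied_parameters: tuple[str, ...]
    readout: str
    base_scenario: Scenario
    pd1_doses: np.ndarray = field(default_factory=default_pd1_doses)
    time_points: np.ndarray = field(default_factory=default_time_points)
    n_sets: int = 2000
    seed: int = 0
    rtol: float = MPSA_RTOL
    atol: float = MPSA_ATOL

    def __post_init__(self) -> None:
        unknown = set(self.varied_parameters) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        if len(self.pd1_doses) != 11:
            raise ValueError("pd1_doses must have 11 entries (0 plus 10 log-spaced)")
        if len(self.time_points) != 10:
            raise ValueError("time_points must have 10 entries")
        if np.any(np.asarray(self.time_points) <= 0):
            raise ValueError("time_points must be > 0")
        if self.n_sets < 2:
            raise ValueError("n_sets must be >= 2")


def module_spec(name: str, *, n_sets: int = 2000, seed: int = 0, **overrides) -> MpsaModuleSpec:
    """Build the spec of one of the three predefined analysis modules.

    The base concentrations are the benchmark dose-response set (close to
    physiological levels); PD-1 is replaced per dose during the runs.
    """
    if name not in MODULE_PARAMETERS:
        raise KeyError(
            f"unknown MPSA module {name!r}; valid: {', '.join(MODULE_PARAMETERS)}"
        )
    return MpsaModuleSpec(
        name=name,
        varied_parameters=MODULE_PARAMETERS[name],
        readout=_MODULE_READOUTS[name],
        base_scenario=builtin_scenario("fig3_base"),
        n_sets=n_sets,
        seed=seed,
        **overrides,
    )


@dataclass(frozen=True)
class MpsaResult:
    """K-S statistics and classification diagnostics of one module."""

    module: str
    ks: Mapping[str, float]          # per varied parameter, in [0, 1]
    acceptance_fraction: float
    error_threshold: float           # mean overall error across sets
    n_sets_used: int
    n_failed: int
    seed: int
    errors: np.ndarray               # overall error per set (NaN = failed)
    samples: np.ndarray              # (n_sets, n_varied) sampled values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.ks),
                "ks_statistic": list(self.ks.values()),
                "module": self.module,
                "n_sets": self.n_sets_used,
                "seed": self.seed,
            }
        )

    def top_parameter(self) -> str:
        return max(self.ks, key=self.ks.get)


def lhs_sample(
    n: int,
    ranges: Mapping[str, tuple[float, float]],
    seed: int,
) -> np.ndarray:
    """Latin hypercube sample of ``n`` parameter sets.

    For every parameter the range is cut into ``n`` equal-width strata
    and one value is drawn uniformly inside each; the per-parameter
    samples are then permuted independently and combined row-wise into
    sets. Columns follow the iteration order of ``ranges``. Deterministic
    per seed.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    columns = []
    for name, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        strata = (np.arange(n) + rng.random(n)) / n
        values = lo + (hi - lo) * strata
        columns.append(rng.permutation(values))
    return np.column_stack(columns)


def _readout_curves(
    spec: MpsaModuleSpec, params: RateParameters
) -> np.ndarray:
    """Readout at every (dose, time point); shape (11, 10)."""
    readout = spec.readout
    pools = spec.base_scenario.pools
    if readout == "pct_bound_shp2":
        idx, total = (_SPECIES_IDX["cp1"], _SPECIES_IDX["cp2"]), pools.shp2T
    elif readout == "pct_bound_pi3k":
        idx, total = (_SPECIES_IDX["pi3kb"],), pools.pi3kT
    elif readout == "pct_active_slp76":
        idx, total = (_SPECIES_IDX["slp76a"],), pools.slp76T
    else:
        raise KeyError(f"unknown MPSA readout {readout!r}")
    if total <= 0:
        raise ValueError(f"readout {readout} undefined: its total pool is zero")

    t_eval = np.concatenate([[0.0], np.asarray(spec.time_points, dtype=np.float64)])
    curves = np.empty((len(spec.pd1_doses), len(spec.time_points)))
    scenario = spec.base_scenario.replace(params=params)
    for i, dose in enumerate(spec.pd1_doses):
        sc = scenario.with_pools(pd1T=float(dose))
        ys = simulate._solve(sc, t_eval, spec.rtol, spec.atol)[1:]
        acc = np.zeros(len(spec.time_points))
        for j in idx:
            acc += ys[:, j]
        curves[i] = 100.0 * acc / total
    return curves


def overall_error(
    param_set: RateParameters,
    spec: MpsaModuleSpec,
    reference: np.ndarray,
) -> float:
    """Sum of squared deviations from the reference over all doses and
    time points. ``reference`` must come from :func:`_readout_curves`
    (or equivalent) with default parameters on the same grid."""
    reference = np.asarray(reference, dtype=np.float64)
    curves = _readout_curves(spec, param_set)
    if curves.shape != reference.shape:
        raise ValueError(f"reference shape {reference.shape} != {curves.shape}")
    return float(np.sum((curves - reference) ** 2))


def classify(errors: Sequence[float]) -> tuple[np.ndarray, float]:
    """Mean-threshold classification into acceptable/unacceptable sets.

    Returns ``(mask, threshold)`` where ``mask[i]`` is True for sets
    with error strictly below the arithmetic-mean threshold (ties count
    as unacceptable). NaN errors (failed runs) are never acceptable.
    """
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size < 2:
        raise ValueError("need at least 2 errors to classify")
    finite = errors[np.isfinite(errors)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite errors to classify")
    threshold = float(np.mean(finite))
    if np.all(finite == finite[0]):
        raise ValueError("degenerate classification: all errors identical")
    mask = np.zeros(errors.size, dtype=bool)
    mask[np.isfinite(errors)] = errors[np.isfinite(errors)] < threshold
    return mask, threshold


def ks_statistic(acceptable_values, unacceptable_values) -> float:
    """Two-sample Kolmogorov-Smirnov distance between class marginals."""
    acc = np.asarray(acceptable_values, dtype=np.float64)
    unacc = np.asarray(unacceptable_values, dtype=np.float64)
    if acc.size == 0 or unacc.size == 0:
        raise ValueError("both classes must be non-empty")
    return float(ks_2samp(acc, unacc, method="asymp").statistic)


def run_mpsa(spec: MpsaModuleSpec, *, progress: bool = False) -> MpsaResult:
    """Execute one full modular sensitivity analysis.

    Pipeline: Latin hypercube sampling of the varied parameters within
    +/-50% of defaults -> overall error per set against the
    default-parameter reference -> mean-threshold classification ->
    per-parameter K-S distance between class marginals. Deterministic
    given the spec (including its seed).
    """
    defaults = spec.base_scenario.params
    ranges = {
        name: (0.5 * defaults[name], 1.5 * defaults[name])
        for name in spec.varied_parameters
    }
    samples = lhs_sample(spec.n_sets, ranges, spec.seed)
    reference = _readout_curves(spec, defaults)

    errors = np.empty(spec.n_sets)
    iterator = range(spec.n_sets)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc=spec.name)
    for i in iterator:
        params = defaults.replace(**dict(zip(spec.varied_parameters, samples[i])))
        try:
            errors[i] = overall_error(params, spec, reference)
        except (simulate.IntegrationError, ArithmeticError):
            errors[i] = np.nan

    n_failed = int(np.sum(~np.isfinite(errors)))
    if n_failed > 0.01 * spec.n_sets:
        import warnings

        warnings.warn(
            f"{n_failed}/{spec.n_sets} parameter sets failed to integrate",
            RuntimeWarning,
            stacklevel=2,
        )
    mask, threshold = classify(errors)
    ok = np.isfinite(errors)
    ks = {
        name: ks_statistic(samples[mask & ok, j], samples[~mask & ok, j])
        for j, name in enumerate(spec.varied_parameters)
    }
    return MpsaResult(
        module=spec.name,
        ks=ks,
        acceptance_fraction=float(np.mean(mask[ok])),
        error_threshold=threshold,
        n_sets_used=int(ok.sum()),
        n_failed=n_failed,
        seed=spec.seed,
        errors=errors,
        samples=samples,
    )
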