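"""Uncertainty machinery: one-way (tornado) sweeps, probabilistic
sensitivity analysis with CEAC, and cTTR scenario analyses.

PSA distributions follow the usual convention in health-economic modelling:
gamma for event rates, beta for utilities, log-normal for costs, each
parameterised by method of moments from (mean, SE). Parameters are sampled
independently; each parameter owns a seed substream derived from the master
seed and the parameter's path, so adding a parameter does not perturb the
draws of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .econ import ArmOutcome, CEResult, compute_icer, evaluate_arm, run_base_case
from .errors import ConfigurationError, DomainError
from .params import (
    TTR_DEPENDENT_EVENTS,
    ModelParameters,
    Uncertainty,
    params_from_dict,
)
from .paths import get_by_path, set_in_tree
from .risk import ttr_adjust_rates
from .states import Therapy


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: Optional[float]
    icer_high: Optional[float]

    @property
    def spread(self) -> float:
        vals = [v for v in (self.icer_low, self.icer_high) if v is not None]
        return max(vals) - min(vals) if len(vals) == 2 else float("nan")


def _with_value(params: ModelParameters, path: str, value: float) -> ModelParameters:
    tree = params.model_dump()
    set_in_tree(tree, path, value)
    return params_from_dict(tree)


def univariate_sweep(
    params: ModelParameters, parameter: str, low: float, high: float
) -> TornadoEntry:
    """Re-run the full deterministic model with one parameter at its low
    and high value, all others fixed at base case."""
    get_by_path(params, parameter)  # raises ConfigurationError if unresolvable
    if low > high:
        raise DomainError(f"low {low} exceeds high {high} for {parameter}")
    icers = []
    for value in (low, high):
        res = run_base_case(_with_value(params, parameter, value))
        icers.append(res.icer_per_qaly)
    return TornadoEntry(parameter=parameter, low=low, high=high, icer_low=icers[0], icer_high=icers[1])


def tornado(
    params: ModelParameters, parameters: Optional[Sequence[str]] = None, z: float = 1.959963984540054
) -> list[TornadoEntry]:
    """One-way sweep over every PSA-flagged parameter (or a named subset),
    at mean ± z·SE clamped to the parameter's natural domain."""
    paths = list(parameters) if parameters is not None else sorted(params.uncertainty)
    entries = []
    for path in paths:
        desc = params.uncertainty.get(path)
        if desc is None:
            raise ConfigurationError(f"no uncertainty descriptor for {path!r}")
        mean = float(get_by_path(params, path))
        se = desc.se or 0.0
        lo, hi = mean - z * se, mean + z * se
        lo = max(lo, 0.0)
        if desc.dist == "beta":
            hi = min(hi, 1.0)
        entries.append(univariate_sweep(params, path, lo, hi))
    entries.sort(key=lambda e: (np.isnan(e.spread), -e.spread if not np.isnan(e.spread) else 0.0))
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _moment_draw(dist: str, mean: float, se: float, rng: np.random.Generator) -> float:
    """Method-of-moments draw from the distribution family assigned to the
    parameter class (gamma=rates, beta=utilities, log-normal=costs)."""
    if se == 0.0:
        return mean
    if dist == "gamma":
        if mean <= 0:
            raise DomainError("gamma mean must be > 0 when SE > 0")
        shape = (mean / se) ** 2
        scale = se**2 / mean
        return float(rng.gamma(shape, scale))
    if dist == "beta":
        if not (0.0 < mean < 1.0):
            raise DomainError(f"beta mean {mean} outside (0, 1)")
        var = se**2
        bound = mean * (1.0 - mean)
        if var >= bound:
            raise DomainError("beta SE too large for the given mean")
        nu = bound / var - 1.0
        return float(rng.beta(mean * nu, (1.0 - mean) * nu))
    if dist == "lognormal":
        if mean <= 0:
            raise DomainError("log-normal mean must be > 0 when SE > 0")
        sigma2 = np.log1p((se / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    raise ConfigurationError(f"unknown distribution family {dist!r}")


class PsaSampler:
    """Draw complete parameter sets with per-parameter seed substreams."""

    def __init__(self, params: ModelParameters, seed: int):
        self.params = params
        self.seed = int(seed)
        self._streams: dict[str, np.random.Generator] = {}
        for path in sorted(params.uncertainty):
            key = zlib.crc32(path.encode())
            ss = np.random.SeedSequence(entropy=[self.seed, key])
            self._streams[path] = np.random.Generator(np.random.PCG64(ss))

    def draw(self) -> ModelParameters:
        tree = self.params.model_dump()
        for path, desc in sorted(self.params.uncertainty.items()):
            mean = float(get_by_path(self.params, path))
            value = _moment_draw(desc.dist, mean, desc.se or 0.0, self._streams[path])
            set_in_tree(tree, path, value)
        return params_from_dict(tree)


def draw_psa_sample(params: ModelParameters, seed: int) -> ModelParameters:
    """One probabilistic draw of the full parameter set."""
    return PsaSampler(params, seed).draw()


@dataclass
class PsaResult:
    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    delta_lys: np.ndarray
    iterations: int
    seed: int

    def ce_plane_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "delta_qaly": self.delta_qalys,
                "delta_cost": self.delta_costs,
                "delta_ly": self.delta_lys,
            }
        )


def run_psa(params: ModelParameters, iterations: Optional[int] = None, seed: Optional[int] = None) -> PsaResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Both arms are evaluated on the same draw (correlated sampling), yielding
    one (Δcost, ΔQALY) pair per iteration.
    """
    iterations = int(iterations if iterations is not None else params.settings.psa_iterations)
    seed = int(seed if seed is not None else params.settings.seed)
    if iterations < 1:
        raise DomainError("PSA needs at least one iteration")
    sampler = PsaSampler(params, seed)
    dc = np.empty(iterations)
    dq = np.empty(iterations)
    dl = np.empty(iterations)
    for i in range(iterations):
        drawn = sampler.draw()
        apix = evaluate_arm(drawn, Therapy.APIXABAN)
        vka = evaluate_arm(drawn, Therapy.VKA)
        dc[i] = apix.cost_total - vka.cost_total
        dq[i] = apix.qalys - vka.qalys
        dl[i] = apix.lys - vka.lys
    return PsaResult(delta_costs=dc, delta_qalys=dq, delta_lys=dl, iterations=iterations, seed=seed)


def ceac(psa: PsaResult, wtp_grid: Sequence[float]) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay λ, the fraction of draws with strictly
    positive net monetary benefit λ·ΔQALY − Δcost.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise DomainError("WTP grid must be non-empty")
    nmb = grid[:, None] * psa.delta_qalys[None, :] - psa.delta_costs[None, :]
    return (nmb > 0).mean(axis=1)


# ---------------------------------------------------------------------------
# cTTR scenario analyses


@dataclass
class ScenarioResult:
    scenario: str
    ttr_policy: str
    #: therapy -> event -> adjusted annual rate (the Table-4 echo)
    adjusted_rates: dict[str, dict[str, float]]
    result: CEResult


def run_scenarios(
    params: ModelParameters, scenarios: Optional[Sequence[tuple[str, str]]] = None
) -> list[ScenarioResult]:
    """Deterministic model runs under alternative INR-control assumptions.

    Each scenario is a ``(name, ttr_policy)`` pair; by default the four
    configured-strata scenarios are run: one per cTTR stratum plus the
    equal-mix allocation across clinics.
    """
    if scenarios is None:
        scenarios = [(st.label, f"stratum:{st.label}") for st in params.rates.ttr_strata]
        scenarios.append(("equal distribution across cTTRs", "equal_mix"))
    out = []
    for name, policy in scenarios:
        adjusted = ttr_adjust_rates(params.rates, policy, params.cohort.mean_ttr)
        tree = params.model_dump()
        tree["rates"] = adjusted.model_dump()
        tree["settings"]["ttr_policy"] = policy
        sc_params = params_from_dict(tree)
        result = run_base_case(sc_params)
        echo = {
            th: {ev: getattr(adjusted.for_therapy(th), ev) for ev in TTR_DEPENDENT_EVENTS}
            for th in ("apixaban", "vka")
        }
        out.append(ScenarioResult(scenario=name, ttr_policy=policy, adjusted_rates=echo, result=result))
    return out
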