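"""Scenario grid: {specific, generalized} network x {specific fluctuating,
generalized fluctuating, constant} temperature, run per reef zone.

The registry holds three interaction matrices (one per zone plus the
pooled one) and five temperature profiles (fluctuating per zone, a
generalized fluctuating profile averaging the zone parameters, and
constant profiles at each zone mean). Every (scenario, zone) pair maps
to one integration of the core model, reported as percent composition
at the configured sampling time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mucodyn.community_metrics import fourth_root
from mucodyn.model_core import (
    ANNUAL_OMEGA,
    CommunityState,
    GrowthParams,
    TemperatureProfile,
    integrate,
    phase_for_minimum_day,
    relative_abundances,
)
from mucodyn.network_inference import (
    AbundanceTable,
    InteractionMatrix,
    spearman_matrix,
    threshold_network,
)
from mucodyn.validation_stats import fit_regression, wald_slope_intercept_test

__all__ = [
    "ZONES",
    "NETWORK_PROFILES",
    "TEMPERATURE_PROFILES",
    "DEFAULT_ZONE_CLIMATE",
    "ScenarioSpec",
    "ProfileRegistry",
    "SolverConfig",
    "build_registry",
    "enumerate_scenarios",
    "run_scenario",
    "scenario_report",
]

ZONES = ("inner", "outer")
NETWORK_PROFILES = ("SN", "GN")
TEMPERATURE_PROFILES = ("ST", "GT", "CT")

#: Mean / amplitude (degrees C) of the zone-specific annual temperature
#: sinusoids; the generalized profile averages them.
DEFAULT_ZONE_CLIMATE = {
    "inner": {"mean": 24.0, "amplitude": 7.0},
    "outer": {"mean": 18.0, "amplitude": 5.0},
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the network x temperature grid bound to a reef zone."""

    network_profile: str
    temperature_profile: str
    reef_zone: str

    def __post_init__(self) -> None:
        if self.network_profile not in NETWORK_PROFILES:
            raise ValueError(f"unknown network profile {self.network_profile!r}")
        if self.temperature_profile not in TEMPERATURE_PROFILES:
            raise ValueError(f"unknown temperature profile {self.temperature_profile!r}")
        if self.reef_zone not in ZONES:
            raise ValueError(f"unknown reef zone {self.reef_zone!r}")

    @property
    def label(self) -> str:
        return f"{self.network_profile}-{self.temperature_profile}"


@dataclass
class ProfileRegistry:
    """All interaction matrices and temperature profiles the grid needs."""

    networks: dict[str, InteractionMatrix]  # keys: SN:inner, SN:outer, GN
    temperatures: dict[str, TemperatureProfile]  # ST:inner, ST:outer, GT, CT:inner, CT:outer
    taxon_ids: list[str]

    def network_for(self, spec: ScenarioSpec) -> InteractionMatrix:
        key = "GN" if spec.network_profile == "GN" else f"SN:{spec.reef_zone}"
        return self.networks[key]

    def temperature_for(self, spec: ScenarioSpec) -> TemperatureProfile:
        tp = spec.temperature_profile
        key = "GT" if tp == "GT" else f"{tp}:{spec.reef_zone}"
        return self.temperatures[key]


@dataclass
class SolverConfig:
    """One shared integration configuration for all scenario runs, so
    accuracy differences are attributable to profiles, not tolerances."""

    carrying_capacity: float = 100.0
    init_mode: str = "equal"  # equal | observed
    init_fraction: float = 0.5  # initial total as a fraction of k
    years: float = 3.0
    sample_day_of_year: float = 150.0
    rtol: float = 1e-8
    atol: float = 1e-10
    rho_min: float = 0.7
    p_max: float = 0.001
    minimum_day: float = 45.0
    response: str = "density"

    @property
    def sample_time(self) -> float:
        return (self.years - 1.0) * 365.0 + self.sample_day_of_year


def build_registry(
    inner_table: AbundanceTable,
    outer_table: AbundanceTable,
    config: SolverConfig | None = None,
    zone_climate: dict | None = None,
) -> ProfileRegistry:
    """Infer SN/GN interaction matrices and instantiate all five
    temperature profiles.

    Specific networks come from each zone's samples alone; the
    generalized network pools every sample from both zones. The
    generalized temperature profile averages the two zone climates;
    constant profiles have zero amplitude at each zone's mean.
    """
    config = config or SolverConfig()
    climate = zone_climate or DEFAULT_ZONE_CLIMATE
    if inner_table.taxon_ids != outer_table.taxon_ids:
        only_inner = set(inner_table.taxon_ids) - set(outer_table.taxon_ids)
        only_outer = set(outer_table.taxon_ids) - set(inner_table.taxon_ids)
        raise ValueError(
            "zone tables disagree on taxa: "
            f"inner-only={sorted(only_inner)}, outer-only={sorted(only_outer)}, "
            "or ordering differs"
        )
    taxa = list(inner_table.taxon_ids)
    pooled = AbundanceTable(
        sample_ids=[f"inner:{s}" for s in inner_table.sample_ids]
        + [f"outer:{s}" for s in outer_table.sample_ids],
        taxon_ids=taxa,
        values=np.vstack([inner_table.values, outer_table.values]),
    )

    def infer(table: AbundanceTable) -> InteractionMatrix:
        corr = spearman_matrix(table)
        return threshold_network(corr, rho_min=config.rho_min, p_max=config.p_max)

    networks = {
        "SN:inner": infer(inner_table),
        "SN:outer": infer(outer_table),
        "GN": infer(pooled),
    }

    theta = phase_for_minimum_day(config.minimum_day)
    m_in = climate["inner"]["mean"]
    a_in = climate["inner"]["amplitude"]
    m_out = climate["outer"]["mean"]
    a_out = climate["outer"]["amplitude"]
    temperatures = {
        "ST:inner": TemperatureProfile(m_in, a_in, ANNUAL_OMEGA, theta),
        "ST:outer": TemperatureProfile(m_out, a_out, ANNUAL_OMEGA, theta),
        "GT": TemperatureProfile(
            (m_in + m_out) / 2.0, (a_in + a_out) / 2.0, ANNUAL_OMEGA, theta
        ),
        "CT:inner": TemperatureProfile(m_in, 0.0, ANNUAL_OMEGA, theta),
        "CT:outer": TemperatureProfile(m_out, 0.0, ANNUAL_OMEGA, theta),
    }
    return ProfileRegistry(networks=networks, temperatures=temperatures, taxon_ids=taxa)


def enumerate_scenarios() -> list[tuple[str, str]]:
    """The six (network, temperature) combinations, stable-ordered."""
    return list(itertools.product(NETWORK_PROFILES, TEMPERATURE_PROFILES))


def _initial_state(
    n: int,
    config: SolverConfig,
    observed: AbundanceTable | None = None,
) -> CommunityState:
    k = config.carrying_capacity
    total = config.init_fraction * k
    if config.init_mode == "equal":
        init = np.full(n, total / n)
    elif config.init_mode == "observed":
        if observed is None:
            raise ValueError("init_mode='observed' requires an observed table")
        props = observed.values.mean(axis=0)
        props = props / props.sum()
        init = total * props
    else:
        raise ValueError(f"unknown init_mode {config.init_mode!r}")
    return CommunityState(abundances=init, carrying_capacity=k)


def run_scenario(
    spec: ScenarioSpec,
    registry: ProfileRegistry,
    growth: Sequence[GrowthParams],
    config: SolverConfig | None = None,
    observed: AbundanceTable | None = None,
) -> np.ndarray:
    """Integrate one (scenario, zone) cell; returns percent composition
    (summing to 100) at the configured sampling time."""
    config = config or SolverConfig()
    growth_ids = [g.taxon_id for g in growth]
    if growth_ids != registry.taxon_ids:
        missing = set(registry.taxon_ids) - set(growth_ids)
        raise ValueError(
            f"growth table does not cover registry taxa (missing {sorted(missing)}) "
            "or ordering differs"
        )
    eta = registry.network_for(spec).eta
    profile = registry.temperature_for(spec)
    init = _initial_state(len(growth), config, observed)
    t_end = config.years * 365.0
    out_times = np.linspace(0.0, t_end, max(int(t_end) + 1, 2))
    try:
        traj = integrate(
            growth,
            eta,
            profile,
            init,
            (0.0, t_end),
            out_times,
            response=config.response,  # type: ignore[arg-type]
            rtol=config.rtol,
            atol=config.atol,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"scenario {spec.label} ({spec.reef_zone}): {exc}"
        ) from exc
    return relative_abundances(traj, config.sample_time)


def scenario_report(
    registry: ProfileRegistry,
    growth: Sequence[GrowthParams],
    observed_tables: dict[str, AbundanceTable],
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Run the full 2-zone x 6-scenario grid and regress observed on
    predicted composition (both fourth-root transformed).

    Observed abundances are renormalized over the registry's taxon set
    (mean across the zone's samples) before comparison. Returns a
    12-row frame: zone, scenario, slope, intercept, r_squared, p_value,
    wald_F, wald_p, n.
    """
    config = config or SolverConfig()
    rows = []
    for zone in ZONES:
        table = observed_tables[zone].subset_taxa(registry.taxon_ids)
        obs_mean = table.values.mean(axis=0)
        obs_pct = 100.0 * obs_mean / obs_mean.sum()
        for net, temp in enumerate_scenarios():
            spec = ScenarioSpec(net, temp, zone)
            predicted = run_scenario(spec, registry, growth, config, observed=table)
            fit = fit_regression(fourth_root(obs_pct), fourth_root(predicted))
            wald = wald_slope_intercept_test(fit)
            rows.append(
                {
                    "zone": zone,
                    "scenario": spec.label,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "p_value": fit.p_value,
                    "wald_F": wald.f_statistic,
                    "wald_p": wald.p_value,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
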