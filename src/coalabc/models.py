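"""Demographic model set, parameter priors and unit conversions.

Four competing demographic scenarios for a four-region system, each crossed
with migration and exponential-growth variants to give 14 models:

* scenario 1 — a single panmictic population (stable, or growing);
* scenario 2 — one fragmentation event splitting the ancestral population
  into the four regions simultaneously at τ1;
* scenario 3 — stepwise north→south colonization (region 2 founded from
  region 1 at τ1, region 3 from region 2 at τ2, region 4 from region 3 at
  τ3 — backwards: 4→3 at τ3, 3→2 at τ2, 2→1 at τ1);
* scenario 4 — a deep southern break at τ1 separating region 4 from the
  {1,2,3} block, with nested splits at τ2 ({1} vs {2,3}) and τ3 ({2} vs {3}).

Scenarios 2–4 each appear as {plain, migration, growth, migration+growth};
scenario 1 as {stable, growth}.  Times are in units of 4Ne generations,
shared between loci; the mitochondrial locus differs only through its
4-fold smaller θ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Priors",
    "SplitEvent",
    "DemographicModel",
    "enumerate_models",
    "scenario_topology",
    "draw_parameters",
    "migration_in_natural_units",
    "growth_size_ratio",
    "growth_rate_from_ratio",
    "THETA_RATIO_ITS2_OVER_COI",
]

# Nuclear θ is fixed at 4× the mitochondrial θ (4Neμ vs Neμ at equal μ·L
# contribution; the ratio is part of the model definition, not a free prior).
THETA_RATIO_ITS2_OVER_COI = 4.0


@dataclass
class Priors:
    """Uniform prior bounds for every free parameter.

    θ is per locus; τ in 4Ne-generation units with the nesting
    τ3 < τ2 < τ1 enforced by conditional sampling; ``m`` is the scaled
    migration prior (divide by n_demes−1 for migrants/generation/pair);
    ``alpha`` is the exponential growth rate anchored at the deme's
    founding time.
    """

    theta_coi: tuple[float, float] = (0.25, 7.0)
    tau1: tuple[float, float] = (0.01, 4.0)
    tau23_low: float = 0.001
    m: tuple[float, float] = (0.001, 15.0)
    alpha: tuple[float, float] = (0.25, 0.9)


@dataclass(frozen=True)
class SplitEvent:
    """Backward-in-time merge of ``source`` deme into ``dest`` at ``time_symbol``."""

    time_symbol: str  # "tau1" | "tau2" | "tau3"
    source: int  # 0-based deme index that disappears (backward)
    dest: int


@dataclass(frozen=True)
class DemographicModel:
    model_id: int
    scenario: int
    n_demes: int
    split_events: tuple[SplitEvent, ...]
    has_migration: bool
    has_growth: bool
    label: str = ""

    @property
    def tau_symbols(self) -> list[str]:
        """τ parameters this model actually uses (deduplicated, τ1 first)."""
        syms = {ev.time_symbol for ev in self.split_events}
        if self.has_growth and not syms:
            syms = {"tau1"}  # panmictic growth anchors at tau1
        return [s for s in ("tau1", "tau2", "tau3") if s in syms]


def scenario_topology(scenario: int) -> tuple[SplitEvent, ...]:
    """Backward-in-time split events defining each scenario's topology."""
    if scenario == 1:
        return ()
    if scenario == 2:
        return (
            SplitEvent("tau1", 1, 0),
            SplitEvent("tau1", 2, 0),
            SplitEvent("tau1", 3, 0),
        )
    if scenario == 3:
        return (
            SplitEvent("tau3", 3, 2),
            SplitEvent("tau2", 2, 1),
            SplitEvent("tau1", 1, 0),
        )
    if scenario == 4:
        return (
            SplitEvent("tau3", 2, 1),
            SplitEvent("tau2", 1, 0),
            SplitEvent("tau1", 3, 0),
        )
    raise ValueError(f"invalid scenario {scenario}; must be 1..4")


_SCENARIO_NAMES = {
    1: "panmixia",
    2: "fragmentation",
    3: "north-south colonization",
    4: "southern break",
}


def enumerate_models() -> list[DemographicModel]:
    """The full 14-model grid.

    Ids 1–2 are scenario 1 (stable, growth); ids 3–6, 7–10 and 11–14 are
    scenarios 2–4 each ordered {plain, migration, growth, migration+growth}.
    """
    models: list[DemographicModel] = []
    models.append(
        DemographicModel(1, 1, 1, (), False, False, "panmixia, stable")
    )
    models.append(
        DemographicModel(2, 1, 1, (), False, True, "panmixia, growth")
    )
    next_id = 3
    for scenario in (2, 3, 4):
        topo = scenario_topology(scenario)
        for mig, growth in ((False, False), (True, False), (False, True), (True, True)):
            flags = []
            if mig:
                flags.append("migration")
            if growth:
                flags.append("growth")
            label = f"{_SCENARIO_NAMES[scenario]}" + (
                f" ({', '.join(flags)})" if flags else ""
            )
            models.append(
                DemographicModel(next_id, scenario, 4, topo, mig, growth, label)
            )
            next_id += 1
    return models


def draw_parameters(
    model: DemographicModel,
    priors: Priors,
    rng: np.random.Generator,
) -> dict[str, float]:
    """One prior draw containing only the parameters this model uses.

    τ values are nested by conditional sampling: τ2 ~ U(low, τ1),
    τ3 ~ U(low, τ2).  Always includes ``theta_coi`` and the derived
    ``theta_its2``.
    """
    params: dict[str, float] = {}
    params["theta_coi"] = rng.uniform(*priors.theta_coi)
    params["theta_its2"] = THETA_RATIO_ITS2_OVER_COI * params["theta_coi"]
    syms = model.tau_symbols
    if "tau1" in syms:
        params["tau1"] = rng.uniform(*priors.tau1)
    if "tau2" in syms:
        params["tau2"] = rng.uniform(priors.tau23_low, params["tau1"])
    if "tau3" in syms:
        params["tau3"] = rng.uniform(priors.tau23_low, params["tau2"])
    if model.has_migration:
        params["m"] = rng.uniform(*priors.m)
    if model.has_growth:
        params["alpha"] = rng.uniform(*priors.alpha)
    return params


def migration_in_natural_units(m: float, n_demes: int) -> float:
    """Convert the scaled migration prior to migrants/generation per deme pair.

    The prior is expressed as total migrant copies per generation divided
    among the other demes, so the per-pair rate is m/(n_demes − 1).
    """
    if n_demes < 2:
        raise ValueError("migration requires at least 2 demes")
    return m / (n_demes - 1)


def growth_size_ratio(alpha: float, tau: float) -> float:
    """Ancestral/current size ratio N(τ)/N(0) = exp(−α·τ).

    Inverts the growth-rate definition α = −(1/τ)·ln(N(τ)/N(0)).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return float(np.exp(-alpha * tau))


def growth_rate_from_ratio(ratio: float, tau: float) -> float:
    """α from the size ratio: α = −(1/τ)·ln(ratio); inverse of
    :func:`growth_size_ratio`."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    return float(-np.log(ratio) / tau)
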