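"""Liebig/Monod bioassay simulator with known ground-truth limitation.

Every pipeline stage is testable without downloads: the generator builds
factorial nutrient-addition experiments whose chlorophyll responses follow
a minimum-law Monod growth model with stoichiometric drawdown, plus
lognormal replicate noise, and station nutrient tables with analytic
most-deficient labels.

Growth model (per treatment, integrated in daily steps):

    mu = mu_max(T) * min_i  C_i / (K_i + C_i)
    Chl -> Chl * exp(mu * dt)

New chlorophyll consumes nutrients in stoichiometric proportion (1 µg Chl
per 1 µmol N by default, other elements scaled by the requirement profile);
a step is capped so drawdown never exceeds what is available.  Half-
saturation constants are tied to the stoichiometry, K_i = (R_i/16)·K_N with
K_N = 0.5 µmol/L, so a concentration of m·K_i supports the same chlorophyll
production (0.5·m µg/L) for every nutrient and the concentration-to-
requirement quotient ordering equals the multiplier ordering.

Regimes place the tested nutrients at depleted (0.1·K), intermediate
(serial) or replete (40·K) levels; the ground-truth limitation hierarchy is
the Liebig-minimum structure of those multipliers (co-limitation when the
two lowest quotients fall within the configured band).  Additions are
saturating spikes sized to bioassay practice (able to support ~10 µg/L of
new chlorophyll).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import (
    DEFAULT_FILE_UNITS,
    DEFAULT_STOICHIOMETRY,
    UNIT_FACTORS,
    Concentration,
    Experiment,
    Level,
    LimitationResult,
    Nutrient,
    Station,
    Treatment,
    format_added,
)
from .growth_rates import GrowthResponse, max_growth_rate, net_growth_rate

__all__ = [
    "SyntheticConfig",
    "Survey",
    "REGIMES",
    "half_saturation_constants",
    "liebig_truth",
    "simulate_experiment",
    "simulate_survey",
    "simulate_stations",
    "simulate_response_groups",
]

REGIMES = (
    "gyre",  # N depleted: primary N limitation
    "upwelling",  # Fe depleted under high nitrate: primary Fe
    "transition",  # N and Fe co-depleted near the critical ratio: co-limitation
    "serial_n_fe",  # N primary, Fe serially limiting
    "serial_fe_n",  # Fe primary, N serially limiting
    "serial_n_fe_co",  # N primary, Fe secondary, Co tertiary
    "replete",  # nothing limiting within the incubation
)

#: |latitude| band each regime is drawn from (temperature follows latitude)
_REGIME_LAT = {
    "gyre": (8.0, 35.0),
    "upwelling": (42.0, 65.0),
    "transition": (35.0, 50.0),
    "serial_n_fe": (15.0, 40.0),
    "serial_fe_n": (35.0, 55.0),
    "serial_n_fe_co": (10.0, 30.0),
    "replete": (50.0, 70.0),
}

_DEFAULT_WEIGHTS = {
    "gyre": 0.28,
    "upwelling": 0.22,
    "transition": 0.14,
    "serial_n_fe": 0.12,
    "serial_fe_n": 0.09,
    "serial_n_fe_co": 0.05,
    "replete": 0.10,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the simulator; the seed fully determines all output."""

    seed: int = 0
    n_experiments: int = 500
    panel: tuple = (
        Nutrient.N, Nutrient.P, Nutrient.Fe,
        Nutrient.Mn, Nutrient.Co, Nutrient.Zn,
    )
    design: str | None = None  # None = per-regime default
    replicates: int = 3
    duration: float = 2.0  # days (48 h incubation)
    chl_initial: float = 0.2  # µg/L
    temperature_range: tuple = (-2.0, 30.0)
    noise_cv: float = 0.1  # lognormal replicate CV
    k_ref: float = 5e-7  # mol/L: N half-saturation (0.5 µmol/L)
    depleted_mult: float = 0.1
    replete_mult: float = 40.0
    secondary_mult: float = 1.0
    tertiary_mults: tuple = (0.61, 2.0)
    addition_support: float = 10.0  # µg/L chlorophyll a spike can sustain
    chl_per_n: float = 1.0  # µg chlorophyll per µmol N consumed
    co_band: float = 2.0  # quotient ratio within which two minima co-limit
    limit_mult: float = 10.0  # quotient above which a nutrient cannot limit
    regime_weights: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    n_stations: int = 100
    station_noise_cv: float = 0.0

    def __post_init__(self):
        if self.noise_cv < 0 or self.station_noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def half_saturation_constants(config: SyntheticConfig) -> dict:
    """K_i = (R_i/16) * K_N, mol/L, for all profile nutrients."""
    return {
        n: (r / DEFAULT_STOICHIOMETRY[Nutrient.N]) * config.k_ref
        for n, r in DEFAULT_STOICHIOMETRY.items()
    }


def _consumption_per_ug(config: SyntheticConfig) -> dict:
    """mol of nutrient i consumed per µg of new chlorophyll."""
    return {
        n: (r / DEFAULT_STOICHIOMETRY[Nutrient.N]) * 1e-6 / config.chl_per_n
        for n, r in DEFAULT_STOICHIOMETRY.items()
    }


def grow_treatment(concs: dict, T: float, config: SyntheticConfig):
    """Integrate the minimum-law Monod model over the incubation.

    ``concs`` maps Nutrient -> mol/L (ambient plus any addition); returns
    ``(final_chl, remaining_concs)``.  Drawdown is stoichiometric and capped
    at availability (mass balance)."""
    K = half_saturation_constants(config)
    cons = _consumption_per_ug(config)
    c = {n: float(v) for n, v in concs.items()}
    active = [n for n in c if n in K]
    chl = config.chl_initial
    mu_max = max_growth_rate(T)
    t = 0.0
    while t < config.duration - 1e-12:
        dt = min(1.0, config.duration - t)
        monod = min((c[n] / (K[n] + c[n]) for n in active), default=1.0)
        dchl = chl * (math.exp(mu_max * monod * dt) - 1.0)
        cap = min((c[n] / cons[n] for n in active), default=math.inf)
        dchl = min(dchl, cap)
        for n in active:
            c[n] = max(0.0, c[n] - dchl * cons[n])
        chl += dchl
        t += dt
    return chl, c


def _tested_nutrients(regime: str):
    if regime == "serial_n_fe_co":
        return (Nutrient.N, Nutrient.Fe, Nutrient.Co)
    return (Nutrient.N, Nutrient.Fe)


def _regime_multipliers(regime: str, config: SyntheticConfig) -> dict:
    m = {n: config.replete_mult for n in config.panel
         if n in DEFAULT_STOICHIOMETRY}
    dep = config.depleted_mult
    if regime == "gyre":
        m[Nutrient.N] = dep
    elif regime == "upwelling":
        m[Nutrient.Fe] = dep
    elif regime == "transition":
        m[Nutrient.N] = dep
        m[Nutrient.Fe] = dep
    elif regime == "serial_n_fe":
        m[Nutrient.N] = dep
        m[Nutrient.Fe] = config.secondary_mult
    elif regime == "serial_fe_n":
        m[Nutrient.Fe] = dep
        m[Nutrient.N] = config.secondary_mult
    elif regime == "serial_n_fe_co":
        m[Nutrient.N] = dep
        m[Nutrient.Fe] = config.tertiary_mults[0]
        m[Nutrient.Co] = config.tertiary_mults[1]
    elif regime != "replete":
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    return m


def liebig_truth(multipliers: dict, tested, config: SyntheticConfig) -> LimitationResult:
    """Ground-truth limitation hierarchy from concentration/K quotients.

    Nutrients with quotients >= ``limit_mult`` cannot limit within the
    incubation; the two lowest quotients co-limit when within ``co_band`` of
    each other; remaining limitable nutrients form serial levels (at most
    three levels in total)."""
    ranked = sorted(
        ((multipliers[n], n) for n in tested), key=lambda mn: (mn[0], mn[1].value)
    )
    if not ranked or ranked[0][0] >= config.limit_mult:
        return LimitationResult(category="replete")
    levels = []
    m0 = ranked[0][0]
    idx = 1
    first = {ranked[0][1]}
    while idx < len(ranked) and ranked[idx][0] < config.limit_mult \
            and ranked[idx][0] <= config.co_band * m0:
        first.add(ranked[idx][1])
        idx += 1
    levels.append(Level(nutrients=frozenset(first),
                        tag="co" if len(first) > 1 else "single"))
    while idx < len(ranked) and len(levels) < 3 and ranked[idx][0] < config.limit_mult:
        levels.append(Level(nutrients=frozenset({ranked[idx][1]}), tag="single"))
        idx += 1
    return LimitationResult(category="limited", levels=levels)


def _design_subsets(tested, design: str):
    tested = list(tested)
    if design == "single":
        subsets = [frozenset()] + [frozenset({n}) for n in tested]
    elif design in ("factorial2", "factorial3"):
        k = len(tested)
        subsets = []
        for mask in range(2**k):
            subsets.append(
                frozenset(t for i, t in enumerate(tested) if mask >> i & 1)
            )
    else:
        raise ValueError(f"unknown design {design!r}")
    return sorted(set(subsets), key=lambda s: (len(s), format_added(s)))


def _draw_site(regime: str, config: SyntheticConfig, rng) -> tuple[float, float, float]:
    lo, hi = _REGIME_LAT[regime]
    lat = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
    lon = rng.uniform(-180.0, 180.0)
    t_lo, t_hi = config.temperature_range
    T = float(np.clip(28.0 - 0.38 * abs(lat) + rng.normal(0.0, 1.5), t_lo, t_hi))
    return float(lat), float(lon), T


def _ambient_concentrations(multipliers: dict, config: SyntheticConfig) -> dict:
    K = half_saturation_constants(config)
    out = {}
    for n, m in multipliers.items():
        unit = DEFAULT_FILE_UNITS[n]
        value = m * K[n] / UNIT_FACTORS[unit]
        out[n] = Concentration(value=value, unit=unit)
    return out


def simulate_experiment(config: SyntheticConfig, regime: str, rng=None,
                        experiment_id: str = "sim-1", site=None):
    """Simulate one bioassay experiment.

    Returns ``(experiment, truth)`` where ``truth`` is the analytic
    ground-truth :class:`LimitationResult` of the ambient concentrations
    over the tested nutrient panel.  The experiment's
    ``recorded_limitation`` is set to the truth (playing the role of the
    source study's designation)."""
    rng = config.rng() if rng is None else rng
    tested = _tested_nutrients(regime)
    design = config.design or (
        "factorial3" if len(tested) == 3 else "factorial2"
    )
    if design == "factorial3" and len(tested) < 3:
        raise ValueError(f"regime {regime!r} tests {len(tested)} nutrients; "
                         "factorial3 needs 3")
    multipliers = _regime_multipliers(regime, config)
    truth = liebig_truth(multipliers, tested, config)
    lat, lon, T = _draw_site(regime, config, rng) if site is None else site
    ambient = _ambient_concentrations(multipliers, config)
    cons = _consumption_per_ug(config)

    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    treatments = []
    deterministic = {}
    for added in _design_subsets(tested, design):
        concs = {n: c.molar for n, c in ambient.items()}
        for n in added:
            concs[n] = concs.get(n, 0.0) + config.addition_support * cons[n]
        final, _ = grow_treatment(concs, T, config)
        deterministic[added] = final
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, config.replicates))
        else:
            noise = np.ones(config.replicates)
        treatments.append(
            Treatment(
                added=added,
                chl_final=tuple(final * noise),
                label=format_added(added) or "control",
            )
        )
    exp = Experiment(
        id=experiment_id,
        latitude=lat,
        longitude=lon,
        temperature=T,
        duration=config.duration,
        chl_initial=config.chl_initial,
        nutrients=ambient,
        treatments=treatments,
        design="bottle",
        recorded_limitation=truth,
        source=f"synthetic:{regime}",
    )
    exp._deterministic_finals = deterministic  # noiseless trajectory sidecar
    return exp, truth


@dataclass
class Survey:
    """A simulated experiment collection with its ground-truth sidecar."""

    experiments: list
    truths: dict  # experiment_id -> LimitationResult
    regimes: dict  # experiment_id -> regime name
    sidecar: pd.DataFrame  # per-treatment noiseless responses & covariates

    @property
    def planted_slope(self) -> float:
        """Least-squares slope of the noiseless net growth rate on the
        number of nutrients added — the relationship the survey plants."""
        x = self.sidecar["n_added"].to_numpy(float)
        y = self.sidecar["mu_net_true"].to_numpy(float)
        x = x - x.mean()
        return float((x * y).sum() / (x * x).sum())


def simulate_survey(config: SyntheticConfig) -> Survey:
    """Simulate ``config.n_experiments`` experiments across regimes.

    Regime draws follow ``config.regime_weights``; latitude bands per regime
    and the latitude-temperature relationship plant the covariate structure
    (multi-nutrient serial regimes sit in warmer, lower-latitude waters).
    A single random stream seeded from the config drives everything."""
    rng = config.rng()
    names = sorted(config.regime_weights)
    weights = np.array([config.regime_weights[n] for n in names], dtype=float)
    weights = weights / weights.sum()
    experiments, truths, regimes = [], {}, {}
    rows = []
    draws = rng.choice(len(names), size=config.n_experiments, p=weights)
    for i, ridx in enumerate(draws):
        regime = names[int(ridx)]
        exp_id = f"sim-{i:04d}"
        exp, truth = simulate_experiment(config, regime, rng=rng,
                                         experiment_id=exp_id)
        experiments.append(exp)
        truths[exp_id] = truth
        regimes[exp_id] = regime
        for added, final in exp._deterministic_finals.items():
            rows.append(
                {
                    "experiment_id": exp_id,
                    "regime": regime,
                    "added": format_added(added),
                    "n_added": len(added),
                    "chl_final_true": final,
                    "mu_net_true": net_growth_rate(
                        final, config.chl_initial, config.duration
                    ),
                    "temperature_C": exp.temperature,
                    "lat": exp.latitude,
                }
            )
    sidecar = pd.DataFrame(rows)
    return Survey(experiments=experiments, truths=truths,
                  regimes=regimes, sidecar=sidecar)


_STATION_REGIMES = ("gyre", "upwelling", "southern_mn", "p_depleted")
_STATION_TARGET = {
    "gyre": Nutrient.N,
    "upwelling": Nutrient.Fe,
    "southern_mn": Nutrient.Mn,
    "p_depleted": Nutrient.P,
}


def simulate_stations(config: SyntheticConfig, n_sparse: int = 0):
    """Simulate a station nutrient table with known most-deficient labels.

    Each station draws one nutrient to a depleted quotient and the rest to
    replete quotients; the label is the analytic Liebig minimum (smallest
    C/R).  Optional multiplicative measurement noise perturbs the reported
    concentrations but not the labels.  ``n_sparse`` appends stations with a
    single measured nutrient (below the >= 2 prediction criterion).

    Returns ``(stations, labels)`` with ``labels[station_id]`` a
    :class:`Nutrient` (absent for sparse stations)."""
    rng = config.rng()
    K = half_saturation_constants(config)
    sigma = math.sqrt(math.log(1.0 + config.station_noise_cv**2)) \
        if config.station_noise_cv > 0 else 0.0
    stations, labels = [], {}
    for i in range(config.n_stations):
        regime = _STATION_REGIMES[int(rng.integers(len(_STATION_REGIMES)))]
        target = _STATION_TARGET[regime]
        mult = {}
        for n in config.panel:
            if n not in DEFAULT_STOICHIOMETRY:
                continue
            mult[n] = rng.uniform(0.02, 0.5) if n == target \
                else rng.uniform(5.0, 50.0)
        # label = analytic Liebig minimum of C/R (equals multiplier order)
        label = min(mult, key=lambda n: (mult[n], n.value))
        sid = f"st-{i:04d}"
        concs = {}
        for n, m in mult.items():
            unit = DEFAULT_FILE_UNITS[n]
            value = m * K[n] / UNIT_FACTORS[unit]
            if sigma > 0:
                value *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
            concs[n] = Concentration(value=value, unit=unit)
        lat = float(rng.uniform(-70, 70))
        lon = float(rng.uniform(-180, 180))
        stations.append(Station(id=sid, latitude=lat, longitude=lon,
                                nutrients=concs, depth_m=5.0))
        labels[sid] = label
    for j in range(n_sparse):
        sid = f"st-sparse-{j:04d}"
        stations.append(
            Station(
                id=sid,
                latitude=float(rng.uniform(-70, 70)),
                longitude=float(rng.uniform(-180, 180)),
                nutrients={
                    Nutrient.N: Concentration(rng.uniform(0.1, 10.0), "umol/L")
                },
                depth_m=5.0,
            )
        )
    return stations, labels


def simulate_response_groups(means=(0.03, 0.20, 0.42, 0.73),
                             sds=(0.25, 0.36, 0.47, 0.54),
                             n_per_group: int = 200,
                             seed: int = 0) -> list:
    """Draw normal growth-rate responses with planted per-group means/SDs
    (groups indexed by number of nutrients added, 0..len(means)-1).

    Returns :class:`GrowthResponse` objects suitable for
    :func:`nutlim.meta_trends.group_stats` recovery tests."""
    rng = np.random.default_rng(seed)
    sets = [frozenset(), frozenset({Nutrient.N}),
            frozenset({Nutrient.N, Nutrient.Fe}),
            frozenset({Nutrient.N, Nutrient.Fe, Nutrient.P})]
    out = []
    chl_i, t = 1.0, 1.0
    for k, (mu, sd) in enumerate(zip(means, sds)):
        draws = rng.normal(mu, sd, n_per_group)
        for j, v in enumerate(draws):
            out.append(
                GrowthResponse(
                    experiment_id=f"grp{k}-{j}",
                    added=sets[min(k, len(sets) - 1)],
                    mu_net=float(v),
                    chl_T=chl_i * math.exp(v * t),
                    chl_I=chl_i,
                    t=t,
                )
            )
    return out
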