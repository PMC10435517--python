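"""Chlorophyll-based net growth rates and the empirical temperature maximum.

The net growth rate of a treatment is the log-ratio of final to initial
chlorophyll-a divided by incubation length,

    mu_net = ln(Chl_T / Chl_I) / t   [d^-1],

a net rate by definition (no light or grazing corrections).  The maximum
chlorophyll-specific growth rate is the empirical temperature envelope

    mu_max(T) = 0.59 * exp(0.0633 * T)   [d^-1, T in deg C],

and the relative (temperature-normalized) rate is mu_net / mu_max, which may
exceed 1 — the envelope is empirical, not a hard cap.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import Experiment

log = logging.getLogger(__name__)

__all__ = [
    "MU_MAX_COEFF",
    "MU_MAX_EXPONENT",
    "net_growth_rate",
    "net_growth_rates_per_replicate",
    "max_growth_rate",
    "relative_growth",
    "GrowthResponse",
    "compute_responses",
    "response_counts",
]

MU_MAX_COEFF = 0.59  # d^-1 at 0 degC
MU_MAX_EXPONENT = 0.0633  # per degC


def net_growth_rate(chl_T: float, chl_I: float, t: float) -> float:
    """Net chlorophyll-a growth rate ln(chl_T/chl_I)/t in d^-1.

    All arguments must be strictly positive; the sign of the result reflects
    net growth versus decline."""
    if not (chl_T > 0 and chl_I > 0):
        raise ValueError(f"chlorophyll must be > 0 (got chl_T={chl_T}, chl_I={chl_I})")
    if not t > 0:
        raise ValueError(f"duration must be > 0 days (got {t})")
    return math.log(chl_T / chl_I) / t


def net_growth_rates_per_replicate(replicates, chl_I: float, t: float) -> np.ndarray:
    """Per-replicate net growth rates (used by the classifier's statistics,
    where comparing log chlorophyll is equivalent to comparing these)."""
    reps = np.asarray(replicates, dtype=float)
    if np.any(reps <= 0):
        raise ValueError("all replicates must be > 0 for per-replicate rates")
    if not (chl_I > 0 and t > 0):
        raise ValueError("chl_I and t must be > 0")
    return np.log(reps / chl_I) / t


def max_growth_rate(T: float) -> float:
    """Empirical maximum growth rate 0.59*exp(0.0633*T) d^-1 (T in deg C).

    The fit underlying the coefficients spans roughly -2..35 deg C; outside
    that range a warning is emitted and the extrapolated value returned."""
    if not math.isfinite(T):
        raise ValueError(f"temperature must be finite, got {T}")
    if T < -2.0 or T > 35.0:
        warnings.warn(
            f"temperature {T} degC outside the calibrated -2..35 range; extrapolating",
            stacklevel=2,
        )
    return MU_MAX_COEFF * math.exp(MU_MAX_EXPONENT * T)


def relative_growth(mu_net: float, mu_max: float) -> float:
    """Temperature-normalized rate mu_net/mu_max (dimensionless)."""
    if not mu_max > 0:
        raise ValueError(f"mu_max must be > 0, got {mu_max}")
    return mu_net / mu_max


@dataclass(frozen=True)
class GrowthResponse:
    """Growth metrics for one treatment of one experiment.

    ``mu_net`` is computed from the arithmetic mean of replicate final
    chlorophyll; ``mu_max``/``mu_rel`` are absent when the experiment lacks a
    temperature record."""

    experiment_id: str
    added: frozenset
    mu_net: float
    chl_T: float  # replicate-mean final chlorophyll, µg/L
    chl_I: float  # µg/L
    t: float  # days
    mu_max: float | None = None
    mu_rel: float | None = None
    T: float | None = None

    def __post_init__(self):
        if (self.mu_rel is None) != (self.mu_max is None):
            raise ValueError("mu_rel present iff mu_max present")

    @property
    def n_added(self) -> int:
        return len(self.added)


def compute_responses(experiments) -> list:
    """One :class:`GrowthResponse` per treatment (controls included,
    n_added = 0).  Treatments whose replicate-mean final chlorophyll is zero
    have an undefined log-ratio and are skipped with a log entry."""
    out = []
    for exp in experiments:
        if not isinstance(exp, Experiment):
            raise TypeError("compute_responses expects Experiment objects")
        mu_max = None
        if exp.temperature is not None:
            mu_max = max_growth_rate(exp.temperature)
        for tr in exp.treatments:
            chl_T = tr.mean_chl
            if chl_T <= 0 or exp.chl_initial <= 0:
                log.info(
                    "skipping response with non-positive chlorophyll "
                    "(experiment %s, treatment %s)",
                    exp.id,
                    tr.label or "control",
                )
                continue
            mu = net_growth_rate(chl_T, exp.chl_initial, exp.duration)
            out.append(
                GrowthResponse(
                    experiment_id=exp.id,
                    added=tr.added,
                    mu_net=mu,
                    mu_max=mu_max,
                    mu_rel=None if mu_max is None else relative_growth(mu, mu_max),
                    chl_T=chl_T,
                    chl_I=exp.chl_initial,
                    t=exp.duration,
                    T=exp.temperature,
                )
            )
    return out


def response_counts(responses) -> tuple[int, int]:
    """(number of absolute responses, number of relative responses)."""
    n_abs = len(responses)
    n_rel = sum(1 for r in responses if r.mu_rel is not None)
    return n_abs, n_rel
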