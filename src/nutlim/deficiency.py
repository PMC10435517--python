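"""Stoichiometric nutrient-deficiency prediction and agreement scoring.

Dissolved concentrations are normalized to an assumed-average phytoplankton
requirement (relative molar stoichiometry, P = 1) and the resulting
quotients q_i = C_i / R_i arranged in ascending order; the smallest quotient
flags the most-deficient nutrient, i.e. the nutrient predicted to limit (or
first approach limitation of) community growth.  Si and vitamin B12 carry no
requirement coefficient and are excluded.  A prediction requires at least
two measured nutrients.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .core_data import (
    DEFAULT_STOICHIOMETRY,
    Experiment,
    LimitationResult,
    Nutrient,
)

log = logging.getLogger(__name__)

__all__ = [
    "DeficiencyRanking",
    "AgreementRecord",
    "InsufficientNutrientsError",
    "deficiency_ranking",
    "critical_ratio",
    "score_agreement",
    "map_deficiency",
    "AGREEMENT_CATEGORIES",
]

#: exhaustive, mutually exclusive agreement categories
AGREEMENT_CATEGORIES = (
    "correct",
    "incorrect",
    "limiting_not_measured",
    "replete",
    "colimited_including_predicted",
)

_TIE_RTOL = 1e-9


class InsufficientNutrientsError(ValueError):
    """Fewer than two usable nutrient concentrations: no prediction."""


@dataclass
class DeficiencyRanking:
    """Nutrients ordered (ascending) by concentration-to-requirement
    quotient; ties within relative tolerance 1e-9 are flagged and reported
    as joint most-deficient with deterministic alphabetical order."""

    entries: list  # [(Nutrient, quotient mol/L per unit requirement)] ascending
    tied_most_deficient: tuple = ()

    def __post_init__(self):
        if len(self.entries) < 2:
            raise InsufficientNutrientsError(
                "a deficiency prediction requires >= 2 measured nutrients"
            )

    @property
    def n_measured(self) -> int:
        return len(self.entries)

    @property
    def most_deficient(self) -> Nutrient:
        return self.entries[0][0]

    @property
    def quotients(self) -> dict:
        return dict(self.entries)


def _tied(qa: float, qb: float) -> bool:
    scale = max(abs(qa), abs(qb))
    return abs(qa - qb) <= _TIE_RTOL * scale


def deficiency_ranking(concentrations: dict, profile=None) -> DeficiencyRanking:
    """Rank nutrients by q_i = C_i / R_i (concentrations in mol/L).

    Only nutrients present in both the concentration map and the
    stoichiometry profile participate; zero concentrations are legal
    (q_i = 0).  Raises :class:`InsufficientNutrientsError` below two usable
    nutrients."""
    profile = DEFAULT_STOICHIOMETRY if profile is None else profile
    quotients = []
    for nut, conc in concentrations.items():
        if nut not in profile:
            continue
        c = conc.molar if hasattr(conc, "molar") else float(conc)
        if c < 0 or not math.isfinite(c):
            raise ValueError(f"bad concentration for {nut}: {c}")
        quotients.append((nut, c / profile[nut]))
    # ascending quotient, alphabetical symbol as deterministic tie-break
    quotients.sort(key=lambda nq: (nq[1], nq[0].value))
    ranking = DeficiencyRanking(entries=quotients)
    tied = [quotients[0][0]]
    for nut, q in quotients[1:]:
        if _tied(q, quotients[0][1]):
            tied.append(nut)
    if len(tied) > 1:
        ranking.tied_most_deficient = tuple(sorted(tied, key=lambda n: n.value))
    return ranking


def critical_ratio(profile, a: Nutrient, b: Nutrient, units: str = "mol:mol") -> float:
    """Requirement ratio R_a/R_b, the dissolved-ratio threshold separating
    a-deficiency from b-deficiency (e.g. N:Fe = 2.13 mol:mmol, N:P = 16
    mol:mol)."""
    profile = DEFAULT_STOICHIOMETRY if profile is None else profile
    if a not in profile or b not in profile:
        missing = a if a not in profile else b
        raise ValueError(f"no stoichiometric coefficient for {missing}")
    ratio = profile[a] / profile[b]
    if units == "mol:mol":
        return ratio
    if units == "mol:mmol":
        return ratio / 1000.0
    raise ValueError(f"unknown units {units!r}")


@dataclass
class AgreementRecord:
    """Per-experiment comparison of the stoichiometric prediction with the
    experimentally observed limitation."""

    experiment_id: str
    predicted: Nutrient | None
    observed: LimitationResult
    category: str

    def __post_init__(self):
        if self.category not in AGREEMENT_CATEGORIES:
            raise ValueError(f"bad agreement category {self.category!r}")


def _categorize(predicted, measured, observed: LimitationResult) -> str:
    if observed.category == "replete":
        return "replete"
    primary = observed.primary
    if primary.tag == "co":
        if predicted in primary.nutrients:
            return "colimited_including_predicted"
        if any(n not in measured for n in primary.nutrients):
            return "limiting_not_measured"
        return "incorrect"
    if predicted in primary.nutrients:
        return "correct"
    if any(n not in measured for n in primary.nutrients):
        return "limiting_not_measured"
    return "incorrect"


def score_agreement(experiments, profile=None):
    """Score deficiency predictions against recorded limitation outcomes.

    Returns ``(records, summary)`` where summary maps each agreement
    category to its percentage over valid records.  Experiments lacking
    either a usable prediction basis and observation are excluded and
    logged; an experiment whose recorded outcome is indeterminate is
    likewise excluded."""
    profile = DEFAULT_STOICHIOMETRY if profile is None else profile
    records = []
    for exp in experiments:
        obs = exp.recorded_limitation
        if obs is None or obs.category == "indeterminate":
            log.info("experiment %s lacks a usable observed limitation; excluded", exp.id)
            continue
        measured = {n for n in exp.nutrients if n in profile}
        try:
            ranking = deficiency_ranking(exp.nutrients, profile)
            predicted = ranking.most_deficient
        except InsufficientNutrientsError:
            # prediction impossible; attributable only when the true limiter
            # was unmeasured
            if obs.category == "limited" and any(
                n not in measured for n in obs.primary.nutrients
            ):
                records.append(
                    AgreementRecord(exp.id, None, obs, "limiting_not_measured")
                )
            else:
                log.info("experiment %s: <2 measured nutrients; excluded", exp.id)
            continue
        records.append(
            AgreementRecord(exp.id, predicted, obs, _categorize(predicted, measured, obs))
        )
    n = len(records)
    summary = {
        cat: (100.0 * sum(1 for r in records if r.category == cat) / n if n else float("nan"))
        for cat in AGREEMENT_CATEGORIES
    }
    return records, summary


def map_deficiency(stations, profile=None) -> pd.DataFrame:
    """Per-station most-deficient nutrient (the GEOTRACES-style application).

    Stations failing the >= 2 measured nutrient criterion are retained with
    ``no_prediction`` marked."""
    profile = DEFAULT_STOICHIOMETRY if profile is None else profile
    rows = []
    for st in stations:
        row = {
            "station_id": st.id,
            "lat": st.latitude,
            "lon": st.longitude,
            "most_deficient": "",
            "n_measured": 0,
            "tie": "",
            "no_prediction": False,
        }
        try:
            ranking = deficiency_ranking(st.nutrients, profile)
        except InsufficientNutrientsError:
            row["no_prediction"] = True
            row["n_measured"] = sum(1 for n in st.nutrients if n in profile)
        else:
            row["most_deficient"] = ranking.most_deficient.value
            row["n_measured"] = ranking.n_measured
            row["tie"] = "+".join(n.value for n in ranking.tied_most_deficient)
        rows.append(row)
    return pd.DataFrame(rows)
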