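"""Dataset-level statistics: growth vs number of nutrients added, covariate
regressions, response-vs-dissolved-ratio analyses, and kernel densities.

The central meta-analytic questions are (i) whether supplying more distinct
nutrients yields systematically higher net growth (one-way ANOVA with Tukey
HSD letters plus a simple regression on the number of nutrients added), and
(ii) whether the dissolved N:Fe and N:P ratios predict the magnitude of the
growth response to each addition type, with the assumed-average requirement
ratio as the critical reference line.
"""
from __future__ import annotations

import itertools
import logging
import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DEFAULT_STOICHIOMETRY, Nutrient, format_added
from .deficiency import critical_ratio

log = logging.getLogger(__name__)

__all__ = [
    "GroupStats",
    "RegressionFit",
    "group_stats",
    "ols_fit",
    "ratio_response_analysis",
    "RatioAnalysis",
    "kde",
    "compact_letter_display",
]


@dataclass
class GroupStats:
    """Summary of one n-added group; groups sharing a Tukey letter are not
    significantly different at the ANOVA alpha."""

    key: int  # number of nutrients added (3 = "3 or more")
    n: int
    mean: float
    sd: float
    letter: str = ""


@dataclass
class RegressionFit:
    """Simple least-squares fit with the F-test p-value (identical to the
    two-sided slope t-test for one predictor)."""

    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self):
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"R^2 out of range: {self.r_squared}")
        if self.n < 3:
            raise ValueError("regression requires n >= 3")


def compact_letter_display(keys, significant_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant_pairs`` is an iterable of 2-tuples of keys whose means
    differ significantly; keys sharing a letter in the result are not
    significantly different.  Letters are assigned in the order ``keys`` is
    given (conventionally by ascending group mean)."""
    keys = list(keys)
    sig = {frozenset(p) for p in significant_pairs}
    letter_sets = [set(keys)]
    for pair in sig:
        a, b = tuple(pair)
        for ls in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(ls)
            letter_sets.extend([ls - {a}, ls - {b}])
        # absorb: drop sets contained in another
        letter_sets = [
            s for s in letter_sets
            if s and not any(s < t for t in letter_sets)
        ]
    # deterministic ordering: by first member's position in `keys`
    letter_sets.sort(key=lambda s: [keys.index(k) for k in sorted(s, key=keys.index)])
    letters = {k: "" for k in keys}
    for ls, ch in zip(letter_sets, string.ascii_lowercase):
        for k in ls:
            letters[k] += ch
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def group_stats(responses, normalized: bool = False, alpha: float = 0.05,
                max_group: int = 3):
    """Group growth responses by number of nutrients added (0..max_group+,
    the top group pooling all larger additions) and attach one-way ANOVA
    with Tukey-HSD compact letters.

    ``normalized`` selects the temperature-normalized rate (responses
    without a temperature are dropped, mirroring the absolute-to-relative
    attrition).  Returns ``(groups, anova_f, anova_p)``; with fewer than two
    usable groups the letters stay empty and the ANOVA statistics are NaN."""
    values: dict[int, list] = {}
    for r in responses:
        v = r.mu_rel if normalized else r.mu_net
        if v is None:
            continue
        key = min(r.n_added, max_group)
        values.setdefault(key, []).append(float(v))
    keys = sorted(values)
    groups = [
        GroupStats(
            key=k,
            n=len(values[k]),
            mean=float(np.mean(values[k])),
            sd=float(np.std(values[k], ddof=1)) if len(values[k]) > 1 else float("nan"),
        )
        for k in keys
    ]
    usable = [k for k in keys if len(values[k]) >= 2]
    if len(usable) < 2:
        return groups, float("nan"), float("nan")
    samples = [values[k] for k in usable]
    f, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    sig_pairs = [
        (usable[i], usable[j])
        for i, j in itertools.combinations(range(len(usable)), 2)
        if tukey.pvalue[i, j] <= alpha
    ]
    order = sorted(usable, key=lambda k: np.mean(values[k]))
    letters = compact_letter_display(order, sig_pairs)
    for g in groups:
        g.letter = letters.get(g.key, "")
    return groups, float(f), float(p)


def ols_fit(x, y, predictor: str = "x", response: str = "y") -> RegressionFit:
    """Least-squares simple regression after pairwise deletion of
    non-finite values; R^2 = 1 - SSE/SST = squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"regression requires >= 3 finite pairs, got {len(x)}")
    if np.var(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return RegressionFit(
        predictor=predictor,
        response=response,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


@dataclass
class RatioAnalysis:
    """Regressions of growth response on the log10 dissolved ratio, split by
    addition type, with the critical requirement ratio as reference."""

    pair: tuple
    ratio_units: str
    critical: float  # requirement ratio in ratio_units
    fits: dict = field(default_factory=dict)  # (addition, metric) -> RegressionFit
    excluded: int = 0  # experiments with nonpositive / missing ratio


def dissolved_ratio(experiment, a: Nutrient, b: Nutrient, units: str) -> float | None:
    """Ambient molar ratio of a to b; mol:mmol divides by 1000."""
    ca = experiment.nutrients.get(a)
    cb = experiment.nutrients.get(b)
    if ca is None or cb is None:
        return None
    if cb.molar <= 0:
        return None
    r = ca.molar / cb.molar
    return r / 1000.0 if units == "mol:mmol" else r


def ratio_response_analysis(responses, experiments, pair=(Nutrient.N, Nutrient.Fe),
                            profile=None) -> RatioAnalysis:
    """For each addition type (first nutrient alone, second alone, both
    combined), regress mu_net and mu_rel on log10 of the dissolved ratio.

    N:Fe is reported in mol:mmol, all other pairs in mol:mol (the units in
    which the critical requirement ratios are conventionally quoted).
    Experiments with a zero or missing denominator are excluded and counted
    (concentrations at the detection limit avoid this)."""
    profile = DEFAULT_STOICHIOMETRY if profile is None else profile
    a, b = pair
    units = "mol:mmol" if (a, b) == (Nutrient.N, Nutrient.Fe) else "mol:mol"
    out = RatioAnalysis(
        pair=(a, b), ratio_units=units,
        critical=critical_ratio(profile, a, b, units),
    )
    by_exp = {}
    excluded = set()
    for exp in experiments:
        r = dissolved_ratio(exp, a, b, units)
        if r is None or r <= 0:
            excluded.add(exp.id)
            log.info(
                "experiment %s excluded from %s:%s ratio analysis "
                "(nonpositive or missing ratio; consider storing the "
                "detection limit for censored values)", exp.id, a, b,
            )
            continue
        by_exp[exp.id] = math.log10(r)
    out.excluded = len(excluded)

    additions = {
        a.value: frozenset({a}),
        b.value: frozenset({b}),
        format_added({a, b}): frozenset({a, b}),
    }
    for label, added in additions.items():
        for metric in ("mu_net", "mu_rel"):
            pts = [
                (by_exp[r.experiment_id], getattr(r, metric))
                for r in responses
                if r.added == added and r.experiment_id in by_exp
                and getattr(r, metric) is not None
            ]
            if len(pts) < 3:
                continue
            x, y = zip(*pts)
            try:
                fit = ols_fit(
                    x, y,
                    predictor=f"log10({a}:{b} {units})",
                    response=f"{metric}[{label}]",
                )
            except ValueError:
                continue
            out.fits[(label, metric)] = fit
    return out


def _nrd0_bandwidth(values: np.ndarray) -> float:
    """R density()-style default bandwidth 0.9*min(sd, IQR/1.34)*n^(-1/5),
    with the usual degenerate-spread guards."""
    n = len(values)
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    lo = min(sd, iqr / 1.34)
    if lo == 0:
        lo = sd or abs(float(values[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


def kde(values, bandwidth: float | None = None, n_grid: int = 512,
        cut: float = 3.0):
    """Gaussian kernel density estimate on a regular grid.

    Returns ``(grid, density)``; the default bandwidth follows the nrd0
    rule.  Requires at least two observations."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("kde requires at least 2 observations")
    bw = _nrd0_bandwidth(values) if bandwidth is None else float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(values.min() - cut * bw, values.max() + cut * bw, n_grid)
    z = (grid[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (len(values) * bw * math.sqrt(2 * math.pi))
    return grid, dens
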