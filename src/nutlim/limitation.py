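"""Primary / co- / serial nutrient-limitation classification.

A factorial addition bioassay is read as a lattice of nutrient-addition
sets.  Significant positive chlorophyll-a enhancement of a treatment over
the unamended control identifies the primary limiting nutrient(s); when no
single addition responds but a combined addition does, the pair is
independently co-limiting; once a primary level is established, additions on
top of the primary set that stimulate further growth identify serial
(secondary, then tertiary) limitation.

Two test backends are offered.  ``welch_t`` performs a one-sided Welch test
of mean(b) > mean(a) per comparison (robust to unequal variances, matching
common source-study practice).  ``anova_tukey`` computes studentized-range
(Tukey HSD) adjusted p-values over all treatments of the experiment at once,
controlling the family-wise error rate of the whole classification.
Comparisons can run on raw chlorophyll (``scale="chl"``) or on log
chlorophyll (``scale="log"``), the latter being equivalent to comparing
per-replicate net growth rates and homoscedastic under multiplicative
replicate noise.

Only positive enhancements count as limitation evidence: a significant
*decline* is never classified as limitation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    Experiment,
    Level,
    LimitationResult,
    Nutrient,
    format_added,
    format_limitation,
)

__all__ = [
    "ComparisonResult",
    "LimitationResult",
    "Level",
    "compare",
    "classify",
    "summarize_dataset",
    "DatasetSummary",
    "MesoscaleDesignError",
]


class MesoscaleDesignError(ValueError):
    """Raised when statistical classification is requested for a single-
    replicate mesoscale in-situ enrichment experiment."""


@dataclass
class ComparisonResult:
    """Outcome of one treatment-vs-baseline comparison."""

    set_a: frozenset
    set_b: frozenset
    mean_diff: float  # mean(b) - mean(a) on the analysis scale
    p_value: float
    significant: bool
    direction: str  # "increase" | "decrease" | "none"
    note: str = ""

    def __post_init__(self):
        if self.significant and self.direction != "increase":
            raise ValueError("only positive enhancements may be significant")

    @property
    def indeterminate(self) -> bool:
        return self.note.startswith("indeterminate")

    def label(self) -> str:
        a = format_added(self.set_a) or "control"
        b = format_added(self.set_b) or "control"
        return f"{b} vs {a}"


def _transform(reps, scale):
    arr = np.asarray(reps, dtype=float)
    if scale == "log":
        if np.any(arr <= 0):
            raise ValueError("log scale requires strictly positive replicates")
        return np.log(arr)
    if scale != "chl":
        raise ValueError(f"unknown scale {scale!r}")
    return arr


def _welch_one_sided(a, b):
    res = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
    return float(res.pvalue)


def compare(reps_a, reps_b, alpha: float = 0.05, method: str = "welch_t",
            scale: str = "chl", set_a=frozenset(), set_b=frozenset(),
            p_override: float | None = None) -> ComparisonResult:
    """Compare two replicate groups; significance means mean(b) exceeds
    mean(a) at level ``alpha``.

    With fewer than 3 replicates in either group the comparison is flagged
    indeterminate and never significant.  ``p_override`` lets a family-wise
    procedure substitute an adjusted p-value."""
    a = _transform(reps_a, scale)
    b = _transform(reps_b, scale)
    diff = float(np.mean(b) - np.mean(a))
    direction = "increase" if diff > 0 else ("decrease" if diff < 0 else "none")
    if len(a) < 3 or len(b) < 3:
        return ComparisonResult(
            frozenset(set_a), frozenset(set_b), diff, float("nan"), False,
            direction, note="indeterminate: fewer than 3 replicates",
        )
    if np.var(a) == 0 and np.var(b) == 0:
        # noiseless replicates: the contrast is deterministic
        p = 0.0 if diff > 0 else 1.0
    elif p_override is not None:
        p = float(p_override)
    elif method == "welch_t":
        p = _welch_one_sided(a, b)
    elif method == "anova_tukey":
        p = float(stats.tukey_hsd(a, b).pvalue[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    sig = bool(p <= alpha and diff > 0)
    return ComparisonResult(frozenset(set_a), frozenset(set_b), diff, p, sig, direction)


def _holm_adjust(pvalues):
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


class _Comparator:
    """Per-experiment comparison engine with optional Tukey family and
    optional Holm adjustment over the full comparison lattice."""

    def __init__(self, groups, alpha, method, scale, holm):
        self.groups = {k: _transform(v, scale) for k, v in groups.items()}
        self.alpha = alpha
        self.method = method
        self.scale = scale
        self._adjusted = None
        if method == "anova_tukey":
            self._keys = sorted(self.groups, key=lambda s: (len(s), format_added(s)))
            usable = [k for k in self._keys if len(self.groups[k]) >= 2]
            if len(usable) >= 2:
                res = stats.tukey_hsd(*(self.groups[k] for k in usable))
                idx = {k: i for i, k in enumerate(usable)}
                self._tukey_p = {
                    frozenset((a, b)): float(res.pvalue[idx[a], idx[b]])
                    for a in usable
                    for b in usable
                    if a != b
                }
            else:
                self._tukey_p = {}
        if holm:
            self._adjusted = self._precompute_holm()

    def _family(self):
        """Every comparison the lattice traversal could consult: additions vs
        control and each treatment vs an immediate subset treatment."""
        fam = []
        control = frozenset()
        for k in self.groups:
            if k and control in self.groups:
                fam.append((control, k))
        for a in self.groups:
            for b in self.groups:
                if a and a < b:
                    fam.append((a, b))
        return fam

    def _raw_p(self, ka, kb):
        a, b = self.groups[ka], self.groups[kb]
        if len(a) < 3 or len(b) < 3:
            return None
        if self.method == "welch_t":
            return _welch_one_sided(a, b)
        key = frozenset((ka, kb))
        if key in self._tukey_p:
            return self._tukey_p[key]
        return float(stats.tukey_hsd(a, b).pvalue[0, 1])

    def _precompute_holm(self):
        fam = self._family()
        raw = {pair: self._raw_p(*pair) for pair in fam}
        defined = [pair for pair in fam if raw[pair] is not None]
        adj = _holm_adjust([raw[p] for p in defined]) if defined else []
        return dict(zip(defined, adj))

    def __call__(self, ka, kb) -> ComparisonResult:
        p = None
        if self._adjusted is not None:
            p = self._adjusted.get((ka, kb))
        elif self.method == "anova_tukey":
            p = self._tukey_p.get(frozenset((ka, kb)))
        return compare(
            self.groups[ka], self.groups[kb], alpha=self.alpha,
            method=self.method, scale="chl",  # already transformed
            set_a=ka, set_b=kb, p_override=p,
        )


def classify(experiment: Experiment, alpha: float = 0.05,
             method: str = "welch_t", scale: str = "chl",
             holm: bool = False) -> LimitationResult:
    """Classify a factorial bottle experiment into a limitation hierarchy.

    Deterministic traversal of the addition lattice:

    1. every single addition vs control — significant increases form the
       primary level (several independent responses are flagged
       ``multiple_primary``);
    2. if no single addition responds, every available pair vs control — a
       significant pair is primary co-limitation (ties broken by largest
       mean effect, alternates flagged); with no pairs available the
       experiment is indeterminate (co-limitation untestable);
    3. serial levels: with base set B = union of the previous level, each
       B∪{x} treatment vs the literal B treatment (no imputation: a missing
       base treatment stops serial testing, flagged ``no_base_treatment``);
       a pairwise extension B∪{x,y} counts as serial co-limitation only when
       neither single extension responds.  Repeated once more for tertiary;
    4. nothing significant anywhere and all comparisons determinate →
       replete.
    """
    if experiment.design == "mesoscale_in_situ":
        raise MesoscaleDesignError(
            f"experiment {experiment.id} is a mesoscale in-situ enrichment "
            "(single replicate); it is stored for comparison but never "
            "classified statistically"
        )
    if experiment.control is None:
        return LimitationResult(
            category="indeterminate", reason="missing_control"
        )
    groups = {t.added: t.chl_final for t in experiment.treatments}
    cmp = _Comparator(groups, alpha, method, scale, holm)
    comparisons: list[ComparisonResult] = []
    flags: list[str] = []
    control = frozenset()

    def run(ka, kb):
        c = cmp(ka, kb)
        comparisons.append(c)
        return c

    # --- step 1: primary singles ------------------------------------------
    singles = sorted((k for k in groups if len(k) == 1),
                     key=format_added)
    sig_singles = [k for k in singles if run(control, k).significant]

    levels: list[Level] = []
    if sig_singles:
        nuts = frozenset().union(*sig_singles)
        levels.append(Level(nutrients=nuts, tag="single"))
        if len(sig_singles) > 1:
            flags.append("multiple_primary")
    else:
        # --- step 2: primary co-limitation via pairs ----------------------
        pairs = sorted((k for k in groups if len(k) == 2), key=format_added)
        if not pairs:
            if not singles:
                return LimitationResult(
                    category="indeterminate",
                    comparisons=comparisons,
                    reason="no_testable_additions",
                )
            return LimitationResult(
                category="indeterminate",
                comparisons=comparisons,
                reason="co_limitation_untestable",
            )
        sig_pairs = [(k, c.mean_diff) for k in pairs
                     if (c := run(control, k)).significant]
        if sig_pairs:
            sig_pairs.sort(key=lambda kv: (-kv[1], format_added(kv[0])))
            best = sig_pairs[0][0]
            levels.append(Level(nutrients=best, tag="co"))
            for alt, _ in sig_pairs[1:]:
                flags.append(f"alternate_co:{format_added(alt)}")

    # --- step 3: serial levels --------------------------------------------
    while levels and len(levels) < 3:
        base = frozenset().union(*(lv.nutrients for lv in levels))
        if base not in groups:
            flags.append("no_base_treatment")
            break
        exts = sorted(
            (k for k in groups if base < k and len(k) == len(base) + 1),
            key=format_added,
        )
        sig_exts = [k for k in exts if run(base, k).significant]
        if sig_exts:
            nuts = frozenset().union(*(k - base for k in sig_exts))
            levels.append(Level(nutrients=nuts, tag="single"))
            if len(sig_exts) > 1:
                flags.append(f"multiple_level_{len(levels)}")
            continue
        # serial co: a two-nutrient extension beats the base while neither
        # single extension does
        co_exts = sorted(
            (k for k in groups if base < k and len(k) == len(base) + 2),
            key=format_added,
        )
        sig_co = [(k, c.mean_diff) for k in co_exts
                  if (c := run(base, k)).significant]
        if sig_co:
            sig_co.sort(key=lambda kv: (-kv[1], format_added(kv[0])))
            levels.append(Level(nutrients=sig_co[0][0] - base, tag="co"))
            for alt, _ in sig_co[1:]:
                flags.append(f"alternate_serial_co:{format_added(alt - base)}")
            continue
        break

    if levels:
        return LimitationResult(
            category="limited", levels=levels,
            comparisons=comparisons, flags=flags,
        )

    # --- step 4: replete vs indeterminate ---------------------------------
    if comparisons and all(not c.indeterminate for c in comparisons):
        return LimitationResult(
            category="replete", comparisons=comparisons, flags=flags
        )
    return LimitationResult(
        category="indeterminate",
        comparisons=comparisons,
        flags=flags,
        reason="insufficient_replication",
    )


@dataclass
class DatasetSummary:
    """Counts and percentages per limitation regime."""

    table: pd.DataFrame
    co_serial_fraction: float = float("nan")


def summarize_dataset(results) -> DatasetSummary:
    """Tabulate regime proportions over a list of :class:`LimitationResult`
    (or ``(experiment_id, result)`` pairs)."""
    flat = [r[1] if isinstance(r, tuple) else r for r in results]
    if not flat:
        return DatasetSummary(
            table=pd.DataFrame(columns=["regime", "n", "percent"])
        )
    labels = [format_limitation(r) for r in flat]
    counts = pd.Series(labels).value_counts()
    table = pd.DataFrame(
        {
            "regime": counts.index,
            "n": counts.values,
            "percent": 100.0 * counts.values / len(flat),
        }
    ).reset_index(drop=True)
    co_serial = sum(1 for r in flat if r.is_co_or_serial)
    return DatasetSummary(table=table, co_serial_fraction=co_serial / len(flat))
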