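"""Shared test utilities: toy-experiment builders and independent
brute-force oracles the implementation is checked against."""
from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from nutlim.core_data import (
    Concentration,
    Experiment,
    Level,
    LimitationResult,
    Nutrient,
    Treatment,
    format_added,
)

#: deterministic multiplicative jitter giving every treatment a small,
#: nonzero replicate variance (CV ~ 2%)
JITTER = (0.98, 1.00, 1.02)


def make_experiment(means, exp_id="toy", temperature=15.0, duration=2.0,
                    chl_initial=0.2, nutrients=None, design="bottle",
                    jitter=JITTER, recorded=None):
    """Build a bottle experiment from {added-set: mean final chl}."""
    treatments = [
        Treatment(
            added=frozenset(added),
            chl_final=tuple(m * j for j in jitter),
            label=format_added(added) or "control",
        )
        for added, m in means.items()
    ]
    return Experiment(
        id=exp_id,
        latitude=10.0,
        longitude=-30.0,
        temperature=temperature,
        duration=duration,
        chl_initial=chl_initial,
        nutrients=nutrients or {},
        treatments=treatments,
        design=design,
        recorded_limitation=recorded,
    )


def _welch_increase_p(reps_a, reps_b):
    res = stats.ttest_ind(reps_b, reps_a, equal_var=False, alternative="greater")
    return float(res.pvalue)


def brute_force_classify(experiment, alpha=0.05):
    """Independent reference classifier: enumerates every subset comparison
    explicitly with plain scipy Welch tests, mirroring the documented
    traversal semantics step by step."""
    groups = {t.added: np.asarray(t.chl_final, float) for t in experiment.treatments}
    control = frozenset()
    if control not in groups:
        return LimitationResult(category="indeterminate", reason="missing_control")

    def sig_increase(a, b):
        if np.mean(groups[b]) <= np.mean(groups[a]):
            return False
        return _welch_increase_p(groups[a], groups[b]) <= alpha

    all_sets = sorted(groups, key=lambda s: (len(s), format_added(s)))
    levels, flags = [], []

    sig_singles = [s for s in all_sets if len(s) == 1 and sig_increase(control, s)]
    if sig_singles:
        levels.append(Level(frozenset().union(*sig_singles), "single"))
        if len(sig_singles) > 1:
            flags.append("multiple_primary")
    else:
        pairs = [s for s in all_sets if len(s) == 2]
        if not pairs:
            singles_exist = any(len(s) == 1 for s in all_sets)
            return LimitationResult(
                category="indeterminate",
                reason="co_limitation_untestable" if singles_exist
                else "no_testable_additions",
            )
        sig_pairs = [s for s in pairs if sig_increase(control, s)]
        if sig_pairs:
            # documented tie rule: largest mean effect, then alphabetical
            best = sorted(
                sig_pairs,
                key=lambda s: (np.mean(groups[control]) - np.mean(groups[s]),
                               format_added(s)),
            )[0]
            levels.append(Level(best, "co"))
            for alt in sig_pairs:
                if alt != best:
                    flags.append(f"alternate_co:{format_added(alt)}")

    while levels and len(levels) < 3:
        base = frozenset().union(*(lv.nutrients for lv in levels))
        if base not in groups:
            flags.append("no_base_treatment")
            break
        ext1 = [s for s in all_sets if base < s and len(s) == len(base) + 1
                and sig_increase(base, s)]
        if ext1:
            levels.append(Level(frozenset().union(*(s - base for s in ext1)),
                                "single"))
            if len(ext1) > 1:
                flags.append(f"multiple_level_{len(levels)}")
            continue
        ext2 = [s for s in all_sets if base < s and len(s) == len(base) + 2
                and sig_increase(base, s)]
        if ext2:
            best = sorted(
                ext2,
                key=lambda s: (np.mean(groups[base]) - np.mean(groups[s]),
                               format_added(s - base)),
            )[0]
            levels.append(Level(best - base, "co"))
            for alt in ext2:
                if alt != best:
                    flags.append(
                        f"alternate_serial_co:{format_added(alt - base)}")
            continue
        break

    if levels:
        return LimitationResult(category="limited", levels=levels, flags=flags)
    return LimitationResult(category="replete", flags=flags)


def random_toy_battery(n_cases=100, seed=20240501):
    """Deterministic battery of random factorial toys over <= 3 nutrients:
    random treatment means on a coarse grid, small lognormal replicate
    scatter."""
    rng = np.random.default_rng(seed)
    mean_grid = np.array([0.2, 0.35, 0.6, 1.0, 1.8, 3.2, 5.6])
    panel3 = [Nutrient.N, Nutrient.Fe, Nutrient.Co]
    cases = []
    for i in range(n_cases):
        k = int(rng.integers(2, 4))
        nuts = panel3[:k]
        subsets = [
            frozenset(c)
            for r in range(k + 1)
            for c in itertools.combinations(nuts, r)
        ]
        means = {s: float(rng.choice(mean_grid)) for s in subsets}
        jitter = tuple(np.exp(rng.normal(0.0, 0.03, 3)))
        cases.append(make_experiment(means, exp_id=f"toy-{i}", jitter=jitter))
    return cases


def letters_are_valid(letters, keys, sig_pairs):
    """Defining property of a compact letter display, checked against the
    explicit all-pairs significance list."""
    sig = {frozenset(p) for p in sig_pairs}
    for a, b in itertools.combinations(keys, 2):
        shared = set(letters[a]) & set(letters[b])
        if frozenset((a, b)) in sig and shared:
            return False
        if frozenset((a, b)) not in sig and not shared:
            return False
    return True
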