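"""Temporal variability analysis of index values across stations and years.

The workhorse is a one-way ANOVA on log10(x+1)-transformed index values
followed by Tukey's honestly-significant-difference test over all station
pairs (Tukey–Kramer correction for unequal n), summarised as a compact
letter display: stations sharing a letter are not significantly different.

The advective/diffusive contrast is reported as the ratio of arithmetic
means of the *untransformed* index between the two sediment systems,
with its significance taken from the Tukey test on the system factor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def log10p1(x):
    """log10(x + 1), the standard transform for right-skewed index values."""
    return np.log10(np.asarray(x, dtype=float) + 1.0)


@dataclass
class GroupComparison:
    """Result of an ANOVA + Tukey HSD comparison across groups."""

    groups: Sequence[str]
    means: Mapping[str, float]            # on the analysis (transformed) scale
    n: Mapping[str, int]
    pvalues: Mapping[tuple[str, str], float]  # adjusted, two-sided
    letters: Mapping[str, str]
    transform: str
    alpha: float
    anova_f: float
    anova_p: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.groups),
                "n": [self.n[g] for g in self.groups],
                "mean_transformed": [self.means[g] for g in self.groups],
                "letters": [self.letters[g] for g in self.groups],
            }
        )


def station_boxstats(
    values: Sequence[float],
    stations: Sequence[str],
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Five-number summaries (min, Q1, median, Q3, max) per station.

    Quartiles use linear interpolation.  ``order`` lets the caller impose
    the display ordering (e.g. system first, then descending salinity);
    by default stations appear in first-occurrence order.
    """
    values = np.asarray(values, dtype=float)
    stations = list(stations)
    if len(values) != len(stations):
        raise ValueError("values and stations must align")
    if order is None:
        order = list(dict.fromkeys(stations))
    rows = []
    for st in order:
        v = values[[i for i, s in enumerate(stations) if s == st]]
        if v.size == 0:
            raise ValueError(f"station {st!r} has no values")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {"station": st, "min": v.min(), "q1": q1, "median": med,
             "q3": q3, "max": v.max(), "n": v.size}
        )
    return pd.DataFrame(rows)


def _tukey_pairwise(
    groups: Sequence[str],
    data: Mapping[str, np.ndarray],
) -> tuple[dict[tuple[str, str], float], float, float]:
    """All-pairs Tukey–Kramer adjusted p-values plus the one-way ANOVA F, p.

    p-values come from the studentized-range distribution with the pooled
    within-group variance; with zero within-group variance everywhere the
    comparison degenerates to exact separation (p = 0 for unequal means,
    p = 1 for equal ones).
    """
    k = len(groups)
    ns = {g: data[g].size for g in groups}
    means = {g: float(data[g].mean()) for g in groups}
    N = sum(ns.values())
    df_w = N - k
    if df_w < 1:
        raise ValueError("Tukey HSD needs at least one group with >= 2 values")
    ssw = sum(float(((data[g] - means[g]) ** 2).sum()) for g in groups)
    msw = ssw / df_w

    grand = sum(means[g] * ns[g] for g in groups) / N
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in groups)
    if msw > 0:
        f = (ssb / (k - 1)) / msw
        anova_p = float(stats.f.sf(f, k - 1, df_w))
    else:
        f = math.inf if ssb > 0 else 0.0
        anova_p = 0.0 if ssb > 0 else 1.0

    pvals: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(groups, 2):
        diff = abs(means[a] - means[b])
        if msw > 0:
            se = math.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = diff / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        else:
            p = 1.0 if diff == 0 else 0.0
        pvals[(a, b)] = p
    return pvals, f, anova_p


def compact_letters(
    groups: Sequence[str],
    pvalues: Mapping[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Guarantees: two groups share a letter iff their adjusted p >= alpha.
    Starts from one letter covering all groups; every significant pair
    splits the letter sets containing both; duplicate/subset sets are
    absorbed.  Letters are assigned in order of each set's first group.
    """
    idx = {g: i for i, g in enumerate(groups)}
    sets: list[set[str]] = [set(groups)]
    for (a, b), p in sorted(pvalues.items(), key=lambda kv: (idx[kv[0][0]], idx[kv[0][1]])):
        if p >= alpha:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop empties, proper subsets and duplicates
        sets = []
        for s in new_sets:
            if not s or any(s < t for t in new_sets) or s in sets:
                continue
            sets.append(s)
    sets.sort(key=lambda s: min(idx[g] for g in s))
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, s in enumerate(sets):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in s:
            letters[g] += ch
    return letters


def tukey_letters(
    values: Sequence[float],
    labels: Sequence[str],
    alpha: float = 0.05,
    transform: Callable | None = log10p1,
) -> GroupComparison:
    """One-way ANOVA + Tukey HSD with a compact letter display.

    Values are transformed (default log10(x+1)) before the comparison; the
    reported means are on the transformed scale.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must align")
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    tname = "identity" if transform is None else getattr(transform, "__name__", "custom")
    t = (lambda x: np.asarray(x, dtype=float)) if transform is None else transform
    data = {
        g: t(values[[i for i, l in enumerate(labels) if l == g]]) for g in groups
    }
    for g, v in data.items():
        if v.size < 1:
            raise ValueError(f"group {g!r} is empty")
    pvals, f, anova_p = _tukey_pairwise(groups, data)
    letters = compact_letters(groups, pvals, alpha)
    return GroupComparison(
        groups=groups,
        means={g: float(data[g].mean()) for g in groups},
        n={g: int(data[g].size) for g in groups},
        pvalues=pvals,
        letters=letters,
        transform=tname,
        alpha=alpha,
        anova_f=float(f),
        anova_p=float(anova_p),
    )


def system_contrast(
    values: Sequence[float],
    systems: Sequence[str],
    transform: Callable | None = log10p1,
) -> tuple[float, float]:
    """Advective/diffusive contrast of mean index values.

    Returns ``(ratio, p)`` where ratio is the advective over diffusive
    arithmetic mean of the *untransformed* values and p is the Tukey HSD
    adjusted p-value on the (transformed) two-level system factor.
    """
    values = np.asarray(values, dtype=float)
    systems = list(systems)
    present = set(systems)
    if not {"diffusive", "advective"} <= present:
        raise ValueError("both systems must be represented")
    adv = values[[i for i, s in enumerate(systems) if s == "advective"]]
    dif = values[[i for i, s in enumerate(systems) if s == "diffusive"]]
    if dif.mean() == 0:
        raise ValueError("diffusive mean is zero; ratio undefined")
    ratio = float(adv.mean() / dif.mean())
    cmp = tukey_letters(values, systems, transform=transform)
    key = next(iter(cmp.pvalues))
    return ratio, float(cmp.pvalues[key])
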