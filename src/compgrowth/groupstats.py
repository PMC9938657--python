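"""One-way ANOVA, Tukey HSD and compact-letter displays.

The comparison machinery used on every endpoint of the trial: a
classical one-way between/within decomposition (F, degrees of freedom,
p from the F distribution), Tukey's honestly-significant-difference test
on all group pairs (Tukey-Kramer denominator when group sizes differ),
and the compact-letter display in which groups sharing a letter are not
significantly different at the chosen alpha.

The F statistic and Tukey p-values are delegated to scipy
(``f_oneway`` / ``tukey_hsd``); the letter assignment uses the
insert-and-absorb algorithm with letters ordered by descending group
mean (ties broken by label) so displays are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "groups_from_frame",
]


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        out[str(name)] = arr
    return out


def groups_from_frame(
    frame: pd.DataFrame, group_col: str = "group", value_col: str = "value"
) -> dict[str, np.ndarray]:
    """Split a tidy (group, value) frame into a label -> values mapping."""
    return {
        str(g): sub[value_col].to_numpy(dtype=float)
        for g, sub in frame.groupby(group_col, sort=True)
    }


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    letters: dict[str, str]
    alpha: float


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs Tukey HSD table.

    Returns one row per unordered pair with the mean difference, the
    studentized-range p-value and a significance flag at ``alpha``.
    Unequal group sizes use the Tukey-Kramer standard error.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    data = _validate_groups(groups)
    names = list(data)
    res = stats.tukey_hsd(*data.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mean_diff = float(np.mean(data[names[i]]) - np.mean(data[names[j]]))
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": mean_diff,
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def compact_letter_display(
    pairwise: pd.DataFrame, means: Mapping[str, float]
) -> dict[str, str]:
    """Assign compact letters from a pairwise significance table.

    Insert-and-absorb: start with a single letter set holding all groups;
    for every significant pair split any set containing both; absorb sets
    contained in others. Groups share a letter iff no significant
    difference separates them within some set. Letters are labelled
    'a', 'b', ... over sets ordered by the best (highest-mean) group they
    contain; each group's string lists its letters alphabetically.
    """
    names = sorted(means, key=lambda g: (-means[g], g))
    name_set = set(names)
    seen = set()
    for _, row in pairwise.iterrows():
        pair = frozenset((str(row["group1"]), str(row["group2"])))
        if not pair <= name_set:
            raise ValueError(f"pairwise table references unknown groups {set(pair)}")
        seen.add(pair)
    expected = {
        frozenset((a, b)) for i, a in enumerate(names) for b in names[i + 1 :]
    }
    if seen != expected:
        missing = expected - seen
        raise ValueError(f"pairwise table incomplete; missing pairs {missing}")

    sets: list[set[str]] = [set(names)]
    sig_pairs = [
        (str(r["group1"]), str(r["group2"]))
        for _, r in pairwise.iterrows()
        if bool(r["significant"])
    ]
    for a, b in sig_pairs:
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend((s - {a}, s - {b}))
            else:
                new_sets.append(s)
        # absorb: drop any set contained in another
        sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(i != j and s < t for j, t in enumerate(new_sets))
        ]
        # deduplicate while keeping order
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq

    # letters ordered by the strongest group each set contains
    rank = {g: i for i, g in enumerate(names)}
    sets.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, s in zip(alphabet, sets):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in names}


def one_way_anova(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """Classical one-way ANOVA with Tukey letters.

    F and p come from the between/within decomposition (p from the F
    distribution with (g-1, N-g) degrees of freedom); the compact-letter
    display is derived from the Tukey HSD pairwise table at ``alpha``.
    Identical groups give F = 0, p = 1 and a shared letter.
    """
    data = _validate_groups(groups)
    values = list(data.values())
    n_total = sum(v.size for v in values)
    f_stat, p_value = stats.f_oneway(*values)
    f_stat = float(f_stat)
    if not np.isfinite(f_stat):  # zero within-group variance
        raise ValueError("ANOVA undefined: zero variance within every group")
    means = {g: float(np.mean(v)) for g, v in data.items()}
    pairwise = tukey_hsd(data, alpha=alpha)
    return AnovaResult(
        f_stat=f_stat,
        df_between=len(data) - 1,
        df_within=n_total - len(data),
        p_value=float(p_value),
        group_means=means,
        letters=compact_letter_display(pairwise, means),
        alpha=alpha,
    )
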