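"""One-way ANOVA with Tukey HSD and a compact letter display.

Mirrors the presentation used for rearing-trait tables (mean ± SE followed
by lowercase letters): groups that share any letter are not significantly
different under all-pairwise Tukey comparisons at level alpha.  The
Tukey-Kramer form is used so unequal group sizes are allowed.  Letters are
assigned in descending-mean order via the insert-and-absorb algorithm.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["TraitSample", "AnovaTukeyResult", "anova_tukey", "compact_letter_display"]


@dataclass
class TraitSample:
    trait: str
    groups: Mapping[str, Sequence[float]]

    def validate(self) -> "TraitSample":
        if len(self.groups) < 2:
            raise ValueError(f"trait {self.trait!r}: need at least 2 groups")
        for name, obs in self.groups.items():
            if len(obs) < 2:
                raise ValueError(
                    f"trait {self.trait!r}: group {name!r} has fewer than 2 observations")
        return self


@dataclass
class AnovaTukeyResult:
    trait: str
    F: float                      # +inf flags zero within-group variance with unequal means
    df_between: int
    df_within: int
    p: float
    means: dict[str, float]
    ses: dict[str, float]
    letters: dict[str, str]
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def compact_letter_display(order: Sequence[str],
                           significant: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    ``order`` lists the groups by descending mean; ``significant`` holds the
    pairs judged different.  Two groups share a letter iff their pair is not
    in ``significant``.
    """
    columns: list[set] = [set(order)]
    for pair in significant:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.extend([col - {a}, col - {b}])
        # absorb columns contained in another
        columns = [c for c in columns
                   if c and not any(c < other for other in columns if other is not c)]
        # drop duplicates
        seen: list[set] = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen
    pos = {g: k for k, g in enumerate(order)}
    columns.sort(key=lambda c: min(pos[g] for g in c))
    labels = string.ascii_lowercase
    out = {g: "" for g in order}
    for k, col in enumerate(columns):
        letter = labels[k] if k < len(labels) else f"({k + 1})"
        for g in order:
            if g in col:
                out[g] += letter
    return out


def anova_tukey(sample: TraitSample, alpha: float = 0.05) -> AnovaTukeyResult:
    """Classical one-way ANOVA plus all-pairwise Tukey-Kramer comparisons.

    Degenerate input with zero within-group variance but unequal means is
    flagged with F = +inf (p = 0) and all pairs with unequal means are
    declared different.
    """
    sample.validate()
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    names = list(sample.groups)
    data = [np.asarray(sample.groups[g], dtype=float) for g in names]
    k = len(names)
    n_total = sum(len(d) for d in data)
    means = {g: float(d.mean()) for g, d in zip(names, data)}
    ses = {g: (float(d.std(ddof=1)) / math.sqrt(len(d)) if len(d) > 1 else 0.0)
           for g, d in zip(names, data)}
    df_b, df_w = k - 1, n_total - k
    ssw = sum(float(((d - d.mean()) ** 2).sum()) for d in data)
    order = sorted(names, key=lambda g: -means[g])

    if ssw == 0.0:
        distinct = len({round(m, 12) for m in means.values()}) > 1
        sig = {frozenset((a, b)) for i, a in enumerate(names) for b in names[i + 1:]
               if means[a] != means[b]}
        pair_p = {(a, b): (0.0 if frozenset((a, b)) in sig else 1.0)
                  for i, a in enumerate(names) for b in names[i + 1:]}
        return AnovaTukeyResult(
            trait=sample.trait,
            F=math.inf if distinct else 0.0,
            df_between=df_b, df_within=df_w,
            p=0.0 if distinct else 1.0,
            means=means, ses=ses,
            letters=compact_letter_display(order, sig),
            pairwise_p=pair_p)

    F, p = stats.f_oneway(*data)
    tk = stats.tukey_hsd(*data)
    pair_p: dict[tuple[str, str], float] = {}
    sig: set[frozenset] = set()
    for i, a in enumerate(names):
        for jj in range(i + 1, k):
            b = names[jj]
            pv = float(tk.pvalue[i, jj])
            pair_p[(a, b)] = pv
            if pv < alpha:
                sig.add(frozenset((a, b)))
    return AnovaTukeyResult(
        trait=sample.trait, F=float(F), df_between=df_b, df_within=df_w,
        p=float(p), means=means, ses=ses,
        letters=compact_letter_display(order, sig), pairwise_p=pair_p)
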