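"""SFA-%TE tertile assignment and across-tertile comparison.

Participants are ranked on the percentage of total energy from SFA and
split into low / medium / high consumer thirds.  Food-category
contributions are then compared across tertiles with one-way ANOVA and
Scheffé post hoc pairwise tests; p-values are Bonferroni-adjusted across
the family of categories tested.  The Scheffé criterion is evaluated in
closed form: the pair (i, j) differs when

    (m_i - m_j)^2 / (MSW (1/n_i + 1/n_j))  >  (k - 1) F_crit(alpha; k-1, N-k)

so the groupings can be checked against direct enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TERTILE_LABELS = ("low", "medium", "high")


class InsufficientSampleError(ValueError):
    pass


@dataclass(frozen=True)
class TertileAssignment:
    """Participant -> {low, medium, high} plus the two %TE cut points."""

    labels: pd.Series  # index participant_id, values in TERTILE_LABELS
    cut_points: tuple[float, float]

    def members(self, tertile: str) -> list[str]:
        return list(self.labels.index[self.labels == tertile])

    def sizes(self) -> dict[str, int]:
        return {t: int((self.labels == t).sum()) for t in TERTILE_LABELS}


def assign_tertiles(sfa_pct_te: Mapping[str, float] | pd.Series) -> TertileAssignment:
    """Rank-based split into thirds of SFA %TE.

    Ties are broken by a stable sort on (value, participant_id), so equal
    values may straddle a tertile boundary; when they do a warning is
    emitted.  Group sizes are n//3 with the remainder going to the lower
    tertiles, hence sizes differ by at most n mod 3.
    """
    s = pd.Series(dict(sfa_pct_te)) if not isinstance(sfa_pct_te, pd.Series) else sfa_pct_te
    n = len(s)
    if n < 3:
        raise InsufficientSampleError(f"need >= 3 participants for tertiles, got {n}")
    order = sorted(s.index, key=lambda pid: (s[pid], str(pid)))
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = {}
    pos = 0
    bounds = []
    for label, size in zip(TERTILE_LABELS, sizes):
        block = order[pos : pos + size]
        for pid in block:
            labels[pid] = label
        bounds.append(block[-1])
        pos += size
    cut_points = (float(s[bounds[0]]), float(s[bounds[1]]))
    for b, nxt in ((bounds[0], order[sizes[0]]), (bounds[1], order[sizes[0] + sizes[1]])):
        if s[b] == s[nxt]:
            warnings.warn(
                f"tied SFA %TE value {s[b]:.4g} straddles a tertile boundary; "
                "split resolved by participant_id order",
                stacklevel=2,
            )
    out = pd.Series({pid: labels[pid] for pid in s.index}, name="tertile")
    return TertileAssignment(labels=out, cut_points=cut_points)


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float, int, int]:
    """One-way ANOVA from sums of squares.  Returns (F, p, df_between, df_within).

    With zero between- and within-group variance (all observations equal)
    F is undefined and reported as (0, 1): no evidence of a difference.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    if k < 2 or (ns < 2).any():
        raise ValueError("need >= 2 groups with >= 2 observations each")
    N = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    dfb, dfw = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0, dfb, dfw
        return float("inf"), 0.0, dfb, dfw
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return F, p, dfb, dfw


def scheffe_pairwise(
    groups: Sequence[np.ndarray], alpha: float = 0.05
) -> dict[tuple[int, int], bool]:
    """Scheffé test for every group pair; True means significantly different."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    dfw = N - k
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msw = ssw / dfw if dfw > 0 else 0.0
    f_crit = float(stats.f.isf(alpha, k - 1, dfw))
    out: dict[tuple[int, int], bool] = {}
    for i, j in combinations(range(k), 2):
        diff2 = (groups[i].mean() - groups[j].mean()) ** 2
        if msw == 0.0:
            out[(i, j)] = diff2 > 0
            continue
        stat = diff2 / (msw * (1.0 / ns[i] + 1.0 / ns[j]))
        out[(i, j)] = bool(stat > (k - 1) * f_crit)
    return out


def compact_letters(
    means: Sequence[float], different: Mapping[tuple[int, int], bool]
) -> list[str]:
    """Superscript-letter groupings: groups share a letter iff not different.

    Letters are the maximal cliques of the "not significantly different"
    graph, ordered by the smallest member mean, as in published tables.
    """
    k = len(means)
    adj = [[False] * k for _ in range(k)]
    for i in range(k):
        adj[i][i] = True
    for (i, j), diff in different.items():
        adj[i][j] = adj[j][i] = not diff
    cliques: list[set[int]] = []

    def grow(clique: set[int], candidates: set[int]) -> None:
        extended = False
        for v in sorted(candidates):
            if all(adj[v][u] for u in clique):
                grow(clique | {v}, {c for c in candidates if c > v})
                extended = True
        if not extended and not any(clique < c for c in cliques):
            cliques.append(set(clique))

    grow(set(), set(range(k)))
    cliques = [c for c in cliques if not any(c < other for other in cliques)]
    cliques.sort(key=lambda c: min(means[i] for i in c))
    letters = ["" for _ in range(k)]
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[i] += letter
    return letters


@dataclass(frozen=True)
class TertileReport:
    """Across-tertile comparison of per-participant category values."""

    table: pd.DataFrame  # index category; mean/sd per tertile, F, p, p_adj, letters
    alpha: float
    family_size: int


def compare_tertiles(
    values: pd.DataFrame,
    assignment: TertileAssignment,
    alpha: float = 0.05,
    weights: Mapping[str, float] | None = None,
    family_size: int | None = None,
) -> TertileReport:
    """One-way ANOVA + Scheffé letters per category across SFA tertiles.

    ``values`` is a participants x categories frame (e.g. per-participant
    category contributions).  Bonferroni adjustment uses ``family_size``
    (default: the number of category columns).  Survey-weighted ANOVA
    (frequency weights) is available but off by default.
    """
    members = {t: assignment.members(t) for t in TERTILE_LABELS}
    for t, m in members.items():
        if len(m) < 2:
            raise InsufficientSampleError(f"tertile {t!r} has {len(m)} participants (need >= 2)")
    m_family = family_size if family_size is not None else values.shape[1]
    rows = []
    for cat in values.columns:
        if weights is None:
            groups = [values.loc[members[t], cat].to_numpy(dtype=float) for t in TERTILE_LABELS]
        else:
            # frequency-weight expansion on integerised weights
            groups = []
            for t in TERTILE_LABELS:
                vals = values.loc[members[t], cat].to_numpy(dtype=float)
                reps = np.maximum(
                    1, np.round([weights[p] for p in members[t]]).astype(int)
                )
                groups.append(np.repeat(vals, reps))
        F, p, dfb, dfw = anova_oneway(groups)
        p_adj = min(1.0, p * m_family)
        diff = scheffe_pairwise(groups, alpha=alpha)
        means = [g.mean() for g in groups]
        letters = compact_letters(means, diff)
        row = {"category": cat}
        for t, g, letter in zip(TERTILE_LABELS, groups, letters):
            row[f"{t}_mean"] = g.mean()
            row[f"{t}_sd"] = g.std(ddof=1)
            row[f"{t}_letter"] = letter
        row.update({"F": F, "df_between": dfb, "df_within": dfw, "p": p, "p_adj": p_adj})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("category")
    return TertileReport(table=table, alpha=alpha, family_size=m_family)
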