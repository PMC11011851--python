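"""Statistical machinery for assay and feature tables.

Mann–Whitney–Wilcoxon rank tests for two-class feature comparisons,
one-way ANOVA with Tukey HSD post hoc comparisons and a compact letter
display (the "a, b, c" annotations customary in food-science tables),
plus the CIELAB hue-angle utility.

All p-values are two-sided.  The Mann–Whitney test uses midranks for
ties and switches from exact enumeration to the tie-corrected,
continuity-corrected normal approximation above N = 20 or whenever ties
are present.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TukeyResult",
    "mann_whitney",
    "anova_oneway",
    "tukey_hsd",
    "compact_letters",
    "hue_angle",
    "assay_summary",
]


# ---------------------------------------------------------------------------
# two-sample rank test
# ---------------------------------------------------------------------------


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Mann–Whitney U (for the first sample) and the two-sided p-value.

    ``mode``: ``exact`` enumerates the permutation distribution of U,
    ``normal_approx`` uses the tie-corrected normal approximation with
    continuity correction, ``auto`` picks exact for N <= 20 without ties.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 20 and not has_ties) else "normal_approx"
    if mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError("mode must be 'exact', 'normal_approx' or 'auto'")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# one-way ANOVA and Tukey HSD
# ---------------------------------------------------------------------------


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[object, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=np.float64)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        out[name] = arr
    return out


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across the groups."""
    g = _validate_groups(groups)
    if all(np.all(v == v[0]) for v in g.values()):
        raise ValueError("zero within-group variance; F is undefined")
    f, p = sps.f_oneway(*g.values())
    return float(f), float(p)


@dataclass
class TukeyResult:
    """All pairwise Tukey HSD comparisons plus the compact letter display."""

    comparisons: pd.DataFrame  # group_1, group_2, mean_diff, q, p_adj, significant
    letters: dict[object, str]
    ms_within: float
    alpha: float

    def significant_pairs(self) -> list[tuple[object, object]]:
        sig = self.comparisons[self.comparisons["significant"]]
        return [tuple(r) for r in sig[["group_1", "group_2"]].itertuples(index=False)]


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey (Tukey–Kramer for unbalanced groups) HSD post hoc test.

    q = |mean_i - mean_j| / sqrt(MS_within (1/n_i + 1/n_j) / 2); adjusted
    p-values come from the studentized-range distribution with k groups
    and N - k error degrees of freedom.
    """
    g = _validate_groups(groups)
    names = list(g)
    k = len(names)
    n_total = sum(v.size for v in g.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in g.values())
    df_within = n_total - k
    if ss_within == 0:
        raise ValueError("zero within-group variance; Tukey HSD is undefined")
    ms_within = ss_within / df_within

    rows = []
    for a, b in itertools.combinations(names, 2):
        va, vb = g[a], g[b]
        diff = float(va.mean() - vb.mean())
        se = math.sqrt(ms_within * (1.0 / va.size + 1.0 / vb.size) / 2.0)
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_within))
        rows.append(
            {"group_1": a, "group_2": b, "mean_diff": diff, "q": q,
             "p_adj": min(p_adj, 1.0), "significant": p_adj < alpha}
        )
    comparisons = pd.DataFrame(rows)
    sig = {(r["group_1"], r["group_2"]): bool(r["significant"]) for r in rows}
    sig.update({(b, a): s for (a, b), s in list(sig.items())})
    letters = compact_letters(names, sig)
    return TukeyResult(comparisons=comparisons, letters=letters,
                       ms_within=ms_within, alpha=alpha)


def compact_letters(
    groups: Sequence, significant: Mapping[tuple, bool]
) -> dict[object, str]:
    """Insert-and-absorb compact letter display.

    Two groups share at least one letter iff they are *not* significantly
    different.  Groups are processed in the given label order, so the
    assignment is deterministic.  ``significant`` must contain every
    unordered pair (both orientations or one; asymmetric entries raise).
    """
    groups = list(groups)

    def is_sig(a, b) -> bool:
        fwd = significant.get((a, b))
        rev = significant.get((b, a))
        if fwd is None and rev is None:
            raise ValueError(f"missing significance entry for pair {(a, b)!r}")
        if fwd is not None and rev is not None and fwd != rev:
            raise ValueError(f"inconsistent significance matrix for pair {(a, b)!r}")
        return fwd if fwd is not None else rev

    # letter sets: each is the set of groups sharing that letter
    sets: list[set] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not is_sig(a, b):
            continue
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            sa, sb = s - {b}, s - {a}
            for cand in (sa, sb):
                if not any(cand <= other for other in sets):
                    sets.append(cand)
        # absorb: drop any set contained in another
        sets = [s for s in sets if not any(s < t for t in sets)]

    # order letters by the first (in label order) group they contain
    def rank(s: set) -> tuple:
        return tuple(sorted(groups.index(m) for m in s))

    sets.sort(key=rank)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {gname: "" for gname in groups}
    for i, s in enumerate(sets):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for gname in groups:
            if gname in s:
                letters[gname] += ch
    return letters


# ---------------------------------------------------------------------------
# colour utility and table rendering
# ---------------------------------------------------------------------------


def hue_angle(a_star: float, b_star: float) -> float:
    """CIELAB hue angle h = atan2(b*, a*) in degrees, mapped to [0, 360)."""
    if a_star == 0 and b_star == 0:
        raise ValueError("hue angle undefined at the origin")
    return float(np.degrees(np.arctan2(b_star, a_star)) % 360.0)


def assay_summary(
    assays: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-analyte day summary with mean ± SD and Tukey letter annotations.

    Expects the tidy layout (day, replicate, analyte, value); one row per
    (analyte, day) with columns mean, sd, n, letter, anova_F, anova_p.
    """
    rows = []
    for analyte, sub in assays.groupby("analyte", sort=True):
        groups = {int(day): d["value"].to_numpy() for day, d in sub.groupby("day", sort=True)}
        try:
            f, p = anova_oneway(groups)
            letters = tukey_hsd(groups, alpha=alpha).letters
        except ValueError:
            f, p = float("nan"), float("nan")
            letters = {day: "a" for day in groups}
        for day, vals in groups.items():
            rows.append(
                {"analyte": analyte, "day": day, "mean": float(vals.mean()),
                 "sd": float(vals.std(ddof=1)), "n": int(vals.size),
                 "letter": letters[day], "anova_F": f, "anova_p": p}
            )
    return pd.DataFrame(rows)
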