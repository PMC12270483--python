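"""Group-comparison statistics implemented from first principles.

The three designs used throughout the phenotyping pipeline:

* unpaired two-sample t test (pooled-variance by default, Welch optional);
* one-way ANOVA with Fisher's LSD post hoc — all pairwise t tests sharing
  the within-group mean square and its error df, unadjusted by definition,
  with compact-letter-display group labels ("groups with different letters
  differ at alpha");
* two-way factorial ANOVA with Sidak- or Tukey-adjusted pairwise
  comparisons.  Unbalanced designs are handled by the unweighted cell-means
  analysis (harmonic-mean cell size), which coincides with the classical
  decomposition when the design is balanced.

Only the t, F and studentized-range distributions come from scipy; every
sum of squares, statistic and adjustment is computed here.  All p values
are two-sided and alpha defaults to 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _dist

from .timeseries_io import ParameterError, ValidationError

__all__ = [
    "GroupComparison",
    "t_test_unpaired",
    "one_way_anova",
    "two_way_anova",
    "sidak_adjust",
]


@dataclass
class GroupComparison:
    """Result of one group comparison.

    ``df`` is the error degrees of freedom for a t test and the
    (numerator, denominator) pair for an ANOVA F.  ``posthoc`` is a table of
    pairwise comparisons (present only for ANOVA methods when requested);
    ``effects`` holds the full effect table of a two-way ANOVA; ``letters``
    maps group -> significance letters for Fisher's LSD.
    """

    method: str
    statistic: float
    df: tuple
    p_value: float
    posthoc: Optional[pd.DataFrame] = None
    effects: Optional[pd.DataFrame] = None
    letters: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p value {self.p_value} outside [0, 1]")


def _clean_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < min_n:
        raise ParameterError(f"{name} must be a 1-d sample with n >= {min_n}")
    if not np.all(np.isfinite(x)):
        raise ParameterError(f"{name} contains non-finite values")
    return x


def t_test_unpaired(x, y, welch: bool = False) -> GroupComparison:
    """Two-sided unpaired t test.

    Pooled-variance Student's t by default; ``welch`` switches to the
    Welch–Satterthwaite unequal-variance form.
    """
    x = _clean_sample(x, "x")
    y = _clean_sample(y, "y")
    nx, ny = len(x), len(y)
    mx, my = np.mean(x), np.mean(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            return GroupComparison("welch_t", 0.0, (float(nx + ny - 2),), 1.0)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        t = (mx - my) / math.sqrt(se2)
        method = "welch_t"
    else:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        if sp2 == 0:
            return GroupComparison("student_t", 0.0, (float(df),), 1.0)
        t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
        method = "student_t"
    p = 2.0 * _dist.t.sf(abs(t), df)
    return GroupComparison(method, float(t), (float(df),), float(min(p, 1.0)))


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment 1 - (1 - p)^m for m comparisons."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    return float(-math.expm1(m * math.log1p(-min(p, 1.0))))


# ---------------------------------------------------------------------------
# Compact letter display for Fisher's LSD
# ---------------------------------------------------------------------------


def _maximal_cliques(adjacency: np.ndarray) -> list[frozenset]:
    """All maximal cliques of a small undirected graph, by subset search."""
    k = adjacency.shape[0]
    if k > 15:
        raise ParameterError("letter display supported for at most 15 groups")
    cliques = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        if all(adjacency[i, j] for i, j in itertools.combinations(members, 2)):
            cliques.append(frozenset(members))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    return maximal


def _assign_letters(names: Sequence[str], means: Sequence[float],
                    nonsig: np.ndarray) -> dict:
    """Letters from the maximal cliques of the non-significant-pair graph,
    ordered smallest-mean-first: groups share a letter iff they lie in a
    common clique, so significantly different groups never share one."""
    order = np.argsort(means, kind="stable")
    cliques = _maximal_cliques(nonsig)
    # order cliques by the smallest mean of any member
    rank = {int(g): r for r, g in enumerate(order)}
    cliques.sort(key=lambda c: min(rank[i] for i in c))
    letters = {name: "" for name in names}
    for letter_i, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_i) if letter_i < 26 else f"a{letter_i}"
        for i in sorted(clique, key=lambda i: rank[i]):
            letters[names[i]] += letter
    return letters


def one_way_anova(
    groups: Mapping[str, Sequence[float]],
    posthoc: str = "none",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way fixed-effects ANOVA, optionally followed by Fisher's LSD.

    ``groups`` maps group label to its sample (each n >= 2).  Fisher's LSD
    performs all pairwise t tests using the common within-group mean square
    and N - k error df, unadjusted, and assigns significance letters.
    A design with zero within-group variance is rejected as degenerate.
    """
    if posthoc not in ("none", "fisher_lsd"):
        raise ParameterError(f"unknown posthoc {posthoc!r}")
    names = list(groups)
    if len(names) < 2:
        raise ParameterError("need >= 2 groups")
    samples = [_clean_sample(groups[g], f"group {g!r}") for g in names]
    k = len(samples)
    ns = np.array([len(s) for s in samples])
    means = np.array([np.mean(s) for s in samples])
    N = int(ns.sum())
    grand = float(np.concatenate(samples).mean())

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((s - m) ** 2) for s, m in zip(samples, means)))
    df_b, df_w = k - 1, N - k
    ms_within = ss_within / df_w
    if ms_within == 0:
        raise ValidationError(
            "zero within-group variance: F is undefined for this degenerate design"
        )
    F = (ss_between / df_b) / ms_within
    p = float(_dist.f.sf(F, df_b, df_w))

    result = GroupComparison("one_way_anova", float(F), (float(df_b), float(df_w)), p)
    if posthoc == "fisher_lsd":
        rows = []
        nonsig = np.ones((k, k), dtype=bool)
        for i, j in itertools.combinations(range(k), 2):
            diff = means[i] - means[j]
            se = math.sqrt(ms_within * (1 / ns[i] + 1 / ns[j]))
            t = diff / se
            pp = float(2.0 * _dist.t.sf(abs(t), df_w))
            sig = pp < alpha
            nonsig[i, j] = nonsig[j, i] = not sig
            rows.append(
                {"pair": f"{names[i]} vs {names[j]}", "estimate": float(diff),
                 "t": float(t), "p": pp, "significant": sig}
            )
        result.posthoc = pd.DataFrame(rows)
        result.letters = _assign_letters(names, means, nonsig)
    return result


# ---------------------------------------------------------------------------
# Two-way factorial ANOVA
# ---------------------------------------------------------------------------


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    posthoc: str = "none",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-way factorial ANOVA with interaction, via unweighted cell means.

    Every (A, B) cell must be non-empty, and at least one cell needs a
    replicate so the error term exists.  Sums of squares use cell-mean
    (unweighted-means, Type III-style) weighting with the harmonic-mean cell
    size, which reduces to the classical balanced decomposition when all
    cells share the same n.

    ``posthoc`` = ``"sidak"`` or ``"tukey"`` compares factor-A levels
    pairwise within each level of factor B, using the pooled error mean
    square; Sidak adjusts each pairwise p as 1-(1-p)^m over the m
    comparisons, Tukey refers the studentized range over the a factor-A
    levels to its distribution.

    The headline ``statistic``/``p_value`` are the interaction F; the full
    effect table (A, B, AxB) is in ``effects``.
    """
    if posthoc not in ("none", "sidak", "tukey"):
        raise ParameterError(f"unknown posthoc {posthoc!r}")
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ParameterError(f"column {col!r} not in data")
    y = _clean_sample(data[value].to_numpy(dtype=float), value, min_n=1)
    a_levels = list(dict.fromkeys(data[factor_a]))
    b_levels = list(dict.fromkeys(data[factor_b]))
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ParameterError("each factor needs >= 2 levels")

    cells = {}
    for (la, lb), sub in data.groupby([factor_a, factor_b], sort=False):
        cells[(la, lb)] = sub[value].to_numpy(dtype=float)
    for la in a_levels:
        for lb in b_levels:
            if (la, lb) not in cells or len(cells[(la, lb)]) == 0:
                raise ValidationError(f"empty cell ({factor_a}={la!r}, {factor_b}={lb!r})")

    n_cells = np.array([[len(cells[(la, lb)]) for lb in b_levels] for la in a_levels])
    cell_means = np.array(
        [[float(np.mean(cells[(la, lb)])) for lb in b_levels] for la in a_levels]
    )
    N = int(n_cells.sum())
    df_err = N - a * b
    if df_err <= 0:
        raise ValidationError("no replication: error term undefined (all cells n = 1)")
    ss_err = float(
        sum(np.sum((cells[(la, lb)] - cell_means[i, j]) ** 2)
            for i, la in enumerate(a_levels) for j, lb in enumerate(b_levels))
    )
    ms_err = ss_err / df_err
    if ms_err == 0:
        raise ValidationError("zero within-cell variance: F undefined")

    n_h = a * b / float(np.sum(1.0 / n_cells))  # harmonic-mean cell size
    grand = float(cell_means.mean())
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)
    ss_a = n_h * b * float(np.sum((a_means - grand) ** 2))
    ss_b = n_h * a * float(np.sum((b_means - grand) ** 2))
    inter = cell_means - a_means[:, None] - b_means[None, :] + grand
    ss_ab = n_h * float(np.sum(inter**2))
    df_a, df_b_, df_ab = a - 1, b - 1, (a - 1) * (b - 1)

    rows = []
    for eff, ss, df in (
        (factor_a, ss_a, df_a),
        (factor_b, ss_b, df_b_),
        (f"{factor_a} x {factor_b}", ss_ab, df_ab),
    ):
        F = (ss / df) / ms_err
        rows.append(
            {"effect": eff, "ss": ss, "df": df, "F": float(F),
             "p": float(_dist.f.sf(F, df, df_err))}
        )
    effects = pd.DataFrame(rows)
    inter_row = effects.iloc[2]
    result = GroupComparison(
        "two_way_anova",
        float(inter_row["F"]),
        (float(df_ab), float(df_err)),
        float(inter_row["p"]),
        effects=effects,
    )

    if posthoc != "none":
        pairs = list(itertools.combinations(range(a), 2))
        m = len(pairs) * b
        ph_rows = []
        for j, lb in enumerate(b_levels):
            for i1, i2 in pairs:
                n1, n2 = n_cells[i1, j], n_cells[i2, j]
                diff = cell_means[i1, j] - cell_means[i2, j]
                se = math.sqrt(ms_err * (1 / n1 + 1 / n2))
                if posthoc == "sidak":
                    t = diff / se
                    p_raw = float(2.0 * _dist.t.sf(abs(t), df_err))
                    p_adj = sidak_adjust(p_raw, m)
                    stat = float(t)
                else:  # tukey: studentized range over the a factor-A levels
                    q = abs(diff) / math.sqrt(ms_err * 0.5 * (1 / n1 + 1 / n2))
                    p_raw = float(_dist.studentized_range.sf(q, a, df_err))
                    p_adj = min(p_raw, 1.0)
                    stat = float(q)
                ph_rows.append(
                    {
                        "pair": f"{a_levels[i1]} vs {a_levels[i2]}",
                        factor_b: lb,
                        "estimate": float(diff),
                        "statistic": stat,
                        "p_adj": float(min(p_adj, 1.0)),
                        "significant": p_adj < alpha,
                    }
                )
        result.posthoc = pd.DataFrame(ph_rows)
    return result
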