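"""One-way ANOVA, Duncan's multiple range test and Pearson correlation.

Duncan's multiple range test compares the k ordered group means stepwise.
A pair of means whose ordered positions span p means is significant when
its range exceeds the least significant range

    R_p = q(1 - alpha_p, p, df_error) * sqrt(MSE / n),

where q is the upper quantile of the studentized range distribution and
alpha_p = 1 - (1 - alpha)^(p-1) is Duncan's protection level.  The
stepwise rule additionally declares every pair inside a non-significant
span non-significant, which makes the decisions consistent with a
compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSample",
    "AnovaResult",
    "DuncanResult",
    "one_way_anova",
    "duncan_mrt",
    "correlation_matrix",
]


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSample:
    """Replicate measurements for one group (variety or treatment)."""

    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError(f"group {self.group!r}: need >= 2 replicate values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {self.group!r}: non-finite values")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    mse: float  # within-group mean square, reused by Duncan


@dataclass(frozen=True)
class DuncanResult:
    groups: tuple[str, ...]          # sorted by mean, descending
    means: np.ndarray                # matching order
    mse: float
    df_error: int
    n_harmonic: float
    critical_ranges: dict[int, float]   # p -> R_p for p = 2..k
    significant: np.ndarray          # k x k boolean, order of `groups`
    letters: dict[str, str]          # group -> compact letter display
    alpha: float


def one_way_anova(samples: list[GroupSample], alpha: float = 0.01) -> AnovaResult:
    """Classical fixed-effects one-way decomposition.

    Returns the F statistic, its degrees of freedom and two-sided p value
    from the F distribution, plus the within-group mean square.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    all_vals = np.concatenate([s.values for s in samples])
    grand = all_vals.mean()
    ssb = sum(len(s.values) * (s.values.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s.values - s.values.mean()) ** 2).sum() for s in samples)
    df1 = len(samples) - 1
    df2 = len(all_vals) - len(samples)
    if ssw == 0 and ssb == 0:
        raise DegenerateDataError("all observations identical: ANOVA undefined")
    if ssw == 0:
        raise DegenerateDataError("zero within-group variance everywhere: F undefined")
    mse = ssw / df2
    F = (ssb / df1) / mse
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p, mse=mse)


@lru_cache(maxsize=4096)
def _q_studentized(prob: float, p: int, df: float) -> float:
    # studentized-range quantiles are expensive; identical (prob, p, df)
    # triples recur across every Duncan call
    return float(stats.studentized_range.ppf(prob, p, df))


def duncan_critical_range(p: int, df_error: int, mse: float, n: float, alpha: float) -> float:
    """Least significant range R_p at Duncan's protection level."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    q = _q_studentized(1.0 - alpha_p, p, df_error)
    return float(q * np.sqrt(mse / n))


def _stepwise_decisions(means: np.ndarray, ranges: dict[int, float]) -> np.ndarray:
    """Duncan stepwise decisions on descending-ordered means.

    A pair (i, j) is significant iff every enclosing span (i', j') with
    i' <= i and j' >= j exceeds its own R_p; equivalently, test spans from
    widest to narrowest and never test inside a retained (non-significant)
    span.
    """
    k = len(means)
    sig = np.zeros((k, k), dtype=bool)
    # nonsig_cover[i][j] True if (i, j) lies inside some non-significant span
    covered = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if covered[i, j]:
                continue
            if means[i] - means[j] > ranges[span]:
                sig[i, j] = sig[j, i] = True
            else:
                # absorb: every inner pair is non-significant
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        covered[a, b] = covered[b, a] = True
    return sig


def _letters_from_decisions(groups: tuple[str, ...], sig: np.ndarray) -> dict[str, str]:
    """Compact letter display by insert-and-absorb over descending means.

    Starts from one all-inclusive letter column; each significant pair
    splits the columns containing both members; duplicate/contained
    columns are absorbed.
    """
    k = len(groups)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_cols.append(col - {j})
                    new_cols.append(col - {i})
                else:
                    new_cols.append(col)
            # absorb columns contained in another
            columns = [
                c
                for idx, c in enumerate(new_cols)
                if c and not any(idx != o and c < new_cols[o] for o in range(len(new_cols)))
            ]
            # dedupe
            seen: list[set[int]] = []
            for c in columns:
                if c not in seen:
                    seen.append(c)
            columns = seen
    # order columns by their topmost (best) member for stable lettering
    columns.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for idx, col in enumerate(columns):
        for member in sorted(col):
            letters[groups[member]] += alphabet[idx % len(alphabet)]
    return letters


def duncan_mrt(samples: list[GroupSample], alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with a compact letter display.

    Groups are ordered by descending mean (ties broken by input order).
    Unbalanced designs fall back to the harmonic mean group size.
    """
    anova = one_way_anova(samples, alpha)
    order = sorted(
        range(len(samples)),
        key=lambda i: (-samples[i].values.mean(), i),
    )
    groups = tuple(samples[i].group for i in order)
    means = np.array([samples[i].values.mean() for i in order])
    sizes = np.array([len(samples[i].values) for i in order], dtype=float)
    n_h = len(sizes) / np.sum(1.0 / sizes)  # harmonic mean; equals n when balanced
    k = len(groups)
    ranges = {
        p: duncan_critical_range(p, anova.df2, anova.mse, n_h, alpha) for p in range(2, k + 1)
    }
    sig = _stepwise_decisions(means, ranges)
    letters = _letters_from_decisions(groups, sig)
    return DuncanResult(
        groups=groups,
        means=means,
        mse=anova.mse,
        df_error=anova.df2,
        n_harmonic=float(n_h),
        critical_ranges=ranges,
        significant=sig,
        letters=letters,
        alpha=alpha,
    )


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between numeric columns.

    Returns a tidy frame with columns ``var1, var2, r, r2, p`` for every
    ordered pair (symmetric; diagonal r = 1).  Constant columns are
    excluded with a warning attribute rather than poisoning the matrix.
    """
    num = table.select_dtypes("number")
    if len(num) < 3:
        raise ValueError("need >= 3 rows for correlation")
    constant = [c for c in num.columns if np.isclose(num[c].std(ddof=0), 0.0)]
    kept = [c for c in num.columns if c not in constant]
    rows = []
    for c1 in kept:
        for c2 in kept:
            if c1 == c2:
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(num[c1], num[c2])
            rows.append({"var1": c1, "var2": c2, "r": float(r), "r2": float(r) ** 2, "p": float(p)})
    out = pd.DataFrame(rows)
    out.attrs["excluded_constant"] = constant
    return out
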