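"""Self-contained statistical tests used by all analysis modules.

Implements the classical one-way ANOVA, balanced two-factor ANOVA,
independent two-sample t test (pooled and Welch), exact and
normal-approximation Mann-Whitney U, and paired comparisons (t and
exact sign-flip permutation).  Sums of squares, ranks and permutation
enumeration are computed here from first principles; only tail
probabilities of the reference distributions are delegated to
``scipy.stats``.

Every result carries the test name actually run, its statistic, degrees
of freedom where applicable, a two-sided p-value and a verdict at a
configurable alpha (default 0.05).  No multiple-testing correction is
applied anywhere; callers are expected to count their own tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "GroupComparisonResult",
    "one_way_anova",
    "two_sample_t",
    "mann_whitney_u",
    "two_way_anova",
    "paired_t",
    "paired_sign_flip",
    "welch_pair_detail",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of a single hypothesis test on grouped data."""

    test_name: str
    statistic: float
    p_value: float
    df: tuple[float, ...] = ()
    alpha: float = DEFAULT_ALPHA
    group_sizes: tuple[int, ...] = ()
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    @property
    def verdict(self) -> str:
        return "significant" if self.significant else "not significant"

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": float(self.statistic),
            "df": list(self.df),
            "p_value": float(self.p_value),
            "alpha": self.alpha,
            "verdict": self.verdict,
            "group_sizes": list(self.group_sizes),
            **({"detail": self.detail} if self.detail else {}),
        }


def _as_clean_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def one_way_anova(groups, alpha: float = DEFAULT_ALPHA) -> GroupComparisonResult:
    """Classical between/within sums-of-squares F test.

    Degenerate cases: all values identical gives F = 0, p = 1; zero
    within-group variance with unequal means gives p = 0 (infinite F).
    """
    samples = [_as_clean_array(g, "group") for g in groups]
    if len(samples) < 2:
        raise ValueError("one_way_anova needs at least 2 groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    k = len(samples)
    n_total = sum(s.size for s in samples)
    grand = np.concatenate(samples).mean()
    ssb = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df = (k - 1, n_total - k)
    if ssw == 0.0:
        if ssb == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
    else:
        f_stat = (ssb / df[0]) / (ssw / df[1])
        p = float(_sps.f.sf(f_stat, *df))
        if ssb == 0.0:
            f_stat, p = 0.0, 1.0
    return GroupComparisonResult(
        test_name="one_way_anova",
        statistic=float(f_stat),
        p_value=float(p),
        df=(float(df[0]), float(df[1])),
        alpha=alpha,
        group_sizes=tuple(s.size for s in samples),
        detail={"ss_between": float(ssb), "ss_within": float(ssw)},
    )


def two_sample_t(
    x, y, equal_var: bool = True, alpha: float = DEFAULT_ALPHA
) -> GroupComparisonResult:
    """Independent two-sample t test, pooled (default) or Welch, two-sided."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("two_sample_t needs n >= 2 per sample")
    n1, n2 = x.size, y.size
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    diff = x.mean() - y.mean()
    if v1 == 0.0 and v2 == 0.0:
        # zero variance everywhere: equal means -> p = 1 by convention
        if diff == 0.0:
            t_stat, p, df = 0.0, 1.0, float(n1 + n2 - 2)
        else:
            t_stat = math.copysign(math.inf, diff)
            p, df = 0.0, float(n1 + n2 - 2)
    elif equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        t_stat = diff / se
        p = float(2.0 * _sps.t.sf(abs(t_stat), df))
    else:
        se2 = v1 / n1 + v2 / n2
        se = math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t_stat = diff / se
        p = float(2.0 * _sps.t.sf(abs(t_stat), df))
    return GroupComparisonResult(
        test_name="pooled_t" if equal_var else "welch_t",
        statistic=float(t_stat),
        p_value=float(min(p, 1.0)),
        df=(float(df),),
        alpha=alpha,
        group_sizes=(n1, n2),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x against y, with midrank handling of ties."""
    combined = np.concatenate([x, y])
    ranks = _sps.rankdata(combined)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


EXACT_MAX_N = 12


def mann_whitney_u(
    x, y, exact: bool | None = None, alpha: float = DEFAULT_ALPHA
) -> GroupComparisonResult:
    """Mann-Whitney U with midrank ties, two-sided.

    Exact p by full enumeration of group labelings when the combined
    sample size is <= 12 and there are no ties (or when ``exact=True``
    is forced); otherwise normal approximation with tie and continuity
    corrections.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size < 1 or y.size < 1:
        raise ValueError("mann_whitney_u needs n >= 1 per sample")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    u1 = _u_statistic(x, y)
    if exact is None:
        exact = (n1 + n2) <= EXACT_MAX_N and not has_ties

    if exact:
        u_lo = min(u1, n1 * n2 - u1)
        count = 0
        total = 0
        idx = range(n1 + n2)
        for picks in itertools.combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(picks)] = True
            u_perm = _u_statistic(combined[sel], combined[~sel])
            total += 1
            if u_perm <= u_lo or u_perm >= n1 * n2 - u_lo:
                count += 1
        p = count / total
        name = "mann_whitney_exact"
    else:
        mean_u = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_u <= 0.0:
            # all observations tied: no evidence against the null
            return GroupComparisonResult(
                test_name="mann_whitney_normal",
                statistic=u1,
                p_value=1.0,
                alpha=alpha,
                group_sizes=(n1, n2),
            )
        z = (abs(u1 - mean_u) - 0.5) / math.sqrt(var_u)
        z = max(z, 0.0)
        p = float(min(2.0 * _sps.norm.sf(z), 1.0))
        name = "mann_whitney_normal"
    return GroupComparisonResult(
        test_name=name,
        statistic=u1,
        p_value=float(p),
        alpha=alpha,
        group_sizes=(n1, n2),
    )


def two_way_anova(
    values, factor_a, factor_b, alpha: float = DEFAULT_ALPHA
) -> dict[str, GroupComparisonResult]:
    """Two-crossed-factor ANOVA for (near-)balanced designs.

    For balanced data the classical cell-mean sums of squares are exact
    Type-III tests.  Unbalanced designs are reduced to a balanced subset
    (the first ``min(cell n)`` observations per cell, in input order)
    with a warning.  With one observation per cell the interaction is
    untestable and the additive model is fitted, with the interaction
    reported as such.
    """
    values = _as_clean_array(values, "values")
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (values.size == factor_a.size == factor_b.size):
        raise ValueError("values and factors must have equal length")
    levels_a = list(dict.fromkeys(factor_a.tolist()))
    levels_b = list(dict.fromkeys(factor_b.tolist()))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs >= 2 levels")
    cells: dict[tuple, list[float]] = {}
    for v, a, b in zip(values, factor_a, factor_b):
        cells.setdefault((a, b), []).append(float(v))
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in cells:
                raise ValueError(f"empty design cell ({a!r}, {b!r})")
    counts = {k: len(v) for k, v in cells.items()}
    m = min(counts.values())
    if len(set(counts.values())) > 1:
        warnings.warn(
            f"unbalanced design; restricting every cell to its first {m} "
            "observations",
            stacklevel=2,
        )
        cells = {k: v[:m] for k, v in cells.items()}

    a_n, b_n = len(levels_a), len(levels_b)
    cell = np.array(
        [[np.mean(cells[(a, b)]) for b in levels_b] for a in levels_a]
    )
    grand = cell.mean()
    ss_a = m * b_n * ((cell.mean(axis=1) - grand) ** 2).sum()
    ss_b = m * a_n * ((cell.mean(axis=0) - grand) ** 2).sum()
    ss_ab = m * (
        (cell - cell.mean(axis=1, keepdims=True) - cell.mean(axis=0, keepdims=True) + grand)
        ** 2
    ).sum()
    ss_e = sum(
        ((np.asarray(v) - np.mean(v)) ** 2).sum() for v in cells.values()
    )
    df_a, df_b = a_n - 1, b_n - 1
    df_ab = df_a * df_b
    df_e = a_n * b_n * (m - 1)

    def _f_result(name: str, ss: float, df_num: int, ss_err: float, df_err: int):
        if df_err <= 0:
            return GroupComparisonResult(
                test_name=f"two_way_anova[{name}]",
                statistic=math.nan,
                p_value=math.nan,
                df=(float(df_num), 0.0),
                alpha=alpha,
                detail={"note": "untestable: no error degrees of freedom"},
            )
        ms_err = ss_err / df_err
        if ms_err == 0.0:
            f_stat, p = (0.0, 1.0) if ss == 0.0 else (math.inf, 0.0)
        else:
            f_stat = (ss / df_num) / ms_err
            p = float(_sps.f.sf(f_stat, df_num, df_err))
        return GroupComparisonResult(
            test_name=f"two_way_anova[{name}]",
            statistic=float(f_stat),
            p_value=float(p),
            df=(float(df_num), float(df_err)),
            alpha=alpha,
            detail={"ss": float(ss)},
        )

    if m == 1:
        # additive model: interaction SS becomes the error term
        out = {
            "factor_a": _f_result("factor_a", ss_a, df_a, ss_ab, df_ab),
            "factor_b": _f_result("factor_b", ss_b, df_b, ss_ab, df_ab),
            "interaction": _f_result("interaction", ss_ab, df_ab, 0.0, 0),
        }
    else:
        out = {
            "factor_a": _f_result("factor_a", ss_a, df_a, ss_e, df_e),
            "factor_b": _f_result("factor_b", ss_b, df_b, ss_e, df_e),
            "interaction": _f_result("interaction", ss_ab, df_ab, ss_e, df_e),
        }
    return out


def welch_pair_detail(x, y, alpha: float = DEFAULT_ALPHA) -> GroupComparisonResult:
    """Unadjusted Welch contrast for descriptive pairwise reporting.

    Used after an omnibus ANOVA; the p-value is not corrected and the
    omnibus test remains the headline result.
    """
    res = two_sample_t(x, y, equal_var=False, alpha=alpha)
    return GroupComparisonResult(
        test_name="welch_t_descriptive",
        statistic=res.statistic,
        p_value=res.p_value,
        df=res.df,
        alpha=alpha,
        group_sizes=res.group_sizes,
        detail={"note": "unadjusted pairwise contrast; omnibus ANOVA is the headline"},
    )


def paired_t(x, y, alpha: float = DEFAULT_ALPHA) -> GroupComparisonResult:
    """Two-sided paired t test on per-pair differences x - y."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired_t needs n >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0.0:
        if d.mean() == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, d.mean()), 0.0
    else:
        t_stat = d.mean() / (sd / math.sqrt(n))
        p = float(2.0 * _sps.t.sf(abs(t_stat), n - 1))
    return GroupComparisonResult(
        test_name="paired_t",
        statistic=float(t_stat),
        p_value=float(min(p, 1.0)),
        df=(float(n - 1),),
        alpha=alpha,
        group_sizes=(n, n),
    )


def paired_sign_flip(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    max_exact_n: int = 20,
    n_resamples: int = 10000,
    seed: int = 0,
) -> GroupComparisonResult:
    """Exact (or Monte Carlo) sign-flip permutation test on paired differences.

    The statistic is the mean difference; two-sided p is the fraction of
    sign assignments whose |mean| is at least the observed |mean|.  All
    2^n assignments are enumerated for n <= ``max_exact_n``.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size or x.size < 1:
        raise ValueError("paired samples must be nonempty and equal length")
    d = x - y
    n = d.size
    obs = abs(d.mean())
    if n <= max_exact_n:
        signs = np.array(
            list(itertools.product([1.0, -1.0], repeat=n)), dtype=float
        )
        perm = np.abs(signs @ d) / n
        p = float(np.mean(perm >= obs - 1e-12 * max(obs, 1.0)))
        name = "paired_sign_flip_exact"
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_resamples, n))
        perm = np.abs(signs @ d) / n
        hits = int(np.sum(perm >= obs - 1e-12 * max(obs, 1.0)))
        p = (hits + 1.0) / (n_resamples + 1.0)
        name = "paired_sign_flip_mc"
    return GroupComparisonResult(
        test_name=name,
        statistic=float(d.mean()),
        p_value=float(min(p, 1.0)),
        alpha=alpha,
        group_sizes=(n, n),
    )
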