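"""Cohort statistics on slide-level scores.

Implements the classical fixed-effects one-way ANOVA, Tukey(-Kramer) HSD
pairwise comparisons via the studentized-range distribution, Pearson
correlation, partial correlation given a covariate (residual-on-residual),
and a Welch two-sample t-test for two-arm intervention designs.  The test
statistics are computed from the textbook sums-of-squares formulas; only
the reference distributions (F, t, studentized range) come from scipy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupedScores",
    "StatResult",
    "one_way_anova",
    "tukey_hsd",
    "pearson_corr",
    "partial_corr_given",
    "welch_t_test",
]


@dataclass(frozen=True)
class GroupedScores:
    """Slide scores keyed by group label (age or treatment arm)."""

    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = {
            str(k): np.asarray(v, dtype=np.float64).ravel() for k, v in self.groups.items()
        }
        if any(v.size == 0 for v in groups.values()):
            raise ValueError("every group must be non-empty")
        object.__setattr__(self, "groups", groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n(self) -> int:
        return sum(v.size for v in self.groups.values())


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    df: tuple[float, ...] = ()
    estimate: float | None = None
    pair: tuple[str, str] | None = None
    method: str = ""


def _as_grouped(data: GroupedScores | dict) -> GroupedScores:
    return data if isinstance(data, GroupedScores) else GroupedScores(dict(data))


def _anova_sums(data: GroupedScores):
    values = list(data.groups.values())
    k = len(values)
    n = sum(v.size for v in values)
    grand = np.concatenate(values).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    return k, n, ssb, ssw


def one_way_anova(data: GroupedScores | dict) -> StatResult:
    """Fixed-effects one-way ANOVA: F = (SSB/(k-1)) / (SSW/(n-k))."""
    data = _as_grouped(data)
    k, n, ssb, ssw = _anova_sums(data)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if n <= k:
        raise ValueError(f"ANOVA needs n > k (n={n}, k={k})")
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    if msw == 0.0:
        if msb == 0.0:
            warnings.warn("zero between- and within-group variance; p undefined, reporting 1")
            return StatResult(0.0, 1.0, (k - 1, n - k), method="one-way ANOVA")
        return StatResult(np.inf, 0.0, (k - 1, n - k), method="one-way ANOVA")
    f_stat = msb / msw
    p = float(sps.f.sf(f_stat, k - 1, n - k))
    return StatResult(float(f_stat), p, (k - 1, n - k), method="one-way ANOVA")


def tukey_hsd(data: GroupedScores | dict) -> list[StatResult]:
    """Tukey(-Kramer) HSD: one adjusted comparison per unordered group pair.

    q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)); the adjusted p
    is the studentized-range tail with k groups and n-k error df, valid
    for unequal group sizes via the Kramer adjustment.
    """
    data = _as_grouped(data)
    k, n, _, ssw = _anova_sums(data)
    if k < 2 or n <= k:
        raise ValueError("Tukey HSD needs >= 2 groups and n > k")
    msw = ssw / (n - k)
    results = []
    for (name_i, vi), (name_j, vj) in itertools.combinations(data.groups.items(), 2):
        diff = vi.mean() - vj.mean()
        se = np.sqrt(msw / 2.0 * (1.0 / vi.size + 1.0 / vj.size))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, n - k)) if np.isfinite(q) else 0.0
        results.append(
            StatResult(
                float(q),
                min(max(p, 0.0), 1.0),
                (k, n - k),
                estimate=float(diff),
                pair=(name_i, name_j),
                method="Tukey HSD",
            )
        )
    return results


def pearson_corr(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Sample Pearson correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant input: correlation undefined")
    r = float((xc * yc).sum() / (sx * sy))
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return StatResult(r, p, (n - 2,), estimate=r, method="Pearson correlation")


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_corr_given(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> StatResult:
    """Partial correlation of x and y controlling for covariate z.

    Regresses x and y each on (1, z) by least squares and correlates the
    residual vectors; equals the closed form
    (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2)).  p-value with n-3 df.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    z = np.asarray(z, dtype=np.float64).ravel()
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    if np.ptp(z) == 0.0:
        raise ValueError("covariate z is constant: partial correlation undefined")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    sx = np.sqrt((rx**2).sum())
    sy = np.sqrt((ry**2).sum())
    if sx < 1e-12 * max(1.0, np.abs(x).max()) or sy < 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("degenerate input: a variable is (nearly) collinear with the covariate")
    r = float((rx * ry).sum() / (sx * sy))
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 3) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 3))
    return StatResult(r, p, (n - 3,), estimate=r, method="partial correlation")


def welch_t_test(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both groups have zero variance: Welch test undefined")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(float(t), p, (float(df),), estimate=float(a.mean() - b.mean()), method="Welch t-test")
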