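"""Meta p-value combination methods.

These combiners roll probe p-values up to epitopes and epitope p-values up
to proteins.  The Wilkinson family tests an order statistic of k p-values
against its Beta null: the r-th smallest of k independent uniforms is
Beta(r, k - r + 1), the r-th largest is Beta(k - r + 1, r).  ``wmax_r``
("most members must be significant") is the natural epitope combiner;
``wmin_r`` / Tippett and min-Bonferroni ("at least one significant
epitope") fit the protein level.  Fisher, the harmonic mean p (with the
asymptotically exact Landau tail) and the Cauchy combination test are
provided as dependence-tolerant alternatives.

Small-n conventions: ``wmax_r`` with fewer than r inputs returns 1
(conservative -- a feature narrower than the required order statistic is
never called); ``wmin_r`` falls back to r - 1 iteratively and returns the
single p when only one is available.

Every combiner exists in two forms: a scalar function taking one list of
p-values, and the row-wise :func:`combine_rows` over an (n, k) matrix.  The
scalar form delegates to the row-wise one, so there is a single numerical
code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16

#: offset of the standard Landau location for the mean of k inverse
#: uniforms: 1 - Euler-Mascheroni + ln(pi/2)
_LANDAU_SHIFT = 1.0 - np.euler_gamma + math.log(math.pi / 2.0)


@dataclass(frozen=True)
class MetaMethod:
    """A named combiner; ``r`` is the order for the Wilkinson families."""

    name: str
    r: int = 1

    def __post_init__(self) -> None:
        if self.name not in ("wmax", "wmin", "fisher", "hmp", "cct", "min_bonf"):
            raise ValueError(f"unknown meta p-value method {self.name!r}")
        if self.r < 1:
            raise ValueError("order r must be >= 1")

    def __call__(self, pvals: Sequence[float]) -> float:
        p = _asarray(pvals)
        if p.size == 0:
            return 1.0
        if self.name == "wmax" and p.size < self.r:
            return 1.0
        return float(combine_rows(p[None, :], self)[0])

    @property
    def label(self) -> str:
        if self.name in ("wmax", "wmin"):
            return f"{self.name}{self.r}"
        return self.name


def _asarray(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, P_FLOOR, P_CEIL)


def combine_rows(p: np.ndarray, method: MetaMethod) -> np.ndarray:
    """Combine each row of an (n, k) p-value matrix.

    All rows share the same k, so the Wilkinson small-n fallbacks resolve
    once: ``wmax`` with k < r yields a column of ones, ``wmin`` drops its
    order to k, and k = 1 passes the single column through for every
    method.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError("expected an (n, k) matrix")
    n, k = p.shape
    if k == 0:
        return np.ones(n)
    name, r = method.name, method.r

    if name == "wmax":
        if k < r:
            return np.ones(n)
        statistic = np.sort(p, axis=1)[:, k - r]  # r-th largest
        return stats.beta.cdf(statistic, k - r + 1, r)
    if name == "wmin":
        if k == 1:
            return p[:, 0].copy()
        r_eff = min(r, k)
        statistic = np.sort(p, axis=1)[:, r_eff - 1]
        return stats.beta.cdf(statistic, r_eff, k - r_eff + 1)
    if name == "fisher":
        x = -2.0 * np.log(_clip(p)).sum(axis=1)
        return stats.chi2.sf(x, 2 * k)
    if name == "hmp":
        if k == 1:
            return p[:, 0].copy()
        t = np.mean(1.0 / _clip(p), axis=1)
        tail = stats.landau.sf(t, loc=math.log(k) + _LANDAU_SHIFT, scale=math.pi / 2.0)
        # T = 1 is the null's minimum (every p at 1): the exact tail there is
        # 1, where the asymptotic Landau approximation is not
        return np.where(t <= 1.0 + 1e-12, 1.0, np.minimum(1.0, tail))
    if name == "cct":
        t = np.mean(np.tan((0.5 - _clip(p)) * math.pi), axis=1)
        return stats.cauchy.sf(t)
    if name == "min_bonf":
        return np.minimum(1.0, k * p.min(axis=1))
    raise AssertionError(f"unhandled method {name}")  # pragma: no cover


# -- scalar API -------------------------------------------------------------


def p_wmax(pvals: Sequence[float], r: int = 1) -> float:
    """Wilkinson's r-th maximum: Beta(k - r + 1, r) CDF of the r-th largest p.

    Returns exactly 1 when fewer than ``r`` p-values are supplied.
    """
    return MetaMethod("wmax", r)(pvals)


def p_wmin(pvals: Sequence[float], r: int = 1) -> float:
    """Wilkinson's r-th minimum: Beta(r, k - r + 1) CDF of the r-th smallest p.

    With fewer than ``r`` p-values the order drops iteratively (r - 1,
    r - 2, ...); a single p-value is returned unchanged.  ``r = 1`` is
    Tippett's method, 1 - (1 - p_min)**k.
    """
    return MetaMethod("wmin", r)(pvals)


def p_fisher(pvals: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) against chi-square with 2k df."""
    return MetaMethod("fisher")(pvals)


def p_hmp(pvals: Sequence[float]) -> float:
    """Harmonic-mean p-value with the asymptotically exact Landau tail.

    The statistic is the harmonic mean H = k / sum(1/p_i); the mean of the
    inverse p-values is referred to a Landau distribution with location
    ln(k) + 1 - gamma + ln(pi/2) and scale pi/2, the asymptotic null of
    this heavy-tailed average.  A single p-value passes through unchanged.
    """
    return MetaMethod("hmp")(pvals)


def harmonic_mean_statistic(pvals: Sequence[float]) -> float:
    """The bare harmonic mean H = k / sum(1/p_i) (the hmp test statistic)."""
    p = _clip(_asarray(pvals))
    if p.size == 0:
        return 1.0
    return float(p.size / np.sum(1.0 / p))


def p_cct(pvals: Sequence[float]) -> float:
    """Cauchy combination test: mean of tan((0.5 - p) pi) against standard Cauchy."""
    return MetaMethod("cct")(pvals)


def p_min_bonf(pvals: Sequence[float]) -> float:
    """Bonferroni-corrected minimum: min(1, k * min(p))."""
    return MetaMethod("min_bonf")(pvals)


def get_method(label: str) -> MetaMethod:
    """Parse a method label: wmax1, wmax2, wmin1, wmin2, fisher, hmp, cct, min_bonf."""
    label = label.strip().lower()
    for family in ("wmax", "wmin"):
        if label.startswith(family):
            suffix = label[len(family):] or "1"
            try:
                return MetaMethod(family, int(suffix))
            except ValueError as exc:
                raise ValueError(f"bad Wilkinson order in {label!r}") from exc
    if label in ("fisher", "hmp", "cct", "min_bonf"):
        return MetaMethod(label)
    raise ValueError(f"unknown meta p-value method {label!r}")
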