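"""Bimodality diagnostics: bimodality coefficient, Hartigan's dip, combined verdict.

The perseveration analyses decide between unimodal and bimodal distributions of
per-participant quantities (strategy-use proportions, performance differences)
by combining two diagnostics:

* the bimodality coefficient (BC), a moment-based index built from the
  bias-corrected sample skewness and excess kurtosis (SAS convention), with the
  conventional critical value 0.55 (uniform distribution reference value 5/9);
* Hartigan's dip statistic (D), the maximum distance between the empirical CDF
  and the closest unimodal CDF under the classical AS 217 count-unit
  convention, tested against a Monte-Carlo Uniform(0, 1) null.

A sample is called *unimodal* when BC < 0.55 and the dip is non-significant,
*bimodal* when BC > 0.55 and the dip is significant, and *ambiguous* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "BimodalityReport",
    "bimodality_coefficient",
    "dip_statistic",
    "dip_pvalue",
    "bimodality_verdict",
    "bimodality_report",
    "UndefinedStatisticError",
]

BC_CRITICAL = 0.55
DIP_ALPHA = 0.05


class UndefinedStatisticError(ValueError):
    """Raised when a sample is too small or too degenerate for a statistic."""


@dataclass(frozen=True)
class BimodalityReport:
    """Combined bimodality diagnostic for one numeric sample."""

    n: int
    skewness: float
    excess_kurtosis: float
    bc: float
    dip: float
    p_dip: float
    verdict: Literal["unimodal", "bimodal", "ambiguous"]

    def to_dict(self) -> dict:
        return asdict(self)


def _as_sample(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    return x


def bimodality_coefficient(x, *, bias_corrected: bool = True) -> float:
    """Bimodality coefficient BC = (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3))).

    ``g1`` and ``g2`` are the bias-corrected sample skewness and excess
    kurtosis (the SAS definitions). BC tends to 1/3 for a normal sample and to
    5/9 for a uniform sample; larger values hint at bimodality. The statistic
    is invariant under positive affine transforms of the data.

    With ``bias_corrected=False`` the plain moment estimators are used instead
    (non-default variant).
    """
    x = _as_sample(x)
    n = x.size
    if n < 4:
        raise UndefinedStatisticError(f"BC needs n >= 4, got n={n}")
    if np.ptp(x) == 0.0:
        raise UndefinedStatisticError("BC undefined for a constant sample")
    g1 = stats.skew(x, bias=not bias_corrected)
    g2 = stats.kurtosis(x, fisher=True, bias=not bias_corrected)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


# ---------------------------------------------------------------------------
# Hartigan's dip statistic (AS 217 convention)
# ---------------------------------------------------------------------------

def _gcm_predecessors(xs: np.ndarray) -> np.ndarray:
    """For each index, the previous touch point of the greatest convex minorant."""
    n = xs.size
    mn = np.zeros(n, dtype=np.intp)
    for i in range(1, n):
        mn[i] = i - 1
        while True:
            j = mn[i]
            if j == 0:
                break
            k = mn[j]
            if (xs[i] - xs[j]) * (j - k) < (xs[j] - xs[k]) * (i - j):
                break
            mn[i] = k
    return mn


def _lcm_successors(xs: np.ndarray) -> np.ndarray:
    """For each index, the next touch point of the least concave majorant."""
    n = xs.size
    mj = np.full(n, n - 1, dtype=np.intp)
    for i in range(n - 2, -1, -1):
        mj[i] = i + 1
        while True:
            j = mj[i]
            if j == n - 1:
                break
            k = mj[j]
            if (xs[i] - xs[j]) * (j - k) < (xs[j] - xs[k]) * (i - j):
                break
            mj[i] = k
    return mj


def _envelope_dip(xs: np.ndarray, knots: list, start: int, minorant: bool) -> float:
    """Largest count-unit deviation of the ECDF from one envelope's segments.

    ``knots`` lists envelope touch points (GCM stored high-to-low, LCM
    low-to-high); segments from position ``start`` onward are scanned. The ECDF
    is compared one jump beyond the envelope line: ``(i + 1) - line`` for the
    convex minorant and ``line - (i - 1)`` for the concave majorant, both in
    units of counts, which is what makes the final statistic at least 1/(2n).
    """
    best = 0.0
    for j in range(start, len(knots) - 1):
        seg = 1.0
        if minorant:
            lo, hi = knots[j + 1], knots[j]
        else:
            lo, hi = knots[j], knots[j + 1]
        if hi - lo > 1 and xs[hi] != xs[lo]:
            slope = (hi - lo) / (xs[hi] - xs[lo])
            for i in range(lo, hi + 1):
                line = (xs[i] - xs[lo]) * slope
                dev = (i - lo + 1) - line if minorant else -((i - lo - 1) - line)
                if dev > seg:
                    seg = dev
        best = max(best, seg)
    return best


def dip_statistic(x) -> float:
    """Hartigan's dip statistic of a sample, in [1/(2n), 0.25].

    Iterative greatest-convex-minorant / least-concave-majorant search for the
    modal interval, with deviations measured in ECDF count units and the final
    maximum halved (classical AS 217 formulation). Ties need no perturbation:
    the algorithm operates on the weighted ECDF directly. Degenerate samples
    (all values equal) sit at the floor 1/(2n).
    """
    x = _as_sample(x)
    n = x.size
    if n < 2:
        raise UndefinedStatisticError(f"dip needs n >= 2, got n={n}")
    xs = np.sort(x)
    dip = 1.0  # in 2n-scaled units; enforces the 1/(2n) floor
    if xs[-1] == xs[0]:
        return dip / (2.0 * n)

    mn = _gcm_predecessors(xs)
    mj = _lcm_successors(xs)
    low, high = 0, n - 1

    while True:
        # envelope touch points restricted to the current modal estimate
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_gcm, l_lcm = len(gcm), len(lcm)
        ix_g, ix_l = l_gcm - 1, l_lcm - 1

        if l_gcm != 2 or l_lcm != 2:
            # largest separation between the two envelopes inside [low, high]
            d = 0.0
            y_g, y_l = l_gcm - 2, 1
            while True:
                g_at, l_at = gcm[y_g], lcm[y_l]
                if g_at > l_at:
                    i, j, i1 = g_at, l_at, gcm[y_g + 1]
                    dx = (j - i1 + 1) - (xs[j] - xs[i1]) * (i - i1) / (xs[i] - xs[i1])
                    y_l += 1
                    if dx >= d:
                        d, ix_g, ix_l = dx, y_g + 1, y_l - 1
                else:
                    i, j, i1 = l_at, g_at, lcm[y_l - 1]
                    dx = (xs[j] - xs[i1]) * (i - i1) / (xs[i] - xs[i1]) - (j - i1 - 1)
                    y_g -= 1
                    if dx >= d:
                        d, ix_g, ix_l = dx, y_g + 1, y_l
                if y_g < 0:
                    y_g = 0
                if y_l > l_lcm - 1:
                    y_l = l_lcm - 1
                if gcm[y_g] == lcm[y_l]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        dip_l = _envelope_dip(xs, gcm, ix_g, minorant=True)
        dip_u = _envelope_dip(xs, lcm, ix_l, minorant=False)
        dip = max(dip, dip_l, dip_u)

        done = low == gcm[ix_g] and high == lcm[ix_l]
        low, high = gcm[ix_g], lcm[ix_l]
        if done:
            break

    return dip / (2.0 * n)


def dip_pvalue(x, n_null: int = 2000, rng=None) -> tuple[float, float]:
    """Monte-Carlo p-value of the dip against a Uniform(0, 1) null.

    Simulates ``n_null`` uniform samples of the same size, computes each null
    dip, and returns ``(D, p)`` with the add-one continuity correction
    ``p = (1 + #{D_null >= D}) / (n_null + 1)``.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(rng)
    x = _as_sample(x)
    d = dip_statistic(x)
    n = x.size
    exceed = 0
    for _ in range(n_null):
        if dip_statistic(rng.random(n)) >= d:
            exceed += 1
    return d, (1.0 + exceed) / (n_null + 1.0)


def bimodality_verdict(bc: float, p_dip: float) -> str:
    """Combined verdict: BC below 0.55 with a non-significant dip is unimodal,
    BC above 0.55 with a significant dip is bimodal, anything else ambiguous."""
    if bc < BC_CRITICAL and p_dip > DIP_ALPHA:
        return "unimodal"
    if bc > BC_CRITICAL and p_dip < DIP_ALPHA:
        return "bimodal"
    return "ambiguous"


def bimodality_report(x, n_null: int = 2000, rng=None) -> BimodalityReport:
    """Full combined diagnostic (BC + dip + Monte-Carlo p + verdict)."""
    x = _as_sample(x)
    bc = bimodality_coefficient(x)
    d, p = dip_pvalue(x, n_null=n_null, rng=rng)
    return BimodalityReport(
        n=x.size,
        skewness=float(stats.skew(x, bias=False)),
        excess_kurtosis=float(stats.kurtosis(x, fisher=True, bias=False)),
        bc=bc,
        dip=d,
        p_dip=p,
        verdict=bimodality_verdict(bc, p),
    )
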