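"""The ten regression-based trend tests.

Each method regresses the centered effect sizes ``theta*_j = theta_j - 1``
on the centered class medians ``m*_j`` and tests the slope against zero
with a two-sided Student-t test.  Methods differ in three ways: the
weights (unweighted, inverse variance or SE of the effect size or of its
logarithm, or stratum sample size), whether the fit is forced through
the reference point ``(m* = 0, theta* = 0)``, and whether the reference
class contributes a residual degree of freedom.

Computational realization
-------------------------
* Methods 2 and 10: intercept model on all ``r`` points; df = r - 2.
* Methods 3-7 and 9: the reference point is an exact constraint (its
  effect size is known to be 1 with zero variance), so the fit reduces
  to a through-origin regression on the ``r - 1`` non-reference points;
  the constraint consumes the intercept, leaving df = r - 2.
* Methods 1 and 8: the same through-origin fits but with the reference
  counted as an ordinary zero-residual point, inflating df to r - 1.
  This is exactly what makes them anticonservative, and they are flagged
  ``valid=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .class_effects import EffectEstimates

#: Tolerance (relative to the weighted response scale) below which a
#: residual sum of squares is treated as an exact fit.
_EXACT_FIT_RTOL = 1e-13


class DegenerateWeightError(ValueError):
    """A variance-based weight rule met a zero variance in a non-reference class."""


@dataclass(frozen=True)
class TrendMethod:
    """One of the ten trend-test definitions.

    ``weighted`` / ``intercept`` / ``reference_included`` describe the
    method as practitioners state it; ``constrained_through_reference``
    and ``include_reference_in_df`` pin down the computational
    realization (see module docstring).  ``valid`` is False for the two
    methods known to inflate type I error.
    """

    id: int
    weight_rule: str  # unweighted | inv_var_theta | inv_se_theta |
    #                   inv_var_log | inv_se_log | stratum_n
    weighted: bool
    intercept: bool
    reference_included: bool
    constrained_through_reference: bool
    include_reference_in_df: bool
    valid: bool


METHODS: dict[int, TrendMethod] = {
    m.id: m
    for m in (
        TrendMethod(1, "unweighted", False, False, True, True, True, False),
        TrendMethod(2, "unweighted", False, True, True, False, False, True),
        TrendMethod(3, "unweighted", False, True, False, True, False, True),
        TrendMethod(4, "inv_var_theta", True, True, True, True, False, True),
        TrendMethod(5, "inv_se_theta", True, True, True, True, False, True),
        TrendMethod(6, "inv_var_log", True, True, True, True, False, True),
        TrendMethod(7, "inv_se_log", True, True, True, True, False, True),
        TrendMethod(8, "stratum_n", True, False, True, True, True, False),
        TrendMethod(9, "stratum_n", True, True, False, True, False, True),
        TrendMethod(10, "stratum_n", True, True, True, False, False, True),
    )
}

VALID_METHOD_IDS: tuple[int, ...] = tuple(
    m.id for m in METHODS.values() if m.valid
)


@dataclass(frozen=True)
class TrendResult:
    """Slope test for one method: gamma1-hat, its SE, t, df and p."""

    method_id: int
    slope: float
    slope_se: float
    t_stat: float
    df: int
    p_value: float
    n_points_used: int
    valid: bool
    flags: tuple[str, ...] = ()


def _nonref_weights(rule: str, theta, var, n):
    if rule == "unweighted":
        return np.ones_like(theta)
    if rule == "stratum_n":
        return np.asarray(n, dtype=float)
    if np.any(var <= 0):
        raise DegenerateWeightError(
            "zero log-effect variance in a non-reference class under a "
            f"variance-based weight rule ({rule})"
        )
    if rule in ("inv_var_theta", "inv_se_theta") and np.any(theta <= 0):
        raise DegenerateWeightError(
            "non-positive effect size under a ratio-scale weight rule; "
            "odds/hazard ratios must be positive"
        )
    if rule == "inv_var_theta":
        return 1.0 / (theta**2 * var)
    if rule == "inv_se_theta":
        return 1.0 / (theta * np.sqrt(var))
    if rule == "inv_var_log":
        return 1.0 / var
    if rule == "inv_se_log":
        return 1.0 / np.sqrt(var)
    raise ValueError(f"unknown weight rule {rule!r}")


def compute_weights(method: TrendMethod, estimates: EffectEstimates) -> np.ndarray:
    """Per-class weights for one method, aligned with the class order.

    Non-reference entries follow the method's weight rule.  The
    reference entry is the weight the reference point carries in the
    fit: 1 or ``n_ref`` for the methods that include it as an ordinary
    point (1, 2, 8, 10), and NaN for the constrained methods that treat
    it as an exact constraint (3-7, 9), where no finite weight exists.
    """
    ref = estimates.reference_index
    mask = estimates.nonreference
    w = np.full(estimates.n_classes, np.nan)
    w[mask] = _nonref_weights(
        method.weight_rule,
        estimates.theta[mask],
        estimates.var_log_theta[mask],
        estimates.n[mask],
    )
    if not method.constrained_through_reference or method.include_reference_in_df:
        w[ref] = estimates.n[ref] if method.weight_rule == "stratum_n" else 1.0
    return w


def _t_two_sided(t: float, df: int) -> float:
    return float(2.0 * special.stdtr(df, -abs(t)))


def fit_trend(method: TrendMethod, estimates: EffectEstimates) -> TrendResult:
    """Weighted least-squares slope test for one method.

    Returns the slope (change in effect size per exposure unit), its
    standard error, the t statistic, residual df and the two-sided
    p-value.  Degenerate inputs are flagged rather than failing: all
    ``theta*`` zero -> slope 0 with p = 1 ('no-variation'); a perfect
    fit -> p = 0 ('exact-fit').
    """
    r = estimates.n_classes
    if r < 3:
        raise ValueError("trend tests need at least 3 classes")
    ref = estimates.reference_index
    x_all = estimates.m_star
    y_all = estimates.theta - 1.0
    w_all = compute_weights(method, estimates)

    constrained = method.constrained_through_reference
    if not constrained:
        x, y, w = x_all, y_all, w_all
        df = r - 2
    else:
        # the reference point (0, 0) contributes nothing to the
        # through-origin sums, so fitting on the non-reference points is
        # exact for methods 1 and 8 too; only their df differs
        mask = estimates.nonreference
        x, y, w = x_all[mask], y_all[mask], w_all[mask]
        df = (r - 1) if method.include_reference_in_df else (r - 2)
    if df < 1:
        raise ValueError("fewer residual degrees of freedom than 1")
    n_points = r if (not constrained or method.include_reference_in_df) else r - 1

    if np.all(y_all == 0.0):
        return TrendResult(
            method.id, 0.0, 0.0, 0.0, df, 1.0, n_points, method.valid,
            ("no-variation",),
        )

    if not constrained:
        sw = np.sum(w)
        xb = np.sum(w * x) / sw
        yb = np.sum(w * y) / sw
        sxx = np.sum(w * (x - xb) ** 2)
        sxy = np.sum(w * (x - xb) * (y - yb))
        slope = sxy / sxx
        resid = y - yb - slope * (x - xb)
    else:
        sxx = np.sum(w * x * x)
        slope = np.sum(w * x * y) / sxx
        resid = y - slope * x
    sse = float(np.sum(w * resid**2))

    scale = float(np.sum(w * y * y))
    if sse <= _EXACT_FIT_RTOL * max(scale, np.finfo(float).tiny):
        t = np.inf if slope > 0 else (-np.inf if slope < 0 else 0.0)
        return TrendResult(
            method.id, float(slope), 0.0, t, df, 0.0, n_points, method.valid,
            ("exact-fit",),
        )

    se = float(np.sqrt(sse / df / sxx))
    t = float(slope / se)
    return TrendResult(
        method.id, float(slope), se, t, df, _t_two_sided(t, df),
        n_points, method.valid,
    )


def run_all_methods(
    estimates: EffectEstimates,
    method_ids: tuple[int, ...] | None = None,
) -> list[TrendResult]:
    """Run a set of methods (default: all ten, in id order).

    Per-method failures (degenerate weights, too few classes for a
    particular realization) are recorded on the result as an ``error:``
    flag with NaN statistics instead of aborting the batch.
    """
    ids = tuple(method_ids) if method_ids is not None else tuple(sorted(METHODS))
    out = []
    for i in ids:
        try:
            out.append(fit_trend(METHODS[i], estimates))
        except (DegenerateWeightError, ValueError) as exc:
            out.append(
                TrendResult(
                    i, np.nan, np.nan, np.nan, 0, np.nan, 0,
                    METHODS[i].valid, (f"error: {exc}",),
                )
            )
    return out


def results_to_frame(results: list[TrendResult]) -> pd.DataFrame:
    """Tabulate trend results (one row per method, full precision)."""
    return pd.DataFrame(
        {
            "method_id": [t.method_id for t in results],
            "slope": [t.slope for t in results],
            "se": [t.slope_se for t in results],
            "t": [t.t_stat for t in results],
            "df": [t.df for t in results],
            "p": [t.p_value for t in results],
            "valid": [t.valid for t in results],
            "flags": [";".join(t.flags) for t in results],
        }
    )
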