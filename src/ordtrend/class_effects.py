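"""Discretization and per-class effect estimation.

A continuous exposure (the motivating example is body-mass index in
kg/m**2) is cut into ``r`` ordered classes by fixed cut-points.  For a
binary outcome the effect size of class ``j`` is the odds ratio versus a
reference class; for a time-to-event outcome it is the hazard ratio from
a proportional-hazards model with class indicators.  Alongside each
effect size ``theta_j`` we keep the variance of its logarithm
``sigma2_j = Var(log theta_j)``, the stratum size ``n_j`` and the
centered class median ``m*_j`` — the inputs every trend test consumes.

Conventions: the reference class has ``theta = 1`` exactly, ``sigma2 = 0``
and ``m* = 0``; class intervals are lower-inclusive half-open with the
top interval closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class OutOfRangeError(ValueError):
    """An exposure value falls outside the scheme's overall range."""


class DegenerateClassError(ValueError):
    """A class has a zero cell (no events or no non-events / no subjects).

    Carries ``class_index`` so callers can decide whether to fail or to
    drop the offending replicate.
    """

    def __init__(self, class_index: int, message: str | None = None):
        self.class_index = int(class_index)
        super().__init__(message or f"degenerate class {class_index}")


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


@dataclass(frozen=True)
class ClassScheme:
    """Cut-points, representative medians and reference class.

    Parameters
    ----------
    cut_points
        ``r + 1`` strictly increasing exposure values delimiting ``r``
        classes.  Class ``j`` is ``[cut_j, cut_{j+1})`` except the top
        class, which is closed on the right.
    class_medians
        One representative median per class, each inside its interval.
    reference_index
        Which class is the referent (its effect size is 1 by
        construction).
    center
        Value subtracted from the medians; defaults to the reference
        median so that ``m*_ref == 0``.
    labels
        Optional class names.
    """

    cut_points: tuple[float, ...]
    class_medians: tuple[float, ...]
    reference_index: int = 0
    center: float | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cut_points)
        meds = tuple(float(m) for m in self.class_medians)
        object.__setattr__(self, "cut_points", cuts)
        object.__setattr__(self, "class_medians", meds)
        if len(cuts) < 3:
            raise ValueError("need at least 2 classes (3 cut-points)")
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("cut_points must be strictly increasing")
        r = len(cuts) - 1
        if len(meds) != r:
            raise ValueError(f"expected {r} class medians, got {len(meds)}")
        for j, m in enumerate(meds):
            hi_closed = j == r - 1
            if not (cuts[j] <= m <= cuts[j + 1] if hi_closed else cuts[j] <= m < cuts[j + 1]):
                raise ValueError(f"median {m} outside interval of class {j}")
        if not 0 <= self.reference_index < r:
            raise ValueError("reference_index out of range")
        if self.center is None:
            object.__setattr__(self, "center", meds[self.reference_index])
        elif float(self.center) != meds[self.reference_index]:
            raise ValueError("center must equal the reference class median")
        if self.labels is not None:
            if len(self.labels) != r:
                raise ValueError("one label per class required")
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_classes(self) -> int:
        return len(self.class_medians)

    @property
    def m_star(self) -> np.ndarray:
        """Centered medians ``m_j - center``."""
        return np.asarray(self.class_medians) - self.center

    def label(self, j: int) -> str:
        return self.labels[j] if self.labels else f"class_{j}"


def who_bmi_scheme() -> ClassScheme:
    """The WHO weight-class scheme with its defined class medians.

    Underweight [12, 18.5), normal weight [18.5, 25), overweight
    [25, 30), obese [30, 70]; medians 17, 23, 28, 35 kg/m**2 centered at
    the normal-weight median 23.
    """
    return ClassScheme(
        cut_points=(12.0, 18.5, 25.0, 30.0, 70.0),
        class_medians=(17.0, 23.0, 28.0, 35.0),
        reference_index=1,
        labels=("underweight", "normal weight", "overweight", "obese"),
    )


def discretize(exposure_values, scheme: ClassScheme) -> np.ndarray:
    """Map continuous exposures to class indices ``0..r-1``.

    Intervals are lower-inclusive half-open; the top interval is closed,
    so the maximum cut-point itself belongs to the top class.  Values
    outside ``[cut_0, cut_r]`` raise :class:`OutOfRangeError`.
    """
    z = np.asarray(exposure_values, dtype=float)
    cuts = np.asarray(scheme.cut_points)
    bad = (z < cuts[0]) | (z > cuts[-1]) | ~np.isfinite(z)
    if np.any(bad):
        v = z[bad].ravel()[0]
        raise OutOfRangeError(
            f"exposure value {v} outside range [{cuts[0]}, {cuts[-1]}]"
        )
    idx = np.searchsorted(cuts, z, side="right") - 1
    return np.minimum(idx, scheme.n_classes - 1).astype(np.intp)


@dataclass(frozen=True)
class ContingencyTable:
    """Per-class event / non-event counts (rows in ascending class order)."""

    events: tuple[int, ...]
    non_events: tuple[int, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        ev = tuple(int(e) for e in self.events)
        ne = tuple(int(x) for x in self.non_events)
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "non_events", ne)
        if len(ev) != len(ne):
            raise ValueError("events and non_events must have equal length")
        if len(ev) < 2:
            raise ValueError("need at least 2 classes")
        if any(c < 0 for c in ev + ne):
            raise ValueError("counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.events)

    @property
    def totals(self) -> np.ndarray:
        return np.asarray(self.events) + np.asarray(self.non_events)


def cross_tabulate(outcomes, classes, n_classes: int) -> ContingencyTable:
    """Tabulate a 0/1 outcome vector by class index."""
    y = np.asarray(outcomes, dtype=np.intp)
    c = np.asarray(classes, dtype=np.intp)
    ev = np.bincount(c[y == 1], minlength=n_classes)
    ne = np.bincount(c[y == 0], minlength=n_classes)
    return ContingencyTable(tuple(ev), tuple(ne))


def read_contingency_csv(path) -> tuple[ContingencyTable, tuple[float, ...]]:
    """Read a contingency CSV (class_label, events, non_events, median).

    Rows must be in ascending class order.  Returns the table and the
    per-class medians, from which callers can assemble a
    :class:`ClassScheme`.
    """
    df = pd.read_csv(path)
    required = {"class_label", "events", "non_events", "median"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contingency CSV missing columns: {sorted(missing)}")
    table = ContingencyTable(
        tuple(df["events"]), tuple(df["non_events"]), tuple(df["class_label"])
    )
    return table, tuple(float(m) for m in df["median"])


@dataclass(frozen=True)
class EffectEstimates:
    """Per-class effect sizes and the quantities the trend tests need.

    ``theta`` are odds/hazard ratios versus the reference class (exactly
    1 at the reference); ``var_log_theta`` is ``Var(log theta_j)`` (0 at
    the reference by convention); ``n`` are stratum sizes; ``m_star``
    the centered class medians.
    """

    theta: np.ndarray
    var_log_theta: np.ndarray
    n: np.ndarray
    m_star: np.ndarray
    reference_index: int
    outcome_kind: str  # "binary" | "survival"

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        var = np.asarray(self.var_log_theta, dtype=float)
        n = np.asarray(self.n, dtype=float)
        ms = np.asarray(self.m_star, dtype=float)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "var_log_theta", var)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "m_star", ms)
        ref = self.reference_index
        if not (len(theta) == len(var) == len(n) == len(ms)):
            raise ValueError("field lengths differ")
        if theta[ref] != 1.0 or var[ref] != 0.0 or ms[ref] != 0.0:
            raise ValueError("reference class must have theta=1, var=0, m*=0")
        if np.any(var < 0):
            raise ValueError("var_log_theta must be non-negative")
        if np.any(n < 1):
            raise ValueError("every class needs at least one subject")
        if self.outcome_kind not in ("binary", "survival"):
            raise ValueError("outcome_kind must be 'binary' or 'survival'")

    @property
    def n_classes(self) -> int:
        return len(self.theta)

    @property
    def nonreference(self) -> np.ndarray:
        mask = np.ones(self.n_classes, dtype=bool)
        mask[self.reference_index] = False
        return mask


def odds_ratios_from_table(
    table: ContingencyTable, scheme: ClassScheme
) -> EffectEstimates:
    """Closed-form odds ratios and log-OR variances from cell counts.

    With a single categorical predictor the logistic MLE is the 2x2
    odds ratio of each class versus the reference,
    ``theta_j = (a_j d_ref) / (b_j c_ref)``, and
    ``Var(log theta_j)`` is the sum of reciprocal counts of the four
    cells involved.  A zero cell in any class raises
    :class:`DegenerateClassError`.
    """
    if table.n_classes != scheme.n_classes:
        raise ValueError("table and scheme class counts differ")
    a = np.asarray(table.events, dtype=float)
    b = np.asarray(table.non_events, dtype=float)
    ref = scheme.reference_index
    if a[ref] < 1 or b[ref] < 1:
        raise DegenerateClassError(ref, "reference class has a zero cell")
    zero = (a == 0) | (b == 0)
    if np.any(zero):
        j = int(np.nonzero(zero)[0][0])
        raise DegenerateClassError(j, f"class {j} has a zero cell")
    theta = (a * b[ref]) / (b * a[ref])
    var = 1.0 / a + 1.0 / b + 1.0 / a[ref] + 1.0 / b[ref]
    theta[ref] = 1.0
    var[ref] = 0.0
    return EffectEstimates(
        theta=theta,
        var_log_theta=var,
        n=a + b,
        m_star=scheme.m_star,
        reference_index=ref,
        outcome_kind="binary",
    )


def fit_logistic_classes(outcomes, classes, scheme: ClassScheme) -> EffectEstimates:
    """Maximum-likelihood logistic fit with class indicators.

    Saturated model: agrees with :func:`odds_ratios_from_table` applied
    to the cross-tabulation (the closed form is the exact MLE).  A class
    with all-0 or all-1 outcomes (complete separation) raises
    :class:`DegenerateClassError`.
    """
    import statsmodels.api as sm

    y = np.asarray(outcomes, dtype=float)
    c = np.asarray(classes, dtype=np.intp)
    r = scheme.n_classes
    ref = scheme.reference_index
    table = cross_tabulate(y.astype(int), c, r)
    counts = table.totals
    if np.any(counts == 0):
        j = int(np.nonzero(counts == 0)[0][0])
        raise DegenerateClassError(j, f"class {j} has no subjects")
    zero = (np.asarray(table.events) == 0) | (np.asarray(table.non_events) == 0)
    if np.any(zero):
        j = int(np.nonzero(zero)[0][0])
        raise DegenerateClassError(j, f"class {j} is completely separated")

    nonref = [j for j in range(r) if j != ref]
    X = np.column_stack(
        [np.ones_like(y)] + [(c == j).astype(float) for j in nonref]
    )
    fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
    beta = np.zeros(r)
    var = np.zeros(r)
    cov = fit.cov_params()
    for k, j in enumerate(nonref):
        beta[j] = fit.params[k + 1]
        var[j] = cov[k + 1, k + 1]
    theta = np.exp(beta)
    theta[ref] = 1.0
    var[ref] = 0.0
    return EffectEstimates(
        theta=theta,
        var_log_theta=var,
        n=counts,
        m_star=scheme.m_star,
        reference_index=ref,
        outcome_kind="binary",
    )


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival records with class membership.

    ``time`` holds observed times ``v_i = min(t_i, c_i)`` (> 0),
    ``event`` the indicators ``I(t_i < c_i)`` and ``class_index`` the
    exposure class of each subject.
    """

    time: np.ndarray
    event: np.ndarray
    class_index: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.event, dtype=np.intp)
        c = np.asarray(self.class_index, dtype=np.intp)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", d)
        object.__setattr__(self, "class_index", c)
        if not (len(t) == len(d) == len(c)):
            raise ValueError("field lengths differ")
        if np.any(t <= 0):
            raise ValueError("observed times must be positive")
        if not np.isin(d, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    @classmethod
    def from_csv(cls, path, scheme: ClassScheme) -> "SurvivalData":
        """Read a survival CSV (id, time, event, class_label)."""
        df = pd.read_csv(path)
        required = {"time", "event", "class_label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"survival CSV missing columns: {sorted(missing)}")
        labels = {scheme.label(j): j for j in range(scheme.n_classes)}
        unknown = set(df["class_label"]) - set(labels)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        return cls(
            time=df["time"].to_numpy(float),
            event=df["event"].to_numpy(int),
            class_index=df["class_label"].map(labels).to_numpy(np.intp),
        )

    def __len__(self) -> int:
        return len(self.time)


def _cox_class_indicators(time, event, ci, p, tol, max_iter):
    """Newton-Raphson Cox partial likelihood with Breslow tie handling.

    ``ci`` maps each subject to a non-reference covariate column (or -1
    for the reference).  Because the design rows are one-hot, the
    at-risk outer-product sums reduce to the at-risk linear sums, which
    keeps each iteration O(n) after a single sort.
    """
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    d_s = event[order].astype(bool)
    c_s = ci[order]
    # Breslow risk set at an event time includes everyone with v >= t;
    # tied times must all use the sums at the first index of their group.
    first = np.searchsorted(t_s, t_s, side="left")
    ev_first = first[d_s]
    d_counts = np.bincount(c_s[d_s] + 1, minlength=p + 1).astype(float)[1:]
    onehot = [c_s == k for k in range(p)]

    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(max_iter):
        eta = np.where(c_s >= 0, beta[np.maximum(c_s, 0)], 0.0)
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.empty((p, len(w)))
        for k in range(p):
            s1[k] = np.cumsum(np.where(onehot[k], w, 0.0)[::-1])[::-1]
        s0e = s0[ev_first]
        mu = s1[:, ev_first] / s0e  # p x n_events
        ll = float(eta[d_s].sum() - np.log(s0e).sum())
        score = d_counts - mu.sum(axis=1)
        info = np.diag(mu.sum(axis=1)) - mu @ mu.T
        if it > 0 and abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            return beta, info, it
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving guards rare overshoot on extreme data
        for _ in range(30):
            cand = beta + step
            eta_c = np.where(c_s >= 0, cand[np.maximum(c_s, 0)], 0.0)
            s0_c = np.cumsum(np.exp(eta_c)[::-1])[::-1][ev_first]
            ll_c = float(eta_c[d_s].sum() - np.log(s0_c).sum())
            if ll_c >= ll or np.max(np.abs(step)) < 1e-14:
                break
            step = step / 2.0
        beta = beta + step
        ll_old = ll
    raise ConvergenceError(
        f"Cox fit did not converge in {max_iter} iterations "
        f"(last log-likelihood change {abs(ll - ll_old):.3e})"
    )


def fit_cox_effects(
    data: SurvivalData,
    scheme: ClassScheme,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> EffectEstimates:
    """Hazard ratios per class from a Cox model with class indicators.

    Partial-likelihood estimates ``theta_j = exp(beta_j)`` with
    variances from the inverse observed information; Breslow tie
    handling.  Every class must contain at least one event.
    """
    r = scheme.n_classes
    ref = scheme.reference_index
    c = data.class_index
    if np.any((c < 0) | (c >= r)):
        raise ValueError("class index outside scheme range")
    n = np.bincount(c, minlength=r)
    if np.any(n == 0):
        j = int(np.nonzero(n == 0)[0][0])
        raise DegenerateClassError(j, f"class {j} has no subjects")
    ev = np.bincount(c[data.event == 1], minlength=r)
    if np.any(ev == 0):
        j = int(np.nonzero(ev == 0)[0][0])
        raise DegenerateClassError(j, f"class {j} has no events")

    nonref = [j for j in range(r) if j != ref]
    col = np.full(r, -1, dtype=np.intp)
    for k, j in enumerate(nonref):
        col[j] = k
    ci = col[c]
    beta_nr, info, _ = _cox_class_indicators(
        data.time, data.event, ci, r - 1, tol, max_iter
    )
    cov = np.linalg.inv(info)
    theta = np.ones(r)
    var = np.zeros(r)
    for k, j in enumerate(nonref):
        theta[j] = np.exp(beta_nr[k])
        var[j] = cov[k, k]
    return EffectEstimates(
        theta=theta,
        var_log_theta=var,
        n=n,
        m_star=scheme.m_star,
        reference_index=ref,
        outcome_kind="survival",
    )
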