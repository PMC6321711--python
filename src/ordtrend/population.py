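"""Exposure populations for the simulation pipeline.

The synthetic generator emulates the marginal BMI distribution of a
national health-survey sample of 5,551 adults: class shares of about
1.7/27.3/34.6/36.5% across the four WHO weight classes, class medians
17.8/22.7/27.5/34.0 kg/m**2, overall range 14.2-67.3 kg/m**2, mean 28.9
and SD 6.6.  Within each class values are drawn from a log-normal
truncated to the class interval, with its location solved so the class
median matches the target — a right-skewed family is all the printed
marginals can identify.

User-supplied exposure vectors are loaded from a single-column CSV and
validated against a class scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, special

from .class_effects import ClassScheme, OutOfRangeError, discretize


@dataclass(frozen=True)
class ClassTarget:
    """Marginal targets for one class of the synthetic population."""

    label: str
    lower: float
    upper: float
    proportion: float
    median: float
    log_scale: float  # SD of the underlying normal on the log scale

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("class interval must be non-empty")
        if not self.lower <= self.median <= self.upper:
            raise ValueError(
                f"target median {self.median} outside interval "
                f"[{self.lower}, {self.upper}] for class {self.label!r}"
            )
        if self.proportion <= 0:
            raise ValueError("class proportion must be positive")
        if self.log_scale <= 0:
            raise ValueError("log_scale must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Marginal targets for the synthetic exposure population."""

    classes: tuple[ClassTarget, ...]
    range_limits: tuple[float, float]
    target_mean: float
    target_sd: float

    def __post_init__(self):
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        lo, hi = self.range_limits
        if not lo < hi:
            raise ValueError("range limits must be increasing")

    @property
    def proportions(self) -> np.ndarray:
        p = np.array([c.proportion for c in self.classes])
        return p / p.sum()  # printed percentages may not sum exactly to 100


def default_spec() -> PopulationSpec:
    """The packaged default specification (survey-derived marginals)."""
    text = (
        resources.files("ordtrend.data")
        .joinpath("default_population_spec.json")
        .read_text()
    )
    raw = json.loads(text)
    return PopulationSpec(
        classes=tuple(ClassTarget(**c) for c in raw["classes"]),
        range_limits=tuple(raw["range_limits"]),
        target_mean=raw["target_mean"],
        target_sd=raw["target_sd"],
    )


def _truncated_lognormal_ppf(q, mu, s, lo, hi):
    a = (np.log(lo) - mu) / s
    b = (np.log(hi) - mu) / s
    fa, fb = special.ndtr(a), special.ndtr(b)
    return np.exp(mu + s * special.ndtri(fa + q * (fb - fa)))


def _solve_location(target_median, s, lo, hi):
    def gap(mu):
        return _truncated_lognormal_ppf(0.5, mu, s, lo, hi) - target_median

    return optimize.brentq(gap, np.log(lo) - 8 * s, np.log(hi) + 8 * s, xtol=1e-12)


def make_synthetic_population(
    spec: PopulationSpec,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a synthetic exposure vector matching the spec's marginals.

    Class membership is multinomial on the target proportions; within a
    class, values come from the truncated log-normal whose location is
    solved so its median equals the class target.  Deterministic given
    the generator state.
    """
    cls = rng.choice(len(spec.classes), size=size, p=spec.proportions)
    values = np.empty(size)
    for j, target in enumerate(spec.classes):
        idx = cls == j
        m = int(idx.sum())
        if m == 0:
            continue
        mu = _solve_location(target.median, target.log_scale, target.lower, target.upper)
        values[idx] = _truncated_lognormal_ppf(
            rng.random(m), mu, target.log_scale, target.lower, target.upper
        )
    return values


def load_population(
    path,
    scheme: ClassScheme,
    *,
    drop_out_of_range: bool = False,
    log=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Load an exposure CSV (single column, header ``exposure``).

    Returns ``(values, class_indices)``.  Non-numeric rows raise with
    their line numbers; values outside the scheme range raise unless
    ``drop_out_of_range`` is set, in which case they are excluded and
    the count reported through ``log``.
    """
    df = pd.read_csv(path)
    if "exposure" not in df.columns:
        if df.shape[1] == 1:
            df.columns = ["exposure"]
        else:
            raise ValueError("population CSV needs an 'exposure' column")
    if len(df) == 0:
        raise ValueError("population CSV is empty")
    values = pd.to_numeric(df["exposure"], errors="coerce")
    bad = values.isna() & df["exposure"].notna() | df["exposure"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in np.nonzero(bad.to_numpy())[0]]  # +2: header
        raise ValueError(f"non-numeric exposure values at lines {lines}")
    z = values.to_numpy(float)
    lo, hi = scheme.cut_points[0], scheme.cut_points[-1]
    outside = (z < lo) | (z > hi)
    if outside.any():
        if not drop_out_of_range:
            raise OutOfRangeError(
                f"{int(outside.sum())} exposure value(s) outside "
                f"[{lo}, {hi}]; first offender {z[outside][0]}"
            )
        if log is not None:
            log(f"dropped {int(outside.sum())} out-of-range exposure value(s)")
        z = z[~outside]
        if z.size == 0:
            raise ValueError("no in-range exposure values remain")
    cls = discretize(z, scheme)
    if log is not None:
        counts = np.bincount(cls, minlength=scheme.n_classes)
        log(
            f"loaded n={z.size}, per-class counts {counts.tolist()}, "
            f"mean {z.mean():.2f}, SD {z.std(ddof=1):.2f}"
        )
    return z, cls
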