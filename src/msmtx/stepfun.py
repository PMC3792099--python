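"""Right-continuous step functions for survival-type estimates.

Every nonparametric estimate in this package (cumulative hazard, survival,
cumulative incidence, transition probability entries) is a right-continuous
step function with knots at observed event times, a variance per knot and a
range-respecting confidence interval.  Times are in days since diagnosis
unless a clock-reset analysis says otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StepFunction", "DAYS_PER_YEAR"]

DAYS_PER_YEAR = 365.25

_KINDS = ("survival", "cumhaz", "cif", "prob")


@dataclass
class StepFunction:
    """A right-continuous step estimate.

    Parameters
    ----------
    knots : array of float
        Strictly increasing jump times (days).
    values : array of float
        Value immediately *after* each knot; ``value_at_zero`` applies on
        ``[0, knots[0])``.
    variance : array of float, optional
        Pointwise variance of the estimate at each knot.
    kind : {'survival', 'cumhaz', 'cif', 'prob'}
    ci_level : float
        Nominal two-sided confidence level for :meth:`confidence_band`.
    """

    knots: np.ndarray
    values: np.ndarray
    variance: np.ndarray | None = None
    kind: str = "prob"
    ci_level: float = 0.95
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.knots.ndim != 1 or self.knots.shape != self.values.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def value_at_zero(self) -> float:
        return 1.0 if self.kind == "survival" else 0.0

    def __call__(self, t):
        """Evaluate at times ``t`` (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        padded = np.concatenate([[self.value_at_zero], self.values])
        out = padded[idx + 1]
        return out if out.ndim else float(out)

    def variance_at(self, t):
        if self.variance is None:
            raise ValueError("no variance attached to this StepFunction")
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        padded = np.concatenate([[0.0], self.variance])
        out = padded[idx + 1]
        return out if out.ndim else float(out)

    def confidence_band(self) -> pd.DataFrame:
        """Pointwise CI at the knots.

        Survival uses the log(-log) transform, cumulative hazard and CIF the
        log transform, plain probabilities a linear (clipped) interval; all
        three respect the estimate's natural range.
        """
        if self.variance is None:
            raise ValueError("no variance attached to this StepFunction")
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        v = self.values
        se = np.sqrt(np.clip(self.variance, 0.0, np.inf))
        lo = np.full_like(v, np.nan)
        hi = np.full_like(v, np.nan)
        if self.kind == "survival":
            # log(-log S) scale
            inner = (v > 0) & (v < 1)
            s = v[inner]
            sig = se[inner] / np.abs(s * np.log(s))
            theta = np.log(-np.log(s))
            lo[inner] = np.exp(-np.exp(theta + z * sig))
            hi[inner] = np.exp(-np.exp(theta - z * sig))
            lo[v == 1] = 1.0
            hi[v == 1] = 1.0
            lo[v == 0] = 0.0
            hi[v == 0] = 0.0
        elif self.kind in ("cumhaz", "cif"):
            pos = v > 0
            sig = se[pos] / v[pos]
            lo[pos] = v[pos] * np.exp(-z * sig)
            hi[pos] = v[pos] * np.exp(z * sig)
            lo[~pos] = 0.0
            hi[~pos] = 0.0
            if self.kind == "cif":
                hi = np.minimum(hi, 1.0)
        else:
            lo = np.clip(v - z * se, 0.0, 1.0)
            hi = np.clip(v + z * se, 0.0, 1.0)
        return pd.DataFrame(
            {"time_days": self.knots, "estimate": v, "var": self.variance,
             "lo": lo, "hi": hi}
        )

    def to_frame(self) -> pd.DataFrame:
        if self.variance is not None:
            return self.confidence_band()
        return pd.DataFrame({"time_days": self.knots, "estimate": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def metadata(self) -> dict:
        out = {"kind": self.kind, "ci_level": self.ci_level}
        out.update(self.meta)
        return out

    def metadata_json(self) -> str:
        return json.dumps(self.metadata(), sort_keys=True)

    # -- helpers used across the package -------------------------------------

    def sup_distance(self, other, grid=None) -> float:
        """Sup-norm distance to another step function (or callable)."""
        if grid is None:
            knots = [self.knots]
            if isinstance(other, StepFunction):
                knots.append(other.knots)
            grid = np.unique(np.concatenate(knots + [[0.0]]))
        a = self(grid)
        b = other(grid)
        return float(np.max(np.abs(np.asarray(a) - np.asarray(b))))

    def median(self) -> float:
        """First time the curve drops to <= 0.5 (survival only); NaN if not reached."""
        if self.kind != "survival":
            raise ValueError("median is defined for survival curves")
        below = self.values <= 0.5
        if not below.any():
            return float("nan")
        return float(self.knots[np.argmax(below)])
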