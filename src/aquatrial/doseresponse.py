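"""Dose-response regression of trial performance against dietary quality.

The central estimator is the continuous one-breakpoint linear-plateau
("broken-line") model, the standard tool for locating a nutrient
requirement from a dose-response series:

    y = plateau - slope * max(0, b - x),    slope >= 0

i.e. the response rises linearly with the quality metric x up to a
breakpoint b and is flat beyond it; the breakpoint estimates the level of
the metric needed for maximum response.  The model is continuous at b by
construction.

Fitting profiles the breakpoint: for each candidate b the two linear
parameters (plateau, slope) have a closed-form least-squares solution, so
the profile RSS(b) is minimised over a dense deterministic grid followed
by bounded local refinement — no random restarts, so a fit is exactly
reproducible and invariant to the order of the data points.

A quadratic-plateau variant (y = plateau - c*(b - x)^2 below b, smooth at
the join) is provided for sensitivity analysis, and plain OLS is wrapped
as :func:`fit_linear` for the simple linear relationships.

The API follows the statsmodels convention: a model object is built from
data, ``fit()`` returns a results object carrying estimates, diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateInputError

__all__ = [
    "LinearPlateau",
    "QuadraticPlateau",
    "PlateauResults",
    "LinearFit",
    "fit_linear",
    "fit_linear_plateau",
    "fit_quadratic_plateau",
]


def _as_xy(endog, exog) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(endog, dtype=float).ravel()
    x = np.asarray(exog, dtype=float).ravel()
    if y.shape != x.shape:
        raise DegenerateInputError(f"endog and exog lengths differ: {y.size} vs {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateInputError("endog/exog contain non-finite values")
    return y, x


class _PlateauModel:
    """Shared machinery for profiled plateau models."""

    #: exponent of the deficiency term: 1 = linear limb, 2 = quadratic limb
    _power: int = 1
    _name: str = "linear-plateau"
    _min_n: int = 4

    def __init__(self, endog, exog) -> None:
        y, x = _as_xy(endog, exog)
        if y.size < self._min_n:
            raise DegenerateInputError(
                f"{self._name} fit needs at least {self._min_n} points, got {y.size}"
            )
        if np.ptp(x) == 0:
            raise DegenerateInputError("exog has zero variance")
        self.endog = y
        self.exog = x
        self.nobs = y.size

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, x: str, y: str) -> "_PlateauModel":
        """Build the model from named columns of a DataFrame."""
        return cls(data[y], data[x])

    # -- profiled least squares -----------------------------------------
    def _ls_at(self, b: float) -> tuple[float, float, float]:
        """Closed-form (rss, plateau, slope>=0) at a candidate breakpoint."""
        y, x = self.endog, self.exog
        z = np.maximum(0.0, b - x) ** self._power
        sz, szz, sy, szy = z.sum(), (z * z).sum(), y.sum(), (z * y).sum()
        n = y.size
        det = n * szz - sz * sz
        if det <= 0:  # z constant (all points on the plateau side)
            plateau, slope = sy / n, 0.0
        else:
            # regress y on [1, -z]
            slope = -(n * szy - sz * sy) / det
            plateau = (sy + slope * sz) / n
            if slope < 0:  # falling limb inadmissible: clamp to flat model
                plateau, slope = sy / n, 0.0
        resid = y - (plateau - slope * z)
        return float(resid @ resid), float(plateau), float(slope)

    def fit(self, grid_size: int = 512) -> "PlateauResults":
        """Profile the breakpoint over a dense grid, then refine locally.

        Deterministic: a fixed ``grid_size``-point grid over
        [min(x), max(x)] followed by bounded scalar minimisation between
        the grid neighbours of the best candidate.
        """
        x = self.exog
        lo, hi = float(x.min()), float(x.max())
        grid = np.linspace(lo, hi, grid_size)
        rss_grid = np.array([self._ls_at(b)[0] for b in grid])
        i = int(np.argmin(rss_grid))
        left = grid[max(i - 1, 0)]
        right = grid[min(i + 1, grid_size - 1)]
        if right > left:
            res = optimize.minimize_scalar(
                lambda b: self._ls_at(b)[0],
                bounds=(left, right),
                method="bounded",
                options={"xatol": 1e-10},
            )
            b_hat = float(res.x) if res.fun <= rss_grid[i] else float(grid[i])
        else:
            b_hat = float(grid[i])
        rss, plateau, slope = self._ls_at(b_hat)
        if slope == 0.0:
            # All-plateau: the breakpoint is unidentified; report min(x).
            b_hat = lo
            rss, plateau, slope = self._ls_at(b_hat)
        tss = float(((self.endog - self.endog.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        return PlateauResults(
            model=self,
            breakpoint=b_hat,
            slope=slope,
            plateau=plateau,
            rss=rss,
            r2=r2,
            converged=True,
            plateau_only=slope == 0.0,
        )


class LinearPlateau(_PlateauModel):
    """Broken-line (linear-plateau) dose-response model.

    Parameters
    ----------
    endog : array-like
        Response values (e.g. specific growth rate, %/d).
    exog : array-like
        Dose / quality metric (e.g. DEAAI, %).

    Examples
    --------
    >>> m = LinearPlateau([1.0, 2.0, 3.0, 3.0, 3.0], [1, 2, 3, 4, 5])
    >>> round(m.fit().breakpoint, 6)
    3.0
    """

    _power = 1
    _name = "linear-plateau"


class QuadraticPlateau(_PlateauModel):
    """Quadratic-plateau variant: y = plateau - c*(b - x)^2 below b.

    Smooth (zero slope) at the join; tends to place the breakpoint higher
    than the broken-line model and is offered as a sensitivity check, not
    as the primary estimator.
    """

    _power = 2
    _name = "quadratic-plateau"


@dataclass
class PlateauResults:
    """Results of a profiled plateau fit.

    ``plateau_only`` flags data with no detectable rising limb (slope
    clamped at 0, breakpoint reported at min(x) and not interpretable).
    """

    model: _PlateauModel
    breakpoint: float
    slope: float
    plateau: float
    rss: float
    r2: float
    converged: bool
    plateau_only: bool = False

    @property
    def n(self) -> int:
        return self.model.nobs

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"breakpoint": self.breakpoint, "slope": self.slope, "plateau": self.plateau}
        )

    def predict(self, x) -> np.ndarray:
        """Evaluate the fitted piecewise curve at new x values."""
        x = np.asarray(x, dtype=float)
        z = np.maximum(0.0, self.breakpoint - x) ** self.model._power
        return self.plateau - self.slope * z

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    def bootstrap_breakpoint_ci(
        self, n_boot: int = 500, alpha: float = 0.05, seed: int | None = None
    ) -> tuple[float, float]:
        """Percentile bootstrap confidence interval for the breakpoint."""
        rng = np.random.default_rng(seed)
        y, x = self.model.endog, self.model.exog
        est = []
        for _ in range(n_boot):
            idx = rng.integers(0, y.size, y.size)
            try:
                fit = type(self.model)(y[idx], x[idx]).fit(grid_size=128)
            except DegenerateInputError:
                continue
            est.append(fit.breakpoint)
        lo, hi = np.quantile(est, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)

    def summary(self) -> str:
        lines = [
            f"{self.model._name} fit (profiled least squares)",
            f"  n observations : {self.n}",
            f"  breakpoint     : {self.breakpoint:.4f}",
            f"  slope          : {self.slope:.5f}",
            f"  plateau        : {self.plateau:.4f}",
            f"  RSS            : {self.rss:.6g}",
            f"  R-squared      : {self.r2:.4f}",
        ]
        if self.plateau_only:
            lines.append("  note: no rising limb detected; breakpoint not interpretable")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the data with the fitted curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.exog, self.model.endog
        ax.scatter(x, y, color="k", zorder=3)
        xx = np.linspace(x.min(), x.max(), 200)
        ax.plot(xx, self.predict(xx), color="C1")
        ax.axvline(self.breakpoint, ls="--", color="C1", alpha=0.6)
        ax.set_xlabel("dose / quality metric")
        ax.set_ylabel("response")
        return ax


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with slope inference."""

    slope: float
    intercept: float
    r2: float
    p_slope: float
    stderr_slope: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        return (
            "ordinary least squares fit\n"
            f"  n observations : {self.n}\n"
            f"  slope          : {self.slope:.5f} (SE {self.stderr_slope:.5f}, "
            f"p = {self.p_slope:.4g})\n"
            f"  intercept      : {self.intercept:.4f}\n"
            f"  R-squared      : {self.r2:.4f}"
        )


def fit_linear(x, y) -> LinearFit:
    """OLS fit of y on x with a t-test on the slope (n - 2 df)."""
    y, x = _as_xy(y, x)
    if y.size < 3:
        raise DegenerateInputError(f"linear fit needs at least 3 points, got {y.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("exog has zero variance")
    res = stats.linregress(x, y)
    # stats.linregress leaves r = nan for constant y; report r2 = 0 there
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        p_slope=p,
        stderr_slope=float(res.stderr),
        n=y.size,
    )


def fit_linear_plateau(x, y, grid_size: int = 512) -> PlateauResults:
    """Convenience wrapper: ``LinearPlateau(y, x).fit()``."""
    return LinearPlateau(y, x).fit(grid_size=grid_size)


def fit_quadratic_plateau(x, y, grid_size: int = 512) -> PlateauResults:
    """Convenience wrapper: ``QuadraticPlateau(y, x).fit()``."""
    return QuadraticPlateau(y, x).fit(grid_size=grid_size)
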