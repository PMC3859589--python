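"""Chronosequence regressions: linear, power, and exponential families.

Community metrics (diversity, ordination scores) are related to site age,
stand basal area, or understory light with one of three two-parameter
families,

    linear       y = a + b x
    power        y = a x^b          (x > 0)
    exponential  y = a exp(b x)

fitted by (non)linear least squares.  The nonlinear families are
initialized from log-space linear fits and refined with ``curve_fit``;
R^2 is always computed on the response scale, 1 - SSE/SST, so families are
comparable, and significance comes from the F-test of the fitted model
against the intercept-only model.  :func:`select_model` reproduces a
model-comparison table: the best family is the one with the highest R^2
among significant fits, or "ns" when none is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

FAMILIES = ("linear", "power", "exponential")
FAMILY_CODES = {"linear": "L", "power": "P", "exponential": "E"}


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the log-space initial fit."""

    def __init__(self, message: str, init_fit: "SuccessionFit | None" = None):
        super().__init__(message)
        self.init_fit = init_fit


@dataclass
class SuccessionFit:
    """Results of one family's fit: estimates, fit quality, significance."""

    family: str
    a: float
    b: float
    r2: float
    p_value: float
    n: int
    n_dropped: int = 0           # rows excluded (domain restrictions)

    @property
    def params(self) -> tuple[float, float]:
        return self.a, self.b

    @property
    def code(self) -> str:
        return FAMILY_CODES[self.family]

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "linear":
            return self.a + self.b * x
        if self.family == "power":
            return self.a * x ** self.b
        return self.a * np.exp(self.b * x)

    def summary(self) -> str:
        lines = [
            f"{self.family.capitalize()} regression (n = {self.n})",
            "-" * 40,
            f"  a        {self.a: .6g}",
            f"  b        {self.b: .6g}",
            f"  R^2      {self.r2: .4f}",
            f"  p(F)     {self.p_value: .4g}",
        ]
        if self.n_dropped:
            lines.append(f"  dropped  {self.n_dropped} rows (domain)")
        return "\n".join(lines)


class SuccessionModel:
    """A single-family regression model of a community metric on a predictor.

    statsmodels-style: construct from data, call :meth:`fit` for a
    :class:`SuccessionFit` results object.
    """

    def __init__(self, endog, exog, family: str = "linear",
                 fit_mode: str = "nls"):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if fit_mode not in ("nls", "loglog"):
            raise ValueError("fit_mode must be 'nls' or 'loglog'")
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("endog and exog must be 1-D and equal length")
        ok = np.isfinite(x) & np.isfinite(y)
        self.n_dropped = int((~ok).sum())
        x, y = x[ok], y[ok]
        if family == "power":
            bad = x <= 0
            if bad.any():
                raise ValueError("power family requires strictly positive x")
            drop = y <= 0  # zero responses excluded, not offset
            self.n_dropped += int(drop.sum())
            x, y = x[~drop], y[~drop]
        self.x, self.y, self.family, self.fit_mode = x, y, family, fit_mode
        if self.x.size < 4:
            raise ValueError("need at least 4 usable observations")

    # -- internals ---------------------------------------------------------
    def _log_init(self) -> tuple[float, float]:
        x, y = self.x, self.y
        if self.family == "power":
            lx, ly = np.log(x), np.log(y)
        else:  # exponential: y > 0 needed for the log-space init only
            pos = y > 0
            if pos.sum() < 3:
                raise FitError("exponential init needs positive responses")
            lx, ly = x[pos], np.log(y[pos])
        res = sm.OLS(ly, sm.add_constant(lx)).fit()
        return float(np.exp(res.params[0])), float(res.params[1])

    def _fstat(self, sse: float) -> tuple[float, float]:
        y = self.y
        sst = float(((y - y.mean()) ** 2).sum())
        n = y.size
        if sst <= 0:
            return 0.0, 1.0
        if sse <= 1e-14 * sst:
            return np.inf, 0.0
        f = ((sst - sse) / 1.0) / (sse / (n - 2))
        p = float(stats.f.sf(f, 1, n - 2))
        return float(f), p

    def fit(self) -> SuccessionFit:
        x, y = self.x, self.y
        if self.family == "linear":
            res = sm.OLS(y, sm.add_constant(x)).fit()
            a, b = (float(v) for v in res.params)
            pred = a + b * x
        else:
            a0, b0 = self._log_init()
            if self.fit_mode == "loglog":
                a, b = a0, b0
            else:
                func = ((lambda t, a, b: a * t ** b) if self.family == "power"
                        else (lambda t, a, b: a * np.exp(b * t)))
                try:
                    (a, b), _ = optimize.curve_fit(func, x, y, p0=(a0, b0),
                                                   maxfev=20000)
                except (RuntimeError, optimize.OptimizeWarning) as exc:
                    init = self._finish(a0, b0)
                    raise FitError(f"curve_fit failed: {exc}", init) from exc
            pred = (a * x ** b) if self.family == "power" else a * np.exp(b * x)
        sse = float(((y - pred) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        _, p = self._fstat(sse)
        return SuccessionFit(self.family, a, b, float(max(min(r2, 1.0), 0.0)),
                             p, x.size, self.n_dropped)

    def _finish(self, a: float, b: float) -> SuccessionFit:
        pred = (a * self.x ** b) if self.family == "power" \
            else a * np.exp(b * self.x)
        sse = float(((self.y - pred) ** 2).sum())
        sst = float(((self.y - self.y.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        _, p = self._fstat(sse)
        return SuccessionFit(self.family, a, b, max(min(r2, 1.0), 0.0), p,
                             self.x.size, self.n_dropped)


def fit_model(x, y, family: str, fit_mode: str = "nls") -> SuccessionFit:
    return SuccessionModel(y, x, family=family, fit_mode=fit_mode).fit()


@dataclass
class ModelSelection:
    """All family fits plus the winner (highest significant R^2)."""

    fits: dict[str, SuccessionFit]
    best: SuccessionFit | None       # None <=> no significant family ("ns")
    alpha: float

    @property
    def is_significant(self) -> bool:
        return self.best is not None

    @property
    def code(self) -> str:
        return self.best.code if self.best else "-"

    @property
    def r2(self) -> float | None:
        return self.best.r2 if self.best else None

    def table(self):
        import pandas as pd
        rows = [{"family": f.family, "code": f.code, "a": f.a, "b": f.b,
                 "r2": f.r2, "p": f.p_value, "selected": f is self.best}
                for f in self.fits.values()]
        return pd.DataFrame(rows)


def select_model(x, y, families=FAMILIES, alpha: float = 0.05,
                 fit_mode: str = "nls") -> ModelSelection:
    """Fit every applicable family and pick the best significant one.

    Families whose domain restrictions cannot be met (e.g. power with
    non-positive predictors) are skipped silently; a family whose nonlinear
    fit fails falls back to its log-space initialization fit.
    """
    fits: dict[str, SuccessionFit] = {}
    for fam in families:
        try:
            fits[fam] = fit_model(x, y, fam, fit_mode=fit_mode)
        except FitError as exc:
            if exc.init_fit is not None:
                fits[fam] = exc.init_fit
        except ValueError:
            continue
    significant = [f for f in fits.values() if f.p_value <= alpha]
    best = max(significant, key=lambda f: f.r2) if significant else None
    return ModelSelection(fits, best, alpha)
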