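"""Chapman–Richards regrowth model with a fixed asymptote.

The carbon of a regrowing stand of age ``t`` follows

    Y(t) = A · (1 − e^{−k t})^c,      A, k, c > 0

where ``A`` (Mg C ha⁻¹) is the carrying capacity — here fixed to the
bias-corrected median AGC of old-growth forest under the same
conditions — ``k`` (yr⁻¹) sets how fast the curve saturates and ``c``
shapes the early-age behaviour (c > 1 gives a sigmoidal start). Only
``k`` and ``c`` are estimated, by nonlinear least squares on the
bias-corrected median AGC per age of one group (driver category or
region × disturbance class).

The API follows the statsmodels convention: build a
:class:`ChapmanRichardsModel` from data, call :meth:`fit` and receive a
:class:`ChapmanRichardsResults` carrying estimates, standard errors,
confidence intervals, diagnostics and derived regrowth statistics
(mean accumulation rate over the first *n* years, time to reach a
fraction of the asymptote).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .attribution import AgeAGCTable

__all__ = [
    "chapman_richards",
    "ChapmanRichardsModel",
    "ChapmanRichardsResults",
    "TimeToFraction",
    "old_growth_asymptote",
]

#: default multi-start grid used when the initial fit fails to converge
RESTART_K = (0.01, 0.05, 0.1, 0.3)
RESTART_C = (0.5, 1.0, 2.0, 4.0)


def chapman_richards(t, A, k, c):
    """Evaluate Y(t) = A(1 − e^(−k t))^c (vectorised, Y(0) = 0 exactly)."""
    t = np.asarray(t, dtype=float)
    return A * np.power(-np.expm1(-k * t), c)


def old_growth_asymptote(
    agc_raster: np.ndarray,
    old_growth_mask: np.ndarray,
    group_mask: np.ndarray | None = None,
    bias_offset: float = 0.0,
) -> float:
    """Median old-growth AGC of a group minus the group's bias offset.

    The result is the fixed asymptote of that group's growth model, on
    the same bias-corrected scale as its age table.
    """
    mask = np.asarray(old_growth_mask, dtype=bool)
    if group_mask is not None:
        mask = mask & np.asarray(group_mask, dtype=bool)
    vals = np.asarray(agc_raster, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no old-growth pixels in group")
    return float(np.median(vals)) - bias_offset


@dataclass
class TimeToFraction:
    """Integer and closed-form time for Y(t) to reach ``fraction·A``."""

    fraction: float
    years: int | None
    exact: float
    reached: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.reached:
            return f"{self.years} yr (exact {self.exact:.2f})"
        return f"not reached (exact {self.exact:.2f} yr)"


class ChapmanRichardsModel:
    """Chapman–Richards curve with fixed asymptote, fitted to an age table.

    Parameters
    ----------
    age, agc
        Stand ages (years) and bias-corrected median AGC (Mg C ha⁻¹),
        one point per age. At least three distinct ages are required.
    asymptote
        Fixed carrying capacity A (> 0), typically from
        :func:`old_growth_asymptote`.
    group
        Optional label carried through to the results.
    """

    def __init__(self, age, agc, asymptote: float, group: str = ""):
        self.age = np.asarray(age, dtype=float)
        self.agc = np.asarray(agc, dtype=float)
        if self.age.shape != self.agc.shape or self.age.ndim != 1:
            raise ValueError("age and agc must be 1-D arrays of equal length")
        if np.unique(self.age).size < 3:
            raise ValueError("need at least three distinct ages to fit (k, c)")
        if asymptote <= 0:
            raise ValueError("asymptote must be positive")
        self.asymptote = float(asymptote)
        self.group = group

    @classmethod
    def from_age_table(cls, table: AgeAGCTable, asymptote: float) -> "ChapmanRichardsModel":
        return cls(table.ages, table.medians, asymptote, group=table.group)

    # -- internals ---------------------------------------------------------

    def _curve(self, t, k, c):
        return chapman_richards(t, self.asymptote, k, c)

    def _sse(self, k, c) -> float:
        r = self.agc - self._curve(self.age, k, c)
        return float(r @ r)

    def _try_fit(self, k0: float, c0: float):
        return optimize.curve_fit(
            self._curve,
            self.age,
            self.agc,
            p0=(k0, c0),
            bounds=((1e-8, 1e-8), (10.0, 50.0)),
            maxfev=20_000,
        )

    def fit(
        self,
        k0: float = 0.1,
        c0: float = 1.0,
        ci_method: str = "asymptotic",
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> "ChapmanRichardsResults":
        """Estimate (k, c) by bounded least squares with a restart grid.

        ``ci_method`` is ``"asymptotic"`` (t-intervals from the
        curvature of the objective) or ``"bootstrap"`` (residual
        resampling over age rows, ``n_boot`` refits, percentile
        intervals).
        """
        starts = [(k0, c0)] + [
            (k, c) for k in RESTART_K for c in RESTART_C if (k, c) != (k0, c0)
        ]
        best = None
        diagnostics: list[str] = []
        for ks, cs in starts:
            try:
                popt, pcov = self._try_fit(ks, cs)
            except (RuntimeError, ValueError) as exc:
                diagnostics.append(f"start ({ks}, {cs}): {exc}")
                continue
            sse = self._sse(*popt)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, popt, pcov)
            if best is not None and len(diagnostics) == 0:
                break  # first start converged; restarts only on failure
        if best is None:
            raise RuntimeError(
                "Chapman–Richards fit failed from every start: " + "; ".join(diagnostics)
            )
        sse, popt, pcov = best
        k_hat, c_hat = (float(popt[0]), float(popt[1]))

        n = self.age.size
        dof = max(n - 2, 1)
        residuals = self.agc - self._curve(self.age, k_hat, c_hat)
        residual_sd = float(np.sqrt(sse / dof))

        boot_params = None
        if ci_method == "bootstrap":
            boot_params = self._bootstrap(k_hat, c_hat, residuals, n_boot, seed)
        elif ci_method != "asymptotic":
            raise ValueError("ci_method must be 'asymptotic' or 'bootstrap'")

        return ChapmanRichardsResults(
            model=self,
            k=k_hat,
            c=c_hat,
            cov=np.asarray(pcov, dtype=float),
            residuals=residuals,
            residual_sd=residual_sd,
            dof=dof,
            boot_params=boot_params,
            diagnostics=diagnostics,
        )

    def _bootstrap(self, k_hat, c_hat, residuals, n_boot, seed):
        rng = np.random.default_rng(seed)
        fitted = self._curve(self.age, k_hat, c_hat)
        out = np.empty((n_boot, 2))
        out.fill(np.nan)
        for b in range(n_boot):
            y_star = fitted + rng.choice(residuals, size=residuals.size, replace=True)
            try:
                popt, _ = optimize.curve_fit(
                    self._curve,
                    self.age,
                    y_star,
                    p0=(k_hat, c_hat),
                    bounds=((1e-8, 1e-8), (10.0, 50.0)),
                    maxfev=5_000,
                )
                out[b] = popt
            except (RuntimeError, ValueError):
                continue
        return out[~np.isnan(out).any(axis=1)]


class ChapmanRichardsResults:
    """Fitted Chapman–Richards curve: estimates, uncertainty, predictions."""

    def __init__(self, model, k, c, cov, residuals, residual_sd, dof,
                 boot_params=None, diagnostics=()):
        self.model = model
        self.k = k
        self.c = c
        self.cov = cov
        self.residuals = residuals
        self.residual_sd = residual_sd
        self.dof = dof
        self.boot_params = boot_params
        self.diagnostics = list(diagnostics)

    # -- parameter summaries ----------------------------------------------

    @property
    def asymptote(self) -> float:
        return self.model.asymptote

    @property
    def group(self) -> str:
        return self.model.group

    @property
    def params(self) -> pd.Series:
        return pd.Series({"k": self.k, "c": self.c})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({"k": math.sqrt(self.cov[0, 0]), "c": math.sqrt(self.cov[1, 1])})

    @property
    def n_ages(self) -> int:
        return self.model.age.size

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """95% (by default) confidence intervals for k and c."""
        if self.boot_params is not None and len(self.boot_params) >= 10:
            lo = np.percentile(self.boot_params, 100 * alpha / 2, axis=0)
            hi = np.percentile(self.boot_params, 100 * (1 - alpha / 2), axis=0)
        else:
            tcrit = stats.t.ppf(1 - alpha / 2, self.dof)
            est = np.array([self.k, self.c])
            se = self.bse.to_numpy()
            lo, hi = est - tcrit * se, est + tcrit * se
        return pd.DataFrame({"lower": lo, "upper": hi}, index=["k", "c"])

    # -- predictions and regrowth statistics ------------------------------

    def predict(self, t):
        """Predicted bias-corrected AGC at age t (Mg C ha⁻¹)."""
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            raise ValueError("age must be non-negative")
        return chapman_richards(t, self.asymptote, self.k, self.c)

    def prediction_band(self, t, alpha: float = 0.05, n_draws: int = 500,
                        seed: int | None = None):
        """Pointwise CI of the curve via parameter draws (bootstrap if run,
        otherwise Gaussian draws from the asymptotic covariance)."""
        t = np.asarray(t, dtype=float)
        if self.boot_params is not None and len(self.boot_params) >= 10:
            draws = self.boot_params
        else:
            rng = np.random.default_rng(seed)
            draws = rng.multivariate_normal([self.k, self.c], self.cov, size=n_draws)
            draws = np.clip(draws, 1e-8, None)
        curves = np.stack([chapman_richards(t, self.asymptote, kk, cc) for kk, cc in draws])
        lo = np.percentile(curves, 100 * alpha / 2, axis=0)
        hi = np.percentile(curves, 100 * (1 - alpha / 2), axis=0)
        return lo, hi

    def mean_rate_first_n_years(self, n: int = 20) -> float:
        """Mean accumulation rate over the first n years, Y(n)/n (Mg C ha⁻¹ yr⁻¹)."""
        if n <= 0:
            raise ValueError("n must be ≥ 1")
        return float(self.predict(n)) / n

    def time_to_fraction(self, fraction: float = 0.9, max_years: int = 200) -> TimeToFraction:
        """Smallest integer age with Y(t) ≥ fraction·A, and the closed form.

        The curve never attains A exactly, so ``fraction`` must be < 1.
        Closed form: t* = −ln(1 − fraction^{1/c}) / k.
        """
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        exact = -math.log(1.0 - fraction ** (1.0 / self.c)) / self.k
        years = int(math.ceil(exact - 1e-9))
        if years <= max_years:
            return TimeToFraction(fraction, years, exact, True)
        return TimeToFraction(fraction, None, exact, False)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Chapman-Richards regrowth fit" + (f" [{self.group}]" if self.group else ""),
            "=" * 46,
            f"asymptote A (fixed)  {self.asymptote:10.3f}  Mg C/ha",
            f"n age rows           {self.n_ages:10d}",
            f"residual sd          {self.residual_sd:10.3f}  Mg C/ha",
            "-" * 46,
            "param      estimate        se     ci95_lo     ci95_hi",
        ]
        for p in ("k", "c"):
            lines.append(
                f"{p:>5} {self.params[p]:12.5f} {self.bse[p]:9.5f}"
                f" {ci.loc[p, 'lower']:11.5f} {ci.loc[p, 'upper']:11.5f}"
            )
        rate = self.mean_rate_first_n_years(20)
        ttf = self.time_to_fraction(0.9)
        lines += [
            "-" * 46,
            f"mean rate, first 20 yr  {rate:8.3f}  Mg C/ha/yr",
            f"time to 90% of A        {ttf}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "group": self.group,
            "A": self.asymptote,
            "k": self.k,
            "c": self.c,
            "k_se": float(self.bse["k"]),
            "c_se": float(self.bse["c"]),
            "k_ci95": [float(ci.loc["k", "lower"]), float(ci.loc["k", "upper"])],
            "c_ci95": [float(ci.loc["c", "lower"]), float(ci.loc["c", "upper"])],
            "residual_sd": self.residual_sd,
            "n_ages": int(self.n_ages),
        }
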