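"""Steady-state Michaelis–Menten kinetics.

Initial rates are extracted from product-formation timecourses by ordinary
least squares, then v₀ = k_cat·[E]·[S]/(K_M + [S]) is fitted by nonlinear
least squares, statsmodels-style: build a `MichaelisMenten` model from the
rate data and call :meth:`MichaelisMenten.fit` to obtain a
`MichaelisMentenResults` object carrying estimates, standard errors and a
``summary()`` table.

Units: substrate concentrations in μM, enzyme concentration in nM, rates in
μM/s, so K_M is reported in μM, k_cat in s⁻¹ and the catalytic efficiency
k_cat/K_M in M⁻¹ s⁻¹ (K_M converted to molar).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class InsufficientDataError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class InitialRate:
    concentration: float  # μM
    v0: float             # μM/s
    se: float             # μM/s


def _quadratic_aic_gain(t: np.ndarray, p: np.ndarray) -> float:
    """AIC improvement of a quadratic over a linear product-vs-time fit."""
    n = t.size
    lin = np.polyfit(t, p, 1)
    quad = np.polyfit(t, p, 2)
    rss1 = float(((p - np.polyval(lin, t)) ** 2).sum())
    rss2 = float(((p - np.polyval(quad, t)) ** 2).sum())
    if rss1 <= 0 or rss2 <= 0:
        return 0.0
    aic1 = n * math.log(rss1 / n) + 2 * 2
    aic2 = n * math.log(rss2 / n) + 2 * 3
    return aic1 - aic2


def initial_rates(timecourses: pd.DataFrame) -> list[InitialRate]:
    """Initial velocity per substrate concentration.

    ``timecourses`` needs columns ``concentration``, ``time`` and
    ``product``.  v₀ is the least-squares slope of product vs time with a
    fitted (not forced) intercept; ≥3 timepoints per concentration are
    required.  A warning fires when a quadratic term improves the fit by
    more than 10 AIC units (sign of substrate depletion).
    """
    rates, _ = _rates_with_pooled_errors(timecourses)
    return rates


def _rates_with_pooled_errors(timecourses: pd.DataFrame):
    """OLS initial rates plus slope SDs from the pooled relative noise.

    Assay noise is close to proportional to the measured product, so the
    relative residuals of all timecourses estimate one noise scale with
    Σ(nᵢ − 2) degrees of freedom — far steadier than the 1–2 residual
    degrees of freedom a single timecourse offers.  Slope variances follow
    exactly from the OLS weights with per-point sd = ε̂·|v₀|·t.
    """
    rates: list[InitialRate] = []
    pooled_num, pooled_dof = 0.0, 0
    groups = []
    for conc, grp in timecourses.groupby("concentration", sort=True):
        t = grp["time"].to_numpy(dtype=float)
        p = grp["product"].to_numpy(dtype=float)
        if t.size < 3:
            raise InsufficientDataError(
                f"concentration {conc}: need ≥3 timepoints, got {t.size}"
            )
        fit = stats.linregress(t, p)
        if t.size >= 4 and _quadratic_aic_gain(t, p) > 10:
            warnings.warn(
                f"timecourse at [S]={conc} is visibly nonlinear "
                "(possible product depletion)"
            )
        resid = p - (fit.slope * t + fit.intercept)
        pred = np.abs(fit.slope) * t
        ok = pred > 0
        pooled_num += float(((resid[ok] / pred[ok]) ** 2).sum())
        pooled_dof += t.size - 2
        groups.append((float(conc), t, float(fit.slope)))
    eps2 = pooled_num / pooled_dof if pooled_dof > 0 else 0.0
    for conc, t, slope in groups:
        w = (t - t.mean()) / ((t - t.mean()) ** 2).sum()
        var_slope = float((w**2 * (slope * t) ** 2).sum()) * eps2
        rates.append(InitialRate(conc, slope, math.sqrt(var_slope)))
    return rates, eps2


@dataclass
class MichaelisMentenResults:
    """Fitted kinetic parameters with uncertainties.

    ``efficiency`` is k_cat/K_M in M⁻¹ s⁻¹ with its standard error
    propagated from the fit covariance (including the k_cat–K_M
    covariance term).
    """

    K_M: float              # μM
    K_M_se: float
    k_cat: float            # s⁻¹
    k_cat_se: float
    efficiency: float       # M⁻¹ s⁻¹
    efficiency_se: float
    enzyme_conc: float      # nM
    n_concentrations: int
    covariance: np.ndarray  # 2×2, order (k_cat, K_M)
    unreliable: bool = False

    @property
    def params(self) -> pd.Series:
        return pd.Series({"k_cat": self.k_cat, "K_M": self.K_M})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({"k_cat": self.k_cat_se, "K_M": self.K_M_se})

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit",
            "=" * 44,
            f"{'K_M':<14}{self.K_M:>10.4g} ± {self.K_M_se:<10.2g} uM",
            f"{'k_cat':<14}{self.k_cat:>10.4g} ± {self.k_cat_se:<10.2g} 1/s",
            f"{'k_cat/K_M':<14}{self.efficiency:>10.4g} ± "
            f"{self.efficiency_se:<10.2g} 1/(M s)",
            f"{'[E]':<14}{self.enzyme_conc:>10.4g} nM",
            f"{'n([S])':<14}{self.n_concentrations:>10d}",
        ]
        if self.unreliable:
            lines.append("warning: K_M poorly identified by the sampled [S]")
        return "\n".join(lines)


class MichaelisMenten:
    """Michaelis–Menten model of initial rates at known enzyme concentration.

    Parameters
    ----------
    rates : list of `InitialRate` or (concentration, v0) pairs
        Substrate concentrations in μM and initial velocities in μM/s.
    enzyme_conc : float
        Enzyme concentration in nM.

    Examples
    --------
    >>> model = MichaelisMenten([(5, 0.0031), (15, 0.0065), (30, 0.0099),
    ...                          (90, 0.0153), (280, 0.0183)], enzyme_conc=100)
    >>> results = model.fit()
    >>> round(results.K_M, 1)  # doctest: +SKIP
    28.0
    """

    def __init__(self, rates, enzyme_conc: float, sigma=None):
        conc, v0, se = [], [], []
        for item in rates:
            if isinstance(item, InitialRate):
                conc.append(item.concentration)
                v0.append(item.v0)
                se.append(item.se)
            else:
                conc.append(float(item[0]))
                v0.append(float(item[1]))
                se.append(0.0)
        self.conc = np.asarray(conc, dtype=float)
        self.v0 = np.asarray(v0, dtype=float)
        if sigma is not None:
            self.sigma = np.asarray(sigma, dtype=float)
        else:
            self.sigma = np.asarray(se, dtype=float)
        self.enzyme_conc = float(enzyme_conc)
        if np.unique(self.conc).size < 5:
            raise InsufficientDataError(
                "need ≥5 distinct substrate concentrations"
            )
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")

    @classmethod
    def from_timecourses(
        cls, timecourses: pd.DataFrame, enzyme_conc: float
    ) -> "MichaelisMenten":
        return cls(initial_rates(timecourses), enzyme_conc)

    def predict(self, k_cat: float, K_M: float, conc=None) -> np.ndarray:
        s = self.conc if conc is None else np.asarray(conc, dtype=float)
        e_um = self.enzyme_conc * 1e-3  # nM → μM
        return k_cat * e_um * s / (K_M + s)

    def fit(self) -> MichaelisMentenResults:
        """Weighted nonlinear least squares.

        Starting values: K_M₀ = median [S], k_cat₀ = max v₀/[E].  When the
        rates carry standard errors (e.g. built via `from_timecourses`,
        which pools the timecourse residuals), the fit uses them as known
        absolute sigmas, so parameter covariances reflect the measured
        noise; otherwise rates are weighted by their magnitude (relative
        noise) with the scale estimated from the fit residuals.
        """
        e_um = self.enzyme_conc * 1e-3
        p0 = [max(self.v0.max(), 1e-12) / e_um, float(np.median(self.conc))]
        if np.all(self.sigma > 0):
            sigma, absolute = self.sigma, True
        else:
            sigma = np.maximum(np.abs(self.v0), 1e-12 * max(self.v0.max(), 1e-12))
            sigma, absolute = sigma, False
        try:
            popt, pcov = optimize.curve_fit(
                lambda s, kcat, km: kcat * e_um * s / (km + s),
                self.conc,
                self.v0,
                p0=p0,
                sigma=sigma,
                absolute_sigma=absolute,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            raise FitError(f"Michaelis-Menten fit failed: {exc}") from exc
        k_cat, K_M = float(popt[0]), float(popt[1])
        if k_cat <= 0 or K_M <= 0:
            raise FitError("non-positive kinetic parameters")
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        k_se, km_se = float(se[0]), float(se[1])
        efficiency = k_cat / (K_M * 1e-6)
        rel_var = (
            (k_se / k_cat) ** 2
            + (km_se / K_M) ** 2
            - 2.0 * float(pcov[0, 1]) / (k_cat * K_M)
        )
        eff_se = efficiency * math.sqrt(max(rel_var, 0.0))
        unreliable = bool(
            not math.isfinite(km_se)
            or (K_M > 0 and km_se / K_M > 1.0)
            or K_M < self.conc.min() / 10.0
            or K_M > self.conc.max() * 10.0
        )
        return MichaelisMentenResults(
            K_M=K_M,
            K_M_se=km_se,
            k_cat=k_cat,
            k_cat_se=k_se,
            efficiency=efficiency,
            efficiency_se=eff_se,
            enzyme_conc=self.enzyme_conc,
            n_concentrations=int(np.unique(self.conc).size),
            covariance=pcov,
            unreliable=unreliable,
        )


def fit_michaelis_menten(rates, enzyme_conc: float) -> MichaelisMentenResults:
    """Convenience wrapper: build the model and fit in one call."""
    return MichaelisMenten(rates, enzyme_conc).fit()
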