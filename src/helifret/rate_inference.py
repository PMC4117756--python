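"""Kinetic quantities from dwell tables.

Each substep dwell is modeled as exponential with a single rate, so the
maximum-likelihood rate is the reciprocal mean of the uncensored dwells
and its standard error follows from the delta method, ``rate / sqrt(n)``
(a seeded bootstrap is available as a cross-check).  Dwells truncated by
dissociation, strand separation, photobleaching or the end of the
recording are censored and excluded from the default estimate; their
count is reported.

Higher-level fits:

* association constant: zero-intercept (weighted) least squares of the
  binding rate against protein concentration -- the binding rate must
  vanish at zero protein, so the intercept is fixed unless the free
  intercept is requested for diagnostics;
* ATP dependence of unwinding: Michaelis-Menten
  ``v = Vmax [ATP] / (Km + [ATP])`` by nonlinear least squares;
* equilibrium binding: fluorescence-polarization isotherm
  ``P(c) = P0 + (Pmax - P0) c / (Kd + c)``;
* temperature effect: per-substep rate ratios with propagated errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import OptimizeWarning, curve_fit

from .substep_segmentation import DwellTable


@dataclass
class RateEstimate:
    substep: str
    rate: float          # s^-1
    sem: float
    n: int               # uncensored dwells used
    n_censored: int = 0
    condition: str = ""


def estimate_rate(
    dwells,
    censored=None,
    substep: str = "",
    condition: str = "",
    n_boot: int = 0,
    seed: int | None = None,
) -> RateEstimate:
    """Exponential MLE rate = 1 / mean(uncensored dwells), with SEM.

    ``n_boot > 0`` replaces the delta-method SEM by the standard
    deviation of ``n_boot`` bootstrap resamples (seeded).
    """
    dwells = np.asarray(dwells, dtype=float)
    if censored is None:
        censored = np.zeros(dwells.shape, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    keep = dwells[~censored]
    if keep.size == 0:
        raise ValueError(f"no uncensored dwells for substep {substep!r}")
    if np.any(keep <= 0):
        raise ValueError("dwell times must be positive")
    rate = 1.0 / keep.mean()
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = 1.0 / rng.choice(keep, size=(n_boot, keep.size), replace=True).mean(axis=1)
        sem = float(boots.std(ddof=1))
    else:
        sem = rate / np.sqrt(keep.size)
    return RateEstimate(substep, float(rate), float(sem), int(keep.size),
                        int(censored.sum()), condition)


def estimate_off_rate(
    total_bound_times, censored=None, condition: str = "", **kw
) -> RateEstimate:
    """Off rate = 1 / mean total bound time (uncensored events only)."""
    est = estimate_rate(total_bound_times, censored, substep="off",
                        condition=condition, **kw)
    return est


def rates_from_dwell_table(table: DwellTable, n_boot: int = 0, seed=None) -> pd.DataFrame:
    """Per-condition, per-substep rate table (tidy)."""
    rows = []
    for (cond, sub), grp in table.dwells.groupby(["condition", "substep"], sort=True):
        try:
            est = estimate_rate(
                grp["dwell_s"].to_numpy(), grp["censored"].to_numpy(),
                substep=sub, condition=cond, n_boot=n_boot, seed=seed,
            )
        except ValueError:
            continue  # substeps with only censored dwells are unreportable
        rows.append((cond, sub, est.rate, est.sem, est.n, est.n_censored))
    for cond, grp in table.events.groupby("condition", sort=True):
        keep = grp.loc[~grp["bound_censored"], "total_bound_s"].to_numpy()
        if keep.size:
            est = estimate_rate(keep, substep="off", condition=cond,
                                n_boot=n_boot, seed=seed)
            rows.append((cond, "off", est.rate, est.sem, est.n,
                         int(grp["bound_censored"].sum())))
    return pd.DataFrame(
        rows, columns=["condition", "substep", "rate", "sem", "n", "n_censored"]
    )


@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n: int


def fit_association_constant(
    concentrations, rates, errors=None, fit_intercept: bool = False
) -> LinearFit:
    """Slope of binding rate vs protein concentration (k_on, M^-1 s^-1).

    Weighted least squares with weights 1/error^2 when per-point errors
    are given.  The intercept is fixed at zero by default.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(rates, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    if np.any(y < 0):
        raise ValueError("rates must be >= 0")
    w = None
    if errors is not None:
        errors = np.asarray(errors, dtype=float)
        if np.any(errors <= 0):
            raise ValueError("errors must be > 0 when supplied")
        w = 1.0 / errors**2
    exog = sm.add_constant(c) if fit_intercept else c[:, None]
    model = sm.WLS(y, exog, weights=w if w is not None else 1.0)
    res = model.fit()
    # with known per-point errors the parameter covariance is fixed by
    # those errors; do not rescale by the (few-dof) residual variance
    bse = res.bse / np.sqrt(res.scale) if w is not None and res.scale > 0 else res.bse
    if fit_intercept:
        icpt, slope = res.params
        icpt_se, slope_se = bse
    else:
        slope, slope_se = res.params[0], bse[0]
        icpt, icpt_se = 0.0, 0.0
    with np.errstate(invalid="ignore"):  # R^2 undefined for all-zero rates
        rsq = float(res.rsquared)
    return LinearFit(float(slope), float(icpt), float(slope_se), float(icpt_se),
                     rsq, c.size)


@dataclass
class MMFit:
    vmax: float          # s^-1
    km: float            # M
    vmax_se: float
    km_se: float
    converged: bool
    n: int


def fit_michaelis_menten(atp_concs, unwinding_rates, errors=None) -> MMFit:
    """Nonlinear least squares of v = Vmax * x / (Km + x).

    Initial guesses: Vmax = max rate, Km = concentration nearest
    half-maximal rate.  A failed fit is returned flagged (NaN estimates,
    ``converged=False``), never silently.
    """
    x = np.asarray(atp_concs, dtype=float)
    y = np.asarray(unwinding_rates, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct ATP concentrations")
    vmax0 = float(y.max())
    km0 = float(x[np.argmin(np.abs(y - vmax0 / 2.0))])
    km0 = km0 if km0 > 0 else float(np.median(x))

    def mm(x_, vmax, km):
        return vmax * x_ / (km + x_)

    try:
        popt, pcov = curve_fit(
            mm, x, y, p0=[vmax0, km0], sigma=errors,
            absolute_sigma=errors is not None, maxfev=10000,
        )
        se = np.sqrt(np.diag(pcov))
        ok = bool(np.all(np.isfinite(popt)) and popt[0] > 0 and popt[1] > 0)
        return MMFit(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]),
                     ok, x.size)
    except RuntimeError:
        return MMFit(float("nan"), float("nan"), float("nan"), float("nan"),
                     False, x.size)


def fold_change(rates_reference, rates_test) -> pd.DataFrame:
    """Per-substep rate ratios test/reference with propagated SE and 95% CI.

    Inputs are sequences of :class:`RateEstimate`; substep labels must
    match one-to-one.
    """
    ref = {r.substep: r for r in rates_reference}
    test = {r.substep: r for r in rates_test}
    if set(ref) != set(test):
        raise ValueError(
            f"substep labels differ: {sorted(ref)} vs {sorted(test)}"
        )
    rows = []
    for sub in ref:
        r0, r1 = ref[sub], test[sub]
        ratio = r1.rate / r0.rate
        se = ratio * np.hypot(r1.sem / r1.rate, r0.sem / r0.rate)
        rows.append((sub, ratio, se, ratio - 1.96 * se, ratio + 1.96 * se))
    return pd.DataFrame(
        rows, columns=["substep", "ratio", "se", "ci_low", "ci_high"]
    ).sort_values("substep", ignore_index=True)


@dataclass
class IsothermFit:
    kd: float            # M
    p_floor: float       # polarization of free RNA
    p_ceiling: float     # polarization at saturation
    kd_se: float
    converged: bool
    identifiable: bool   # False when the data do not constrain Kd
    n: int


def fit_binding_isotherm(protein_concs, polarizations, errors=None) -> IsothermFit:
    """Kd from a fluorescence-polarization binding curve.

    Fits ``P(c) = P0 + (Pmax - P0) * c / (Kd + c)``.  A flat curve (no
    binding signal) leaves Kd unconstrained; this is reported via
    ``identifiable=False`` rather than a spurious number.
    """
    c = np.asarray(protein_concs, dtype=float)
    p = np.asarray(polarizations, dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct protein concentrations")

    def iso(c_, p0, pmax, kd):
        return p0 + (pmax - p0) * c_ / (kd + c_)

    span = float(p.max() - p.min())
    kd0 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    try:
        with warnings.catch_warnings():
            # a flat curve cannot constrain the covariance; that outcome
            # is reported through the identifiability flag
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(
                iso, c, p, p0=[p.min(), p.max(), kd0], sigma=errors,
                absolute_sigma=errors is not None, maxfev=20000,
            )
        p0, pmax, kd = popt
        kd_se = float(np.sqrt(pcov[2, 2]))
        converged = bool(np.all(np.isfinite(popt)))
        identifiable = (
            converged and kd > 0 and np.isfinite(kd_se)
            and kd_se < 5.0 * abs(kd) and abs(pmax - p0) > 1e-12
            and span > 0
        )
        return IsothermFit(float(kd), float(p0), float(pmax), kd_se,
                           converged, identifiable, c.size)
    except RuntimeError:
        return IsothermFit(float("nan"), float("nan"), float("nan"), float("nan"),
                           False, False, c.size)


def rate_vs_covariate_slope(covariate, rates, errors=None) -> LinearFit:
    """Free-intercept (weighted) regression of a rate on a covariate.

    Used for invariance checks: a slope whose confidence interval covers
    zero means the covariate does not modulate that substep.
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(rates, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct covariate values")
    w = 1.0 / np.asarray(errors, dtype=float) ** 2 if errors is not None else None
    res = sm.WLS(y, sm.add_constant(x), weights=w if w is not None else 1.0).fit()
    bse = res.bse / np.sqrt(res.scale) if w is not None and res.scale > 0 else res.bse
    return LinearFit(float(res.params[1]), float(res.params[0]),
                     float(bse[1]), float(bse[0]),
                     float(res.rsquared), x.size)
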