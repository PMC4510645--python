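"""Enzyme kinetics: substrate-inhibition Michaelis-Menten, progress curves, IC50.

Three fitted models:

* initial-rate data, uncompetitive substrate inhibition
  ``v = Vmax * S / (KM + S * (1 + S / Ki))`` (reduces to plain
  Michaelis-Menten as ``Ki -> inf``); ``kcat = Vmax / [E]``;
* progress curves under the integrated first-order rate law
  ``ln([S0]/[St]) = k * t`` with ``k = kcat/KM * [E]``, fitted by linear
  regression through the origin over at least 50% substrate conversion;
* log-logistic inhibition, ``y = 100 / (1 + 10**(log10[I] - logIC50))``
  (Hill slope fixed at -1; normalized percent activity).

Units are carried explicitly: substrate in mM, rates in uM/min, time in
minutes, enzyme concentration in the unit named by the caller.  Standard
errors come from the local curvature of the least-squares objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

ENZYME_UNIT_TO_MM = {"M": 1e3, "mM": 1.0, "uM": 1e-3, "µM": 1e-3,
                     "nM": 1e-6, "pM": 1e-9}


class KineticsError(ValueError):
    pass


@dataclass
class RateDataset:
    """Initial-rate measurements: substrate (mM) vs rate (uM/min)."""

    substrate_conc: np.ndarray
    rate: np.ndarray
    enzyme_conc: float | None = None
    enzyme_conc_unit: str = "nM"

    def __post_init__(self):
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_conc.shape != self.rate.shape:
            raise KineticsError("substrate and rate vectors differ in length")
        if len(self.substrate_conc) < 4:
            raise KineticsError("need >= 4 points for a 3-parameter fit")
        if (self.substrate_conc < 0).any():
            raise KineticsError("negative substrate concentration")
        if self.enzyme_conc is not None and self.enzyme_conc_unit not in ENZYME_UNIT_TO_MM:
            raise KineticsError(f"unknown enzyme unit {self.enzyme_conc_unit!r}")


@dataclass
class ProgressCurve:
    """Substrate remaining (mM) over time (min) for one reaction."""

    time: np.ndarray
    substrate_remaining: np.ndarray
    S0: float | None = None
    enzyme_conc: float | None = None
    enzyme_conc_unit: str = "nM"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.substrate_remaining = np.asarray(self.substrate_remaining, dtype=float)
        if self.time.shape != self.substrate_remaining.shape:
            raise KineticsError("time and substrate vectors differ in length")
        if self.S0 is None:
            self.S0 = float(self.substrate_remaining[self.time.argmin()])
        if self.S0 <= 0:
            raise KineticsError("S0 must be positive")


@dataclass
class SubstrateInhibitionFit:
    vmax: float            # uM/min
    km: float              # mM
    ki: float              # mM (inf for the plain Michaelis-Menten variant)
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    kcat: float | None = None            # 1/min
    kcat_over_km: float | None = None    # 1/(min mM)
    kcat_over_km_se: float | None = None
    aicc: float | None = None
    model: str = "substrate_inhibition"

    @property
    def optimum_substrate(self) -> float:
        """Substrate concentration maximising the rate, sqrt(KM * Ki)."""
        return math.sqrt(self.km * self.ki)

    def predict(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return substrate_inhibition_rate(S, self.vmax, self.km, self.ki)


@dataclass
class IC50Fit:
    log_ic50: float          # log10 of IC50 in the input concentration unit
    log_ic50_se: float
    converged: bool = True

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50


def substrate_inhibition_rate(S, vmax, km, ki):
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S * (1.0 + S / ki))


def michaelis_menten_rate(S, vmax, km):
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S)


def _aicc(resid: np.ndarray, n_params: int) -> float:
    n = len(resid)
    rss = float(np.sum(resid ** 2))
    if rss <= 0:
        rss = np.finfo(float).tiny
    aic = n * math.log(rss / n) + 2 * n_params
    denom = n - n_params - 1
    return aic + (2 * n_params * (n_params + 1) / denom if denom > 0 else math.inf)


def _kcat_from_vmax(vmax_uM_min: float, enzyme_conc: float, unit: str) -> float:
    # kcat [1/min] = Vmax [uM/min] / [E] [uM]
    e_mM = enzyme_conc * ENZYME_UNIT_TO_MM[unit]
    e_uM = e_mM * 1e3
    if e_uM <= 0:
        raise KineticsError("enzyme concentration must be positive")
    return vmax_uM_min / e_uM


def fit_substrate_inhibition(
    data: RateDataset,
    with_inhibition: bool = True,
    weighting: str = "none",
) -> SubstrateInhibitionFit:
    """Least-squares fit of the substrate-inhibition rate law.

    Starting values follow robust rules for unimodal rate data: Vmax0 is
    1.2x the largest observed rate, KM0 the substrate at half-max on the
    ascending limb, Ki0 the largest substrate tested.  Parameters are
    bounded at zero; ``with_inhibition=False`` fits plain Michaelis-Menten
    (Ki fixed at infinity).  ``weighting="relative"`` minimises relative
    residuals (the 1/Y^2 weighting used for constant-CV measurement error);
    the default is ordinary (unweighted) least squares.  When the enzyme
    concentration is supplied, kcat and kcat/KM are derived with unit
    conversion.
    """
    if weighting not in ("none", "relative"):
        raise KineticsError(f"unknown weighting {weighting!r}")
    S, v = data.substrate_conc, data.rate
    sigma = np.maximum(np.abs(v), 1e-12) if weighting == "relative" else None
    vmax0 = float(v.max()) * 1.2
    if vmax0 <= 0:
        raise KineticsError("all rates are non-positive")
    imax = int(v.argmax())
    asc = S <= S[imax]
    half = np.abs(v[asc] - v.max() / 2.0)
    km0 = float(S[asc][half.argmin()]) or float(np.median(S[S > 0]))
    ki0 = float(S.max())

    converged = True
    if with_inhibition:
        try:
            popt, pcov = curve_fit(substrate_inhibition_rate, S, v,
                                   p0=[vmax0, km0, ki0], sigma=sigma,
                                   bounds=(0, np.inf), maxfev=20000)
        except RuntimeError:
            popt, pcov = [vmax0, km0, ki0], np.full((3, 3), np.nan)
            converged = False
        vmax, km, ki = map(float, popt)
        perr = np.sqrt(np.diag(pcov))
        se = {"vmax": float(perr[0]), "km": float(perr[1]), "ki": float(perr[2])}
        resid = v - substrate_inhibition_rate(S, *popt)
        n_params = 3
        model = "substrate_inhibition"
    else:
        try:
            popt, pcov = curve_fit(michaelis_menten_rate, S, v, p0=[vmax0, km0],
                                   sigma=sigma, bounds=(0, np.inf), maxfev=20000)
        except RuntimeError:
            popt, pcov = [vmax0, km0], np.full((2, 2), np.nan)
            converged = False
        vmax, km, ki = float(popt[0]), float(popt[1]), math.inf
        perr = np.sqrt(np.diag(pcov))
        se = {"vmax": float(perr[0]), "km": float(perr[1]), "ki": math.nan}
        resid = v - michaelis_menten_rate(S, *popt)
        n_params = 2
        model = "michaelis_menten"
    if min(vmax, km) <= 0 or (with_inhibition and ki <= 0):
        converged = False

    fit = SubstrateInhibitionFit(vmax=vmax, km=km, ki=ki, se=se, converged=converged,
                                 aicc=_aicc(resid, n_params), model=model)
    if data.enzyme_conc is not None:
        fit.kcat = _kcat_from_vmax(vmax, data.enzyme_conc, data.enzyme_conc_unit)
        eff, eff_se = derive_catalytic_efficiency(
            fit.kcat, km,
            se_kcat=(se["vmax"] / vmax * fit.kcat if np.isfinite(se["vmax"]) else None),
            se_km=se["km"] if np.isfinite(se["km"]) else None)
        fit.kcat_over_km = eff
        fit.kcat_over_km_se = eff_se
    return fit


def fit_michaelis_menten(data: RateDataset) -> SubstrateInhibitionFit:
    """Plain Michaelis-Menten fit (the Ki -> infinity limiting case)."""
    return fit_substrate_inhibition(data, with_inhibition=False)


def derive_catalytic_efficiency(
    kcat: float,
    km: float,
    se_kcat: float | None = None,
    se_km: float | None = None,
) -> tuple[float, float | None]:
    """kcat/KM with a delta-method standard error.

    The relative error is ``sqrt((se_kcat/kcat)**2 + (se_km/KM)**2)``.
    """
    if km == 0:
        raise KineticsError("KM is zero; catalytic efficiency undefined")
    eff = kcat / km
    if se_kcat is None or se_km is None:
        return eff, None
    rel = math.sqrt((se_kcat / kcat) ** 2 + (se_km / km) ** 2)
    return eff, abs(eff) * rel


def fit_integrated_rate(curve: ProgressCurve, min_conversion: float = 0.5) -> dict:
    """First-order rate constant from a progress curve.

    Regresses ``ln(S0/St)`` on ``t`` through the origin; ``k`` is the slope
    and ``kcat/KM = k / [E]``.  The curve must cover at least
    ``min_conversion`` of the substrate (the standard protocol tracks >50%
    of the reaction), and every ``St`` must be positive.
    """
    t = curve.time
    St = curve.substrate_remaining
    if (St <= 0).any():
        raise KineticsError("non-positive substrate concentration in progress curve")
    conversion = 1.0 - St.min() / curve.S0
    if conversion < min_conversion - 1e-12:
        raise KineticsError(
            f"progress curve covers only {100 * conversion:.1f}% conversion; "
            f">= {100 * min_conversion:.0f}% required")
    y = np.log(curve.S0 / St)
    denom = float(np.sum(t ** 2))
    if denom == 0:
        raise KineticsError("all time points are zero")
    k = float(np.sum(t * y) / denom)
    yhat = k * t
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    out = {"k": k, "r_squared": r2, "kcat_over_km": None}
    if curve.enzyme_conc is not None:
        e_mM = curve.enzyme_conc * ENZYME_UNIT_TO_MM[curve.enzyme_conc_unit]
        out["kcat_over_km"] = k / e_mM  # 1/(min mM)
    return out


def fit_ic50(
    inhibitor_conc,
    pct_activity,
    fit_slope: bool = False,
) -> IC50Fit:
    """Log-logistic IC50 fit on normalized percent activity.

    Model ``y = 100 / (1 + 10**((log10[I] - logIC50) * (-slope)))`` with the
    Hill slope fixed at -1 unless ``fit_slope=True``.  Points at [I] = 0
    anchor the normalisation and are excluded from the log-scale fit.  When
    the data show no transition (all activities near 100% or near 0%) the
    fit is flagged non-converged.
    """
    I = np.asarray(inhibitor_conc, dtype=float)
    y = np.asarray(pct_activity, dtype=float)
    if I.shape != y.shape:
        raise KineticsError("inhibitor and activity vectors differ in length")
    pos = I > 0
    if pos.sum() < (3 if fit_slope else 2):
        raise KineticsError("need inhibitor concentrations above zero to fit an IC50")
    logI = np.log10(I[pos])
    yy = y[pos]
    no_transition = yy.min() > 80.0 or yy.max() < 20.0

    def model_fixed(x, logic50):
        return 100.0 / (1.0 + 10.0 ** (x - logic50))

    def model_slope(x, logic50, hill):
        return 100.0 / (1.0 + 10.0 ** ((x - logic50) * -hill))

    # start at the concentration closest to half-activity
    x0 = float(logI[np.abs(yy - 50.0).argmin()])
    converged = True
    try:
        if fit_slope:
            popt, pcov = curve_fit(model_slope, logI, yy, p0=[x0, -1.0], maxfev=20000)
        else:
            popt, pcov = curve_fit(model_fixed, logI, yy, p0=[x0], maxfev=20000)
        log_ic50 = float(popt[0])
        se = float(np.sqrt(pcov[0, 0]))
    except RuntimeError:
        log_ic50, se = x0, math.nan
        converged = False
    if no_transition or not np.isfinite(se):
        converged = False
    return IC50Fit(log_ic50=log_ic50, log_ic50_se=se, converged=converged)
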