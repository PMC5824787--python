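"""Initial rates from HPLC peak areas and Michaelis–Menten parameter fitting.

Rates: with equal detector response for substrate and product peaks, the
converted fraction is f = product / (product + substrate) and the initial
rate v = f * [S]_total / t; f above ~0.3 is flagged as leaving the
initial-rate regime.

Fitting: nonlinear least squares of v = Vmax [S] / (KM + [S]) with
positivity enforced by fitting (log Vmax, log KM); standard errors come
from the Jacobian at the optimum (delta method back to the natural scale).
Derived quantities are the turnover number kcat = Vmax / E0 and the
catalytic efficiency kcat / KM reported in s^-1 M^-1 (KM in µM is converted
to M).  Enzyme concentration defaults to 0.3 µM, the assay concentration
the comparative table assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


def rate_from_peaks(product_area: float, substrate_area: float,
                    total_substrate_uM: float, time_s: float,
                    response_factor: float = 1.0) -> float:
    """Initial rate (µM/s) from product and substrate peak areas.

    response_factor scales the product area relative to substrate before
    forming the converted fraction (1 = equal detector response).
    """
    if product_area < 0 or substrate_area < 0:
        raise ValueError("peak areas must be >= 0")
    if product_area == 0 and substrate_area == 0:
        raise ValueError("both peak areas are zero")
    if time_s <= 0:
        raise ValueError("reaction time must be > 0")
    prod = product_area / response_factor
    f = prod / (prod + substrate_area)
    if f > 0.3:
        warnings.warn(f"converted fraction {f:.2f} > 0.30: "
                      "outside initial-rate regime")
    return f * total_substrate_uM / time_s


@dataclass
class KineticFit:
    """Fitted Michaelis–Menten parameters with derived quantities."""

    vmax_uM_per_s: float
    vmax_se: float
    km_uM: float
    km_se: float
    e0_uM: float
    n_points: int
    converged: bool
    rss: float

    @property
    def kcat_per_s(self) -> float:
        return self.vmax_uM_per_s / self.e0_uM

    @property
    def kcat_se(self) -> float:
        return self.vmax_se / self.e0_uM

    @property
    def efficiency_per_s_per_M(self) -> float:
        return self.kcat_per_s / (self.km_uM * 1e-6)

    def predict(self, s):
        s = np.asarray(s, float)
        return self.vmax_uM_per_s * s / (self.km_uM + s)


def fit_mm(substrate_uM, rates_uM_per_s, e0_uM: float = 0.3) -> KineticFit:
    """Fit v = Vmax [S] / (KM + [S]) to initial-rate data.

    Start values: Vmax0 = max(v); KM0 = the [S] whose rate is nearest
    Vmax0/2.  A small grid of KM restarts guards against local minima.
    """
    s = np.asarray(substrate_uM, float)
    v = np.asarray(rates_uM_per_s, float)
    if s.size != v.size:
        raise ValueError("substrate and rate arrays differ in length")
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be > 0")
    if np.any(v < 0):
        raise ValueError("rates must be >= 0")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all rates are zero; nothing to fit")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])

    def resid(theta):
        vmax, km = np.exp(theta)
        return vmax * s / (km + s) - v

    best = None
    for km_factor in (1.0, 0.3, 3.0, 10.0):
        x0 = np.log([vmax0, max(km0 * km_factor, 1e-6)])
        try:
            res = least_squares(resid, x0, method="lm", xtol=1e-14,
                                ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None or not best.success:
        raise RuntimeError("Michaelis-Menten fit failed to converge "
                           f"(start Vmax={vmax0}, KM={km0})")
    vmax, km = np.exp(best.x)
    if km > 10 * s.max():
        warnings.warn(f"KM ({km:.3g} µM) above 10x the largest [S]: "
                      "KM poorly constrained")
    # covariance of the log-parameters from the Jacobian; delta method
    n, p = s.size, 2
    rss = float(2 * best.cost)
    dof = max(n - p, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov_log = np.linalg.inv(jtj) * (rss / dof)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
    except np.linalg.LinAlgError:
        se_log = np.array([np.nan, np.nan])
    vmax_se = vmax * se_log[0]
    km_se = km * se_log[1]
    return KineticFit(float(vmax), float(vmax_se), float(km), float(km_se),
                      float(e0_uM), int(n), True, rss)


def fit_cofactor_km(nad_uM, rates_uM_per_s, e0_uM: float = 0.3) -> KineticFit:
    """KM for the NAD+ cofactor at saturating peptide: same engine as fit_mm
    with [NAD+] as the varied substrate."""
    return fit_mm(nad_uM, rates_uM_per_s, e0_uM)


def efficiency_consistency(kcat_per_s: float, km_uM: float,
                           reported_efficiency: float,
                           rel_tol: float = 0.05) -> bool:
    """Whether a reported kcat/KM agrees with the quoted kcat and KM.

    Published tables occasionally carry efficiency cells that do not match
    their own kcat and KM at rounding precision; this flags them.
    """
    derived = kcat_per_s / (km_uM * 1e-6)
    return abs(derived - reported_efficiency) <= rel_tol * derived


def comparative_table(fits: dict, wt_key: str) -> pd.DataFrame:
    """Percent-of-WT comparison across variants, per peptide substrate.

    fits: {(variant, peptide): KineticFit}; wt_key names the wild-type
    variant, which must be fitted for every peptide present.  Percent
    columns are 100 x variant / WT on the same peptide.  The formatted
    columns follow report conventions (kcat 4 decimals, KM 2, efficiency
    and percentages to integers); raw floats are retained.
    """
    peptides = {pep for (_, pep) in fits}
    for pep in peptides:
        if (wt_key, pep) not in fits:
            raise ValueError(f"missing WT fit for peptide {pep!r}")
    rows = []
    for (variant, pep), fit in fits.items():
        wt = fits[(wt_key, pep)]
        rows.append({
            "variant": variant, "peptide": pep,
            "kcat_per_s": fit.kcat_per_s, "kcat_se": fit.kcat_se,
            "kcat_pct_wt": 100.0 * fit.kcat_per_s / wt.kcat_per_s,
            "km_uM": fit.km_uM, "km_se": fit.km_se,
            "km_pct_wt": 100.0 * fit.km_uM / wt.km_uM,
            "efficiency_per_s_per_M": fit.efficiency_per_s_per_M,
            "efficiency_pct_wt":
                100.0 * fit.efficiency_per_s_per_M / wt.efficiency_per_s_per_M,
        })
    df = pd.DataFrame(rows).sort_values(["peptide", "variant"]).reset_index(
        drop=True)
    df["kcat_fmt"] = df["kcat_per_s"].round(4)
    df["km_fmt"] = df["km_uM"].round(2)
    df["efficiency_fmt"] = df["efficiency_per_s_per_M"].round(0).astype(int)
    for col in ("kcat_pct_wt", "km_pct_wt", "efficiency_pct_wt"):
        df[col + "_fmt"] = df[col].round(0).astype(int)
    return df
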