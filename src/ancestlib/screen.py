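"""Plate-screen analysis: slopes, fold-over-wild-type, hit calling, rescreens.

Fluorogenic deacylation time courses are reduced to initial slopes by
ordinary least squares over an automatically chosen early window (the
longest prefix, at least 3 points, whose linear fit keeps R^2 >= 0.95, so
plateauing curves contribute only their linear phase).  Activities are
normalized per plate: fold = (slope - mean blank) / (mean WT - mean blank).
Variants at or above the fold threshold (default 2, "at least 2-fold over
wild type") are primary hits; triplicate rescreens are verified with a
one-sided Welch t-test against wild-type replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class WellTimecourse:
    """One well's fluorescence time course."""

    well: str
    variant_id: str          # variant name, or "" for controls
    role: str                # "variant" | "WT" | "blank"
    time_s: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size < 3:
            raise ValueError(f"well {self.well}: need >= 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"well {self.well}: times must be strictly increasing")
        if t.size != f.size:
            raise ValueError(f"well {self.well}: time/fluorescence length mismatch")
        self.time_s, self.fluorescence = t, f


@dataclass(frozen=True)
class ScreenConfig:
    fold_threshold: float = 2.0
    window_r2: float = 0.95
    min_window_points: int = 3
    rescreen_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be > 0")


def _ols_slope(t: np.ndarray, f: np.ndarray) -> tuple:
    """(slope, R^2); R^2 = 1 for an exact fit of a constant/linear signal."""
    if np.ptp(t) == 0:
        raise ValueError("all time points identical")
    slope, intercept = np.polyfit(t, f, 1)
    resid = f - (slope * t + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), r2


def initial_slope(tc: WellTimecourse, cfg: ScreenConfig = ScreenConfig()
                  ) -> tuple:
    """Initial rate (fluorescence units/s) and R^2 over the selected window.

    The window is the longest prefix (>= cfg.min_window_points) whose OLS
    fit has R^2 >= cfg.window_r2; if no prefix qualifies, the minimal
    prefix is used.
    """
    t, f = tc.time_s, tc.fluorescence
    best = None
    for k in range(cfg.min_window_points, t.size + 1):
        slope, r2 = _ols_slope(t[:k], f[:k])
        if r2 >= cfg.window_r2:
            best = (slope, r2)
    if best is None:
        best = _ols_slope(t[:cfg.min_window_points], f[:cfg.min_window_points])
    return best


def z_prime(wt_slopes, blank_slopes) -> float:
    """Z'-factor plate QC on control slopes (1 is ideal; < 0 unusable)."""
    wt = np.asarray(wt_slopes, float)
    bl = np.asarray(blank_slopes, float)
    spread = abs(wt.mean() - bl.mean())
    if spread == 0:
        return -np.inf
    return 1.0 - 3.0 * (wt.std(ddof=1 if wt.size > 1 else 0)
                        + bl.std(ddof=1 if bl.size > 1 else 0)) / spread


def normalize_plate(wells: list, cfg: ScreenConfig = ScreenConfig()) -> tuple:
    """Per-variant fold-over-WT for one plate.

    fold = (slope - mean blank) / (mean WT - mean blank).  Returns
    (folds: dict variant -> fold, qc: dict).  Raises if the plate has no WT
    or blank wells, or if WT does not rise above blank (invalid plate).
    """
    wt = [initial_slope(w, cfg)[0] for w in wells if w.role == "WT"]
    blank = [initial_slope(w, cfg)[0] for w in wells if w.role == "blank"]
    if not wt or not blank:
        raise ValueError("plate needs at least one WT and one blank well")
    wt_mean, blank_mean = float(np.mean(wt)), float(np.mean(blank))
    if wt_mean <= blank_mean:
        raise ValueError("invalid plate: WT slope does not exceed blank slope")
    span = wt_mean - blank_mean
    folds = {}
    for w in wells:
        if w.role != "variant":
            continue
        slope, _ = initial_slope(w, cfg)
        folds[w.variant_id] = (slope - blank_mean) / span
    qc = {"wt_mean_slope": wt_mean, "blank_mean_slope": blank_mean,
          "z_prime": z_prime(wt, blank)}
    return folds, qc


def call_hits(folds: dict, cfg: ScreenConfig = ScreenConfig()) -> list:
    """Variants with fold >= threshold, sorted by fold descending."""
    hits = [(v, f) for v, f in folds.items() if f >= cfg.fold_threshold]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


@dataclass
class ScreenHit:
    variant_id: str
    primary_fold: float
    rescreen_mean: float
    rescreen_sd: float
    p_value: float
    verified: bool


def welch_one_sided(a, b) -> float:
    """One-sided Welch t-test p-value for mean(a) > mean(b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        return 0.0 if a.mean() > b.mean() else 1.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.pvalue)


def verify_rescreen(primary_hits: list, rescreen_folds: dict,
                    wt_folds, cfg: ScreenConfig = ScreenConfig()) -> list:
    """Verify primary hits from triplicate rescreens against WT replicates.

    Verified iff rescreen mean fold >= threshold AND one-sided Welch
    p-value <= alpha.
    """
    out = []
    for variant, primary_fold in primary_hits:
        folds = np.asarray(rescreen_folds[variant], float)
        p = welch_one_sided(folds, wt_folds)
        mean, sd = float(folds.mean()), float(folds.std(ddof=1))
        out.append(ScreenHit(variant, primary_fold, mean, sd, p,
                             bool(mean >= cfg.fold_threshold
                                  and p <= cfg.rescreen_alpha)))
    return out


# ---------------------------------------------------------------------------
# Plate CSV interface

PLATE_COLUMNS = ["plate_id", "well", "role", "variant_id", "time_s",
                 "fluorescence"]


def wells_from_frame(df: pd.DataFrame) -> dict:
    """Group a long-format plate table into {plate_id: [WellTimecourse]}."""
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    plates = {}
    for (plate, well), g in df.groupby(["plate_id", "well"], sort=True):
        g = g.sort_values("time_s")
        role = g["role"].iloc[0]
        variant = "" if pd.isna(g["variant_id"].iloc[0]) else str(
            g["variant_id"].iloc[0])
        plates.setdefault(plate, []).append(
            WellTimecourse(str(well), variant, role,
                           g["time_s"].to_numpy(),
                           g["fluorescence"].to_numpy()))
    return plates


def analyze_plates(df: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()
                   ) -> tuple:
    """Normalize every plate and call hits across the whole screen.

    Returns (folds: variant -> fold, hits, qc per plate).  Folds are not
    pooled across plates; each variant is normalized within its own plate.
    """
    plates = wells_from_frame(df)
    folds, qc = {}, {}
    for plate_id, wells in plates.items():
        f, q = normalize_plate(wells, cfg)
        folds.update(f)
        qc[plate_id] = q
    return folds, call_hits(folds, cfg), qc
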