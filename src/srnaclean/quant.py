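"""qPCR quantification and titration-based safe-input-volume determination.

Quantification cycles (Cp) are called by the second-derivative-maximum
method on a locally smoothed curve.  A standard curve is the least-squares
line of Cp against log10 input copies over a dilution series; its slope m
gives the reaction efficiency E = 10^(-1/m) - 1, and unknowns are
quantified by inverting the line: copies = 10^((b - Cp)/(-m)).

The titration fit regresses log10 contaminant cpm on log10 plasma input
volume (reagent contaminants give slopes near -1) and solves for the
smallest input volume whose predicted contaminant level falls below a cpm
threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_interp_spline
from scipy.signal import savgol_filter

DEFAULT_THRESHOLD_CPM = 100.0
SLOPE_PLAUSIBLE_RANGE = (-1.5, -0.5)


# ---------------------------------------------------------------------------
# Cp calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpResult:
    cp: float | None
    flagged: bool = False
    reason: str | None = None


def call_cp(
    fluorescence: Sequence[float],
    cycles: Sequence[float] | None = None,
    noise_floor: float = 1.0,
    smooth_window: int = 5,
) -> CpResult:
    """Quantification cycle by the second-derivative-maximum method.

    The curve is smoothed with a local quartic Savitzky-Golay filter
    (window ``smooth_window``; a quartic passes smooth sigmoids through
    essentially unchanged while damping per-cycle noise) and interpolated
    with a septic (order-7) spline, whose analytic second derivative is
    maximised on a fine cycle grid.  Curves whose overall fluorescence rise is below
    ``noise_floor`` are flagged as no-amplification; curves without a
    positive interior second-derivative peak are flagged as unusable.
    """
    f = np.asarray(fluorescence, dtype=float)
    if f.size < 10:
        raise ValueError("need at least 10 cycles to call a Cp")
    x = np.arange(1.0, f.size + 1.0) if cycles is None else np.asarray(cycles, dtype=float)
    smooth = savgol_filter(f, smooth_window, min(4, smooth_window - 1))
    if smooth[-1] - smooth[0] < noise_floor:
        return CpResult(None, True, "no_amplification")
    spline = make_interp_spline(x, smooth, k=7)
    grid = np.linspace(x[3], x[-4], 16001)
    d2 = spline(grid, 2)
    i = int(np.argmax(d2))
    if d2[i] <= 0:
        return CpResult(None, True, "no_second_derivative_peak")
    if i == 0 or i == len(grid) - 1:
        return CpResult(None, True, "peak_at_boundary")
    return CpResult(float(grid[i]), False, None)


def call_cp_set(curveset, **kwargs) -> list[CpResult]:
    """Call Cp for every reaction of an AmplificationCurveSet."""
    return [call_cp(row, curveset.cycles, **kwargs) for row in curveset.fluorescence]


# ---------------------------------------------------------------------------
# standard curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration line Cp = b + m * log10(copies)."""

    m: float  # slope, cycles per log10 copies (negative for valid curves)
    b: float  # intercept, cycles at 1 copy
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency E = 10^(-1/m) - 1."""
        return 10.0 ** (-1.0 / self.m) - 1.0

    @property
    def valid(self) -> bool:
        return self.m < 0


def fit_standard_curve(dilution_series: Iterable[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Cp against log10 copies over a dilution series.

    Requires at least three distinct concentrations (a seven-order-of-
    magnitude series is typical)."""
    pairs = [(c, cp) for c, cp in dilution_series]
    if len({c for c, _ in pairs}) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    logc = np.log10([c for c, _ in pairs])
    cp = np.array([cp for _, cp in pairs])
    if np.ptp(logc) == 0:
        raise ValueError("zero variance in log10(copies)")
    res = stats.linregress(logc, cp)
    return StandardCurve(m=float(res.slope), b=float(res.intercept), r_squared=float(res.rvalue**2))


def quantify(cp: float | CpResult, curve: StandardCurve) -> float | None:
    """Absolute copies from a Cp via the standard curve inverse
    10^((b - Cp)/(-m)); flagged Cp values yield no estimate."""
    if isinstance(cp, CpResult):
        if cp.flagged or cp.cp is None:
            return None
        cp = cp.cp
    if not curve.valid:
        raise ValueError(f"invalid standard curve (m = {curve.m:.3g} >= 0)")
    return float(10.0 ** ((curve.b - cp) / (-curve.m)))


def quantify_replicates(cps: Sequence[float | CpResult], curve: StandardCurve) -> float | None:
    """Average replicate Cp values (reactions run in duplicate) before
    quantification; returns None when no replicate is usable."""
    vals = []
    for cp in cps:
        if isinstance(cp, CpResult):
            if cp.flagged or cp.cp is None:
                continue
            vals.append(cp.cp)
        else:
            vals.append(cp)
    if not vals:
        return None
    return quantify(float(np.mean(vals)), curve)


# ---------------------------------------------------------------------------
# titration fitting and safe input volume
# ---------------------------------------------------------------------------

@dataclass
class TitrationFit:
    """Per-contaminant log-log fits and safe-volume determinations.

    ``table`` is indexed by contaminant with columns slope, intercept,
    r_squared, safe_volume_fit, safe_volume_tested and flag.  The overall
    safe volume is the maximum of the per-contaminant fit-based volumes
    (the binding constraint); the empirically smallest tested volume at
    which every contaminant meets the threshold is reported alongside.
    """

    table: pd.DataFrame
    threshold_cpm: float
    overall_safe_volume: float
    overall_safe_volume_tested: float

    def to_json(self) -> str:
        payload = {
            "threshold_cpm": self.threshold_cpm,
            "overall_safe_volume_uL": self.overall_safe_volume,
            "overall_safe_volume_tested_uL": self.overall_safe_volume_tested,
            "per_contaminant": json.loads(self.table.to_json(orient="index")),
        }
        return json.dumps(payload, indent=2, allow_nan=True)


def safe_input_volume(
    cpm_table: pd.DataFrame,
    threshold_cpm: float = DEFAULT_THRESHOLD_CPM,
    floor_reads: float = 0.5,
) -> TitrationFit:
    """Determine the minimal plasma input volume suppressing each
    contaminant below ``threshold_cpm``.

    ``cpm_table`` is long-form with columns (contaminant, volume_uL, cpm)
    and, when zero cpm values occur, library_size (retained reads) so zeros
    can be floored at the ``floor_reads``-read pseudo-cpm.  Per contaminant,
    log10(cpm) is regressed on log10(volume); the fit-based safe volume
    solves predicted cpm = threshold, and the smallest tested volume whose
    mean cpm meets the threshold is reported alongside.  Contaminants absent
    everywhere are flagged unconstrained at the smallest tested volume.
    """
    required = {"contaminant", "volume_uL", "cpm"}
    if not required.issubset(cpm_table.columns):
        raise ValueError(f"cpm_table needs columns {sorted(required)}")
    rows = []
    min_tested = float(cpm_table["volume_uL"].min())
    for name, grp in cpm_table.groupby("contaminant", sort=True):
        flags = []
        vols = grp["volume_uL"].to_numpy(dtype=float)
        cpm = grp["cpm"].to_numpy(dtype=float)
        if (cpm == 0).any():
            if "library_size" not in grp.columns or grp["library_size"].isna().any():
                raise ValueError(
                    f"{name}: zero cpm values require a library_size column for the pseudo-cpm floor"
                )
            floor = floor_reads / grp["library_size"].to_numpy(dtype=float) * 1e6
            cpm = np.maximum(cpm, floor)
        mean_by_vol = grp.groupby("volume_uL")["cpm"].mean()
        tested_ok = mean_by_vol[mean_by_vol <= threshold_cpm]
        safe_tested = float(tested_ok.index.min()) if len(tested_ok) else float("nan")

        if (grp["cpm"] == 0).all():
            rows.append((name, np.nan, np.nan, np.nan, min_tested, safe_tested, "unconstrained"))
            continue
        n_nonzero_vols = grp.loc[grp["cpm"] > 0, "volume_uL"].nunique()
        if n_nonzero_vols < 3:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, safe_tested, "insufficient_data"))
            continue
        res = stats.linregress(np.log10(vols), np.log10(cpm))
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
        if slope < 0:
            safe_fit = float(10.0 ** ((np.log10(threshold_cpm) - intercept) / slope))
        else:
            safe_fit = float("nan")
            flags.append("nonnegative_slope")
        if not (SLOPE_PLAUSIBLE_RANGE[0] <= slope <= SLOPE_PLAUSIBLE_RANGE[1]):
            flags.append("slope_outlier")
        rows.append((name, slope, intercept, r2, safe_fit, safe_tested, ";".join(flags)))
    table = pd.DataFrame(
        rows,
        columns=["contaminant", "slope", "intercept", "r_squared",
                 "safe_volume_fit", "safe_volume_tested", "flag"],
    ).set_index("contaminant")
    fit_vals = table["safe_volume_fit"].dropna()
    overall = float(fit_vals.max()) if len(fit_vals) else min_tested
    tested_vals = table["safe_volume_tested"].dropna()
    overall_tested = float(tested_vals.max()) if len(tested_vals) else float("nan")
    return TitrationFit(
        table=table,
        threshold_cpm=threshold_cpm,
        overall_safe_volume=overall,
        overall_safe_volume_tested=overall_tested,
    )
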