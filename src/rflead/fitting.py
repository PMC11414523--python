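"""Fit model heating curves to measured delta-T data.

Measured lead-tip temperature rises are first corrected for the scanner's
per-wire transmit-gain (TG) calibration.  TG is recorded in counts of 0.1 dB,
so a TG difference of dTG counts scales RF power — and hence delta_T — by
10^(dTG/100); 30 counts is a factor of two.  The corrected rise for wire j is

    delta_Tc_j = delta_Tmeasured_j * 10^((TG_APS_j - TG_ref)/100).

Each model predicts delta_T versus length only up to a scale factor, which is
fitted by least squares (closed form).  The transmission line model may also
profile its reflection coefficient Gamma over [0, 1].  Models with different
numbers of free parameters are ranked by the ordinary-least-squares Akaike
information criterion, AIC = n*ln(RSS/n) + 2*(K+1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .media import Wavenumber
from .transfer import delta_T_tlm

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class TemperatureMeasurement:
    """One wire's heating measurement and its error components.

    ``wire_length`` in m; ``measured_delta_T`` in deg C (noise can make small
    values slightly negative); ``tg_aps`` is the mean auto-prescan transmit
    gain in counts and ``tg_aps_sd`` its SD over repeats;
    ``probe_difference`` is the disagreement between the two tip probes and
    ``baseline_sd`` the pre-RF baseline SD, both in deg C.
    """

    wire_length: float
    measured_delta_T: float
    tg_aps: float
    tg_aps_sd: float = 0.0
    probe_difference: float = 0.0
    baseline_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.wire_length > 0:
            raise ValueError("wire_length must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Fitted scale (and optionally Gamma) with goodness-of-fit summaries."""

    scale: float
    rmse: float
    aic: float
    n_free_params: int
    gamma: float | None = None
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.n_free_params not in (1, 2):
            raise ValueError("n_free_params must be 1 or 2")


def tg_correct(measurement: TemperatureMeasurement, tg_ref: float) -> float:
    """Transmit-gain corrected temperature rise, deg C."""
    return measurement.measured_delta_T * 10.0 ** ((measurement.tg_aps - tg_ref) / 100.0)


def tg_error_component(measurement: TemperatureMeasurement, tg_ref: float | None = None) -> float:
    """Delta-T uncertainty induced by TG variation over prescan repeats.

    First-order propagation of tg_aps_sd through the correction:
    |d(delta_Tc)/d(TG)| * sd = |delta_Tc| * ln(10)/100 * tg_aps_sd.
    """
    if tg_ref is None:
        tg_ref = measurement.tg_aps
    corrected = tg_correct(measurement, tg_ref)
    return abs(corrected) * (_LN10 / 100.0) * measurement.tg_aps_sd


def combined_error(measurement: TemperatureMeasurement, tg_ref: float | None = None) -> float:
    """Root-sum-square of the three delta-T error sources: probe
    disagreement, TG-variation propagation, and baseline SD."""
    components = (
        measurement.probe_difference,
        tg_error_component(measurement, tg_ref),
        measurement.baseline_sd,
    )
    if any(c < 0 for c in components):
        raise ValueError("error components must be >= 0")
    return math.sqrt(sum(c * c for c in components))


def aic(rss: float, n: int, k_params: int) -> float:
    """Ordinary-least-squares Akaike information criterion.

    AIC = n*ln(RSS/n) + 2*(K+1), with the +1 counting the error variance.
    Lower is better; only differences are meaningful.
    """
    if n <= k_params + 2:
        raise ValueError(f"need n > k_params + 2 data points, got n={n}, K={k_params}")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        warnings.warn("zero residual sum of squares: AIC is -inf", UserWarning, stacklevel=2)
        return -math.inf
    return n * math.log(rss / n) + 2.0 * (k_params + 1)


def fit_scale(
    predictions: Sequence[float], observations: Sequence[float], n_free_params: int = 1
) -> FitResult:
    """Closed-form least-squares scale of a model curve onto data.

    c = sum(y*p) / sum(p^2) minimizes sum((y - c*p)^2); RMSE uses 1/n
    normalization.  ``n_free_params`` is the model's total free-parameter
    count for the AIC (2 when Gamma was also profiled upstream).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(observations, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predictions and observations must be 1-D arrays of equal length")
    if p.size < 2:
        raise ValueError("need at least 2 data points")
    ss = float(np.dot(p, p))
    if ss == 0:
        raise ValueError("degenerate fit: all model predictions are zero")
    c = float(np.dot(y, p)) / ss
    residuals = y - c * p
    rss = float(np.dot(residuals, residuals))
    rmse = math.sqrt(rss / p.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        a = aic(rss, p.size, n_free_params)
    return FitResult(scale=c, rmse=rmse, aic=a, n_free_params=n_free_params, n_points=p.size)


def _tlm_rmse_at_gamma(
    gamma: float, k: Wavenumber, lengths: np.ndarray, observations: np.ndarray
) -> tuple[float, float]:
    predictions = np.asarray(delta_T_tlm(1.0, k, float(gamma), lengths))
    ss = float(np.dot(predictions, predictions))
    if ss == 0:
        return math.inf, 0.0
    c = float(np.dot(observations, predictions)) / ss
    residuals = observations - c * predictions
    return math.sqrt(float(np.dot(residuals, residuals)) / lengths.size), c

def fit_gamma_and_scale(
    k: Wavenumber,
    lengths: Sequence[float],
    observations: Sequence[float],
    gamma_grid_step: float = 1e-3,
) -> FitResult:
    """Profile the reflection coefficient Gamma over [0, 1] and fit the scale
    in closed form at each Gamma; return the global RMSE minimizer.

    A grid search (default step 1e-3) is followed by bounded local
    refinement.  The result carries 2 free parameters (scale and Gamma).
    """
    lengths = np.asarray(lengths, dtype=float)
    y = np.asarray(observations, dtype=float)
    if lengths.shape != y.shape or lengths.ndim != 1:
        raise ValueError("lengths and observations must be 1-D arrays of equal length")
    if lengths.size < 3:
        raise ValueError("need at least 3 data points to fit Gamma and scale")

    grid = np.arange(0.0, 1.0 + gamma_grid_step / 2, gamma_grid_step)
    grid = np.minimum(grid, 1.0 - 1e-9)  # keep clear of the Gamma=1, d=n*lambda/2 pole
    rmses = np.array([_tlm_rmse_at_gamma(g, k, lengths, y)[0] for g in grid])
    i = int(np.argmin(rmses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda g: _tlm_rmse_at_gamma(float(g), k, lengths, y)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-7},
    )
    gamma_best = float(res.x) if res.fun <= rmses[i] else float(grid[i])
    rmse, scale = _tlm_rmse_at_gamma(gamma_best, k, lengths, y)
    rss = rmse**2 * lengths.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        a = aic(rss, lengths.size, 2)
    return FitResult(
        scale=scale, rmse=rmse, aic=a, n_free_params=2, gamma=gamma_best, n_points=lengths.size
    )


# ---------------------------------------------------------------------------
# measurement table I/O

MEASUREMENT_COLUMNS = (
    "length_cm",
    "delta_T_C",
    "tg_aps",
    "tg_aps_sd",
    "probe_diff_C",
    "baseline_sd_C",
)


def read_measurements(path: str | Path) -> list[TemperatureMeasurement]:
    """Read a measurement CSV (header ``length_cm, delta_T_C, tg_aps,
    tg_aps_sd, probe_diff_C, baseline_sd_C``); lengths convert cm -> m.

    Malformed rows raise with the offending CSV line number.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {', '.join(missing)}")
    out = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            values = [float(row[c]) for c in MEASUREMENT_COLUMNS]
            if any(math.isnan(v) for v in values):
                raise ValueError("non-numeric or empty cell")
            out.append(
                TemperatureMeasurement(
                    wire_length=values[0] / 100.0,
                    measured_delta_T=values[1],
                    tg_aps=values[2],
                    tg_aps_sd=values[3],
                    probe_difference=values[4],
                    baseline_sd=values[5],
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from exc
    return out


def write_measurements(measurements: Sequence[TemperatureMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "length_cm": [m.wire_length * 100.0 for m in measurements],
            "delta_T_C": [m.measured_delta_T for m in measurements],
            "tg_aps": [m.tg_aps for m in measurements],
            "tg_aps_sd": [m.tg_aps_sd for m in measurements],
            "probe_diff_C": [m.probe_difference for m in measurements],
            "baseline_sd_C": [m.baseline_sd for m in measurements],
        }
    ).to_csv(path, index=False)
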