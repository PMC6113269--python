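"""Time-series-level cleaning of parcel BOLD signals.

The canonical order is detrend -> nuisance regression -> band-pass
(0.01-0.08 Hz), i.e. the standard resting-state sequence after the
image-space steps. Global-signal regression is deliberately not offered:
it distorts correlation patterns and the analysis this package supports
does not use it.

The band-pass is a zero-phase (forward-backward) Butterworth filter,
order 2 per pass, so filtering adds no phase shift that would perturb
interregional correlations.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .cohort import NuisanceSet
from .datatypes import ParcelTimeSeries

DEFAULT_LOW_HZ = 0.01
DEFAULT_HIGH_HZ = 0.08


def detrend_linear(series: ParcelTimeSeries) -> ParcelTimeSeries:
    """Remove the least-squares line (intercept + slope) from each parcel.

    Residual columns have zero mean and zero linear trend.
    """
    if series.n_samples < 3:
        raise ValueError("detrending needs at least 3 time samples")
    detrended = scipy.signal.detrend(series.values, axis=0, type="linear")
    return series.with_values(detrended)


def regress_nuisance(series: ParcelTimeSeries, nuisance: NuisanceSet) -> ParcelTimeSeries:
    """Residualize every parcel on the nuisance regressors (plus an
    intercept, always included so residuals are mean-free).

    Raises if the regressor matrix is rank-deficient, naming the collinear
    columns.
    """
    reg = nuisance.regressors
    if reg.shape[0] != series.n_samples:
        raise ValueError(
            f"nuisance rows ({reg.shape[0]}) != series samples ({series.n_samples})"
        )
    design = np.column_stack([np.ones(reg.shape[0]), reg])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(reg, nuisance.names)
        raise ValueError(f"nuisance regressors are rank-deficient: {bad}")
    beta, *_ = np.linalg.lstsq(design, series.values, rcond=None)
    residual = series.values - design @ beta
    return series.with_values(residual)


def _collinear_columns(reg: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (reported in errors)."""
    design = np.column_stack([np.ones(reg.shape[0]), reg])
    bad = []
    for j in range(reg.shape[1]):
        reduced = np.delete(design, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
            bad.append(names[j])
    return bad


def bandpass(
    series: ParcelTimeSeries,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = 2,
) -> ParcelTimeSeries:
    """Zero-phase Butterworth band-pass keeping the low-frequency
    oscillations that carry resting-state connectivity.

    ``order`` is the per-pass filter order; the forward-backward pass
    doubles the effective roll-off and cancels phase distortion.
    """
    nyq = series.nyquist_hz
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyq:.4f} Hz"
        )
    sos = scipy.signal.butter(
        order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos"
    )
    # even-reflection padding keeps edge transients from leaking
    # out-of-band power into these short (T ~ 200) records
    filtered = scipy.signal.sosfiltfilt(sos, series.values, axis=0, padtype="even")
    return series.with_values(filtered)


def clean(
    series: ParcelTimeSeries,
    nuisance: NuisanceSet | None = None,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> ParcelTimeSeries:
    """Full cleaning pipeline: detrend, regress nuisance (if given),
    band-pass. Shape and parcel labels are preserved throughout."""
    out = detrend_linear(series)
    if nuisance is not None:
        out = regress_nuisance(out, nuisance)
    return bandpass(out, low_hz=low_hz, high_hz=high_hz)
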