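"""Spectral analysis of unevenly sampled, incomplete time series.

The workhorse is the classical Lomb-Scargle periodogram, the least-squares
spectral estimator that remains valid when sampling is uneven or entries
are missing — the typical situation in longitudinal omics profiling, where
clinic visits are irregular and individual analytes drop below detection.
Missing values are simply omitted (they reduce the series to an unevenly
sampled one), never imputed on this path.

With the variance normalization used here the power of white noise is O(1)
per frequency, and on a complete, evenly spaced grid the estimator
coincides exactly with the classical (Schuster) periodogram at the Fourier
frequencies.

Autocorrelations are provided two ways: (i) through a cosine-weighted sum
of Lomb-Scargle power over the frequency grid (a Wiener–Khinchin surrogate
appropriate for a one-sided, phaseless power spectrum), and (ii) by
interpolating the observed points onto a uniform grid (cubic by default)
and applying the standard biased estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d

from .omics import OmicsInputError

__all__ = [
    "FrequencyGrid",
    "Periodogram",
    "AutocorrelationResult",
    "make_frequency_grid",
    "lomb_scargle",
    "autocorrelation_via_spectrum",
    "autocorrelation_interpolated",
]


@dataclass
class FrequencyGrid:
    """Strictly increasing positive frequencies (cycles per time unit)."""

    frequencies: np.ndarray
    oversampling: float = 1.0
    f_max_rule: str = "nyquist_mean"
    span: float = 0.0

    def __len__(self) -> int:
        return len(self.frequencies)


def _observed_times(times) -> np.ndarray:
    if isinstance(times, (list, tuple)) and times and hasattr(times[0], "time"):
        return np.array([p.time for p in times], dtype=float)
    return np.asarray(times, dtype=float)


def make_frequency_grid(
    times, oversampling: float = 1.0, f_max_rule: str = "nyquist_mean"
) -> FrequencyGrid:
    """Frequency grid k/(oversampling·T), k = 1 … floor(f_max·oversampling·T).

    T is the span of the observed times; f_max is the pseudo-Nyquist limit
    1/(2·mean adjacent spacing) (default) or 1/(2·min spacing).
    """
    t = np.unique(_observed_times(times))
    if t.size < 3:
        raise OmicsInputError("frequency grid needs >= 3 distinct observed times")
    if oversampling < 1:
        raise OmicsInputError("oversampling must be >= 1")
    spacings = np.diff(t)
    if f_max_rule == "nyquist_mean":
        f_max = 1.0 / (2.0 * spacings.mean())
    elif f_max_rule == "nyquist_min":
        f_max = 1.0 / (2.0 * spacings.min())
    else:
        raise OmicsInputError(f"unknown f_max rule {f_max_rule!r}")
    span = float(t[-1] - t[0])
    n_freq = int(np.floor(f_max * oversampling * span + 1e-9))
    freqs = np.arange(1, n_freq + 1) / (oversampling * span)
    return FrequencyGrid(freqs, oversampling, f_max_rule, span)


@dataclass
class Periodogram:
    """Lomb-Scargle power on a frequency grid (variance-normalized)."""

    grid: FrequencyGrid
    power: np.ndarray
    n_obs: int
    normalization: str = "variance"

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies


def _as_grid(grid) -> FrequencyGrid:
    if isinstance(grid, FrequencyGrid):
        return grid
    freqs = np.asarray(grid, dtype=float)
    return FrequencyGrid(freqs)


def _drop_missing(times, values):
    t = _observed_times(times)
    x = np.asarray(values, dtype=float)
    keep = ~np.isnan(x)
    return t[keep], x[keep]


def lomb_scargle(times, values, grid) -> Periodogram:
    """Classical variance-normalized Lomb-Scargle periodogram.

    With x̄, s² the sample mean and variance (ddof=1) of the observed
    values and τ(ω) defined by tan(2ωτ) = Σ sin 2ωt_j / Σ cos 2ωt_j,

        P(ω) = 1/(2s²) · { [Σ(x_j−x̄)cos ω(t_j−τ)]² / Σcos²ω(t_j−τ)
                         + [Σ(x_j−x̄)sin ω(t_j−τ)]² / Σsin²ω(t_j−τ) }.

    NaN entries are dropped before evaluation (uneven-sampling path).
    """
    grid = _as_grid(grid)
    t, x = _drop_missing(times, values)
    if t.size < 3:
        raise OmicsInputError(
            f"Lomb-Scargle needs >= 3 observed points, got {t.size}"
        )
    var = x.var(ddof=1)
    if var <= 0:
        raise OmicsInputError("constant series: Lomb-Scargle power undefined")
    y = x - x.mean()
    omega = 2.0 * np.pi * grid.frequencies[:, None]  # (M, 1)
    wt = omega * t[None, :]  # (M, n)
    tau = np.arctan2(np.sin(2.0 * wt).sum(axis=1), np.cos(2.0 * wt).sum(axis=1)) / (
        2.0 * omega[:, 0]
    )
    arg = wt - omega * tau[:, None]
    c = np.cos(arg)
    s = np.sin(arg)
    cc = (c * c).sum(axis=1)
    ss = (s * s).sum(axis=1)
    yc = (y[None, :] * c).sum(axis=1)
    ys = (y[None, :] * s).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        power = (yc * yc / cc + ys * ys / ss) / (2.0 * var)
    power = np.where(np.isfinite(power), power, 0.0)
    return Periodogram(grid, power, int(t.size))


@dataclass
class AutocorrelationResult:
    """Normalized autocorrelation on a uniform lag grid (value 1 at lag 0)."""

    lags: np.ndarray
    values: np.ndarray
    method: str


def autocorrelation_via_spectrum(times, values, grid) -> AutocorrelationResult:
    """Autocorrelation as the cosine transform of Lomb-Scargle power.

    Lags are uniform with spacing T/M (T the observed span, M the grid
    size) and extend to T/2: with a discrete spectrum at frequencies k/T
    the cosine transform is periodic with period T, so larger lags carry
    no information.  The lag-0 value normalizes the result to exactly 1.
    """
    grid = _as_grid(grid)
    pg = lomb_scargle(times, values, grid)
    t, _ = _drop_missing(times, values)
    span = t[-1] - t[0]
    M = len(grid.frequencies)
    lags = np.arange(M // 2 + 1) * (span / M)
    acov = (pg.power[None, :] * np.cos(2.0 * np.pi * grid.frequencies[None, :] * lags[:, None])).sum(axis=1)
    return AutocorrelationResult(lags, acov / acov[0], "spectrum-inverse")


def autocorrelation_interpolated(
    times, values, interp_order: int = 3, n_grid: int | None = None
) -> AutocorrelationResult:
    """Autocorrelation after interpolating onto a uniform grid.

    Observed points are interpolated (cubic by default, linear with
    ``interp_order=1``) onto a uniform grid with the same span and
    ``n_grid`` points (default: the number of observed points); no
    extrapolation beyond the observed endpoints.  The biased estimator
    r_j = c_j / c_0 is applied on the uniform grid.
    """
    if interp_order not in (1, 3):
        raise OmicsInputError("interp_order must be 1 (linear) or 3 (cubic)")
    t, x = _drop_missing(times, values)
    need = 4 if interp_order == 3 else 2
    if t.size < need:
        raise OmicsInputError(
            f"interpolated autocorrelation needs >= {need} observed points for "
            f"order {interp_order}; try interp_order=1"
        )
    kind = "cubic" if interp_order == 3 else "linear"
    n = t.size if n_grid is None else int(n_grid)
    tu = np.linspace(t[0], t[-1], n)
    xu = interp1d(t, x, kind=kind)(tu)
    y = xu - xu.mean()
    c = np.correlate(y, y, mode="full")[n - 1 :] / n
    if c[0] <= 0:
        raise OmicsInputError("constant series: autocorrelation undefined")
    dt = tu[1] - tu[0] if n > 1 else 0.0
    lags = np.arange(n) * dt
    return AutocorrelationResult(lags, c / c[0], "interpolation")
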