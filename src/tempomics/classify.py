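"""Temporal-pattern classification of omics time series.

Each component's series is assigned to exactly one class:

* a dominant-frequency class ``f_k`` — the series carries significant
  spectral power, maximal at the k-th grid frequency;
* ``SpikeMax`` / ``SpikeMin`` — a singular event of unusually high or low
  intensity at one time point;
* a time-series-model class (AR / MA / ARMA / WhiteNoise, optionally with
  parameters); or
* ``Unclassified``.

Significance cutoffs come from a bootstrap null: surrogate series are
built by resampling the pooled observed values of the whole dataset with
replacement onto the real time grid (with the dataset's average
missingness), destroying temporal structure while preserving the marginal
value distribution.  Cutoffs are quantiles of the surrogate statistics.

By default the three null tests (dominant spectral power, series maximum,
series minimum) are calibrated *jointly*: the per-statistic quantile level
is raised above the nominal one until the fraction of surrogates exceeding
any of the three cutoffs equals ``1 - quantile``.  This keeps the overall
rate of null series leaving ``Unclassified`` at the nominal level; set
``calibration="marginal"`` for plain per-statistic quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .omics import OmicsInputError, TimeSeriesSet
from .spectral import (
    FrequencyGrid,
    autocorrelation_interpolated,
    autocorrelation_via_spectrum,
    lomb_scargle,
    make_frequency_grid,
)

__all__ = [
    "NullCutoffs",
    "ClassificationResult",
    "ModelFit",
    "bootstrap_cutoffs",
    "classify_time_series",
    "fit_model",
    "group_by_model",
    "CUTOFF_METHODS",
    "MODEL_METHODS",
]

CUTOFF_METHODS = ("periodogram", "autocorr_spectrum", "autocorr_interp")
MODEL_METHODS = ("model_kind", "model_params")


@dataclass
class NullCutoffs:
    """Bootstrap-calibrated cutoffs for one dataset, grid, and method."""

    frequencies: np.ndarray  # grid frequencies (or positive lags)
    per_frequency: np.ndarray  # marginal quantile of the statistic per bin
    statistic_cutoff: float  # cutoff on the max statistic over bins
    spike_max_cutoff: float
    spike_min_cutoff: float
    quantile: float
    adjusted_quantile: float  # per-statistic level after joint calibration
    n_boot: int
    seed: int
    method: str = "periodogram"
    calibration: str = "familywise"

    def to_dict(self) -> dict:
        return {
            "frequencies": self.frequencies.tolist(),
            "per_frequency": self.per_frequency.tolist(),
            "statistic_cutoff": self.statistic_cutoff,
            "spike_max_cutoff": self.spike_max_cutoff,
            "spike_min_cutoff": self.spike_min_cutoff,
            "quantile": self.quantile,
            "adjusted_quantile": self.adjusted_quantile,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "method": self.method,
            "calibration": self.calibration,
        }


def _statistic_vector(t, x, grid, method):
    """Statistic compared bin-wise against cutoffs: LS power, or |acf| at
    positive lags."""
    if method == "periodogram":
        return lomb_scargle(t, x, grid).power
    if method == "autocorr_spectrum":
        return np.abs(autocorrelation_via_spectrum(t, x, grid).values[1:])
    if method == "autocorr_interp":
        n_grid = len(np.atleast_1d(t))
        return np.abs(
            autocorrelation_interpolated(t, x, n_grid=n_grid).values[1:]
        )
    raise OmicsInputError(f"unknown cutoff method {method!r}")


def bootstrap_cutoffs(
    tss: TimeSeriesSet,
    grid: FrequencyGrid | None = None,
    quantile: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "periodogram",
    calibration: str = "familywise",
) -> NullCutoffs:
    """Bootstrap null cutoffs from pooled observed values.

    Surrogates resample the pooled values with replacement onto the real
    time grid, applying the dataset's average missingness.  Per-bin cutoffs
    are marginal quantiles; the decision cutoff for frequency/lag classes
    is a quantile of the surrogate *maximum* statistic; spike cutoffs are
    quantiles of surrogate series maxima and minima.
    """
    if not 0.0 < quantile < 1.0:
        raise OmicsInputError("quantile must be in (0, 1)")
    if n_boot < 100:
        raise OmicsInputError("n_boot must be >= 100")
    if method not in CUTOFF_METHODS:
        raise OmicsInputError(f"unknown cutoff method {method!r}")
    if calibration not in ("familywise", "marginal"):
        raise OmicsInputError(f"unknown calibration {calibration!r}")
    if not tss.series:
        raise OmicsInputError("empty TimeSeriesSet")
    values = np.array([v for vec in tss.series.values() for v in vec])
    pool = values[~np.isnan(values)]
    if pool.size == 0:
        raise OmicsInputError("no observed values to pool")
    missing_rate = 1.0 - pool.size / values.size
    t = tss.time_values
    if grid is None:
        grid = make_frequency_grid(t)
    rng = np.random.default_rng(seed)

    stat_rows = []
    maxima = np.empty(n_boot)
    minima = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            x = rng.choice(pool, size=t.size, replace=True)
            if missing_rate > 0:
                mask = rng.random(t.size) < missing_rate
                x = np.where(mask, np.nan, x)
            obs = x[~np.isnan(x)]
            if obs.size >= max(4, 3) and obs.var(ddof=1) > 0:
                break
        else:  # pragma: no cover - pathological pools only
            raise OmicsInputError("could not draw a usable surrogate series")
        stat_rows.append(_statistic_vector(t, x, grid, method))
        maxima[b] = obs.max()
        minima[b] = obs.min()
    stat = np.vstack(stat_rows)
    max_stat = stat.max(axis=1)

    per_freq = np.quantile(stat, quantile, axis=0)
    if calibration == "marginal":
        level = quantile
    else:
        target = 1.0 - quantile

        def exceed_frac(lvl):
            c_stat = np.quantile(max_stat, lvl)
            c_max = np.quantile(maxima, lvl)
            c_min = np.quantile(minima, 1.0 - lvl)
            hits = (max_stat > c_stat) | (maxima > c_max) | (minima < c_min)
            return hits.mean()

        lo, hi = quantile, 1.0 - 0.5 / n_boot
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if exceed_frac(mid) > target:
                lo = mid
            else:
                hi = mid
        level = hi

    bins = (
        grid.frequencies
        if method == "periodogram"
        else np.arange(1, stat.shape[1] + 1, dtype=float)
    )
    return NullCutoffs(
        frequencies=bins,
        per_frequency=per_freq,
        statistic_cutoff=float(np.quantile(max_stat, level)),
        spike_max_cutoff=float(np.quantile(maxima, level)),
        spike_min_cutoff=float(np.quantile(minima, 1.0 - level)),
        quantile=quantile,
        adjusted_quantile=float(level),
        n_boot=n_boot,
        seed=seed,
        method=method,
        calibration=calibration,
    )


@dataclass
class ClassificationResult:
    """Exactly one class label per input component."""

    assignments: dict  # component -> label
    statistic: dict  # component -> decision statistic
    cutoff: dict  # component -> cutoff compared against
    method: str
    class_bins: np.ndarray | None = None  # frequency (or lag) per class index

    def members(self, label: str) -> list:
        return [c for c, lab in self.assignments.items() if lab == label]

    def class_labels(self) -> list:
        return sorted(set(self.assignments.values()))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "component": list(self.assignments),
                "class": [self.assignments[c] for c in self.assignments],
                "statistic": [self.statistic.get(c, np.nan) for c in self.assignments],
                "cutoff": [self.cutoff.get(c, np.nan) for c in self.assignments],
                "method": self.method,
            }
        )


def classify_time_series(
    tss: TimeSeriesSet,
    method: str = "periodogram",
    cutoffs: NullCutoffs | None = None,
    grid: FrequencyGrid | None = None,
    max_p: int = 2,
    max_q: int = 2,
    criterion: str = "bic",
    parameter_round: int = 1,
) -> ClassificationResult:
    """Assign every component to exactly one temporal-pattern class.

    Cutoff-based methods test, in order of precedence: dominant
    frequency/lag class (max statistic above the null cutoff, ties broken
    toward the lowest bin), then SpikeMax (series maximum above cutoff),
    then SpikeMin, else Unclassified.  Model methods label each series by
    the selected model kind, optionally with rounded parameters.
    """
    if method in CUTOFF_METHODS:
        if cutoffs is None:
            raise OmicsInputError(f"method {method!r} requires bootstrap cutoffs")
        if cutoffs.method != method:
            raise OmicsInputError(
                f"cutoffs were built for method {cutoffs.method!r}, not {method!r}"
            )
        return _classify_with_cutoffs(tss, method, cutoffs, grid)
    if method in MODEL_METHODS:
        return _classify_by_model(
            tss, method, max_p=max_p, max_q=max_q, criterion=criterion,
            parameter_round=parameter_round,
        )
    raise OmicsInputError(f"unknown classification method {method!r}")


def _classify_with_cutoffs(tss, method, cutoffs, grid):
    t = tss.time_values
    if grid is None and method in ("periodogram", "autocorr_spectrum"):
        grid = make_frequency_grid(t)
    assignments, stat_out, cut_out = {}, {}, {}
    for comp, vec in tss.series.items():
        obs = vec[~np.isnan(vec)]
        label = "Unclassified"
        stat_val = np.nan
        cut_val = np.nan
        stat = None
        if obs.size >= 4 and obs.var(ddof=1) > 0:
            try:
                stat = _statistic_vector(t, vec, grid, method)
            except OmicsInputError:
                stat = None
        if stat is not None and len(stat) == len(cutoffs.per_frequency):
            k = int(np.argmax(stat))  # ties -> lowest bin
            if stat[k] > cutoffs.statistic_cutoff:
                label = f"f{k + 1}"
                stat_val = float(stat[k])
                cut_val = cutoffs.statistic_cutoff
        if label == "Unclassified" and obs.size:
            if obs.max() > cutoffs.spike_max_cutoff:
                label = "SpikeMax"
                stat_val = float(obs.max())
                cut_val = cutoffs.spike_max_cutoff
            elif obs.min() < cutoffs.spike_min_cutoff:
                label = "SpikeMin"
                stat_val = float(obs.min())
                cut_val = cutoffs.spike_min_cutoff
        assignments[comp] = label
        stat_out[comp] = stat_val
        cut_out[comp] = cut_val
    return ClassificationResult(
        assignments, stat_out, cut_out, method, class_bins=cutoffs.frequencies
    )


# ---------------------------------------------------------------------------
# Model-based classification
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Selected ARMA-family model for one series."""

    kind: str  # AR | MA | ARMA | WhiteNoise
    p: int
    q: int
    params: np.ndarray = field(default_factory=lambda: np.empty(0))
    ic: float = np.inf


def fit_model(
    series,
    max_p: int = 2,
    max_q: int = 2,
    criterion: str = "bic",
) -> ModelFit:
    """Fit all ARMA(p, q) candidates, 0 <= p <= max_p, 0 <= q <= max_q, by
    maximum likelihood and select by information criterion.

    ``criterion`` is ``"bic"`` (default — its stronger complexity penalty
    keeps the selected *kind* stable at the sample sizes typical here) or
    ``"aicc"``.  Kind is AR if q = 0 < p, MA if p = 0 < q, ARMA if both
    positive, WhiteNoise if both zero.  Non-convergent candidates are
    skipped with a warning.
    """
    from statsmodels.tsa.arima.model import ARIMA

    x = np.asarray(series, dtype=float)
    if np.isnan(x).any():
        raise OmicsInputError("fit_model requires a complete series")
    if x.size < 10 * (max_p + max_q + 1):
        raise OmicsInputError(
            f"series of length {x.size} too short for max orders "
            f"({max_p}, {max_q}); need >= {10 * (max_p + max_q + 1)}"
        )
    best = None
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = ARIMA(x, order=(p, 0, q), trend="c").fit()
                ic = float(res.bic if criterion == "bic" else res.aicc)
                if not np.isfinite(ic):
                    raise ValueError("non-finite information criterion")
            except Exception as exc:
                warnings.warn(f"ARMA({p},{q}) fit failed and was skipped: {exc}")
                continue
            if best is None or ic < best.ic:
                params = np.concatenate([res.arparams, res.maparams])
                best = ModelFit(_kind(p, q), p, q, params, ic)
    if best is None:
        raise OmicsInputError("no ARMA candidate converged")
    return best


def _kind(p: int, q: int) -> str:
    if p == 0 and q == 0:
        return "WhiteNoise"
    if q == 0:
        return "AR"
    if p == 0:
        return "MA"
    return "ARMA"


def _classify_by_model(tss, method, max_p, max_q, criterion, parameter_round):
    from scipy.interpolate import interp1d

    t = tss.time_values
    assignments, stat_out, cut_out = {}, {}, {}
    for comp, vec in tss.series.items():
        obs_mask = ~np.isnan(vec)
        if obs_mask.sum() < 10 * (max_p + max_q + 1):
            assignments[comp] = "Unclassified"
            stat_out[comp] = np.nan
            cut_out[comp] = np.nan
            continue
        to, xo = t[obs_mask], vec[obs_mask]
        tu = np.linspace(to[0], to[-1], len(to))
        kind_interp = "cubic" if len(to) >= 4 else "linear"
        xu = interp1d(to, xo, kind=kind_interp)(tu)
        try:
            fit = fit_model(xu, max_p=max_p, max_q=max_q, criterion=criterion)
        except OmicsInputError:
            assignments[comp] = "Unclassified"
            stat_out[comp] = np.nan
            cut_out[comp] = np.nan
            continue
        if method == "model_kind":
            assignments[comp] = fit.kind
        else:
            rounded = np.round(fit.params, parameter_round)
            assignments[comp] = (
                f"{fit.kind}({fit.p},{fit.q})[" +
                ",".join(f"{v:+.{parameter_round}f}" for v in rounded) + "]"
            )
        stat_out[comp] = fit.ic
        cut_out[comp] = np.nan
    return ClassificationResult(assignments, stat_out, cut_out, method)


def group_by_model(fits: dict, parameter_tolerance: float) -> list:
    """Partition components into classes of same model kind/orders with
    parameter vectors within tolerance (max-norm), transitively closed by
    single linkage on the tolerance graph."""
    if parameter_tolerance <= 0:
        raise OmicsInputError("parameter_tolerance must be > 0")
    comps = list(fits)
    parent = list(range(len(comps)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(len(comps)):
        fi = fits[comps[i]]
        for j in range(i + 1, len(comps)):
            fj = fits[comps[j]]
            if (fi.kind, fi.p, fi.q) != (fj.kind, fj.p, fj.q):
                continue
            if fi.params.size == 0 and fj.params.size == 0:
                union(i, j)
            elif fi.params.size == fj.params.size and np.max(
                np.abs(fi.params - fj.params), initial=0.0
            ) < parameter_tolerance:
                union(i, j)
    classes: dict = {}
    for i, comp in enumerate(comps):
        classes.setdefault(find(i), []).append(comp)
    return [sorted(v) for _, v in sorted(classes.items())]
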