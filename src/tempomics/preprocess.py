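"""Normalization and filtering of omics measurements.

Implements the preprocessing steps of the time-course workflow: tagging of
low values as missing, missing-fraction filtering of extracted series,
across-sample quantile normalization (with a missing-data-aware variant),
Box-Cox power transformation with maximum-likelihood choice of the
exponent, normalization of each series relative to a reference time point,
and a generic element-wise function applier.

Quantile normalization with missing values: each sample's sorted observed
values sit at plotting positions ``(k - 0.5)/m``; the reference quantile
function is the across-sample mean of the per-sample (linearly
interpolated) empirical quantile functions, and each sample's values are
replaced by the reference evaluated at the sample's own positions.  With
complete, equally sized samples this reduces to the textbook method
(rank-wise means).  Ties within a sample receive the mean of the reference
values they span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .omics import (
    MISSING,
    ComponentEntry,
    OmicsInputError,
    OmicsObject,
    TimePoint,
    TimeSeriesSet,
)

__all__ = [
    "FilterReport",
    "BoxCoxFit",
    "tag_low_values",
    "filter_missing_fraction",
    "quantile_normalize",
    "boxcox_transform",
    "boxcox_fit_transform",
    "normalize_to_reference",
    "applier",
]


@dataclass
class FilterReport:
    """What a filtering/tagging step did: counts, removals, thresholds."""

    tagged_low: int = 0
    removed_components: list = field(default_factory=list)  # (id, reason)
    thresholds: dict = field(default_factory=dict)


def tag_low_values(
    obj: OmicsObject, channel: int, threshold: float
) -> tuple[OmicsObject, FilterReport]:
    """Replace values below ``threshold`` with MISSING; metadata untouched."""
    if not np.isfinite(threshold) and threshold != -np.inf:
        raise OmicsInputError("threshold must be finite or -inf")
    out = obj.copy()
    report = FilterReport(thresholds={"low": threshold, "channel": channel})
    for comps in out.samples.values():
        for e in comps.values():
            if channel < len(e.measurements):
                v = e.measurements[channel]
                if v is not MISSING and v < threshold:
                    e.measurements[channel] = MISSING
                    report.tagged_low += 1
    return out, report


def filter_missing_fraction(
    tss: TimeSeriesSet, max_missing_fraction: float
) -> tuple[TimeSeriesSet, FilterReport]:
    """Drop components whose missing fraction exceeds the cutoff."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise OmicsInputError(
            f"max_missing_fraction must be in [0, 1], got {max_missing_fraction}"
        )
    report = FilterReport(thresholds={"max_missing_fraction": max_missing_fraction})
    kept = {}
    for comp, vec in tss.series.items():
        frac = float(np.mean(np.isnan(vec)))
        if frac > max_missing_fraction:
            report.removed_components.append(
                (comp, f"missing fraction {frac:.3f} > {max_missing_fraction}")
            )
        else:
            kept[comp] = vec.copy()
    return TimeSeriesSet(list(tss.times), kept, tss.channel), report


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


def _mean_quantile_function(observed_per_sample):
    """Across-sample mean empirical quantile function Q̄(p).

    Each sample contributes Q_s, the linear interpolant of its sorted
    values at plotting positions (k-0.5)/m, held constant outside
    [p_1, p_m].
    """
    interps = []
    for vals in observed_per_sample:
        v = np.sort(vals)
        m = len(v)
        pos = (np.arange(1, m + 1) - 0.5) / m
        interps.append((pos, v))

    def qbar(p):
        p = np.asarray(p, dtype=float)
        return np.mean([np.interp(p, pos, v) for pos, v in interps], axis=0)

    return qbar


def quantile_normalize(obj: OmicsObject, channel: int = 0) -> OmicsObject:
    """Across-sample quantile normalization of one measurement channel.

    Missing entries stay missing; observed values are mapped through the
    across-sample mean quantile function (see module docstring).
    """
    if obj.n_samples < 2:
        raise OmicsInputError("quantile normalization needs at least 2 samples")
    observed = {}
    for label, comps in obj.samples.items():
        vals = [
            e.measurements[channel]
            for e in comps.values()
            if channel < len(e.measurements) and e.measurements[channel] is not MISSING
        ]
        if not vals:
            raise OmicsInputError(f"sample {label!r} has no observed values")
        observed[label] = np.array(vals, dtype=float)
    qbar = _mean_quantile_function(list(observed.values()))
    out = obj.copy()
    for label, comps in out.samples.items():
        vals = observed[label]
        m = len(vals)
        order = np.argsort(vals, kind="stable")
        pos = (np.arange(1, m + 1) - 0.5) / m
        ref = qbar(pos)  # reference values for ranks 1..m
        # ties: average the reference values spanned by each tied group
        mapped = np.empty(m)
        sorted_vals = vals[order]
        i = 0
        while i < m:
            j = i
            while j + 1 < m and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            mapped[i : j + 1] = ref[i : j + 1].mean()
            i = j + 1
        new_sorted_to_orig = np.empty(m)
        new_sorted_to_orig[order] = mapped
        k = 0
        for e in comps.values():
            if channel < len(e.measurements) and e.measurements[channel] is not MISSING:
                e.measurements[channel] = float(new_sorted_to_orig[k])
                k += 1
    return out


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


@dataclass
class BoxCoxFit:
    """Fitted Box-Cox exponent, pre-transform shift, and log-likelihood."""

    lmbda: float
    shift: float
    loglik: float


def boxcox_transform(x: np.ndarray, lmbda: float) -> np.ndarray:
    """(x^λ - 1)/λ for λ != 0, ln x for λ = 0 (the continuous limit)."""
    x = np.asarray(x, dtype=float)
    if lmbda == 0.0:
        return np.log(x)
    return (np.power(x, lmbda) - 1.0) / lmbda


def boxcox_fit_transform(
    values,
    lmbda: float | None = None,
    interval: tuple = (-5.0, 5.0),
) -> tuple[BoxCoxFit, np.ndarray]:
    """Box-Cox transform with the exponent chosen by profile likelihood.

    Nonpositive inputs trigger an automatic shift of ``1e-3 - min`` so all
    shifted values are strictly positive; the shift is recorded in the fit.
    Pass ``lmbda`` to skip estimation and transform at a fixed exponent.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise OmicsInputError("Box-Cox needs >= 2 finite values")
    if np.ptp(x) == 0:
        raise OmicsInputError("Box-Cox likelihood is degenerate on constant input")
    shift = 0.0
    if x.min() <= 0:
        shift = 1e-3 - x.min()
    xs = x + shift
    if lmbda is None:
        res = optimize.minimize_scalar(
            lambda lm: -stats.boxcox_llf(lm, xs),
            bounds=interval,
            method="bounded",
            options={"xatol": 1e-6},
        )
        lmbda = float(res.x)
    fit = BoxCoxFit(lmbda=float(lmbda), shift=shift, loglik=float(stats.boxcox_llf(lmbda, xs)))
    return fit, boxcox_transform(xs, fit.lmbda)


# ---------------------------------------------------------------------------
# Reference-point normalization
# ---------------------------------------------------------------------------


def normalize_to_reference(
    tss: TimeSeriesSet, reference
) -> tuple[TimeSeriesSet, FilterReport]:
    """Subtract each series' value at the reference time point.

    Operates on log-scale values, so subtraction corresponds to fold change
    relative to the reference.  Components missing at the reference are
    removed and reported; other missing entries propagate.
    """
    if isinstance(reference, TimePoint):
        ref_time = reference.time
    else:
        ref_time = float(reference)
    tv = tss.time_values
    idx = np.where(np.isclose(tv, ref_time))[0]
    if idx.size == 0:
        raise OmicsInputError(
            f"reference time {ref_time} not in grid; available: {tv.tolist()}"
        )
    i = int(idx[0])
    report = FilterReport(thresholds={"reference_time": ref_time})
    kept = {}
    for comp, vec in tss.series.items():
        if np.isnan(vec[i]):
            report.removed_components.append((comp, "missing at reference"))
        else:
            kept[comp] = vec - vec[i]
    return TimeSeriesSet(list(tss.times), kept, tss.channel), report


# ---------------------------------------------------------------------------
# Generic applier
# ---------------------------------------------------------------------------


def applier(obj: OmicsObject, fn, scope: str = "measurements") -> OmicsObject:
    """Apply ``fn`` element-wise across the object; MISSING passes through.

    Structure (sample/component keys, list lengths, MISSING placement) is
    preserved exactly.  Exceptions from ``fn`` are re-raised with the
    (sample, component) coordinates attached.
    """
    if scope not in ("measurements", "metadata"):
        raise OmicsInputError(f"unknown scope {scope!r}")
    out = obj.copy()
    for label, comps in out.samples.items():
        for comp, e in comps.items():
            target = e.measurements if scope == "measurements" else e.metadata
            for i, v in enumerate(target):
                if v is MISSING:
                    continue
                try:
                    target[i] = fn(v)
                except Exception as exc:
                    raise OmicsInputError(
                        f"applier function failed at (sample={label!r}, "
                        f"component={comp!r}, index={i}): {exc}"
                    ) from exc
    return out
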