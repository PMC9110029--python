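"""Trace fitting and step-number selection for transport assays.

Two fitting layers are provided.  The empirical *lag + single exponential*
model summarises a trace by its amplitude A, lag (the minimum time before
signal appears, equal to the sum of the transport steps' time constants) and
an exponential rate λ.  The mechanistic layer fits the sequential-step ODE
model of :mod:`sectransport.kinetic_model` to traces at each candidate step
number n, minimising the root-mean-square deviation (RMSD) between model and
data; the RMSD profile, normalised to its scan minimum, selects the best n.
A plateau in that profile (RMSD keeps falling and flattens out as n grows)
means the steps are too fast and numerous to resolve, and no unique n is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, FitError, ParameterError
from .kinetic_model import (
    AssayConditions,
    RateParameters,
    SegmentedRateParameters,
    simulate_segmented_trace,
    simulate_trace,
)

__all__ = [
    "TransportTrace",
    "LagExpFit",
    "StepScanResult",
    "VariantFitResult",
    "fit_lag_exponential",
    "normalized_rmsd",
    "average_traces",
    "scan_steps",
    "fit_variant",
    "DEFAULT_N_RANGE",
]

#: Default candidate step numbers for the RMSD scan.
DEFAULT_N_RANGE = range(1, 21)

# Multi-start grid for the per-step rate (min^-1): local optima at wrong n
# are common, so every fit is restarted from log-spaced initial rates.
_KSTEP_STARTS = np.geomspace(0.5, 50.0, 5)


@dataclass
class TransportTrace:
    """One replicate's luminescence time course with metadata."""

    times: np.ndarray
    signal: np.ndarray
    construct: str = "unknown"
    condition: str = "unknown"
    replicate: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise DataError("times and signal must be 1-D arrays of equal length")
        if len(self.times) < 20:
            raise DataError("trace must have at least 20 points")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise DataError("signal contains non-finite values")


@dataclass(frozen=True)
class LagExpFit:
    """Parameters of the lag + single-exponential trace model."""

    A: float
    lag: float
    lam: float
    residual_rmsd: float


@dataclass
class StepScanResult:
    """Normalized RMSD as a function of candidate step number n."""

    n_values: np.ndarray
    rmsd: np.ndarray
    normalized_rmsd: np.ndarray
    best_n: Optional[int]
    params: list  # per-n dict of fitted parameters
    failed: list = field(default_factory=list)
    plateau: bool = False
    replicate_mode: str = "average"

    def params_at(self, n: int) -> dict:
        idx = int(np.flatnonzero(self.n_values == n)[0])
        return self.params[idx]

    @property
    def best_params(self) -> Optional[dict]:
        return None if self.best_n is None else self.params_at(self.best_n)


@dataclass
class VariantFitResult:
    """Two-segment fit of a variant construct against fixed native kinetics."""

    scan: StepScanResult
    native: RateParameters
    brightness_rel: float

    @property
    def best_n_var(self) -> Optional[int]:
        return self.scan.best_n

    @property
    def best_params(self) -> Optional[dict]:
        return self.scan.best_params


def _lag_exp_model(t, A, lag, lam):
    return np.where(t < lag, 0.0, A * (1.0 - np.exp(-lam * np.maximum(t - lag, 0.0))))


def fit_lag_exponential(trace: TransportTrace) -> LagExpFit:
    """Least-squares fit of signal(t) = A (1 - exp(-λ(t - lag))) for t >= lag.

    Initialisation is geometric: lag from the 10%-of-maximum crossing, λ from
    the 10-90% rise time — robust for sigmoidal transport traces.
    """
    t, y = trace.times, trace.signal
    ymax = float(np.max(y))
    if ymax <= 0 or ymax - float(np.min(y)) < 1e-12:
        raise FitError("flat trace: amplitude indistinguishable from zero")
    t10 = t[np.argmax(y >= 0.1 * ymax)]
    t90 = t[np.argmax(y >= 0.9 * ymax)]
    lam0 = 1.0 / max(t90 - t10, t[1] - t[0])
    x0 = np.array([ymax, max(t10, 1e-6), lam0])
    res = least_squares(
        lambda p: _lag_exp_model(t, *p) - y,
        x0,
        bounds=([1e-12, 0.0, 1e-9], [np.inf, t[-1], np.inf]),
        method="trf",
    )
    if not res.success:
        raise FitError(f"lag+exponential fit did not converge: {res.message}")
    A, lag, lam = res.x
    return LagExpFit(A=float(A), lag=float(lag), lam=float(lam),
                     residual_rmsd=float(np.sqrt(np.mean(res.fun**2))))


def normalized_rmsd(model_curve, data_curve) -> float:
    """Root-mean-square deviation between two aligned curves."""
    m = np.asarray(model_curve, dtype=float)
    d = np.asarray(data_curve, dtype=float)
    if m.shape != d.shape:
        raise DataError(f"curve length mismatch: {m.shape} vs {d.shape}")
    return float(np.sqrt(np.mean((m - d) ** 2)))


def average_traces(traces: Sequence[TransportTrace]) -> TransportTrace:
    """Pointwise replicate average; all traces must share one time grid."""
    if not traces:
        raise DataError("no traces to average")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise DataError("traces do not share a common time grid")
    sig = np.mean([tr.signal for tr in traces], axis=0)
    first = traces[0]
    return TransportTrace(times=t0.copy(), signal=sig, construct=first.construct,
                          condition=first.condition, replicate=-1)


def _conditions_for(times: np.ndarray, cond: Optional[AssayConditions]) -> tuple:
    """Assay conditions on the data grid; ensures simulation starts at t=0."""
    base = cond or AssayConditions()
    if times[0] == 0.0:
        return AssayConditions(base.substrate_conc, base.site_conc, times), slice(None)
    grid = np.concatenate([[0.0], times])
    return AssayConditions(base.substrate_conc, base.site_conc, grid), slice(1, None)


def _profile_brightness(shape: np.ndarray, data: np.ndarray) -> float:
    """Optimal signal scale for a fixed-shape model curve (linear profiling)."""
    denom = float(shape @ shape)
    if denom <= 0:
        return 1.0
    return max(float(shape @ data) / denom, 1e-12)


def _fit_single_n(n, t, y, fixed, cond, warm=None):
    """Best (k_step, k_fail, brightness) at one candidate n; multi-start.

    ``warm`` optionally provides (k_step, k_fail) from the neighbouring n of
    a scan, rescaled so the total transit time is preserved — this keeps the
    RMSD profile smooth where the steps are too fast to resolve.
    """
    acond, sl = _conditions_for(t, cond)

    def model_shape(k_step, k_fail):
        p = RateParameters(n=n, k_step=k_step, k_fail=k_fail, brightness=1.0, **fixed)
        return simulate_trace(p, acond).signal[sl]

    def residuals(theta):
        shape = model_shape(np.exp(theta[0]), np.exp(theta[1]))
        b = _profile_brightness(shape, y)
        return b * shape - y

    starts = [np.log([k0, 0.3]) for k0 in _KSTEP_STARTS]
    if warm is not None:
        starts.insert(0, np.log(np.maximum(warm, [1e-3, 1e-6])))
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(np.log([1e-3, 1e-6]), np.log([1e4, 1e3])),
                method="trf",
                xtol=1e-10,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise FitError(f"all optimizer starts failed at n={n}")
    k_step, k_fail = np.exp(best.x)
    shape = model_shape(k_step, k_fail)
    b = _profile_brightness(shape, y)
    rmsd = normalized_rmsd(b * shape, y)
    return {"n": n, "k_step": float(k_step), "k_fail": float(k_fail),
            "brightness": float(b), "k_block": fixed.get("k_block"), "rmsd": rmsd}


def _finalize_scan(n_values, rmsd, params, failed, mode) -> StepScanResult:
    n_values = np.asarray(n_values)
    rmsd = np.asarray(rmsd, dtype=float)
    ok = np.isfinite(rmsd)
    if not ok.any():
        raise FitError("every candidate n failed to fit")
    rmin = float(np.nanmin(rmsd))
    if rmin == 0.0:  # exact fit: normalized profile is 1 there, inf elsewhere
        with np.errstate(divide="ignore"):
            norm = np.where(rmsd == 0.0, 1.0, np.inf)
    else:
        norm = rmsd / rmin
    # smallest n within 0.1% of the scan minimum
    candidates = n_values[ok & (norm <= 1.001)]
    best_n = int(candidates.min())
    # plateau: profile still flat/decreasing at the top of the scan range —
    # the step number is not resolvable (steps too fast to count)
    plateau = False
    if ok[-1] and norm[-1] <= 1.01 and len(norm) >= 5:
        tail = norm[-5:]
        plateau = bool(np.all(np.diff(tail) <= 1e-3))
    if plateau:
        best_n = None
    return StepScanResult(n_values=n_values, rmsd=rmsd, normalized_rmsd=norm,
                          best_n=best_n, params=params, failed=failed,
                          plateau=plateau, replicate_mode=mode)


def scan_steps(
    traces: Sequence[TransportTrace] | TransportTrace,
    fixed: Optional[Mapping[str, float]] = None,
    n_range: Iterable[int] = DEFAULT_N_RANGE,
    replicate_mode: str = "average",
    cond: Optional[AssayConditions] = None,
) -> StepScanResult:
    """RMSD scan over candidate step numbers for the single-segment model.

    At each n the model is fit to the data with k_step, k_fail and
    brightness floating and k_block/k_on/k_off fixed (defaults: the
    previously determined assay constants).  The returned profile is
    normalised so its minimum is exactly 1; ``best_n`` is the smallest n
    within 0.1% of that minimum, or None when the profile plateaus.

    ``replicate_mode``: "average" fits the replicate-averaged trace;
    "per_replicate" fits each trace and averages RMSD and parameters
    (their SEM is reported under ``param_sem``).
    """
    if isinstance(traces, TransportTrace):
        traces = [traces]
    n_values = sorted(set(int(n) for n in n_range))
    if not n_values:
        raise ParameterError("n_range is empty")
    fixed = dict(fixed or {})
    for key, val in RateParameters(n=1, k_step=1.0).to_dict().items():
        if key in ("k_block", "k_on", "k_off"):
            fixed.setdefault(key, val)
    extra = set(fixed) - {"k_block", "k_on", "k_off"}
    if extra:
        raise ParameterError(f"unsupported fixed parameters: {sorted(extra)}")

    if replicate_mode == "average":
        fit_targets = [average_traces(traces)]
    elif replicate_mode == "per_replicate":
        fit_targets = list(traces)
    else:
        raise ParameterError(f"unknown replicate_mode {replicate_mode!r}")

    rmsd, params, failed = [], [], []
    prev = None  # warm start carried along the scan
    for n in n_values:
        per_target = []
        try:
            for tr in fit_targets:
                warm = None
                if prev is not None:
                    warm = (prev["k_step"] * n / prev["n"], prev["k_fail"])
                per_target.append(_fit_single_n(n, tr.times, tr.signal, fixed, cond, warm))
            prev = per_target[0]
        except FitError:
            failed.append(n)
            rmsd.append(np.nan)
            params.append(None)
            continue
        entry = {k: float(np.mean([p[k] for p in per_target]))
                 for k in ("k_step", "k_fail", "brightness")}
        entry["n"] = n
        entry["k_block"] = fixed["k_block"]
        if len(per_target) > 1:
            entry["param_sem"] = {
                k: float(np.std([p[k] for p in per_target], ddof=1) / np.sqrt(len(per_target)))
                for k in ("k_step", "k_fail", "brightness")
            }
        rmsd.append(float(np.mean([p["rmsd"] for p in per_target])))
        params.append(entry)
    return _finalize_scan(n_values, rmsd, params, failed, replicate_mode)


def _fit_variant_n(n_var, t, y, native, brightness, float_k_block, cond, warm=None):
    """Best variable-segment rates at one candidate n_var."""
    acond, sl = _conditions_for(t, cond)

    def model(k_step_var, k_fail_var, k_block_var):
        p = SegmentedRateParameters(
            native=native, n_var=n_var, k_step_var=k_step_var,
            k_fail_var=k_fail_var, k_block_var=k_block_var, brightness=brightness,
        )
        return simulate_segmented_trace(p, acond).signal[sl]

    k_block0 = native.k_block
    if float_k_block:
        def residuals(theta):
            return model(*np.exp(theta)) - y
        lo, hi = np.log([1e-3, 1e-6, 1e-6]), np.log([1e4, 1e3, 1e3])
        x0_tail = np.log([0.3, max(k_block0, 1e-3)])
    else:
        def residuals(theta):
            return model(np.exp(theta[0]), np.exp(theta[1]), k_block0) - y
        lo, hi = np.log([1e-3, 1e-6]), np.log([1e4, 1e3])
        x0_tail = np.log([0.3])

    starts = [np.concatenate([[np.log(k0)], x0_tail]) for k0 in _KSTEP_STARTS]
    if warm is not None:
        starts.insert(0, np.log(np.maximum(warm, 1e-6)))
    best = None
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise FitError(f"all optimizer starts failed at n_var={n_var}")
    vals = np.exp(best.x)
    out = {"n_var": n_var, "k_step_var": float(vals[0]), "k_fail_var": float(vals[1]),
           "k_block_var": float(vals[2]) if float_k_block else float(k_block0),
           "brightness": float(brightness),
           "rmsd": float(np.sqrt(2 * best.cost / len(y)))}
    return out


def fit_variant(
    traces: Sequence[TransportTrace] | TransportTrace,
    native: RateParameters,
    brightness_rel: float = 1.0,
    n_var_range: Iterable[int] = DEFAULT_N_RANGE,
    float_k_block: bool = False,
    replicate_mode: str = "average",
    cond: Optional[AssayConditions] = None,
) -> VariantFitResult:
    """Scan n_var for a variant construct with native kinetics held fixed.

    The native segment (initiation, flanking domains, tag crossing) comes
    from a prior :func:`scan_steps` on the short-topology construct and is
    never altered.  Brightness is fixed to the variant's measured value
    relative to the native construct; k_step_var and k_fail_var float, and
    k_block_var additionally floats when ``float_k_block`` is set.
    """
    if isinstance(traces, TransportTrace):
        traces = [traces]
    if brightness_rel <= 0:
        raise ParameterError("brightness_rel must be > 0")
    n_values = sorted(set(int(n) for n in n_var_range))
    if not n_values or min(n_values) < 1:
        raise ParameterError("n_var_range must contain positive integers")
    brightness = brightness_rel * native.brightness

    if replicate_mode == "average":
        fit_targets = [average_traces(traces)]
    elif replicate_mode == "per_replicate":
        fit_targets = list(traces)
    else:
        raise ParameterError(f"unknown replicate_mode {replicate_mode!r}")

    rmsd, params, failed = [], [], []
    keys = ("k_step_var", "k_fail_var", "k_block_var")
    prev = None
    for n_var in n_values:
        per_target = []
        try:
            for tr in fit_targets:
                warm = None
                if prev is not None:
                    warm = [prev["k_step_var"] * n_var / prev["n_var"], prev["k_fail_var"]]
                    if float_k_block:
                        warm.append(prev["k_block_var"])
                per_target.append(
                    _fit_variant_n(n_var, tr.times, tr.signal, native,
                                   brightness, float_k_block, cond, warm))
            prev = per_target[0]
        except FitError:
            failed.append(n_var)
            rmsd.append(np.nan)
            params.append(None)
            continue
        entry = {k: float(np.mean([p[k] for p in per_target])) for k in keys}
        entry["n_var"] = n_var
        entry["brightness"] = float(brightness)
        if len(per_target) > 1:
            entry["param_sem"] = {
                k: float(np.std([p[k] for p in per_target], ddof=1) / np.sqrt(len(per_target)))
                for k in keys
            }
        rmsd.append(float(np.mean([p["rmsd"] for p in per_target])))
        params.append(entry)
    scan = _finalize_scan(n_values, rmsd, params, failed, replicate_mode)
    return VariantFitResult(scan=scan, native=native, brightness_rel=brightness_rel)
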