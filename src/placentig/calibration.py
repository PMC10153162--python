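"""CaliPro-style iterative Latin-hypercube calibration of the transfer model.

The 11 optimized parameters (three rate flows, three receptor endpoints, five
volumes) are calibrated against gestational-age-binned fetal IgG measurements
(cordocentesis-style mean ± SD per subclass).  Each iteration draws a Latin
hypercube from the current ranges, simulates every draw, applies the pass
criterion, and shrinks the ranges to the passing sets' 1st-99th percentile
envelope; iteration stops once the pass fraction reaches the termination
threshold.  Unlike least-squares fitting, the product is a *range* of
parameter sets that recapitulate the data, not a single point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .parameters import OPTIMIZED_PARAMETERS, SUBCLASSES, TABLE1_RANGES, TransferParameters
from .transfer import ReceptorVariant, SimulationResult, simulate_transfer


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CordocentesisDataset:
    """Gestational-age-binned fetal IgG measurements, per subclass.

    ``bins`` has columns subclass, time_weeks, mean_M, sd_M, n; bin times are
    strictly increasing within each subclass, with at least a first and a
    final bin.
    """

    bins: pd.DataFrame

    def __post_init__(self):
        required = {"subclass", "time_weeks", "mean_M", "sd_M", "n"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        for sub, grp in self.bins.groupby("subclass"):
            t = grp["time_weeks"].to_numpy()
            if len(t) < 2:
                raise ValueError(f"{sub}: need at least first and final bins")
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"{sub}: bin times must be strictly increasing")
        if (self.bins["sd_M"] < 0).any():
            raise ValueError("standard deviations must be non-negative")

    @property
    def first_time(self) -> float:
        return float(self.bins["time_weeks"].min())

    @property
    def final_time(self) -> float:
        return float(self.bins["time_weeks"].max())

    def subclass_bins(self, subclass: str) -> pd.DataFrame:
        return self.bins[self.bins["subclass"] == subclass].sort_values("time_weeks")

    @classmethod
    def from_csv(cls, path) -> "CordocentesisDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.bins.to_csv(path, index=False)


@dataclass(frozen=True)
class ParameterRanges:
    """Lower/upper bounds for the 11 optimized transfer parameters."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...] = OPTIMIZED_PARAMETERS

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or len(self.lower) != len(self.names):
            raise ValueError("bounds must match the parameter names")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bounds must not exceed upper bounds")

    @classmethod
    def table1(cls) -> "ParameterRanges":
        lo, hi = zip(*(TABLE1_RANGES[p] for p in OPTIMIZED_PARAMETERS))
        return cls(np.array(lo), np.array(hi))

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterRanges":
        unknown = set(d) - set(OPTIMIZED_PARAMETERS)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(OPTIMIZED_PARAMETERS) - set(d)
        if missing:
            raise KeyError(f"missing parameter(s): {sorted(missing)}")
        lo, hi = zip(*(d[p] for p in OPTIMIZED_PARAMETERS))
        return cls(np.array(lo), np.array(hi))

    def to_dict(self) -> dict:
        return {n: [float(l), float(u)]
                for n, l, u in zip(self.names, self.lower, self.upper)}

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return (values >= self.lower) & (values <= self.upper)

    def expand(self, fraction: float) -> "ParameterRanges":
        """Widen each range symmetrically by *fraction* of its width."""
        half = 0.5 * fraction * (self.upper - self.lower)
        return ParameterRanges(np.maximum(self.lower - half, 0.0),
                               self.upper + half, self.names)


# ---------------------------------------------------------------------------
# Sampling and pass criterion
# ---------------------------------------------------------------------------


def lhs_sample(ranges: ParameterRanges, n: int, seed: int) -> np.ndarray:
    """Latin hypercube sample (n, n_params) with uniform marginals.

    Each dimension is stratified into n equal slices with exactly one draw per
    slice.  Degenerate dimensions (lower == upper) are held constant with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    d = len(ranges.names)
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    unit = sampler.random(n)
    width = ranges.upper - ranges.lower
    degenerate = width == 0
    if degenerate.any():
        names = [ranges.names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"degenerate range(s) held constant: {names}")
    return ranges.lower + unit * width


def pass_criterion(sim: SimulationResult, data: CordocentesisDataset) -> bool:
    """CaliPro pass rule applied per subclass (all must pass).

    A simulation passes a subclass if its trajectory lies at or below
    mean + 1*SD at the first bin time, and within 1.5*SD of the mean at the
    final bin time.
    """
    t0, t1 = data.first_time, data.final_time
    if sim.t[0] > t0 or sim.t[-1] < t1:
        raise ValueError("simulation does not cover the first and final bins")
    fetal0 = sim.fetal_at(t0)
    fetal1 = sim.fetal_at(t1)
    for j, sub in enumerate(SUBCLASSES):
        grp = data.subclass_bins(sub)
        if grp.empty:
            raise ValueError(f"dataset lacks bins for {sub}")
        first, final = grp.iloc[0], grp.iloc[-1]
        if fetal0[j] > first["mean_M"] + first["sd_M"]:
            return False
        if abs(fetal1[j] - final["mean_M"]) > 1.5 * final["sd_M"]:
            return False
    return True


# ---------------------------------------------------------------------------
# Calibrator
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Outcome of an iterative calibration run."""

    ranges: ParameterRanges
    passing_sets: np.ndarray          # (n_pass, 11)
    pass_fractions: list[float]       # one per iteration
    seed: int
    converged: bool


class CaliProCalibrator(BaseEstimator):
    """Iterative LHS pass/fail calibrator for the placental transfer model.

    Parameters
    ----------
    n_per_iter : LHS draws per iteration.
    termination_fraction : stop once this fraction of draws passes.
    max_iter : iteration cap (non-convergence is flagged, not an error).
    percentile_envelope : (low, high) percentiles of the passing sets used to
        shrink the ranges between iterations.
    base_params : template providing the non-optimized parameters.

    Attributes (after :meth:`fit`)
    ------------------------------
    ranges_ : refined ParameterRanges
    passing_sets_ : passing parameter sets from the last iteration
    pass_fractions_ : per-iteration pass fraction
    result_ : the full CalibrationResult
    """

    def __init__(self, n_per_iter: int = 200, termination_fraction: float = 0.95,
                 max_iter: int = 10, percentile_envelope: tuple = (1.0, 99.0),
                 base_params: TransferParameters | None = None,
                 variant: ReceptorVariant = ReceptorVariant.EC_BOTH,
                 rtol: float = 1e-8, atol: float = 1e-12):
        self.n_per_iter = n_per_iter
        self.termination_fraction = termination_fraction
        self.max_iter = max_iter
        self.percentile_envelope = percentile_envelope
        self.base_params = base_params
        self.variant = variant
        self.rtol = rtol
        self.atol = atol

    def _simulate(self, values: np.ndarray, final_time: float) -> SimulationResult:
        base = self.base_params or TransferParameters()
        params = base.with_optimized(values)
        stop = min(max(final_time + 0.5, final_time), 42.0)
        return simulate_transfer(params, self.variant, t_span=(0.0, stop),
                                 rtol=self.rtol, atol=self.atol)

    def fit(self, data: CordocentesisDataset, initial: ParameterRanges | None = None,
            seed: int = 0) -> "CaliProCalibrator":
        ranges = initial if initial is not None else ParameterRanges.table1()
        rng_seed = int(seed)
        fractions: list[float] = []
        passing = np.empty((0, len(ranges.names)))
        converged = False
        expanded_once = False
        it = 0
        while it < self.max_iter:
            sample = lhs_sample(ranges, self.n_per_iter, seed=rng_seed + it)
            ok = np.zeros(len(sample), dtype=bool)
            for i, row in enumerate(sample):
                sim = self._simulate(row, data.final_time)
                ok[i] = pass_criterion(sim, data)
            frac = float(ok.mean())
            fractions.append(frac)
            passing = sample[ok]
            if not ok.any():
                if expanded_once:
                    raise RuntimeError(
                        "calibration failed: no passing sets after expansion")
                warnings.warn("no passing sets; expanding ranges by 10%")
                ranges = ranges.expand(0.10)
                expanded_once = True
                it += 1
                continue
            if frac >= self.termination_fraction:
                converged = True
                break
            lo_p, hi_p = self.percentile_envelope
            new_lo = np.percentile(passing, lo_p, axis=0)
            new_hi = np.percentile(passing, hi_p, axis=0)
            ranges = ParameterRanges(new_lo, new_hi, ranges.names)
            it += 1

        self.ranges_ = ranges
        self.passing_sets_ = passing
        self.pass_fractions_ = fractions
        self.result_ = CalibrationResult(ranges=ranges, passing_sets=passing,
                                         pass_fractions=fractions, seed=rng_seed,
                                         converged=converged)
        return self


def calibrate(data: CordocentesisDataset,
              initial: ParameterRanges | None = None,
              n_per_iter: int = 200,
              termination_fraction: float = 0.95,
              max_iter: int = 10,
              seed: int = 0,
              **kwargs) -> CalibrationResult:
    """Functional wrapper around :class:`CaliProCalibrator`."""
    cal = CaliProCalibrator(n_per_iter=n_per_iter,
                            termination_fraction=termination_fraction,
                            max_iter=max_iter, **kwargs)
    cal.fit(data, initial=initial, seed=seed)
    return cal.result_
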