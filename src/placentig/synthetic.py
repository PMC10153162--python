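"""Synthetic fixture-data generators.

Every dataset the analysis pipeline consumes can be generated here from known
ground-truth parameters: cordocentesis-style gestational-age-binned fetal IgG
(for calibration), Transwell transcytosis time series (for the in vitro
model), and maternal booster-response curves (for the immunization model).
Noise is Gaussian on concentrations with SD proportional to the mean
(default CV 10%), truncated at zero — mimicking how the source datasets are
reported (per-bin mean ± SD) without redistributing any study data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CordocentesisDataset
from .huvec import simulate_transwell
from .immunization import simulate_booster
from .parameters import (
    SUBCLASSES,
    HuvecParameters,
    ImmunizationParameters,
    TransferParameters,
)
from .transfer import simulate_transfer

#: default gestational-age bins, weeks (first and final anchor the pass rule)
DEFAULT_BINS = (17.0, 22.0, 27.0, 32.0, 36.0, 41.0)

#: default Transwell sampling times, minutes
TRANSWELL_TIMES = (15.0, 30.0, 60.0, 120.0)


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground truth plus sampling/noise description for one synthetic dataset."""

    cv: float = 0.1            # noise SD as a fraction of the mean
    n: int = 107               # replicates per bin / time point
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noisy_replicates(rng: np.random.Generator, mean: float, cv: float,
                      n: int) -> np.ndarray:
    """n Gaussian draws around *mean* with SD cv*mean, truncated at zero."""
    if cv == 0:
        return np.full(n, mean)
    return np.clip(rng.normal(mean, cv * mean, size=n), 0.0, None)


def generate_cordocentesis(
    design: SyntheticDesign = SyntheticDesign(),
    truth: TransferParameters | None = None,
    bins=DEFAULT_BINS,
) -> CordocentesisDataset:
    """Binned per-subclass fetal IgG mean/SD/n from a ground-truth simulation."""
    truth = truth or TransferParameters()
    bins = np.asarray(bins, dtype=float)
    if np.any(bins < 0) or np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be non-negative and strictly increasing")
    sim = simulate_transfer(truth, t_span=(0.0, min(float(bins[-1]) + 0.5, 42.0)))
    rng = design.rng()
    rows = []
    for j, sub in enumerate(SUBCLASSES):
        for t in bins:
            level = float(sim.fetal_at(t)[j])
            reps = _noisy_replicates(rng, level, design.cv, design.n)
            sd = float(reps.std(ddof=1)) if design.n > 1 else design.cv * level
            rows.append((sub, t, float(reps.mean()), sd, design.n))
    return CordocentesisDataset(pd.DataFrame(
        rows, columns=["subclass", "time_weeks", "mean_M", "sd_M", "n"]))


def generate_transwell_series(
    design: SyntheticDesign = SyntheticDesign(cv=0.1, n=3),
    truth: HuvecParameters | None = None,
    conditions=((0.0, 0.5), (0.0, 0.125)),
    times=TRANSWELL_TIMES,
    permeability_baseline: float = 10.0,
    inject_outlier: bool = False,
) -> pd.DataFrame:
    """Transwell measurement table for (IgG1, IgG4) apical dose conditions.

    Columns: condition_id, replicate, time_min, igg1_mg_ml, igg4_mg_ml,
    fitc_perm_pct.  ``inject_outlier`` inflates one replicate's permeability
    tenfold so the 3-SD exclusion rule has something to catch.
    """
    truth = truth or HuvecParameters()
    rng = design.rng()
    rows = []
    for cid, (d1, d4) in enumerate(conditions):
        res = simulate_transwell(truth, igg1_apical=d1, igg4_apical=d4)
        for rep in range(design.n):
            perm = permeability_baseline * (1 + 0.05 * rng.standard_normal())
            for t in times:
                t1, t4 = res.transcytosed_mg_ml(t)
                rows.append((
                    cid, rep, t,
                    float(_noisy_replicates(rng, t1, design.cv, 1)[0]),
                    float(_noisy_replicates(rng, t4, design.cv, 1)[0]),
                    perm,
                ))
    tab = pd.DataFrame(rows, columns=["condition_id", "replicate", "time_min",
                                      "igg1_mg_ml", "igg4_mg_ml",
                                      "fitc_perm_pct"])
    if inject_outlier:
        last = (tab["condition_id"] == tab["condition_id"].max()) & \
               (tab["replicate"] == tab["replicate"].max())
        tab.loc[last, "fitc_perm_pct"] *= 10.0
    return tab


def generate_booster_series(
    design: SyntheticDesign = SyntheticDesign(cv=0.15, n=105),
    truth: ImmunizationParameters | None = None,
    times=(0.0, 7.0, 14.0, 21.0, 28.0, 42.0, 60.0, 90.0),
) -> pd.DataFrame:
    """Maternal α-PT IgG time series (response-model units) after one booster.

    Columns: time_days, mean, sd, n.
    """
    truth = truth or ImmunizationParameters()
    resp = simulate_booster(truth, duration_days=max(max(times), 60.0) + 1)
    rng = design.rng()
    rows = []
    for t in times:
        level = float(resp.igg_at(t))
        reps = _noisy_replicates(rng, level, design.cv, design.n)
        sd = float(reps.std(ddof=1)) if design.n > 1 else design.cv * level
        rows.append((t, float(reps.mean()), sd, design.n))
    return pd.DataFrame(rows, columns=["time_days", "mean", "sd", "n"])


# ---------------------------------------------------------------------------
# Fit-recovery utilities (used by tests and the calibration harness)
# ---------------------------------------------------------------------------


def fit_transwell(series: pd.DataFrame,
                  igg4_doses=(0.5, 0.125),
                  initial: HuvecParameters | None = None):
    """Least-squares fit of (fcrn0, ktrans) to an IgG4 Transwell time series.

    The series must contain single-ligand IgG4 conditions matching
    ``igg4_doses`` (condition order as generated).  Returns a fitted
    HuvecParameters.
    """
    from scipy.optimize import least_squares

    base = initial or HuvecParameters()
    grouped = series.groupby(["condition_id", "time_min"])["igg4_mg_ml"].mean()

    def residuals(theta):
        fcrn0, ktrans = np.exp(theta)
        p = base.replace(fcrn0=fcrn0, ktrans=ktrans)
        out = []
        for cid, dose in enumerate(igg4_doses):
            res = simulate_transwell(p, igg4_apical=dose)
            for t in sorted(series["time_min"].unique()):
                out.append(res.transcytosed_mg_ml(t)[1] - grouped[cid, t])
        return np.array(out)

    theta0 = np.log([base.fcrn0, base.ktrans])
    sol = least_squares(residuals, theta0, method="lm")
    fcrn0, ktrans = np.exp(sol.x)
    return base.replace(fcrn0=float(fcrn0), ktrans=float(ktrans))


def fit_booster(series: pd.DataFrame,
                initial: ImmunizationParameters | None = None):
    """Least-squares fit of the secretion amplitude (k_asc*k_igg*ag0 product).

    The maternal response is linear in the product of antigen dose, plasma
    cell generation and secretion rates, so only that product is
    identifiable from a single titer curve; it is fitted via k_igg with the
    other factors fixed, and returned alongside the fitted parameters.
    """
    from scipy.optimize import least_squares

    base = initial or ImmunizationParameters()
    times = series["time_days"].to_numpy(dtype=float)
    target = series["mean"].to_numpy(dtype=float)

    def residuals(theta):
        p = base.replace(k_igg=float(np.exp(theta[0])))
        resp = simulate_booster(p, duration_days=max(times.max(), 60.0) + 1)
        return resp.igg_at(times) - target

    sol = least_squares(residuals, np.log([base.k_igg]), method="lm")
    fitted = base.replace(k_igg=float(np.exp(sol.x[0])))
    product = fitted.k_igg * fitted.k_asc * fitted.ag0
    return fitted, product
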