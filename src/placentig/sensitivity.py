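"""Global sensitivity analysis: LHS perturbation + orthogonalized PLS regression.

Parameter sets are drawn by Latin hypercube sampling from the calibrated
ranges, a scalar model outcome is simulated for each, and a single-response
orthogonalized PLS (O-PLS) model regresses the outcome on the 11 parameters.
Variable importance in projection (VIP) scores rank the parameters; signs are
attached post hoc from each parameter's loading on the predictive latent
variable (LV1), so a negative VIP marks a parameter whose increase lowers the
outcome.  Model quality is summarized by 5-fold cross-validated Q² and an
empirical permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .calibration import ParameterRanges, lhs_sample
from .parameters import OPTIMIZED_PARAMETERS, TransferParameters
from .transfer import simulate_transfer, subclass_entropy


class OPLS(BaseEstimator, RegressorMixin):
    """Single-response orthogonalized partial least squares regression.

    Removes ``n_orthogonal`` Y-orthogonal components from X (Trygg-Wold
    O-PLS), then fits one predictive PLS component.  The predictive latent
    variable is oriented so that its regression coefficient on y is positive,
    aligning LV1 with the direction of maximum Y variance.

    Attributes
    ----------
    x_mean_, x_std_, y_mean_, y_std_ : scaling applied before decomposition
    w_ortho_, p_ortho_ : orthogonal weights/loadings, shape (n_orthogonal, p)
    weights_ : predictive component weights (unit norm), shape (p,)
    loadings_ : predictive X loadings, shape (p,)
    q_ : y loading of the predictive component (scalar, positive)
    scores_, ortho_scores_ : training scores on LV1 / orthogonal components
    coef_ : regression coefficients on the (scaled) filtered X
    r_squared_ : training R²
    vip_ : signed VIP scores (sum of squares equals n_features)
    """

    def __init__(self, n_orthogonal: int = 1, standardize: bool = True):
        self.n_orthogonal = n_orthogonal
        self.standardize = standardize

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        y = np.asarray(y, dtype=float)
        if np.std(y) == 0:
            raise ValueError("outcome is constant; OPLS model is degenerate")

        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0, ddof=1) if self.standardize else np.ones(X.shape[1])
        self.x_std_ = np.where(self.x_std_ == 0, 1.0, self.x_std_)
        self.y_mean_ = y.mean()
        self.y_std_ = np.std(y, ddof=1) if self.standardize else 1.0

        Xc = (X - self.x_mean_) / self.x_std_
        yc = (y - self.y_mean_) / self.y_std_

        w_os, p_os = [], []
        for _ in range(self.n_orthogonal):
            w = Xc.T @ yc
            w /= np.linalg.norm(w)
            t = Xc @ w
            p = Xc.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:       # no orthogonal variation left
                break
            w_o /= norm
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            w_os.append(w_o)
            p_os.append(p_o)
        self.w_ortho_ = np.array(w_os).reshape(len(w_os), X.shape[1])
        self.p_ortho_ = np.array(p_os).reshape(len(p_os), X.shape[1])

        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        q = (yc @ t) / (t @ t)
        if q < 0:                  # orient LV1 along increasing y
            w, t, p, q = -w, -t, -p, -q
        self.weights_ = w
        self.loadings_ = p
        self.q_ = float(q)
        self.scores_ = t
        self.ortho_scores_ = (np.array([Xc @ wo for wo in self.w_ortho_])
                              if len(self.w_ortho_) else np.empty((0, len(t))))
        self.coef_ = q * w
        resid = yc - q * t
        self.r_squared_ = float(1.0 - (resid @ resid) / (yc @ yc))
        # single predictive component: VIP_j = sqrt(p) * |w_j|, signed by the
        # parameter's loading on LV1
        pdim = X.shape[1]
        self.vip_ = np.sqrt(pdim) * np.abs(w) * np.sign(self.loadings_)
        return self

    def _filter(self, Xc: np.ndarray) -> np.ndarray:
        for w_o, p_o in zip(self.w_ortho_, self.p_ortho_):
            t_o = Xc @ w_o
            Xc = Xc - np.outer(t_o, p_o)
        return Xc

    def transform(self, X) -> np.ndarray:
        """Scores on the predictive latent variable (LV1)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        Xc = self._filter((X - self.x_mean_) / self.x_std_)
        return Xc @ self.weights_

    def predict(self, X) -> np.ndarray:
        return self.transform(X) * self.q_ * self.y_std_ + self.y_mean_


def fit_opls1(X, y, n_orthogonal: int = 1, standardize: bool = True) -> OPLS:
    """Fit a single-response OPLS model (thin wrapper over :class:`OPLS`)."""
    return OPLS(n_orthogonal=n_orthogonal, standardize=standardize).fit(X, y)


def q_squared(model: OPLS, X, y, folds: int = 5, seed: int = 0) -> float:
    """Cross-validated predictive power Q² = 1 - PRESS / TSS.

    The model is refit on each training split and predicts the held-out
    points; squared prediction errors are pooled over folds and compared to
    the total sum of squares around the overall mean.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    press = 0.0
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        if np.std(y[train]) == 0:
            import warnings
            warnings.warn("fold with constant outcome skipped")
            continue
        est = clone(model).fit(X[train], y[train])
        err = y[test] - est.predict(X[test])
        press += float(err @ err)
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def permutation_pvalue(X, y, n_perm: int = 1000, seed: int = 0,
                       model: OPLS | None = None, folds: int = 5) -> float:
    """Empirical p-value of the cross-validated MSE against permuted labels.

    Counts permuted models whose held-out MSE is at most the real model's,
    with add-one smoothing: p = (1 + n_better) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    model = model if model is not None else OPLS()
    y = np.asarray(y, dtype=float)
    n = len(y)

    def cv_mse(yy, fold_seed):
        q2 = q_squared(model, X, yy, folds=folds, seed=fold_seed)
        tss = float(((yy - yy.mean()) ** 2).sum())
        return (1.0 - q2) * tss / n

    real = cv_mse(y, fold_seed=seed)
    rng = np.random.default_rng(seed)
    better = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if np.std(perm) == 0:
            continue
        if cv_mse(perm, fold_seed=seed) <= real:
            better += 1
    return (1 + better) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Outcome evaluation and the full analysis
# ---------------------------------------------------------------------------


OUTCOMES = ("total_igg", "entropy", "optimal_tvax")


def _evaluate_outcome(outcome: str, values: np.ndarray,
                      base: TransferParameters, horizon: float = 40.0) -> float:
    params = base.with_optimized(values)
    if outcome == "optimal_tvax":
        from .immunization import optimize_tvax
        return float(optimize_tvax(horizon, params=params))
    res = simulate_transfer(params, t_span=(0.0, horizon))
    fetal = res.fetal_at(horizon)
    if outcome == "total_igg":
        return float(fetal.sum())
    if outcome == "entropy":
        return subclass_entropy(fetal)
    raise ValueError(f"unknown outcome {outcome!r}")


@dataclass
class PerturbationDesign:
    """LHS predictor matrix and simulated outcome vector."""

    X: np.ndarray                  # (n, 11)
    y: np.ndarray                  # (n,)
    names: tuple[str, ...]
    outcome: str
    n_failed: int = 0


@dataclass
class SensitivityReport:
    """Fitted OPLS model plus ranked VIP table for one outcome."""

    outcome: str
    model: OPLS
    design: PerturbationDesign
    q2: float
    permutation_p: float | None
    vip_table: pd.DataFrame = field(init=False)

    def __post_init__(self):
        tab = pd.DataFrame({
            "parameter": self.design.names,
            "vip": self.model.vip_,
        })
        tab["abs_vip"] = tab["vip"].abs()
        self.vip_table = (tab.sort_values("abs_vip", ascending=False)
                          .drop(columns="abs_vip").reset_index(drop=True))

    def top_parameters(self, k: int = 3) -> list[str]:
        return list(self.vip_table["parameter"].head(k))

    def summary(self) -> dict:
        return {
            "outcome": self.outcome,
            "r2": self.model.r_squared_,
            "q2": self.q2,
            "permutation_p": self.permutation_p,
            "n": len(self.design.y),
            "n_failed": self.design.n_failed,
            "vip": dict(zip(self.design.names,
                            map(float, self.model.vip_))),
        }


def build_design(outcome: str, ranges: ParameterRanges, n: int = 1000,
                 seed: int = 0, base: TransferParameters | None = None,
                 horizon: float = 40.0) -> PerturbationDesign:
    """Draw an LHS design and simulate the outcome for every parameter set."""
    base = base or TransferParameters()
    X = lhs_sample(ranges, n, seed=seed)
    y = np.empty(n)
    ok = np.ones(n, dtype=bool)
    for i, row in enumerate(X):
        try:
            y[i] = _evaluate_outcome(outcome, row, base, horizon)
        except Exception:
            ok[i] = False
    n_failed = int((~ok).sum())
    if n_failed > 0.01 * n:
        raise RuntimeError(f"{n_failed}/{n} simulations failed")
    return PerturbationDesign(X=X[ok], y=y[ok], names=ranges.names,
                              outcome=outcome, n_failed=n_failed)


def run_global_sensitivity(outcome: str,
                           ranges: ParameterRanges | None = None,
                           n: int = 1000,
                           seed: int = 0,
                           n_orthogonal: int = 1,
                           n_perm: int | None = None,
                           base: TransferParameters | None = None,
                           horizon: float = 40.0) -> SensitivityReport:
    """LHS-perturb, simulate, and fit the OPLS sensitivity model.

    ``n_perm=None`` skips the (costly) permutation test; pass e.g. 1000 to
    attach an empirical p-value.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    ranges = ranges if ranges is not None else ParameterRanges.table1()
    design = build_design(outcome, ranges, n=n, seed=seed, base=base,
                          horizon=horizon)
    model = OPLS(n_orthogonal=n_orthogonal).fit(design.X, design.y)
    q2 = q_squared(model, design.X, design.y, folds=5, seed=seed)
    p = (permutation_pvalue(design.X, design.y, n_perm=n_perm, seed=seed,
                            model=model)
         if n_perm else None)
    return SensitivityReport(outcome=outcome, model=model, design=design,
                             q2=q2, permutation_p=p)


def vip_rank_stability(outcome: str, ranges: ParameterRanges | None = None,
                       n: int = 1000, seeds: tuple[int, int] = (0, 1)) -> float:
    """Spearman rank correlation of |VIP| between two seeds (stability check)."""
    from scipy.stats import spearmanr
    reports = [run_global_sensitivity(outcome, ranges, n=n, seed=s)
               for s in seeds]
    vips = [np.abs(r.model.vip_) for r in reports]
    return float(spearmanr(vips[0], vips[1]).statistic)
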