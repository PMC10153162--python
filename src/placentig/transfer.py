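"""Compartmental ODE model of transplacental IgG transport.

The model tracks the four IgG subclasses through five compartments of the
maternal-fetal interface: maternal blood, syncytiotrophoblast (STB) endosomes,
villous stroma, endothelial-cell (EC) endosomes, and fetal blood.  IgG is taken
up fluid-phase into STB endosomes, where it either binds FcRn (at the acidified
endosomal pH) and is transcytosed to the stroma, or is degraded in lysosomes.
From the stroma it is taken up by ECs, where it can bind FcRn or FcγRIIb;
bound complexes are transcytosed into fetal blood, where IgG decays
first-order.  Receptor totals rise parabolically over gestation, so transfer
accelerates toward term.  Maternal subclass concentrations are boundary
conditions: constant for bulk IgG, or a time-varying input for vaccine-induced
antigen-specific IgG (see :mod:`placentig.immunization`).

All rate parameters with units L/week act as volumetric flows: a flow ``k``
moving species at concentration ``C`` transports ``k*C`` mol/week, which is
divided by the receiving (or losing) compartment volume to give a
concentration derivative, so moles are conserved between compartments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import entropy as _shannon_entropy

from .parameters import SUBCLASSES, TransferParameters

#: state variables tracked per species within the placenta/fetus
STATE_NAMES = ("stb_free", "stb_complex", "stroma", "ec_free",
               "ec_fcrn_complex", "ec_fcgr2b_complex", "fetal")
N_STATE = len(STATE_NAMES)

GESTATION_WEEKS = 40.0


class ReceptorVariant(enum.Enum):
    """Which Fc receptors the endothelial layer expresses."""

    EC_BOTH = "ec_both"
    EC_FCRN_ONLY = "ec_fcrn_only"
    EC_FCGR2B_ONLY = "ec_fcgr2b_only"


def apply_variant(params: TransferParameters,
                  variant: ReceptorVariant) -> TransferParameters:
    """Zero the EC receptor endpoint(s) excluded by *variant*."""
    if variant is ReceptorVariant.EC_FCRN_ONLY:
        return params.replace(fcgr2b_ec_end=0.0)
    if variant is ReceptorVariant.EC_FCGR2B_ONLY:
        return params.replace(fcrn_ec_end=0.0)
    return params


@dataclass(frozen=True)
class FcRSchedule:
    """Parabolic rise of total Fc receptor expression over gestation.

    The scheduled total is 0 at conception, grows as ``(t/term_time)**shape``,
    and is clamped at ``endpoint`` beyond term.
    """

    endpoint: float
    term_time: float = GESTATION_WEEKS
    shape: float = 2.0

    def value(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("gestational time must be non-negative")
        frac = np.minimum(t, self.term_time) / self.term_time
        out = self.endpoint * frac ** self.shape
        return float(out) if out.ndim == 0 else out


def fcr_schedule_value(t: float, schedule: FcRSchedule) -> float:
    """Scheduled total receptor concentration (M) at gestational time *t*."""
    return schedule.value(t)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


@dataclass
class _Species:
    """Kinetic description of one transported IgG species set.

    ``maternal`` maps gestational time (weeks) to the maternal concentration
    vector (M) of the ``n`` species; ``kon_fcrn``/``kon_fcgr2b`` are the
    per-species association rates (1/(M week)).
    """

    maternal: Callable[[float], np.ndarray]
    kon_fcrn: np.ndarray
    kon_fcgr2b: np.ndarray
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.labels)


def bulk_species(params: TransferParameters) -> _Species:
    """The four bulk subclasses with constant maternal concentrations."""
    igg0 = np.asarray(params.igg0, dtype=float)
    return _Species(
        maternal=lambda t: igg0,
        kon_fcrn=params.kon_fcrn,
        kon_fcgr2b=params.kon_fcgr2b,
        labels=SUBCLASSES,
    )


def _rhs(t: float, y: np.ndarray, p: TransferParameters, sp: _Species,
         schedules: dict[str, FcRSchedule]) -> np.ndarray:
    n = sp.n
    y = y.reshape(N_STATE, n)
    stb_f, stb_c, stro, ec_f, ec_cn, ec_cb, fet = y

    rn_stb_free = max(schedules["fcrn_stb"].value(t) - stb_c.sum(), 0.0)
    rn_ec_free = max(schedules["fcrn_ec"].value(t) - ec_cn.sum(), 0.0)
    rb_ec_free = max(schedules["fcgr2b_ec"].value(t) - ec_cb.sum(), 0.0)

    koff = p.koff_week
    mat = sp.maternal(t)

    # FcRn binds free IgG inside acidified endosomes (STB and EC); FcγRIIb
    # binds IgG at the EC surface, i.e. directly from the stromal pool.
    bind_stb = sp.kon_fcrn * stb_f * rn_stb_free - koff * stb_c
    bind_ecn = sp.kon_fcrn * ec_f * rn_ec_free - koff * ec_cn
    bind_ecb = sp.kon_fcgr2b * stro * rb_ec_free - koff * ec_cb

    d = np.empty_like(y)
    # STB endosomes: uptake from maternal blood, degradation, FcRn binding
    d[0] = (p.k_up * mat - p.k_deg * stb_f) / p.v_stb - bind_stb
    # STB FcRn complexes: binding minus transcytosis to stroma
    d[1] = bind_stb - (p.k_trans / p.v_stb) * stb_c
    # Stroma: transcytosed complexes in, EC fluid-phase uptake out, surface
    # FcγRIIb capture out (complex concentrations live in the EC volume frame)
    d[2] = (p.k_trans * stb_c - p.k_up * stro) / p.v_str - bind_ecb * (p.v_ec / p.v_str)
    # EC endosomes: uptake, degradation, endosomal FcRn binding
    d[3] = (p.k_up * stro - p.k_deg * ec_f) / p.v_ec - bind_ecn
    d[4] = bind_ecn - (p.k_trans / p.v_ec) * ec_cn
    d[5] = bind_ecb - (p.k_trans / p.v_ec) * ec_cb
    # Fetal blood: transcytosis in, first-order decay
    d[6] = (p.k_trans / p.v_f) * (ec_cn + ec_cb) - p.delta_ab * fet
    return d.ravel()


def placental_rhs(t: float, state: np.ndarray, params: TransferParameters,
                  variant: ReceptorVariant = ReceptorVariant.EC_BOTH) -> np.ndarray:
    """Time derivative of the bulk four-subclass placental state.

    ``state`` is the flattened (7, 4) array ordered by :data:`STATE_NAMES`
    rows and subclass columns.
    """
    if np.min(state) < -1e-6:
        raise ValueError("state has negative entries beyond tolerance")
    p = apply_variant(params, variant)
    return _rhs(t, np.asarray(state, dtype=float), p, bulk_species(p),
                receptor_schedules(p))


def receptor_schedules(params: TransferParameters,
                       term_time: float = GESTATION_WEEKS,
                       shape: float = 2.0) -> dict[str, FcRSchedule]:
    return {
        "fcrn_stb": FcRSchedule(params.fcrn_stb_end, term_time, shape),
        "fcrn_ec": FcRSchedule(params.fcrn_ec_end, term_time, shape),
        "fcgr2b_ec": FcRSchedule(params.fcgr2b_ec_end, term_time, shape),
    }


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the solver message."""


@dataclass
class SimulationResult:
    """Trajectory of the placental model on a gestational time grid."""

    t: np.ndarray                       # weeks, strictly increasing
    states: np.ndarray                  # (N_STATE, n_species, n_t), molar
    labels: tuple[str, ...]
    params: TransferParameters
    maternal: Callable[[float], np.ndarray]
    diagnostics: dict = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        """(n_species, n_t) trajectory of one state variable."""
        return self.states[STATE_NAMES.index(name)]

    @property
    def fetal(self) -> np.ndarray:
        return self.state("fetal")

    def at(self, t: float) -> np.ndarray:
        """States interpolated at time *t*: shape (N_STATE, n_species)."""
        out = np.empty(self.states.shape[:2])
        for i in range(self.states.shape[0]):
            for j in range(self.states.shape[1]):
                out[i, j] = np.interp(t, self.t, self.states[i, j])
        return out

    def fetal_at(self, t: float) -> np.ndarray:
        return self.at(t)[STATE_NAMES.index("fetal")]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns time_weeks, compartment, subclass, concentration_M."""
        rows = []
        for i, comp in enumerate(STATE_NAMES):
            for j, lab in enumerate(self.labels):
                rows.append(pd.DataFrame({
                    "time_weeks": self.t,
                    "compartment": comp,
                    "subclass": lab,
                    "concentration_M": self.states[i, j],
                }))
        return pd.concat(rows, ignore_index=True)


def simulate_transfer(
    params: TransferParameters,
    variant: ReceptorVariant = ReceptorVariant.EC_BOTH,
    t_span: tuple[float, float] = (0.0, GESTATION_WEEKS),
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "BDF",
    species: _Species | None = None,
    y0: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the placental transfer model from empty placenta/fetus.

    Parameters
    ----------
    params : TransferParameters
    variant : ReceptorVariant
        EC receptor expression scenario (ignored when *species* carries
        explicit kinetics and the endpoints are already set).
    t_span : pair of weeks within [0, 42].
    t_eval : output grid; defaults to 0.1-week spacing.
    species : optional custom species set (used by the immunization coupling).
    """
    lo, hi = t_span
    if not (0 <= lo < hi <= 42):
        raise ValueError("t_span must satisfy 0 <= start < stop <= 42 weeks")
    p = apply_variant(params, variant)
    sp = species if species is not None else bulk_species(p)
    sched = receptor_schedules(p)
    if t_eval is None:
        t_eval = np.linspace(lo, hi, int(round((hi - lo) / 0.1)) + 1)
    t_eval = np.asarray(t_eval, dtype=float)
    if y0 is None:
        y0 = np.zeros(N_STATE * sp.n)

    sol = solve_ivp(
        _rhs, (lo, hi), y0, t_eval=t_eval, method=method,
        rtol=rtol, atol=atol, args=(p, sp, sched),
    )
    if not sol.success:
        raise IntegrationError(f"stiff solver failed: {sol.message}")
    states = sol.y.reshape(N_STATE, sp.n, -1)
    return SimulationResult(
        t=sol.t, states=states, labels=sp.labels, params=p,
        maternal=sp.maternal,
        diagnostics={"nfev": sol.nfev, "njev": sol.njev, "status": sol.status},
    )


# ---------------------------------------------------------------------------
# Outcome metrics
# ---------------------------------------------------------------------------


def fetal_maternal_ratio(result: SimulationResult, t: float) -> np.ndarray:
    """Per-species fetal/maternal concentration ratio at time *t*."""
    maternal = np.asarray(result.maternal(t), dtype=float)
    if np.any(maternal <= 0):
        raise ZeroDivisionError("maternal concentration must be positive")
    return result.fetal_at(t) / maternal


def subclass_entropy(fetal: np.ndarray) -> float:
    """Shannon entropy (natural log) of the fetal subclass proportions.

    ``0 * log 0`` contributes zero; an all-zero panel is undefined.
    """
    fetal = np.asarray(fetal, dtype=float)
    if np.any(fetal < 0):
        raise ValueError("subclass concentrations must be non-negative")
    total = fetal.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero subclass panel")
    return float(_shannon_entropy(fetal / total))


def total_fetal_igg(result: SimulationResult, t: float = GESTATION_WEEKS) -> float:
    """Summed fetal concentration (M) over species at time *t*."""
    return float(result.fetal_at(t).sum())


def transfer_hierarchy(result: SimulationResult,
                       t: float = GESTATION_WEEKS) -> tuple[str, ...]:
    """Species labels sorted by descending F:M ratio at time *t*."""
    ratios = fetal_maternal_ratio(result, t)
    order = np.argsort(-ratios)
    return tuple(result.labels[i] for i in order)
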