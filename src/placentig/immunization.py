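"""Maternal booster-response model and the prenatal vaccination testbed.

A four-state linear ODE system (antigen, short- and long-lived antibody
secreting cells, circulating antigen-specific IgG) describes the maternal
anti-pertussis-toxin (α-PT) IgG response to a Tdap booster.  The simulated
maternal α-PT IgG trajectory is fed into the maternal compartment of the
placental transfer model as a time-varying boundary condition, split equally
across the four IgG subclasses.  The vaccine-induced species are carried as
four extra transported species so they compete with the constant bulk
maternal IgG for the same limited Fc receptor pools — receptor limitation is
what makes timing, dose and affinity modulation interact nonlinearly.

The immunization model runs on a daily time base; gestational simulation runs
in weeks (1 week = 7 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import transfer as _tr
from .parameters import (
    DELTA_AB_HALF_LIFE,
    SUBCLASSES,
    ImmunizationParameters,
    TransferParameters,
    kon_from_kd,
    mg_ml_to_molar,
)

DAYS_PER_WEEK = 7.0

PT_LABELS = tuple(f"aPT-{s}" for s in SUBCLASSES)


def default_vaccine_transfer_params() -> TransferParameters:
    """Transfer parameters used by the vaccination testbed.

    Identical to the placental defaults except that fetal IgG decays with the
    31-day half-life the immunization model assumes (delta_ab = ln2 / 31 d),
    rather than the slower printed transfer-table value.
    """
    return TransferParameters(delta_ab=DELTA_AB_HALF_LIFE)


# ---------------------------------------------------------------------------
# Maternal booster response
# ---------------------------------------------------------------------------


def immunization_rhs(t: float, state: np.ndarray,
                     params: ImmunizationParameters) -> np.ndarray:
    """Derivative of (Ag, S_ASC, L_ASC, IgG) on the daily time base.

    Antigen decays first-order and drives generation of antibody-secreting
    cells, split rho : (100 - rho) between short- and long-lived pools; both
    pools secrete IgG, which decays first-order.
    """
    ag, s, l, igg = state
    p = params
    frac_s = p.rho / 100.0
    return np.array([
        -p.delta_ag * ag,
        frac_s * p.k_asc * ag - p.delta_sasc * s,
        (1.0 - frac_s) * p.k_asc * ag - p.delta_lasc * l,
        p.k_igg * (s + l) - p.delta_igg * igg,
    ])


@dataclass
class MaternalResponse:
    """Simulated maternal response to one booster dose.

    ``t`` is in days post-vaccination; ``igg`` is α-PT IgG in mg/ml.
    """

    t: np.ndarray
    ag: np.ndarray
    s_asc: np.ndarray
    l_asc: np.ndarray
    igg: np.ndarray
    params: ImmunizationParameters
    dose_scale: float
    _interp: object = field(default=None, repr=False)

    def igg_at(self, t_days: float | np.ndarray) -> np.ndarray:
        """α-PT IgG (mg/ml) at arbitrary days post-vaccination (0 before)."""
        t_days = np.asarray(t_days, dtype=float)
        out = np.zeros(t_days.shape if t_days.ndim else ())
        tt = np.clip(t_days, 0.0, self._interp.t_max)
        vals = self._interp(np.atleast_1d(tt))[3]
        vals = np.where(np.atleast_1d(t_days) < 0, 0.0, vals)
        return float(vals[0]) if t_days.ndim == 0 else vals + out

    @property
    def peak_day(self) -> float:
        return float(self.t[np.argmax(self.igg)])


def simulate_booster(params: ImmunizationParameters,
                     dose_scale: float = 1.0,
                     duration_days: float = 250.0,
                     rtol: float = 1e-10,
                     atol: float = 1e-12) -> MaternalResponse:
    """Integrate the booster response from (Ag0*dose_scale, 0, 0, baseline)."""
    if dose_scale < 0:
        raise ValueError("dose_scale must be non-negative")
    if duration_days < 60:
        raise ValueError("duration must cover at least 60 days")
    y0 = np.array([params.ag0 * dose_scale, 0.0, 0.0, params.baseline_igg])
    t_eval = np.arange(0.0, duration_days + 1e-9, 0.1)
    sol = solve_ivp(immunization_rhs, (0.0, duration_days), y0,
                    t_eval=t_eval, args=(params,), rtol=rtol, atol=atol,
                    dense_output=True, method="LSODA")
    if not sol.success:  # pragma: no cover - linear system, should not fail
        raise RuntimeError(f"booster integration failed: {sol.message}")
    interp = sol.sol
    interp.t_max = duration_days
    return MaternalResponse(t=sol.t, ag=sol.y[0], s_asc=sol.y[1],
                            l_asc=sol.y[2], igg=sol.y[3], params=params,
                            dose_scale=dose_scale, _interp=interp)


# ---------------------------------------------------------------------------
# Coupling to the placental model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VaccineScenario:
    """One prenatal immunization experiment."""

    t_vax: float                       # weeks gestational age at vaccination
    gestational_length: float = 40.0   # weeks at delivery
    dose_scale: float = 1.0
    kd_scale_fcrn: float = 1.0         # scales K_D of vaccine-induced IgG only
    kd_scale_fcgr2b: float = 1.0
    fcrn_stb_factor: float = 1.0       # multiplies the receptor endpoints
    fcgr2b_ec_factor: float = 1.0
    fcrn_ec_factor: float = 1.0

    def __post_init__(self):
        if not 0 < self.t_vax < self.gestational_length <= 42:
            raise ValueError(
                "require 0 < t_vax < gestational_length <= 42 weeks")
        for name in ("dose_scale", "kd_scale_fcrn", "kd_scale_fcgr2b",
                     "fcrn_stb_factor", "fcgr2b_ec_factor", "fcrn_ec_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _scenario_params(scenario: VaccineScenario,
                     params: TransferParameters) -> TransferParameters:
    return params.replace(
        fcrn_stb_end=params.fcrn_stb_end * scenario.fcrn_stb_factor,
        fcgr2b_ec_end=params.fcgr2b_ec_end * scenario.fcgr2b_ec_factor,
        fcrn_ec_end=params.fcrn_ec_end * scenario.fcrn_ec_factor,
    )


def _combined_species(params: TransferParameters, scenario: VaccineScenario,
                      maternal_pt) -> _tr._Species:
    """Bulk subclasses plus vaccine-induced α-PT subclasses (n=8).

    ``maternal_pt`` maps gestational weeks to total maternal α-PT IgG (M).
    """
    igg0 = np.asarray(params.igg0, dtype=float)
    kon_n = np.concatenate([
        params.kon_fcrn,
        kon_from_kd(params.kd_fcrn * scenario.kd_scale_fcrn, params.koff)
        * params.time_scale,
    ])
    kon_b = np.concatenate([
        params.kon_fcgr2b,
        kon_from_kd(params.kd_fcgr2b * scenario.kd_scale_fcgr2b, params.koff)
        * params.time_scale,
    ])

    def maternal(t: float) -> np.ndarray:
        pt_each = maternal_pt(t) / 4.0  # equal split across subclasses
        return np.concatenate([igg0, np.full(4, pt_each)])

    return _tr._Species(maternal=maternal, kon_fcrn=kon_n, kon_fcgr2b=kon_b,
                        labels=SUBCLASSES + PT_LABELS)


def simulate_vaccination(
    scenario: VaccineScenario,
    params: TransferParameters | None = None,
    imm: ImmunizationParameters | None = None,
    coupling: str = "interpolant",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> _tr.SimulationResult:
    """Simulate gestation with a booster at ``scenario.t_vax``.

    Integration runs in two legs: bulk-only up to t_vax (the antigen-specific
    placental states are all zero there), then the eight-species system from
    t_vax to delivery.  ``coupling='interpolant'`` drives the antigen-specific
    maternal concentration from a separately integrated booster response;
    ``coupling='monolithic'`` co-integrates the four immunization states with
    the placental states in a single ODE system.
    """
    params = params if params is not None else default_vaccine_transfer_params()
    imm = imm or ImmunizationParameters()
    p = _scenario_params(scenario, params)
    t_vax, gl = scenario.t_vax, scenario.gestational_length

    # Leg 1: bulk only, empty placenta -> t_vax
    leg1 = _tr.simulate_transfer(p, t_span=(0.0, t_vax), rtol=rtol, atol=atol)
    y_bulk = leg1.states[:, :, -1]

    if coupling == "interpolant":
        resp = simulate_booster(imm, dose_scale=scenario.dose_scale,
                                duration_days=max((gl - t_vax) * DAYS_PER_WEEK, 60.0) + 1)

        def maternal_pt(t_weeks: float) -> float:
            titer = resp.igg_at((t_weeks - t_vax) * DAYS_PER_WEEK)
            return mg_ml_to_molar(titer * imm.igg_unit_mg_ml)

        sp = _combined_species(p, scenario, maternal_pt)
        y0 = np.zeros((_tr.N_STATE, 8))
        y0[:, :4] = y_bulk
        res = _tr.simulate_transfer(p, t_span=(t_vax, gl), species=sp,
                                    y0=y0.ravel(), rtol=rtol, atol=atol)
        res.diagnostics["booster"] = resp
        return res
    if coupling == "monolithic":
        return _simulate_monolithic(p, scenario, imm, y_bulk, rtol, atol)
    raise ValueError(f"unknown coupling mode: {coupling!r}")


def _simulate_monolithic(p, scenario, imm, y_bulk, rtol, atol):
    """Single ODE system: 56 placental states + 4 immunization states."""
    t_vax, gl = scenario.t_vax, scenario.gestational_length
    sched = _tr.receptor_schedules(p)
    # species object whose maternal PT level is injected per call
    cell = {"pt": 0.0}
    sp = _combined_species(p, scenario, lambda t: cell["pt"])
    n_plac = _tr.N_STATE * 8

    def rhs(t, y):
        imm_state = y[n_plac:]
        cell["pt"] = mg_ml_to_molar(max(imm_state[3], 0.0) * imm.igg_unit_mg_ml)
        d_plac = _tr._rhs(t, y[:n_plac], p, sp, sched)
        # immunization model runs in days; t is weeks
        d_imm = immunization_rhs(t * DAYS_PER_WEEK, imm_state, imm) * DAYS_PER_WEEK
        return np.concatenate([d_plac, d_imm])

    y0 = np.zeros(n_plac + 4)
    y0[:n_plac] = np.column_stack([y_bulk, np.zeros((_tr.N_STATE, 4))]).reshape(
        _tr.N_STATE, 8).ravel()
    y0[n_plac] = imm.ag0 * scenario.dose_scale
    y0[n_plac + 3] = imm.baseline_igg

    t_eval = np.linspace(t_vax, gl, int(round((gl - t_vax) / 0.1)) + 1)
    sol = solve_ivp(rhs, (t_vax, gl), y0, t_eval=t_eval, method="BDF",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise _tr.IntegrationError(f"coupled integration failed: {sol.message}")
    states = sol.y[:n_plac].reshape(_tr.N_STATE, 8, -1)
    res = _tr.SimulationResult(t=sol.t, states=states,
                               labels=SUBCLASSES + PT_LABELS, params=p,
                               maternal=sp.maternal,
                               diagnostics={"nfev": sol.nfev})
    res.diagnostics["immunization_states"] = sol.y[n_plac:]
    return res


def coupled_fetal_pt_igg(
    scenario: VaccineScenario,
    params: TransferParameters | None = None,
    imm: ImmunizationParameters | None = None,
    coupling: str = "interpolant",
) -> float:
    """Total fetal α-PT IgG (M) at delivery for one vaccination scenario."""
    res = simulate_vaccination(scenario, params, imm, coupling=coupling)
    fetal = res.fetal_at(scenario.gestational_length)
    return float(fetal[4:].sum())


# ---------------------------------------------------------------------------
# Vaccination-design experiments
# ---------------------------------------------------------------------------


def optimize_tvax(
    gestational_length: float,
    grid: np.ndarray | None = None,
    params: TransferParameters | None = None,
    imm: ImmunizationParameters | None = None,
    scenario_kwargs: dict | None = None,
    return_curve: bool = False,
):
    """Vaccination week maximizing fetal α-PT IgG at delivery.

    The default grid spans weeks 10-38 in 1-week steps; weeks at or past
    delivery are infeasible and dropped.  Ties resolve to the earliest week.
    """
    if grid is None:
        grid = np.arange(10.0, 39.0)
    grid = np.asarray([g for g in np.asarray(grid, float)
                       if g < gestational_length])
    if grid.size == 0:
        raise ValueError("no feasible vaccination times before delivery")
    kw = scenario_kwargs or {}
    titers = np.array([
        coupled_fetal_pt_igg(
            VaccineScenario(t_vax=g, gestational_length=gestational_length, **kw),
            params, imm)
        for g in grid
    ])
    best = float(grid[int(np.argmax(titers))])
    if return_curve:
        return best, grid, titers
    return best


_RECEPTOR_FACTORS = {
    "fcrn_stb": "fcrn_stb_factor",
    "fcgr2b_ec": "fcgr2b_ec_factor",
    "fcrn_ec": "fcrn_ec_factor",
}


def fcr_deficiency_effect(
    receptor: str,
    fold: float,
    t_vax: float = 25.0,
    gestational_length: float = 40.0,
    params: TransferParameters | None = None,
    imm: ImmunizationParameters | None = None,
) -> float:
    """Percent change in fetal α-PT IgG when one receptor endpoint is scaled.

    ``fold`` multiplies the endpoint (0.1 = 10-fold deficiency).  Returns the
    signed percent change versus the unperturbed baseline.
    """
    if receptor not in _RECEPTOR_FACTORS:
        raise ValueError(f"unknown receptor {receptor!r}")
    if fold <= 0:
        raise ValueError("fold must be positive")
    base = coupled_fetal_pt_igg(
        VaccineScenario(t_vax=t_vax, gestational_length=gestational_length),
        params, imm)
    pert = coupled_fetal_pt_igg(
        VaccineScenario(t_vax=t_vax, gestational_length=gestational_length,
                        **{_RECEPTOR_FACTORS[receptor]: fold}),
        params, imm)
    return 100.0 * (pert - base) / base


def dose_compensation(
    receptor: str,
    deficiency_fold: float = 10.0,
    dose_grid: np.ndarray | None = None,
    t_vax: float = 25.0,
    gestational_length: float = 40.0,
    params: TransferParameters | None = None,
    imm: ImmunizationParameters | None = None,
) -> float:
    """Smallest dose fold restoring the no-deficiency baseline titer.

    Returns the smallest grid dose whose fetal α-PT IgG under a
    ``1/deficiency_fold`` receptor deficiency meets or exceeds the
    unperturbed dose-1 baseline; raises if no grid dose suffices.
    """
    if receptor not in _RECEPTOR_FACTORS:
        raise ValueError(f"unknown receptor {receptor!r}")
    if dose_grid is None:
        dose_grid = np.arange(1.0, 11.0)
    base = coupled_fetal_pt_igg(
        VaccineScenario(t_vax=t_vax, gestational_length=gestational_length),
        params, imm)
    factor = {_RECEPTOR_FACTORS[receptor]: 1.0 / deficiency_fold}
    for dose in np.asarray(dose_grid, dtype=float):
        titer = coupled_fetal_pt_igg(
            VaccineScenario(t_vax=t_vax, gestational_length=gestational_length,
                            dose_scale=float(dose), **factor),
            params, imm)
        if titer >= base:
            return float(dose)
    raise RuntimeError("compensating dose not reachable within the grid")


def affinity_modulation(
    kd_scale_fcrn: float = 1.0,
    kd_scale_fcgr2b: float = 1.0,
    t_vax: float = 25.0,
    gestational_length: float = 40.0,
    params: TransferParameters | None = None,
    imm: ImmunizationParameters | None = None,
) -> float:
    """Percent change in fetal α-PT IgG when the vaccine-induced IgG's K_D is scaled.

    Scales below 1 mean higher affinity.  Only the antigen-specific species is
    modified; the bulk background keeps its printed affinities (and keeps
    competing for receptors).
    """
    if kd_scale_fcrn <= 0 or kd_scale_fcgr2b <= 0:
        raise ValueError("K_D scale factors must be positive")
    base = coupled_fetal_pt_igg(
        VaccineScenario(t_vax=t_vax, gestational_length=gestational_length),
        params, imm)
    pert = coupled_fetal_pt_igg(
        VaccineScenario(t_vax=t_vax, gestational_length=gestational_length,
                        kd_scale_fcrn=kd_scale_fcrn,
                        kd_scale_fcgr2b=kd_scale_fcgr2b),
        params, imm)
    return 100.0 * (pert - base) / base
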