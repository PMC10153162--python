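"""Parameter containers for the placental transfer, HUVEC, and immunization models.

All concentrations are molar (M), volumes are liters, and volumetric flows are
L/week unless stated otherwise.  The four IgG subclasses are always carried in
the fixed order IgG1, IgG2, IgG3, IgG4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

SUBCLASSES = ("IgG1", "IgG2", "IgG3", "IgG4")

#: IgG molecular weight used for mg/ml <-> M conversion, g/mol.
IGG_MW = 150_000.0


def mg_ml_to_molar(c: float | np.ndarray) -> float | np.ndarray:
    """Convert an IgG concentration from mg/ml (= g/L) to molar at 150 kDa."""
    return np.asarray(c, dtype=float) / IGG_MW


def molar_to_mg_ml(c: float | np.ndarray) -> float | np.ndarray:
    """Convert an IgG concentration from molar to mg/ml at 150 kDa."""
    return np.asarray(c, dtype=float) * IGG_MW


def kon_from_kd(kd: float | np.ndarray, koff: float | np.ndarray):
    """Association rate from equilibrium dissociation constant: k_on = k_off / K_D.

    Raises
    ------
    ValueError
        If any input is non-positive.
    """
    kd = np.asarray(kd, dtype=float)
    koff = np.asarray(koff, dtype=float)
    if np.any(kd <= 0) or np.any(koff <= 0):
        raise ValueError("kd and koff must be strictly positive")
    out = koff / kd
    return float(out) if out.ndim == 0 else out


def subclass_vector(igg1: float, igg2: float, igg3: float, igg4: float) -> np.ndarray:
    """Ordered, validated panel of the four subclass concentrations (M)."""
    v = np.array([igg1, igg2, igg3, igg4], dtype=float)
    if np.any(v < 0):
        raise ValueError("subclass concentrations must be non-negative")
    return v


# ---------------------------------------------------------------------------
# Placental transfer model (Table 1)
# ---------------------------------------------------------------------------

#: Fetal IgG decay rate implied by a 31-day IgG half-life, 1/week.
DELTA_AB_HALF_LIFE = float(np.log(2) / (31.0 / 7.0))

#: Printed fetal IgG decay value, used as the default, 1/week.
DELTA_AB_TABLE = 0.02

#: Optimized parameter ranges (lower, upper) for the 11 calibrated parameters.
TABLE1_RANGES: dict[str, tuple[float, float]] = {
    "k_up": (0.0872, 0.0982),
    "k_trans": (0.0569, 0.0743),
    "k_deg": (8.4733, 9.0809),
    "fcrn_stb_end": (3.33e-5, 4.94e-5),
    "fcgr2b_ec_end": (2.73e-5, 3.33e-5),
    "fcrn_ec_end": (2.36e-6, 2.86e-6),
    "v_m": (5.552, 5.619),
    "v_stb": (0.224, 0.258),
    "v_str": (0.165, 0.179),
    "v_ec": (0.247, 0.275),
    "v_f": (0.254, 0.271),
}

OPTIMIZED_PARAMETERS = tuple(TABLE1_RANGES)


@dataclass(frozen=True, eq=False)
class TransferParameters:
    """Placental IgG transfer model parameters.

    Defaults are the midpoints of the optimized ranges for the 11 calibrated
    parameters plus the literature-derived constants: maternal subclass
    concentrations, per-subclass K_D for FcRn and FcγRIIb, the shared
    dissociation rate k_off, and the fetal decay rate delta_ab.
    """

    k_up: float = 0.0927          # L/week, maternal->STB and stroma->EC uptake
    k_trans: float = 0.0656       # L/week, complex transcytosis
    k_deg: float = 8.7771         # L/week, lysosomal degradation of free endosomal IgG
    fcrn_stb_end: float = 4.135e-5   # M, STB FcRn at term
    fcgr2b_ec_end: float = 3.03e-5   # M, EC FcγRIIb at term
    fcrn_ec_end: float = 2.61e-6     # M, EC FcRn at term
    igg0: np.ndarray = field(
        default_factory=lambda: subclass_vector(3.78e-5, 1.81e-5, 2.35e-6, 2.27e-6)
    )  # M, maternal subclass concentrations
    kd_fcrn: np.ndarray = field(
        default_factory=lambda: np.array([1.25e-8, 2e-8, 3.3e-8, 5e-8])
    )  # M
    kd_fcgr2b: np.ndarray = field(
        default_factory=lambda: np.array([1e-5, 5e-5, 5e-6, 5e-6])
    )  # M
    koff: float = 0.15            # 1/week on the model time base (see time_scale)
    v_m: float = 5.5855           # L
    v_stb: float = 0.241          # L
    v_str: float = 0.172          # L
    v_ec: float = 0.261           # L
    v_f: float = 0.2625           # L
    delta_ab: float = DELTA_AB_TABLE  # 1/week
    #: multiplicative conversion applied to koff/kon to move the binding
    #: kinetics onto the weekly time base; 1.0 interprets the printed kinetic
    #: rates as already being per-week.
    time_scale: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            arr = np.asarray(v, dtype=float)
            if np.any(arr <= 0) and f.name not in ("fcrn_ec_end", "fcgr2b_ec_end", "fcrn_stb_end"):
                raise ValueError(f"parameter {f.name} must be strictly positive")
            if np.any(arr < 0):
                raise ValueError(f"parameter {f.name} must be non-negative")
        for name in ("igg0", "kd_fcrn", "kd_fcgr2b"):
            if np.asarray(getattr(self, name)).shape != (4,):
                raise ValueError(f"{name} must have exactly four subclass entries")

    def __eq__(self, other) -> bool:
        if not isinstance(other, TransferParameters):
            return NotImplemented
        return all(np.array_equal(getattr(self, f.name), getattr(other, f.name))
                   for f in fields(self))

    __hash__ = object.__hash__

    @property
    def koff_week(self) -> float:
        return self.koff * self.time_scale

    @property
    def kon_fcrn(self) -> np.ndarray:
        """Per-subclass FcRn association rate, 1/(M week)."""
        return kon_from_kd(self.kd_fcrn, self.koff) * self.time_scale

    @property
    def kon_fcgr2b(self) -> np.ndarray:
        """Per-subclass FcγRIIb association rate, 1/(M week)."""
        return kon_from_kd(self.kd_fcgr2b, self.koff) * self.time_scale

    def replace(self, **kwargs) -> "TransferParameters":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, values: dict) -> "TransferParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise KeyError(f"unknown transfer parameter(s): {sorted(unknown)}")
        vals = dict(values)
        for name in ("igg0", "kd_fcrn", "kd_fcgr2b"):
            if name in vals:
                vals[name] = np.asarray(vals[name], dtype=float)
        return cls(**vals)

    def optimized_values(self) -> np.ndarray:
        """The 11 calibrated parameters, in the canonical order."""
        return np.array([getattr(self, p) for p in OPTIMIZED_PARAMETERS])

    def with_optimized(self, values: np.ndarray) -> "TransferParameters":
        """Copy with the 11 calibrated parameters replaced (canonical order)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(OPTIMIZED_PARAMETERS),):
            raise ValueError("expected one value per optimized parameter")
        return self.replace(**dict(zip(OPTIMIZED_PARAMETERS, values)))


def table1_midpoint() -> TransferParameters:
    """Transfer parameters at the midpoint of every optimized range."""
    mids = {k: 0.5 * (lo + hi) for k, (lo, hi) in TABLE1_RANGES.items()}
    return TransferParameters(**mids)


# ---------------------------------------------------------------------------
# HUVEC in vitro transcytosis model (Table 2)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HuvecParameters:
    """Parameters of the in vitro HUVEC transcytosis model (per-minute time base)."""

    fcrn0: float = 2200e-9        # M (2200 nM)
    ktrans: float = 2.5e-5        # 1/minute
    kdeg: float = 0.01            # 1/minute; absent from the core rate equations,
                                  # enabled only via the use_kdeg toggle
    kd_igg1: float = 1.25e-8      # M
    kd_igg4: float = 5e-8         # M
    koff: float = 0.15            # 1/minute
    use_kdeg: bool = False

    def __post_init__(self):
        for name in ("fcrn0", "ktrans", "kdeg", "kd_igg1", "kd_igg4", "koff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")

    @property
    def kon_igg1(self) -> float:
        return kon_from_kd(self.kd_igg1, self.koff)

    @property
    def kon_igg4(self) -> float:
        return kon_from_kd(self.kd_igg4, self.koff)

    def replace(self, **kwargs) -> "HuvecParameters":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Tdap immunization model (Table 3)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImmunizationParameters:
    """Plasma-cell activation / antibody secretion model parameters (per-day)."""

    k_asc: float = 0.6        # plasma-cell generation, 1/(1e6 PBMC day Ag-unit)
    k_igg: float = 0.0475     # antibody production, mg/ml (1e6 PBMC)/day
    ag0: float = 100.0        # initial antigen dose, mg/ml (stimulus units)
    rho: float = 96.0         # % short-lived ASCs
    delta_ag: float = 0.15    # 1/day
    delta_igg: float = 0.033  # 1/day
    delta_sasc: float = 0.173  # 1/day
    delta_lasc: float = 6.6e-4  # 1/day
    baseline_igg: float = 0.0  # pre-boost anti-PT IgG, response-model units
    #: mass concentration (mg/ml) represented by one unit of the response
    #: model's IgG variable.  The response model's titer unit is arbitrary
    #: (it was fitted to booster-response titer data); the default maps one
    #: unit to 1 ug/ml so that a peak response of ~70 units corresponds to
    #: ~70 ug/ml of antigen-specific IgG — trace-level relative to the
    #: ~10 mg/ml bulk IgG background, as antigen-specific serum IgG is.
    igg_unit_mg_ml: float = 1e-3

    def __post_init__(self):
        if not 0 <= self.rho <= 100:
            raise ValueError("rho must be a percentage in [0, 100]")
        for name in ("k_asc", "k_igg", "ag0", "delta_ag", "delta_igg",
                     "delta_sasc", "delta_lasc", "igg_unit_mg_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.baseline_igg < 0:
            raise ValueError("baseline_igg must be non-negative")

    def replace(self, **kwargs) -> "ImmunizationParameters":
        return replace(self, **kwargs)
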