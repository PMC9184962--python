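"""Right-hand sides and algebraic closures of the cell-cycle control models.

Four nested ODE models of mitotic control are defined here, each a refinement
of the previous one:

``model1``
    Time-delayed negative feedback between MPF (the CycB:Cdk1 dimer) and the
    APC/C ubiquitin ligase, with an intermediary kinase providing the delay.
    Activation terms use Michaelis-Menten (zero-order ultrasensitive) kinetics.
``model2``
    The delay is realised mechanistically by the Greatwall-ENSA-PP2A:B55
    pathway: MPF activates Gwl, Gwl phosphorylates ENSA, and phospho-ENSA
    sequesters the B55 phosphatase (a coherent feed-forward loop onto APC/C).
    Cyclin degradation is driven by the polyubiquitinated fraction of the
    CycB pool, computed from an ordered-distributive ubiquitination chain.
``model3``
    Adds dephosphorylation of Gwl by PP2A:B55, closing a double-negative
    (positive) feedback loop that makes B55 -- and hence APC/C activity --
    a bistable function of MPF.
``model4``
    Adds inhibitory tyrosine phosphorylation of Cdk1 by Wee1, reversed by
    Cdc25, with both enzymes multi-site substrates of MPF.  Total cyclin
    (CycBT) and active MPF become separate variables, and MPF activity is a
    bistable (hysteretic) function of CycBT.

Checkpoint arrest (G2, spindle-assembly, G1) and the size-controlled division
cycle are parameter-level variants of ``model4``.

Units: time in minutes; all concentrations are dimensionless activity units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterSet",
    "ModelDefinition",
    "CheckpointScenario",
    "DomainError",
    "InvariantViolation",
    "validate_state",
    "UB_CHAIN_DEPTH",
    "ub_fraction",
    "tqssa_complex",
    "wee1_active_fraction",
    "cdc25_active_fraction",
    "model1_rhs",
    "model2_rhs",
    "model3_rhs",
    "model4_rhs",
    "get_model",
    "apply_checkpoint",
    "MODEL_IDS",
]

#: Number of ubiquitin moieties CycB must carry before the proteasome
#: degrades it.  The degradable fraction ``f`` is the steady-state occupancy
#: of the top state of an ordered-distributive chain of this depth.
UB_CHAIN_DEPTH = 4


class DomainError(ValueError):
    """An algebraic closure was evaluated outside its physical domain."""


class InvariantViolation(ValueError):
    """A state vector violates a conservation or ordering invariant."""


# --------------------------------------------------------------------------
# Parameter container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """Named rate constants, Michaelis constants and total concentrations.

    One instance holds the parameters of a single model variant.  Fields not
    used by a model are left at ``None``.  Rate constants are per minute
    (per concentration unit where bimolecular); totals and Michaelis
    constants are dimensionless concentration units; ``mu`` (specific growth
    rate, size model only) is per minute.
    """

    # cyclin B synthesis / degradation
    ksy_cycb: float | None = None
    kde1_cycb: float | None = None
    kde2_cycb: float | None = None
    kde3_cycb: float = 0.0          # Cdh1-mediated G1 degradation; 0 = off
    # Greatwall (or the intermediary kinase of model 1)
    kph_gwl: float | None = None
    kdp1_gwl: float | None = None
    kdp2_gwl: float | None = None
    # APC/C phosphorylation
    kph_apc: float | None = None
    kdp_apc: float | None = None
    # ENSA phosphorylation and the B55 complex
    kph_ensa: float | None = None
    kcat: float | None = None
    Km_tqssa: float | None = None   # (kdi2 + kcat) / kas2
    # APC_P:Cdc20 association
    kas1: float | None = None
    kdi1: float | None = None
    # tyrosine-phosphorylation switch (model 4)
    kph1_cdk: float | None = None
    kph2_cdk: float | None = None
    kdp1_cdk: float | None = None
    kdp2_cdk: float | None = None
    # Michaelis constants of the model-1 ultrasensitive activations
    Jph_kin: float | None = None
    Jdp_kin: float | None = None
    Jph_apc: float | None = None
    Jdp_apc: float | None = None
    # total concentrations
    Kin_tot: float | None = None
    Gwl_tot: float | None = None
    APC_tot: float | None = None
    B55_tot: float | None = None
    ENSA_tot: float | None = None
    Cdc20_tot: float | None = None
    Wee1_tot: float | None = None
    Cdc25_tot: float | None = None
    PP: float | None = None
    CAP: float | None = None
    deUb: float | None = None
    # specific growth rate (size-control model only)
    mu: float | None = None

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if v is not None and v < 0:
                raise ValueError(f"parameter {f_.name} must be non-negative, got {v}")

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the named parameters overridden."""
        unknown = set(overrides) - {f_.name for f_ in fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)

    def as_dict(self, drop_none: bool = True) -> dict[str, float]:
        d = {f_.name: getattr(self, f_.name) for f_ in fields(self)}
        if drop_none:
            d = {k: v for k, v in d.items() if v is not None}
        return d


# --------------------------------------------------------------------------
# Algebraic closures
# --------------------------------------------------------------------------
#
# All four closures are steady-state occupancies of ordered-distributive
# modification chains or binding equilibria.  They are written as ratios of
# geometric sums, which are singularity-free at ratio 1 (the rational forms
# r^4(1-r)/(1-r^5) etc. have removable 0/0 singularities there).  For
# arguments above 1 the sums are evaluated in powers of 1/x so that large
# ratios cannot overflow.

def _geom_ratio(x: np.ndarray | float, num_powers: Sequence[int],
                den_top: int) -> np.ndarray | float:
    """sum(x**i for i in num_powers) / sum(x**i for i in 0..den_top)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        safe = np.where(x <= 1.0, x, 1.0)
        num_lo = sum(safe**i for i in num_powers)
        den_lo = sum(safe**i for i in range(den_top + 1))
        inv = np.where(x > 1.0, 1.0 / np.where(x > 1.0, x, 2.0), 1.0)
        num_hi = sum(inv ** (den_top - i) for i in num_powers)
        den_hi = sum(inv ** (den_top - i) for i in range(den_top + 1))
    out = np.where(x <= 1.0, num_lo / den_lo, num_hi / den_hi)
    return float(out) if out.ndim == 0 else out


def ub_fraction(r):
    """Fraction of the CycB pool carrying the full polyubiquitin chain.

    CycB is ubiquitinated sequentially (ordered-distributive mechanism) by
    APC_P:Cdc20 and deubiquitinated at constant activity ``deUb``; ``r`` is
    the ratio of ubiquitination to deubiquitination activity,
    [APC_P:C20]/[deUb].  The chain has ``UB_CHAIN_DEPTH`` + 1 states with
    geometric steady-state occupancies, and only the top state (four
    ubiquitins) is degraded, so

        f(r) = r^4 / (1 + r + r^2 + r^3 + r^4),

    equivalently r^4(1-r)/(1-r^5) away from r = 1.  Monotone from f(0) = 0
    to f(inf) = 1, with f(1) = 1/5.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise DomainError("ubiquitination activity ratio must be >= 0")
    return _geom_ratio(r, [UB_CHAIN_DEPTH], UB_CHAIN_DEPTH)


def tqssa_complex(ensaP, b55_tot, km):
    """[ENSA_P:B55] by the total quasi-steady-state approximation.

    The phosphatase B55 is sequestered by its inhibitory substrate
    phospho-ENSA.  With ``ensaP`` the *total* phospho-ENSA (free + bound),
    the complex concentration C is the smaller root of

        C^2 - B*C + ensaP*b55_tot = 0,   B = ensaP + b55_tot + km,

    evaluated in the cancellation-free form
    2*ensaP*b55_tot / (B + sqrt(B^2 - 4*ensaP*b55_tot)).
    Always 0 <= C <= min(ensaP, b55_tot).
    """
    ensaP = np.asarray(ensaP, dtype=float)
    if np.any(ensaP < 0) or b55_tot <= 0 or km <= 0:
        raise DomainError("tqssa_complex requires ensaP >= 0, b55_tot > 0, km > 0")
    B = ensaP + b55_tot + km
    disc = B * B - 4.0 * ensaP * b55_tot
    out = 2.0 * ensaP * b55_tot / (B + np.sqrt(disc))
    return float(out) if out.ndim == 0 else out


def wee1_active_fraction(s):
    """Active (hypo-phosphorylated) fraction of Wee1 as a function of MPF.

    Wee1 is phosphorylated on eight sites by MPF (ordered-distributive) and
    dephosphorylated by the counter-acting phosphatase CAP; ``s`` is the
    activity ratio [MPF]/[CAP].  States P0-P4 of the nine phospho-states are
    active, so the active fraction is

        (1 + s + ... + s^4) / (1 + s + ... + s^8),

    equivalently (1-s^5)/(1-s^9) away from s = 1.  Decreases from 1 at
    s = 0 to 0 as s -> inf, with value 5/9 at s = 1.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise DomainError("phosphorylation activity ratio must be >= 0")
    return _geom_ratio(s, range(5), 8)


def cdc25_active_fraction(s):
    """Active (hyper-phosphorylated) fraction of Cdc25 as a function of MPF.

    Same nine-state chain as :func:`wee1_active_fraction`, but states P5-P8
    are the active ones:  s^5(1-s^4)/(1-s^9), i.e.
    (s^5 + ... + s^8)/(1 + ... + s^8).  Increases from 0 to 1, value 4/9 at
    s = 1, and the complement of the Wee1 fraction for every s.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise DomainError("phosphorylation activity ratio must be >= 0")
    return _geom_ratio(s, range(5, 9), 8)


# --------------------------------------------------------------------------
# Right-hand sides
# --------------------------------------------------------------------------

def _check_dim(state: np.ndarray, n: int, model_id: str) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (n,):
        raise ValueError(f"{model_id} expects a state vector of length {n}, "
                         f"got shape {state.shape}")
    return state


def model1_rhs(state, p: ParameterSet) -> np.ndarray:
    """Negative-feedback oscillator: d/dt of [MPF, KinP, APCP].

    MPF activates an intermediary kinase (Michaelis-Menten kinetics), which
    activates APC/C, which degrades cyclin B and hence MPF.  Free forms by
    conservation: Kin = Kin_tot - KinP, APC = APC_tot - APCP.
    """
    M, K, A = _check_dim(state, 3, "model1")
    Kin = p.Kin_tot - K
    APC = p.APC_tot - A
    dM = p.ksy_cycb - (p.kde1_cycb + p.kde2_cycb * A) * M
    dK = (p.kph_gwl * M * Kin / (p.Jph_kin + Kin)
          - p.kdp1_gwl * p.PP * K / (p.Jdp_kin + K))
    dA = (p.kph_apc * K * APC / (p.Jph_apc + APC)
          - p.kdp_apc * p.PP * A / (p.Jdp_apc + A))
    return np.array([dM, dK, dA])


def _beg_core(M, G, E, A, C, p: ParameterSet, gwl_by_b55: bool):
    """Shared Gwl/ENSA/B55/APC/Cdc20 fluxes of models 2-4.

    Returns (dGwlP, dENSAP, dAPCP, dAPCPC20, f, B55_free).  Closure inputs
    are clamped at zero so that root-finders may probe slightly outside the
    physical state box; trajectories themselves never leave it.
    """
    EB = tqssa_complex(E if E > 0.0 else 0.0, p.B55_tot, p.Km_tqssa)
    B55 = p.B55_tot - EB
    f = ub_fraction((C if C > 0.0 else 0.0) / p.deUb)
    dp_gwl = p.kdp1_gwl * p.PP + (p.kdp2_gwl * B55 if gwl_by_b55 else 0.0)
    dG = p.kph_gwl * M * (p.Gwl_tot - G) - dp_gwl * G
    dE = p.kph_ensa * G * (p.ENSA_tot - E) - p.kcat * EB
    dA = p.kph_apc * M * (p.APC_tot - A) - p.kdp_apc * B55 * A
    dC = p.kas1 * (A - C) * (p.Cdc20_tot - C) - p.kdi1 * C
    return dG, dE, dA, dC, f, B55


def model2_rhs(state, p: ParameterSet) -> np.ndarray:
    """BEG feed-forward loop: d/dt of [MPF, GwlP, ENSAP, APCP, APCPC20].

    Cyclin degradation is (kde1 + f*kde2)*[MPF] with f the polyubiquitinated
    fraction; ENSA dephosphorylation goes through the tQSSA complex; APC_P
    binds Cdc20 by mass action (free APC_P = APCP - APCPC20).
    """
    M, G, E, A, C = _check_dim(state, 5, "model2")
    dG, dE, dA, dC, f, _ = _beg_core(M, G, E, A, C, p, gwl_by_b55=False)
    dM = p.ksy_cycb - (p.kde1_cycb + f * p.kde2_cycb) * M
    return np.array([dM, dG, dE, dA, dC])


def model3_rhs(state, p: ParameterSet) -> np.ndarray:
    """Model 2 plus dephosphorylation of Gwl by B55 (bistable APC/C switch).

    Identical to :func:`model2_rhs` except that GwlP is dephosphorylated at
    rate (kdp1_gwl*PP + kdp2_gwl*B55_free)*GwlP; with kdp2_gwl = 0 the two
    models coincide exactly.
    """
    M, G, E, A, C = _check_dim(state, 5, "model3")
    dG, dE, dA, dC, f, _ = _beg_core(M, G, E, A, C, p, gwl_by_b55=True)
    dM = p.ksy_cycb - (p.kde1_cycb + f * p.kde2_cycb) * M
    return np.array([dM, dG, dE, dA, dC])


def model4_rhs(state, p: ParameterSet) -> np.ndarray:
    """Tyrosine-phosphorylation switch:
    d/dt of [CycBT, MPF, GwlP, ENSAP, APCP, APCPC20].

    Total cyclin CycBT and active MPF share the APC/C-driven degradation
    factor (kde1 + f*kde2 + kde3*(APC_tot - APCP)); the kde3 term is the
    Cdh1-mediated G1-checkpoint route and vanishes at the default
    kde3_cycb = 0.  MPF is additionally inactivated by Wee1
    (rate kph1*Wee1P + kph2*Wee1, the unphosphorylated form being more
    active) and reactivated from the phospho-Cdk1 pool (CycBT - MPF) by
    Cdc25 (rate kdp1*Cdc25 + kdp2*Cdc25P, the phosphorylated form being
    more active).  Wee1/Cdc25 partitioning follows the nine-state
    multisite-phosphorylation closures at ratio s = MPF/CAP.
    """
    BT, M, G, E, A, C = _check_dim(state, 6, "model4")
    dG, dE, dA, dC, f, _ = _beg_core(M, G, E, A, C, p, gwl_by_b55=True)
    deg = p.kde1_cycb + f * p.kde2_cycb + p.kde3_cycb * (p.APC_tot - A)
    s = (M if M > 0.0 else 0.0) / p.CAP
    W = p.Wee1_tot * wee1_active_fraction(s)
    WP = p.Wee1_tot - W
    C25P = p.Cdc25_tot * cdc25_active_fraction(s)
    C25 = p.Cdc25_tot - C25P
    dBT = p.ksy_cycb - deg * BT
    dM = (p.ksy_cycb - deg * M
          - (p.kph1_cdk * WP + p.kph2_cdk * W) * M
          + (p.kdp1_cdk * C25 + p.kdp2_cdk * C25P) * (BT - M))
    return np.array([dBT, dM, dG, dE, dA, dC])


# --------------------------------------------------------------------------
# Model definitions and closures
# --------------------------------------------------------------------------

def _closures_beg(state, p: ParameterSet) -> dict[str, float]:
    names = ["MPF", "GwlP", "ENSAP", "APCP", "APCPC20"]
    off = 1 if len(state) >= 6 else 0
    M, G, E, A, C = (state[off + i] for i in range(5))
    EB = tqssa_complex(E, p.B55_tot, p.Km_tqssa)
    out = {
        "ENSAPB55": EB,
        "B55_free": p.B55_tot - EB,
        "f": float(ub_fraction(C / p.deUb)),
    }
    if off:  # model 4: Wee1/Cdc25 partitioning
        s = M / p.CAP
        out["Wee1_active"] = p.Wee1_tot * float(wee1_active_fraction(s))
        out["Cdc25P_active"] = p.Cdc25_tot * float(cdc25_active_fraction(s))
    return out


@dataclass(frozen=True)
class ModelDefinition:
    """A model as a pure evaluatable object: state layout plus rhs/closures."""

    id: str
    state_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, ParameterSet], np.ndarray]
    closures: Callable[[np.ndarray, ParameterSet], dict[str, float]] | None = None
    #: conserved pairs (variable, total-parameter name) for invariant checks
    conservation: tuple[tuple[str, str], ...] = ()
    scenario: "CheckpointScenario | None" = None
    base: "ModelDefinition | None" = None

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def derived(self, state, p: ParameterSet) -> dict[str, float]:
        return self.closures(np.asarray(state, float), p) if self.closures else {}


_BEG_CONS = (("GwlP", "Gwl_tot"), ("ENSAP", "ENSA_tot"),
             ("APCP", "APC_tot"), ("APCPC20", "Cdc20_tot"))

MODEL1 = ModelDefinition(
    id="model1",
    state_names=("MPF", "KinP", "APCP"),
    rhs=model1_rhs,
    conservation=(("KinP", "Kin_tot"), ("APCP", "APC_tot")),
)

MODEL2 = ModelDefinition(
    id="model2",
    state_names=("MPF", "GwlP", "ENSAP", "APCP", "APCPC20"),
    rhs=model2_rhs,
    closures=_closures_beg,
    conservation=_BEG_CONS,
)

MODEL3 = ModelDefinition(
    id="model3",
    state_names=("MPF", "GwlP", "ENSAP", "APCP", "APCPC20"),
    rhs=model3_rhs,
    closures=_closures_beg,
    conservation=_BEG_CONS,
)

MODEL4 = ModelDefinition(
    id="model4",
    state_names=("CycBT", "MPF", "GwlP", "ENSAP", "APCP", "APCPC20"),
    rhs=model4_rhs,
    closures=_closures_beg,
    conservation=_BEG_CONS,
)

_REGISTRY: dict[str, ModelDefinition] = {
    m.id: m for m in (MODEL1, MODEL2, MODEL3, MODEL4)
}

MODEL_IDS = tuple(_REGISTRY)


def get_model(model_id: str) -> ModelDefinition:
    """Look up a model definition by id ('model1' ... 'model4')."""
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; "
                       f"known ids: {sorted(_REGISTRY)}") from None


# --------------------------------------------------------------------------
# Checkpoint variants
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CheckpointScenario:
    """A checkpoint modelled as a parameter change of model 4.

    G2 (unreplicated DNA): part of Cdc25 is sequestered -> Cdc25_tot lowered.
    SAC (unaligned chromosomes): mitotic checkpoint complexes sequester
    Cdc20 -> Cdc20_tot lowered.
    G1 (damaged DNA): Cdh1 stays active and targets cyclin B through
    unphosphorylated APC/C -> kde3_cycb raised from 0.
    """

    kind: str = "none"
    overrides: Mapping[str, float] = field(default_factory=dict)

    _ALLOWED = {
        "none": set(),
        "G2": {"Cdc25_tot"},
        "SAC": {"Cdc20_tot"},
        "G1": {"kde3_cycb"},
    }
    _DEFAULTS = {
        "none": {},
        "G2": {"Cdc25_tot": 0.4},
        "SAC": {"Cdc20_tot": 0.1},
        "G1": {"kde3_cycb": 0.2},
    }

    def __post_init__(self) -> None:
        if self.kind not in self._ALLOWED:
            raise ValueError(f"unknown checkpoint kind {self.kind!r}; "
                             f"known: {sorted(self._ALLOWED)}")
        extra = set(self.overrides) - self._ALLOWED[self.kind]
        if extra:
            raise ValueError(f"scenario {self.kind!r} may only override "
                             f"{sorted(self._ALLOWED[self.kind])}, got {sorted(extra)}")
        if not self.overrides and self.kind != "none":
            object.__setattr__(self, "overrides", dict(self._DEFAULTS[self.kind]))

    def apply(self, p: ParameterSet) -> ParameterSet:
        return p.replace(**dict(self.overrides)) if self.overrides else p


def validate_state(model: ModelDefinition, state, p: ParameterSet,
                   tol: float = 1e-9, check_binding: bool = True) -> None:
    """Raise :class:`InvariantViolation` if ``state`` is unphysical.

    Checks non-negativity, every conserved variable against its total
    (e.g. GwlP <= Gwl_tot), APCPC20 <= APCP (Cdc20 binds phospho-APC only),
    and MPF <= CycBT for model 4 (active MPF is part of the total cyclin
    pool; the region MPF > CycBT is unreachable).

    ``check_binding=False`` skips the APCPC20 <= APCP ordering: it
    constrains admissible *initial* states, but the equations as written
    dephosphorylate the whole phospho-APC pool while Cdc20 unbinds slowly,
    so trajectories can overshoot it transiently during mitotic exit.
    """
    state = np.asarray(state, dtype=float)
    names = model.state_names
    if np.any(state < -tol):
        raise InvariantViolation(f"negative concentration in state {state}")
    for var, total in model.conservation:
        cap = getattr(p, total)
        if cap is not None and state[names.index(var)] > cap + tol:
            raise InvariantViolation(f"{var} = {state[names.index(var)]:.6g} "
                                     f"exceeds {total} = {cap:.6g}")
    if check_binding and "APCPC20" in names and "APCP" in names:
        if state[names.index("APCPC20")] > state[names.index("APCP")] + tol:
            raise InvariantViolation("APCPC20 exceeds APCP")
    if "CycBT" in names:
        if state[names.index("MPF")] > state[names.index("CycBT")] + tol:
            raise InvariantViolation("MPF exceeds CycBT (unreachable region)")


def apply_checkpoint(model: ModelDefinition,
                     scenario: CheckpointScenario) -> ModelDefinition:
    """Return ``model`` with the checkpoint's parameter overrides baked in.

    With ``kind='none'`` the input model is returned unchanged.  The
    returned definition keeps a reference to the unmodified ``base`` so the
    arrest-free dynamics can be restored exactly.
    """
    if model.id != "model4" and model.base is None:
        raise ValueError("checkpoints are defined for model4 only")
    if scenario.kind == "none":
        return model.base or model
    base = model.base or model

    def rhs(state, p, _s=scenario, _r=base.rhs):
        return _r(state, _s.apply(p))

    def closures(state, p, _s=scenario, _c=base.closures):
        return _c(state, _s.apply(p))

    return ModelDefinition(
        id=f"{base.id}_{scenario.kind.lower()}",
        state_names=base.state_names,
        rhs=rhs,
        closures=closures,
        conservation=base.conservation,
        scenario=scenario,
        base=base,
    )
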