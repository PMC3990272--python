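"""Four-state Markov cohort engine for the two treatment arms.

States
------
``MLP``  minimal light perception — the baseline Retinitis Pigmentosa state,
         where the usual-care cohort stays for the whole horizon.
``LP``   light perception (visual acuity +).
``CF``   counting fingers (visual acuity ++).
``RL``   reading letters (visual acuity +++).
``EXPLANTED`` bookkeeping state for patients whose device was surgically
         removed; carries baseline economics (utility ``uExplant``, annual
         cost ``cRP``) and lets explantation be costed exactly once.

The published model leaves several structural choices open (when the visual-
acuity allocation happens, when the explantation hazard starts, which states
it applies to, what happens to the residual MLP mass, which states pay the
annual device-upkeep cost).  All of them are explicit fields of
:class:`StructureConfig`; :mod:`argus_cua.calibrate` enumerates the candidate
grid and selects the configuration that reproduces the published results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, range_implied_parameters

__all__ = [
    "STATES", "MLP", "LP", "CF", "RL", "EXPLANTED",
    "StructureConfig", "CohortTrace", "StructuralError",
    "build_transition_matrix", "run_cohort", "resolve_parameters",
]

STATES: tuple[str, ...] = ("MLP", "LP", "CF", "RL", "EXPLANTED")
MLP, LP, CF, RL, EXPLANTED = range(5)
N_STATES = len(STATES)
_ROW_TOL = 1e-12


class StructuralError(ValueError):
    """A transition row acquired probability mass outside [0, 1]."""


@dataclass(frozen=True)
class StructureConfig:
    """Explicit encoding of every structural choice the model leaves open.

    Defaults are the calibrated configuration (see ``calibrate.select_structure``):
    visual-acuity outcomes allocated in cycle 0, residual MLP mass stationary,
    10%/year upward drift LP→CF→RL afterwards, explantation hazard from cycle 1
    applied to the improved states into an absorbing EXPLANTED state, SAE cost
    and disutility in cycle 0 only, device cost at cycle 0, annual upkeep cost
    attached to EXPLANTED occupancy, first cycle undiscounted, no half-cycle
    correction, and working parameter values recovered from the printed ±25%
    ranges rather than the 2-dp deterministic column.
    """

    transition_semantics: str = "first_cycle_allocation"  # | "per_cycle_from_MLP"
    upward_rate: float = 0.10
    mlp_drift: bool = False  # does residual MLP mass also move up at upward_rate?
    explant_start: int = 1  # first cycle in which the explantation hazard applies
    explant_source: str = "va_states"  # | "implanted" (also MLP residual)
    explant_destination: str = "explanted"  # | "mlp" (recycle into baseline state)
    sae_first_cycle_only: bool = True
    device_cost_cycle: int = 0
    others_coverage: str = "explanted"  # | "implanted" | "all" | "none"
    discount_convention: str = "first_cycle_undiscounted"  # | "all_cycles_discounted"
    half_cycle_correction: bool = False
    mode_policy: str = "range_implied"  # | "printed"

    def __post_init__(self) -> None:
        if self.transition_semantics not in ("first_cycle_allocation", "per_cycle_from_MLP"):
            raise ValueError(f"unknown transition_semantics {self.transition_semantics!r}")
        if not (0.0 <= self.upward_rate <= 1.0):
            raise ValueError(f"upward_rate {self.upward_rate} out of [0,1]")
        if self.explant_start < 0:
            raise ValueError("explant_start must be >= 0")
        if self.explant_source not in ("implanted", "va_states"):
            raise ValueError(f"unknown explant_source {self.explant_source!r}")
        if self.explant_destination not in ("explanted", "mlp"):
            raise ValueError(f"unknown explant_destination {self.explant_destination!r}")
        if self.others_coverage not in ("explanted", "implanted", "all", "none"):
            raise ValueError(f"unknown others_coverage {self.others_coverage!r}")
        if self.discount_convention not in ("first_cycle_undiscounted", "all_cycles_discounted"):
            raise ValueError(f"unknown discount_convention {self.discount_convention!r}")
        if self.mode_policy not in ("printed", "range_implied"):
            raise ValueError(f"unknown mode_policy {self.mode_policy!r}")

    @property
    def explant_absorbing(self) -> bool:
        return self.explant_destination == "explanted"

    def digest(self) -> str:
        """Short reproducible label for reports and run manifests."""
        sem = "alloc0" if self.transition_semantics == "first_cycle_allocation" else "percyc"
        return (
            f"{sem}-drift{int(self.mlp_drift)}-e{self.explant_start}"
            f"{'I' if self.explant_source == 'implanted' else 'V'}"
            f"{'X' if self.explant_absorbing else 'M'}"
            f"-oth:{self.others_coverage}-{self.mode_policy}"
        )


def resolve_parameters(ps: ParameterSet, sc: StructureConfig) -> ParameterSet:
    """Apply the structure's mode policy to a deterministic parameter set.

    Called once at pipeline entry (scenario runs, calibration scoring) —
    never on sampled sets, whose working values must pass through verbatim.
    """
    return range_implied_parameters(ps) if sc.mode_policy == "range_implied" else ps


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and event incidence for one arm.

    ``occupancy[t]`` is the distribution over :data:`STATES` during cycle
    ``t`` (year ``t+1`` of the model); ``sae_incidence[t]`` and
    ``explant_incidence[t]`` are the proportions newly experiencing a serious
    adverse event / explantation in that cycle.
    """

    arm: str
    occupancy: np.ndarray  # (n_cycles, n_states)
    sae_incidence: np.ndarray  # (n_cycles,)
    explant_incidence: np.ndarray  # (n_cycles,)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def check(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise StructuralError(f"occupancy rows do not sum to 1: {sums}")
        if (self.occupancy < -1e-12).any():
            raise StructuralError("negative occupancy")

    def to_frame(self):
        """Tidy export: one row per (cycle, state)."""
        import pandas as pd

        rows = []
        for t in range(self.n_cycles):
            for s, name in enumerate(STATES):
                rows.append(
                    dict(cycle=t, state=name, occupancy=self.occupancy[t, s],
                         sae_incidence=self.sae_incidence[t],
                         explant_incidence=self.explant_incidence[t], arm=self.arm)
                )
        return pd.DataFrame(rows)


def _va_matrix(ps: ParameterSet, sc: StructureConfig, cycle: int, strict: bool = True) -> np.ndarray:
    """Visual-acuity movement for one cycle (no explantation)."""
    m = np.eye(N_STATES)
    allocate = (
        cycle == 0
        if sc.transition_semantics == "first_cycle_allocation"
        else True
    )
    if allocate:
        pv = (float(ps.pVAplus), float(ps.pVAplusplus), float(ps.pVAplusplusplus))
        stay = 1.0 - sum(pv)
        if stay < -_ROW_TOL and strict:
            raise StructuralError(
                f"MLP row: allocation probabilities sum to {sum(pv):.6g} > 1"
            )
        # non-strict mode lets a sampled allocation mass slightly above 1
        # through as a negative residual, as the published simulation did
        m[MLP, MLP] = stay if stay < 0 else max(stay, 0.0)
        m[MLP, LP], m[MLP, CF], m[MLP, RL] = pv
    if cycle >= 1 or sc.transition_semantics == "per_cycle_from_MLP":
        up = sc.upward_rate
        if sc.mlp_drift and not allocate:
            m[MLP, MLP] -= up
            m[MLP, LP] += up
        m[LP, LP] -= up
        m[LP, CF] += up
        m[CF, CF] -= up
        m[CF, RL] += up
    return m


def _explant_matrix(ps: ParameterSet, sc: StructureConfig, cycle: int) -> np.ndarray:
    m = np.eye(N_STATES)
    if cycle < sc.explant_start:
        return m
    pexp = float(ps.pExplant)
    sources = (MLP, LP, CF, RL) if sc.explant_source == "implanted" else (LP, CF, RL)
    dest = EXPLANTED if sc.explant_absorbing else MLP
    for s in sources:
        if s == dest:
            continue
        m[s, s] = 1.0 - pexp
        m[s, dest] += pexp
    return m


def build_transition_matrix(
    ps: ParameterSet, sc: StructureConfig, cycle: int, strict: bool = True
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix over :data:`STATES`.

    Visual-acuity movement is applied first, then the explantation hazard
    (competing risks resolved multiplicatively in that order).  With
    ``strict=False`` an allocation mass above 1 is tolerated (negative MLP
    residual); rows still sum to 1.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    m = _va_matrix(ps, sc, cycle, strict) @ _explant_matrix(ps, sc, cycle)
    rows = m.sum(axis=1)
    for i, total in enumerate(rows):
        if abs(total - 1.0) > 1e-9 or (strict and (m[i] < -_ROW_TOL).any()):
            raise StructuralError(f"row {STATES[i]} is not a probability vector: {m[i]}")
    return m


def run_cohort(
    arm: str,
    ps: ParameterSet,
    sc: StructureConfig,
    horizon: int | None = None,
    strict: bool = True,
) -> CohortTrace:
    """Propagate a unit cohort through the model and record the trace.

    ``arm`` is ``"argus"`` (prosthesis) or ``"cau"`` (care as usual, which by
    construction stays at minimal light perception with no events).
    """
    if arm not in ("argus", "cau"):
        raise ValueError(f"unknown arm {arm!r}; expected 'argus' or 'cau'")
    horizon = int(ps.horizon if horizon is None else horizon)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")

    occ = np.zeros((horizon, N_STATES))
    sae = np.zeros(horizon)
    expl = np.zeros(horizon)
    if arm == "cau":
        occ[:, MLP] = 1.0
        return CohortTrace(arm=arm, occupancy=occ, sae_incidence=sae, explant_incidence=expl)

    y = np.zeros(N_STATES)
    y[MLP] = 1.0
    for t in range(horizon):
        y_mid = y @ _va_matrix(ps, sc, t, strict)
        e = _explant_matrix(ps, sc, t)
        # new explantations = mass leaving each source state this cycle
        expl[t] = sum(y_mid[s] * (1.0 - e[s, s]) for s in range(N_STATES) if s != EXPLANTED)
        y = y_mid @ e
        occ[t] = y
    if sc.sae_first_cycle_only:
        sae[0] = float(ps.pSAE)
    else:
        sae[:] = float(ps.pSAE)
    trace = CohortTrace(arm=arm, occupancy=occ, sae_incidence=sae, explant_incidence=expl)
    if strict:
        trace.check()
    return trace
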