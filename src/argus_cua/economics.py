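"""Discounted cost/QALY accumulation, ICER and net monetary benefit.

Per cycle ``t`` the cohort accrues

* cost: occupancy-weighted annual state costs (stepped — lower with better
  visual acuity — or constant at the baseline care cost), plus the annual
  device-upkeep cost for the states the structure assigns it to, plus
  per-event costs for new serious adverse events and explantations, plus the
  one-time device + implantation cost in the configured cycle (prosthesis arm
  only);
* QALYs: occupancy-weighted state utilities minus the SAE disutility times
  new SAE incidence.

Both streams are discounted at the annual rates in the parameter set; under
the default convention cycle 0 is undiscounted, i.e. the weight of cycle
``t`` is ``(1+r)^-t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import EXPLANTED, CohortTrace, StructureConfig
from .parameters import ParameterSet

__all__ = [
    "ArmResult", "discount_factor", "discount_weights", "annuity",
    "accumulate", "incremental", "icer", "icer_status", "nmb",
]


def discount_factor(t: int, r: float, convention: str = "first_cycle_undiscounted") -> float:
    """Present-value weight of cycle ``t`` at annual rate ``r``."""
    if t < 0:
        raise ValueError("cycle index must be >= 0")
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    shift = 0 if convention == "first_cycle_undiscounted" else 1
    return (1.0 + r) ** -(t + shift)


def discount_weights(horizon: int, r: float, convention: str = "first_cycle_undiscounted") -> np.ndarray:
    return np.array([discount_factor(t, r, convention) for t in range(horizon)])


def annuity(r: float, horizon: int) -> float:
    """Closed-form sum of discount weights, Σ_{t=0}^{H-1} (1+r)^-t."""
    if r == 0:
        return float(horizon)
    v = 1.0 / (1.0 + r)
    return (1.0 - v**horizon) / (1.0 - v)


@dataclass
class ArmResult:
    """Discounted totals and per-cycle streams for one arm of one scenario."""

    arm: str
    scenario: str
    horizon: int
    discounted_cost: float
    discounted_qaly: float
    cost_stream: np.ndarray  # undiscounted, per cycle
    qaly_stream: np.ndarray
    disc_cost_stream: np.ndarray
    disc_qaly_stream: np.ndarray

    def check(self) -> None:
        assert abs(self.discounted_cost - self.disc_cost_stream.sum()) < 1e-9 * max(1.0, abs(self.discounted_cost))
        assert abs(self.discounted_qaly - self.disc_qaly_stream.sum()) < 1e-9


def accumulate(
    trace: CohortTrace,
    ps: ParameterSet,
    sc: StructureConfig,
    cost_mode: str = "stepped",
    horizon: int | None = None,
    scenario: str = "",
) -> ArmResult:
    """Convert a cohort trace into discounted cost and QALY totals."""
    if cost_mode not in ("stepped", "constant"):
        raise ValueError(f"unknown cost_mode {cost_mode!r}")
    H = trace.n_cycles
    if horizon is not None and horizon != H:
        raise ValueError(f"trace has {H} cycles but horizon {horizon} requested")
    pv = ps

    if cost_mode == "stepped":
        state_cost = np.array([pv.cRP, pv.cVAplus, pv.cVAplusplus, pv.cVAplusplusplus, pv.cRP], float)
    else:
        state_cost = np.full(5, float(pv.cRP))
    state_util = np.array([pv.uRP, pv.uVAplus, pv.uVAplusplus, pv.uVAplusplusplus, pv.uExplant], float)

    occ = trace.occupancy
    cost = occ @ state_cost
    if sc.others_coverage == "implanted":
        cost = cost + float(pv.cOthers) * occ[:, :EXPLANTED].sum(axis=1)
    elif sc.others_coverage == "explanted":
        cost = cost + float(pv.cOthers) * occ[:, EXPLANTED]
    elif sc.others_coverage == "all":
        cost = cost + float(pv.cOthers) * np.ones(H)
    cost = cost + float(pv.cSAE) * trace.sae_incidence
    cost = cost + float(pv.cExplant) * trace.explant_incidence
    if trace.arm == "argus" and 0 <= sc.device_cost_cycle < H:
        cost = cost.copy()
        cost[sc.device_cost_cycle] += float(pv.cArgusII)

    qaly = occ @ state_util - float(pv.uSAE) * trace.sae_incidence

    wc = discount_weights(H, float(pv.cDR), sc.discount_convention)
    wq = discount_weights(H, float(pv.oDR), sc.discount_convention)
    if sc.half_cycle_correction:
        # half-cycle correction halves the first and appends half a final cycle
        wc = wc.copy(); wq = wq.copy()
        wc[0] *= 0.5; wq[0] *= 0.5

    res = ArmResult(
        arm=trace.arm, scenario=scenario, horizon=H,
        discounted_cost=float(cost @ wc), discounted_qaly=float(qaly @ wq),
        cost_stream=cost, qaly_stream=qaly,
        disc_cost_stream=cost * wc, disc_qaly_stream=qaly * wq,
    )
    res.check()
    return res


def incremental(intervention: ArmResult, comparator: ArmResult) -> tuple[float, float]:
    """(Δcost, ΔQALY) of intervention over comparator, unrounded."""
    return (
        intervention.discounted_cost - comparator.discounted_cost,
        intervention.discounted_qaly - comparator.discounted_qaly,
    )


def icer_status(d_cost: float, d_qaly: float) -> str:
    """Classify an incremental pair: ok / undefined / dominant / dominated."""
    if d_qaly == 0.0:
        return "undefined"
    if d_qaly > 0.0 and d_cost <= 0.0:
        return "dominant"
    if d_qaly < 0.0 and d_cost > 0.0:
        return "dominated"
    return "ok"


def icer(intervention: ArmResult, comparator: ArmResult) -> float:
    """Incremental cost-effectiveness ratio in €/QALY from unrounded totals.

    Returns NaN when the QALY increment is zero (undefined ICER); use
    :func:`icer_status` to distinguish dominance cases.
    """
    d_cost, d_qaly = incremental(intervention, comparator)
    if d_qaly == 0.0:
        return math.nan
    return d_cost / d_qaly


def nmb(intervention: ArmResult, comparator: ArmResult, wtp: float) -> float:
    """Net monetary benefit ``wtp·ΔQALY − Δcost``; positive ⇔ cost-effective."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    d_cost, d_qaly = incremental(intervention, comparator)
    return wtp * d_qaly - d_cost
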