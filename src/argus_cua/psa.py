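"""Probabilistic sensitivity analysis: Beta-PERT sampling, Monte Carlo
propagation, probabilistic ICER, CE plane and acceptability curves.

Each uncertain parameter is drawn independently from a Beta distribution
rescaled to its published [min, max] range.  Three parameterizations are
supported:

``direct``  Beta(alpha1, alpha2) = Beta(5, 5) — the published shape columns.
``pert``    classic PERT, Beta(1 + 4·(m−min)/(max−min), 1 + 4·(max−m)/(max−min)).
``gamma``   PERT with the published shape constant 8 in place of 4.

With the symmetric ±25% ranges all three are symmetric about the mode, so
sample means — and therefore the headline probabilistic results — are
insensitive to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import accumulate
from .markov import StructureConfig, run_cohort
from .parameters import (
    PARAM_NAMES, PROBABILITY_PARAMS, DistributionSpec, ParameterSet,
)

__all__ = [
    "PSAResult", "sample_beta_pert", "beta_shape_parameters",
    "draw_parameter_set", "draw_violations", "run_psa", "summarize_psa", "ceac",
]

_MAX_RESAMPLE = 100


def beta_shape_parameters(spec: DistributionSpec, method: str = "direct") -> tuple[float, float]:
    """Beta shape pair (a, b) for a spec under the chosen parameterization."""
    if method == "direct":
        return spec.alpha1, spec.alpha2
    shape = 4.0 if method == "pert" else spec.shape
    span = spec.max - spec.min
    frac = (spec.mode - spec.min) / span
    return 1.0 + shape * frac, 1.0 + shape * (1.0 - frac)


def sample_beta_pert(
    spec: DistributionSpec, rng: np.random.Generator, method: str = "direct", size=None
):
    """Draw from the Beta-PERT distribution of one parameter.

    A ``fixed`` spec returns its mode; otherwise the draw is
    ``min + (max − min)·B`` with ``B`` Beta-distributed, so samples always lie
    in [min, max].
    """
    if spec.kind == "fixed":
        return spec.mode if size is None else np.full(size, spec.mode)
    if not (spec.min < spec.max):
        raise ValueError(f"degenerate beta_pert range [{spec.min}, {spec.max}]")
    a, b = beta_shape_parameters(spec, method)
    return spec.min + (spec.max - spec.min) * rng.beta(a, b, size=size)


def draw_violations(ps: ParameterSet) -> list[str]:
    """Hard feasibility constraints a sampled set must satisfy.

    Only the constraints the cohort engine needs: probabilities within [0, 1]
    and a visual-acuity allocation mass of at most 1.  The stepped cost
    ordering is deliberately *not* enforced on draws — the ranges of adjacent
    state costs overlap, so independent draws cross occasionally; that is
    ordinary parameter uncertainty, not an infeasible model.
    """
    v = []
    for name in PROBABILITY_PARAMS:
        x = float(getattr(ps, name))
        if not (0.0 <= x <= 1.0):
            v.append(f"{name}: probability {x} out of [0,1]")
    mass = float(ps.pVAplus) + float(ps.pVAplusplus) + float(ps.pVAplusplusplus)
    if mass > 1.0:
        v.append(f"visual-acuity allocation mass {mass:.6g} > 1")
    return v


def draw_parameter_set(
    ps: ParameterSet,
    rng: np.random.Generator,
    method: str = "direct",
    on_violation: str = "allow",
) -> tuple[ParameterSet, int]:
    """One joint draw of all uncertain parameters.

    Fixed parameters pass through.  A joint violation — the three sampled
    visual-acuity probabilities summing above 1, which their wide ±25% ranges
    make common (≈39% of draws) rather than exceptional — is handled per
    ``on_violation``:

    ``allow`` (default)  keep the draw; the cohort engine carries the excess
        as a negative MLP residual in that draw.  Unconstrained symmetric
        sampling keeps the simulation means at the deterministic values,
        which is how the published probabilistic block behaves.
    ``normalize``  rescale the three probabilities to sum to 1 (no residual
        MLP mass in that draw); shifts the mean allocation mass down.
    ``resample``  reject and redraw the whole vector; truncates the upper
        tail of the allocation mass and biases the means further.

    Returns the drawn set and the number of violations encountered so
    callers can log the frequency.
    """
    if on_violation not in ("allow", "normalize", "resample"):
        raise ValueError(f"unknown on_violation {on_violation!r}")
    violations = 0
    for _ in range(_MAX_RESAMPLE):
        values = {
            name: float(sample_beta_pert(getattr(ps, name).spec, rng, method))
            for name in PARAM_NAMES
        }
        mass = values["pVAplus"] + values["pVAplusplus"] + values["pVAplusplusplus"]
        if mass > 1.0:
            violations += 1
            if on_violation == "resample":
                continue
            if on_violation == "normalize":
                for name in ("pVAplus", "pVAplusplus", "pVAplusplusplus"):
                    values[name] /= mass
        drawn = ps.with_values(values)
        if on_violation == "allow" or not draw_violations(drawn):
            return drawn, violations
    raise RuntimeError(f"could not draw a valid parameter set in {_MAX_RESAMPLE} attempts")


@dataclass
class PSAResult:
    """Monte Carlo draws of per-arm discounted totals and increments."""

    n: int
    seed: int
    horizon: int
    cost_mode: str
    method: str
    costs: pd.DataFrame  # columns: argus, cau  (one row per draw)
    qalys: pd.DataFrame
    d_cost: np.ndarray
    d_qaly: np.ndarray
    params: pd.DataFrame  # sampled parameter values, one row per draw
    rejections: int = 0

    def digest(self) -> str:
        """Hash of the draw matrix — equal seeds give equal digests."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.d_cost).tobytes())
        h.update(np.ascontiguousarray(self.d_qaly).tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        out = self.params.copy()
        out["cost_argus"] = self.costs["argus"].to_numpy()
        out["cost_cau"] = self.costs["cau"].to_numpy()
        out["qaly_argus"] = self.qalys["argus"].to_numpy()
        out["qaly_cau"] = self.qalys["cau"].to_numpy()
        out["d_cost"] = self.d_cost
        out["d_qaly"] = self.d_qaly
        return out


def run_psa(
    ps: ParameterSet,
    sc: StructureConfig,
    n: int = 1000,
    seed: int = 0,
    horizon: int | None = None,
    cost_mode: str = "stepped",
    method: str = "direct",
    on_violation: str = "allow",
) -> PSAResult:
    """Propagate parameter uncertainty through both arms, ``n`` times.

    Each iteration draws one joint parameter set and re-runs both arms with
    it (common random parameters across arms).  Reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    horizon = int(ps.horizon if horizon is None else horizon)
    rng = np.random.default_rng(seed)
    cost = np.empty((n, 2))
    qaly = np.empty((n, 2))
    rows = []
    rejections = 0
    strict = on_violation != "allow"
    for i in range(n):
        drawn, rej = draw_parameter_set(ps, rng, method, on_violation)
        rejections += rej
        rows.append(drawn.value_dict())
        for j, arm in enumerate(("argus", "cau")):
            trace = run_cohort(arm, drawn, sc, horizon, strict=strict)
            res = accumulate(trace, drawn, sc, cost_mode=cost_mode)
            cost[i, j] = res.discounted_cost
            qaly[i, j] = res.discounted_qaly
    costs = pd.DataFrame(cost, columns=["argus", "cau"])
    qalys = pd.DataFrame(qaly, columns=["argus", "cau"])
    return PSAResult(
        n=n, seed=seed, horizon=horizon, cost_mode=cost_mode, method=method,
        costs=costs, qalys=qalys,
        d_cost=cost[:, 0] - cost[:, 1], d_qaly=qaly[:, 0] - qaly[:, 1],
        params=pd.DataFrame(rows), rejections=rejections,
    )


def summarize_psa(res: PSAResult) -> dict:
    """Means of the simulation and the probabilistic ICER (ratio of means).

    The mean-of-ratios is also exposed for comparison but the headline
    probabilistic ICER is mean(Δcost)/mean(ΔQALY).
    """
    mean_dc = float(res.d_cost.mean())
    mean_dq = float(res.d_qaly.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = res.d_cost / res.d_qaly
    return {
        "n": res.n,
        "mean_cost_argus": float(res.costs["argus"].mean()),
        "mean_cost_cau": float(res.costs["cau"].mean()),
        "mean_qaly_argus": float(res.qalys["argus"].mean()),
        "mean_qaly_cau": float(res.qalys["cau"].mean()),
        "mean_d_cost": mean_dc,
        "mean_d_qaly": mean_dq,
        "icer": mean_dc / mean_dq if mean_dq != 0.0 else float("nan"),
        "mean_of_ratios": float(np.mean(ratios[np.isfinite(ratios)])) if np.isfinite(ratios).any() else float("nan"),
    }


def ceac(res: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the proportion of draws with positive
    net monetary benefit ``wtp·ΔQALY − Δcost``.
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0, 50001, 1000)
    wtp_grid = np.asarray(list(wtp_grid), float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if (wtp_grid < 0).any():
        raise ValueError("willingness-to-pay values must be >= 0")
    prop = [
        float(np.mean(w * res.d_qaly - res.d_cost > 0.0)) for w in wtp_grid
    ]
    return pd.DataFrame({"wtp": wtp_grid, "proportion_cost_effective": prop})
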