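"""The published scenario grid and table rendering.

Six scenarios: the 25-year base case, shortened horizons of 20 and 10 years,
and the same three horizons under the conservative constant-cost assumption
(every health state costed at the baseline annual care cost, i.e. no cost
reduction with improved visual acuity).  Each scenario is run
deterministically and, optionally, probabilistically.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .economics import ArmResult, accumulate, icer, icer_status, incremental
from .markov import StructureConfig, resolve_parameters, run_cohort
from .parameters import ParameterSet, default_table1
from .psa import PSAResult, ceac, run_psa, summarize_psa

__all__ = [
    "SCENARIOS", "ScenarioResult", "run_deterministic", "run_scenario",
    "run_grid", "render_tables", "round_half_up",
]

#: label -> (horizon in years, cost mode)
SCENARIOS: dict[str, tuple[int, str]] = {
    "base25": (25, "stepped"),
    "h20": (20, "stepped"),
    "h10": (10, "stepped"),
    "const25": (25, "constant"),
    "const20": (20, "constant"),
    "const10": (10, "constant"),
}


@dataclass
class ScenarioResult:
    label: str
    horizon: int
    cost_mode: str
    argus: ArmResult
    cau: ArmResult
    d_cost: float
    d_qaly: float
    icer: float
    icer_status: str
    psa_summary: dict | None = None
    psa: PSAResult | None = None
    n: int = 0
    seed: int | None = None


def run_deterministic(
    label: str,
    ps: ParameterSet | None = None,
    sc: StructureConfig | None = None,
) -> ScenarioResult:
    """Run one scenario deterministically (no Monte Carlo block)."""
    if label not in SCENARIOS:
        raise ValueError(f"unknown scenario {label!r}; valid: {sorted(SCENARIOS)}")
    ps = default_table1() if ps is None else ps
    sc = StructureConfig() if sc is None else sc
    horizon, cost_mode = SCENARIOS[label]
    pv = resolve_parameters(ps, sc)
    arms = {}
    for arm in ("argus", "cau"):
        trace = run_cohort(arm, pv, sc, horizon)
        arms[arm] = accumulate(trace, pv, sc, cost_mode=cost_mode, scenario=label)
    d_cost, d_qaly = incremental(arms["argus"], arms["cau"])
    return ScenarioResult(
        label=label, horizon=horizon, cost_mode=cost_mode,
        argus=arms["argus"], cau=arms["cau"],
        d_cost=d_cost, d_qaly=d_qaly,
        icer=icer(arms["argus"], arms["cau"]),
        icer_status=icer_status(d_cost, d_qaly),
    )


def run_scenario(
    label: str,
    ps: ParameterSet | None = None,
    sc: StructureConfig | None = None,
    n: int = 1000,
    seed: int = 0,
) -> ScenarioResult:
    """Run one scenario with both the deterministic and probabilistic blocks."""
    res = run_deterministic(label, ps, sc)
    if n > 0:
        ps = default_table1() if ps is None else ps
        sc = StructureConfig() if sc is None else sc
        psa_res = run_psa(
            ps, sc, n=n, seed=seed, horizon=res.horizon, cost_mode=res.cost_mode
        )
        res.psa = psa_res
        res.psa_summary = summarize_psa(psa_res)
        res.n = n
        res.seed = seed
    return res


def run_grid(
    ps: ParameterSet | None = None,
    sc: StructureConfig | None = None,
    n: int = 1000,
    seed: int = 0,
) -> dict[str, ScenarioResult]:
    """Run all six published scenarios; PSA seeds offset per scenario."""
    out = {}
    for i, label in enumerate(SCENARIOS):
        out[label] = run_scenario(label, ps, sc, n=n, seed=seed + i)
    return out


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt_eur(x: float) -> str:
    return f"{round_half_up(x):,.0f}"


def _fmt_qaly(x: float) -> str:
    return f"{round_half_up(x, 2):.2f}"


def render_tables(results: list[ScenarioResult] | dict[str, ScenarioResult]) -> dict[str, pd.DataFrame]:
    """Per-scenario tables mirroring the published layout.

    Rows: Argus II / CAU / Increment / ICER; columns: deterministic and
    probabilistic discounted costs and QALYs.  Costs are rounded half-up to
    whole euros, QALYs to two decimals; the ICER is computed from unrounded
    totals.  Scenarios without a probabilistic block leave those columns
    empty.
    """
    if isinstance(results, dict):
        results = list(results.values())
    if not results:
        raise ValueError("no scenario results to render")
    tables: dict[str, pd.DataFrame] = {}
    for r in results:
        s = r.psa_summary
        det_icer = "undefined" if r.icer_status == "undefined" else _fmt_eur(r.icer)
        rows = {
            "Argus II": [
                _fmt_eur(r.argus.discounted_cost), _fmt_qaly(r.argus.discounted_qaly),
                _fmt_eur(s["mean_cost_argus"]) if s else "", _fmt_qaly(s["mean_qaly_argus"]) if s else "",
            ],
            "CAU": [
                _fmt_eur(r.cau.discounted_cost), _fmt_qaly(r.cau.discounted_qaly),
                _fmt_eur(s["mean_cost_cau"]) if s else "", _fmt_qaly(s["mean_qaly_cau"]) if s else "",
            ],
            "Increment": [
                _fmt_eur(r.d_cost), _fmt_qaly(r.d_qaly),
                _fmt_eur(s["mean_d_cost"]) if s else "", _fmt_qaly(s["mean_d_qaly"]) if s else "",
            ],
            "ICERs": [det_icer, "", _fmt_eur(s["icer"]) if s else "", ""],
        }
        tables[r.label] = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["Disc costs", "Disc QALYs", "Disc costs (PSA)", "Disc QALYs (PSA)"],
        )
    return tables


def tables_to_text(tables: dict[str, pd.DataFrame]) -> str:
    parts = []
    for label, df in tables.items():
        parts.append(f"== {label} ==")
        parts.append(df.to_string())
        parts.append("")
    return "\n".join(parts)
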