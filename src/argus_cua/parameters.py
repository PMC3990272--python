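"""Model inputs: costs, transition probabilities, utilities and their uncertainty.

Every model input is a :class:`Param` — a ``float`` subclass that carries its
:class:`DistributionSpec` (Beta-PERT range and shape constants, or ``fixed``).
A :class:`ParameterSet` bundles the 21 named inputs together with the cohort
settings (size, start age, horizon) and validates the economic invariants
(probabilities in [0, 1], ordered stepped state costs, utilities in [0, 1]).

Two value policies exist for the four transition probabilities whose published
deterministic values were rounded to two decimals while their ±25% uncertainty
ranges were printed at higher precision: ``printed`` takes the deterministic
column verbatim, ``range_implied`` inverts the ±25% construction of the ranges
(mode = mean of min/0.75 and max/1.25).  The calibrated default pipeline uses
``range_implied``; see :mod:`argus_cua.calibrate`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "DistributionSpec",
    "Param",
    "ParameterSet",
    "default_table1",
    "range_implied_parameters",
    "load_parameters",
    "loads_parameters",
    "validate",
    "pert_range",
]

#: names of parameters that are probabilities (bounded to [0, 1])
PROBABILITY_PARAMS = ("pVAplus", "pVAplusplus", "pVAplusplusplus", "pSAE", "pExplant")
#: names of parameters that are utilities or utility decrements (bounded to [0, 1])
UTILITY_PARAMS = ("uRP", "uVAplus", "uVAplusplus", "uVAplusplusplus", "uSAE", "uExplant")
#: names of cost parameters (non-negative, in 2012 €)
COST_PARAMS = (
    "cArgusII", "cRP", "cVAplus", "cVAplusplus", "cVAplusplusplus",
    "cSAE", "cExplant", "cOthers",
)
RATE_PARAMS = ("cDR", "oDR")
PARAM_NAMES = RATE_PARAMS + COST_PARAMS + PROBABILITY_PARAMS + UTILITY_PARAMS


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty description of a single model input.

    ``kind`` is ``"beta_pert"`` for parameters sampled in the probabilistic
    analysis and ``"fixed"`` for the discount rates.  ``shape`` is the PERT
    shape constant (published as "Gamma", 8); ``alpha1``/``alpha2`` are the
    Beta shape constants (5, 5) used by the default sampling parameterization.
    """

    kind: str  # "fixed" | "beta_pert"
    mode: float
    min: float
    max: float
    shape: float = 8.0
    alpha1: float = 5.0
    alpha2: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "beta_pert"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not (self.min <= self.mode <= self.max):
            raise ValueError(
                f"range must bracket mode: min={self.min} mode={self.mode} max={self.max}"
            )
        if self.kind == "fixed" and not (self.min == self.mode == self.max):
            raise ValueError("fixed spec requires min = mode = max")

    @property
    def implied_mode(self) -> float:
        """Mode implied by the ±25% construction of the printed range.

        The published ranges were built as [0.75·m, 1.25·m]; inverting both
        endpoints and averaging recovers the unrounded working value m.  For a
        ``fixed`` spec this is simply the mode.
        """
        if self.kind == "fixed":
            return self.mode
        return (self.min / 0.75 + self.max / 1.25) / 2.0


class Param(float):
    """A float that remembers its uncertainty specification.

    Behaves as a plain number in arithmetic; ``.kind``, ``.min``, ``.max``,
    ``.mode`` and ``.spec`` expose the distribution metadata.
    """

    spec: DistributionSpec

    def __new__(cls, value: float, spec: DistributionSpec | None = None) -> "Param":
        obj = super().__new__(cls, value)
        if spec is None:
            v = float(value)
            spec = DistributionSpec("fixed", v, v, v)
        obj.spec = spec
        return obj

    @property
    def kind(self) -> str:
        return self.spec.kind

    @property
    def mode(self) -> float:
        return self.spec.mode

    @property
    def min(self) -> float:  # noqa: A003 - mirrors the published column name
        return self.spec.min

    @property
    def max(self) -> float:  # noqa: A003
        return self.spec.max

    def __repr__(self) -> str:
        return f"Param({float(self)!r}, kind={self.spec.kind!r})"


def pert_range(mode: float, spread: float = 0.25) -> tuple[float, float]:
    """Symmetric ±``spread`` uncertainty range around ``mode``."""
    return mode * (1.0 - spread), mode * (1.0 + spread)


def _fixed(value: float) -> Param:
    return Param(value, DistributionSpec("fixed", value, value, value))


def _pert(value: float, lo: float, hi: float) -> Param:
    return Param(value, DistributionSpec("beta_pert", value, lo, hi))


@dataclass(frozen=True)
class ParameterSet:
    """All named model inputs plus cohort settings.

    Costs are 2012 € (one-time for the device, SAE and explantation; per year
    otherwise), probabilities are per-year, utilities per-year weights.
    """

    # discount rates (fixed per pharmacoeconomic guidance)
    cDR: Param
    oDR: Param
    # costs
    cArgusII: Param
    cRP: Param
    cVAplus: Param
    cVAplusplus: Param
    cVAplusplusplus: Param
    cSAE: Param
    cExplant: Param
    cOthers: Param
    # probabilities
    pVAplus: Param
    pVAplusplus: Param
    pVAplusplusplus: Param
    pSAE: Param
    pExplant: Param
    # utilities
    uRP: Param
    uVAplus: Param
    uVAplusplus: Param
    uVAplusplusplus: Param
    uSAE: Param
    uExplant: Param
    # cohort settings
    cohort_size: int = 1000
    start_age: int = 46
    horizon: int = 25

    def replace(self, **overrides: object) -> "ParameterSet":
        """Return a copy with the given fields replaced.

        Numeric overrides of uncertain parameters keep the original
        distribution spec so the probabilistic analysis remains configured.
        """
        updates: dict[str, object] = {}
        for name, value in overrides.items():
            if name in PARAM_NAMES and not isinstance(value, Param):
                old: Param = getattr(self, name)
                updates[name] = Param(float(value), old.spec)
            else:
                updates[name] = value
        return dataclasses.replace(self, **updates)

    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        """Replace working values only (specs untouched); used by the PSA."""
        return self.replace(**dict(values))

    def value_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def validate(self) -> list[str]:
        return validate(self)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        params = {}
        for name in PARAM_NAMES:
            p: Param = getattr(self, name)
            params[name] = {
                "value": float(p),
                "min": p.spec.min,
                "max": p.spec.max,
                "distribution": p.spec.kind,
            }
        return {
            "parameters": params,
            "settings": {
                "horizon_years": self.horizon,
                "cohort_size": self.cohort_size,
                "start_age": self.start_age,
                "cost_discount_rate": float(self.cDR),
                "outcome_discount_rate": float(self.oDR),
            },
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def default_table1() -> ParameterSet:
    """The published model-parameter table, verbatim.

    Deterministic values and Beta-PERT min/max ranges exactly as printed;
    the discount rates are ``fixed`` at 3.5%/year.
    """
    return ParameterSet(
        cDR=_fixed(0.035),
        oDR=_fixed(0.035),
        cArgusII=_pert(90800, 68100, 113500),
        cRP=_pert(11789, 8841, 14736),
        cVAplus=_pert(9431, 7073, 11789),
        cVAplusplus=_pert(8252, 6189, 10315),
        cVAplusplusplus=_pert(7073, 5305, 8841),
        cSAE=_pert(1000, 750, 1250),
        cExplant=_pert(2000, 1500, 2500),
        cOthers=_pert(300, 225, 375),
        pVAplus=_pert(0.74, 0.554, 0.924),
        pVAplusplus=_pert(0.21, 0.154, 0.257),
        pVAplusplusplus=_pert(0.04, 0.029, 0.049),
        pSAE=_pert(0.3, 0.225, 0.375),
        pExplant=_pert(0.02, 0.013, 0.021),
        uRP=_pert(0.26, 0.195, 0.325),
        uVAplus=_pert(0.35, 0.263, 0.438),
        uVAplusplus=_pert(0.52, 0.39, 0.65),
        uVAplusplusplus=_pert(0.54, 0.405, 0.675),
        uSAE=_pert(0.16, 0.12, 0.2),
        uExplant=_pert(0.26, 0.195, 0.325),
    )


def range_implied_parameters(ps: ParameterSet | None = None) -> ParameterSet:
    """Working values recovered from the printed ±25% uncertainty ranges.

    The published deterministic column rounds the transition probabilities to
    two decimals (0.74/0.21/0.04/0.02) while the ranges preserve more digits;
    inverting min = 0.75·m, max = 1.25·m recovers the unrounded values
    (≈0.7389/0.2055/0.0389/0.0171).  For every other parameter the implied
    mode coincides with the printed value to within rounding noise.

    Only parameters still exactly at their published defaults (value, min and
    max all unchanged) are adjusted — user overrides and sampled values pass
    through verbatim.
    """
    ps = default_table1() if ps is None else ps
    published = default_table1()
    values: dict[str, float] = {}
    for name in PARAM_NAMES:
        p: Param = getattr(ps, name)
        d: Param = getattr(published, name)
        untouched = (
            float(p) == float(d)
            and p.spec.mode == d.spec.mode
            and p.spec.min == d.spec.min
            and p.spec.max == d.spec.max
        )
        values[name] = p.spec.implied_mode if untouched else float(p)
    return ps.with_values(values)


def validate(ps: ParameterSet) -> list[str]:
    """Check every economic invariant; return human-readable violations.

    An empty list means the set is valid.  Violations are collected (not
    raised) so a config file with several problems reports them all at once.
    """
    v: list[str] = []
    for name in PROBABILITY_PARAMS:
        x = float(getattr(ps, name))
        if not (0.0 <= x <= 1.0):
            v.append(f"{name}: probability {x} out of [0,1]")
    for name in UTILITY_PARAMS:
        x = float(getattr(ps, name))
        if not (0.0 <= x <= 1.0):
            v.append(f"{name}: utility {x} out of [0,1]")
    for name in COST_PARAMS:
        x = float(getattr(ps, name))
        if x < 0.0:
            v.append(f"{name}: negative cost {x}")
    mass = float(ps.pVAplus) + float(ps.pVAplusplus) + float(ps.pVAplusplusplus)
    if mass > 1.0 + 1e-12:
        v.append(f"pVAplus+pVAplusplus+pVAplusplusplus: probability mass {mass:.6g} > 1")
    steps = [
        ("cRP", "cVAplus"), ("cVAplus", "cVAplusplus"), ("cVAplusplus", "cVAplusplusplus"),
    ]
    for hi, lo in steps:
        if float(getattr(ps, hi)) < float(getattr(ps, lo)) - 1e-9:
            v.append(f"{hi} < {lo}: stepped state costs must be non-increasing")
    for name in PARAM_NAMES:
        p: Param = getattr(ps, name)
        if not (p.spec.min <= p.spec.mode <= p.spec.max):
            v.append(f"{name}: range [{p.spec.min}, {p.spec.max}] does not bracket mode {p.spec.mode}")
    if ps.horizon < 1:
        v.append(f"horizon: {ps.horizon} must be >= 1")
    if ps.cohort_size < 1:
        v.append(f"cohort_size: {ps.cohort_size} must be >= 1")
    return v


# ---------------------------------------------------------------------- config


class ParameterError(ValueError):
    """Raised for malformed or invalid parameter config documents."""


_SETTING_KEYS = {
    "horizon_years": "horizon",
    "cohort_size": "cohort_size",
    "start_age": "start_age",
    "cost_discount_rate": "cDR",
    "outcome_discount_rate": "oDR",
}


def loads_parameters(text: str, fmt: str = "yaml") -> ParameterSet:
    """Parse a YAML or JSON config document into a validated ParameterSet."""
    try:
        doc = json.loads(text) if fmt == "json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParameterError(f"malformed config document: {exc}") from exc
    return _from_document(doc or {})


def load_parameters(source: str | Path | Mapping | None) -> ParameterSet:
    """Load a ParameterSet from a YAML/JSON file, a mapping, or ``None``.

    Missing fields fall back to the published defaults.  Invariant violations
    raise :class:`ParameterError` listing every violation.
    """
    if source is None:
        return default_table1()
    if isinstance(source, Mapping):
        return _from_document(dict(source))
    path = Path(source)
    fmt = "json" if path.suffix.lower() == ".json" else "yaml"
    return loads_parameters(path.read_text(), fmt=fmt)


def _from_document(doc: Mapping) -> ParameterSet:
    if not isinstance(doc, Mapping):
        raise ParameterError(f"config root must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - {"parameters", "settings"}
    if unknown:
        raise ParameterError(f"unknown top-level keys: {sorted(unknown)}")
    ps = default_table1()
    overrides: dict[str, object] = {}

    params = doc.get("parameters") or {}
    if not isinstance(params, Mapping):
        raise ParameterError("'parameters' must be a mapping keyed by parameter name")
    for key, entry in params.items():
        if key not in PARAM_NAMES:
            raise ParameterError(f"unknown parameter key {key!r}")
        old: Param = getattr(ps, key)
        if isinstance(entry, (int, float)):
            entry = {"value": entry}
        if not isinstance(entry, Mapping):
            raise ParameterError(f"parameter {key!r}: entry must be a number or mapping")
        bad = set(entry) - {"value", "min", "max", "distribution"}
        if bad:
            raise ParameterError(f"parameter {key!r}: unknown keys {sorted(bad)}")
        value = float(entry.get("value", float(old)))
        kind = entry.get("distribution", old.spec.kind)
        lo = float(entry.get("min", old.spec.min))
        hi = float(entry.get("max", old.spec.max))
        # a bare value override inherits the default range, stretched to
        # bracket the new value so validation reports the substantive rule
        if "min" not in entry:
            lo = min(lo, value)
        if "max" not in entry:
            hi = max(hi, value)
        if kind == "fixed":
            lo = hi = value
        try:
            spec = DistributionSpec(kind, value, lo, hi, old.spec.shape, old.spec.alpha1, old.spec.alpha2)
        except ValueError as exc:
            raise ParameterError(f"parameter {key!r}: {exc}") from exc
        overrides[key] = Param(value, spec)

    settings = doc.get("settings") or {}
    if not isinstance(settings, Mapping):
        raise ParameterError("'settings' must be a mapping")
    for key, value in settings.items():
        if key not in _SETTING_KEYS:
            raise ParameterError(f"unknown settings key {key!r}")
        target = _SETTING_KEYS[key]
        if target in ("cDR", "oDR"):
            overrides[target] = _fixed(float(value))
        else:
            overrides[target] = int(value)

    out = ps.replace(**overrides)
    violations = validate(out)
    if violations:
        raise ParameterError("invalid parameters: " + "; ".join(violations))
    return out
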