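"""Parameter book: loading, validation and serialisation.

A single structured YAML file carries every model input — the four Weibull
curves, unit costs, utilities, dosing and PAP rules, strategy switches,
model conventions, and the sensitivity-analysis parameter list — so that
every analysis is reproducible from one file.  Two fixtures ship with the
package: ``default_params.yaml`` (the parameter table exactly as printed in
the source material, under the uncalibrated default conventions) and
``calibrated_params.yaml`` (the frozen output of the one-time calibration,
see :mod:`rascea.calibrate`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .cohort import ModelConfig
from .costing import CostBook, DosingRule, PAPSchedule, StrategySpec
from .outcomes import UtilityBook
from .survival import CurveBook, WeibullCurve, median_time, rescale_to_median

__all__ = [
    "ParamSpec",
    "ParamSet",
    "ConfigError",
    "load_config",
    "save_config",
    "default_config_path",
    "calibrated_config_path",
]


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: deterministic range and PSA distribution.

    ``target`` is a dotted reference resolved by :meth:`ParamSet.with_value`
    (e.g. ``costs.folfiri_per_cycle``, ``utilities.u_pfs``,
    ``curves.os_cetuximab.median``).  ``psa_distribution`` is ``triangular``
    for costs, ``beta`` for proportions/utilities, ``fixed`` for quantities
    held at base in the probabilistic analysis.
    """

    name: str
    base: float
    low: float
    high: float
    psa_distribution: str
    target: str

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: require low <= base <= high")
        if self.psa_distribution not in ("beta", "triangular", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.psa_distribution}")
        if self.psa_distribution == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires a [0, 1]-bounded range")


@dataclass(frozen=True)
class ParamSet:
    """The complete, validated parameter book."""

    model: ModelConfig
    curves: CurveBook
    costs: CostBook
    dosing: DosingRule
    pap: PAPSchedule
    utilities: UtilityBook
    control: StrategySpec
    cetuximab: StrategySpec
    param_specs: tuple[ParamSpec, ...] = ()
    seed: int = 20170411
    threshold: float = 22200.0
    provenance: dict = field(default_factory=dict)

    def strategy(self, arm: str) -> StrategySpec:
        if arm == "control":
            return self.control
        if arm == "cetuximab":
            return self.cetuximab
        raise ValueError(f"unknown arm {arm!r}")

    def with_value(self, target: str, value: float) -> "ParamSet":
        """Return a copy with the dotted ``target`` set to ``value``.

        Survival curves are perturbed through their median survival time
        (``curves.<role>.median``), which preserves the shape parameter.
        ``coverage_fraction`` applies to both strategies; other strategy
        fields address the cetuximab arm.
        """
        head, _, rest = target.partition(".")
        if head == "costs":
            if rest.startswith("sae."):
                sae = dict(self.costs.sae_unit_costs)
                event = rest.split(".", 1)[1]
                if event not in sae:
                    raise KeyError(f"unknown SAE event {event!r}")
                sae[event] = value
                return replace(self, costs=replace(self.costs, sae_unit_costs=sae))
            return replace(self, costs=replace(self.costs, **{rest: value}))
        if head == "utilities":
            return replace(self, utilities=replace(self.utilities, **{rest: value}))
        if head == "dosing":
            return replace(self, dosing=replace(self.dosing, **{rest: value}))
        if head == "model":
            return replace(self, model=replace(self.model, **{rest: value}))
        if head == "coverage_fraction" and not rest:
            return replace(
                self,
                control=replace(self.control, coverage_fraction=value),
                cetuximab=replace(self.cetuximab, coverage_fraction=value),
            )
        if head == "cetuximab":
            return replace(self, cetuximab=replace(self.cetuximab, **{rest: value}))
        if head == "curves":
            role, _, leaf = rest.partition(".")
            if leaf != "median":
                raise KeyError(f"curves can only be perturbed via median, got {target}")
            curve = getattr(self.curves, role)
            new = rescale_to_median(curve, value)
            return replace(self, curves=replace(self.curves, **{role: new}))
        raise KeyError(f"unknown parameter target {target!r}")


_SECTIONS = (
    "model", "curves", "costs", "dosing", "pap", "utilities",
    "strategies", "param_specs", "seed", "threshold", "provenance",
)
_CURVE_ROLES = ("pfs_control", "pfs_cetuximab", "os_control", "os_cetuximab")


def _build(cls, section: dict, name: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        errors.append(f"{name}: unknown keys {sorted(unknown)}")
    try:
        return cls(**{k: v for k, v in section.items() if k in known})
    except (TypeError, ValueError) as exc:
        errors.append(f"{name}: {exc}")
        return None


def load_config(path: str | Path) -> ParamSet:
    """Load and validate a parameter file; every violation is reported."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    errors: list[str] = []
    if not isinstance(raw, dict) or not raw:
        raise ConfigError([f"missing required sections: {', '.join(_SECTIONS[:8])}"])

    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        errors.append(f"top level: unknown keys {sorted(unknown)}")
    for required in _SECTIONS[:8]:
        if required not in raw:
            errors.append(f"missing required section {required!r}")
    if errors and any(e.startswith("missing") for e in errors):
        raise ConfigError(errors)

    model = _build(ModelConfig, raw["model"], "model", errors)

    curve_sec = raw["curves"]
    curves = None
    missing_roles = [r for r in _CURVE_ROLES if r not in curve_sec]
    if missing_roles:
        errors.append(f"curves: missing roles {missing_roles}")
    else:
        built = {}
        for role in _CURVE_ROLES:
            c = _build(WeibullCurve, curve_sec[role], f"curves.{role}", errors)
            if c is not None:
                built[role] = c
        if len(built) == 4:
            curves = CurveBook(**built)

    costs = _build(CostBook, raw["costs"], "costs", errors)
    dosing = _build(DosingRule, raw["dosing"], "dosing", errors)
    pap = _build(PAPSchedule, raw["pap"], "pap", errors)
    utilities = _build(UtilityBook, raw["utilities"], "utilities", errors)

    strat_sec = raw["strategies"]
    control = cetux = None
    for arm in ("control", "cetuximab"):
        if arm not in strat_sec:
            errors.append(f"strategies: missing {arm!r}")
        else:
            built_s = _build(
                StrategySpec, {"name": arm, **strat_sec[arm]}, f"strategies.{arm}", errors
            )
            if arm == "control":
                control = built_s
            else:
                cetux = built_s

    specs: list[ParamSpec] = []
    for i, entry in enumerate(raw.get("param_specs", []) or []):
        entry = dict(entry)
        # survival-median specs may leave base/low/high null: they are
        # derived from the loaded curve (base = median, range +/- 25%)
        if entry.get("base") is None and entry.get("target", "").startswith("curves."):
            role = entry["target"].split(".")[1]
            if curves is not None:
                med = median_time(getattr(curves, role))
                entry.update(base=med, low=0.75 * med, high=1.25 * med)
        try:
            specs.append(ParamSpec(**entry))
        except (TypeError, ValueError) as exc:
            errors.append(f"param_specs[{i}]: {exc}")

    if errors:
        raise ConfigError(errors)

    return ParamSet(
        model=model,
        curves=curves,
        costs=costs,
        dosing=dosing,
        pap=pap,
        utilities=utilities,
        control=control,
        cetuximab=cetux,
        param_specs=tuple(specs),
        seed=int(raw.get("seed", 20170411)),
        threshold=float(raw.get("threshold", 22200.0)),
        provenance=raw.get("provenance", {}) or {},
    )


def _asdict(ps: ParamSet) -> dict:
    def curve(c: WeibullCurve) -> dict:
        return {"scale": c.scale, "shape": c.shape, "time_unit": c.time_unit,
                "label": c.label}

    def strat(s: StrategySpec) -> dict:
        d = dataclasses.asdict(s)
        d.pop("name")
        return d

    return {
        "model": dataclasses.asdict(ps.model),
        "curves": {r: curve(getattr(ps.curves, r)) for r in _CURVE_ROLES},
        "costs": dataclasses.asdict(ps.costs),
        "dosing": dataclasses.asdict(ps.dosing),
        "pap": dataclasses.asdict(ps.pap),
        "utilities": dataclasses.asdict(ps.utilities),
        "strategies": {"control": strat(ps.control), "cetuximab": strat(ps.cetuximab)},
        "param_specs": [dataclasses.asdict(s) for s in ps.param_specs],
        "seed": ps.seed,
        "threshold": ps.threshold,
        "provenance": ps.provenance,
    }


def save_config(ps: ParamSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_asdict(ps), sort_keys=False))


def _data_path(name: str) -> Path:
    return Path(resources.files("rascea").joinpath("data", name))


def default_config_path() -> Path:
    """The shipped parameter table under uncalibrated default conventions."""
    return _data_path("default_params.yaml")


def calibrated_config_path() -> Path:
    """The frozen output of the one-time calibration."""
    return _data_path("calibrated_params.yaml")
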