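"""Model inputs: types, validation, (de)serialization, and the built-in
Moroccan 2022 reference parameter set.

The model compares six oral antipsychotic arms (olanzapine, risperidone and
aripiprazole, each as an orally disintegrating tablet, ODT, and as a standard
oral tablet, SOT) over a one-year horizon.  Every arm is described by an
adherence distribution over three medication-possession-ratio (MPR) strata,
per-cycle relapse probabilities stratified by adherence, annual
adverse-event probabilities, and a daily acquisition cost.  Shared inputs are
a utility table (adherence stratum x health state), a healthcare
resource-use matrix, and unit costs in 2022 Moroccan dirhams (MAD).
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources as _resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import yaml

__all__ = [
    "CATEGORIES",
    "STATES",
    "AE_TYPES",
    "USAGE_COLUMNS",
    "AdherenceDistribution",
    "StrategyParams",
    "UtilityTable",
    "ResourceUseMatrix",
    "UnitCostTable",
    "EngineConfig",
    "ModelParameters",
    "Violation",
    "ValidationReport",
    "ParameterError",
    "validate_parameters",
    "load_parameters",
    "save_parameters",
    "morocco_2022_parameters",
    "reference_base_case",
    "reference_annual_outcomes",
]

#: Adherence strata, ordered from most to least adherent (MPR >= 80%,
#: 60-80%, <= 60%).
CATEGORIES: Tuple[str, ...] = ("compliant", "partial", "non")

#: Health states over the one-year horizon.
STATES: Tuple[str, ...] = ("stable", "relapse_outpt", "relapse_hosp")

#: Treatment-emergent adverse events modelled as annual Bernoulli events.
AE_TYPES: Tuple[str, ...] = ("eps", "weight_gain", "diabetes")

#: Usage columns of the resource-use matrix.
USAGE_COLUMNS: Tuple[str, ...] = (
    "stable_per_month",
    "outpt_relapse_per_event",
    "hosp_relapse_per_event",
    "eps_per_event",
    "weight_gain_per_event",
)

_SUM_TOL = 1e-9


class ParameterError(Exception):
    """Raised when a parameter file is missing, malformed, or invalid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AdherenceDistribution:
    """Distribution of patients over the three MPR adherence strata.

    ``mpr_by_category`` carries the representative medication possession
    ratio used to prorate drug acquisition cost; the defaults are the
    midpoints of the published category ranges.
    """

    p_compliant: float
    p_partial: float
    p_non: float
    mpr_by_category: Dict[str, float] = field(
        default_factory=lambda: {"compliant": 0.90, "partial": 0.70, "non": 0.40}
    )

    @property
    def shares(self) -> Dict[str, float]:
        return {
            "compliant": self.p_compliant,
            "partial": self.p_partial,
            "non": self.p_non,
        }

    def copy(self) -> "AdherenceDistribution":
        return AdherenceDistribution(
            self.p_compliant, self.p_partial, self.p_non,
            dict(self.mpr_by_category),
        )


@dataclass
class StrategyParams:
    """One treatment arm.

    Relapse probabilities are *per cycle* (see the outcome engine's cycle
    exponent); adverse-event probabilities are annual.
    """

    name: str
    formulation: str  # "ODT" or "SOT"
    daily_drug_cost: float  # MAD/day
    adherence: AdherenceDistribution
    p_relapse_hosp: Dict[str, float]  # category -> per-cycle probability
    p_relapse_outpt: Dict[str, float]
    ae_probs: Dict[str, float]  # AE type -> annual probability

    def copy(self) -> "StrategyParams":
        return StrategyParams(
            self.name, self.formulation, self.daily_drug_cost,
            self.adherence.copy(),
            dict(self.p_relapse_hosp), dict(self.p_relapse_outpt),
            dict(self.ae_probs),
        )


@dataclass
class UtilityTable:
    """Health-state utilities by adherence stratum.

    ``u[(category, state)]`` is the utility weight in [0, 1]; within each
    stratum utilities are ordered stable >= outpatient relapse >=
    hospitalized relapse.
    """

    u: Dict[Tuple[str, str], float]

    def value(self, category: str, state: str) -> float:
        return self.u[(category, state)]

    def copy(self) -> "UtilityTable":
        return UtilityTable(dict(self.u))


@dataclass
class ResourceUseMatrix:
    """Healthcare resource quantities by usage column.

    ``quantity[(resource, column)]``: visits/hours/days per month (stable
    column) or per event (relapse and adverse-event columns).
    """

    quantity: Dict[Tuple[str, str], float]

    @property
    def resources(self) -> List[str]:
        seen: List[str] = []
        for r, _ in self.quantity:
            if r not in seen:
                seen.append(r)
        return seen

    def get(self, resource: str, column: str) -> float:
        return self.quantity.get((resource, column), 0.0)

    def column(self, column: str) -> Dict[str, float]:
        return {r: self.quantity.get((r, column), 0.0) for r in self.resources}

    def copy(self) -> "ResourceUseMatrix":
        return ResourceUseMatrix(dict(self.quantity))


@dataclass
class UnitCostTable:
    """Unit cost (MAD) of each healthcare resource."""

    cost_per_unit: Dict[str, float]

    def copy(self) -> "UnitCostTable":
        return UnitCostTable(dict(self.cost_per_unit))


@dataclass
class EngineConfig:
    """Engine configuration and calibrated constants.

    ``cycle_exponent_K`` converts per-cycle relapse probabilities into annual
    outcome probabilities under a continuous-hazard assumption
    (p_stable = (1 - ph - po) ** K); the shipped default is calibrated once
    against the published annual outcome table.  ``stable_care_scale``
    scales the monthly stable-state outpatient basket (see the costing
    module for why it is a declared reconciliation device).
    """

    horizon_days: float = 365.0
    cycle_exponent_K: float = 3.4750083
    hosp_episode_days: float = 11.7
    outpt_episode_days: float = 30.0
    n_patients: int = 1_000_000
    seed: int = 2022
    wtp: float = 250_832.40  # MAD per QALY
    psa_iterations: int = 1000
    psa_se_fraction_prob: float = 0.10
    psa_se_fraction_cost: float = 0.20
    owsa_range_fraction: float = 0.20
    stable_care_scale: float = 0.0

    def copy(self) -> "EngineConfig":
        return replace(self)


@dataclass
class ModelParameters:
    """The full input set: arms, groups, shared tables and configuration."""

    strategies: List[StrategyParams]
    group_definitions: Dict[str, List[str]]
    utilities: UtilityTable
    resource_use: ResourceUseMatrix
    unit_costs: UnitCostTable
    config: EngineConfig

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"unknown strategy {name!r}")

    @property
    def strategy_names(self) -> List[str]:
        return [s.name for s in self.strategies]

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            [s.copy() for s in self.strategies],
            {g: list(m) for g, m in self.group_definitions.items()},
            self.utilities.copy(),
            self.resource_use.copy(),
            self.unit_costs.copy(),
            self.config.copy(),
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    code: str
    path: str
    message: str


@dataclass
class ValidationReport:
    violations: List[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, code: str, path: str, message: str) -> None:
        self.violations.append(Violation(code, path, message))

    def codes(self) -> List[str]:
        return [v.code for v in self.violations]

    def __iter__(self):
        return iter(self.violations)

    def __len__(self):
        return len(self.violations)


def _check_prob(report: ValidationReport, code: str, path: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        report.add(code, path, f"{x} outside [0, 1]")


def validate_parameters(p: ModelParameters) -> ValidationReport:
    """Check every type invariant; violations are data, not exceptions."""
    rep = ValidationReport()

    names = p.strategy_names
    for n in names:
        if names.count(n) > 1:
            rep.add("DUPLICATE_ARM", f"strategies.{n}", "duplicate arm name")
            break
    for g, members in p.group_definitions.items():
        for m in members:
            if m not in names:
                rep.add("UNKNOWN_GROUP_MEMBER", f"groups.{g}",
                        f"group member {m!r} is not a strategy")

    for s in p.strategies:
        a = s.adherence
        total = a.p_compliant + a.p_partial + a.p_non
        if abs(total - 1.0) > _SUM_TOL:
            rep.add("ADHERENCE_SUM", f"strategies.{s.name}.adherence",
                    f"adherence must sum to 1 (got {total})")
        for cat, share in a.shares.items():
            _check_prob(rep, "PROB_RANGE",
                        f"strategies.{s.name}.adherence.{cat}", share)
        for cat in CATEGORIES:
            if cat not in a.mpr_by_category:
                rep.add("MPR_MISSING", f"strategies.{s.name}.mpr.{cat}",
                        "missing MPR")
                continue
            _check_prob(rep, "MPR_RANGE", f"strategies.{s.name}.mpr.{cat}",
                        a.mpr_by_category[cat])
        m = a.mpr_by_category
        if all(c in m for c in CATEGORIES):
            if not (m["compliant"] >= m["partial"] >= m["non"]):
                rep.add("MPR_ORDER", f"strategies.{s.name}.mpr",
                        "MPR must be non-increasing across strata")

        for cat in CATEGORIES:
            ph = s.p_relapse_hosp.get(cat)
            po = s.p_relapse_outpt.get(cat)
            if ph is None or po is None:
                rep.add("RELAPSE_MISSING",
                        f"strategies.{s.name}.relapse.{cat}",
                        "missing relapse probability")
                continue
            _check_prob(rep, "PROB_RANGE",
                        f"strategies.{s.name}.p_relapse_hosp.{cat}", ph)
            _check_prob(rep, "PROB_RANGE",
                        f"strategies.{s.name}.p_relapse_outpt.{cat}", po)
            if ph + po >= 1.0:
                rep.add("COMPETING_RISK_SUM",
                        f"strategies.{s.name}.relapse.{cat}",
                        f"hosp+outpt relapse must be < 1 (got {ph + po})")
        for ae, prob in s.ae_probs.items():
            _check_prob(rep, "PROB_RANGE",
                        f"strategies.{s.name}.ae_probs.{ae}", prob)
        if s.daily_drug_cost < 0:
            rep.add("DRUG_COST_NEGATIVE", f"strategies.{s.name}.daily_drug_cost",
                    f"negative drug cost {s.daily_drug_cost}")

    for (cat, state), u in p.utilities.u.items():
        if not (0.0 <= u <= 1.0):
            rep.add("UTILITY_RANGE", f"utilities.{cat}.{state}",
                    f"utility {u} outside [0, 1]")
    for cat in CATEGORIES:
        try:
            us = p.utilities.value(cat, "stable")
            uo = p.utilities.value(cat, "relapse_outpt")
            uh = p.utilities.value(cat, "relapse_hosp")
        except KeyError:
            rep.add("UTILITY_MISSING", f"utilities.{cat}", "missing utility")
            continue
        if not (us >= uo >= uh):
            rep.add("UTILITY_ORDER", f"utilities.{cat}",
                    "utilities must be ordered stable >= outpatient >= hospitalized")

    for (res, col), q in p.resource_use.quantity.items():
        if q < 0:
            rep.add("QUANTITY_NEGATIVE", f"resource_use.{res}.{col}",
                    f"negative quantity {q}")
    # inpatient days are only consumed during a hospitalized relapse
    for res in p.resource_use.resources:
        if res == "hospital_day":
            for col in USAGE_COLUMNS:
                if col != "hosp_relapse_per_event" and p.resource_use.get(res, col) != 0:
                    rep.add("HOSP_QUANTITY_COLUMN", f"resource_use.{res}.{col}",
                            "hospital days only accrue in the hospitalized-relapse column")

    for res, c in p.unit_costs.cost_per_unit.items():
        if c < 0:
            rep.add("UNIT_COST_NEGATIVE", f"unit_costs.{res}", f"negative cost {c}")
    for res in p.resource_use.resources:
        if res not in p.unit_costs.cost_per_unit:
            rep.add("MISSING_UNIT_COST", f"unit_costs.{res}",
                    f"resource {res!r} has no unit cost")

    cfg = p.config
    if cfg.horizon_days <= 0:
        rep.add("CONFIG_HORIZON", "config.horizon_days", "horizon must be > 0")
    if cfg.cycle_exponent_K <= 0:
        rep.add("CONFIG_K", "config.cycle_exponent_K", "K must be > 0")
    for nm in ("hosp_episode_days", "outpt_episode_days"):
        v = getattr(cfg, nm)
        if not (0 <= v <= cfg.horizon_days):
            rep.add("CONFIG_EPISODE", f"config.{nm}",
                    f"{v} outside [0, horizon]")
    if cfg.n_patients < 1:
        rep.add("CONFIG_N", "config.n_patients", "n_patients must be >= 1")
    if cfg.wtp < 0:
        rep.add("CONFIG_WTP", "config.wtp", "willingness to pay must be >= 0")

    return rep


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_CSV_FILES = {
    "adherence": "adherence.csv",
    "relapse": "relapse.csv",
    "adverse_events": "adverse_events.csv",
    "utilities": "utilities.csv",
    "resources": "resources.csv",
}

_YAML_KEYS = {"config", "groups", "strategies", "mpr_by_category", "files"}

_CONFIG_KEYS = {
    "horizon_days", "cycle_exponent_K", "hosp_episode_days",
    "outpt_episode_days", "n_patients", "seed", "wtp", "psa_iterations",
    "psa_se_fraction_prob", "psa_se_fraction_cost", "owsa_range_fraction",
    "stable_care_scale",
}


def _num(text: str, table: str, row: int, col: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise ParameterError(
            f"{table}: malformed number {text!r} at row {row}, column {col!r}"
        ) from None


def _read_csv(path: Path, table: str) -> List[Dict[str, str]]:
    if not path.exists():
        raise ParameterError(f"missing table {table!r}: file {path} not found")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ParameterError(f"table {table!r} in {path} is empty")
    return rows


def load_parameters(path: "str | Path") -> ModelParameters:
    """Load a parameter set from a ``params.yaml`` + CSV bundle.

    ``path`` may be the YAML file itself or the directory containing it.
    Percentages in the adherence, relapse and adverse-event tables are
    converted to fractions here; all internal arithmetic is on fractions.
    Unknown YAML keys are rejected.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "params.yaml"
    if not path.exists():
        raise ParameterError(f"parameter file {path} not found")
    base = path.parent
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterError(f"{path}: expected a mapping at top level")
    unknown = set(doc) - _YAML_KEYS
    if unknown:
        raise ParameterError(f"{path}: unknown keys {sorted(unknown)}")
    for key in ("config", "strategies", "groups"):
        if key not in doc:
            raise ParameterError(f"{path}: missing section {key!r}")

    cfg_doc = dict(doc["config"])
    unknown = set(cfg_doc) - _CONFIG_KEYS
    if unknown:
        raise ParameterError(f"{path}: unknown config keys {sorted(unknown)}")
    config = EngineConfig(**cfg_doc)

    mpr = {k: float(v) for k, v in doc.get(
        "mpr_by_category", {"compliant": 0.90, "partial": 0.70, "non": 0.40}
    ).items()}

    files = dict(_CSV_FILES)
    files.update(doc.get("files", {}))

    adherence_rows = _read_csv(base / files["adherence"], "adherence")
    relapse_rows = _read_csv(base / files["relapse"], "relapse")
    ae_rows = _read_csv(base / files["adverse_events"], "adverse_events")
    util_rows = _read_csv(base / files["utilities"], "utilities")
    res_rows = _read_csv(base / files["resources"], "resources (quantities and unit costs)")

    adherence: Dict[str, AdherenceDistribution] = {}
    for i, row in enumerate(adherence_rows):
        adherence[row["medication"]] = AdherenceDistribution(
            p_compliant=_num(row["compliant_pct"], "adherence", i, "compliant_pct") / 100.0,
            p_partial=_num(row["partially_compliant_pct"], "adherence", i,
                           "partially_compliant_pct") / 100.0,
            p_non=_num(row["non_compliant_pct"], "adherence", i, "non_compliant_pct") / 100.0,
            mpr_by_category=dict(mpr),
        )

    relapse_h: Dict[str, Dict[str, float]] = {}
    relapse_o: Dict[str, Dict[str, float]] = {}
    for i, row in enumerate(relapse_rows):
        med, cat = row["medication"], row["category"]
        relapse_h.setdefault(med, {})[cat] = _num(
            row["hospitalized_pct"], "relapse", i, "hospitalized_pct") / 100.0
        relapse_o.setdefault(med, {})[cat] = _num(
            row["outpatient_pct"], "relapse", i, "outpatient_pct") / 100.0

    ae: Dict[str, Dict[str, float]] = {}
    for i, row in enumerate(ae_rows):
        ae[row["medication"]] = {
            "eps": _num(row["eps_pct"], "adverse_events", i, "eps_pct") / 100.0,
            "weight_gain": _num(row["weight_gain_pct"], "adverse_events", i,
                                "weight_gain_pct") / 100.0,
            "diabetes": _num(row["diabetes_pct"], "adverse_events", i,
                             "diabetes_pct") / 100.0,
        }

    u: Dict[Tuple[str, str], float] = {}
    for i, row in enumerate(util_rows):
        state = row["state"]
        for cat in CATEGORIES:
            u[(cat, state)] = _num(row[cat], "utilities", i, cat)

    quantity: Dict[Tuple[str, str], float] = {}
    cost_per_unit: Dict[str, float] = {}
    for i, row in enumerate(res_rows):
        res = row["resource"]
        for col in USAGE_COLUMNS:
            quantity[(res, col)] = _num(row[col], "resources", i, col)
        cost_per_unit[res] = _num(row["unit_cost_mad"], "resources", i, "unit_cost_mad")

    strategies: List[StrategyParams] = []
    for name, meta in doc["strategies"].items():
        extra = set(meta) - {"formulation", "daily_drug_cost_mad"}
        if extra:
            raise ParameterError(f"{path}: unknown strategy keys {sorted(extra)} for {name!r}")
        for table, mapping in (("adherence", adherence), ("relapse", relapse_h),
                               ("adverse_events", ae)):
            if name not in mapping:
                raise ParameterError(f"strategy {name!r} missing from table {table!r}")
        strategies.append(StrategyParams(
            name=name,
            formulation=str(meta["formulation"]),
            daily_drug_cost=float(meta["daily_drug_cost_mad"]),
            adherence=adherence[name],
            p_relapse_hosp=relapse_h[name],
            p_relapse_outpt=relapse_o[name],
            ae_probs=ae[name],
        ))

    params = ModelParameters(
        strategies=strategies,
        group_definitions={g: list(m) for g, m in doc["groups"].items()},
        utilities=UtilityTable(u),
        resource_use=ResourceUseMatrix(quantity),
        unit_costs=UnitCostTable(cost_per_unit),
        config=config,
    )
    report = validate_parameters(params)
    if not report.ok:
        first = report.violations[0]
        raise ParameterError(
            f"invalid parameter set ({len(report)} violation(s)); first: "
            f"[{first.code}] {first.path}: {first.message}"
        )
    return params


def save_parameters(params: ModelParameters, out_dir: "str | Path") -> Path:
    """Write ``params.yaml`` plus the five CSV tables; returns the YAML path.

    ``load_parameters(save_parameters(p))`` is value-identical to ``p`` for
    inputs whose percentages are representable in decimal (all fixtures).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def fmt(x: float) -> str:
        return format(x, ".12g")

    with open(out / "adherence.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["medication", "compliant_pct", "partially_compliant_pct",
                    "non_compliant_pct"])
        for s in params.strategies:
            a = s.adherence
            w.writerow([s.name, fmt(a.p_compliant * 100), fmt(a.p_partial * 100),
                        fmt(a.p_non * 100)])

    with open(out / "relapse.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["medication", "category", "hospitalized_pct", "outpatient_pct"])
        for s in params.strategies:
            for cat in CATEGORIES:
                w.writerow([s.name, cat, fmt(s.p_relapse_hosp[cat] * 100),
                            fmt(s.p_relapse_outpt[cat] * 100)])

    with open(out / "adverse_events.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["medication", "eps_pct", "weight_gain_pct", "diabetes_pct"])
        for s in params.strategies:
            w.writerow([s.name] + [fmt(s.ae_probs[a] * 100) for a in AE_TYPES])

    with open(out / "utilities.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["state"] + list(CATEGORIES))
        for state in STATES:
            w.writerow([state] + [fmt(params.utilities.value(c, state))
                                  for c in CATEGORIES])

    with open(out / "resources.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["resource"] + list(USAGE_COLUMNS) + ["unit_cost_mad"])
        resources = list(params.resource_use.resources)
        for res in params.unit_costs.cost_per_unit:
            if res not in resources:
                resources.append(res)
        for res in resources:
            w.writerow([res]
                       + [fmt(params.resource_use.get(res, c)) for c in USAGE_COLUMNS]
                       + [fmt(params.unit_costs.cost_per_unit[res])])

    cfg = params.config
    doc = {
        "config": {k: getattr(cfg, k) for k in sorted(_CONFIG_KEYS)},
        "groups": {g: list(m) for g, m in params.group_definitions.items()},
        "strategies": {
            s.name: {"formulation": s.formulation,
                     "daily_drug_cost_mad": s.daily_drug_cost}
            for s in params.strategies
        },
        "mpr_by_category": dict(params.strategies[0].adherence.mpr_by_category)
        if params.strategies else {},
        "files": dict(_CSV_FILES),
    }
    yaml_path = out / "params.yaml"
    with open(yaml_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return yaml_path


# ---------------------------------------------------------------------------
# Built-in fixtures (Moroccan 2022 reference set)
# ---------------------------------------------------------------------------

def _data_dir() -> Path:
    return Path(str(_resources.files("odtcea"))) / "data" / "morocco_2022"


def morocco_2022_parameters() -> ModelParameters:
    """The built-in Moroccan 2022 reference parameter set (six arms)."""
    return load_parameters(_data_dir() / "params.yaml")


def reference_base_case() -> Dict[str, Tuple[float, float]]:
    """Published base-case totals: strategy/group -> (cost MAD, QALY).

    These are *inputs* (a printed results table), used for ICER identity
    checks and for calibrating the stable-care scale; they are not produced
    by this package's engine.
    """
    rows = _read_csv(_data_dir() / "base_case.csv", "base_case")
    return {r["strategy"]: (float(r["total_cost_mad"]), float(r["total_qaly"]))
            for r in rows}


def reference_annual_outcomes() -> Dict[str, Tuple[float, float, float]]:
    """Published annual outcome percentages: group -> (stable, hosp, outpt)."""
    rows = _read_csv(_data_dir() / "annual_outcomes.csv", "annual_outcomes")
    return {r["group"]: (float(r["stable_pct"]), float(r["hospitalized_pct"]),
                         float(r["outpatient_pct"]))
            for r in rows}


def file_hashes(path: "str | Path") -> Dict[str, str]:
    """SHA-256 of every file in a parameter bundle (for run manifests)."""
    path = Path(path)
    base = path.parent if path.is_file() else path
    out = {}
    for f in sorted(base.glob("*")):
        if f.is_file():
            out[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out
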