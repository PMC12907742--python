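"""Model parameter containers, validation, and config I/O.

Everything the projection needs — the national population projection, baseline
prevalences, the annual transition probabilities, severity splits, and unit
costs — is bundled into a :class:`ModelParameters`.  Parameters load from a
single YAML config (see ``data/uk_reference.yaml`` for the packaged reference
set) and validate against the model's structural invariants.

Validation is non-throwing: :func:`validate` returns a list of
:class:`Violation` records so that callers can report every problem at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import BAND_INDEX, BAND_LABELS, N_BANDS, SEXES, State

__all__ = [
    "StratifiedTable",
    "SeveritySplit",
    "SeverityCostRatios",
    "TransitionRateSet",
    "CostParameters",
    "ModelParameters",
    "Violation",
    "SchemaError",
    "load_parameters",
    "save_parameters",
    "validate",
]


class SchemaError(ValueError):
    """Raised when a config file is structurally unusable (missing table, bad band)."""


@dataclass
class Violation:
    """One broken invariant: where it happened and which rule it breaks."""

    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message}"


# ---------------------------------------------------------------------------
# stratified tables


@dataclass
class StratifiedTable:
    """A value per (age band, sex) cell with its unit recorded.

    ``values`` has shape (n_bands, 2) with columns ordered (male, female).
    Units in use: "probability", "gbp_per_person_year", "proportion".
    """

    name: str
    values: np.ndarray
    unit: str = "probability"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BANDS, 2):
            raise SchemaError(
                f"{self.name}: expected shape ({N_BANDS}, 2), got {self.values.shape}"
            )

    def value(self, band: str, sex: str) -> float:
        return float(self.values[BAND_INDEX[band], SEXES.index(sex)])

    @classmethod
    def from_mapping(
        cls, name: str, mapping: dict, unit: str = "probability", fill: float = 0.0
    ) -> "StratifiedTable":
        """Build from ``{band_label: value or [male, female]}``; absent bands take ``fill``."""
        values = np.full((N_BANDS, 2), fill, dtype=float)
        for label, v in mapping.items():
            label = str(label)
            if label not in BAND_INDEX:
                raise SchemaError(f"{name}: unknown age band {label!r}")
            pair = (v, v) if np.isscalar(v) else tuple(v)
            if len(pair) != 2:
                raise SchemaError(f"{name}: band {label} needs a scalar or [male, female]")
            values[BAND_INDEX[label]] = pair
        return cls(name=name, values=values, unit=unit)

    def to_mapping(self) -> dict:
        return {label: [float(m), float(f)] for label, (m, f) in zip(BAND_LABELS, self.values)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_band": label, "sex": sex, "value": float(self.values[i, j])}
            for i, label in enumerate(BAND_LABELS)
            for j, sex in enumerate(SEXES)
        ]
        return pd.DataFrame(rows)


# severity-split age groups; the 30-34 band has no group of its own and uses
# the youngest available row
_SEVERITY_GROUPS = ("35-64", "65-74", "75-84", "85+")


def _severity_group_for_band(band_label: str) -> str:
    lower = 100 if band_label.endswith("+") else int(band_label.split("-")[0])
    if lower < 65:
        return "35-64"
    if lower < 75:
        return "65-74"
    if lower < 85:
        return "75-84"
    return "85+"


@dataclass
class SeveritySplit:
    """(mild, moderate, severe) proportions of prevalent AD dementia per age group."""

    by_group: dict[str, tuple[float, float, float]]

    def for_band(self, band_label: str, normalised: bool = True) -> np.ndarray:
        triple = np.asarray(self.by_group[_severity_group_for_band(band_label)], dtype=float)
        if normalised:
            # printed splits carry rounding; renormalise so occupancy sums exactly
            triple = triple / triple.sum()
        return triple

    def as_band_matrix(self) -> np.ndarray:
        """(n_bands, 3) matrix of normalised (mild, moderate, severe) proportions."""
        return np.stack([self.for_band(lbl) for lbl in BAND_LABELS])


@dataclass
class SeverityCostRatios:
    """Stage-specific multipliers on the all-severity AD cost, (mild, moderate, severe)."""

    health: tuple[float, float, float]
    social: tuple[float, float, float]


@dataclass
class TransitionRateSet:
    """Annual transition probabilities on the allowed edges of the disease graph.

    Forward: MCI->mild, mild->moderate, moderate->severe.  Backward (staging
    misclassification): moderate->mild, severe->moderate.  Each disease state
    carries its own mortality; onset (unimpaired->MCI) is the only age-specific
    rate and lives in ``incidence``.
    """

    mci_to_mild: float
    mild_to_moderate: float
    moderate_to_severe: float
    moderate_to_mild: float
    severe_to_moderate: float
    mortality: dict[str, float]  # keys: mci, mild, moderate, severe
    incidence: StratifiedTable  # unimpaired -> MCI, per (band, sex)

    def outflow(self, state: State) -> float:
        """Total probability of leaving ``state`` in one cycle (excl. incidence)."""
        if state == State.MCI:
            return self.mci_to_mild + self.mortality["mci"]
        if state == State.MILD:
            return self.mild_to_moderate + self.mortality["mild"]
        if state == State.MODERATE:
            return (
                self.moderate_to_severe + self.moderate_to_mild + self.mortality["moderate"]
            )
        if state == State.SEVERE:
            return self.severe_to_moderate + self.mortality["severe"]
        raise ValueError(f"no outflow defined for {state}")

    def edge_probabilities(self) -> dict[tuple[str, str], float]:
        """Every (origin, destination) edge incl. mortality, for ledger-style accounting."""
        return {
            ("mci", "mild"): self.mci_to_mild,
            ("mild", "moderate"): self.mild_to_moderate,
            ("moderate", "severe"): self.moderate_to_severe,
            ("moderate", "mild"): self.moderate_to_mild,
            ("severe", "moderate"): self.severe_to_moderate,
            ("mci", "dead"): self.mortality["mci"],
            ("mild", "dead"): self.mortality["mild"],
            ("moderate", "dead"): self.mortality["moderate"],
            ("severe", "dead"): self.mortality["severe"],
        }


@dataclass
class CostParameters:
    """Unit costs: per-person-year HCRU and social care, visit prices, drug price.

    ``ad_hcru`` is the all-severity AD healthcare cost per band (identical for
    both sexes in the source table, stored once per band).  ``social_ad`` is the
    all-severity AD social-care cost by sex.  ``social_utilisation`` is the
    fraction of the AD dementia population using formal social care.
    """

    england_hcru: StratifiedTable  # £/person-year, general (non-AD) population
    ad_hcru: np.ndarray  # £/person-year, all-severity AD, per band
    social_general: dict[str, float]  # keys: under_18, age_18_64, age_65_plus
    social_ad: dict[str, float]  # keys: male, female
    social_utilisation: float
    ratios: SeverityCostRatios
    primary_visit_cost: float
    specialist_visit_cost: float
    drug_price_annual: float | None = None

    def __post_init__(self) -> None:
        self.ad_hcru = np.asarray(self.ad_hcru, dtype=float)
        if self.ad_hcru.shape != (N_BANDS,):
            raise SchemaError(f"ad_hcru: expected shape ({N_BANDS},), got {self.ad_hcru.shape}")

    def social_general_by_band(self) -> np.ndarray:
        """General-population social-care £/person-year per band (age-65 switch)."""
        out = np.empty(N_BANDS)
        for i, label in enumerate(BAND_LABELS):
            lower = 100 if label.endswith("+") else int(label.split("-")[0])
            if lower < 20:  # 15-19 straddles 18 and is treated as under-18
                out[i] = self.social_general["under_18"]
            elif lower < 65:
                out[i] = self.social_general["age_18_64"]
            else:
                out[i] = self.social_general["age_65_plus"]
        return out


@dataclass
class ModelParameters:
    """The full parameter bundle driving one projection."""

    population: dict[int, np.ndarray]  # year -> (n_bands, 2) persons
    ad_prevalence: StratifiedTable  # baseline AD dementia prevalence by sex
    mci_prevalence: StratifiedTable  # baseline MCI-due-to-AD prevalence (all-sex)
    severity_split: SeveritySplit
    transitions: TransitionRateSet
    costs: CostParameters
    base_year: int = 2020
    horizon_year: int = 2040
    currency: str = "GBP 2019"
    provenance: dict[str, str] = field(default_factory=dict)

    def population_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "age_band": lbl, "sex": sex, "value": float(arr[i, j])}
            for y, arr in sorted(self.population.items())
            for i, lbl in enumerate(BAND_LABELS)
            for j, sex in enumerate(SEXES)
        ]
        return pd.DataFrame(rows)

    def with_transitions(self, transitions: TransitionRateSet) -> "ModelParameters":
        return replace(self, transitions=transitions)


# ---------------------------------------------------------------------------
# validation

_SEVERITY_SUM_TOL = 1e-3  # printed percentage rounding: rows may sum to 99.99/100.01%


def validate(params: ModelParameters) -> list[Violation]:
    """Check every structural invariant; return one record per broken rule."""
    v: list[Violation] = []

    # population coverage and positivity
    years = sorted(params.population)
    for y in range(params.base_year, params.horizon_year + 1):
        if y not in params.population:
            v.append(Violation("population", f"projection missing year {y}"))
    for y in years:
        arr = params.population[y]
        if arr.shape != (N_BANDS, 2):
            v.append(Violation("population", f"year {y}: bad shape {arr.shape}"))
        elif (arr < 0).any():
            v.append(Violation("population", f"year {y}: negative counts"))

    # prevalence / incidence tables: probabilities in [0, 1]
    for tbl in (params.ad_prevalence, params.mci_prevalence, params.transitions.incidence):
        if (tbl.values < 0).any() or (tbl.values > 1).any():
            v.append(Violation(tbl.name, "probabilities outside [0, 1]"))
    # joint disease prevalence cannot exceed 1 in any cell
    joint = params.ad_prevalence.values + params.mci_prevalence.values
    if (joint > 1).any():
        bad = np.argwhere(joint > 1)[0]
        v.append(
            Violation(
                "prevalence",
                f"AD + MCI prevalence exceeds 1 at band {BAND_LABELS[bad[0]]}, {SEXES[bad[1]]}",
            )
        )

    # incidence non-decreasing with age (within each sex)
    inc = params.transitions.incidence.values
    if (np.diff(inc, axis=0) < -1e-12).any():
        v.append(Violation("incidence", "MCI incidence decreases with age band"))

    # severity splits
    for group, triple in params.severity_split.by_group.items():
        t = np.asarray(triple, dtype=float)
        if (t < 0).any() or (t > 1).any():
            v.append(Violation("severity_split", f"group {group}: proportion outside [0, 1]"))
        if abs(t.sum() - 1.0) > _SEVERITY_SUM_TOL:
            v.append(Violation("severity_split", f"group {group}: sums to {t.sum():.4f}"))

    # transitions: each probability in [0, 1]; outgoing sums <= 1
    tr = params.transitions
    for name, p in [
        ("mci_to_mild", tr.mci_to_mild),
        ("mild_to_moderate", tr.mild_to_moderate),
        ("moderate_to_severe", tr.moderate_to_severe),
        ("moderate_to_mild", tr.moderate_to_mild),
        ("severe_to_moderate", tr.severe_to_moderate),
        *[(f"mortality.{k}", p) for k, p in tr.mortality.items()],
    ]:
        if not (0.0 <= p <= 1.0):
            v.append(Violation(f"transitions.{name}", f"probability {p} outside [0, 1]"))
    for state in (State.MCI, State.MILD, State.MODERATE, State.SEVERE):
        s = tr.outflow(state)
        if s > 1.0 + 1e-12:
            v.append(
                Violation(
                    f"transitions.{state.value}",
                    f"outgoing probabilities sum to {s:.4f} > 1",
                )
            )

    # costs
    c = params.costs
    if (c.england_hcru.values < 0).any():
        v.append(Violation("costs.england_hcru", "negative cost"))
    if (c.ad_hcru < 0).any():
        v.append(Violation("costs.ad_hcru", "negative cost"))
    for k, val in {**c.social_general, **c.social_ad}.items():
        if val < 0:
            v.append(Violation(f"costs.social.{k}", "negative cost"))
    if not (0.0 <= c.social_utilisation <= 1.0):
        v.append(Violation("costs.social_utilisation", f"{c.social_utilisation} outside [0, 1]"))
    for kind, triple in [("health", c.ratios.health), ("social", c.ratios.social)]:
        if any(r <= 0 for r in triple):
            v.append(Violation(f"costs.ratios.{kind}", "non-positive severity cost ratio"))
    for name, val in [
        ("primary_visit_cost", c.primary_visit_cost),
        ("specialist_visit_cost", c.specialist_visit_cost),
    ]:
        if val < 0:
            v.append(Violation(f"costs.{name}", "negative cost"))
    if c.drug_price_annual is not None and c.drug_price_annual < 0:
        v.append(Violation("costs.drug_price_annual", "negative drug price"))

    return v


# ---------------------------------------------------------------------------
# config I/O


def _require(cfg: dict, key: str) -> dict:
    if key not in cfg:
        raise SchemaError(f"config missing required section {key!r}")
    return cfg[key]


def _build_population(section: dict) -> dict[int, np.ndarray]:
    if "synthetic" in section:
        from .synthetic import SyntheticPopulationConfig, synthetic_population_projection

        cfg = SyntheticPopulationConfig(**section["synthetic"])
        return synthetic_population_projection(cfg)
    if "csv" in section:
        return population_from_frame(pd.read_csv(section["csv"]))
    if "table" in section:
        out = {}
        for year, bands in section["table"].items():
            arr = np.zeros((N_BANDS, 2))
            for label, pair in bands.items():
                if str(label) not in BAND_INDEX:
                    raise SchemaError(f"population: unknown age band {label!r}")
                arr[BAND_INDEX[str(label)]] = pair
            out[int(year)] = arr
        return out
    raise SchemaError("population section needs one of: synthetic, csv, table")


def population_from_frame(df: pd.DataFrame) -> dict[int, np.ndarray]:
    """Read a long-format population table (year, age_band, sex, value)."""
    out: dict[int, np.ndarray] = {}
    for (year,), grp in df.groupby(["year"]):
        arr = np.zeros((N_BANDS, 2))
        for _, row in grp.iterrows():
            band = str(row["age_band"])
            if band not in BAND_INDEX:
                raise SchemaError(f"population: unknown age band {band!r}")
            arr[BAND_INDEX[band], SEXES.index(row["sex"])] = row["value"]
        out[int(year)] = arr
    return out


def parameters_from_config(cfg: dict) -> ModelParameters:
    """Build a ModelParameters from a parsed config mapping."""
    meta = cfg.get("meta", {})
    prev = _require(cfg, "prevalence")
    inc = _require(cfg, "incidence")
    trans = _require(cfg, "transitions")
    sev = _require(cfg, "severity")
    costs = _require(cfg, "costs")

    population = _build_population(_require(cfg, "population"))

    transitions = TransitionRateSet(
        mci_to_mild=float(trans["mci_to_mild"]),
        mild_to_moderate=float(trans["mild_to_moderate"]),
        moderate_to_severe=float(trans["moderate_to_severe"]),
        moderate_to_mild=float(trans["moderate_to_mild"]),
        severe_to_moderate=float(trans["severe_to_moderate"]),
        mortality={k: float(p) for k, p in _require(trans, "mortality").items()},
        incidence=StratifiedTable.from_mapping("incidence.mci", inc["mci"], "probability"),
    )

    ratios = SeverityCostRatios(
        health=tuple(float(x) for x in sev["cost_ratios"]["health"]),
        social=tuple(float(x) for x in sev["cost_ratios"]["social"]),
    )
    ad_hcru_map = costs["ad_hcru"]
    ad_hcru = np.zeros(N_BANDS)
    for label, val in ad_hcru_map.items():
        if str(label) not in BAND_INDEX:
            raise SchemaError(f"ad_hcru: unknown age band {label!r}")
        ad_hcru[BAND_INDEX[str(label)]] = float(val)

    cost_params = CostParameters(
        england_hcru=StratifiedTable.from_mapping(
            "england_hcru", costs["england_hcru"], "gbp_per_person_year"
        ),
        ad_hcru=ad_hcru,
        social_general={k: float(x) for k, x in costs["social_general"].items()},
        social_ad={k: float(x) for k, x in costs["social_ad"].items()},
        social_utilisation=float(costs["social_utilisation"]),
        ratios=ratios,
        primary_visit_cost=float(costs["primary_visit_cost"]),
        specialist_visit_cost=float(costs["specialist_visit_cost"]),
        drug_price_annual=(
            float(costs["drug_price_annual"])
            if costs.get("drug_price_annual") is not None
            else None
        ),
    )

    return ModelParameters(
        population=population,
        ad_prevalence=StratifiedTable.from_mapping(
            "ad_prevalence", prev["ad_dementia"], "probability"
        ),
        mci_prevalence=StratifiedTable.from_mapping(
            "mci_prevalence", prev["mci"], "probability"
        ),
        severity_split=SeveritySplit(
            by_group={g: tuple(float(x) for x in t) for g, t in sev["split"].items()}
        ),
        transitions=transitions,
        costs=cost_params,
        base_year=int(meta.get("base_year", 2020)),
        horizon_year=int(meta.get("horizon_year", 2040)),
        currency=str(meta.get("currency", "GBP 2019")),
        provenance={str(k): str(v) for k, v in cfg.get("provenance", {}).items()},
    )


def load_parameters(config_path: str | Path) -> ModelParameters:
    """Load and build a ModelParameters from a YAML config file.

    Raises :class:`SchemaError` naming the missing/invalid field; invariant
    violations are left to :func:`validate` so they can be reported together.
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config root must be a mapping")
    params = parameters_from_config(cfg)
    # flag every default the config did not trace to a source
    if "transitions" not in params.provenance:
        params.provenance["transitions"] = "unspecified"
    return params


def parameters_to_config(params: ModelParameters) -> dict:
    """Serialise a ModelParameters back to the config mapping form."""
    tr = params.transitions
    return {
        "meta": {
            "base_year": params.base_year,
            "horizon_year": params.horizon_year,
            "currency": params.currency,
        },
        "population": {
            "table": {
                int(y): {
                    lbl: [float(m), float(f)]
                    for lbl, (m, f) in zip(BAND_LABELS, arr)
                }
                for y, arr in sorted(params.population.items())
            }
        },
        "prevalence": {
            "ad_dementia": params.ad_prevalence.to_mapping(),
            "mci": params.mci_prevalence.to_mapping(),
        },
        "incidence": {"mci": tr.incidence.to_mapping()},
        "transitions": {
            "mci_to_mild": tr.mci_to_mild,
            "mild_to_moderate": tr.mild_to_moderate,
            "moderate_to_severe": tr.moderate_to_severe,
            "moderate_to_mild": tr.moderate_to_mild,
            "severe_to_moderate": tr.severe_to_moderate,
            "mortality": dict(tr.mortality),
        },
        "severity": {
            "split": {g: list(t) for g, t in params.severity_split.by_group.items()},
            "cost_ratios": {
                "health": list(params.costs.ratios.health),
                "social": list(params.costs.ratios.social),
            },
        },
        "costs": {
            "england_hcru": params.costs.england_hcru.to_mapping(),
            "ad_hcru": {lbl: float(v) for lbl, v in zip(BAND_LABELS, params.costs.ad_hcru)},
            "social_general": dict(params.costs.social_general),
            "social_ad": dict(params.costs.social_ad),
            "social_utilisation": params.costs.social_utilisation,
            "primary_visit_cost": params.costs.primary_visit_cost,
            "specialist_visit_cost": params.costs.specialist_visit_cost,
            "drug_price_annual": params.costs.drug_price_annual,
        },
        "provenance": dict(params.provenance),
    }


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a ModelParameters to YAML; round-trips through load to 1e-12."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(parameters_to_config(params), fh, sort_keys=False)
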