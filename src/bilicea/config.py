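"""Country configurations, treatment regimens, and result I/O.

Each country carries one YAML file with every economic input of the model:
per-vial drug prices, grade ≥3 adverse-event management costs and per-arm
probabilities, per-cycle examination/administration/best-supportive-care
costs, a one-time end-of-life cost, health-state utilities, mean body
surface area, the annual discount rate and the willingness-to-pay
threshold.  All monetary values are USD; the exchange rates used by the
source price lists are kept as comments in the YAML files and never enter
any computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "AE_NAMES",
    "ARMS",
    "DrugPrice",
    "RegimenComponent",
    "CountryConfig",
    "ModelSettings",
    "ConfigError",
    "first_line_regimen",
    "folfox_course",
    "io_regimen",
    "load_country_config",
    "builtin_configs",
    "apply_overrides",
    "write_results",
    "read_results",
]

#: the four grade ≥3 adverse events costed in the first cycle
AE_NAMES = ("neutropenia", "leukopenia", "thrombocytopenia", "anemia")

#: arm identifiers: experimental = pembrolizumab + gemcitabine/cisplatin,
#: control = gemcitabine/cisplatin alone
ARMS = ("experimental", "control")

RESULT_COLUMNS = [
    "country",
    "arm",
    "cost",
    "qaly",
    "incremental_cost",
    "incremental_qaly",
    "icer",
]

#: dominance tokens allowed in the ICER column of a results table
ICER_TOKENS = ("dominant", "dominated", "undefined")


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or violates an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugPrice:
    """Price of one vial/pack of a drug: ``vial_mg`` milligrams for ``usd_per_vial``."""

    drug_name: str
    vial_mg: float
    usd_per_vial: float

    def validate(self) -> None:
        if not self.vial_mg > 0:
            raise ConfigError(f"{self.drug_name}: vial_mg must be > 0")
        if self.usd_per_vial < 0:
            raise ConfigError(f"{self.drug_name}: usd_per_vial must be >= 0")


@dataclass(frozen=True)
class RegimenComponent:
    """One drug of a regimen.

    ``dose_mg`` is a flat dose when ``per_m2`` is False, otherwise mg/m² to be
    scaled by body surface area.  ``max_cycles`` of ``None`` means the drug is
    given for as long as the patient remains progression-free.
    """

    drug_name: str
    dose_mg: float
    per_m2: bool
    administrations_per_cycle: int = 1
    max_cycles: int | None = None

    def __post_init__(self) -> None:
        if not self.dose_mg > 0:
            raise ConfigError(f"{self.drug_name}: dose must be > 0")
        if self.administrations_per_cycle not in (1, 2):
            raise ConfigError(
                f"{self.drug_name}: administrations_per_cycle must be 1 or 2"
            )
        if self.max_cycles is not None and self.max_cycles < 1:
            raise ConfigError(f"{self.drug_name}: max_cycles must be >= 1")


# First-line regimens on the 21-day cycle: pembrolizumab 200 mg flat on day 1
# (at most 35 cycles), gemcitabine 1,000 mg/m² and cisplatin 25 mg/m² on days
# 1 and 8, cisplatin capped at 8 cycles.  The control arm receives the same
# chemotherapy backbone without pembrolizumab.
_FIRST_LINE = {
    "experimental": (
        RegimenComponent("pembrolizumab", 200.0, per_m2=False,
                         administrations_per_cycle=1, max_cycles=35),
        RegimenComponent("gemcitabine", 1000.0, per_m2=True,
                         administrations_per_cycle=2, max_cycles=None),
        RegimenComponent("cisplatin", 25.0, per_m2=True,
                         administrations_per_cycle=2, max_cycles=8),
    ),
    "control": (
        RegimenComponent("gemcitabine", 1000.0, per_m2=True,
                         administrations_per_cycle=2, max_cycles=None),
        RegimenComponent("cisplatin", 25.0, per_m2=True,
                         administrations_per_cycle=2, max_cycles=8),
    ),
}

# Second-line FOLFOX, expressed per 14-day course (mFOLFOX6 dosing):
# oxaliplatin 85 mg/m², leucovorin 400 mg/m², fluorouracil 2,800 mg/m²
# (bolus + 46-h infusion combined).  The engine prorates one course to the
# 21-day model cycle with a factor of 1.5.
_FOLFOX_COURSE = (
    RegimenComponent("oxaliplatin", 85.0, per_m2=True),
    RegimenComponent("leucovorin", 400.0, per_m2=True),
    RegimenComponent("fluorouracil", 2800.0, per_m2=True),
)

#: prorating factor from a 14-day FOLFOX course to the 21-day model cycle
FOLFOX_CYCLE_FACTOR = 21.0 / 14.0

# Post-progression immunotherapy costed as one 200 mg pembrolizumab
# administration per cycle (the specific agent is configurable in principle;
# pembrolizumab pricing is the shipped default).
_IO_REGIMEN = (
    RegimenComponent("pembrolizumab", 200.0, per_m2=False,
                     administrations_per_cycle=1),
)


def first_line_regimen(arm: str) -> tuple[RegimenComponent, ...]:
    """The first-line drug regimen of ``arm`` ('experimental' or 'control')."""
    try:
        return _FIRST_LINE[arm]
    except KeyError:
        raise ConfigError(f"unknown arm {arm!r}; expected one of {ARMS}") from None


def folfox_course() -> tuple[RegimenComponent, ...]:
    """Second-line FOLFOX components, per 14-day course."""
    return _FOLFOX_COURSE


def io_regimen() -> tuple[RegimenComponent, ...]:
    """Post-progression immunotherapy components, per 21-day cycle."""
    return _IO_REGIMEN


@dataclass(frozen=True)
class CountryConfig:
    """All economic inputs of the model for one country (USD throughout)."""

    country: str
    drug_prices: Mapping[str, DrugPrice]
    ae_costs: Mapping[str, float]
    ae_prob_pem: Mapping[str, float]
    ae_prob_chem: Mapping[str, float]
    examination_cost: float
    administration_cost: float
    bsc_cost: float
    eol_cost: float
    u_pfs: float
    u_pd: float
    bsa: float
    discount_rate: float
    wtp: float
    second_line_prop_pem: float = 0.47
    second_line_prop_chem: float = 0.49
    io_prop_pem: float = 0.009
    io_prop_chem: float = 0.011

    def validate(self) -> None:
        for price in self.drug_prices.values():
            price.validate()
        for name, mapping in (("ae_costs", self.ae_costs),
                              ("ae_prob_pem", self.ae_prob_pem),
                              ("ae_prob_chem", self.ae_prob_chem)):
            missing = set(AE_NAMES) - set(mapping)
            if missing:
                raise ConfigError(f"{name}: missing adverse events {sorted(missing)}")
            extra = set(mapping) - set(AE_NAMES)
            if extra:
                raise ConfigError(f"{name}: unknown adverse events {sorted(extra)}")
        for name in ("ae_prob_pem", "ae_prob_chem"):
            for ae, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{ae}]: probability outside [0,1]")
        for ae, c in self.ae_costs.items():
            if c < 0:
                raise ConfigError(f"ae_costs[{ae}]: negative cost")
        for name in ("examination_cost", "administration_cost", "bsc_cost",
                     "eol_cost"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: negative cost")
        for name in ("u_pfs", "u_pd"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name}: utility outside [0,1]")
        if self.u_pd > self.u_pfs:
            raise ConfigError("u_pd must not exceed u_pfs")
        if not self.bsa > 0:
            raise ConfigError("bsa must be > 0")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if not self.wtp > 0:
            raise ConfigError("wtp must be > 0")
        for name in ("second_line_prop_pem", "second_line_prop_chem",
                     "io_prop_pem", "io_prop_chem"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: proportion outside [0,1]")
        if self.second_line_prop_pem + self.io_prop_pem > 1.0:
            raise ConfigError("experimental-arm second-line proportions exceed 1")
        if self.second_line_prop_chem + self.io_prop_chem > 1.0:
            raise ConfigError("control-arm second-line proportions exceed 1")

    def price(self, drug_name: str) -> DrugPrice:
        try:
            return self.drug_prices[drug_name]
        except KeyError:
            raise ConfigError(
                f"{self.country}: no price for drug {drug_name!r}"
            ) from None


@dataclass(frozen=True)
class ModelSettings:
    """Cycle structure of the partitioned survival model.

    A 21-day cycle over a 10-year horizon gives 174 cycles; by that point
    essentially all patients of both arms have died.  State occupancy is
    evaluated at cycle starts by default; ``half_cycle_correction`` switches
    the evaluation to cycle midpoints.
    """

    cycle_days: float = 21.0
    horizon_years: float = 10.0
    half_cycle_correction: bool = False
    seed: int = 42

    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon_years * 365.25 / self.cycle_days)

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / 365.25 * 12.0

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = {
    "country", "drug_prices", "ae_costs", "ae_prob_pem", "ae_prob_chem",
    "examination_cost", "administration_cost", "bsc_cost", "eol_cost",
    "u_pfs", "u_pd", "bsa", "discount_rate", "wtp",
}
_OPTIONAL_KEYS = {
    "second_line_prop_pem", "second_line_prop_chem",
    "io_prop_pem", "io_prop_chem",
}


def _config_from_mapping(raw: Mapping, source: str) -> CountryConfig:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{source}: top level must be a mapping")
    keys = set(raw)
    missing = _REQUIRED_KEYS - keys
    if missing:
        raise ConfigError(f"{source}: missing required field(s) {sorted(missing)}")
    unknown = keys - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise ConfigError(f"{source}: unknown field(s) {sorted(unknown)}")

    prices: dict[str, DrugPrice] = {}
    raw_prices = raw["drug_prices"]
    if not isinstance(raw_prices, Mapping):
        raise ConfigError(f"{source}: drug_prices must be a mapping")
    for drug, entry in raw_prices.items():
        if not isinstance(entry, Mapping) or set(entry) != {"vial_mg", "usd_per_vial"}:
            raise ConfigError(
                f"{source}: drug_prices[{drug}] must have exactly "
                "vial_mg and usd_per_vial"
            )
        prices[drug] = DrugPrice(drug, float(entry["vial_mg"]),
                                 float(entry["usd_per_vial"]))

    def _float_map(key: str) -> dict[str, float]:
        m = raw[key]
        if not isinstance(m, Mapping):
            raise ConfigError(f"{source}: {key} must be a mapping")
        return {str(k): float(v) for k, v in m.items()}

    kwargs = dict(
        country=str(raw["country"]),
        drug_prices=prices,
        ae_costs=_float_map("ae_costs"),
        ae_prob_pem=_float_map("ae_prob_pem"),
        ae_prob_chem=_float_map("ae_prob_chem"),
    )
    for key in _REQUIRED_KEYS - {"country", "drug_prices", "ae_costs",
                                 "ae_prob_pem", "ae_prob_chem"}:
        kwargs[key] = float(raw[key])
    for key in _OPTIONAL_KEYS & keys:
        kwargs[key] = float(raw[key])

    config = CountryConfig(**kwargs)
    config.validate()
    return config


def load_country_config(path: str | Path) -> CountryConfig:
    """Load and validate one country configuration from a YAML file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _config_from_mapping(raw, source=str(path))


_BUILTIN_FILES = {
    "China": "china.yaml",
    "Japan": "japan.yaml",
    "US": "us.yaml",
    "Switzerland": "switzerland.yaml",
}


def builtin_configs() -> dict[str, CountryConfig]:
    """The four shipped country configurations (China, Japan, US, Switzerland)."""
    out: dict[str, CountryConfig] = {}
    data = resources.files("bilicea") / "data"
    for country, fname in _BUILTIN_FILES.items():
        raw = yaml.safe_load((data / fname).read_text())
        out[country] = _config_from_mapping(raw, source=fname)
    return out


def builtin_config(country: str) -> CountryConfig:
    """One shipped configuration, looked up case-insensitively."""
    configs = builtin_configs()
    for name, cfg in configs.items():
        if name.lower() == country.lower():
            return cfg
    raise ConfigError(
        f"no builtin configuration for {country!r}; "
        f"available: {sorted(configs)}"
    )


def config_to_mapping(config: CountryConfig) -> dict:
    """Serialize a configuration back to the YAML-dialect mapping."""
    return {
        "country": config.country,
        "drug_prices": {
            d: {"vial_mg": p.vial_mg, "usd_per_vial": p.usd_per_vial}
            for d, p in config.drug_prices.items()
        },
        "ae_costs": dict(config.ae_costs),
        "ae_prob_pem": dict(config.ae_prob_pem),
        "ae_prob_chem": dict(config.ae_prob_chem),
        "examination_cost": config.examination_cost,
        "administration_cost": config.administration_cost,
        "bsc_cost": config.bsc_cost,
        "eol_cost": config.eol_cost,
        "u_pfs": config.u_pfs,
        "u_pd": config.u_pd,
        "bsa": config.bsa,
        "discount_rate": config.discount_rate,
        "wtp": config.wtp,
        "second_line_prop_pem": config.second_line_prop_pem,
        "second_line_prop_chem": config.second_line_prop_chem,
        "io_prop_pem": config.io_prop_pem,
        "io_prop_chem": config.io_prop_chem,
    }


def save_country_config(config: CountryConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_mapping(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# parameter overrides (used by the sensitivity analyses)
# ---------------------------------------------------------------------------

def apply_overrides(config: CountryConfig, overrides: Mapping[str, float]
                    ) -> CountryConfig:
    """Return a copy of ``config`` with dotted-path parameters replaced.

    Recognised ids: plain scalar field names (``u_pfs``, ``eol_cost`` ...),
    ``drug_price.<name>`` (USD per vial), ``ae_cost.<name>``,
    ``ae_prob_pem.<name>`` and ``ae_prob_chem.<name>``.

    Cross-field invariants are deliberately NOT re-validated: one-way
    sensitivity excursions (e.g. raising u_pd past u_pfs) are legitimate
    model perturbations even where a base-case config would be rejected.
    """
    prices = dict(config.drug_prices)
    ae_costs = dict(config.ae_costs)
    ae_prob_pem = dict(config.ae_prob_pem)
    ae_prob_chem = dict(config.ae_prob_chem)
    scalars: dict[str, float] = {}
    for key, value in overrides.items():
        if "." in key:
            group, name = key.split(".", 1)
            if group == "drug_price":
                old = prices[name]
                prices[name] = replace(old, usd_per_vial=float(value))
            elif group == "ae_cost":
                if name not in ae_costs:
                    raise ConfigError(f"unknown adverse event {name!r}")
                ae_costs[name] = float(value)
            elif group == "ae_prob_pem":
                ae_prob_pem[name] = float(value)
            elif group == "ae_prob_chem":
                ae_prob_chem[name] = float(value)
            else:
                raise ConfigError(f"unknown parameter group {group!r}")
        else:
            if key in ("country", "drug_prices"):
                raise ConfigError(f"cannot override {key!r}")
            if not hasattr(config, key):
                raise ConfigError(f"unknown parameter {key!r}")
            scalars[key] = float(value)
    return replace(config, drug_prices=prices, ae_costs=ae_costs,
                   ae_prob_pem=ae_prob_pem, ae_prob_chem=ae_prob_chem,
                   **scalars)


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------

def _coerce_result_frame(result) -> pd.DataFrame:
    if isinstance(result, pd.DataFrame):
        frame = result.copy()
    elif hasattr(result, "to_frame_rows"):        # a CEAResult
        frame = pd.DataFrame(result.to_frame_rows(), columns=RESULT_COLUMNS)
    elif isinstance(result, Iterable):
        rows: list = []
        for item in result:
            if hasattr(item, "to_frame_rows"):
                rows.extend(item.to_frame_rows())
            else:
                rows.append(item)
        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    else:
        raise TypeError(f"cannot serialize result of type {type(result)!r}")
    missing = set(RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"result table missing column(s) {sorted(missing)}")
    return frame[RESULT_COLUMNS]


def write_results(result, path: str | Path) -> None:
    """Write a Table-2-shaped results table as CSV (plus a JSON mirror).

    ``result`` may be a ``CEAResult``, an iterable of them, or a DataFrame
    already holding the columns country/arm/cost/qaly/incremental_cost/
    incremental_qaly/icer.  Undefined ICERs are written as the explicit
    tokens ``dominant``/``dominated``/``undefined``, never as numbers.
    The matching reader round-trips all numeric values exactly.
    """
    frame = _coerce_result_frame(result)
    path = Path(path)
    frame.to_csv(path, index=False)
    records = frame.where(pd.notna(frame), None).to_dict(orient="records")
    path.with_suffix(".json").write_text(json.dumps(records, indent=2))


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    frame = pd.read_csv(path, dtype={"icer": object})

    def _parse_icer(v):
        if pd.isna(v) or v in ICER_TOKENS:
            return v if not pd.isna(v) else v
        return float(v)

    frame["icer"] = frame["icer"].map(_parse_icer)
    return frame[RESULT_COLUMNS] if set(RESULT_COLUMNS) <= set(frame.columns) else frame
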