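"""Study-level reading-time evidence and country/pricing configuration.

The evidence corpus holds one row per published reader-timing arm pair:
reading time per CT scan without CAD, with CAD, and the reported
difference.  Times may be summarised as mean +/- SD, median (IQR) or a
bare central value; the sign convention for the difference is
``with_cad - no_cad``, so a negative difference is time saved.

The settings object carries hourly radiologist cost per country (with
exchange rates to EUR frozen at their 2022 averages), the three CAD
pricing models, and the pre-screening scenario parameters.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import warnings
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
from pydantic import BaseModel, model_validator

logger = logging.getLogger(__name__)

Locator = Union[str, Path]

#: CSV column order for the corpus schema (JSON mirrors the same keys).
CORPUS_COLUMNS = [
    "study_label",
    "country",
    "modality",
    "cad_product",
    "reading_mode",
    "reader_label",
    "no_cad_central",
    "no_cad_dispersion_kind",
    "no_cad_dispersion",
    "no_cad_lo",
    "no_cad_hi",
    "with_cad_central",
    "with_cad_dispersion_kind",
    "with_cad_dispersion",
    "with_cad_lo",
    "with_cad_hi",
    "diff_seconds",
    "diff_ci_lo",
    "diff_ci_hi",
    "p_value",
]


class Modality(str, Enum):
    CT = "CT"
    LOW_DOSE_CT = "low_dose_CT"


class ReadingMode(str, Enum):
    SECOND_READER = "second_reader"
    CONCURRENT_READER = "concurrent_reader"


class DispersionKind(str, Enum):
    SD = "sd"
    IQR_BOUNDS = "iqr_bounds"
    CI_BOUNDS = "ci_bounds"
    NONE = "none"


class TimeSummary(BaseModel):
    """A published per-scan reading-time summary, in seconds.

    ``central`` is a mean (for ``sd``/``none`` dispersion) or a median
    (for ``iqr_bounds``).  ``bounds`` carries the quartiles or CI limits
    when the study reported an interval instead of an SD.
    """

    central: float
    dispersion: Optional[float] = None
    dispersion_kind: DispersionKind = DispersionKind.NONE
    bounds: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "TimeSummary":
        if self.central <= 0:
            raise ValueError(f"reading time must be positive, got {self.central}")
        if self.dispersion_kind == DispersionKind.SD:
            if self.dispersion is None or self.dispersion <= 0:
                raise ValueError("dispersion_kind=sd requires a positive dispersion")
            if self.bounds is not None:
                raise ValueError("dispersion_kind=sd excludes bounds")
        elif self.dispersion_kind in (DispersionKind.IQR_BOUNDS, DispersionKind.CI_BOUNDS):
            if self.bounds is None:
                raise ValueError(f"dispersion_kind={self.dispersion_kind.value} requires bounds")
            lo, hi = self.bounds
            if not lo <= self.central <= hi:
                raise ValueError(
                    f"bounds ({lo}, {hi}) must bracket the central value {self.central}"
                )
        return self


class ReadingTimeObservation(BaseModel):
    """One arm pair of a published reader-timing study.

    Multi-reader studies contribute one observation per reader sharing a
    ``study_label``; aggregation across readers is a pooling-stage policy.
    """

    study_label: str
    country: str
    modality: Modality
    cad_product: str
    reading_mode: ReadingMode
    reader_label: str = ""
    time_no_cad: TimeSummary
    time_with_cad: TimeSummary
    reported_difference_seconds: Optional[float] = None
    reported_difference_ci: Optional[tuple[float, float]] = None
    p_value_text: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ReadingTimeObservation":
        if self.reported_difference_ci is not None:
            lo, hi = self.reported_difference_ci
            if lo > hi:
                raise ValueError(f"difference CI ({lo}, {hi}) must satisfy lo <= hi")
        d = self.reported_difference_seconds
        if d is not None:
            if self.reading_mode == ReadingMode.SECOND_READER and d <= 0:
                raise ValueError(
                    f"{self.study_label}: second-reader difference must be positive "
                    f"(CAD review adds time), got {d}"
                )
            if self.reading_mode == ReadingMode.CONCURRENT_READER and d >= 0:
                raise ValueError(
                    f"{self.study_label}: concurrent-reader difference must be negative "
                    f"(CAD saves time), got {d}"
                )
        return self

    @property
    def difference_seconds(self) -> float:
        """Signed difference with_cad - no_cad; falls back to the centrals."""
        if self.reported_difference_seconds is not None:
            return self.reported_difference_seconds
        return self.time_with_cad.central - self.time_no_cad.central


class CountrySetting(BaseModel):
    """Hourly radiologist cost in local currency with its EUR conversion.

    ``hourly_cost_eur`` is the exact product local x rate;
    ``hourly_cost_eur_printed`` rounds it to the whole euro, which is the
    precision at which such salary figures are quoted.
    """

    name: str
    hourly_cost_local: float
    currency_code: str
    eur_per_local_unit: float

    @model_validator(mode="after")
    def _check(self) -> "CountrySetting":
        if self.hourly_cost_local <= 0 or self.eur_per_local_unit <= 0:
            raise ValueError("hourly cost and exchange rate must be positive")
        return self

    @property
    def hourly_cost_eur(self) -> float:
        return convert_to_eur(self.hourly_cost_local, self.eur_per_local_unit)

    @property
    def hourly_cost_eur_printed(self) -> int:
        from .report import round_half_up

        return int(round_half_up(self.hourly_cost_eur, 0))


class PricingKind(str, Enum):
    PAY_PER_USE = "pay_per_use"
    ONE_OFF_LICENSE = "one_off_license"
    YEARLY_SUBSCRIPTION = "yearly_subscription"


class PricingModel(BaseModel):
    """One CAD pricing model: per-case fee range, one-off license or annual fee."""

    kind: PricingKind
    price_eur: Optional[float] = None
    price_range_eur: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "PricingModel":
        if self.kind == PricingKind.PAY_PER_USE:
            if self.price_range_eur is None:
                raise ValueError("pay_per_use requires a (lo, hi) per-case price range")
            lo, hi = self.price_range_eur
            if not 0 < lo <= hi:
                raise ValueError(f"pay-per-use price range ({lo}, {hi}) must be positive with lo <= hi")
        else:
            if self.price_eur is None or self.price_eur <= 0:
                raise ValueError(f"{self.kind.value} requires a positive scalar price")
        return self


class ScenarioConfig(BaseModel):
    """Pre-screening scenario parameters: nodule prevalence range and rule-out fraction."""

    prevalence_lo: float
    prevalence_hi: float
    ruleout_fraction: float

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if not 0 <= self.prevalence_lo <= self.prevalence_hi <= 1:
            raise ValueError("need 0 <= prevalence_lo <= prevalence_hi <= 1")
        if not 0 <= self.ruleout_fraction <= 1:
            raise ValueError("ruleout_fraction must be in [0, 1]")
        return self


class PrintedPooled(BaseModel):
    """A pooled mean with 95% CI transcribed from the published evidence table."""

    mean: float
    ci_lo: float
    ci_hi: float


class Settings(BaseModel):
    """Country, pricing and scenario configuration for a break-even run."""

    countries: list[CountrySetting]
    pricing: list[PricingModel]
    scenario: ScenarioConfig
    printed_pooled: dict[str, PrintedPooled] = {}
    printed_scenarios: dict[str, PrintedPooled] = {}

    def country(self, name: str) -> CountrySetting:
        for c in self.countries:
            if c.name == name:
                return c
        raise KeyError(name)

    def pricing_model(self, kind: str) -> PricingModel:
        for p in self.pricing:
            if p.kind.value == kind:
                return p
        raise KeyError(kind)


def convert_to_eur(amount: float, eur_per_local_unit: float) -> float:
    """Convert a local-currency amount to EUR at a fixed rate."""
    if eur_per_local_unit <= 0:
        raise ValueError(f"exchange rate must be positive, got {eur_per_local_unit}")
    return amount * eur_per_local_unit


# ---------------------------------------------------------------------------
# corpus IO


class SchemaError(ValueError):
    """A corpus row is missing a mandatory field or violates the schema."""


def _opt_float(row: dict, field: str) -> Optional[float]:
    v = row.get(field)
    if v is None or v == "":
        return None
    return float(v)


def _row_to_observation(row: dict, index: int) -> ReadingTimeObservation:
    for field in ("study_label", "reading_mode", "no_cad_central", "with_cad_central"):
        if row.get(field) in (None, ""):
            raise SchemaError(f"row {index}: missing mandatory field {field!r}")

    def summary(prefix: str) -> TimeSummary:
        kind = row.get(f"{prefix}_dispersion_kind") or "none"
        lo = _opt_float(row, f"{prefix}_lo")
        hi = _opt_float(row, f"{prefix}_hi")
        return TimeSummary(
            central=float(row[f"{prefix}_central"]),
            dispersion=_opt_float(row, f"{prefix}_dispersion"),
            dispersion_kind=DispersionKind(kind),
            bounds=(lo, hi) if lo is not None and hi is not None else None,
        )

    ci_lo = _opt_float(row, "diff_ci_lo")
    ci_hi = _opt_float(row, "diff_ci_hi")
    try:
        return ReadingTimeObservation(
            study_label=row["study_label"],
            country=row.get("country", ""),
            modality=Modality(row.get("modality", "CT")),
            cad_product=row.get("cad_product", ""),
            reading_mode=ReadingMode(row["reading_mode"]),
            reader_label=row.get("reader_label") or "",
            time_no_cad=summary("no_cad"),
            time_with_cad=summary("with_cad"),
            reported_difference_seconds=_opt_float(row, "diff_seconds"),
            reported_difference_ci=(ci_lo, ci_hi) if ci_lo is not None and ci_hi is not None else None,
            p_value_text=row.get("p_value") or None,
        )
    except ValueError as exc:
        raise SchemaError(f"row {index} ({row.get('study_label')}): {exc}") from exc


def _observation_to_row(obs: ReadingTimeObservation) -> dict:
    def expand(prefix: str, ts: TimeSummary) -> dict:
        lo, hi = ts.bounds if ts.bounds is not None else (None, None)
        return {
            f"{prefix}_central": ts.central,
            f"{prefix}_dispersion_kind": ts.dispersion_kind.value,
            f"{prefix}_dispersion": ts.dispersion,
            f"{prefix}_lo": lo,
            f"{prefix}_hi": hi,
        }

    ci = obs.reported_difference_ci
    row = {
        "study_label": obs.study_label,
        "country": obs.country,
        "modality": obs.modality.value,
        "cad_product": obs.cad_product,
        "reading_mode": obs.reading_mode.value,
        "reader_label": obs.reader_label,
        **expand("no_cad", obs.time_no_cad),
        **expand("with_cad", obs.time_with_cad),
        "diff_seconds": obs.reported_difference_seconds,
        "diff_ci_lo": ci[0] if ci else None,
        "diff_ci_hi": ci[1] if ci else None,
        "p_value": obs.p_value_text,
    }
    return {k: ("" if row[k] is None else row[k]) for k in CORPUS_COLUMNS}


def load_corpus(path_or_fixture: Locator = "table1") -> list[ReadingTimeObservation]:
    """Read a reading-time corpus from CSV/JSON, or the packaged evidence table.

    The locator ``"table1"`` loads the packaged transcription of the
    published evidence: 2 second-reader and 6 concurrent-reader
    observations (one study contributes two reader rows).
    """
    if path_or_fixture == "table1":
        text = resources.files("cad_breakeven.data").joinpath("table1.csv").read_text()
        return _parse_corpus_csv(io.StringIO(text))
    path = Path(path_or_fixture)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text() or "[]")
        obs = [_row_to_observation(r, i) for i, r in enumerate(rows)]
    else:
        with open(path, newline="") as fh:
            obs = _parse_corpus_csv(fh)
    if not obs:
        warnings.warn(f"corpus {path_or_fixture!r} is empty", stacklevel=2)
    return obs


def _parse_corpus_csv(fh) -> list[ReadingTimeObservation]:
    reader = csv.DictReader(fh)
    return [_row_to_observation(row, i) for i, row in enumerate(reader)]


def write_corpus(observations: Sequence[ReadingTimeObservation], path: Locator) -> None:
    """Write observations to CSV or JSON in the documented schema."""
    path = Path(path)
    rows = [_observation_to_row(o) for o in observations]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CORPUS_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# settings IO


def load_settings(path: Locator = "default") -> Settings:
    """Load country/pricing/scenario configuration from YAML or JSON.

    The packaged default reproduces the published inputs: hourly costs of
    EUR 196 (USA), 127 (UK) and 45 (Poland); pay-per-use EUR 5.9-8.8,
    one-off license EUR 51,616, yearly subscription EUR 20,000; nodule
    prevalence 22-51% with an 80% rule-out of nodule-free scans.
    """
    if path == "default":
        text = resources.files("cad_breakeven.data").joinpath("settings.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    countries = [CountrySetting(**c) for c in raw["countries"]]
    pricing = []
    for p in raw["pricing"]:
        price = p.get("price_eur")
        if isinstance(price, (list, tuple)):
            pricing.append(PricingModel(kind=p["kind"], price_range_eur=tuple(price)))
        else:
            pricing.append(PricingModel(kind=p["kind"], price_eur=price))
    scenario = ScenarioConfig(**raw["scenario"])
    printed = {k: PrintedPooled(**v) for k, v in raw.get("printed_pooled", {}).items()}
    printed_sc = {k: PrintedPooled(**v) for k, v in raw.get("printed_scenarios", {}).items()}
    return Settings(
        countries=countries,
        pricing=pricing,
        scenario=scenario,
        printed_pooled=printed,
        printed_scenarios=printed_sc,
    )
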