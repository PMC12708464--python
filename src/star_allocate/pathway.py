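"""Domain types, validation and serialization for ICS pathway datasets.

A dataset describes one Integrated Care System's disease-care pathway:

* baseline **interventions** — current activity (people treated per year),
  the number needed to treat (NNT), a 0–100 relative benefit score anchored
  at a benchmark of 100, and annual cost;
* candidate **pathway improvements** — one record per improvement *scenario*
  (e.g. 10%/25%/50% uptake), each carrying either the inputs needed to
  compute a population health benefit (PHB) gain or the PHB gain itself,
  plus either a gross implementation cost / offset savings decomposition or
  a net annual cost directly.

Two on-disk layouts are supported: a ``csv_bundle`` directory
(``interventions.csv``, ``improvements.csv``, ``meta.json``) and a single
JSON document.  Round-trips are lossless.

Sign convention: input cost fields (``annual_cost``, ``implementation_cost``,
``offset_savings``) are non-negative; only *net* cost may be negative, and a
negative net cost means a net saving to the system.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import IO, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "DatasetError",
    "SchemaError",
    "InterventionRecord",
    "ImprovementScenario",
    "ICSDataset",
    "load_dataset",
    "save_dataset",
    "dataset_to_json_dict",
    "dataset_from_json_dict",
    "export_json_schema",
]


class DatasetError(ValueError):
    """A dataset violated a model invariant."""


class SchemaError(DatasetError):
    """An input file did not conform to the declared schema."""


class InterventionRecord(BaseModel):
    """One baseline intervention in the current care pathway."""

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    name: str = ""
    segment: str = ""
    n_treated: int = Field(ge=0, description="people treated per year")
    nnt: float = Field(ge=1, description="number needed to treat")
    benefit_score: float = Field(ge=0, le=100, description="VAS relative benefit")
    annual_cost: float = Field(ge=0, description="currency units per year")


class ImprovementScenario(BaseModel):
    """One candidate pathway improvement under one scenario / uptake level.

    The PHB gain is either supplied directly (``phb_gain``) or derived from
    ``additional_treated / nnt * benefit_score``; if both are present they
    must agree within 0.5%.  The net annual cost is either supplied
    (``net_cost``) or derived as ``implementation_cost - offset_savings``.

    ``rank_printed``, ``cost_ratio_printed``, ``cost_phb_ratio_printed``,
    ``recommended_flag`` and ``consistency_flag`` are transcription
    annotations carried by the packaged fixtures: ``consistency_flag`` is
    True when the published cost/PHB ratio is reproducible from the published
    net cost and PHB gain at two-decimal rounding.  ``cost_ratio_printed``
    uses NaN for a published "N/A" and inf for a published "∞".
    """

    model_config = ConfigDict(frozen=True)

    improvement_id: str = Field(min_length=1)
    name: str = ""
    scenario_label: str = "base"
    additional_treated: Optional[int] = Field(None, ge=0)
    nnt: Optional[float] = Field(None, ge=1)
    benefit_score: Optional[float] = Field(None, ge=0, le=100)
    phb_gain: Optional[float] = Field(None, ge=0)
    implementation_cost: Optional[float] = Field(None, ge=0)
    offset_savings: Optional[float] = Field(None, ge=0)
    net_cost: Optional[float] = None
    rank_printed: Optional[int] = Field(None, ge=1)
    cost_ratio_printed: Optional[float] = None
    cost_phb_ratio_printed: Optional[float] = None
    recommended_flag: bool = False
    consistency_flag: Optional[bool] = None

    @model_validator(mode="after")
    def _coherent(self) -> "ImprovementScenario":
        triple = (
            self.additional_treated is not None
            and self.nnt is not None
            and self.benefit_score is not None
        )
        if self.phb_gain is None and not triple:
            raise ValueError(
                "either phb_gain or the full (additional_treated, nnt, "
                "benefit_score) triple must be supplied"
            )
        if self.phb_gain is not None and triple:
            computed = self.additional_treated / self.nnt * self.benefit_score
            ref = max(abs(computed), abs(self.phb_gain))
            if ref > 0 and abs(computed - self.phb_gain) / ref > 0.005:
                raise ValueError(
                    f"supplied phb_gain {self.phb_gain} disagrees with computed "
                    f"{computed:.2f} by more than 0.5%"
                )
        if self.net_cost is None and self.implementation_cost is None:
            raise ValueError(
                "either net_cost or implementation_cost must be supplied"
            )
        if (
            self.net_cost is not None
            and self.implementation_cost is not None
            and self.offset_savings is not None
        ):
            derived = self.implementation_cost - self.offset_savings
            if abs(derived - self.net_cost) > 0.5:
                raise ValueError(
                    f"net_cost {self.net_cost} disagrees with implementation_cost "
                    f"- offset_savings = {derived}"
                )
        return self

    @property
    def key(self) -> tuple[str, str]:
        return (self.improvement_id, self.scenario_label)

    @property
    def effective_phb_gain(self) -> float:
        """PHB gain: supplied value, else additional_treated / NNT x score."""
        if self.phb_gain is not None:
            return float(self.phb_gain)
        return self.additional_treated / self.nnt * self.benefit_score

    @property
    def effective_net_cost(self) -> float:
        """Net annual cost (signed); negative means a net saving."""
        if self.net_cost is not None:
            return float(self.net_cost)
        return self.implementation_cost - (self.offset_savings or 0.0)


class ICSDataset(BaseModel):
    """A named dataset: population context, pathway and improvement list."""

    model_config = ConfigDict(frozen=True)

    name: str = Field(min_length=1)
    population_copd: int = Field(gt=0)
    currency_label: str = "GBP"
    provenance: Literal["fixture", "synthetic", "user"] = "user"
    interventions: list[InterventionRecord] = Field(default_factory=list)
    improvements: list[ImprovementScenario] = Field(default_factory=list)
    extras: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _unique(self) -> "ICSDataset":
        seen: set[str] = set()
        for rec in self.interventions:
            if rec.id in seen:
                raise ValueError(f"duplicate intervention id {rec.id!r}")
            seen.add(rec.id)
        pairs: set[tuple[str, str]] = set()
        for imp in self.improvements:
            if imp.key in pairs:
                raise ValueError(
                    f"duplicate improvement scenario {imp.improvement_id!r} / "
                    f"{imp.scenario_label!r}"
                )
            pairs.add(imp.key)
        return self


# --- CSV bundle layout -------------------------------------------------------

INTERVENTION_COLUMNS = [
    "id", "name", "segment", "n_treated", "nnt", "benefit_score", "annual_cost",
]
IMPROVEMENT_COLUMNS = [
    "improvement_id", "name", "scenario_label",
    "additional_treated", "nnt", "benefit_score", "phb_gain",
    "implementation_cost", "offset_savings", "net_cost",
    "rank_printed", "cost_ratio_printed", "cost_phb_ratio_printed",
    "recommended_flag", "consistency_flag",
]

_SPECIAL_FLOATS = {"NA": math.nan, "inf": math.inf, "-inf": -math.inf}


def _opt_float(s: str) -> Optional[float]:
    if s == "":
        return None
    if s in _SPECIAL_FLOATS:
        return _SPECIAL_FLOATS[s]
    return float(s)


def _opt_int(s: str) -> Optional[int]:
    return None if s == "" else int(s)


def _opt_bool(s: str) -> Optional[bool]:
    if s == "":
        return None
    if s.lower() in ("true", "1"):
        return True
    if s.lower() in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        if v.is_integer() and abs(v) < 1e15:
            return str(int(v))
        return repr(v)
    return str(v)


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise SchemaError(f"missing file: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def _intervention_from_row(row: pd.Series, where: str) -> InterventionRecord:
    try:
        return InterventionRecord(
            id=row["id"],
            name=row["name"],
            segment=row["segment"],
            n_treated=int(row["n_treated"]),
            nnt=float(row["nnt"]),
            benefit_score=float(row["benefit_score"]),
            annual_cost=float(row["annual_cost"]),
        )
    except (ValidationError, ValueError) as exc:
        raise DatasetError(f"{where} (id={row.get('id', '?')!r}): {exc}") from exc


def _improvement_from_row(row: pd.Series, where: str) -> ImprovementScenario:
    try:
        return ImprovementScenario(
            improvement_id=row["improvement_id"],
            name=row.get("name", ""),
            scenario_label=row["scenario_label"] or "base",
            additional_treated=_opt_int(row["additional_treated"]),
            nnt=_opt_float(row["nnt"]),
            benefit_score=_opt_float(row["benefit_score"]),
            phb_gain=_opt_float(row["phb_gain"]),
            implementation_cost=_opt_float(row["implementation_cost"]),
            offset_savings=_opt_float(row["offset_savings"]),
            net_cost=_opt_float(row.get("net_cost", "")),
            rank_printed=_opt_int(row.get("rank_printed", "")),
            cost_ratio_printed=_opt_float(row.get("cost_ratio_printed", "")),
            cost_phb_ratio_printed=_opt_float(row.get("cost_phb_ratio_printed", "")),
            recommended_flag=_opt_bool(row["recommended_flag"]) or False,
            consistency_flag=_opt_bool(row["consistency_flag"]),
        )
    except (ValidationError, ValueError) as exc:
        raise DatasetError(
            f"{where} (improvement_id={row.get('improvement_id', '?')!r}): {exc}"
        ) from exc


def _load_csv_bundle(path: Path) -> ICSDataset:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"missing file: {meta_path}")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))

    idf = _read_table(path / "interventions.csv", INTERVENTION_COLUMNS)
    interventions = [
        _intervention_from_row(row, f"interventions.csv row {i + 2}")
        for i, row in idf.iterrows()
    ]
    mdf = _read_table(
        path / "improvements.csv",
        [c for c in IMPROVEMENT_COLUMNS if "printed" not in c and c not in ("name", "net_cost")],
    )
    improvements = [
        _improvement_from_row(row, f"improvements.csv row {i + 2}")
        for i, row in mdf.iterrows()
    ]
    try:
        return ICSDataset(
            name=meta["name"],
            population_copd=meta["population_copd"],
            currency_label=meta.get("currency_label", "GBP"),
            provenance=meta.get("provenance", "user"),
            interventions=interventions,
            improvements=improvements,
            extras=meta.get("extras", {}),
        )
    except ValidationError as exc:
        raise DatasetError(str(exc)) from exc


def _write_csv(path: Path, columns: list[str], rows: list[list]) -> None:
    lines = [",".join(columns)]
    for row in rows:
        cells = []
        for v in row:
            s = _fmt(v)
            if any(ch in s for ch in ',"\n'):
                s = '"' + s.replace('"', '""') + '"'
            cells.append(s)
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _save_csv_bundle(dataset: ICSDataset, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    _write_csv(
        path / "interventions.csv",
        INTERVENTION_COLUMNS,
        [
            [r.id, r.name, r.segment, r.n_treated, r.nnt, r.benefit_score, r.annual_cost]
            for r in dataset.interventions
        ],
    )
    _write_csv(
        path / "improvements.csv",
        IMPROVEMENT_COLUMNS,
        [
            [
                m.improvement_id, m.name, m.scenario_label,
                m.additional_treated, m.nnt, m.benefit_score, m.phb_gain,
                m.implementation_cost, m.offset_savings, m.net_cost,
                m.rank_printed, m.cost_ratio_printed, m.cost_phb_ratio_printed,
                m.recommended_flag, m.consistency_flag,
            ]
            for m in dataset.improvements
        ],
    )
    meta = {
        "name": dataset.name,
        "population_copd": dataset.population_copd,
        "currency_label": dataset.currency_label,
        "provenance": dataset.provenance,
        "extras": dataset.extras,
    }
    (path / "meta.json").write_text(
        json.dumps(meta, indent=2, ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8",
    )


# --- single-document JSON ----------------------------------------------------

def _float_out(v):
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
    return v


def _float_in(v):
    if isinstance(v, str) and v in _SPECIAL_FLOATS:
        return _SPECIAL_FLOATS[v]
    return v


def dataset_to_json_dict(dataset: ICSDataset) -> dict:
    """JSON-safe dict mirroring the dataset (NaN/inf encoded as strings)."""
    doc = dataset.model_dump(mode="python")
    for imp in doc["improvements"]:
        for k, v in imp.items():
            imp[k] = _float_out(v)
    return doc


def dataset_from_json_dict(doc: dict) -> ICSDataset:
    doc = json.loads(json.dumps(doc))  # deep copy
    for imp in doc.get("improvements", []):
        for k, v in imp.items():
            imp[k] = _float_in(v)
    try:
        return ICSDataset(**doc)
    except ValidationError as exc:
        raise DatasetError(str(exc)) from exc


def load_dataset_json(fp: IO[str]) -> ICSDataset:
    """Load the single-document JSON format from an open text stream."""
    return dataset_from_json_dict(json.load(fp))


def dump_dataset_json(dataset: ICSDataset, fp: IO[str]) -> None:
    json.dump(dataset_to_json_dict(dataset), fp, indent=2, ensure_ascii=False)
    fp.write("\n")


# --- public entry points -----------------------------------------------------

def load_dataset(path, format: Optional[str] = None) -> ICSDataset:
    """Load a validated :class:`ICSDataset`.

    ``format`` is ``"csv_bundle"`` (a directory) or ``"json"`` (a single
    file); when omitted it is inferred from the path.  Validation failures
    raise :class:`DatasetError` naming the offending file/row; structural
    problems (missing files or columns) raise :class:`SchemaError`.
    """
    path = Path(path)
    if format is None:
        format = "csv_bundle" if path.is_dir() else "json"
    if format == "csv_bundle":
        return _load_csv_bundle(path)
    if format == "json":
        with open(path, encoding="utf-8") as fp:
            return load_dataset_json(fp)
    raise ValueError(f"unknown format {format!r}")


def save_dataset(dataset: ICSDataset, path, format: Optional[str] = None) -> None:
    """Write a dataset; ``load_dataset(save_dataset(d)) == d`` field-for-field."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv_bundle"
    if format == "csv_bundle":
        _save_csv_bundle(dataset, path)
    elif format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fp:
            dump_dataset_json(dataset, fp)
    else:
        raise ValueError(f"unknown format {format!r}")


def export_json_schema(path=None) -> dict:
    """JSON Schema for the single-document format (written if a path given)."""
    schema = ICSDataset.model_json_schema()
    schema["$schema"] = "https://json-schema.org/draft/2020-12/schema"
    schema["title"] = "ICSDataset"
    if path is not None:
        Path(path).write_text(
            json.dumps(schema, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return schema
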