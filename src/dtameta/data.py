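"""Study tables: types, validation, reading/writing, packaged fixtures.

A *study* is one diagnostic trial summarised by its 2x2 confusion table
(TP, FN, FP, TN) plus metadata used for subgrouping.  A :class:`StudySet`
is an ordered, id-unique collection of studies — the unit every analysis
in this package consumes.

The packaged fixture ``liu2021_mir21`` holds the 2x2 tables of 30 trials
from 26 published articles evaluating exosomal microRNA-21 as a cancer
biomarker, with subgroup labels (ethnicity, cancer group, specimen
source) materialised as columns; see ``fixtures/README.md`` for the
labelling conventions.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .exceptions import FixtureNotFoundError, FormatError, ValidationError

__all__ = [
    "Study2x2",
    "StudySet",
    "read_studies",
    "load_fixture",
    "list_fixtures",
    "write_results",
    "STUDY_COLUMNS",
]

#: canonical column order for study CSV files
STUDY_COLUMNS = [
    "study_id",
    "article_id",
    "year",
    "country",
    "ethnicity_group",
    "cancer_label",
    "cancer_group",
    "pancreatic",
    "sample_source",
    "sample_group",
    "tp",
    "fn",
    "fp",
    "tn",
    "sample_size",
]

_MANDATORY = ("study_id", "tp", "fn", "fp", "tn")

ETHNICITY_GROUPS = ("caucasian", "asian", "unknown")
CANCER_GROUPS = ("digestive", "breast", "lung", "other", "unknown")
SAMPLE_GROUPS = ("plasma", "serum", "other", "unknown")


@dataclass(frozen=True)
class Study2x2:
    """One trial's confusion counts plus metadata and subgroup labels.

    ``tp``/``fn`` form the diseased arm and ``fp``/``tn`` the
    non-diseased arm; both arms must be non-empty.  ``sample_size``, when
    known, must equal the sum of the four cells.
    """

    study_id: str
    tp: int
    fn: int
    fp: int
    tn: int
    article_id: str = ""
    year: int | None = None
    country: str = "unknown"
    ethnicity_group: str = "unknown"
    cancer_label: str = "unknown"
    cancer_group: str = "unknown"
    pancreatic: bool = False
    sample_source: str = "unknown"
    sample_group: str = "unknown"
    sample_size: int | None = None

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(
                    f"study {self.study_id!r}: count {name}={v!r} is not an integer"
                )
            if v < 0:
                raise ValidationError(
                    f"study {self.study_id!r}: negative count {name}={v}"
                )
        if self.tp + self.fn < 1:
            raise ValidationError(
                f"study {self.study_id!r}: no diseased arm (tp+fn == 0)"
            )
        if self.fp + self.tn < 1:
            raise ValidationError(
                f"study {self.study_id!r}: no non-diseased arm (fp+tn == 0)"
            )
        if self.sample_size is not None:
            total = self.tp + self.fn + self.fp + self.tn
            if total != self.sample_size:
                raise ValidationError(
                    f"study {self.study_id!r}: cells sum to {total} but "
                    f"sample_size is {self.sample_size}"
                )
        if not self.article_id:
            object.__setattr__(self, "article_id", self.study_id)

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fn, self.fp, self.tn)

    def has_zero_cell(self) -> bool:
        return 0 in self.counts


@dataclass
class StudySet:
    """Ordered collection of :class:`Study2x2` with unique ids."""

    studies: list[Study2x2]
    provenance: str = ""

    def __post_init__(self):
        if not self.studies:
            raise ValidationError("StudySet must contain at least one study")
        seen: set[str] = set()
        for s in self.studies:
            if s.study_id in seen:
                raise ValidationError(f"duplicate study_id {s.study_id!r}")
            seen.add(s.study_id)

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[Study2x2]:
        return iter(self.studies)

    def __getitem__(self, key: int | str) -> Study2x2:
        if isinstance(key, str):
            for s in self.studies:
                if s.study_id == key:
                    return s
            raise KeyError(key)
        return self.studies[key]

    @property
    def ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    @property
    def n_articles(self) -> int:
        return len({s.article_id for s in self.studies})

    def exclude(self, exclude_ids: Iterable[str]) -> "StudySet":
        wanted = list(exclude_ids)
        unknown = set(wanted) - set(self.ids)
        if unknown:
            raise KeyError(f"unknown study ids: {sorted(unknown)}")
        kept = [s for s in self.studies if s.study_id not in set(wanted)]
        return StudySet(kept, provenance=f"{self.provenance} minus {sorted(wanted)}")

    def subset(self, predicate) -> "StudySet":
        kept = [s for s in self.studies if predicate(s)]
        return StudySet(kept, provenance=f"{self.provenance} (subset)")

    def groupby(self, column: str) -> dict[str, "StudySet"]:
        """Partition by a metadata column; insertion order of levels."""
        if column not in {f.name for f in dataclasses.fields(Study2x2)}:
            raise KeyError(f"unknown grouping column {column!r}")
        out: dict[str, list[Study2x2]] = {}
        for s in self.studies:
            out.setdefault(str(getattr(s, column)), []).append(s)
        return {
            k: StudySet(v, provenance=f"{self.provenance} [{column}={k}]")
            for k, v in out.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.studies:
            d = dataclasses.asdict(s)
            rows.append({c: d[c] for c in STUDY_COLUMNS})
        return pd.DataFrame(rows, columns=STUDY_COLUMNS)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["pancreatic"] = df["pancreatic"].map({True: "true", False: "false"})
        df.to_csv(path, index=False)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(raw: str, row_id: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"row {row_id!r}: cannot parse boolean {raw!r}")


def _parse_count(raw: str, name: str, row_id: str) -> int:
    raw = raw.strip()
    try:
        val = int(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row_id!r}: count {name}={raw!r} is not an integer"
        ) from None
    return val


def _rows_to_studyset(rows: list[dict], provenance: str) -> StudySet:
    studies = []
    for row in rows:
        rid = (row.get("study_id") or "").strip()
        if not rid:
            raise ValidationError("row with empty study_id")
        counts = {k: _parse_count(row[k], k, rid) for k in ("tp", "fn", "fp", "tn")}
        ss_raw = (row.get("sample_size") or "").strip()
        sample_size = int(ss_raw) if ss_raw else None
        year_raw = (row.get("year") or "").strip()
        studies.append(
            Study2x2(
                study_id=rid,
                article_id=(row.get("article_id") or "").strip(),
                year=int(year_raw) if year_raw else None,
                country=(row.get("country") or "unknown").strip() or "unknown",
                ethnicity_group=(row.get("ethnicity_group") or "unknown").strip()
                or "unknown",
                cancer_label=(row.get("cancer_label") or "unknown").strip()
                or "unknown",
                cancer_group=(row.get("cancer_group") or "unknown").strip()
                or "unknown",
                pancreatic=_parse_bool(row.get("pancreatic") or "", rid),
                sample_source=(row.get("sample_source") or "unknown").strip()
                or "unknown",
                sample_group=(row.get("sample_group") or "unknown").strip()
                or "unknown",
                sample_size=sample_size,
                **counts,
            )
        )
    return StudySet(studies, provenance=provenance)


def read_studies(path, dialect: str | None = None) -> StudySet:
    """Read a validated :class:`StudySet` from a delimited text file.

    Parameters
    ----------
    path
        CSV/TSV file with at least the columns
        ``study_id, tp, fn, fp, tn``; remaining columns are optional and
        default to "unknown"/absent.
    dialect
        Delimiter: ``","`` or ``"\\t"``.  By default the delimiter is
        sniffed from the header (comma vs tab, comma canonical).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    if dialect is None:
        header = text.splitlines()[0]
        dialect = "\t" if header.count("\t") > header.count(",") else ","
    reader = csv.DictReader(text.splitlines(), delimiter=dialect)
    missing = [c for c in _MANDATORY if c not in (reader.fieldnames or [])]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    return _rows_to_studyset(list(reader), provenance=str(path))


_FIXTURES = {
    "liu2021_mir21": "liu2021_mir21.csv",
}


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str) -> StudySet:
    """Load a packaged study table by name.

    ``"liu2021_mir21"`` is the 30-trial exosomal miR-21 cancer-diagnosis
    dataset (26 articles, 2008-2020); trials that share an article carry
    the same ``article_id`` but are pooled as independent units.
    """
    if name not in _FIXTURES:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {list_fixtures()}"
        )
    ref = resources.files("dtameta.fixtures") / _FIXTURES[name]
    text = ref.read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    return _rows_to_studyset(list(reader), provenance=f"fixture:{name}")


def _jsonable(obj):
    """Convert result objects (dataclasses, arrays, scalars) to JSON-safe."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_results(results, path, format: str = "json") -> None:
    """Serialise a result object losslessly to JSON, or flat to CSV.

    JSON uses ``repr``-grade float precision so that re-reading the file
    reproduces every value bit-identically.  CSV expects tabular content
    (a DataFrame, a list of records, or a sequence of (x, y) points).
    """
    path = Path(path)
    if format == "json":
        payload = _jsonable(results)
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif format == "csv":
        if isinstance(results, pd.DataFrame):
            results.to_csv(path, index=False)
        else:
            payload = _jsonable(results)
            if isinstance(payload, dict):
                pd.DataFrame([payload]).to_csv(path, index=False)
            else:
                pd.DataFrame(payload).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; use 'json' or 'csv'")
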