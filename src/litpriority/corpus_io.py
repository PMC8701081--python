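"""Read, validate and filter publication metadata.

Input is a table of publication records — one row per paper with at least an
abstract and a publication date — in the CORD-19 metadata CSV layout
(columns ``title``, ``abstract``, ``publish_time``) or a minimal JSONL
dialect with keys ``{doc_id, abstract, pub_date, language_tag}``.  Records
with unparseable dates, empty abstracts, non-English abstracts or dates
outside the study period are dropped (never clipped) and counted in a
:class:`LoadReport`.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DocumentRecord",
    "StudyPeriod",
    "LoadReport",
    "read_metadata",
    "filter_records",
    "write_jsonl",
]

_ISO_DATE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")

# Small English function-word set for the language heuristic below.
_EN_MARKERS = frozenset(
    "the of and in to a is for with that on by are was were as from this "
    "be at or an have has".split()
)


@dataclass(frozen=True)
class DocumentRecord:
    """One publication: identifier, abstract text and day-level date."""

    doc_id: str
    abstract: str
    pub_date: date
    title: str | None = None
    language_tag: str | None = None


@dataclass(frozen=True)
class StudyPeriod:
    """Closed study interval plus the outbreak anchor date.

    ``outbreak_start`` is the epidemic starting point from which research
    time distances are measured; it must not postdate the study start.
    """

    start_date: date
    end_date: date
    outbreak_start: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")
        if self.outbreak_start > self.start_date:
            raise ValueError("outbreak_start must be <= start_date")

    def contains(self, d: date) -> bool:
        return self.start_date <= d <= self.end_date


@dataclass
class LoadReport:
    """Bookkeeping for dropped rows during loading and filtering."""

    n_rows: int = 0
    n_loaded: int = 0
    dropped_bad_date: int = 0
    dropped_missing_abstract: int = 0
    dropped_empty_abstract: int = 0
    dropped_non_english: int = 0
    dropped_out_of_period: int = 0
    empty_result: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def parse_iso_date(value: object) -> date | None:
    """Parse a strict ``YYYY-MM-DD`` string to a date, else ``None``.

    Year-only values such as ``"2020"`` are rejected: day-level windows
    need day-level dates.
    """
    if not isinstance(value, str):
        return None
    m = _ISO_DATE.match(value.strip())
    if m is None:
        return None
    try:
        return date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    except ValueError:  # e.g. month 13, day 45
        return None


def _is_blank(value: object) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and not value.strip()
    )


def read_metadata(
    path: str | Path,
    dialect: str = "cord19_csv",
    report: LoadReport | None = None,
) -> tuple[list[DocumentRecord], LoadReport]:
    """Load publication records from ``path``.

    Parameters
    ----------
    path:
        CSV (``dialect="cord19_csv"``) or JSON-lines (``dialect="jsonl"``)
        file.
    dialect:
        ``cord19_csv`` requires columns ``abstract`` and ``publish_time``;
        an id is taken from ``cord_uid`` or ``sha`` when present, else the
        row index.  ``jsonl`` requires keys ``abstract`` and ``pub_date``.
    report:
        Optional existing report to accumulate into.

    Rows whose date does not parse as a full ISO-8601 day are dropped and
    counted in ``report.dropped_bad_date``; rows with a missing abstract
    field are dropped and counted too (empty-but-present abstracts survive
    loading and are removed later by :func:`filter_records`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = report or LoadReport()

    if dialect == "cord19_csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        for col in ("abstract", "publish_time"):
            if col not in frame.columns:
                raise ValueError(f"required column missing from {path.name}: {col!r}")
        rows: Iterable[dict] = (
            {
                "doc_id": row.get("cord_uid") or row.get("sha") or f"row{idx}",
                "abstract": row.get("abstract"),
                "pub_date": row.get("publish_time"),
                "title": row.get("title"),
                "language_tag": row.get("language_tag"),
            }
            for idx, row in enumerate(frame.to_dict("records"))
        )
    elif dialect == "jsonl":
        def _iter_jsonl() -> Iterable[dict]:
            with path.open() as fh:
                for idx, line in enumerate(fh):
                    if not line.strip():
                        continue
                    obj = json.loads(line)
                    for key in ("abstract", "pub_date"):
                        if key not in obj:
                            raise ValueError(
                                f"required key missing from {path.name}: {key!r}"
                            )
                    obj.setdefault("doc_id", f"row{idx}")
                    yield obj
        rows = _iter_jsonl()
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    records: list[DocumentRecord] = []
    for row in rows:
        report.n_rows += 1
        if _is_blank(row.get("abstract")):
            report.dropped_missing_abstract += 1
            continue
        parsed = parse_iso_date(row.get("pub_date"))
        if parsed is None:
            report.dropped_bad_date += 1
            continue
        records.append(
            DocumentRecord(
                doc_id=str(row["doc_id"]),
                abstract=str(row["abstract"]),
                pub_date=parsed,
                title=None if _is_blank(row.get("title")) else str(row.get("title")),
                language_tag=None
                if _is_blank(row.get("language_tag"))
                else str(row.get("language_tag")).lower(),
            )
        )
    report.n_loaded = len(records)
    return records, report


def looks_english(text: str) -> bool:
    """Lightweight English heuristic for untagged abstracts.

    A text is accepted when at least 85% of its alphabetic characters are
    ASCII and, for texts of ten or more tokens, at least one common English
    function word appears.  Synthetic corpora always carry an explicit
    language tag, so this path only handles real-world untagged data.
    """
    letters = [c for c in text if c.isalpha()]
    if not letters:
        return False
    ascii_frac = sum(c.isascii() for c in letters) / len(letters)
    if ascii_frac < 0.85:
        return False
    tokens = re.findall(r"[a-zA-Z]+", text.lower())
    if len(tokens) >= 10 and not any(t in _EN_MARKERS for t in tokens):
        return False
    return True


def filter_records(
    records: Sequence[DocumentRecord],
    period: StudyPeriod,
    report: LoadReport | None = None,
) -> list[DocumentRecord]:
    """Keep English records with non-empty abstracts dated inside the period.

    Order-preserving and idempotent.  A record with a ``language_tag`` is
    English iff the tag starts with ``"en"``; untagged records go through
    :func:`looks_english`.
    """
    report = report or LoadReport()
    kept: list[DocumentRecord] = []
    for rec in records:
        if not rec.abstract.strip():
            report.dropped_empty_abstract += 1
            continue
        if rec.language_tag is not None:
            is_en = rec.language_tag.startswith("en")
        else:
            is_en = looks_english(rec.abstract)
        if not is_en:
            report.dropped_non_english += 1
            continue
        if not period.contains(rec.pub_date):
            report.dropped_out_of_period += 1
            continue
        kept.append(rec)
    report.empty_result = not kept
    return kept


def write_jsonl(records: Sequence[DocumentRecord], path: str | Path) -> None:
    """Serialize records to the JSONL dialect readable by :func:`read_metadata`."""
    with Path(path).open("w") as fh:
        for rec in records:
            obj = {
                "doc_id": rec.doc_id,
                "abstract": rec.abstract,
                "pub_date": rec.pub_date.isoformat(),
            }
            if rec.title is not None:
                obj["title"] = rec.title
            if rec.language_tag is not None:
                obj["language_tag"] = rec.language_tag
            fh.write(json.dumps(obj) + "\n")
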