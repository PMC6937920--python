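"""JSONL and plain-text report I/O.

Reports travel as JSONL records with fields ``report_id``, ``description``
and ``impression``, or as a directory of ``.txt`` files in which the two
blocks are separated by a line reading ``IMPRESSION:`` (the report id is
the file stem).  Extractions and gold annotations are JSONL, one object
per report, with stable key order so identical runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Type, TypeVar

from pydantic import BaseModel

from .pipeline import ReportExtraction
from .preprocess import RawReport
from .synthetic import GoldAnnotation

IMPRESSION_DELIMITER = "IMPRESSION:"

M = TypeVar("M", bound=BaseModel)


def write_jsonl(path: str | Path, records: Iterable[BaseModel]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(record.model_dump(mode="json"), ensure_ascii=False))
            fh.write("\n")


def read_jsonl(path: str | Path, model: Type[M]) -> list[M]:
    records: list[M] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(model.model_validate(json.loads(line)))
    return records


def read_reports_jsonl(path: str | Path) -> list[RawReport]:
    return read_jsonl(path, RawReport)


def read_report_txt(path: str | Path) -> RawReport:
    """Parse one plain-text report file (description, delimiter, impression)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    description, _, impression = text.partition(IMPRESSION_DELIMITER)
    return RawReport(
        report_id=path.stem,
        description=description.strip(),
        impression=impression.strip(),
    )


def read_reports_dir(path: str | Path) -> list[RawReport]:
    return [read_report_txt(p) for p in sorted(Path(path).glob("*.txt"))]


def read_reports(path: str | Path) -> list[RawReport]:
    """Dispatch on path type: JSONL file or directory of .txt files."""
    path = Path(path)
    if path.is_dir():
        return read_reports_dir(path)
    return read_reports_jsonl(path)


def read_gold_jsonl(path: str | Path) -> list[GoldAnnotation]:
    return read_jsonl(path, GoldAnnotation)


def read_extractions_jsonl(path: str | Path) -> list[ReportExtraction]:
    return read_jsonl(path, ReportExtraction)


def write_extractions(path: str | Path, extractions: Sequence[ReportExtraction]) -> None:
    write_jsonl(path, extractions)


def write_gold(path: str | Path, golds: Sequence[GoldAnnotation]) -> None:
    write_jsonl(path, golds)
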