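"""CSV reading/writing for lipid-panel cohorts.

Schema (header required, comma-separated, UTF-8)::

    subject_id,sex,age_years,tc_mgdl,hdl_mgdl,tg_mgdl,ldl_direct_mgdl

``sex`` is ``girl`` or ``boy``; a missing direct LDL measurement is an
empty field.  ``read_cohort(write_cohort(panels))`` is field-identical
(floats are written in shortest round-trip form).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .lipids import LipidPanel, Sex

__all__ = ["COLUMNS", "read_cohort", "write_cohort"]

COLUMNS = [
    "subject_id",
    "sex",
    "age_years",
    "tc_mgdl",
    "hdl_mgdl",
    "tg_mgdl",
    "ldl_direct_mgdl",
]


class CohortFormatError(ValueError):
    """Malformed cohort CSV (bad header or row); message carries the line number."""


def write_cohort(panels: Iterable[LipidPanel], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for p in panels:
            writer.writerow(
                [
                    p.subject_id,
                    p.sex.value,
                    repr(float(p.age_years)),
                    repr(float(p.tc)),
                    repr(float(p.hdl)),
                    repr(float(p.tg)),
                    "" if p.ldl_direct is None else repr(float(p.ldl_direct)),
                ]
            )


def read_cohort(path) -> list[LipidPanel]:
    path = Path(path)
    panels: list[LipidPanel] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file") from None
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise CohortFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                panels.append(_parse_row(row, idx))
            except (ValueError, IndexError) as exc:
                raise CohortFormatError(f"{path}: line {lineno}: {exc}") from exc
    return panels


def _parse_row(row: Sequence[str], idx: dict[str, int]) -> LipidPanel:
    ldl_raw = row[idx["ldl_direct_mgdl"]].strip()
    return LipidPanel(
        subject_id=row[idx["subject_id"]],
        sex=Sex(row[idx["sex"]].strip()),
        age_years=float(row[idx["age_years"]]),
        tc=float(row[idx["tc_mgdl"]]),
        hdl=float(row[idx["hdl_mgdl"]]),
        tg=float(row[idx["tg_mgdl"]]),
        ldl_direct=float(ldl_raw) if ldl_raw else None,
    )
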