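"""Exam-level reliability/SEM tables: ingestion, summaries, consistency audit.

Published examination statistics usually arrive as one row per sitting
("diet"): number of scored items, Cronbach's alpha, the SD of candidate
marks and the SEM, all on the percentage-point mark scale.  This module
reads such tables from CSV, reproduces summary rows (unweighted mean and
sample SD per column over a chosen span of diets), and audits each row's
internal consistency — does the printed SEM equal ``sd·sqrt(1 − alpha)``
within a tolerance that allows for two-decimal rounding of alpha?

Two fixture tables ship with the package: the MRCP(UK) Part 1 and Part 2
written examinations 2002/3–2008/3, and the first eight Specialty
Certificate Examinations (SCEs, 2008–9).  The audit exposes a handful of
Part 1 rows whose printed SEM cannot be reproduced from the printed SD and
alpha — most likely SEMs computed from unrounded alphas — while every SCE
row reconciles within rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .ctt import CttError, RangeRestrictionQuery, restriction_of_range_correlation

__all__ = [
    "ExamDietRecord",
    "SeriesSummary",
    "TableError",
    "read_exam_table",
    "bundled_table_path",
    "load_bundled_table",
    "filter_records",
    "summarize",
    "sem_consistency_check",
    "audit_table",
    "restriction_adjusted_comparison",
]

#: Audit tolerance, percentage points.  Alpha is printed to 2 dp, so an
#: SEM recomputed from it can drift by up to ≈ sd·0.005/(2·sqrt(1−alpha))
#: — under 0.05 for every bundled row — while the genuinely inconsistent
#: rows miss by 0.07-0.33.
DEFAULT_AUDIT_TOLERANCE = 0.05

_NUMERIC_COLUMNS = ("n_scored_items", "alpha", "sd", "sem", "n_candidates")


class TableError(ValueError):
    """Malformed exam-statistics table."""


@dataclass(frozen=True)
class ExamDietRecord:
    """One sitting of one examination.

    ``diet`` is "YYYY/N" for the thrice-yearly MRCP(UK) written papers and
    a bare year for SCEs.  Fields the source table leaves blank are None,
    never zero.
    """

    exam: str
    diet: str
    n_scored_items: int | None
    alpha: float | None
    sd: float | None
    sem: float | None
    n_candidates: int | None = None

    def diet_key(self) -> tuple[int, int]:
        """(year, sitting) sort/filter key; bare years sort as sitting 0."""
        parts = self.diet.split("/")
        year = int(parts[0])
        sitting = int(parts[1]) if len(parts) > 1 else 0
        return (year, sitting)


@dataclass(frozen=True)
class SeriesSummary:
    """Unweighted per-column mean / sample SD / median over a record set."""

    n_records: int
    columns: dict  # column -> {"mean": .., "sd": .., "median": .., "n": ..}

    def mean(self, column: str) -> float:
        return self.columns[column]["mean"]

    def sd(self, column: str) -> float:
        return self.columns[column]["sd"]

    def median(self, column: str) -> float:
        return self.columns[column]["median"]


def read_exam_table(path) -> list[ExamDietRecord]:
    """Parse and validate an exam-statistics CSV.

    Header ``exam,diet,n_scored_items,alpha,sd,sem[,n_candidates]``;
    percentages are plain numbers (6.98 means 6.98 percentage points).
    Blank cells become missing values.  Raises :class:`TableError` on an
    empty file, malformed numbers, alpha outside [0, 1], negative sd/sem,
    or duplicate (exam, diet) keys.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableError(f"empty exam table: {path}") from exc
    required = {"exam", "diet", "n_scored_items", "alpha", "sd", "sem"}
    if not required.issubset(df.columns):
        raise TableError(
            f"missing columns {sorted(required - set(df.columns))} in {path}"
        )
    if len(df) == 0:
        raise TableError(f"no data rows in {path}")
    records: list[ExamDietRecord] = []
    seen: set[tuple[str, str]] = set()
    for row_number, row in df.iterrows():
        exam = str(row["exam"]).strip()
        diet = str(row["diet"]).strip()
        key = (exam, diet)
        if key in seen:
            raise TableError(f"duplicate (exam, diet) key {key} in {path}")
        seen.add(key)
        values: dict[str, float | None] = {}
        for col in _NUMERIC_COLUMNS:
            raw = row.get(col)
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() in ("", "-"):
                values[col] = None
                continue
            try:
                values[col] = float(raw)
            except ValueError as exc:
                raise TableError(
                    f"malformed numeric {col}={raw!r} at row {row_number} in {path}"
                ) from exc
        alpha = values["alpha"]
        if alpha is not None and not 0.0 <= alpha <= 1.0:
            raise TableError(f"alpha {alpha} outside [0, 1] at row {row_number}")
        for col in ("sd", "sem"):
            if values[col] is not None and values[col] < 0:
                raise TableError(f"negative {col} at row {row_number}")
        records.append(
            ExamDietRecord(
                exam=exam,
                diet=diet,
                n_scored_items=(
                    int(values["n_scored_items"])
                    if values["n_scored_items"] is not None
                    else None
                ),
                alpha=alpha,
                sd=values["sd"],
                sem=values["sem"],
                n_candidates=(
                    int(values["n_candidates"])
                    if values["n_candidates"] is not None
                    else None
                ),
            )
        )
    return records


def bundled_table_path(name: str):
    """Path to a bundled fixture: ``table1_mrcp`` or ``table2_sce``."""
    resource = resources.files("examsem.data").joinpath(f"{name}.csv")
    if not resource.is_file():
        raise TableError(f"no bundled table named {name!r}")
    return resource


def load_bundled_table(name: str) -> list[ExamDietRecord]:
    with resources.as_file(bundled_table_path(name)) as path:
        return read_exam_table(path)


def filter_records(
    records: Iterable[ExamDietRecord],
    exam: str | None = None,
    diet_from: str | None = None,
    diet_to: str | None = None,
) -> list[ExamDietRecord]:
    """Select by exam label and an inclusive (year, sitting) diet range."""

    def key(diet: str) -> tuple[int, int]:
        parts = diet.split("/")
        return (int(parts[0]), int(parts[1]) if len(parts) > 1 else 0)

    out = []
    for rec in records:
        if exam is not None and rec.exam != exam:
            continue
        if diet_from is not None and rec.diet_key() < key(diet_from):
            continue
        if diet_to is not None and rec.diet_key() > key(diet_to):
            continue
        out.append(rec)
    return sorted(out, key=lambda r: (r.exam, r.diet_key()))


def summarize(
    records: Sequence[ExamDietRecord],
    predicate: Callable[[ExamDietRecord], bool] | None = None,
) -> SeriesSummary:
    """Unweighted mean, sample SD and median per numeric column.

    Missing cells are ignored column-wise; diets are weighted equally
    regardless of candidate numbers (the convention the published summary
    rows use).  Requires at least 2 records after filtering so the sample
    SD is defined.
    """
    selected = [r for r in records if predicate is None or predicate(r)]
    if len(selected) < 2:
        raise TableError(f"need >= 2 records to summarize, got {len(selected)}")
    columns = {}
    for col in _NUMERIC_COLUMNS:
        values = np.array(
            [getattr(r, col) for r in selected if getattr(r, col) is not None],
            dtype=float,
        )
        if values.size == 0:
            continue
        columns[col] = {
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
            "median": float(np.median(values)),
            "n": int(values.size),
        }
    return SeriesSummary(n_records=len(selected), columns=columns)


def sem_consistency_check(
    record: ExamDietRecord, tolerance: float = DEFAULT_AUDIT_TOLERANCE
) -> tuple[float, float, bool]:
    """Recompute SEM from the row's own SD and alpha; flag disagreement.

    Returns ``(recomputed_sem, delta, flag)`` with
    ``delta = recomputed − printed`` and the flag raised when
    ``|delta| > tolerance`` percentage points.
    """
    if record.alpha is None or record.sd is None or record.sem is None:
        raise TableError(
            f"({record.exam}, {record.diet}): alpha, sd and sem must all be present"
        )
    recomputed = record.sd * float(np.sqrt(1.0 - record.alpha))
    delta = recomputed - record.sem
    return recomputed, delta, abs(delta) > tolerance


def audit_table(
    records: Sequence[ExamDietRecord],
    tolerance: float = DEFAULT_AUDIT_TOLERANCE,
) -> pd.DataFrame:
    """Run the SEM consistency check over a whole table.

    One row per record: exam, diet, printed values, recomputed SEM, delta
    and flag.  Records with any missing field are skipped (they cannot be
    audited, and the bundled tables have none missing among audited
    columns).
    """
    rows = []
    for rec in records:
        if rec.alpha is None or rec.sd is None or rec.sem is None:
            continue
        recomputed, delta, flag = sem_consistency_check(rec, tolerance)
        rows.append(
            {
                "exam": rec.exam,
                "diet": rec.diet,
                "alpha": rec.alpha,
                "sd": rec.sd,
                "sem": rec.sem,
                "recomputed_sem": recomputed,
                "delta": delta,
                "flag": flag,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["tolerance"] = tolerance
    return frame


def restriction_adjusted_comparison(
    records_a: Sequence[ExamDietRecord],
    records_b: Sequence[ExamDietRecord],
) -> dict:
    """What would series A's reliability be at series B's ability spread?

    Treats series A's mean alpha as an unrestricted correlation with the
    candidates' ability spread equal to A's mean SD, then applies the
    Ghiselli restriction correction down to series B's mean SD.  A lower
    adjusted value quantifies how much of the reliability gap between two
    sequential examinations is explained by range restriction alone.
    """
    summary_a = summarize(records_a)
    summary_b = summarize(records_b)
    sd_a, sd_b = summary_a.mean("sd"), summary_b.mean("sd")
    if sd_b <= 0:
        raise CttError("degenerate target series: zero mean SD")
    alpha_a = summary_a.mean("alpha")
    adjusted = restriction_of_range_correlation(
        RangeRestrictionQuery(
            unrestricted_r=alpha_a,
            unrestricted_sd=sd_a,
            restricted_sd=min(sd_b, sd_a),
        )
    )
    return {
        "series_a": {
            "alpha": alpha_a,
            "sd": sd_a,
            "sem": summary_a.mean("sem"),
        },
        "series_b": {
            "alpha": summary_b.mean("alpha"),
            "sd": sd_b,
            "sem": summary_b.mean("sem"),
        },
        "alpha_a_adjusted_to_sd_b": adjusted,
    }
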