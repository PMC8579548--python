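"""Reading, validation and classification of long-format adverse-event records.

Adverse events (AEs) in oncology trials are coded with the CTCAE lexicon:
each record carries a severity *grade* (1 = mild … 5 = death) and, optionally,
an organ-system *domain* (26 in CTCAE v4) and a specific AE *term* (~790).
Analyses run at one of five refinement levels, from grades alone to the full
term-by-grade cross, and each level maps every record to a *class label* —
the row unit of the downstream contingency tables.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_GRADES = frozenset({1, 2, 3, 4, 5})

#: canonical internal column names, in serialization order
CANONICAL_COLUMNS = ("patient_id", "arm", "grade", "domain", "term", "cycle")


class ClassLevel(enum.Enum):
    """The five refinement levels at which AE records are classified.

    GRADE uses severity alone; DOMAIN and TERM use the organ class or the
    specific event; DOMAIN_GRADE and TERM_GRADE cross them with severity,
    which at full CTCAE v4 cardinality would give 26 x 5 = 130 and
    790 x 5 = 3950 possible classes.
    """

    GRADE = "grade"
    DOMAIN = "domain"
    DOMAIN_GRADE = "domain_grade"
    TERM = "term"
    TERM_GRADE = "term_grade"

    @property
    def needs_domain(self) -> bool:
        return self in (ClassLevel.DOMAIN, ClassLevel.DOMAIN_GRADE)

    @property
    def needs_term(self) -> bool:
        return self in (ClassLevel.TERM, ClassLevel.TERM_GRADE)

    @property
    def uses_grade(self) -> bool:
        return self in (ClassLevel.GRADE, ClassLevel.DOMAIN_GRADE, ClassLevel.TERM_GRADE)


@dataclass(frozen=True)
class AERecord:
    """One adverse-event report for one patient."""

    patient_id: str
    arm: str
    grade: int
    domain: str | None = None
    term: str | None = None
    cycle: int | None = None

    def __post_init__(self) -> None:
        if self.grade not in VALID_GRADES:
            raise ValueError(f"grade must be in 1..5, got {self.grade!r}")
        if self.cycle is not None and self.cycle < 1:
            raise ValueError(f"cycle must be a positive integer, got {self.cycle!r}")


@dataclass
class AEDataset:
    """Validated long-format AE records plus the ordered treatment arms.

    ``records`` is a DataFrame with the canonical columns ``patient_id``,
    ``arm``, ``grade`` and, when available, ``domain``, ``term``, ``cycle``.
    ``arms`` preserves first-appearance order and may list arms with no
    records after filtering.

    ``n_per_arm`` optionally carries the enrolment (safety-population) size
    of each arm. An AE listing only names patients who reported at least one
    event, so without this metadata incidence denominators fall back to the
    distinct patients observed per arm — an overestimate of incidence when
    event-free patients exist.
    """

    records: pd.DataFrame
    arms: list[str] = field(default_factory=list)
    n_per_arm: dict[str, int] | None = None

    def __post_init__(self) -> None:
        df = self.records
        for col in ("patient_id", "arm", "grade"):
            if col not in df.columns:
                raise ValueError(f"records frame lacks mandatory column {col!r}")
        if not self.arms:
            self.arms = list(dict.fromkeys(df["arm"]))
        unknown = set(df["arm"]) - set(self.arms)
        if unknown:
            raise ValueError(f"records reference arms not in arms list: {sorted(unknown)}")
        bad = set(df["grade"]) - VALID_GRADES
        if bad:
            raise ValueError(f"grades outside 1..5: {sorted(bad)}")
        per_patient = df.groupby("patient_id", sort=False)["arm"].nunique()
        split = per_patient[per_patient > 1]
        if not split.empty:
            raise ValueError(
                "patients assigned to more than one arm: "
                + ", ".join(map(str, split.index[:5]))
            )
        if self.n_per_arm is not None:
            observed = df.groupby("arm", sort=False)["patient_id"].nunique()
            for arm in self.arms:
                if int(observed.get(arm, 0)) > self.n_per_arm.get(arm, 0):
                    raise ValueError(
                        f"arm {arm!r} has more observed patients than its "
                        f"stated enrolment {self.n_per_arm.get(arm)}"
                    )

    @property
    def has_domain(self) -> bool:
        return "domain" in self.records.columns

    @property
    def has_term(self) -> bool:
        return "term" in self.records.columns

    @property
    def has_cycle(self) -> bool:
        return "cycle" in self.records.columns

    def __len__(self) -> int:
        return len(self.records)

    def patients_per_arm(self) -> dict[str, int]:
        """Incidence denominators: stated enrolment if known, else the
        distinct patients observed per arm."""
        if self.n_per_arm is not None:
            return {arm: int(self.n_per_arm[arm]) for arm in self.arms}
        counts = self.records.groupby("arm", sort=False)["patient_id"].nunique()
        return {arm: int(counts.get(arm, 0)) for arm in self.arms}

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in CANONICAL_COLUMNS if c in self.records.columns]
        self.records.to_csv(path, index=False, columns=cols)


def read_ae_long(
    path: str | Path,
    mapping: Mapping[str, str] | None = None,
) -> AEDataset:
    """Read a long-format AE CSV (one row per AE record) into an ``AEDataset``.

    Parameters
    ----------
    path:
        CSV file with a header row; UTF-8.
    mapping:
        Maps the canonical roles ``id``, ``group``, ``grade`` (mandatory) and
        ``domain``, ``term``, ``cycle`` (optional) to column names in the
        file. Defaults to identity names ``patient_id``, ``group``, ``grade``,
        ``domain``, ``term``, ``cycle`` where present.

    Rows with an empty patient id, group or grade are rejected and reported
    by (1-based, header-exclusive) row number. Grades must be integers 1..5.
    A patient appearing in two arms is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    if raw.empty:
        raise ValueError(f"no records in {path}")

    mapping = dict(mapping or {})
    defaults = {
        "id": "patient_id", "group": "group", "grade": "grade",
        "domain": "domain", "term": "term", "cycle": "cycle",
    }
    for role in ("id", "group", "grade"):
        col = mapping.get(role, defaults[role])
        if col not in raw.columns:
            raise ValueError(f"mapped column {col!r} for {role!r} not in file")
        mapping.setdefault(role, col)
    for role in ("domain", "term", "cycle"):
        col = mapping.get(role)
        if col is not None and col not in raw.columns:
            raise ValueError(f"mapped column {col!r} for {role!r} not in file")
        if col is None and defaults[role] in raw.columns:
            mapping[role] = defaults[role]

    out = pd.DataFrame({
        "patient_id": raw[mapping["id"]].str.strip(),
        "arm": raw[mapping["group"]].str.strip(),
        "grade": raw[mapping["grade"]].str.strip(),
    })
    for role, col in (("domain", mapping.get("domain")), ("term", mapping.get("term"))):
        if col is not None:
            out[role] = raw[col].str.strip()
    if mapping.get("cycle") is not None:
        out["cycle"] = raw[mapping["cycle"]].str.strip()

    # validate mandatory fields row by row; report original row numbers
    rownum = pd.RangeIndex(1, len(out) + 1)
    bad_rows: list[tuple[int, str]] = []
    empty = (out["patient_id"] == "") | (out["arm"] == "") | (out["grade"] == "")
    for i in rownum[empty.to_numpy()]:
        bad_rows.append((int(i), "empty mandatory field"))
    grade_num = pd.to_numeric(out["grade"], errors="coerce")
    non_int = grade_num.isna() | (grade_num != grade_num.round())
    bad_grade = (~empty) & (non_int | ~grade_num.isin(list(VALID_GRADES)))
    for i in rownum[bad_grade.to_numpy()]:
        bad_rows.append((int(i), f"invalid grade {out['grade'].iloc[i - 1]!r}"))
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in sorted(bad_rows)[:10])
        raise ValueError(f"{len(bad_rows)} invalid row(s) in {path}: {detail}")

    out["grade"] = grade_num.astype(int)
    if "cycle" in out.columns:
        cyc = pd.to_numeric(out["cycle"].replace("", pd.NA), errors="coerce")
        if ((cyc.notna()) & ((cyc < 1) | (cyc != cyc.round()))).any():
            raise ValueError("cycle values must be positive integers")
        out["cycle"] = cyc.astype("Int64")

    ds = AEDataset(out)
    logger.info("read %d AE records, %d arms from %s", len(ds), len(ds.arms), path)
    return ds


def filter_cycle(data: AEDataset, cycle: int) -> AEDataset:
    """Keep only records reported at the given treatment cycle.

    The arm list is unchanged, so patients-per-arm denominators computed on
    the filtered dataset reflect only patients with records at that cycle.
    """
    if not data.has_cycle:
        raise ValueError("dataset has no cycle column; cannot filter by cycle")
    kept = data.records[data.records["cycle"] == cycle]
    if kept.empty:
        logger.warning("cycle filter %r matched no records", cycle)
    return AEDataset(kept.reset_index(drop=True), arms=list(data.arms),
                     n_per_arm=data.n_per_arm)


def derive_class_label(
    record: AERecord | Mapping[str, object],
    level: ClassLevel,
) -> str:
    """Deterministic class label of one record at a refinement level.

    GRADE -> ``"G<g>"``; DOMAIN -> the domain; DOMAIN_GRADE -> ``"<domain>:G<g>"``
    (e.g. ``"Metabolism:G2"``); TERM and TERM_GRADE analogously.
    """
    get = record.get if isinstance(record, Mapping) else lambda k, d=None: getattr(record, k, d)
    grade = get("grade")
    domain = get("domain") or None
    term = get("term") or None
    if level.needs_domain and not domain:
        raise ValueError(f"level {level.name} requires a domain")
    if level.needs_term and not term:
        raise ValueError(f"level {level.name} requires a term")
    if level is ClassLevel.GRADE:
        return f"G{grade}"
    base = domain if level.needs_domain else term
    if level in (ClassLevel.DOMAIN, ClassLevel.TERM):
        return str(base)
    return f"{base}:G{grade}"


def class_labels(data: AEDataset, level: ClassLevel) -> tuple[pd.Series, int]:
    """Vectorised class labels for every usable record at ``level``.

    Returns the label Series (indexed like ``data.records``) and the number
    of records excluded because the level's domain/term field was missing;
    exclusions are logged. Records are never excluded at GRADE level.
    """
    df = data.records
    if level.needs_domain and not data.has_domain:
        raise ValueError("dataset has no domain column; cannot classify at domain level")
    if level.needs_term and not data.has_term:
        raise ValueError("dataset has no term column; cannot classify at term level")

    if level is ClassLevel.GRADE:
        return "G" + df["grade"].astype(str), 0

    key = "domain" if level.needs_domain else "term"
    usable = df[key].astype(str).str.strip() != ""
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("excluded %d record(s) with missing %s at level %s",
                    n_dropped, key, level.name)
    sub = df.loc[usable]
    if level in (ClassLevel.DOMAIN, ClassLevel.TERM):
        labels = sub[key].astype(str)
    else:
        labels = sub[key].astype(str) + ":G" + sub["grade"].astype(str)
    return labels, n_dropped
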