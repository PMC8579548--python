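"""Incidence tables and the doubled (stacked) contingency table.

The unit of analysis is patient-level incidence: pi_ij is the proportion of
patients in arm j who reported at least one AE of class i — repeat events of
the same class within a patient do not count again. *Doubling* augments each
class row pi_i with its complement 1 - pi_i, so every (class, complement)
pair has unit sum in every arm and all arms carry equal column mass. CA on
the doubled table then treats presence and absence symmetrically and gives
each treatment equal weight regardless of enrolment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import AEDataset, ClassLevel, class_labels

logger = logging.getLogger(__name__)

#: suffix marking the complement ("absence") row of a doubled pair
COMPLEMENT_SUFFIX = "−"  # minus sign


def _class_sort_key(label: str):
    # grade-within-domain/term numeric order: "Nausea:G10" after "Nausea:G2"
    m = re.fullmatch(r"(.*):G(\d+)", label)
    if m:
        return (0, m.group(1), int(m.group(2)))
    m = re.fullmatch(r"G(\d+)", label)
    if m:
        return (0, "", int(m.group(1)))
    return (0, label, -1)


@dataclass
class IncidenceTable:
    """I x J matrix of per-arm incidence proportions.

    ``pi[i, j]`` is the fraction of arm ``arms[j]``'s patients with >= 1 AE
    of class ``classes[i]``; ``n_per_arm`` holds patient denominators when
    known (None when the table was entered directly from printed percentages).
    """

    classes: list[str]
    arms: list[str]
    pi: np.ndarray
    n_per_arm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (len(self.classes), len(self.arms)):
            raise ValueError(
                f"pi shape {self.pi.shape} does not match "
                f"{len(self.classes)} classes x {len(self.arms)} arms"
            )
        if len(self.arms) < 2:
            raise ValueError("need at least two arms")
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("incidence proportions must lie in [0, 1]")
        if self.n_per_arm is not None:
            self.n_per_arm = np.asarray(self.n_per_arm, dtype=float)
        zero = ~self.pi.any(axis=1)
        if zero.any():
            dropped = [c for c, z in zip(self.classes, zero) if z]
            logger.warning("dropping %d all-zero class row(s): %s", len(dropped), dropped)
            self.classes = [c for c, z in zip(self.classes, zero) if not z]
            self.pi = self.pi[~zero]
        if not len(self.classes):
            raise ValueError("incidence table has no non-zero class rows")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        vals = self.pi * 100 if percent else self.pi
        return pd.DataFrame(vals, index=pd.Index(self.classes, name="class"),
                            columns=self.arms)

    def to_csv(self, path: str | Path, percent: bool = False) -> None:
        self.to_frame(percent=percent).to_csv(path)


@dataclass
class DoubledTable:
    """2I x J stacked table: each class row followed by its complement row.

    Invariants forced by construction: ``value(class) + value(complement)``
    is exactly 1 cellwise, and every column sums exactly to I.
    """

    row_labels: list[str]
    arms: list[str]
    values: np.ndarray
    source: IncidenceTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.arms)):
            raise ValueError("values shape does not match labels")
        if len(self.row_labels) % 2:
            raise ValueError("a doubled table has an even number of rows")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("doubled values must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.row_labels) // 2

    @property
    def class_labels(self) -> list[str]:
        return self.row_labels[0::2]

    def strip_complements(self) -> IncidenceTable:
        """Inverse of :func:`double`: recover the incidence table."""
        inc = self.source
        if inc is not None:
            return inc
        return IncidenceTable(list(self.class_labels), list(self.arms),
                              self.values[0::2].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.row_labels, name="row"),
                            columns=self.arms)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def incidence_table(data: AEDataset, level: ClassLevel) -> IncidenceTable:
    """Patient-level incidence of each AE class by arm.

    The denominator for arm j is the number of distinct patients with any
    record in that arm; the numerator counts patients once per class however
    many qualifying records they have. Classes are ordered lexicographically,
    grades numerically within domain/term for combined levels.
    """
    if not len(data):
        raise ValueError("dataset is empty")
    n_patients = data.patients_per_arm()
    empty_arms = [a for a, n in n_patients.items() if n == 0]
    if empty_arms:
        raise ValueError(f"arm(s) with zero patients: {empty_arms}")

    labels, _ = class_labels(data, level)
    sub = data.records.loc[labels.index]
    hits = pd.DataFrame({
        "class": labels, "arm": sub["arm"], "patient_id": sub["patient_id"],
    }).drop_duplicates()
    counts = hits.groupby(["class", "arm"], sort=False).size().unstack(fill_value=0)

    classes = sorted(counts.index, key=_class_sort_key)
    counts = counts.reindex(index=classes, columns=data.arms, fill_value=0)
    denom = np.array([n_patients[a] for a in data.arms], dtype=float)
    pi = counts.to_numpy(dtype=float) / denom
    return IncidenceTable(classes, list(data.arms), pi, n_per_arm=denom)


def from_percent_table(
    classes: Sequence[str],
    arms: Sequence[str],
    percents: Sequence[Sequence[float]] | np.ndarray,
) -> IncidenceTable:
    """Build an incidence table from printed percentages (0-100 scale)."""
    percents = np.asarray(percents, dtype=float)
    if np.any(percents < 0) or np.any(percents > 100):
        bad = percents[(percents < 0) | (percents > 100)]
        raise ValueError(f"percent entries outside [0, 100]: {bad[:5]}")
    return IncidenceTable(list(classes), list(arms), percents / 100.0, n_per_arm=None)


def double(inc: IncidenceTable) -> DoubledTable:
    """Stack each incidence row with its complement, interleaved.

    Row order is (class_1, class_1-, class_2, class_2-, ...), complement
    labels carrying a trailing minus sign. Column sums equal I exactly.
    """
    I, J = inc.pi.shape
    values = np.empty((2 * I, J), dtype=float)
    values[0::2] = inc.pi
    values[1::2] = 1.0 - inc.pi
    labels: list[str] = []
    for c in inc.classes:
        labels.append(c)
        labels.append(c + COMPLEMENT_SUFFIX)
    return DoubledTable(labels, list(inc.arms), values, source=inc)


def average_profile(inc: IncidenceTable) -> np.ndarray:
    """Unweighted across-arm mean incidence of each class.

    This is the 'hypothetical average toxicity profile' the CA origin
    represents (each arm weighted equally, matching the doubled table's
    equal column masses).
    """
    return inc.pi.mean(axis=1)
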