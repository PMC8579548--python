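"""Synthetic patient-level AE data and the two printed trial tables.

The generator draws, for every patient and AE class, an independent
Bernoulli indicator with the class's target per-arm incidence pi*_ij and
emits one long-format record per hit. That is exactly the sampling model
under which patient-level incidence is the sufficient summary, so the
downstream pipeline (incidence -> doubling -> CA) recovers pi* up to
binomial noise. No within-patient correlation, onset times, or dropout are
simulated.

Two fixed fixtures expose the published grade-level incidence tables of the
NSABP R04 (rectal-cancer chemoradiation, four arms) and B35 (DCIS endocrine
therapy, adherent/non-adherent by drug) trials, as printed percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contingency import IncidenceTable, from_percent_table
from .ingest import AEDataset

__all__ = [
    "GeneratorSpec", "generate", "table3_fixture", "table5_fixture",
]


@dataclass
class GeneratorSpec:
    """Target world for the AE generator.

    ``classes`` are (domain, term, grade) triples — domain/term may be None
    for grade-only worlds. ``pi`` is the I x J target incidence matrix
    aligned with ``classes`` x ``arms``. With ``cycles`` set, each cycle is
    an independent Bernoulli draw at the same pi.
    """

    arms: dict[str, int]                       # arm -> n patients
    classes: list[tuple[str | None, str | None, int]]
    pi: np.ndarray
    cycles: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (len(self.classes), len(self.arms)):
            raise ValueError("pi shape must be (n classes, n arms)")
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("pi entries must lie in [0, 1]")
        if any(n < 1 for n in self.arms.values()):
            raise ValueError("every arm needs at least one patient")
        for _, _, g in self.classes:
            if g not in (1, 2, 3, 4, 5):
                raise ValueError(f"grade must be 1..5, got {g!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        doc = yaml.safe_load(Path(path).read_text())
        classes = [
            (c.get("domain"), c.get("term"), int(c["grade"])) for c in doc["classes"]
        ]
        return cls(
            arms={str(k): int(v) for k, v in doc["arms"].items()},
            classes=classes,
            pi=np.asarray(doc["pi"], dtype=float),
            cycles=doc.get("cycles"),
            seed=int(doc.get("seed", 0)),
        )


def generate(spec: GeneratorSpec) -> AEDataset:
    """Draw a patient-level AE dataset from independent Bernoulli incidences.

    Every patient in arm j gets, for class i (and each cycle if requested),
    a record with probability pi[i, j]. Patient ids are globally unique
    across arms; output is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    arm_names = list(spec.arms)
    cycles = [None] if spec.cycles is None else list(range(1, spec.cycles + 1))
    has_domain = any(d is not None for d, _, _ in spec.classes)
    has_term = any(t is not None for _, t, _ in spec.classes)

    rows: dict[str, list] = {k: [] for k in ("patient_id", "arm", "grade")}
    if has_domain:
        rows["domain"] = []
    if has_term:
        rows["term"] = []
    if spec.cycles is not None:
        rows["cycle"] = []

    pid = 0
    for j, arm in enumerate(arm_names):
        n = spec.arms[arm]
        ids = [f"P{pid + k + 1:05d}" for k in range(n)]
        pid += n
        for cyc in cycles:
            # n x I Bernoulli draws for this arm (and cycle)
            hits = rng.random((n, len(spec.classes))) < spec.pi[:, j]
            whom, which = np.nonzero(hits)
            for p, i in zip(whom, which):
                domain, term, grade = spec.classes[i]
                rows["patient_id"].append(ids[p])
                rows["arm"].append(arm)
                rows["grade"].append(grade)
                if has_domain:
                    rows["domain"].append("" if domain is None else domain)
                if has_term:
                    rows["term"].append("" if term is None else term)
                if spec.cycles is not None:
                    rows["cycle"].append(cyc)

    df = pd.DataFrame(rows)
    df["grade"] = df["grade"].astype(int) if len(df) else pd.Series([], dtype=int)
    if "cycle" in df.columns and len(df):
        df["cycle"] = df["cycle"].astype("Int64")
    return AEDataset(df, arms=arm_names, n_per_arm=dict(spec.arms))


# Printed grade-level incidence tables (percent of patients per arm).

_R04_ARMS = ["5-FU", "5-FU+Oxa", "Cape", "Cape+Oxa"]
_R04_PERCENTS = [
    # 5-FU   5-FU+Oxa  Cape   Cape+Oxa
    [1.22,   2.75,     1.23,  3.96],   # G1
    [60.67,  74.01,    63.08, 70.73],  # G2
    [25.31,  38.53,    27.39, 39.94],  # G3
    [0.61,   3.06,     2.15,  4.27],   # G4
    [0.31,   0.31,     1.23,  1.52],   # G5
]

_B35_ARMS = [
    "Anastrozole (adherent)", "Tamoxifen (adherent)",
    "Anastrozole (non-adherent)", "Tamoxifen (non-adherent)",
]
_B35_PERCENTS = [
    # Ana-adh  Tam-adh  Ana-non  Tam-non
    [38.22,    40.69,   49.66,   52.23],   # G2
    [2.22,     3.91,    10.61,   11.94],   # G3
    [0.188,    0.279,   0.903,   3.279],   # G4
]


def table3_fixture() -> IncidenceTable:
    """Published R04 grade-by-treatment incidence table (percent, 5 x 4).

    Treatment columns only; the derived Average column is excluded.
    """
    return from_percent_table(
        [f"G{g}" for g in range(1, 6)], _R04_ARMS, _R04_PERCENTS
    )


def table5_fixture() -> IncidenceTable:
    """Published B35 cycle-1 grade-by-group incidence table (percent, 3 x 4).

    Grades 2-4 by adherent/non-adherent drug group. The derived Average
    column is excluded (its printed G3 entry is internally inconsistent).
    """
    return from_percent_table(
        ["G2", "G3", "G4"], _B35_ARMS, _B35_PERCENTS
    )
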