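import numpy as np
import pandas as pd
import pytest

from toxca import AEDataset, ClassLevel, GeneratorSpec, generate


@pytest.fixture
def toy_dataset() -> AEDataset:
    """100-patient, two-arm toy world: grades 1-5, domains C/D, terms E-H."""
    rng = np.random.default_rng(42)
    n = 100
    df = pd.DataFrame({
        "patient_id": [str(i) for i in range(1, n + 1)],
        "arm": ["A"] * 50 + ["B"] * 50,
        "grade": rng.integers(1, 6, n),
        "domain": rng.choice(["C", "D"], n),
        "term": rng.choice(["E", "F", "G", "H"], n),
    })
    return AEDataset(df)


@pytest.fixture
def small_dataset() -> AEDataset:
    """Hand-built dataset with known incidences for exact checks."""
    rows = [
        # patient, arm, grade, domain, term, cycle
        ("p1", "A", 3, "Gastro", "Nausea", 1),
        ("p1", "A", 3, "Gastro", "Nausea", 1),   # duplicate record, same class
        ("p1", "A", 2, "Gastro", "Diarrhea", 2),
        ("p2", "A", 2, "Neuro", "Headache", 1),
        ("p3", "B", 3, "Gastro", "Nausea", 1),
        ("p4", "B", 1, "", "", 1),               # missing domain/term
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "arm", "grade",
                                     "domain", "term", "cycle"])
    df["cycle"] = df["cycle"].astype("Int64")
    return AEDataset(df)


@pytest.fixture
def grade_spec() -> GeneratorSpec:
    """Two-arm grade-only generator spec with a planted grade-3 excess in B."""
    pi = np.array([
        [0.30, 0.30],
        [0.40, 0.40],
        [0.20, 0.45],   # planted delta = 0.25 on G3 in arm B
        [0.05, 0.05],
    ])
    return GeneratorSpec(
        arms={"A": 1000, "B": 1000},
        classes=[(None, None, g) for g in (1, 2, 3, 4)],
        pi=pi,
        seed=7,
    )


def random_doubled(rng: np.random.Generator, I: int = 4, J: int = 3) -> np.ndarray:
    """Random doubled table: I proportion rows interleaved with complements."""
    pi = rng.uniform(0.02, 0.98, size=(I, J))
    out = np.empty((2 * I, J))
    out[0::2] = pi
    out[1::2] = 1 - pi
    return out
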