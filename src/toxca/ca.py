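"""Correspondence analysis of the doubled table.

Standard CA via the SVD of standardized residuals. With P the table scaled
to unit grand total, r and c its row and column mass vectors, the residual
matrix is

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2},   S = U Sigma V^T.

Squared singular values are the principal inertias; their sum is the total
inertia — the chi-square statistic of the table divided by its grand total.
Row principal coordinates F = D_r^{-1/2} U Sigma place class profiles so
inter-point distances approximate chi-square distances; standard coordinates
Phi = D_r^{-1/2} U are the mass-standardized axes; the contribution of row i
to axis k is r_i Phi_ik^2 = U_ik^2, summing to 1 per axis. Columns (arms)
are treated symmetrically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contingency import DoubledTable

#: singular values below RANK_TOL * sigma_1 are treated as numerical zeros
RANK_TOL = 1e-12


@dataclass
class CAResult:
    """Masses, inertia decomposition and coordinate sets of a fitted CA.

    All coordinate matrices have K columns (retained dimensions, descending
    inertia). ``row_contrib[i, k]`` is row i's share of axis k's inertia.
    """

    row_labels: list[str]
    col_labels: list[str]
    row_masses: np.ndarray          # r, sums to 1
    col_masses: np.ndarray          # c, sums to 1
    singular_values: np.ndarray     # sigma_k, descending, > 0
    row_principal: np.ndarray       # F = D_r^{-1/2} U Sigma
    col_principal: np.ndarray       # G = D_c^{-1/2} V Sigma
    row_standard: np.ndarray        # Phi = D_r^{-1/2} U
    col_standard: np.ndarray        # Gamma = D_c^{-1/2} V
    U: np.ndarray                   # left singular vectors (contribution coords)
    V: np.ndarray
    total_inertia: float

    @property
    def K(self) -> int:
        """Number of retained (non-degenerate) dimensions."""
        return len(self.singular_values)

    @property
    def inertias(self) -> np.ndarray:
        """Principal inertias lambda_k = sigma_k^2."""
        return self.singular_values ** 2

    @property
    def explained_pct(self) -> np.ndarray:
        """Percentage of total inertia per dimension (sums to 100)."""
        lam = self.inertias
        if self.total_inertia == 0:
            return np.zeros(0)
        return 100.0 * lam / lam.sum()

    @property
    def row_contrib(self) -> np.ndarray:
        """ctr_ik = r_i Phi_ik^2 = U_ik^2; columns sum to 1."""
        return self.U ** 2

    def to_dict(self) -> dict:
        return {
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
            "row_masses": self.row_masses.tolist(),
            "col_masses": self.col_masses.tolist(),
            "singular_values": self.singular_values.tolist(),
            "inertias": self.inertias.tolist(),
            "total_inertia": self.total_inertia,
            "explained_pct": [round(p, 2) for p in self.explained_pct],
            "row_principal": self.row_principal.tolist(),
            "col_principal": self.col_principal.tolist(),
            "row_standard": self.row_standard.tolist(),
            "col_standard": self.col_standard.tolist(),
            "row_contrib": self.row_contrib.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def ca_fit(tab: DoubledTable | np.ndarray) -> CAResult:
    """Fit correspondence analysis to a doubled (or any non-negative) table.

    Dimensions with singular value below ``RANK_TOL * sigma_1`` are dropped.
    A degenerate table whose columns are all proportional yields a valid
    result with K = 0 and zero total inertia. The sign of each dimension is
    fixed so the largest-|U| row entry is positive, making outputs
    reproducible across SVD implementations (axis reflections relative to
    any published figure remain legitimate).
    """
    if isinstance(tab, DoubledTable):
        X = tab.values
        row_labels, col_labels = list(tab.row_labels), list(tab.arms)
    else:
        X = np.asarray(tab, dtype=float)
        row_labels = [f"r{i}" for i in range(X.shape[0])]
        col_labels = [f"c{j}" for j in range(X.shape[1])]
    if np.any(X < 0):
        raise ValueError("table entries must be non-negative")
    total = X.sum()
    if total <= 0:
        raise ValueError("table has zero grand total")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("table has an all-zero row or column")

    dr = 1.0 / np.sqrt(r)
    dc = 1.0 / np.sqrt(c)
    S = dr[:, None] * (P - np.outer(r, c)) * dc[None, :]
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    V = Vt.T

    if sv.size and sv[0] > 0:
        keep = sv > RANK_TOL * sv[0]
    else:
        keep = np.zeros(sv.shape, dtype=bool)
    U, sv, V = U[:, keep], sv[keep], V[:, keep]

    # sign convention: dominant row loading positive per dimension
    for k in range(sv.size):
        i = np.argmax(np.abs(U[:, k]))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]

    Phi = dr[:, None] * U
    Gamma = dc[:, None] * V
    F = Phi * sv
    G = Gamma * sv
    return CAResult(
        row_labels=row_labels,
        col_labels=col_labels,
        row_masses=r,
        col_masses=c,
        singular_values=sv,
        row_principal=F,
        col_principal=G,
        row_standard=Phi,
        col_standard=Gamma,
        U=U,
        V=V,
        total_inertia=float((sv ** 2).sum()),
    )


def explained_inertia(res: CAResult, ndim: int) -> float:
    """Cumulative percentage of inertia in the first ``ndim`` dimensions."""
    if ndim < 0:
        raise ValueError("ndim must be non-negative")
    return float(res.explained_pct[: min(ndim, res.K)].sum())


def plane_contribution(res: CAResult, dims: tuple[int, int] = (1, 2)) -> np.ndarray:
    """Per-row percent contribution to the inertia of a plane.

    ``dims`` are 1-based dimension indices; ``dims=(k, k)`` reduces to the
    single-axis contribution 100 * ctr_ik. Sums to 100 over all rows.
    """
    d1, d2 = dims
    for d in (d1, d2):
        if not 1 <= d <= res.K:
            raise ValueError(f"dimension {d} out of range 1..{res.K}")
    lam = res.inertias
    F = res.row_principal
    if d1 == d2:
        return 100.0 * res.row_contrib[:, d1 - 1]
    num = res.row_masses * (F[:, d1 - 1] ** 2 + F[:, d2 - 1] ** 2)
    return 100.0 * num / (lam[d1 - 1] + lam[d2 - 1])


def arm_origin_distances(res: CAResult) -> np.ndarray:
    """Chi-square distance of each arm's profile from the average profile.

    The Euclidean norm of an arm's principal coordinates over all retained
    dimensions; the origin is the centroid (the hypothetical average
    toxicity profile), and sum_j c_j d_j^2 equals the total inertia.
    """
    if res.K == 0:
        return np.zeros(len(res.col_labels))
    return np.linalg.norm(res.col_principal, axis=1)
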