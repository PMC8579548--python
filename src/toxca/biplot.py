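"""Asymmetric contribution biplots and display-class selection.

Arms are drawn in principal coordinates; AE classes in *contribution
coordinates* — standard coordinates scaled by the square root of the row
mass, i.e. the left singular vectors U directly — so a class's squared
distance from the origin along an axis equals its contribution to that
axis's inertia. Classes worth labelling are chosen objectively: keep a
class when its contribution to the displayed plane and its average relative
frequency both clear configurable thresholds. The AUTO contribution
threshold is the average contribution 100/I, the natural "more than its
share" cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .ca import CAResult, plane_contribution
from .contingency import COMPLEMENT_SUFFIX, IncidenceTable, average_profile

logger = logging.getLogger(__name__)

AUTO = "auto"


@dataclass
class BiplotConfig:
    """Display configuration for a contribution biplot.

    ``min_contribution_pct`` may be a number or ``"auto"`` (= 100/I, the
    average contribution over the I presence classes). ``min_relfreq_pct``
    thresholds the unweighted across-arm average incidence, on the 0-100
    scale. ``per_dimension`` filters on the maximum single-axis contribution
    of the two displayed axes instead of the plane contribution.
    """

    dims: tuple[int, int] = (1, 2)
    min_contribution_pct: float | Literal["auto"] = 0.0
    min_relfreq_pct: float = 0.0
    show_complements: bool = False
    per_dimension: bool = False
    title: str | None = None

    def __post_init__(self) -> None:
        d1, d2 = self.dims
        if d1 < 1 or d2 < 1 or d1 == d2:
            raise ValueError("dims must be distinct 1-based dimension indices")
        if self.min_contribution_pct != AUTO and self.min_contribution_pct < 0:
            raise ValueError("min_contribution_pct must be >= 0 or 'auto'")
        if self.min_relfreq_pct < 0:
            raise ValueError("min_relfreq_pct must be >= 0")


@dataclass
class BiplotSelection:
    """Classes retained for display, with the statistics that decided it."""

    kept: list[str]
    table: pd.DataFrame  # per class: contribution_pct, avg_relfreq_pct, kept
    contribution_threshold_pct: float
    relfreq_threshold_pct: float


@dataclass
class BiplotData:
    """Everything needed to draw one biplot."""

    dims: tuple[int, int]
    arm_labels: list[str]
    arm_points: np.ndarray           # J x 2, principal coordinates
    class_labels: list[str]          # kept classes only
    class_points: np.ndarray         # len(kept) x 2, contribution coordinates
    explained_pct: tuple[float, float]
    all_class_labels: list[str] = field(default_factory=list)
    all_class_points: np.ndarray | None = None
    title: str | None = None

    @property
    def axis_labels(self) -> tuple[str, str]:
        d1, d2 = self.dims
        e1, e2 = self.explained_pct
        return (f"Dim {d1} ({e1:.2f}%)", f"Dim {d2} ({e2:.2f}%)")


def auto_threshold(n_classes: int) -> float:
    """Average-contribution display threshold 100/I, rounded to 2 decimals.

    E.g. 21 classes -> 4.76, 20 -> 5.0, 61 -> 1.64.
    """
    if n_classes < 1:
        raise ValueError("need at least one class")
    return round(100.0 / n_classes, 2)


def _presence_mask(labels: list[str]) -> np.ndarray:
    return np.array([not lab.endswith(COMPLEMENT_SUFFIX) for lab in labels])


def select_classes(
    res: CAResult,
    inc: IncidenceTable,
    cfg: BiplotConfig | None = None,
) -> BiplotSelection:
    """Choose AE classes to display under contribution/frequency thresholds.

    A class is kept iff its percent contribution to the cfg.dims plane
    meets ``min_contribution_pct`` and its average relative frequency
    (unweighted across-arm mean incidence, in percent) meets
    ``min_relfreq_pct``. Complement rows are excluded unless
    ``show_complements``. An empty selection is a warning, not an error.
    """
    cfg = cfg or BiplotConfig()
    contrib = plane_contribution(res, cfg.dims)
    if cfg.per_dimension:
        d1, d2 = cfg.dims
        contrib = 100.0 * np.maximum(
            res.row_contrib[:, d1 - 1], res.row_contrib[:, d2 - 1]
        )

    presence = _presence_mask(res.row_labels)
    thr = cfg.min_contribution_pct
    if thr == AUTO:
        thr = auto_threshold(int(presence.sum()))

    avg_freq = pd.Series(100.0 * average_profile(inc), index=inc.classes)
    rows = []
    for i, lab in enumerate(res.row_labels):
        if not presence[i] and not cfg.show_complements:
            continue
        base = lab[:-1] if lab.endswith(COMPLEMENT_SUFFIX) else lab
        freq = float(avg_freq.get(base, np.nan))
        freq_ok = np.isnan(freq) or freq >= cfg.min_relfreq_pct
        rows.append((lab, contrib[i], freq, bool(contrib[i] >= thr and freq_ok)))
    table = pd.DataFrame(
        rows, columns=["class", "contribution_pct", "avg_relfreq_pct", "kept"]
    ).set_index("class")
    kept = list(table.index[table["kept"]])
    if not kept:
        logger.warning("selection thresholds (%.4g%%, %.4g%%) kept no classes",
                       thr, cfg.min_relfreq_pct)
    return BiplotSelection(kept, table, float(thr), cfg.min_relfreq_pct)


def assemble_biplot(
    res: CAResult,
    selection: BiplotSelection,
    cfg: BiplotConfig | None = None,
) -> BiplotData:
    """Project arms (principal) and kept classes (contribution) on cfg.dims."""
    cfg = cfg or BiplotConfig()
    d1, d2 = cfg.dims
    if d2 > res.K or d1 > res.K:
        raise ValueError(f"dims {cfg.dims} exceed retained dimensions K={res.K}")
    cols = [d1 - 1, d2 - 1]
    arm_points = res.col_principal[:, cols]
    idx = {lab: i for i, lab in enumerate(res.row_labels)}
    kept_idx = [idx[lab] for lab in selection.kept]
    class_points = res.U[kept_idx][:, cols] if kept_idx else np.empty((0, 2))
    pct = res.explained_pct
    return BiplotData(
        dims=(d1, d2),
        arm_labels=list(res.col_labels),
        arm_points=arm_points,
        class_labels=list(selection.kept),
        class_points=class_points,
        explained_pct=(float(pct[d1 - 1]), float(pct[d2 - 1])),
        all_class_labels=list(res.row_labels),
        all_class_points=res.U[:, cols],
        title=cfg.title,
    )


def render_biplot(
    bp: BiplotData,
    path: str | Path,
    format: str | None = None,
) -> Path:
    """Write the biplot as SVG or PNG with origin cross-hairs.

    Output bytes are deterministic for a fixed input and matplotlib
    version (SVG hash salt and date metadata are pinned).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "svg").lower()
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported format {fmt!r}")

    with plt.rc_context({"svg.hashsalt": "toxca"}):
        fig, ax = plt.subplots(figsize=(7, 6))
        ax.axhline(0, color="0.6", lw=0.8, zorder=1)
        ax.axvline(0, color="0.6", lw=0.8, zorder=1)
        if len(bp.class_labels):
            ax.scatter(bp.class_points[:, 0], bp.class_points[:, 1],
                       marker="o", s=28, color="#c44e52", zorder=2, label="AE class")
            for lab, (x, y) in zip(bp.class_labels, bp.class_points):
                ax.annotate(lab, (x, y), fontsize=8, color="#c44e52",
                            xytext=(3, 3), textcoords="offset points")
        ax.scatter(bp.arm_points[:, 0], bp.arm_points[:, 1],
                   marker="^", s=60, color="#4c72b0", zorder=3, label="Arm")
        for lab, (x, y) in zip(bp.arm_labels, bp.arm_points):
            ax.annotate(lab, (x, y), fontsize=9, fontweight="bold",
                        color="#4c72b0", xytext=(4, -8), textcoords="offset points")
        xl, yl = bp.axis_labels
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        if bp.title:
            ax.set_title(bp.title)
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        plt.close(fig)
    return path
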