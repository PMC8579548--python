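"""End-to-end runs: long-format AE data in, tables / CA results / biplots out.

`run_ca` mirrors the semantics of an interactive AE-CA session — choose the
column mapping, the class level(s), an optional cycle filter and display
thresholds — but as a plain function writing static artifacts, one set per
requested level:

    <out>/<level>_incidence.csv      patient-level incidence table (percent)
    <out>/<level>_doubled.csv        doubled 2I x J table (proportions)
    <out>/<level>_ca.json            full CA result
    <out>/<level>_classes.csv        per-class contribution/frequency and kept flag
    <out>/<level>_biplot.<fmt>       contribution biplot
    <out>/inertia_summary.csv        per-level class counts and inertia decomposition

Validation failures raise before anything is written; artifacts of a level
that fails mid-run are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import biplot as bp
from .ca import CAResult, ca_fit, explained_inertia
from .contingency import IncidenceTable, double, incidence_table
from .ingest import AEDataset, ClassLevel, filter_cycle, read_ae_long
from .synthetic import GeneratorSpec, generate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one `run_ca` invocation."""

    levels: Sequence[ClassLevel] = (ClassLevel.GRADE,)
    mapping: Mapping[str, str] | None = None
    cycle: int | None = None
    dims: tuple[int, int] = (1, 2)
    min_contribution_pct: float | Literal["auto"] = 0.0
    min_relfreq_pct: float = 0.0
    out_dir: str | Path = "toxca_out"
    image_format: str = "svg"
    render: bool = True


@dataclass
class LevelResult:
    """Artifacts and fitted objects for one class level."""

    level: ClassLevel
    incidence: IncidenceTable
    ca: CAResult
    selection: bp.BiplotSelection
    n_excluded_records: int
    files: list[Path] = field(default_factory=list)


def _level_key(level: ClassLevel) -> str:
    return level.value


def run_level(
    data: AEDataset,
    level: ClassLevel,
    cfg: RunConfig,
    out_dir: Path | None = None,
) -> LevelResult:
    """Run incidence -> doubling -> CA -> selection (-> files) at one level."""
    from .ingest import class_labels

    _, n_excluded = class_labels(data, level)  # validates required columns
    inc = incidence_table(data, level)
    tab = double(inc)
    res = ca_fit(tab)
    sel_cfg = bp.BiplotConfig(
        dims=cfg.dims,
        min_contribution_pct=cfg.min_contribution_pct,
        min_relfreq_pct=cfg.min_relfreq_pct,
        title=f"{level.name} level",
    )
    dims_ok = res.K >= max(cfg.dims)
    selection = (bp.select_classes(res, inc, sel_cfg) if dims_ok
                 else bp.BiplotSelection([], pd.DataFrame(), 0.0, 0.0))

    result = LevelResult(level, inc, res, selection, n_excluded)
    if out_dir is None:
        return result

    key = _level_key(level)
    written: list[Path] = []
    try:
        f = out_dir / f"{key}_incidence.csv"
        inc.to_csv(f, percent=True); written.append(f)
        f = out_dir / f"{key}_doubled.csv"
        tab.to_csv(f); written.append(f)
        f = out_dir / f"{key}_ca.json"
        res.to_json(f); written.append(f)
        if dims_ok:
            f = out_dir / f"{key}_classes.csv"
            selection.table.to_csv(f); written.append(f)
            data_bp = bp.assemble_biplot(res, selection, sel_cfg)
            if cfg.render:
                f = out_dir / f"{key}_biplot.{cfg.image_format}"
                bp.render_biplot(data_bp, f, cfg.image_format); written.append(f)
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
    result.files = written
    logger.info(
        "level %s: I=%d J=%d K=%d total inertia=%.6f, %d record(s) excluded",
        level.name, inc.n_classes, len(inc.arms), res.K, res.total_inertia,
        n_excluded,
    )
    return result


def run_ca(
    data: AEDataset | str | Path,
    config: RunConfig | None = None,
    **kwargs,
) -> dict[ClassLevel, LevelResult]:
    """Full analysis at each requested class level, writing artifacts.

    ``data`` may be an ``AEDataset`` or a path to a long-format CSV (read
    with ``config.mapping``). Returns the per-level results keyed by level;
    also writes ``inertia_summary.csv`` collecting class counts and the
    percent of inertia per dimension across levels.
    """
    cfg = config or RunConfig(**kwargs)
    if not isinstance(data, AEDataset):
        data = read_ae_long(data, cfg.mapping)
    if cfg.cycle is not None:
        data = filter_cycle(data, cfg.cycle)

    # validate level requirements up front so nothing is written on failure
    for level in cfg.levels:
        if level.needs_domain and not data.has_domain:
            raise ValueError(f"level {level.name} needs a domain column")
        if level.needs_term and not data.has_term:
            raise ValueError(f"level {level.name} needs a term column")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    results: dict[ClassLevel, LevelResult] = {}
    for level in cfg.levels:
        results[level] = run_level(data, level, cfg, out_dir)

    summary = inertia_summary(results)
    summary.to_csv(out_dir / "inertia_summary.csv")
    return results


def inertia_summary(results: Mapping[ClassLevel, LevelResult]) -> pd.DataFrame:
    """Per-level class counts and inertia decomposition (percent, 2 d.p.)."""
    rows = []
    for level, r in results.items():
        pct = r.ca.explained_pct
        row = {"level": level.name, "n_classes": r.incidence.n_classes}
        for k in range(r.ca.K):
            row[f"dim{k + 1}_pct"] = round(float(pct[k]), 2)
        row["two_dim_pct"] = round(explained_inertia(r.ca, 2), 2)
        row["total_inertia"] = r.ca.total_inertia
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")


def run_synth(spec: GeneratorSpec | str | Path, out_csv: str | Path) -> Path:
    """Generate a synthetic AE dataset and write it as long-format CSV."""
    if not isinstance(spec, GeneratorSpec):
        spec = GeneratorSpec.from_yaml(spec)
    ds = generate(spec)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    ds.to_csv(out_csv)
    logger.info("wrote %d records (seed %d) to %s", len(ds), spec.seed, out_csv)
    return out_csv
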