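"""Readers and writers for annotation, gold-particle and summary tables.

The canonical interchange format is a delimited text table (CSV, or TSV for
``.tsv`` paths) with a documented column map; an optional spreadsheet reader
accepts one-sheet-per-protein workbooks of the same layout.  Raw coordinate
tables are in pixels unless the dialect declares nm; montage outputs are
always nm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .model import (
    GoldParticleRaw,
    LocalizationEstimate,
    NpcAnnotation,
    SchemaError,
)

__all__ = [
    "TableDialect",
    "SUMMARY_COLUMNS",
    "read_particle_table",
    "read_particle_workbook",
    "read_annotations",
    "write_annotations",
    "write_particle_table",
    "write_summary_table",
    "read_summary_table",
]

log = logging.getLogger(__name__)

#: Column set of the per-protein summary table, in order.
SUMMARY_COLUMNS = ["Nup", "Z ave", "Z err", "R ave", "R err", "N(R)", "N(Z)", "NPCs"]

ANNOTATION_COLUMNS = [
    "npc_id", "micrograph_id", "center_x_px", "center_y_px",
    "ne_axis_angle_rad", "nucleoplasm_side", "scale_nm_per_px", "nup_label",
]


@dataclass(frozen=True)
class TableDialect:
    """Column map and unit declaration for particle tables.

    ``units`` is ``"px"`` for raw image coordinates or ``"nm"`` for
    coordinates already in the common montage frame (x along the NE plane,
    y along the pore axis).  ``nup_col`` of ``None`` means the table holds a
    single protein whose label is ``default_label`` (or the file stem).
    """

    particle_id_col: str = "particle_id"
    npc_id_col: str = "npc_id"
    x_col: str = "x"
    y_col: str = "y"
    units: str = "px"
    nup_col: str | None = None
    default_label: str | None = None

    def __post_init__(self):
        if self.units not in ("px", "nm"):
            raise ValueError(f"units must be 'px' or 'nm', got {self.units!r}")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.index[out.isna() & df[col].notna()]
    if len(bad):
        raise SchemaError(
            f"{path}: non-numeric value in column {col!r} at row {int(bad[0])}"
        )
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise SchemaError(f"{path}: missing value in column {col!r} at row {row}")
    return out.astype(float)


def _particles_from_frame(df: pd.DataFrame, dialect: TableDialect, path) -> list[GoldParticleRaw]:
    xs = _numeric(df, dialect.x_col, path)
    ys = _numeric(df, dialect.y_col, path)
    return [
        GoldParticleRaw(
            particle_id=str(pid), npc_id=str(nid), x_px=float(x), y_px=float(y)
        )
        for pid, nid, x, y in zip(
            df[dialect.particle_id_col], df[dialect.npc_id_col], xs, ys
        )
    ]


def read_particle_table(
    path: Union[str, Path], dialect: TableDialect = TableDialect()
) -> dict[str, list[GoldParticleRaw]]:
    """Read a gold-particle coordinate table, grouped by protein label.

    Returns a mapping ``nup_label -> particles`` preserving row order.  An
    empty table yields an empty mapping with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = [dialect.particle_id_col, dialect.npc_id_col, dialect.x_col, dialect.y_col]
    if dialect.nup_col:
        required.append(dialect.nup_col)
    _require_columns(df, required, path)
    if df.empty:
        log.warning("particle table %s is empty", path)
        return {}
    if dialect.nup_col:
        return {
            str(label): _particles_from_frame(group, dialect, path)
            for label, group in df.groupby(dialect.nup_col, sort=False)
        }
    label = dialect.default_label or path.stem
    return {label: _particles_from_frame(df, dialect, path)}


def read_particle_workbook(
    path: Union[str, Path], dialect: TableDialect = TableDialect()
) -> dict[str, list[GoldParticleRaw]]:
    """Read a spreadsheet with one sheet per tagged protein (sheet name = label)."""
    path = Path(path)
    sheets = pd.read_excel(path, sheet_name=None)
    out: dict[str, list[GoldParticleRaw]] = {}
    for name, df in sheets.items():
        _require_columns(
            df,
            [dialect.particle_id_col, dialect.npc_id_col, dialect.x_col, dialect.y_col],
            f"{path}[{name}]",
        )
        if df.empty:
            log.warning("sheet %s of %s is empty", name, path)
            continue
        out[str(name)] = _particles_from_frame(df, dialect, f"{path}[{name}]")
    return out


def read_annotations(path: Union[str, Path]) -> list[NpcAnnotation]:
    """Read per-NPC annotations (see :data:`ANNOTATION_COLUMNS` for the layout).

    Enforces npc_id uniqueness and a positive length scale.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, ANNOTATION_COLUMNS, path)
    if df.empty:
        log.warning("annotation table %s is empty", path)
        return []
    dup = df["npc_id"].astype(str).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate npc_id {df['npc_id'][dup].iloc[0]!r}")
    cx = _numeric(df, "center_x_px", path)
    cy = _numeric(df, "center_y_px", path)
    ang = _numeric(df, "ne_axis_angle_rad", path)
    scale = _numeric(df, "scale_nm_per_px", path)
    if (scale <= 0).any() or not scale.map(math.isfinite).all():
        row = int(scale.index[(scale <= 0) | ~scale.map(math.isfinite)][0])
        raise ValueError(f"{path}: scale_nm_per_px must be > 0 (row {row})")
    return [
        NpcAnnotation(
            npc_id=str(r.npc_id),
            micrograph_id=str(r.micrograph_id),
            center_px=(float(cx[i]), float(cy[i])),
            ne_axis_angle=float(ang[i]),
            nucleoplasm_side=str(r.nucleoplasm_side),
            scale_nm_per_px=float(scale[i]),
            nup_label=str(r.nup_label),
        )
        for i, r in df.iterrows()
    ]


def write_annotations(annotations: list[NpcAnnotation], path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "npc_id": [a.npc_id for a in annotations],
            "micrograph_id": [a.micrograph_id for a in annotations],
            "center_x_px": [a.center_px[0] for a in annotations],
            "center_y_px": [a.center_px[1] for a in annotations],
            "ne_axis_angle_rad": [a.ne_axis_angle for a in annotations],
            "nucleoplasm_side": [a.nucleoplasm_side for a in annotations],
            "scale_nm_per_px": [a.scale_nm_per_px for a in annotations],
            "nup_label": [a.nup_label for a in annotations],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def write_particle_table(
    particles_by_label: dict[str, list],
    path: Union[str, Path],
    dialect: TableDialect = TableDialect(nup_col="nup_label", units="nm"),
) -> Path:
    """Write particles (raw or common-frame) of several proteins to one table."""
    path = Path(path)
    rows = []
    for label, parts in particles_by_label.items():
        for p in parts:
            x = getattr(p, "x_nm", None)
            if x is None:
                x, y = p.x_px, p.y_px
            else:
                y = p.z_nm
            rows.append(
                {
                    dialect.nup_col or "nup_label": label,
                    dialect.particle_id_col: p.particle_id,
                    dialect.npc_id_col: p.npc_id,
                    dialect.x_col: x,
                    dialect.y_col: y,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)
    return path


def write_summary_table(
    estimates: list[LocalizationEstimate], path: Union[str, Path]
) -> Path:
    """Write the per-protein summary with the fixed eight-column layout."""
    if not estimates:
        raise ValueError("write_summary_table requires a nonempty estimate list")
    path = Path(path)
    df = pd.DataFrame(
        {
            "Nup": [e.nup_label for e in estimates],
            "Z ave": [e.z_ave_nm for e in estimates],
            "Z err": [e.z_err_nm for e in estimates],
            "R ave": [e.r_ave_nm for e in estimates],
            "R err": [e.r_err_nm for e in estimates],
            "N(R)": [e.n_r for e in estimates],
            "N(Z)": [e.n_z for e in estimates],
            "NPCs": [e.n_npcs for e in estimates],
        },
        columns=SUMMARY_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_summary_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, SUMMARY_COLUMNS, path)
    return df
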