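"""Spot-intensity tables for case-control 2D PAGE experiments.

A 2D PAGE experiment yields one gel per subject and, after spot detection
and matching, a spots x gels table of intensities.  Analysis is carried out
on *relative* intensities: each spot's volume divided by the total volume on
its gel, expressed as a percentage and log2-transformed ("log2 percent
volume").  On that scale no value can exceed ``log2(100)`` and a cell is
missing ("NA") when the protein was either not expressed or expressed below
the limit of detection.

This module owns the :class:`GelMatrix` container that every other module
consumes, the TSV/CSV readers and writers, and the raw-volume ->
log2-percent-volume preprocessing step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL",
    "CASE",
    "NU_MAX",
    "ModelConstants",
    "GelMatrix",
    "read_intensity_table",
    "read_design",
    "write_gel_matrix",
    "to_relative_log2",
]

CONTROL = "control"
CASE = "case"

#: Theoretical maximum of a log2 relative percentage volume: a single spot
#: carrying the gel's entire volume sits at log2(100) ~ 6.64.
NU_MAX: float = math.log2(100.0)

_GROUP_ALIASES = {
    "control": CONTROL,
    "ctrl": CONTROL,
    "case": CASE,
}


@dataclass(frozen=True)
class ModelConstants:
    """Detection limit ``d`` and maximum expression value ``nu``.

    Both are on the log2 percent-volume scale.  The default detection limit
    matches the simulation studies this package reproduces.
    """

    d: float = -8.67
    nu: float = NU_MAX

    def __post_init__(self) -> None:
        if not self.d < self.nu:
            raise ValueError(f"detection limit d={self.d} must be below nu={self.nu}")


@dataclass
class GelMatrix:
    """Log2 relative spot intensities with missingness and group labels.

    Parameters
    ----------
    values
        ``(S, G)`` float array of log2 percent volumes.  Entries under
        ``missing_mask`` carry NaN and no numeric meaning.
    missing_mask
        ``(S, G)`` boolean array; True marks an "NA" cell.
    spot_ids, gel_ids
        Row and column identifiers.
    groups
        Per-gel label, each ``"control"`` or ``"case"``.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    spot_ids: list[str]
    gel_ids: list[str]
    groups: list[str]
    constants: ModelConstants = field(default_factory=ModelConstants)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        s, g = self.values.shape
        if self.missing_mask.shape != (s, g):
            raise ValueError("values and missing_mask shapes differ")
        if len(self.spot_ids) != s or len(self.gel_ids) != g or len(self.groups) != g:
            raise ValueError("id/group lengths inconsistent with matrix shape")
        if len(set(self.spot_ids)) != s:
            raise ValueError("duplicate spot ids")
        bad = sorted(set(self.groups) - {CONTROL, CASE})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if CONTROL not in self.groups or CASE not in self.groups:
            raise ValueError("need at least one control and one case gel")
        self.values = np.where(self.missing_mask, np.nan, self.values)
        obs = self.values[~self.missing_mask]
        if obs.size and np.nanmax(obs) > self.constants.nu + 1e-9:
            raise ValueError(
                f"observed intensity exceeds the maximum expression value nu={self.constants.nu:.4f}"
            )

    # -- convenience views ------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_gels(self) -> int:
        return self.values.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        """Boolean per-gel indicator, True for case gels."""
        return np.asarray([g == CASE for g in self.groups], dtype=bool)

    def subset_spots(self, index: np.ndarray | list[int]) -> "GelMatrix":
        idx = np.asarray(index)
        return replace(
            self,
            values=self.values[idx],
            missing_mask=self.missing_mask[idx],
            spot_ids=[self.spot_ids[i] for i in idx],
        )


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column (gel_id, group) design file; header optional."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"design file {path} needs two columns (gel_id, group)")
    first = str(df.iloc[0, 1]).strip().lower()
    if first not in _GROUP_ALIASES:  # header row
        df = df.iloc[1:]
    design: dict[str, str] = {}
    for _, row in df.iterrows():
        gel = str(row.iloc[0]).strip()
        raw = str(row.iloc[1]).strip().lower()
        if raw not in _GROUP_ALIASES:
            raise ValueError(f"unknown group label {raw!r} for gel {gel!r}")
        design[gel] = _GROUP_ALIASES[raw]
    return design


def read_intensity_table(
    path: str | Path,
    design: str | Path | dict[str, str],
    constants: ModelConstants | None = None,
) -> GelMatrix:
    """Read a spots x gels intensity table plus its design into a GelMatrix.

    The table is tab- or comma-delimited with spot ids in the first column
    and gel ids in the header row.  Missing cells are the literal string
    ``"NA"`` or empty.  ``design`` maps every gel id to ``control``/``case``
    and may be a path or an in-memory mapping.
    """
    if not isinstance(design, dict):
        design = read_design(design)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    spot_ids = [str(s) for s in df.index]
    if len(set(spot_ids)) != len(spot_ids):
        dupes = sorted({s for s in spot_ids if spot_ids.count(s) > 1})
        raise ValueError(f"duplicate spot ids: {dupes}")
    gel_ids = [str(g) for g in df.columns]
    missing_gels = [g for g in gel_ids if g not in design]
    if missing_gels:
        raise ValueError(f"gels absent from design: {missing_gels}")

    raw = df.to_numpy(dtype=object)
    values = np.full(raw.shape, np.nan)
    mask = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            txt = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if txt == "" or txt.upper() == "NA":
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(txt)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {txt!r} at spot {spot_ids[i]!r}, gel {gel_ids[j]!r}"
                ) from None
    groups = [design[g] for g in gel_ids]
    return GelMatrix(
        values=values,
        missing_mask=mask,
        spot_ids=spot_ids,
        gel_ids=gel_ids,
        groups=groups,
        constants=constants or ModelConstants(),
    )


def write_gel_matrix(gm: GelMatrix, matrix_path: str | Path, design_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally the design) as TSV; missing -> "NA"."""
    df = pd.DataFrame(gm.values, index=gm.spot_ids, columns=gm.gel_ids)
    df.index.name = "spot_id"
    df.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%.10g")
    if design_path is not None:
        pd.DataFrame({"gel_id": gm.gel_ids, "group": gm.groups}).to_csv(
            design_path, sep="\t", index=False
        )


def to_relative_log2(raw: np.ndarray, missing_mask: np.ndarray | None = None) -> np.ndarray:
    """Convert raw spot volumes to log2 relative percentage volumes.

    Each gel (column) is scaled by its total observed volume so that the
    non-missing relative volumes on a gel sum to 100%, then log2-transformed:
    ``out[s, g] = log2(100 * raw[s, g] / sum_s' raw[s', g])``.

    Zeros are mapped to missing (NaN): a zero volume is indistinguishable
    from non-detection.  Missing inputs stay missing.
    """
    raw = np.asarray(raw, dtype=float)
    if missing_mask is None:
        missing_mask = np.isnan(raw)
    else:
        missing_mask = np.asarray(missing_mask, dtype=bool) | np.isnan(raw)
    work = np.where(missing_mask, np.nan, raw)
    if np.nanmin(np.where(missing_mask, np.inf, raw)) < 0:
        raise ValueError("raw volumes must be non-negative")
    work = np.where(work == 0.0, np.nan, work)
    totals = np.nansum(work, axis=0)
    dead = ~(totals > 0)
    if np.any(dead):
        raise ValueError(f"gel column(s) {np.flatnonzero(dead).tolist()} have no positive volume")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2(100.0 * work / totals)
    return out
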