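"""STDEV×COEFF contour maps and categorical SAR-effect classification.

The contoured quantity for column j is sd_j × b_j — the standard
deviation of the descriptor column times its PLS coefficient, the
conventional display behind CoMSIA contour plots. Favorable regions are
columns at or above the per-field favorable percentile (default 80th);
unfavorable at or below the unfavorable percentile (default 20th).
Compounds are then classified per field as POSITIVE / NEUTRAL / NEGATIVE
by comparing the weight of their own field values inside favorable vs
unfavorable regions.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fields import DescriptorMatrix, FieldKind, GridSpec, read_dx, write_dx
from .pls import PLSModel

__all__ = [
    "EffectLabel",
    "ContourSet",
    "SAREffectRow",
    "SAR_FIELDS",
    "stdev_coeff_values",
    "extract_contours",
    "classify_compound_effects",
    "export_contour_set",
    "import_contour_masks",
]

# Tables of categorical effects carry steric, hydrophobic, donor and
# acceptor columns; electrostatic contours are computed but not classified.
SAR_FIELDS = (FieldKind.STERIC, FieldKind.HYDROPHOBIC, FieldKind.DONOR, FieldKind.ACCEPTOR)


class EffectLabel(enum.Enum):
    POSITIVE = "positive"
    NEUTRAL = "neutral"
    NEGATIVE = "negative"


@dataclass
class ContourSet:
    field_kind: FieldKind
    favorable_mask: np.ndarray    # boolean, over this field's retained columns
    unfavorable_mask: np.ndarray
    favorable_threshold: float
    unfavorable_threshold: float
    grid_indices: np.ndarray      # grid point index of each retained column
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        if np.any(self.favorable_mask & self.unfavorable_mask):
            raise ValueError("favorable and unfavorable masks must be disjoint")


@dataclass
class SAREffectRow:
    compound_id: str
    labels: dict[FieldKind, EffectLabel]


def stdev_coeff_values(model: PLSModel, X: DescriptorMatrix) -> np.ndarray:
    """Per-column sd_j × b_j over the retained descriptor columns."""
    sds = X.X.std(axis=0)
    return sds * model.coefficients


def extract_contours(
    values: np.ndarray,
    X: DescriptorMatrix,
    favorable_percentile: float = 80.0,
    unfavorable_percentile: float = 20.0,
) -> dict[FieldKind, ContourSet]:
    """Threshold STDEV×COEFF values into favorable/unfavorable masks.

    Percentiles are computed per field over that field's retained columns
    only. Fields with fewer than 5 retained columns get empty masks and a
    warning.
    """
    values = np.asarray(values, dtype=float)
    out: dict[FieldKind, ContourSet] = {}
    for kind, idx in X.block_slices.items():
        v = values[idx]
        gidx = np.array([X.column_meta[j][1] for j in idx])
        if v.size < 5:
            warnings.warn(
                f"{kind.value}: only {v.size} retained columns; contour masks left empty",
                stacklevel=2,
            )
            fav = np.zeros(v.size, dtype=bool)
            unfav = np.zeros(v.size, dtype=bool)
            thr_hi = thr_lo = float("nan")
        else:
            thr_hi = float(np.percentile(v, favorable_percentile))
            thr_lo = float(np.percentile(v, unfavorable_percentile))
            fav = v >= thr_hi
            unfav = (v <= thr_lo) & ~fav
        out[kind] = ContourSet(
            field_kind=kind,
            favorable_mask=fav,
            unfavorable_mask=unfav,
            favorable_threshold=thr_hi,
            unfavorable_threshold=thr_lo,
            grid_indices=gidx,
            grid=X.grid,
        )
    return out


def classify_compound_effects(
    compound_id: str,
    descriptor_row: np.ndarray,
    X: DescriptorMatrix,
    contours: Mapping[FieldKind, ContourSet],
    threshold: float = 0.1,
) -> SAREffectRow:
    """Label one compound POSITIVE/NEUTRAL/NEGATIVE per SAR field.

    score = (Σ|v| over favorable columns − Σ|v| over unfavorable columns)
    normalized by the compound's total |v| for the field; labels at
    ±``threshold``. ``descriptor_row`` is the compound's processed
    descriptor row (same columns as ``X``).
    """
    descriptor_row = np.asarray(descriptor_row, dtype=float).ravel()
    if descriptor_row.shape[0] != len(X.column_meta):
        raise ValueError("descriptor row length does not match the training grid columns")
    labels: dict[FieldKind, EffectLabel] = {}
    slices = X.block_slices
    for kind in SAR_FIELDS:
        if kind not in slices or kind not in contours:
            labels[kind] = EffectLabel.NEUTRAL
            continue
        v = np.abs(descriptor_row[slices[kind]])
        total = float(v.sum())
        if total == 0.0:
            labels[kind] = EffectLabel.NEUTRAL
            continue
        cs = contours[kind]
        score = (float(v[cs.favorable_mask].sum()) - float(v[cs.unfavorable_mask].sum())) / total
        if score > threshold:
            labels[kind] = EffectLabel.POSITIVE
        elif score < -threshold:
            labels[kind] = EffectLabel.NEGATIVE
        else:
            labels[kind] = EffectLabel.NEUTRAL
    return SAREffectRow(compound_id=compound_id, labels=labels)


# ---------------------------------------------------------------------------
# export


def export_contour_set(
    cs: ContourSet,
    values: np.ndarray,
    X: DescriptorMatrix,
    out_dir: str | Path,
) -> list[Path]:
    """Write a field's STDEV×COEFF values and 0/1 masks as OpenDX grids.

    Grid points not retained as descriptor columns carry 0.
    """
    if cs.grid is None:
        raise ValueError("contour set has no grid; cannot export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idx = X.block_slices[cs.field_kind]
    full = np.zeros(cs.grid.n_points)
    full[cs.grid_indices] = np.asarray(values, dtype=float)[idx]
    written = []
    path = out_dir / f"{cs.field_kind.value}_stdev_coeff.dx"
    write_dx(full, cs.grid, path)
    written.append(path)
    for name, mask in (("favorable", cs.favorable_mask), ("unfavorable", cs.unfavorable_mask)):
        full_mask = np.zeros(cs.grid.n_points)
        full_mask[cs.grid_indices[mask]] = 1.0
        path = out_dir / f"{cs.field_kind.value}_{name}.dx"
        write_dx(full_mask, cs.grid, path)
        written.append(path)
    return written


def import_contour_masks(
    favorable_path: str | Path, unfavorable_path: str | Path, grid_indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Read exported 0/1 mask grids back into column-space boolean masks."""
    fav_full, _ = read_dx(favorable_path)
    unfav_full, _ = read_dx(unfavorable_path)
    return fav_full[grid_indices] > 0.5, unfav_full[grid_indices] > 0.5
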