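"""CoMSIA Gaussian similarity-index fields on a shared rectangular grid.

The similarity index of field F for molecule j at grid point q is

    A_F(q) = − Σ_i  w_probe,F · w_i,F · exp(−α · r_iq²)

with α the attenuation factor (0.3 Å⁻² by default), r_iq the atom–grid
distance in Å, and w_i,F the atomic property weight: vdW radius cubed
(steric), partial charge (electrostatic), atomic logP increment
(hydrophobic), or a 0/1 donor/acceptor flag. The probe is an sp³ carbon
with radius 1.52 Å, charge +1 and unit hydrophobic/donor/acceptor weights.
Values are clamped to ±clamp_magnitude (default 30, mirroring the
conventional column cut-off). The probe radius does not enter the Gaussian
similarity index itself; it is carried in the parameter set for reporting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dataset import MoleculeRecord

__all__ = [
    "FieldKind",
    "FieldParams",
    "GridSpec",
    "FieldMatrix",
    "DescriptorMatrix",
    "build_grid",
    "similarity_field",
    "compute_field_matrices",
    "assemble_descriptor_matrix",
    "write_dx",
    "read_dx",
]


class FieldKind(enum.Enum):
    STERIC = "steric"
    ELECTROSTATIC = "electrostatic"
    HYDROPHOBIC = "hydrophobic"
    DONOR = "donor"
    ACCEPTOR = "acceptor"


ALL_FIELDS = tuple(FieldKind)


@dataclass
class FieldParams:
    """CoMSIA grid and probe parameters (defaults follow the study setup)."""

    attenuation_alpha: float = 0.3   # Å⁻²
    probe_radius: float = 1.52       # Å, carried for reporting
    probe_charge: float = 1.0        # e
    probe_hydrophobicity: float = 1.0
    probe_donor: float = 1.0
    probe_acceptor: float = 1.0
    clamp_magnitude: float = 30.0
    grid_spacing: float = 2.0        # Å
    grid_margin: float = 4.0         # Å

    def __post_init__(self) -> None:
        if self.attenuation_alpha <= 0 or self.grid_spacing <= 0 or self.clamp_magnitude <= 0:
            raise ValueError("attenuation, spacing and clamp must be positive")

    def probe_weight(self, kind: FieldKind) -> float:
        return {
            FieldKind.STERIC: 1.0,
            FieldKind.ELECTROSTATIC: self.probe_charge,
            FieldKind.HYDROPHOBIC: self.probe_hydrophobicity,
            FieldKind.DONOR: self.probe_donor,
            FieldKind.ACCEPTOR: self.probe_acceptor,
        }[kind]


@dataclass(frozen=True)
class GridSpec:
    origin: np.ndarray
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if any(c <= 0 for c in self.counts):
            raise ValueError("grid counts must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid point coordinates, shape (n_points, 3), z fastest."""
        axes = [self.origin[d] + self.spacing * np.arange(self.counts[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        hi = self.origin + self.spacing * (np.array(self.counts) - 1)
        return np.all((coords >= self.origin - 1e-9) & (coords <= hi + 1e-9), axis=1)


@dataclass
class FieldMatrix:
    field_kind: FieldKind
    values: np.ndarray  # (n_molecules, n_grid_points)


def build_grid(molecules: Sequence[MoleculeRecord], params: FieldParams | None = None) -> GridSpec:
    """Axis-aligned grid covering the union bounding box of all atoms plus
    ``grid_margin`` on every side, discretized at ``grid_spacing``."""
    if not molecules:
        raise ValueError("cannot build a grid from an empty molecule list")
    params = params or FieldParams()
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - params.grid_margin
    hi = coords.max(axis=0) + params.grid_margin
    counts = tuple(int(np.ceil((hi[d] - lo[d]) / params.grid_spacing - 1e-9)) + 1 for d in range(3))
    return GridSpec(origin=lo, spacing=params.grid_spacing, counts=counts)


def _atomic_weights(molecule: MoleculeRecord, kind: FieldKind) -> np.ndarray:
    if kind is FieldKind.STERIC:
        return np.array([a.vdw_radius**3 for a in molecule.atoms])
    if kind is FieldKind.ELECTROSTATIC:
        return np.array([a.partial_charge for a in molecule.atoms])
    if kind is FieldKind.HYDROPHOBIC:
        return np.array([a.hydrophobicity for a in molecule.atoms])
    if kind is FieldKind.DONOR:
        return np.array([1.0 if a.is_donor else 0.0 for a in molecule.atoms])
    if kind is FieldKind.ACCEPTOR:
        return np.array([1.0 if a.is_acceptor else 0.0 for a in molecule.atoms])
    raise ValueError(f"unknown field kind {kind!r}")


def similarity_field(
    molecule: MoleculeRecord,
    grid: GridSpec,
    field_kind: FieldKind,
    params: FieldParams | None = None,
) -> np.ndarray:
    """Similarity-index vector of one molecule over all grid points."""
    params = params or FieldParams()
    if not isinstance(field_kind, FieldKind):
        raise ValueError(f"unknown field kind {field_kind!r}")
    weights = _atomic_weights(molecule, field_kind)
    pts = grid.points()
    diff = molecule.coords[:, None, :] - pts[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    gauss = np.exp(-params.attenuation_alpha * r2)
    values = -params.probe_weight(field_kind) * (weights @ gauss)
    return np.clip(values, -params.clamp_magnitude, params.clamp_magnitude)


def compute_field_matrices(
    molecules: Sequence[MoleculeRecord],
    grid: GridSpec,
    params: FieldParams | None = None,
    kinds: Iterable[FieldKind] = ALL_FIELDS,
) -> list[FieldMatrix]:
    params = params or FieldParams()
    out = []
    for kind in kinds:
        rows = np.vstack([similarity_field(m, grid, kind, params) for m in molecules])
        out.append(FieldMatrix(field_kind=kind, values=rows))
    return out


@dataclass
class DescriptorMatrix:
    """Filtered, centered, block-scaled field columns — the PLS input.

    ``column_meta`` records (field kind, grid index) provenance for every
    retained column. ``raw`` holds the retained columns before centering
    and scaling so cross-validation can recompute both on subsets.
    """

    X: np.ndarray
    column_meta: list[tuple[FieldKind, int]]
    column_means: np.ndarray
    block_scales: dict[FieldKind, float]
    filter_sd: float
    raw: np.ndarray = dc_field(repr=False, default=None)
    grid: GridSpec | None = None

    @property
    def block_slices(self) -> dict[FieldKind, np.ndarray]:
        out: dict[FieldKind, list[int]] = {}
        for j, (kind, _) in enumerate(self.column_meta):
            out.setdefault(kind, []).append(j)
        return {k: np.array(v) for k, v in out.items()}

    def transform(self, fields: Sequence[FieldMatrix]) -> np.ndarray:
        """Apply the training filter/centering/scaling to new molecules."""
        by_kind = {f.field_kind: f.values for f in fields}
        cols = []
        for kind, gidx in self.column_meta:
            if kind not in by_kind:
                raise KeyError(f"missing field matrix for {kind}")
            cols.append(by_kind[kind][:, gidx])
        raw = np.stack(cols, axis=1)
        x = raw - self.column_means
        for kind, idx in self.block_slices.items():
            x[:, idx] /= self.block_scales[kind]
        return x


def assemble_descriptor_matrix(
    fields: Sequence[FieldMatrix],
    filter_sd: float = 0.01,
    grid: GridSpec | None = None,
) -> DescriptorMatrix:
    """Filter near-constant columns, mean-center, and block-scale.

    Columns whose standard deviation falls below ``filter_sd`` are dropped.
    Each field block is divided by the square root of its total retained
    variance, so every block contributes equal total variance to X.
    """
    n_mol = fields[0].values.shape[0]
    kept_cols: list[np.ndarray] = []
    raw_cols: list[np.ndarray] = []
    meta: list[tuple[FieldKind, int]] = []
    block_scales: dict[FieldKind, float] = {}
    means: list[float] = []
    for fm in fields:
        if fm.values.shape[0] != n_mol:
            raise ValueError("field matrices disagree on molecule count")
        sd = fm.values.std(axis=0)
        keep = np.flatnonzero(sd >= filter_sd)
        if keep.size == 0:
            continue
        block = fm.values[:, keep].astype(float)
        mu = block.mean(axis=0)
        centered = block - mu
        total_var = float((centered**2).mean(axis=0).sum())
        scale = np.sqrt(total_var) if total_var > 0 else 1.0
        kept_cols.append(centered / scale)
        raw_cols.append(block)
        block_scales[fm.field_kind] = scale
        meta.extend((fm.field_kind, int(g)) for g in keep)
        means.extend(mu.tolist())
    if not kept_cols:
        raise ValueError(f"all columns filtered out at sd threshold {filter_sd}")
    return DescriptorMatrix(
        X=np.concatenate(kept_cols, axis=1),
        raw=np.concatenate(raw_cols, axis=1),
        column_meta=meta,
        column_means=np.array(means),
        block_scales=block_scales,
        filter_sd=filter_sd,
        grid=grid,
    )


def preprocess_like(meta: list[tuple[FieldKind, int]], raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict[FieldKind, float]]:
    """Center and block-scale a raw retained-column matrix.

    Used by cross-validation to recompute centering/scaling on a training
    subset while keeping the column filter fixed.
    """
    mu = raw.mean(axis=0)
    x = raw - mu
    scales: dict[FieldKind, float] = {}
    kinds = {k for k, _ in meta}
    for kind in kinds:
        idx = np.array([j for j, (k, _) in enumerate(meta) if k == kind])
        total_var = float((x[:, idx] ** 2).mean(axis=0).sum())
        s = np.sqrt(total_var) if total_var > 0 else 1.0
        x[:, idx] /= s
        scales[kind] = s
    return x, mu, scales


# ---------------------------------------------------------------------------
# grid export


def write_dx(values: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write one scalar field over the grid as an OpenDX file."""
    from gridData import Grid

    data = np.asarray(values, dtype=float).reshape(grid.counts)
    g = Grid(data, origin=np.asarray(grid.origin), delta=grid.spacing)
    g.export(str(path), file_format="dx")


def read_dx(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an OpenDX scalar field back into (flat values, GridSpec)."""
    from gridData import Grid

    g = Grid(str(path))
    spacing = float(np.asarray(g.delta).flat[0])
    spec = GridSpec(origin=np.asarray(g.origin), spacing=spacing, counts=tuple(g.grid.shape))
    return g.grid.ravel(), spec
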