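"""Pharmacophore feature detection and rigid feature-based alignment.

Molecules are aligned to a reference hypothesis by enumerating
kind-consistent feature matchings and superposing each candidate with the
Kabsch algorithm; the matching with the lowest feature RMSD wins. The
alignment is rigid (no torsional flexibility) and rotations are always
proper (no reflections), so chirality is preserved.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dataset import MoleculeRecord

__all__ = [
    "FeatureKind",
    "PharmacophoreFeature",
    "ReferenceHypothesis",
    "AlignmentResult",
    "detect_features",
    "kabsch_superpose",
    "align_molecule",
    "read_reference_hypothesis",
    "default_reference_hypothesis",
]

MATCHING_CAP = 5000


class FeatureKind(enum.Enum):
    """The seven-feature chemistry alphabet: acceptor, donor, hydrophobe,
    negative/positive ionizable, aromatic ring."""

    A = "acceptor"
    D = "donor"
    H = "hydrophobe"
    N = "negative"
    P = "positive"
    R = "aromatic_ring"


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: FeatureKind
    position: np.ndarray
    tolerance: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be positive")


@dataclass
class ReferenceHypothesis:
    features: list[PharmacophoreFeature]
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(self.features) < 3:
            raise ValueError("a reference hypothesis needs at least 3 features")


@dataclass
class AlignmentResult:
    rotation: np.ndarray
    translation: np.ndarray
    matched_pairs: list[tuple[int, int]]
    feature_rmsd: float


# ---------------------------------------------------------------------------
# detection

_POLAR_NEIGHBORS = {"N", "O"}


def detect_features(molecule: MoleculeRecord, tolerance: float = 1.0) -> list[PharmacophoreFeature]:
    """Detect pharmacophore features on an annotated molecule.

    Rules: A/D features sit on flagged acceptor/donor heteroatoms; H
    features at centroids of connected apolar-carbon clusters of size ≥ 3
    (carbon not bonded to N or O); R at aromatic ring centroids; N/P at
    centroids of connected clusters of formally charged atoms. The output
    ordering (kind, then lexicographic position) is deterministic.
    """
    feats: list[PharmacophoreFeature] = []
    coords = molecule.coords
    for i, atom in enumerate(molecule.atoms):
        if atom.is_acceptor:
            feats.append(PharmacophoreFeature(FeatureKind.A, coords[i], tolerance))
        if atom.is_donor:
            feats.append(PharmacophoreFeature(FeatureKind.D, coords[i], tolerance))

    neighbors: dict[int, set[int]] = {i: set() for i in range(len(molecule.atoms))}
    for i, j in molecule.bonds:
        neighbors[i].add(j)
        neighbors[j].add(i)

    def is_apolar_carbon(i: int) -> bool:
        if molecule.atoms[i].element != "C":
            return False
        return not any(molecule.atoms[j].element in _POLAR_NEIGHBORS for j in neighbors[i])

    apolar = {i for i in range(len(molecule.atoms)) if is_apolar_carbon(i)}
    for cluster in _connected_components(apolar, neighbors):
        if len(cluster) >= 3:
            feats.append(
                PharmacophoreFeature(FeatureKind.H, coords[sorted(cluster)].mean(axis=0), tolerance)
            )

    for ring in molecule.aromatic_rings:
        feats.append(PharmacophoreFeature(FeatureKind.R, coords[list(ring)].mean(axis=0), tolerance))

    for sign, kind in ((-1, FeatureKind.N), (1, FeatureKind.P)):
        charged = {
            i for i, a in enumerate(molecule.atoms) if a.formal_charge * sign > 0
        }
        for cluster in _connected_components(charged, neighbors):
            feats.append(
                PharmacophoreFeature(kind, coords[sorted(cluster)].mean(axis=0), tolerance)
            )

    key = lambda f: (f.kind.name, round(f.position[0], 6), round(f.position[1], 6), round(f.position[2], 6))
    return sorted(feats, key=key)


def _connected_components(nodes: set[int], neighbors: dict[int, set[int]]) -> list[set[int]]:
    remaining = set(nodes)
    comps = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        frontier = [seed]
        while frontier:
            node = frontier.pop()
            for nb in neighbors[node]:
                if nb in remaining and nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        remaining -= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1, reflections refused). Transformed points are
    ``moving @ rotation.T + translation``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 point pairs")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    # collinear (or coincident) point sets leave the rotation undetermined
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set; rotation is undetermined")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = fc - rotation @ mc
    transformed = a @ rotation.T + fc
    rmsd = math.sqrt(float(np.mean(np.sum((transformed - fixed) ** 2, axis=1))))
    return rotation, translation, rmsd


# ---------------------------------------------------------------------------
# alignment


def align_molecule(
    molecule: MoleculeRecord,
    reference: ReferenceHypothesis,
    features: Sequence[PharmacophoreFeature] | None = None,
) -> tuple[MoleculeRecord, AlignmentResult]:
    """Rigidly align a molecule to a reference hypothesis.

    Enumerates kind-consistent maximal feature matchings (each shared kind
    contributes min(count) pairs), capped at ``MATCHING_CAP`` candidates
    ranked by a pose-invariant internal-distance heuristic, superposes each
    with Kabsch, and keeps the matching with minimal feature RMSD (ties:
    larger matching, then lexicographic pair order).
    """
    if features is None:
        features = detect_features(molecule)
    features = list(features)
    mol_by_kind: dict[FeatureKind, list[int]] = {}
    ref_by_kind: dict[FeatureKind, list[int]] = {}
    for i, f in enumerate(features):
        mol_by_kind.setdefault(f.kind, []).append(i)
    for j, f in enumerate(reference.features):
        ref_by_kind.setdefault(f.kind, []).append(j)

    shared = sorted(set(mol_by_kind) & set(ref_by_kind), key=lambda k: k.name)
    n_pairs = sum(min(len(mol_by_kind[k]), len(ref_by_kind[k])) for k in shared)
    if n_pairs < 3:
        available = sorted(k.name for k in mol_by_kind)
        raise ValueError(
            "unalignable: fewer than 3 kind-consistent feature pairs "
            f"(molecule kinds: {available})"
        )

    per_kind_options = [
        _kind_injections(k, mol_by_kind[k], ref_by_kind[k], features, reference.features)
        for k in shared
    ]
    # cap the cartesian product by trimming each kind's candidate list,
    # worst-scoring (by the distance-consistency heuristic) first
    while _product_size(per_kind_options) > MATCHING_CAP:
        largest = max(range(len(per_kind_options)), key=lambda i: len(per_kind_options[i]))
        per_kind_options[largest] = per_kind_options[largest][:-1]

    mol_coords = np.array([f.position for f in features])
    ref_coords = np.array([f.position for f in reference.features])

    best: tuple[float, int, list[tuple[int, int]], np.ndarray, np.ndarray] | None = None
    for combo in itertools.product(*per_kind_options):
        pairs = sorted(p for inj in combo for p in inj)
        if len(pairs) < 3:
            continue
        mv = mol_coords[[p[0] for p in pairs]]
        fx = ref_coords[[p[1] for p in pairs]]
        try:
            rot, trans, rmsd = kabsch_superpose(mv, fx)
        except ValueError:
            continue
        cand = (rmsd, -len(pairs), pairs, rot, trans)
        if best is None or (cand[0], cand[1], cand[2]) < (best[0], best[1], best[2]):
            best = cand
    if best is None:
        raise ValueError("unalignable: all candidate matchings were geometrically degenerate")

    rmsd, _, pairs, rot, trans = best
    aligned = molecule.with_coords(molecule.coords @ rot.T + trans)
    return aligned, AlignmentResult(rotation=rot, translation=trans, matched_pairs=pairs, feature_rmsd=rmsd)


def _kind_injections(
    kind: FeatureKind,
    mol_idx: list[int],
    ref_idx: list[int],
    mol_feats: Sequence[PharmacophoreFeature],
    ref_feats: Sequence[PharmacophoreFeature],
) -> list[list[tuple[int, int]]]:
    """All maximal injective matchings for one kind, best heuristic first.

    The heuristic scores a matching by how well intra-set pairwise feature
    distances agree between molecule and reference — invariant to the
    molecule's initial pose.
    """
    m, r = len(mol_idx), len(ref_idx)
    size = min(m, r)
    injections: list[list[tuple[int, int]]] = []
    if m <= r:
        for ref_subset in itertools.permutations(ref_idx, size):
            injections.append(list(zip(mol_idx, ref_subset)))
    else:
        for mol_subset in itertools.permutations(mol_idx, size):
            injections.append(sorted(zip(mol_subset, ref_idx)))

    def score(inj: list[tuple[int, int]]) -> float:
        if len(inj) < 2:
            return 0.0
        mol_pts = np.array([mol_feats[i].position for i, _ in inj])
        ref_pts = np.array([ref_feats[j].position for _, j in inj])
        dm = np.linalg.norm(mol_pts[:, None] - mol_pts[None, :], axis=-1)
        dr = np.linalg.norm(ref_pts[:, None] - ref_pts[None, :], axis=-1)
        return float(np.abs(dm - dr).sum())

    return sorted(injections, key=lambda inj: (score(inj), inj))


def _product_size(options: list[list]) -> int:
    total = 1
    for opt in options:
        total *= max(len(opt), 1)
    return total


# ---------------------------------------------------------------------------
# reference hypothesis IO

_KIND_BY_LETTER = {k.name: k for k in FeatureKind}


def read_reference_hypothesis(path: str | Path, source_label: str | None = None) -> ReferenceHypothesis:
    """Read a whitespace-delimited ``kind x y z tolerance`` feature file."""
    path = Path(path)
    features = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind_str, x, y, z, tol = line.split()
        features.append(
            PharmacophoreFeature(
                kind=_KIND_BY_LETTER[kind_str],
                position=np.array([float(x), float(y), float(z)]),
                tolerance=float(tol),
            )
        )
    return ReferenceHypothesis(features=features, source_label=source_label or path.name)


def default_reference_hypothesis() -> ReferenceHypothesis:
    """The packaged synthetic stand-in hypothesis (1 A, 3 D, 3 R)."""
    from importlib import resources

    path = resources.files("chromqsar.data").joinpath("reference_hypothesis_synthetic.txt")
    with resources.as_file(path) as p:
        return read_reference_hypothesis(p, source_label="synthetic stand-in")
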