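"""Structure and activity input handling.

Reads SDF V2000 structure files and MIC activity tables, converts MIC
(µg/mL) to pMIC (−log10 of molar MIC by default), and attaches the
per-atom property weights the CoMSIA similarity fields consume: partial
charges (Gasteiger iterative electronegativity equalization), van der
Waals radii (packaged Bondi table), atomic hydrophobicity (Wildman–Crippen
logP increments) and hydrogen-bond donor/acceptor flags (SMARTS rules).
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "MoleculeRecord",
    "Organism",
    "Split",
    "ActivityRecord",
    "read_structures",
    "write_structures",
    "read_activity_table",
    "derive_pmic",
    "mic_to_pmic",
    "annotate_atoms",
    "molecule_from_smiles",
    "load_vdw_radii",
]


class Organism(enum.Enum):
    ECOLI = "E. coli"
    SAUREUS = "S. aureus"


class Split(enum.Enum):
    TRAIN = "train"
    TEST = "test"
    UNASSIGNED = "unassigned"


@dataclass
class AtomRecord:
    """One atom as a property-bearing point in 3D.

    ``partial_charge`` is in elementary charge units, ``vdw_radius`` in Å,
    ``hydrophobicity`` is the unitless atomic logP increment. An atom may
    be both donor and acceptor (e.g. a hydroxyl oxygen).
    """

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float = 0.0
    hydrophobicity: float = 0.0
    is_donor: bool = False
    is_acceptor: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")


@dataclass
class MoleculeRecord:
    """An ordered collection of atoms; the unit of alignment and field
    computation. ``bonds`` and ``aromatic_rings`` hold connectivity where
    known (real molecules); synthetic pseudo-molecules may leave them empty.
    """

    id: str
    atoms: list[AtomRecord]
    molecular_weight: float = 0.0
    formal_charge: int = 0
    bonds: list[tuple[int, int]] = field(default_factory=list)
    aromatic_rings: list[tuple[int, ...]] = field(default_factory=list)
    rdkit_mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "MoleculeRecord":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=c.copy()) for a, c in zip(self.atoms, coords)]
        return replace(self, atoms=atoms)


@dataclass
class ActivityRecord:
    """MIC measurement for one compound against one organism.

    ``pmic`` is defined only for uncensored records; censored entries
    (MIC reported as "> X") keep the bound in ``mic``.
    """

    compound_id: str
    organism: Organism
    mic: float
    censored: bool = False
    pmic: float | None = None
    split: Split = Split.UNASSIGNED


# ---------------------------------------------------------------------------
# parameter tables

_ORGANISM_ALIASES = {
    "e. coli": Organism.ECOLI,
    "e.coli": Organism.ECOLI,
    "e_coli": Organism.ECOLI,
    "ecoli": Organism.ECOLI,
    "escherichia coli": Organism.ECOLI,
    "s. aureus": Organism.SAUREUS,
    "s.aureus": Organism.SAUREUS,
    "s_aureus": Organism.SAUREUS,
    "saureus": Organism.SAUREUS,
    "staphylococcus aureus": Organism.SAUREUS,
}

_vdw_cache: dict[str, float] | None = None


def load_vdw_radii() -> dict[str, float]:
    """Element → van der Waals radius (Å) from the packaged table."""
    global _vdw_cache
    if _vdw_cache is None:
        table = {}
        path = resources.files("chromqsar.data").joinpath("vdw_radii.csv")
        with path.open() as fh:
            for row in csv.DictReader(fh):
                table[row["element"]] = float(row["radius_angstrom"])
        _vdw_cache = table
    return _vdw_cache


def parse_organism(label: str) -> Organism:
    key = str(label).strip().lower()
    if key not in _ORGANISM_ALIASES:
        raise ValueError(f"unknown organism label {label!r}")
    return _ORGANISM_ALIASES[key]


# ---------------------------------------------------------------------------
# structures


def _mol_to_record(mol: Chem.Mol, idx: int, allow_embed: bool) -> MoleculeRecord:
    name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{idx}"
    if mol.GetNumConformers() == 0 or _is_flat(mol):
        if not allow_embed:
            raise ValueError(
                f"molecule {name!r} (block {idx}) has no 3D coordinates; "
                "enable embedding to generate a conformer"
            )
        mol = Chem.AddHs(mol)
        if AllChem.EmbedMolecule(mol, randomSeed=0xF00D) != 0:
            raise ValueError(f"3D embedding failed for molecule {name!r}")
        AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    conf = mol.GetConformer()
    atoms = [
        AtomRecord(
            element=a.GetSymbol(),
            position=np.array(conf.GetAtomPosition(a.GetIdx())),
            formal_charge=a.GetFormalCharge(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    rings = [
        tuple(ring)
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]
    return MoleculeRecord(
        id=name,
        atoms=atoms,
        molecular_weight=rdMolDescriptors.CalcExactMolWt(mol),
        formal_charge=Chem.GetFormalCharge(mol),
        bonds=bonds,
        aromatic_rings=rings,
        rdkit_mol=mol,
    )


def _is_flat(mol: Chem.Mol) -> bool:
    conf = mol.GetConformer()
    zs = np.array([conf.GetAtomPosition(i).z for i in range(mol.GetNumAtoms())])
    return bool(np.all(zs == 0.0))


def read_structures(path: str | Path, allow_embed: bool = False) -> list[MoleculeRecord]:
    """Read an SDF V2000 file into :class:`MoleculeRecord` objects.

    Molecules whose z-coordinates are identically zero are treated as 2D
    and rejected unless ``allow_embed`` generates a conformer in-process.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"malformed molecule block at index {idx} in {path}")
        records.append(_mol_to_record(mol, idx, allow_embed))
    return records


def write_structures(molecules: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write molecules back to SDF, preserving atom order and coordinates."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for rec in molecules:
            mol = rec.rdkit_mol
            if mol is None:
                mol = _record_to_rdkit(rec)
            else:
                mol = Chem.Mol(mol)
            conf = mol.GetConformer()
            for i, atom in enumerate(rec.atoms):
                conf.SetAtomPosition(i, atom.position.tolist())
            mol.SetProp("_Name", rec.id)
            writer.write(mol)
    finally:
        writer.close()


def _record_to_rdkit(rec: MoleculeRecord) -> Chem.Mol:
    rw = Chem.RWMol()
    for atom in rec.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j in rec.bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    conf = Chem.Conformer(len(rec.atoms))
    for i, atom in enumerate(rec.atoms):
        conf.SetAtomPosition(i, atom.position.tolist())
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return mol


def molecule_from_smiles(smiles: str, name: str = "mol", seed: int = 0xF00D) -> MoleculeRecord:
    """Build an annotated 3D molecule from SMILES (testing/fixture helper)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise ValueError(f"embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    mol.SetProp("_Name", name)
    return annotate_atoms(_mol_to_record(mol, 0, allow_embed=False))


# ---------------------------------------------------------------------------
# activities


def mic_to_pmic(mic: float, molecular_weight: float, basis: str = "molar") -> float:
    """Convert a MIC in µg/mL to pMIC.

    With ``basis="molar"`` (default) the MIC is first converted to mol/L
    using the molecular weight (µg/mL ≡ mg/L, so molar MIC =
    mic·10⁻³ / MW), then pMIC = −log10(molar MIC). ``basis="mass"`` takes
    −log10 of the µg/mL value directly.
    """
    if mic <= 0:
        raise ValueError(f"MIC must be positive, got {mic}")
    if basis == "molar":
        if molecular_weight <= 0:
            raise ValueError(f"molecular weight must be positive, got {molecular_weight}")
        return -math.log10(mic * 1e-3 / molecular_weight)
    if basis == "mass":
        return -math.log10(mic)
    raise ValueError(f"unknown pMIC basis {basis!r}")


def _parse_mic(raw) -> tuple[float, bool] | None:
    """Return (mic, censored) or None for a missing value."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text or text.lower() in {"nan", "na", "-"}:
        return None
    censored = False
    if text.startswith(">"):
        censored = True
        text = text[1:].strip()
    mic = float(text)
    if mic <= 0:
        raise ValueError(f"non-positive MIC {mic}")
    return mic, censored


def read_activity_table(
    path: str | Path,
    mw_by_id: dict[str, float] | None = None,
    pmic_basis: str = "molar",
) -> list[ActivityRecord]:
    """Read an activity CSV with columns compound_id, organism, mic[, split].

    Censored rows ("> 512") keep the bound with ``censored=True`` and no
    pMIC. Rows with a missing MIC are dropped and counted in the log.
    When ``mw_by_id`` is given, pMIC is derived immediately for uncensored
    rows; otherwise use :func:`derive_pmic` after structures are loaded.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "organism", "mic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    records: list[ActivityRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        parsed = _parse_mic(row["mic"])
        if parsed is None:
            n_dropped += 1
            continue
        mic, censored = parsed
        organism = parse_organism(row["organism"])
        split = Split.UNASSIGNED
        if "split" in df.columns and isinstance(row.get("split"), str) and row["split"].strip():
            split = Split(row["split"].strip().lower())
        rec = ActivityRecord(
            compound_id=str(row["compound_id"]).strip(),
            organism=organism,
            mic=mic,
            censored=censored,
            split=split,
        )
        if not censored:
            if pmic_basis == "mass":
                rec.pmic = mic_to_pmic(mic, 1.0, basis="mass")
            elif mw_by_id is not None and rec.compound_id in mw_by_id:
                rec.pmic = mic_to_pmic(mic, mw_by_id[rec.compound_id], basis="molar")
        records.append(rec)
    if n_dropped:
        logger.info("dropped %d activity rows with missing MIC", n_dropped)
    return records


def derive_pmic(
    activities: Sequence[ActivityRecord],
    molecules: Sequence[MoleculeRecord],
    basis: str = "molar",
) -> list[ActivityRecord]:
    """Fill pMIC for uncensored records using molecular weights by id."""
    mw = {m.id: m.molecular_weight for m in molecules}
    out = []
    for rec in activities:
        rec = replace(rec)
        if not rec.censored:
            if basis == "molar" and rec.compound_id not in mw:
                raise KeyError(f"no structure for compound {rec.compound_id!r}")
            rec.pmic = mic_to_pmic(rec.mic, mw.get(rec.compound_id, 1.0), basis=basis)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# per-atom parameterization

# donor: N or O bearing at least one hydrogen
_DONOR = Chem.MolFromSmarts("[#7,#8;!H0]")
# acceptor: O with a lone pair, or N with an available lone pair — excluding
# amide/sulfonamide N, nitro N and pyrrole-type aromatic N whose lone pair
# is delocalized
_ACCEPTOR = Chem.MolFromSmarts(
    "[$([#8;+0]),"
    "$([N;X1;+0]),"
    "$([N;X2;+0;!$(N=O)]),"
    "$([N;X3;+0;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][SX4]=[OX1]);!$([NX3](=O)=O)]),"
    "$([n;X2;+0])]"
)


def annotate_atoms(molecule: MoleculeRecord) -> MoleculeRecord:
    """Attach CoMSIA per-atom property weights to every atom.

    Partial charges come from the Gasteiger iterative electronegativity
    equalization scheme, vdW radii from the packaged element table,
    hydrophobicity from Wildman–Crippen atomic logP increments, and
    donor/acceptor flags from SMARTS substructure rules.
    """
    mol = molecule.rdkit_mol
    if mol is None:
        raise ValueError(f"molecule {molecule.id!r} carries no chemistry; cannot annotate")
    mol = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(mol)
    crippen = rdMolDescriptors._CalcCrippenContribs(mol)
    radii = load_vdw_radii()
    donors = {i for (i,) in mol.GetSubstructMatches(_DONOR)}
    acceptors = {i for (i,) in mol.GetSubstructMatches(_ACCEPTOR)}
    atoms = []
    for i, (atom_rec, rd_atom) in enumerate(zip(molecule.atoms, mol.GetAtoms())):
        symbol = rd_atom.GetSymbol()
        if symbol not in radii:
            raise KeyError(f"element {symbol!r} missing from the vdW radius table")
        charge = float(rd_atom.GetDoubleProp("_GasteigerCharge"))
        if not math.isfinite(charge):
            charge = 0.0
        atoms.append(
            replace(
                atom_rec,
                partial_charge=charge,
                vdw_radius=radii[symbol],
                hydrophobicity=float(crippen[i][0]),
                is_donor=i in donors,
                is_acceptor=i in acceptors,
            )
        )
    total = sum(a.partial_charge for a in atoms)
    if abs(total - molecule.formal_charge) > 1e-3:
        # Gasteiger conserves total charge; residual here means bad input
        logger.warning(
            "molecule %s: partial charges sum to %.4f (formal charge %d)",
            molecule.id,
            total,
            molecule.formal_charge,
        )
    return replace(molecule, atoms=atoms, rdkit_mol=mol)
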