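"""Protein structure model: PDB I/O, backbone superposition, ligand
ensembles, first-layer residue selection and alanine substitution.

The in-memory model is deliberately small: a structure is an ordered list
of residues, each an ordered list of atoms with coordinates and vdW radii
already resolved. Hydrogens and waters are discarded on read; alternate
locations are collapsed to the highest-occupancy position. Hetero groups
(everything HETATM that is not water or a configured ion) are kept apart
from the polymer as candidate ligands.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .config import RunConfig, load_vdw_radii
from .geometry import kabsch, place_atom

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

# Key identifying a residue within a structure: (chain, seqnum, insertion code)
ResidueKey = tuple[str, int, str]

# Ideal Cbeta internal coordinates (built from C, N, CA).
CB_BOND = 1.53
CB_ANGLE = 110.5      # N-CA-CB
CB_TORSION = -122.6   # C-N-CA-CB improper; places CB on the L-amino-acid side


@dataclass
class AtomRecord:
    """A heavy atom with resolved coordinates and an assigned vdW radius."""

    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float
    is_backbone: bool = False
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw radius must be positive for atom {self.name}")


@dataclass
class Residue:
    chain: str
    seqnum: int
    icode: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.seqnum, self.icode)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not found in residue {self.key} ({self.name})")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def has_backbone(self) -> bool:
        return all(self.has_atom(n) for n in ("N", "CA", "C"))

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class LigandGroup:
    """A hetero group (one residue's worth of HETATM records)."""

    name: str
    chain: str
    seqnum: int
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def group_id(self) -> str:
        return f"{self.name}_{self.chain}{self.seqnum}"


@dataclass
class ProteinStructure:
    source_id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[LigandGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate residue keys in {self.source_id}")

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"residue {key} not found in {self.source_id}")

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues}

    def protein_atoms(self) -> list[tuple[ResidueKey, AtomRecord]]:
        return [(r.key, a) for r in self.residues for a in r.atoms]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """A deep copy with all coordinates mapped through x -> R x + t."""
        out = copy.deepcopy(self)
        for res in out.residues:
            for a in res.atoms:
                a.coords = rotation @ a.coords + translation
        for lig in out.ligands:
            for a in lig.atoms:
                a.coords = rotation @ a.coords + translation
        return out


@dataclass
class LigandEnsemble:
    """Union of ligand heavy atoms from superposed holo structures,
    expressed in the template frame. Empty means apo-template mode."""

    atoms: list[tuple[str, AtomRecord]] = field(default_factory=list)

    @property
    def apo_mode(self) -> bool:
        return len(self.atoms) == 0

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for _, a in self.atoms])


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    if not el or el == "X":
        # fall back to the first alphabetic character of the atom name
        for ch in atom.name:
            if ch.isalpha():
                return ch.upper()
        return ""
    return el


def read_structure(
    path: str | Path,
    vdw_radii: dict[str, float] | None = None,
    ion_names: tuple[str, ...] = RunConfig().ion_names,
) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Takes model 1 of multi-model files; discards hydrogens, waters and
    configured ions; resolves altlocs to the highest-occupancy copy (ties
    broken by file order); assigns vdW radii by element. Unknown elements
    raise, naming the offending atom.
    """
    if vdw_radii is None:
        vdw_radii = load_vdw_radii()
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    residues: list[Residue] = []
    ligands: list[LigandGroup] = []
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES:
                continue
            picked: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                if atom.name not in picked:
                    picked[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > picked[atom.name].occ:
                    picked[atom.name] = atom
            atoms: list[AtomRecord] = []
            for name in order:
                atom = picked[name]
                el = _element_of(atom)
                if el not in vdw_radii:
                    raise ValueError(
                        f"{path}: unknown element {el!r} for atom {name} "
                        f"in residue {res.name} {chain.name}{res.seqid.num}"
                    )
                atoms.append(
                    AtomRecord(
                        name=name,
                        element=el,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        vdw_radius=vdw_radii[el],
                        is_backbone=name in BACKBONE_ATOMS,
                        occupancy=atom.occ,
                    )
                )
            if not atoms:
                continue
            is_het = res.het_flag == "H"
            if is_het and res.name in ion_names:
                continue
            if is_het:
                ligands.append(
                    LigandGroup(name=res.name, chain=chain.name, seqnum=res.seqid.num, atoms=atoms)
                )
            else:
                icode = res.seqid.icode.strip()
                residues.append(
                    Residue(chain=chain.name, seqnum=res.seqid.num, icode=icode, name=res.name, atoms=atoms)
                )
    return ProteinStructure(source_id=Path(path).stem, residues=residues, ligands=ligands)


def validate_flexible(structure: ProteinStructure, keys: list[ResidueKey]) -> None:
    """Residues subject to rotamer placement must have a full N/CA/C backbone."""
    rmap = structure.residue_map()
    for key in keys:
        if key not in rmap:
            raise KeyError(f"residue {key} not in structure {structure.source_id}")
        if not rmap[key].has_backbone():
            raise ValueError(
                f"residue {key} ({rmap[key].name}) lacks backbone atoms required for flexibility"
            )


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a minimal, deterministic PDB file (ATOM/HETATM/TER/END)."""
    lines: list[str] = []
    serial = 1

    def fmt(record: str, atom: AtomRecord, resname: str, chain: str, seqnum: int, icode: str) -> str:
        nonlocal serial
        name = atom.name
        # PDB atom-name column convention: element right-aligned in cols 13-14
        if len(name) < 4 and len(atom.element) == 1:
            name = f" {name}"
        x, y, z = atom.coords
        line = (
            f"{record:<6}{serial:>5} {name:<4} {resname:<3} {chain:>1}"
            f"{seqnum:>4}{icode or ' ':>1}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2}"
        )
        serial += 1
        return line

    for res in structure.residues:
        for atom in res.atoms:
            lines.append(fmt("ATOM", atom, res.name, res.chain, res.seqnum, res.icode))
    if structure.residues:
        lines.append(f"TER   {serial:>5}")
        serial += 1
    for lig in structure.ligands:
        for atom in lig.atoms:
            lines.append(fmt("HETATM", atom, lig.name, lig.chain, lig.seqnum, ""))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def superpose_backbone(
    mobile: ProteinStructure, template: ProteinStructure
) -> SuperpositionResult:
    """Least-squares rigid superposition on Calpha atoms matched by residue key."""
    tmap = template.residue_map()
    P, Q = [], []
    for res in mobile.residues:
        if res.key in tmap and res.has_atom("CA") and tmap[res.key].has_atom("CA"):
            P.append(res.atom("CA").coords)
            Q.append(tmap[res.key].atom("CA").coords)
    if len(P) < 3:
        raise ValueError(
            f"only {len(P)} Calpha pairs matched between {mobile.source_id} "
            f"and {template.source_id}; need >= 3"
        )
    R, t, rmsd = kabsch(np.array(P), np.array(Q))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_matched=len(P))


def superpose_all(
    structures: list[ProteinStructure],
    template: ProteinStructure,
    rmsd_max: float = 1.0,
) -> list[ProteinStructure]:
    """Superpose every structure onto the template, dropping backbone outliers.

    A mobile structure whose Calpha rmsd after superposition exceeds
    ``rmsd_max`` is excluded with a warning (the fixed-backbone assumption
    does not hold for it).
    """
    out: list[ProteinStructure] = []
    for st in structures:
        result = superpose_backbone(st, template)
        if result.rmsd > rmsd_max:
            warnings.warn(
                f"{st.source_id}: Calpha rmsd {result.rmsd:.3f} A exceeds "
                f"{rmsd_max:.3f} A; dropped as a backbone outlier"
            )
            continue
        out.append(st.transformed(result.rotation, result.translation))
    return out


def build_ligand_ensemble(structures: list[ProteinStructure]) -> LigandEnsemble:
    """Union of all ligand heavy atoms over superposed structures.

    Provenance (source structure id) is retained per atom. An empty
    ensemble (no holo structure) is returned with a warning: apo-template
    mode, where first-layer residues must be supplied manually.
    """
    atoms: list[tuple[str, AtomRecord]] = []
    for st in structures:
        for lig in st.ligands:
            for a in lig.atoms:
                atoms.append((f"{st.source_id}:{lig.group_id}", a))
    if not atoms:
        warnings.warn("no ligands found in any structure: apo-template mode")
    return LigandEnsemble(atoms=atoms)


def select_flr(
    template: ProteinStructure, ensemble: LigandEnsemble, cutoff: float = 5.0
) -> list[ResidueKey]:
    """First-layer residues: any residue with an atom within ``cutoff`` of
    the ligand ensemble. Sorted by residue key."""
    if ensemble.apo_mode:
        raise ValueError(
            "empty ligand ensemble: select first-layer residues manually in apo mode"
        )
    from scipy.spatial import cKDTree

    tree = cKDTree(ensemble.coords())
    selected: set[ResidueKey] = set()
    for res in template.residues:
        d, _ = tree.query(res.coords(), k=1)
        if np.min(d) <= cutoff:
            selected.add(res.key)
    if not selected:
        raise ValueError(
            "no residues within cutoff of the ligand ensemble; "
            "check the superposition or the cutoff"
        )
    return sorted(selected)


def build_cb(res: Residue) -> np.ndarray:
    """Ideal tetrahedral Cbeta position from the N/CA/C backbone."""
    n = res.atom("N").coords
    ca = res.atom("CA").coords
    c = res.atom("C").coords
    return place_atom(c, n, ca, CB_BOND, CB_ANGLE, CB_TORSION)


def ala_substitute(
    structure: ProteinStructure,
    keys: list[ResidueKey],
    vdw_radii: dict[str, float] | None = None,
) -> ProteinStructure:
    """Substitute the listed residues with Ala (Gly left unchanged).

    Side-chain atoms beyond Cbeta are removed; a missing Cbeta is rebuilt at
    ideal tetrahedral geometry. Pro is substituted like any other residue.
    The input structure is not modified.
    """
    if vdw_radii is None:
        vdw_radii = load_vdw_radii()
    out = copy.deepcopy(structure)
    rmap = out.residue_map()
    for key in keys:
        res = rmap[key]
        if res.name == "GLY":
            continue
        if not res.has_backbone():
            raise ValueError(f"residue {key} lacks backbone atoms; cannot substitute")
        kept = [a for a in res.atoms if a.name in BACKBONE_ATOMS or a.name == "CB"]
        if not any(a.name == "CB" for a in kept):
            kept.append(
                AtomRecord(
                    name="CB",
                    element="C",
                    coords=build_cb(res),
                    vdw_radius=vdw_radii["C"],
                    is_backbone=False,
                )
            )
        res.atoms = kept
        res.name = "ALA"
    return out


def write_flr_tsv(keys: list[ResidueKey], structure: ProteinStructure, path: str | Path) -> None:
    rmap = structure.residue_map()
    lines = ["chain\tseqnum\ticode\tresname"]
    for key in keys:
        chain, seqnum, icode = key
        lines.append(f"{chain}\t{seqnum}\t{icode}\t{rmap[key].name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_residue_keys_tsv(path: str | Path) -> list[ResidueKey]:
    keys: list[ResidueKey] = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        chain, seqnum, icode = line.split("\t")[:3]
        keys.append((chain, int(seqnum), icode))
    return keys
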