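"""Rotamer library handling, side-chain construction and steric clash tests.

A rotamer is a tuple of chi dihedral angles for one residue type. Side
chains are rebuilt from the fixed backbone by sequential internal-coordinate
placement using the ideal-geometry tables in :mod:`sidechain_tables`;
chi angles of the rebuilt side chain reproduce the inputs exactly (NeRF
construction). Rotamers whose side chains clash with the rigid environment
are removed before combinatorial search (Gly and Ala have no chi angles and
are never flexible).

The clash criterion is the soft van der Waals overlap test: two atoms clash
iff d < r1 + r2 - CTD, with the clash tolerance distance CTD defaulting to
1.0 A. Atom pairs separated by three or fewer bonds within the same residue
are exempt, as usual for 1-2/1-3/1-4 interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .config import ClashParams, load_vdw_radii
from .geometry import dihedral, place_atom
from .sidechain_tables import (
    CHI_COUNTS,
    CHI_DEFS,
    RIGID_TYPES,
    SIDECHAIN_TOPOLOGY,
    bond_distances,
)
from .structure import AtomRecord, ProteinStructure, Residue, ResidueKey, build_cb


@dataclass(frozen=True)
class Rotamer:
    chi: tuple[float, ...]
    probability: float | None = None


@dataclass
class RotamerLibrary:
    """Backbone-independent rotamer library: residue type -> ordered rotamers."""

    rotamers: dict[str, list[Rotamer]] = field(default_factory=dict)

    def __getitem__(self, resname: str) -> list[Rotamer]:
        return self.rotamers[resname]

    def __contains__(self, resname: str) -> bool:
        return resname in self.rotamers

    @property
    def n_rotamers(self) -> int:
        return sum(len(v) for v in self.rotamers.values())


@dataclass
class RotamerPlacement:
    """One rotamer's side-chain atoms (beyond Cbeta) built in the template frame."""

    residue_key: ResidueKey
    resname: str
    rotamer_index: int
    atoms: list[AtomRecord]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees to (-180, 180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    if a == -180.0:
        a = 180.0
    return a


def load_rotamer_library(path: str | Path) -> RotamerLibrary:
    """Parse a TSV rotamer library.

    Columns: residue_name, rotamer_id, chi1..chi4 (unused chis blank or
    ``NA``), optional probability. Lines starting with ``#`` and the header
    are skipped. Angles are normalized to (-180, 180]. The chi count of
    every row must match the residue type.
    """
    lib: dict[str, list[Rotamer]] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "residue_name":
            continue
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}")
        resname = fields[0].upper()
        if resname not in CHI_COUNTS:
            raise ValueError(f"{path}:{lineno}: unknown residue type {resname!r}")
        chi_fields = fields[2:6]
        chis: list[float] = []
        for cf in chi_fields:
            cf = cf.strip()
            if cf in ("", "NA", "-"):
                break
            try:
                chis.append(normalize_angle(float(cf)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad chi value {cf!r}") from exc
        if len(chis) != CHI_COUNTS[resname]:
            raise ValueError(
                f"{path}:{lineno}: {resname} needs {CHI_COUNTS[resname]} chi angles, "
                f"got {len(chis)}"
            )
        prob = None
        if len(fields) >= 7 and fields[6].strip() not in ("", "NA"):
            prob = float(fields[6])
        lib.setdefault(resname, []).append(Rotamer(chi=tuple(chis), probability=prob))
    return RotamerLibrary(rotamers=lib)


def write_rotamer_library(library: RotamerLibrary, path: str | Path) -> None:
    lines = ["residue_name\trotamer_id\tchi1\tchi2\tchi3\tchi4\tprobability"]
    for resname in sorted(library.rotamers):
        for i, rot in enumerate(library.rotamers[resname]):
            chis = [f"{c:.1f}" for c in rot.chi] + [""] * (4 - len(rot.chi))
            prob = "" if rot.probability is None else f"{rot.probability:.4f}"
            lines.append(f"{resname}\t{i}\t" + "\t".join(chis) + f"\t{prob}")
    Path(path).write_text("\n".join(lines) + "\n")


def apply_rotamer(
    residue: Residue,
    resname: str,
    chi: tuple[float, ...],
    rotamer_index: int = -1,
    vdw_radii: dict[str, float] | None = None,
) -> RotamerPlacement:
    """Build the side chain (beyond Cbeta) for the given chi angles.

    The backbone N/CA/C and Cbeta anchor the construction; Cbeta is taken
    from the residue if present, else rebuilt at ideal geometry. Atoms are
    placed sequentially by internal coordinates, so the measured chi
    dihedrals of the result equal the inputs.
    """
    if resname not in SIDECHAIN_TOPOLOGY:
        raise ValueError(f"unknown or rigid residue type {resname!r}")
    if len(chi) != CHI_COUNTS[resname]:
        raise ValueError(
            f"{resname} needs {CHI_COUNTS[resname]} chi angles, got {len(chi)}"
        )
    if vdw_radii is None:
        vdw_radii = load_vdw_radii()
    placed: dict[str, np.ndarray] = {
        "N": residue.atom("N").coords,
        "CA": residue.atom("CA").coords,
        "C": residue.atom("C").coords,
    }
    placed["CB"] = residue.atom("CB").coords if residue.has_atom("CB") else build_cb(residue)
    atoms: list[AtomRecord] = []
    for atom, element, parent, angle_ref, torsion_ref, bond, angle, tors in SIDECHAIN_TOPOLOGY[resname]:
        if tors[0] == "chi":
            _, idx, offset = tors
            torsion = chi[idx - 1] + offset
        else:
            torsion = tors[1]
        coords = place_atom(
            placed[torsion_ref], placed[angle_ref], placed[parent], bond, angle, torsion
        )
        placed[atom] = coords
        atoms.append(
            AtomRecord(
                name=atom,
                element=element,
                coords=coords,
                vdw_radius=vdw_radii[element],
                is_backbone=False,
            )
        )
    return RotamerPlacement(
        residue_key=residue.key, resname=resname, rotamer_index=rotamer_index, atoms=atoms
    )


def measure_chi(residue: Residue) -> tuple[float, ...]:
    """Measure the chi dihedrals of a residue from its atom coordinates."""
    if residue.name not in CHI_DEFS:
        return ()
    values = []
    for quad in CHI_DEFS[residue.name]:
        coords = [residue.atom(name).coords for name in quad]
        values.append(dihedral(*coords))
    return tuple(values)


def clash(a1: AtomRecord, a2: AtomRecord, params: ClashParams) -> bool:
    """Soft steric clash: d < r1 + r2 - CTD."""
    d = float(np.linalg.norm(a1.coords - a2.coords))
    return d < a1.vdw_radius + a2.vdw_radius - params.ctd


@dataclass
class _FixedEnvironment:
    """KD-tree over the rigid atoms a rotamer must not clash with."""

    coords: np.ndarray
    radii: np.ndarray
    keys: list[ResidueKey]
    names: list[str]
    tree: cKDTree
    max_radius: float


def build_fixed_environment(
    structure: ProteinStructure, slr_keys: list[ResidueKey]
) -> _FixedEnvironment:
    """Rigid atoms for clash pre-filtering: every backbone atom plus the
    full side chains of non-flexible residues, plus Cbeta of the flexible
    residues themselves."""
    slr = set(slr_keys)
    coords, radii, keys, names = [], [], [], []
    for res in structure.residues:
        for a in res.atoms:
            if res.key in slr and not a.is_backbone and a.name != "CB":
                continue
            coords.append(a.coords)
            radii.append(a.vdw_radius)
            keys.append(res.key)
            names.append(a.name)
    arr = np.array(coords)
    return _FixedEnvironment(
        coords=arr,
        radii=np.array(radii),
        keys=keys,
        names=names,
        tree=cKDTree(arr),
        max_radius=float(np.max(radii)),
    )


def _clashes_fixed(
    placement: RotamerPlacement, env: _FixedEnvironment, params: ClashParams
) -> bool:
    dists = bond_distances(placement.resname)
    for atom in placement.atoms:
        reach = atom.vdw_radius + env.max_radius - params.ctd
        if reach <= 0:
            continue
        for j in env.tree.query_ball_point(atom.coords, reach):
            if (
                env.keys[j] == placement.residue_key
                and dists.get(atom.name, {}).get(env.names[j], 99) <= 3
            ):
                continue  # 1-2/1-3/1-4 exclusion within the residue
            d = float(np.linalg.norm(atom.coords - env.coords[j]))
            if d < atom.vdw_radius + env.radii[j] - params.ctd:
                return True
    return False


def prefilter_rotamers(
    library: RotamerLibrary,
    structure: ProteinStructure,
    slr_keys: list[ResidueKey],
    params: ClashParams,
    vdw_radii: dict[str, float] | None = None,
) -> dict[ResidueKey, list[RotamerPlacement]]:
    """Place every library rotamer on every flexible residue and keep the
    ones that do not clash with the rigid environment.

    Returns, per residue (sorted by key), the surviving placements in
    library order; the placement's ``rotamer_index`` is the library index.
    A residue with zero surviving rotamers is a hard error — the pocket
    cannot be enumerated.
    """
    if vdw_radii is None:
        vdw_radii = load_vdw_radii()
    rmap = structure.residue_map()
    env = build_fixed_environment(structure, slr_keys)
    out: dict[ResidueKey, list[RotamerPlacement]] = {}
    for key in sorted(slr_keys):
        res = rmap[key]
        if res.name in RIGID_TYPES:
            raise ValueError(f"residue {key} ({res.name}) has no rotamers")
        if res.name not in library:
            raise ValueError(f"no rotamers for type {res.name} (residue {key}) in library")
        survivors: list[RotamerPlacement] = []
        for i, rot in enumerate(library[res.name]):
            placement = apply_rotamer(res, res.name, rot.chi, rotamer_index=i, vdw_radii=vdw_radii)
            if not _clashes_fixed(placement, env, params):
                survivors.append(placement)
        if not survivors:
            raise ValueError(
                f"residue {key} ({res.name}): all rotamers clash with the fixed "
                "structure; the pocket cannot be built"
            )
        out[key] = survivors
    return out


def conformer_structure(
    template: ProteinStructure,
    placements: dict[ResidueKey, RotamerPlacement],
) -> ProteinStructure:
    """A full-atom copy of the template with each flexible residue's side
    chain replaced by the given placement (for PDB export of individual
    conformers or cluster medoids)."""
    import copy

    out = copy.deepcopy(template)
    rmap = out.residue_map()
    for key, placement in placements.items():
        res = rmap[key]
        res.atoms = [
            a for a in res.atoms if a.is_backbone or a.name == "CB"
        ] + copy.deepcopy(placement.atoms)
    return out
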