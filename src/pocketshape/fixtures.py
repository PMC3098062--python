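"""Deterministic synthetic test systems.

``make_toy_system`` builds a concave binding pocket from scratch: a
spherical-shell wall of rigid pseudo-residues (Gly blobs) with an opening
toward +z, a ring of flexible Leu residues on the rim whose side chains
hang into the cavity, and one or more small rigid carbon ligands placed
inside the pocket near the flexible side chains. Together with a mini
rotamer library this exercises every pipeline stage — first-layer
selection, Ala substitution, lattice generation, rotamer pre-filtering,
conformer enumeration, encoding, clustering and ligand scoring — without
any external input.

The construction is purely analytic plus a seeded RNG for small jitters,
so the same spec and seed reproduce byte-identical PDB output.

``make_planted_clusters`` generates bit-string collections with known
cluster structure for validating the clustering stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bitmap import ShapeBitString
from .config import load_vdw_radii
from .geometry import place_atom
from .rotamers import Rotamer, RotamerLibrary, apply_rotamer, write_rotamer_library
from .structure import (
    AtomRecord,
    LigandGroup,
    ProteinStructure,
    Residue,
    write_structure,
)

# Regular tetrahedron vertex directions (unit vectors).
_TET = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)

# Mini backbone-independent library: chi tuples per residue type, in
# preference order. Values are common staggered/ring-fit combinations.
_MINI_LIBRARY_CHI: dict[str, list[tuple[float, ...]]] = {
    "LEU": [(-60.0, 160.0), (-120.0, 80.0), (80.0, 120.0), (-60.0, 180.0)],
    "SER": [(-65.0,), (65.0,), (180.0,)],
    "VAL": [(175.0,), (-60.0,), (60.0,)],
    "TYR": [(-65.0, 90.0), (180.0, 80.0), (60.0, 90.0)],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the toy system. Same spec + seed -> identical output."""

    n_flexible_residues: int = 4
    pocket_depth: float = 7.0        # shell radius; cavity depth ~ this value, A
    lattice_extent: float = 6.0      # trim padding the system is designed for, A
    rotamers_per_residue: int = 3
    ligand_size: int = 4             # heavy atoms per toy ligand
    n_ligands: int = 2
    opening_deg: float = 40.0        # polar half-angle of the pocket mouth
    flexible_type: str = "LEU"
    seed: int = 7

    def __post_init__(self) -> None:
        if not (1 <= self.n_flexible_residues <= 12):
            raise ValueError("n_flexible_residues must be in 1..12")
        if self.pocket_depth < 5.0:
            raise ValueError("pocket too shallow to fit side chains and a ligand")
        if self.rotamers_per_residue < 1 or self.ligand_size < 1 or self.n_ligands < 1:
            raise ValueError("all fixture sizes must be positive")
        if self.rotamers_per_residue > len(_MINI_LIBRARY_CHI[self.flexible_type]):
            raise ValueError(
                f"at most {len(_MINI_LIBRARY_CHI[self.flexible_type])} rotamers "
                f"available for {self.flexible_type}"
            )


def _fibonacci_shell(radius: float, max_z_frac: float, spacing: float) -> np.ndarray:
    """Quasi-uniform points on a sphere, keeping z <= max_z_frac * radius."""
    n = max(8, int(4.0 * np.pi * radius**2 / spacing**2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    theta = golden * i
    pts = radius * np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    return pts[pts[:, 2] <= max_z_frac * radius]


def _rotation_to(u: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotation mapping ``reference`` onto ``u`` (Rodrigues)."""
    a = reference / np.linalg.norm(reference)
    b = u / np.linalg.norm(u)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _wall_residue(center: np.ndarray, index: int, radii: dict[str, float], rng) -> Residue:
    """A rigid Gly pseudo-residue: a compact 4-atom blob around ``center``."""
    rot = _rotation_to(center / np.linalg.norm(center), np.array([0.0, 0.0, 1.0]))
    offsets = 0.45 * (_TET @ rot.T)
    jitter = rng.uniform(-0.05, 0.05, size=(4, 3))
    names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
    atoms = [
        AtomRecord(
            name=nm,
            element=el,
            coords=center + offsets[i] + jitter[i],
            vdw_radius=radii[el],
            is_backbone=True,
        )
        for i, (nm, el) in enumerate(names)
    ]
    return Residue(chain="A", seqnum=index, icode="", name="GLY", atoms=atoms)


def _flexible_residue(
    seqnum: int,
    azimuth: float,
    spec: FixtureSpec,
    library: RotamerLibrary,
    radii: dict[str, float],
) -> Residue:
    """A flexible residue on the rim, side chain built at library rotamer 0.

    All flexible residues share one construction rotated about z, so the
    same chi values behave identically at every position.
    """
    R = spec.pocket_depth
    theta = np.radians(57.0)  # polar angle of the rim seat
    ca = R * np.array(
        [np.sin(theta) * np.cos(azimuth), np.sin(theta) * np.sin(azimuth), np.cos(theta)]
    )
    target = np.array([0.0, 0.0, 0.5])
    u = target - ca
    u /= np.linalg.norm(u)
    rot = _rotation_to(u, _TET[0])
    # local tetrahedral frame, co-rotating with the azimuth
    spin = np.cross(np.array([0.0, 0.0, 1.0]), u)
    spin /= np.linalg.norm(spin)
    # align the second tetrahedral arm's projection with the azimuthal tangent
    arm2 = rot @ _TET[1]
    proj = arm2 - np.dot(arm2, u) * u
    align = _rotation_to(spin, proj / np.linalg.norm(proj))
    frame = align @ rot
    n_dir, c_dir = frame @ _TET[1], frame @ _TET[2]
    n_pos = ca + 1.46 * n_dir
    c_pos = ca + 1.52 * c_dir
    cb_pos = ca + 1.53 * u
    o_pos = place_atom(n_pos, ca, c_pos, 1.23, 120.8, 0.0)
    atoms = [
        AtomRecord("N", "N", n_pos, radii["N"], is_backbone=True),
        AtomRecord("CA", "C", ca, radii["C"], is_backbone=True),
        AtomRecord("C", "C", c_pos, radii["C"], is_backbone=True),
        AtomRecord("O", "O", o_pos, radii["O"], is_backbone=True),
        AtomRecord("CB", "C", cb_pos, radii["C"], is_backbone=False),
    ]
    res = Residue(chain="A", seqnum=seqnum, icode="", name=spec.flexible_type, atoms=atoms)
    placement = apply_rotamer(
        res, spec.flexible_type, library[spec.flexible_type][0].chi, rotamer_index=0,
        vdw_radii=radii,
    )
    res.atoms.extend(placement.atoms)
    return res


def make_mini_library(spec: FixtureSpec) -> RotamerLibrary:
    """A small backbone-independent rotamer library for the fixture types."""
    lib: dict[str, list[Rotamer]] = {}
    for resname, chis in _MINI_LIBRARY_CHI.items():
        k = min(spec.rotamers_per_residue, len(chis))
        lib[resname] = [Rotamer(chi=c) for c in chis[:k]]
    return RotamerLibrary(rotamers=lib)


def make_toy_system(
    spec: FixtureSpec,
) -> tuple[ProteinStructure, RotamerLibrary, list[LigandGroup]]:
    """Build the toy scaffold, its mini rotamer library and toy ligands.

    The scaffold is a spherical-shell cup (opening toward +z) of rigid Gly
    blobs, with ``n_flexible_residues`` flexible residues seated on the rim
    whose side chains reach into the cavity. Ligand atoms are distributed
    azimuthally so that every flexible residue has a ligand atom within
    the 5 A first-layer cutoff.
    """
    rng = np.random.default_rng(spec.seed)
    radii = load_vdw_radii()
    library = make_mini_library(spec)
    R = spec.pocket_depth
    max_z = float(np.cos(np.radians(spec.opening_deg)))

    n_flex = spec.n_flexible_residues
    azimuths = [2.0 * np.pi * i / n_flex for i in range(n_flex)]
    flex_cas = [
        R * np.array(
            [np.sin(np.radians(57.0)) * np.cos(a), np.sin(np.radians(57.0)) * np.sin(a),
             np.cos(np.radians(57.0))]
        )
        for a in azimuths
    ]

    # the side chain roots: carve wall material around both CA and CB so a
    # reasonable spread of rotamers stays clash-free
    flex_cbs = []
    for ca in flex_cas:
        u = np.array([0.0, 0.0, 0.5]) - ca
        u /= np.linalg.norm(u)
        flex_cbs.append(ca + 1.53 * u)

    shell = _fibonacci_shell(R, max_z, spacing=2.3)
    residues: list[Residue] = []
    seq = 1
    for pt in shell:
        if any(np.linalg.norm(pt - ca) < 4.0 for ca in flex_cas):
            continue  # carve a seat for the flexible residues
        if any(np.linalg.norm(pt - cb) < 4.0 for cb in flex_cbs):
            continue
        residues.append(_wall_residue(pt, seq, radii, rng))
        seq += 1

    flex_keys = []
    for i, a in enumerate(azimuths):
        res = _flexible_residue(100 + i, a, spec, library, radii)
        residues.append(res)
        flex_keys.append(res.key)

    ligands: list[LigandGroup] = []
    atom_counter = 0
    for j in range(spec.n_ligands):
        atoms = []
        for i in range(spec.ligand_size):
            az = azimuths[atom_counter % n_flex] + rng.uniform(-0.15, 0.15)
            rho = 1.0 + 0.25 * (atom_counter % 2)
            z = 1.0 - 0.8 * i
            xyz = np.array([rho * np.cos(az), rho * np.sin(az), z])
            atoms.append(AtomRecord(f"C{i + 1}", "C", xyz, radii["C"], is_backbone=False))
            atom_counter += 1
        ligands.append(LigandGroup(name=f"LG{j + 1}", chain="L", seqnum=201 + j, atoms=atoms))

    structure = ProteinStructure(source_id=f"toy_seed{spec.seed}", residues=residues)
    if not structure.residues:
        raise ValueError("fixture spec produced an empty scaffold")
    return structure, library, ligands


def make_holo_structures(
    template: ProteinStructure,
    ligands: list[LigandGroup],
    seed: int = 0,
) -> list[ProteinStructure]:
    """One holo copy of the template per ligand, each displaced by a random
    rigid transform (so the superposition stage has real work to do)."""
    rng = np.random.default_rng(seed)
    out = []
    for j, lig in enumerate(ligands):
        holo = ProteinStructure(
            source_id=f"{template.source_id}_holo{j + 1}",
            residues=[],
            ligands=[],
        )
        import copy as _copy

        holo.residues = _copy.deepcopy(template.residues)
        holo.ligands = [_copy.deepcopy(lig)]
        # random proper rotation (QR of a Gaussian matrix) + translation
        A = rng.normal(size=(3, 3))
        Q, Rm = np.linalg.qr(A)
        Q = Q @ np.diag(np.sign(np.diag(Rm)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        t = rng.uniform(-5.0, 5.0, size=3)
        holo = holo.transformed(Q, t)
        holo.source_id = f"{template.source_id}_holo{j + 1}"
        out.append(holo)
    return out


def materialize(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the toy system to disk: apo template PDB, one holo PDB per
    ligand, and the mini rotamer library TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template, library, ligands = make_toy_system(spec)
    paths: dict[str, Path] = {}
    template_path = outdir / "template.pdb"
    write_structure(template, template_path)
    paths["template"] = template_path
    for j, holo in enumerate(make_holo_structures(template, ligands, seed=spec.seed)):
        p = outdir / f"holo_{j + 1}.pdb"
        write_structure(holo, p)
        paths[f"holo_{j + 1}"] = p
    lib_path = outdir / "library.tsv"
    write_rotamer_library(library, lib_path)
    paths["library"] = lib_path
    return paths


def make_planted_clusters(
    n_strings: int,
    n_bits: int,
    k: int,
    noise_bits: int,
    seed: int,
    max_tries: int = 10000,
) -> tuple[list[ShapeBitString], np.ndarray]:
    """Bit strings with planted cluster structure and ground-truth labels.

    ``k`` random centers are drawn with pairwise Hamming distance at least
    ``4 * noise_bits`` (rejection sampling); each member is its cluster
    center with at most ``noise_bits`` random bit flips. Cluster sizes are
    as equal as possible. Labels are returned alongside the strings.
    """
    if k > n_strings:
        raise ValueError("k cannot exceed n_strings")
    rng = np.random.default_rng(seed)
    min_sep = 4 * noise_bits
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < k:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {k} centers with pairwise Hamming >= {min_sep} "
                f"in {n_bits} bits"
            )
        cand = rng.integers(0, 2, size=n_bits).astype(np.uint8)
        if all(int(np.sum(cand != c)) >= min_sep for c in centers):
            centers.append(cand)
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            assert int(np.sum(centers[a_i] != centers[b_i])) >= min_sep

    strings: list[ShapeBitString] = []
    labels = np.zeros(n_strings, dtype=int)
    for i in range(n_strings):
        c = i % k
        bits = centers[c].copy()
        n_flips = int(rng.integers(0, noise_bits + 1)) if noise_bits > 0 else 0
        if n_flips:
            pos = rng.choice(n_bits, size=n_flips, replace=False)
            bits[pos] ^= 1
        strings.append(ShapeBitString(bits=bits, conformer_ids=[i]))
        labels[i] = c + 1
    return strings, labels
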