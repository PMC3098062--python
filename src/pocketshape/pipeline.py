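"""Staged pipeline driver.

Each stage reads the previous stage's serialized outputs from a workspace
directory and writes its own, so stages can be run standalone (via the CLI
subcommands) or chained by :func:`run_pipeline` with byte-identical
results. The stage order is:

    superpose -> pocket -> enumerate -> encode -> cluster -> compat -> report

All outputs are plain-text TSV/JSON/PDB with fixed formatting and no
timestamps, so a rerun with the same inputs and config reproduces the
output directory byte for byte. The config snapshot is written into the
workspace for provenance and reread by every stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import bitmap, clustering, grid, ligand as ligand_mod, rotamers, search, structure
from .config import RunConfig
from .grid import Lattice


def _workspace(workdir: str | Path) -> Path:
    p = Path(workdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def init_workspace(
    workdir: str | Path,
    config: RunConfig,
    template: str | Path,
    holos: list[str | Path],
    library: str | Path,
) -> Path:
    """Record the config snapshot and input paths."""
    ws = _workspace(workdir)
    (ws / "config.txt").write_text(config.to_text())
    lines = [f"template\t{Path(template).resolve()}"]
    for h in holos:
        lines.append(f"holo\t{Path(h).resolve()}")
    lines.append(f"library\t{Path(library).resolve()}")
    (ws / "inputs.txt").write_text("\n".join(lines) + "\n")
    return ws


def _read_inputs(ws: Path) -> tuple[RunConfig, Path, list[Path], Path]:
    config = RunConfig.from_text((ws / "config.txt").read_text())
    template = None
    holos: list[Path] = []
    library = None
    for line in (ws / "inputs.txt").read_text().splitlines():
        kind, path = line.split("\t")
        if kind == "template":
            template = Path(path)
        elif kind == "holo":
            holos.append(Path(path))
        elif kind == "library":
            library = Path(path)
    if template is None or library is None:
        raise ValueError("workspace inputs.txt lacks template or library")
    return config, template, holos, library


# ---------------------------------------------------------------- superpose

def stage_superpose(workdir: str | Path) -> None:
    """Superpose holo structures onto the template; build the ligand
    ensemble and select first-layer residues."""
    ws = Path(workdir)
    config, template_path, holo_paths, _ = _read_inputs(ws)
    radii = structure_radii(config)
    template = structure.read_structure(template_path, radii, config.ion_names)
    holos = [structure.read_structure(p, radii, config.ion_names) for p in holo_paths]
    rmsd_lines = ["source_id\trmsd\tn_matched\tkept"]
    kept = []
    for h in holos:
        res = structure.superpose_backbone(h, template)
        keep = res.rmsd <= config.superpose_rmsd_max
        rmsd_lines.append(f"{h.source_id}\t{res.rmsd:.6f}\t{res.n_matched}\t{int(keep)}")
        if keep:
            moved = h.transformed(res.rotation, res.translation)
            kept.append(moved)
            structure.write_structure(moved, ws / f"superposed_{h.source_id}.pdb")
    (ws / "superpose_rmsd.tsv").write_text("\n".join(rmsd_lines) + "\n")
    ensemble = structure.build_ligand_ensemble(kept)
    ens_lines = ["source\tatom\telement\tx\ty\tz\tvdw"]
    for src, a in ensemble.atoms:
        x, y, z = a.coords
        ens_lines.append(
            f"{src}\t{a.name}\t{a.element}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{a.vdw_radius:.3f}"
        )
    (ws / "ensemble.tsv").write_text("\n".join(ens_lines) + "\n")
    flr = structure.select_flr(template, ensemble, config.flr_cutoff)
    structure.write_flr_tsv(flr, template, ws / "flr.tsv")


def structure_radii(config: RunConfig) -> dict[str, float]:
    from .config import load_vdw_radii

    return load_vdw_radii(config.vdw_table)


def _read_ensemble(ws: Path, config: RunConfig) -> structure.LigandEnsemble:
    atoms = []
    for line in (ws / "ensemble.tsv").read_text().splitlines()[1:]:
        if not line.strip():
            continue
        src, name, el, x, y, z, r = line.split("\t")
        atoms.append(
            (
                src,
                structure.AtomRecord(
                    name=name, element=el, coords=np.array([float(x), float(y), float(z)]),
                    vdw_radius=float(r),
                ),
            )
        )
    return structure.LigandEnsemble(atoms=atoms)


# ------------------------------------------------------------------- pocket

def stage_pocket(workdir: str | Path) -> None:
    """Ala-substitute the first layer, lay the lattice, select the second
    layer."""
    ws = Path(workdir)
    config, template_path, _, _ = _read_inputs(ws)
    radii = structure_radii(config)
    template = structure.read_structure(template_path, radii, config.ion_names)
    flr = structure.read_residue_keys_tsv(ws / "flr.tsv")
    ensemble = _read_ensemble(ws, config)
    ala = structure.ala_substitute(template, flr, radii)
    structure.write_structure(ala, ws / "ala_template.pdb")
    lattice = grid.generate_pocket_points(
        ala,
        ensemble,
        flr,
        spacing=config.spacing,
        trim_cutoff=config.trim_cutoff,
        psp_min=config.psp_min_directions,
        psp_range=config.psp_range,
    )
    lines = ["id\ti\tj\tk\tx\ty\tz"]
    for pid, (t, xyz) in enumerate(zip(lattice.triples, lattice.coords())):
        lines.append(f"{pid}\t{t[0]}\t{t[1]}\t{t[2]}\t{xyz[0]:.3f}\t{xyz[1]:.3f}\t{xyz[2]:.3f}")
    (ws / "lattice.tsv").write_text("\n".join(lines) + "\n")
    slr = grid.select_slr(template, lattice, flr, config.contact_params(), config.slr_cutoff)
    structure.write_flr_tsv(slr, template, ws / "slr.tsv")


def _read_lattice(ws: Path, config: RunConfig) -> Lattice:
    triples = []
    for line in (ws / "lattice.tsv").read_text().splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        triples.append([int(f[1]), int(f[2]), int(f[3])])
    return Lattice(origin=np.zeros(3), spacing=config.spacing, triples=np.array(triples, int))


# ---------------------------------------------------------------- enumerate

def stage_enumerate(workdir: str | Path) -> None:
    """Pre-filter rotamers against the rigid structure, build the
    interaction graph and enumerate all clash-free conformers."""
    ws = Path(workdir)
    config, template_path, _, library_path = _read_inputs(ws)
    radii = structure_radii(config)
    template = structure.read_structure(template_path, radii, config.ion_names)
    slr = structure.read_residue_keys_tsv(ws / "slr.tsv")
    structure.validate_flexible(template, slr)
    library = rotamers.load_rotamer_library(library_path)
    placements = rotamers.prefilter_rotamers(
        library, template, slr, config.clash_params(), radii
    )
    surv_lines = ["chain\tseqnum\ticode\tresname\trotamer_index\t" + "\t".join(f"chi{i}" for i in range(1, 5))]
    for key in sorted(placements):
        res = template.residue(key)
        for p in placements[key]:
            chis = library[res.name][p.rotamer_index].chi
            chi_cols = [f"{c:.1f}" for c in chis] + [""] * (4 - len(chis))
            surv_lines.append(
                f"{key[0]}\t{key[1]}\t{key[2]}\t{res.name}\t{p.rotamer_index}\t" + "\t".join(chi_cols)
            )
    (ws / "rotamers_surviving.tsv").write_text("\n".join(surv_lines) + "\n")

    graph = search.build_interaction_graph(placements, config.clash_params())
    keys = sorted(placements)
    header = "conformer_id\t" + "\t".join(f"{k[0]}:{k[1]}{k[2]}" for k in keys)
    rows = [header]
    n = 0
    for conf in search.enumerate_conformers(graph):
        lib_idx = [placements[k][conf.assignment[k]].rotamer_index for k in keys]
        rows.append(f"{conf.conformer_id}\t" + "\t".join(str(i) for i in lib_idx))
        n += 1
    assert n == search.count_conformers(graph)
    (ws / "conformers.tsv").write_text("\n".join(rows) + "\n")


def _read_conformers(ws: Path) -> tuple[list[structure.ResidueKey], list[list[int]]]:
    lines = (ws / "conformers.tsv").read_text().splitlines()
    header = lines[0].split("\t")[1:]
    keys = []
    for h in header:
        chain, rest = h.split(":")
        i = len(rest)
        while i > 0 and not rest[i - 1].isdigit():
            i -= 1
        keys.append((chain, int(rest[:i]), rest[i:]))
    assignments = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        assignments.append([int(v) for v in f[1:]])
    return keys, assignments


def _rebuild_placements(
    ws: Path, config: RunConfig
) -> dict[structure.ResidueKey, dict[int, rotamers.RotamerPlacement]]:
    """Rebuild surviving placements keyed by library rotamer index."""
    _, template_path, _, library_path = _read_inputs(ws)
    radii = structure_radii(config)
    template = structure.read_structure(template_path, radii, config.ion_names)
    library = rotamers.load_rotamer_library(library_path)
    out: dict[structure.ResidueKey, dict[int, rotamers.RotamerPlacement]] = {}
    for line in (ws / "rotamers_surviving.tsv").read_text().splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        key = (f[0], int(f[1]), f[2])
        resname = f[3]
        idx = int(f[4])
        res = template.residue(key)
        out.setdefault(key, {})[idx] = rotamers.apply_rotamer(
            res, resname, library[resname][idx].chi, rotamer_index=idx, vdw_radii=radii
        )
    return out


# ------------------------------------------------------------------- encode

def stage_encode(workdir: str | Path) -> None:
    """Encode every conformer's contact pattern, classify lattice points,
    deduplicate bit strings and merge near-identical ones."""
    ws = Path(workdir)
    config, _, _, _ = _read_inputs(ws)
    lattice = _read_lattice(ws, config)
    keys, assignments = _read_conformers(ws)
    placements = _rebuild_placements(ws, config)
    coords = lattice.coords()
    tree = cKDTree(coords)
    params = config.contact_params()

    # per (residue, library rotamer) contacted-point masks; conformer
    # contact sets are unions of these
    n_pts = lattice.n_points
    masks: dict[tuple[structure.ResidueKey, int], np.ndarray] = {}
    for key, by_idx in placements.items():
        for idx, pl in by_idx.items():
            m = np.zeros(n_pts, dtype=bool)
            hit = grid.contact_point_indices(
                np.array([a.coords for a in pl.atoms]),
                np.array([a.vdw_radius for a in pl.atoms]),
                coords,
                params,
                tree=tree,
            )
            m[hit] = True
            masks[(key, idx)] = m

    intersection = np.ones(n_pts, dtype=bool)
    union = np.zeros(n_pts, dtype=bool)
    table: dict[bytes, list[int]] = {}
    full_bits: dict[bytes, np.ndarray] = {}
    for cid, assign in enumerate(assignments):
        m = np.zeros(n_pts, dtype=bool)
        for key, idx in zip(keys, assign):
            m |= masks[(key, idx)]
        intersection &= m
        union |= m
        b = np.packbits(m).tobytes()
        if b in table:
            table[b].append(cid)
        else:
            table[b] = [cid]
            full_bits[b] = m.copy()

    points = grid.PocketPoints(
        lattice=lattice,
        always_free=np.flatnonzero(~union),
        always_contact=np.flatnonzero(intersection),
        conditional=np.flatnonzero(union & ~intersection),
    )
    grid.write_points_tsv(points, ws / "points_classified.tsv")

    # conditional-contact residues
    per_res: dict[structure.ResidueKey, set[int]] = {}
    cond_mask = np.zeros(n_pts, dtype=bool)
    cond_mask[points.conditional] = True
    for (key, idx), m in masks.items():
        per_res.setdefault(key, set()).update(np.flatnonzero(m & cond_mask).tolist())
    ccr = grid.identify_ccrs(sorted(placements), per_res)
    _, template_path, _, _ = _read_inputs(ws)
    template = structure.read_structure(template_path, structure_radii(config), config.ion_names)
    structure.write_flr_tsv(ccr, template, ws / "ccr.tsv")

    # unique strings over conditional points (always-point columns are
    # constant across conformers, so full-pattern identity == conditional
    # identity)
    strings = []
    for b, cids in table.items():
        bits = full_bits[b][points.conditional].astype(np.uint8)
        strings.append(bitmap.ShapeBitString(bits=bits, conformer_ids=sorted(cids)))
    bitmap.write_strings_tsv(strings, ws / "strings_unique.tsv")
    merged = bitmap.merge_similar(strings, config.merge_threshold)
    bitmap.write_strings_tsv(merged, ws / "strings_merged.tsv")


# ------------------------------------------------------------------ cluster

def stage_cluster(workdir: str | Path) -> None:
    """Dissimilarity matrix, MDS embedding, k-medoids partition, medoids,
    and the two-way bit ordering for heat-map export."""
    ws = Path(workdir)
    config, _, _, _ = _read_inputs(ws)
    strings = bitmap.read_strings_tsv(ws / "strings_merged.tsv")
    n = len(strings)
    if n < 2:
        (ws / "clusters.tsv").write_text(
            "string_id\tcluster\tis_medoid\n" + ("0\t1\t1\n" if n else "")
        )
        (ws / "embedding.tsv").write_text("string_id\tpc1\tpc2\tpc3\n" + ("0\t0.0\t0.0\t0.0\n" if n else ""))
        (ws / "dissimilarity.tsv").write_text("\n")
        (ws / "bit_order.tsv").write_text("leaf_order\n")
        return
    D = bitmap.dissimilarity_matrix(strings)
    header = "\t".join(str(i) for i in range(n))
    rows = ["\t" + header]
    for i in range(n):
        rows.append(str(i) + "\t" + "\t".join(f"{v:.6f}" for v in D[i]))
    (ws / "dissimilarity.tsv").write_text("\n".join(rows) + "\n")

    emb = clustering.mds_embed(D, dims=3)
    rows = ["string_id\tpc1\tpc2\tpc3"]
    for i in range(n):
        rows.append(f"{i}\t" + "\t".join(f"{v:.6f}" for v in emb[i]))
    (ws / "embedding.tsv").write_text("\n".join(rows) + "\n")

    model = clustering.assign_clusters(D, config.cluster_k, config.cluster_k_range)
    medoid_set = set(model.medoids.values())
    rows = ["string_id\tcluster\tis_medoid"]
    for i in range(n):
        rows.append(f"{i}\t{model.labels[i]}\t{int(i in medoid_set)}")
    (ws / "clusters.tsv").write_text("\n".join(rows) + "\n")

    bits = bitmap.bit_matrix(strings)
    if bits.shape[1] >= 2:
        leaf_order, _ = clustering.cluster_bits(bits)
    else:
        leaf_order = np.arange(bits.shape[1])
    (ws / "bit_order.tsv").write_text(
        "leaf_order\n" + "\n".join(str(i) for i in leaf_order) + "\n"
    )


# ------------------------------------------------------------------- compat

def stage_compat(workdir: str | Path) -> None:
    """Ligand volumes on the lattice and the string-by-ligand
    incompatibility profile, rows ordered by cluster."""
    ws = Path(workdir)
    config, _, holo_paths, _ = _read_inputs(ws)
    lattice = _read_lattice(ws, config)
    points, _cls = _read_points(ws, config)
    strings = bitmap.read_strings_tsv(ws / "strings_merged.tsv")
    ensemble = _read_ensemble(ws, config)
    tree = cKDTree(lattice.coords())
    by_ligand: dict[str, list[structure.AtomRecord]] = {}
    for src, atom in ensemble.atoms:
        by_ligand.setdefault(src, []).append(atom)
    volumes = [
        ligand_mod.encode_ligand_volume(src, atoms, lattice, config.contact_params(), tree=tree)
        for src, atoms in sorted(by_ligand.items())
    ]
    vol_rows = ["ligand_id\tn_points\tpoint_ids"]
    for v in volumes:
        ids = ",".join(str(i) for i in sorted(v.point_ids))
        vol_rows.append(f"{v.ligand_id}\t{v.n_points}\t{ids}")
    (ws / "ligand_volumes.tsv").write_text("\n".join(vol_rows) + "\n")

    profile = ligand_mod.incompatibility_profile(volumes, strings, points)
    labels = _read_cluster_labels(ws)
    order = sorted(range(len(strings)), key=lambda i: (labels[i], i)) if labels is not None else list(range(len(strings)))
    rows = ["string_id\tcluster\t" + "\t".join(v.ligand_id for v in volumes)]
    for i in order:
        lab = labels[i] if labels is not None else 1
        rows.append(f"{i}\t{lab}\t" + "\t".join(str(v) for v in profile[i]))
    (ws / "compat.tsv").write_text("\n".join(rows) + "\n")


def _read_points(ws: Path, config: RunConfig) -> tuple[grid.PocketPoints, np.ndarray]:
    triples, classes = [], []
    for line in (ws / "points_classified.tsv").read_text().splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        triples.append([int(f[1]), int(f[2]), int(f[3])])
        classes.append(int(f[7]))
    lattice = Lattice(origin=np.zeros(3), spacing=config.spacing, triples=np.array(triples, int))
    cls = np.array(classes, int)
    return (
        grid.PocketPoints(
            lattice=lattice,
            always_free=np.flatnonzero(cls == 0),
            always_contact=np.flatnonzero(cls == 2),
            conditional=np.flatnonzero(cls == 1),
        ),
        cls,
    )


def _read_cluster_labels(ws: Path) -> np.ndarray | None:
    path = ws / "clusters.tsv"
    if not path.exists():
        return None
    labels = []
    for line in path.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        labels.append(int(f[1]))
    return np.array(labels, int) if labels else None


# ------------------------------------------------------------------- report

def stage_report(workdir: str | Path) -> dict:
    """Key-residue attribution and the machine-readable run summary."""
    ws = Path(workdir)
    config, _, _, _ = _read_inputs(ws)
    strings = bitmap.read_strings_tsv(ws / "strings_merged.tsv")
    unique = bitmap.read_strings_tsv(ws / "strings_unique.tsv")
    keys, assignments = _read_conformers(ws)
    conformer_rotamers = {
        cid: dict(zip(keys, assign)) for cid, assign in enumerate(assignments)
    }
    ccr = structure.read_residue_keys_tsv(ws / "ccr.tsv")
    labels = _read_cluster_labels(ws)
    emb = []
    for line in (ws / "embedding.tsv").read_text().splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        emb.append([float(v) for v in f[1:]])
    embedding = np.array(emb) if emb else np.zeros((len(strings), 3))

    if len(strings) >= 2 and labels is not None and len(labels) == len(strings):
        report = clustering.key_residue_association(
            strings, conformer_rotamers, embedding, labels, ccr
        )
        rows = ["chain\tseqnum\ticode\teta2_pc1\teta2_pc2\teta2_pc3\tnmi\trank"]
        for rank, r in enumerate(report.ranking, start=1):
            e = report.eta_squared[r]
            rows.append(
                f"{r[0]}\t{r[1]}\t{r[2]}\t{e[0]:.6f}\t{e[1]:.6f}\t{e[2]:.6f}\t{report.nmi[r]:.6f}\t{rank}"
            )
        (ws / "key_residues.tsv").write_text("\n".join(rows) + "\n")

    flr = structure.read_residue_keys_tsv(ws / "flr.tsv")
    slr = structure.read_residue_keys_tsv(ws / "slr.tsv")
    _, cls = _read_points(ws, config)
    n_conformers = len(assignments)
    n_unique = len(unique)
    n_merged = len(strings)
    summary = {
        "n_flr": len(flr),
        "n_slr": len(slr),
        "n_ccr": len(ccr),
        "n_points": int(len(cls)),
        "n_always_free": int(np.sum(cls == 0)),
        "n_always_contact": int(np.sum(cls == 2)),
        "n_conditional": int(np.sum(cls == 1)),
        "n_conformers": n_conformers,
        "n_unique_strings": n_unique,
        "n_merged_strings": n_merged,
        "fold_reduction": round(n_conformers / n_unique, 4) if n_unique else None,
        "fold_reduction_merged": round(n_conformers / n_merged, 4) if n_merged else None,
        "n_clusters": int(len(set(labels.tolist()))) if labels is not None else 1,
    }
    (ws / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


STAGES = [
    ("superpose", stage_superpose),
    ("pocket", stage_pocket),
    ("enumerate", stage_enumerate),
    ("encode", stage_encode),
    ("cluster", stage_cluster),
    ("compat", stage_compat),
    ("report", stage_report),
]


def run_pipeline(
    workdir: str | Path,
    config: RunConfig,
    template: str | Path,
    holos: list[str | Path],
    library: str | Path,
) -> dict:
    """Run every stage in order; returns the summary dict.

    Any stage failure aborts with the stage name attached to the error.
    """
    ws = init_workspace(workdir, config, template, holos, library)
    summary: dict = {}
    for name, fn in STAGES:
        try:
            result = fn(ws)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "report":
            summary = result
    return summary
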