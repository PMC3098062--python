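"""Shared fixtures: the in-memory toy system run through every stage, and
a materialized on-disk pipeline workspace."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
from scipy.spatial import cKDTree

from pocketshape.bitmap import ShapeBitString, deduplicate
from pocketshape.config import RunConfig, load_vdw_radii
from pocketshape.fixtures import FixtureSpec, make_holo_structures, make_toy_system, materialize
from pocketshape.grid import classify_points, contact_point_indices, generate_pocket_points, select_slr
from pocketshape.pipeline import run_pipeline
from pocketshape.rotamers import prefilter_rotamers
from pocketshape.search import build_interaction_graph, enumerate_conformers
from pocketshape.structure import (
    ala_substitute,
    build_ligand_ensemble,
    select_flr,
    superpose_all,
)


@pytest.fixture(scope="session")
def radii():
    return load_vdw_radii()


@pytest.fixture(scope="session")
def toy():
    """The default toy system taken through every stage in memory."""
    spec = FixtureSpec()
    cfg = RunConfig()
    template, library, ligands = make_toy_system(spec)
    holos = make_holo_structures(template, ligands, seed=spec.seed)
    superposed = superpose_all(holos, template, cfg.superpose_rmsd_max)
    ensemble = build_ligand_ensemble(superposed)
    flr = select_flr(template, ensemble, cfg.flr_cutoff)
    ala = ala_substitute(template, flr)
    lattice = generate_pocket_points(
        ala, ensemble, flr, cfg.spacing, cfg.trim_cutoff,
        cfg.psp_min_directions, cfg.psp_range,
    )
    slr = select_slr(template, lattice, flr, cfg.contact_params(), cfg.slr_cutoff)
    placements = prefilter_rotamers(library, template, slr, cfg.clash_params())
    graph = build_interaction_graph(placements, cfg.clash_params())
    conformers = list(enumerate_conformers(graph))

    coords = lattice.coords()
    tree = cKDTree(coords)
    contact = {}
    for key, pls in placements.items():
        for p in pls:
            idx = contact_point_indices(
                np.array([a.coords for a in p.atoms]),
                np.array([a.vdw_radius for a in p.atoms]),
                coords, cfg.contact_params(), tree=tree,
            )
            contact[(key, p.rotamer_index)] = frozenset(int(i) for i in idx)
    contact_sets = [
        frozenset().union(
            *[contact[(k, placements[k][ri].rotamer_index)] for k, ri in c.assignment.items()]
        )
        for c in conformers
    ]
    points = classify_points(lattice, contact_sets)
    cond = points.conditional
    strings = deduplicate(
        (
            c.conformer_id,
            ShapeBitString(bits=np.isin(cond, sorted(s)).astype(np.uint8)),
        )
        for c, s in zip(conformers, contact_sets)
    )
    return SimpleNamespace(
        spec=spec, cfg=cfg, template=template, library=library, ligands=ligands,
        holos=holos, superposed=superposed, ensemble=ensemble, flr=flr, ala=ala,
        lattice=lattice, slr=slr, placements=placements, graph=graph,
        conformers=conformers, contact=contact, contact_sets=contact_sets,
        points=points, strings=strings,
    )


@pytest.fixture(scope="session")
def toy_workspace(tmp_path_factory):
    """The default toy system materialized to disk and run end to end."""
    root = tmp_path_factory.mktemp("toy_ws")
    paths = materialize(FixtureSpec(), root / "fx")
    ws = root / "ws"
    summary = run_pipeline(
        ws, RunConfig(), paths["template"],
        [paths["holo_1"], paths["holo_2"]], paths["library"],
    )
    return SimpleNamespace(root=root, paths=paths, ws=ws, summary=summary)
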