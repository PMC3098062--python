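"""Run configuration and shared parameter objects.

Defaults follow the published protocol this tool implements: 1.0 A lattice
spacing, 5 A first-layer cutoff, 3 A second-layer cutoff, 6 A lattice trim,
clash tolerance distance (CTD) 1.0 A, contact padding distance (CPD) 0.5 A,
and a 5-bit merge threshold for near-identical shape strings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


def load_vdw_radii(path: str | Path | None = None) -> dict[str, float]:
    """Load the element -> vdW radius (A) table.

    By default reads the Bondi-style table shipped with the package; a
    user-supplied TSV (``element<TAB>radius``, ``#`` comments) overrides it.
    """
    if path is None:
        text = (
            resources.files("pocketshape").joinpath("data/vdw_radii.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, radius = line.split("\t")
        table[element.upper()] = float(radius)
    return table


@dataclass(frozen=True)
class ClashParams:
    """Steric clash test parameters: atoms clash iff d < r1 + r2 - ctd."""

    ctd: float = 1.0  # clash tolerance distance, A

    def __post_init__(self) -> None:
        if self.ctd < 0:
            raise ValueError("ctd must be >= 0")


@dataclass(frozen=True)
class ContactParams:
    """Point-atom contact test parameters: contact iff d < r_vdw + cpd."""

    cpd: float = 0.5  # contact padding distance, A

    def __post_init__(self) -> None:
        if self.cpd < 0:
            raise ValueError("cpd must be >= 0")


@dataclass
class RunConfig:
    """Full pipeline configuration with the documented defaults."""

    spacing: float = 1.0          # lattice spacing, A
    flr_cutoff: float = 5.0       # first-layer residue cutoff from ligand ensemble, A
    slr_cutoff: float = 3.0       # second-layer residue cutoff from contact points, A
    trim_cutoff: float = 6.0      # lattice trim distance, A
    ctd: float = 1.0              # clash tolerance distance, A
    cpd: float = 0.5              # contact padding distance, A
    merge_threshold: int = 5      # Hamming merge threshold, bits (strict <)
    cluster_k: int | str = "auto" # cluster count or silhouette auto-selection
    cluster_k_range: tuple[int, int] = (2, 15)
    superpose_rmsd_max: float = 1.0  # Calpha rmsd above which a mobile structure is dropped
    psp_min_directions: int = 4   # buriedness: min blocked scan directions of 7
    psp_range: float = 8.0        # buriedness: max ray length, A
    ion_names: tuple[str, ...] = ("ZN", "CA", "MG", "NA", "K", "CL", "MN", "FE", "NI", "CU", "SO4", "PO4")
    seed: int = 0
    vdw_table: str | None = None  # optional path overriding the shipped radii

    def clash_params(self) -> ClashParams:
        return ClashParams(ctd=self.ctd)

    def contact_params(self) -> ContactParams:
        return ContactParams(cpd=self.cpd)

    def to_text(self) -> str:
        """Flat key=value snapshot, written into every output directory."""
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name}={value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs: dict[str, object] = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, raw = line.split("=", 1)
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            default = getattr(cls(), key)
            if key == "cluster_k":
                kwargs[key] = raw if raw == "auto" else int(raw)
            elif key == "cluster_k_range":
                lo, hi = raw.split(",")
                kwargs[key] = (int(lo), int(hi))
            elif key == "ion_names":
                kwargs[key] = tuple(v for v in raw.split(",") if v)
            elif key == "vdw_table":
                kwargs[key] = None if raw == "None" else raw
            elif isinstance(default, bool):
                kwargs[key] = raw == "True"
            elif isinstance(default, int):
                kwargs[key] = int(raw)
            elif isinstance(default, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)  # type: ignore[arg-type]
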