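"""Pocket-based structure selection for ensemble docking.

Given per-frame pocket detections (point-cloud grids with an energy per
pocket) and a reference ligand, each frame gets a pocket exposure score
— the best, over its pockets, fraction of ligand atoms lying within a
radius of any grid point.  Frames are filtered by an adaptive exposure
cutoff that starts at 0.5 and relaxes in 0.1 steps until more than a
minimum number of frames survive.  The surviving frames' pocket-atom
coordinates are PCA-reduced, k-means-clustered into five groups, and
each cluster contributes its most favourable-energy frame as a docking
receptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .ensemble_io import MolecularTopology, _parse_atom_line
from .shift import fit_projection_matrix, project_matrix

__all__ = [
    "LigandReference",
    "Pocket",
    "PocketGridSet",
    "ExposureSeries",
    "FilterResult",
    "ClusterSelection",
    "read_ligand_pdb",
    "read_pocket_grid_pdb",
    "write_ligand_pdb",
    "write_pocket_grid_pdb",
    "pocket_overlap",
    "frame_exposure",
    "compute_exposures",
    "adaptive_filter",
    "extract_pocket_atoms",
    "cluster_and_select",
]


@dataclass
class LigandReference:
    """Heavy-atom coordinates of the reference (crystallographic) ligand."""

    coords: np.ndarray
    atom_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or not len(self.coords):
            raise ValueError("ligand needs at least one (x, y, z) atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite ligand coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Pocket:
    """One detected pocket: a grid-point cloud plus its energy score
    (arbitrary units, more negative = more favourable)."""

    grid_points: np.ndarray
    energy: float = 0.0

    def __post_init__(self) -> None:
        self.grid_points = np.asarray(self.grid_points, dtype=float)
        if not len(self.grid_points):
            raise ValueError("a pocket needs at least one grid point")


@dataclass
class PocketGridSet:
    """Per-frame pocket detections for an ensemble."""

    frames: list[list[Pocket]]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class ExposureSeries:
    """Per-frame pocket exposure scores in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("exposure scores must lie in [0, 1]")


@dataclass
class FilterResult:
    final_cutoff: float
    retained_frame_indices: np.ndarray
    cutoff_trace: list[tuple[float, int]]


@dataclass
class ClusterSelection:
    labels: np.ndarray                       # per-retained-frame cluster id
    representatives: dict[int, int]          # cluster id -> frame position
    representative_energies: dict[int, float]


# ---------------------------------------------------------------------------
# Input files

def read_ligand_pdb(path: str | Path) -> LigandReference:
    """Read ligand heavy atoms from ATOM/HETATM records of a PDB file."""
    coords, names = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line[:6] in ("ATOM  ", "HETATM"):
                name, _, _, _, _, _, xyz, _, element = _parse_atom_line(line, lineno)
                if element in ("H", "D"):
                    continue
                coords.append(xyz)
                names.append(name)
    if not coords:
        raise ValueError(f"no atoms found in ligand file {path}")
    return LigandReference(np.array(coords), names)


def read_pocket_grid_pdb(path: str | Path) -> list[Pocket]:
    """Read one frame's pockets from a PDB-format point cloud.

    Grid points of one pocket share a residue sequence number; the
    pocket energy is carried in the B-factor column (identical for all
    points of a pocket — the first is used).
    """
    groups: dict[int, list] = {}
    energies: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line[:6] not in ("ATOM  ", "HETATM"):
                continue
            try:
                resid = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                bfac_field = line[60:66].strip()
                energy = float(bfac_field) if bfac_field else 0.0
            except ValueError as exc:
                raise ValueError(
                    f"unparseable grid record at line {lineno} of {path}"
                ) from exc
            groups.setdefault(resid, []).append(xyz)
            energies.setdefault(resid, energy)
    return [
        Pocket(np.array(groups[rid]), energies[rid]) for rid in sorted(groups)
    ]


def write_ligand_pdb(ligand: LigandReference, path: str | Path) -> None:
    """Write a ligand as HETATM records (residue LIG)."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(ligand.coords, start=1):
            name = ligand.atom_names[i - 1] if ligand.atom_names else f"C{i}"
            fh.write(
                f"HETATM{i:5d} {name:<4s}LIG L   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
            )
        fh.write("END\n")


def write_pocket_grid_pdb(pockets: list[Pocket], path: str | Path) -> None:
    """Write pockets as a PDB point cloud: one residue id per pocket,
    pocket energy in the B-factor column."""
    with open(path, "w") as fh:
        serial = 1
        for p_id, pocket in enumerate(pockets, start=1):
            for x, y, z in pocket.grid_points:
                fh.write(
                    f"HETATM{serial:5d} {'GP':<4s}PKT P{p_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{pocket.energy:6.2f}"
                    f"           X\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Exposure scoring

def pocket_overlap(
    grid: np.ndarray | Pocket, ligand: LigandReference, radius: float = 1.0
) -> float:
    """Fraction of ligand atoms within ``radius`` of any grid point."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = grid.grid_points if isinstance(grid, Pocket) else np.asarray(grid, float)
    if len(points) == 0:
        warnings.warn("empty pocket grid; overlap is 0", stacklevel=2)
        return 0.0
    nearest = cdist(ligand.coords, points).min(axis=1)
    return float(np.mean(nearest <= radius))


def frame_exposure(
    pockets: list[Pocket], ligand: LigandReference, radius: float = 1.0
) -> float:
    """Best pocket overlap in a frame; 0 when no pockets were detected."""
    if not pockets:
        return 0.0
    return max(pocket_overlap(p, ligand, radius) for p in pockets)


def compute_exposures(
    grids: PocketGridSet, ligand: LigandReference, radius: float = 1.0
) -> ExposureSeries:
    return ExposureSeries(
        np.array([frame_exposure(f, ligand, radius) for f in grids.frames])
    )


# ---------------------------------------------------------------------------
# Filtering and selection

def adaptive_filter(
    scores: ExposureSeries,
    start_cutoff: float = 0.5,
    step: float = 0.1,
    min_retained: int = 100,
) -> FilterResult:
    """Retain frames with exposure >= cutoff, relaxing the cutoff in
    ``step`` decrements until more than ``min_retained`` frames survive.

    The cutoff floors at 0.0, where every frame is retained regardless
    of the count, so the procedure always terminates.
    """
    if scores.values.size == 0:
        raise ValueError("empty exposure series")
    if not 0 < start_cutoff <= 1:
        raise ValueError("start_cutoff must lie in (0, 1]")
    if step <= 0:
        raise ValueError("step must be positive")

    trace: list[tuple[float, int]] = []
    k = 0
    while True:
        cutoff = max(round(start_cutoff - k * step, 12), 0.0)
        retained = np.flatnonzero(scores.values >= cutoff)
        trace.append((cutoff, retained.size))
        if retained.size > min_retained or cutoff == 0.0:
            return FilterResult(cutoff, retained, trace)
        k += 1


def extract_pocket_atoms(
    reference_coords: np.ndarray,
    topology: MolecularTopology,
    ligand: LigandReference,
    radius: float = 1.0,
) -> np.ndarray:
    """Indices of protein heavy atoms within ``radius`` of the ligand."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    reference_coords = np.asarray(reference_coords, dtype=float)
    heavy = np.array([e not in ("H", "D") for e in topology.elements])
    nearest = cdist(reference_coords, ligand.coords).min(axis=1)
    indices = np.flatnonzero(heavy & (nearest <= radius))
    if indices.size == 0:
        raise ValueError(
            f"no protein heavy atoms within {radius} Å of the ligand; "
            "consider a larger radius"
        )
    return indices


def cluster_and_select(
    pocket_coords: np.ndarray,
    energies: np.ndarray,
    k: int = 5,
    seed: int = 0,
    n_components: int = 2,
    n_init: int = 10,
) -> ClusterSelection:
    """Cluster retained frames by pocket conformation and pick
    representatives.

    ``pocket_coords`` holds one flattened pocket-atom coordinate vector
    per retained frame.  Coordinates are PCA-reduced, partitioned by
    seeded k-means (best of ``n_init`` restarts), and each cluster's
    representative is its minimum-energy frame (ties: lowest index).
    """
    pocket_coords = np.asarray(pocket_coords, dtype=float)
    energies = np.asarray(energies, dtype=float)
    n = pocket_coords.shape[0]
    if energies.shape[0] != n:
        raise ValueError("energies must align with pocket_coords frames")
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} frames")
    n_unique = len(np.unique(pocket_coords, axis=0))
    if n_unique < k:
        raise ValueError(
            f"only {n_unique} distinct pocket conformations; cannot form {k} clusters"
        )

    model = fit_projection_matrix(pocket_coords, n_components)
    reduced = project_matrix(pocket_coords, model).points
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(reduced)

    representatives: dict[int, int] = {}
    representative_energies: dict[int, float] = {}
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        best = members[np.argmin(energies[members])]
        representatives[c] = int(best)
        representative_energies[c] = float(energies[best])
    return ClusterSelection(labels, representatives, representative_energies)
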