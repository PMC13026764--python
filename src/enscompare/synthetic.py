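"""Synthetic ensembles, scenes and score tables with known ground truth.

Every analysis stage of the package can be exercised without external
trajectories or a generative model: harmonic ensembles with prescribed
per-residue fluctuation and block correlations, two-state apo/holo
mixtures, mode-shifted "mutant" ensembles, pocket/ligand scenes with
designed exposure scores, and screening tables with known separability.

The generators emulate the statistical structure the metrics measure —
fluctuation amplitudes, displacement correlations, state weights,
coverage fractions, score separations — not the physics behind it.
All of them are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble_io import ConformationEnsemble, MolecularTopology, Residue
from .pocket import LigandReference, Pocket, PocketGridSet
from .screening import ScreeningTable

__all__ = [
    "HarmonicSpec",
    "TwoStateSpec",
    "SceneSpec",
    "make_backbone",
    "make_harmonic_ensemble",
    "make_two_state_ensemble",
    "make_shifted_ensemble",
    "make_pocket_scene",
    "make_screening_table",
]

# backbone/Cβ offsets from the Cα in a fixed local frame; arbitrary but
# self-consistent constants that keep the trace self-avoiding
_ATOM_OFFSETS = {
    "N": np.array([-1.0, 0.6, -0.5]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.0, 0.6, 0.5]),
    "O": np.array([1.3, 1.7, 0.4]),
    "CB": np.array([0.1, -1.4, 0.3]),
}

_HELIX_RISE = 1.5        # Å per residue
_HELIX_TURN = 100.0      # degrees per residue
_HELIX_RADIUS = 2.3      # Å


@dataclass
class HarmonicSpec:
    """Prescription for a harmonic (Gaussian-fluctuation) ensemble.

    ``sigma_profile`` is the per-residue displacement scale in Å per
    Cartesian coordinate, so the expected RMSF of residue i is
    sigma_i·√3.  ``correlation_blocks`` lists (residues_a, residues_b,
    rho) triples; residues inside a block share a latent factor that
    makes their pairwise displacement correlation exactly rho (negative
    rho anticorrelates the two ranges).
    """

    n_res: int
    n_frames: int
    sigma_profile: np.ndarray
    correlation_blocks: list[tuple[range, range, float]] = field(default_factory=list)
    seed: int = 0
    residue_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.sigma_profile = np.broadcast_to(
            np.asarray(self.sigma_profile, dtype=float), (self.n_res,)
        ).copy()
        if np.any(self.sigma_profile <= 0):
            raise ValueError("sigma_profile must be positive")
        seen: set[int] = set()
        for ra, rb, rho in self.correlation_blocks:
            if not abs(rho) < 1:
                raise ValueError("block correlation must satisfy |rho| < 1")
            members = set(ra) | set(rb)
            if max(members, default=0) >= self.n_res or min(members, default=0) < 0:
                raise ValueError("block residue range outside the chain")
            if members & seen:
                raise ValueError(
                    "overlapping correlation blocks are not representable "
                    "with independent latent factors"
                )
            seen |= members


@dataclass
class TwoStateSpec:
    """Mixture of two reference conformations plus isotropic jitter."""

    apo_coords: np.ndarray
    holo_coords: np.ndarray
    holo_weight: float
    jitter_sigma: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.apo_coords = np.asarray(self.apo_coords, dtype=float)
        self.holo_coords = np.asarray(self.holo_coords, dtype=float)
        if self.apo_coords.shape != self.holo_coords.shape:
            raise ValueError("apo and holo coordinate shapes differ")
        if not 0 <= self.holo_weight <= 1:
            raise ValueError("holo_weight must lie in [0, 1]")


@dataclass
class SceneSpec:
    """Pocket/ligand scene with designed per-frame exposure scores.

    Each exposure must be representable as k/n_ligand_atoms for integer
    k so the measured score can equal the design exactly.
    """

    n_ligand_atoms: int
    exposures: np.ndarray
    n_pockets: int = 1
    pocket_energies: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if np.any((self.exposures < 0) | (self.exposures > 1)):
            raise ValueError("exposures must lie in [0, 1]")
        ks = self.exposures * self.n_ligand_atoms
        if not np.allclose(ks, np.round(ks), atol=1e-9):
            raise ValueError(
                "every exposure must be a multiple of 1/n_ligand_atoms"
            )
        if self.pocket_energies is None:
            self.pocket_energies = np.zeros(len(self.exposures))
        self.pocket_energies = np.asarray(self.pocket_energies, dtype=float)
        if len(self.pocket_energies) != len(self.exposures):
            raise ValueError("pocket_energies must align with exposures")


def make_backbone(
    n_res: int, residue_names: list[str] | str | None = None
) -> tuple[MolecularTopology, np.ndarray]:
    """Ideal-helix reference structure with N, CA, C, O and CB atoms.

    Cα atoms trace a helix (1.5 Å rise, 100° turn, 2.3 Å radius); the
    remaining backbone + Cβ atoms sit at fixed offsets.  Glycine
    residues omit the Cβ.  Residue names default to alanine and may be
    given as a list or a single repeated name.
    """
    if n_res < 2:
        raise ValueError("need at least two residues")
    if residue_names is None:
        residue_names = ["ALA"] * n_res
    elif isinstance(residue_names, str):
        residue_names = [residue_names] * n_res
    if len(residue_names) != n_res:
        raise ValueError("residue_names length must equal n_res")

    residues, atom_names, atom_res, elements, coords = [], [], [], [], []
    for i, resname in enumerate(residue_names):
        residues.append(Residue(i + 1, resname, "A"))
        theta = np.deg2rad(_HELIX_TURN * i)
        ca = np.array(
            [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
        )
        for name in ("N", "CA", "C", "O", "CB"):
            if name == "CB" and resname == "GLY":
                continue
            atom_names.append(name)
            atom_res.append(i)
            elements.append(name[0])
            coords.append(ca + _ATOM_OFFSETS[name])
    topo = MolecularTopology(residues, atom_names, np.array(atom_res), elements)
    return topo, np.array(coords)


def _per_residue_displacements(spec: HarmonicSpec, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean (n_frames, n_res, 3) displacements with the prescribed
    sigma profile and block correlation structure."""
    eps = rng.standard_normal((spec.n_frames, spec.n_res, 3))
    disp = eps.copy()
    for ra, rb, rho in spec.correlation_blocks:
        shared = rng.standard_normal((spec.n_frames, 1, 3))
        a = np.sqrt(1.0 - abs(rho))
        b = np.sqrt(abs(rho))
        idx_a, idx_b = list(ra), list(rb)
        disp[:, idx_a, :] = a * eps[:, idx_a, :] + b * shared
        sgn = 1.0 if rho >= 0 else -1.0
        disp[:, idx_b, :] = a * eps[:, idx_b, :] + sgn * b * shared
    return disp * spec.sigma_profile[None, :, None]


def make_harmonic_ensemble(
    spec: HarmonicSpec, reference_offset: np.ndarray | None = None
) -> ConformationEnsemble:
    """Harmonic ensemble around the ideal-helix reference.

    Each residue's displacement is applied rigidly to all of its atoms,
    so Cα fluctuations and contact-map perturbations are consistent.
    ``reference_offset`` shifts the per-residue reference positions
    before noise is added (used for "mutant" ensembles).
    """
    topo, ref_coords = make_backbone(spec.n_res, spec.residue_names)
    rng = np.random.default_rng(spec.seed)
    disp = _per_residue_displacements(spec, rng)
    if reference_offset is not None:
        reference_offset = np.asarray(reference_offset, dtype=float)
        if reference_offset.shape != (spec.n_res, 3):
            raise ValueError("reference_offset must be (n_res, 3)")
        disp = disp + reference_offset[None]
    atom_disp = disp[:, topo.atom_residue, :]
    return ConformationEnsemble(topo, ref_coords[None] + atom_disp)


def make_two_state_ensemble(
    topology: MolecularTopology, spec: TwoStateSpec
) -> tuple[ConformationEnsemble, np.ndarray]:
    """Bernoulli mixture of two reference conformations.

    Each frame copies the apo or holo coordinates (holo with probability
    ``holo_weight``) and adds isotropic Gaussian jitter.  Returns the
    ensemble together with the true per-frame state labels (True =
    holo).
    """
    if spec.apo_coords.shape[0] != topology.n_atoms:
        raise ValueError("reference coordinates do not match the topology")
    rng = np.random.default_rng(spec.seed)
    labels = rng.random(spec.n_frames) < spec.holo_weight
    frames = np.where(labels[:, None, None], spec.holo_coords, spec.apo_coords)
    frames = frames + spec.jitter_sigma * rng.standard_normal(frames.shape)
    return ConformationEnsemble(topology, frames), labels


def make_shifted_ensemble(
    base: HarmonicSpec, shift_magnitudes: list[float], seed: int | None = None
) -> list[ConformationEnsemble]:
    """"Mutant" ensembles displaced along one fixed conformational mode.

    A seeded random unit mode in per-residue coordinate space is scaled
    to total displacement norm magnitude·mean(sigma) and added to the
    reference before harmonic noise; each output gets independent noise.
    Since the harmonic noise projected onto any unit mode has standard
    deviation sigma, magnitude is the shift in units of the ensemble's
    own spread along the mode.  Magnitude 0 reproduces the base
    statistics.
    """
    if any(m < 0 for m in shift_magnitudes):
        raise ValueError("shift magnitudes must be non-negative")
    if seed is None:
        seed = base.seed
    mode_rng = np.random.default_rng(seed)
    mode = mode_rng.standard_normal((base.n_res, 3))
    mode /= np.linalg.norm(mode)
    scale = float(np.mean(base.sigma_profile))
    out = []
    for k, mag in enumerate(shift_magnitudes):
        spec_k = HarmonicSpec(
            base.n_res,
            base.n_frames,
            base.sigma_profile,
            base.correlation_blocks,
            seed=seed + 1 + k,
            residue_names=base.residue_names,
        )
        out.append(make_harmonic_ensemble(spec_k, reference_offset=mag * scale * mode))
    return out


def make_pocket_scene(
    spec: SceneSpec, out_dir: str | Path | None = None
) -> tuple[PocketGridSet, LigandReference, np.ndarray]:
    """Pocket/ligand scene whose measured exposures equal the design.

    The ligand is a line of atoms 3 Å apart.  In each frame the primary
    pocket's grid points coincide with exactly k ligand atoms (k chosen
    from the designed exposure); any additional pockets are placed far
    from the ligand so they never win the per-frame maximum.  With
    ``out_dir`` the ligand and per-frame grids are also written as PDB
    point clouds (energy in the B-factor column).
    """
    n = spec.n_ligand_atoms
    ligand = LigandReference(
        np.column_stack([3.0 * np.arange(n), np.zeros(n), np.zeros(n)]),
        [f"C{i + 1}" for i in range(n)],
    )
    far = np.array([500.0, 500.0, 500.0])
    frames: list[list[Pocket]] = []
    for f, exposure in enumerate(spec.exposures):
        k = int(round(exposure * n))
        pockets = []
        if k > 0:
            pockets.append(Pocket(ligand.coords[:k].copy(), float(spec.pocket_energies[f])))
        else:
            pockets.append(Pocket(far[None] + [f, 0, 0], float(spec.pocket_energies[f])))
        for extra in range(spec.n_pockets - 1):
            offset = far * (2 + extra) + np.array([10.0 * f, 0.0, 0.0])
            pockets.append(Pocket(offset[None], 0.0))
        frames.append(pockets)
    grids = PocketGridSet(frames)
    if out_dir is not None:
        from .pocket import write_ligand_pdb, write_pocket_grid_pdb

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ligand_pdb(ligand, out_dir / "ligand.pdb")
        for f, pockets in enumerate(frames):
            write_pocket_grid_pdb(pockets, out_dir / f"frame_{f:05d}.pdb")
    return grids, ligand, spec.exposures.copy()


def make_screening_table(
    n_active: int,
    n_decoy: int,
    delta: float,
    seed: int = 0,
    n_structures: int = 1,
) -> ScreeningTable:
    """Binormal screening table with known separability.

    Active scores ~ N(−delta, 1), decoy scores ~ N(0, 1), lower is
    better; with one structure the expected ROC AUC is Φ(delta/√2).
    With several structures the per-structure scores are drawn
    independently from the ligand's class distribution.
    """
    if n_active < 1 or n_decoy < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    n = n_active + n_decoy
    labels = np.zeros(n, dtype=bool)
    labels[:n_active] = True
    means = np.where(labels, -delta, 0.0)
    scores = means[:, None] + rng.standard_normal((n, n_structures))
    ids = [
        f"active_{i + 1}" if labels[i] else f"decoy_{i + 1 - n_active}"
        for i in range(n)
    ]
    structure_ids = [f"structure_{j + 1}" for j in range(n_structures)]
    return ScreeningTable(ids, labels, scores, structure_ids)
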