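"""Two-state (apo/holo) projection of an ensemble and occupancy summaries.

For proteins that change conformation on ligand binding, each frame of
an ensemble is placed in a 2D plane by its Cα RMSD to the ligand-free
(apo) and ligand-bound (holo) reference structures, after per-frame
rigid superposition onto each reference.  State occupancies at an RMSD
cutoff (3 Å by convention) summarise whether both end states were
sampled and toward which one the ensemble is biased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import AtomSelection, ConformationEnsemble, kabsch_superpose

__all__ = [
    "ReferencePair",
    "TwoStateProjection",
    "OccupancySummary",
    "rmsd_to_reference",
    "two_state_project",
    "occupancy",
]


@dataclass
class ReferencePair:
    """Matched apo/holo Cα coordinate sets on equivalent residues.

    Residue matching (removal of redundant chains/residues so both
    structures cover the same segment) is the caller's responsibility.
    """

    apo_coords: np.ndarray
    holo_coords: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.apo_coords = np.asarray(self.apo_coords, dtype=float)
        self.holo_coords = np.asarray(self.holo_coords, dtype=float)
        if self.apo_coords.shape != self.holo_coords.shape:
            raise ValueError(
                f"apo/holo point counts differ: {self.apo_coords.shape[0]} "
                f"vs {self.holo_coords.shape[0]}"
            )
        if self.apo_coords.shape[0] < 3:
            raise ValueError("need at least 3 matched residues")

    def inter_reference_rmsd(self) -> float:
        """RMSD between the two references after superposition."""
        return kabsch_superpose(self.holo_coords, self.apo_coords).fit_rmsd


@dataclass
class TwoStateProjection:
    """Per-frame (RMSD to apo, RMSD to holo) pairs in Å."""

    points: np.ndarray      # (n_frames, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.min() < 0:
            raise ValueError("RMSD values must be non-negative")


@dataclass
class OccupancySummary:
    """Counts of apo-like/holo-like frames at a strict RMSD cutoff."""

    n_frames: int
    n_apo_like: int
    n_holo_like: int
    n_both: int
    n_neither: int
    holo_bias_fraction: float    # fraction of frames with rmsd_holo < rmsd_apo

    def __post_init__(self) -> None:
        if (
            self.n_apo_like + self.n_holo_like - self.n_both + self.n_neither
            != self.n_frames
        ):
            raise ValueError("occupancy counts are not exhaustive")

    @property
    def sampled_both_states(self) -> bool:
        return self.n_apo_like > 0 and self.n_holo_like > 0


def rmsd_to_reference(
    ensemble: ConformationEnsemble, ref: np.ndarray, selection: AtomSelection
) -> np.ndarray:
    """Per-frame RMSD to a reference, each frame superposed first.

    RMSD_t = sqrt( (1/N) Σ_i |x_i^t − x_i^ref|² ) over the selected
    atoms, after the frame's own least-squares rigid fit onto the
    reference, so rigid motions of a frame do not contribute.
    """
    ref = np.asarray(ref, dtype=float)
    sel = selection.indices
    if ref.shape[0] == ensemble.n_atoms:
        ref = ref[sel]
    elif ref.shape[0] != sel.size:
        raise ValueError(
            f"reference has {ref.shape[0]} points; expected {sel.size} "
            f"(selection) or {ensemble.n_atoms} (full topology)"
        )
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        out[f] = kabsch_superpose(ensemble.frames[f, sel], ref).fit_rmsd
    return out


def two_state_project(
    ensemble: ConformationEnsemble,
    pair: ReferencePair,
    selection: AtomSelection,
) -> TwoStateProjection:
    """RMSD of every frame to both references, aligned independently."""
    if selection.n_atoms != pair.apo_coords.shape[0]:
        raise ValueError(
            f"ensemble selection has {selection.n_atoms} atoms but the "
            f"reference pair has {pair.apo_coords.shape[0]} points"
        )
    rmsd_apo = rmsd_to_reference(ensemble, pair.apo_coords, selection)
    rmsd_holo = rmsd_to_reference(ensemble, pair.holo_coords, selection)
    return TwoStateProjection(np.column_stack([rmsd_apo, rmsd_holo]))


def occupancy(proj: TwoStateProjection, cutoff: float = 3.0) -> OccupancySummary:
    """Classify frames at a strict cutoff (a frame at exactly the cutoff
    belongs to neither state)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    apo_like = proj.points[:, 0] < cutoff
    holo_like = proj.points[:, 1] < cutoff
    n = proj.points.shape[0]
    n_both = int(np.sum(apo_like & holo_like))
    n_neither = int(np.sum(~apo_like & ~holo_like))
    return OccupancySummary(
        n_frames=n,
        n_apo_like=int(apo_like.sum()),
        n_holo_like=int(holo_like.sum()),
        n_both=n_both,
        n_neither=n_neither,
        holo_bias_fraction=float(np.mean(proj.points[:, 1] < proj.points[:, 0])),
    )
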