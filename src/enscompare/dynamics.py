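"""Per-residue flexibility, motion correlation and contact analysis.

Implements the comparison statistics used to judge whether one
conformational ensemble (e.g. generated by a sequence-to-ensemble model)
reproduces the dynamics of another (e.g. a molecular-dynamics
trajectory): RMSF profiles compared by Pearson correlation, dynamic
cross-correlation matrices (DCCM) and distance-based contact maps
compared by mean absolute error (MAE), plus stratified breakdowns by
chain region, sequence separation and interaction chemistry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .ensemble_io import AtomSelection, ConformationEnsemble, MolecularTopology

__all__ = [
    "CenteredEnsemble",
    "FlexibilityProfile",
    "PairMatrix",
    "StratumAssignment",
    "center_ensemble",
    "compute_rmsf",
    "profile_pcc",
    "compute_dccm",
    "matrix_mae",
    "compute_contact_map",
    "combine_triangles",
    "stratify_sequence_separation",
    "stratify_termini",
    "classify_interaction_pairs",
    "stratified_mae",
    "ACIDIC",
    "BASIC",
    "AROMATIC",
    "APOLAR",
]

# conventional biochemistry groupings; HIS counted aromatic, not basic
ACIDIC = frozenset({"ASP", "GLU"})
BASIC = frozenset({"LYS", "ARG"})
AROMATIC = frozenset({"PHE", "TYR", "TRP", "HIS"})
APOLAR = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PRO", "GLY"})

_STANDARD_RESIDUES = ACIDIC | BASIC | AROMATIC | APOLAR | {
    "SER", "THR", "ASN", "GLN", "CYS",
}


@dataclass
class CenteredEnsemble:
    """Mean structure and per-frame displacements of a selection.

    Satisfies x_t = mean + displacement_t exactly, so the decomposition
    is lossless.
    """

    mean_coords: np.ndarray      # (n_sel, 3) Å
    displacements: np.ndarray    # (n_frames, n_sel, 3) Å
    residue_labels: list[str]


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF in Å."""

    values: np.ndarray
    residue_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be non-negative")


@dataclass
class PairMatrix:
    """Symmetric residue-by-residue matrix (correlation or distance)."""

    kind: str                 # correlation | mean_min_distance | combined_display
    values: np.ndarray
    residue_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("PairMatrix must be square")
        if self.kind == "correlation":
            if np.abs(self.values).max() > 1 + 1e-9:
                raise ValueError("correlation entries must lie in [-1, 1]")
        elif self.kind == "mean_min_distance":
            if self.values.min() < 0:
                raise ValueError("distance entries must be non-negative")
        elif self.kind != "combined_display":
            raise ValueError(f"unknown PairMatrix kind {self.kind!r}")

    @property
    def n_res(self) -> int:
        return self.values.shape[0]


@dataclass
class StratumAssignment:
    """Category labels per residue or per unordered residue pair."""

    level: str                       # residue | pair
    labels: dict                     # residue position or (i, j) i<j -> label

    def categories(self) -> list[str]:
        return sorted(set(self.labels.values()))


def center_ensemble(
    aligned: ConformationEnsemble, selection: AtomSelection
) -> CenteredEnsemble:
    """Split selected coordinates into ensemble mean plus displacements."""
    if selection.n_atoms == 0:
        raise ValueError("empty atom selection")
    coords = aligned.frames[:, selection.indices, :]
    mean = coords.mean(axis=0)
    labels = [
        aligned.topology.residue_labels()[aligned.topology.atom_residue[i]]
        for i in selection.indices
    ]
    return CenteredEnsemble(mean, coords - mean, labels)


def compute_rmsf(centered: CenteredEnsemble) -> FlexibilityProfile:
    """RMSF_i = sqrt( mean_t |Δx_i^t|^2 ), one value per selected atom."""
    if centered.displacements.shape[0] < 2:
        raise ValueError("RMSF undefined for a single-frame ensemble")
    msd = np.mean(np.sum(centered.displacements**2, axis=2), axis=0)
    return FlexibilityProfile(np.sqrt(msd), centered.residue_labels)


def profile_pcc(a: FlexibilityProfile, b: FlexibilityProfile) -> float:
    """Pearson correlation between two flexibility profiles."""
    x, y = a.values, b.values
    if x.size != y.size:
        raise ValueError(f"profile lengths differ: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 residues for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    return float(stats.pearsonr(x, y).statistic)


def compute_dccm(centered: CenteredEnsemble) -> PairMatrix:
    """Dynamic cross-correlation matrix of displacement vectors.

    C_ij = sum_t Δx_i·Δx_j / sqrt( sum_t |Δx_i|^2 · sum_t |Δx_j|^2 )
    """
    d = centered.displacements
    if d.shape[0] < 2:
        raise ValueError("DCCM undefined for a single-frame ensemble")
    # inner products over frames: (n_res, n_res)
    inner = np.einsum("tik,tjk->ij", d, d)
    norms = np.diag(inner)
    zero = np.flatnonzero(norms <= 0)
    if zero.size:
        bad = ", ".join(centered.residue_labels[i] for i in zero)
        raise ValueError(f"residues with zero total displacement: {bad}")
    C = inner / np.sqrt(np.outer(norms, norms))
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return PairMatrix("correlation", C, centered.residue_labels)


def matrix_mae(m: PairMatrix, ref: PairMatrix, include_diagonal: bool = True) -> float:
    """Mean absolute element-wise difference between two pair matrices."""
    if m.kind != ref.kind:
        raise ValueError(f"kind mismatch: {m.kind} vs {ref.kind}")
    if m.values.shape != ref.values.shape:
        raise ValueError(
            f"shape mismatch: {m.values.shape} vs {ref.values.shape}"
        )
    diff = np.abs(m.values - ref.values)
    if include_diagonal:
        return float(diff.mean())
    n = m.n_res
    mask = ~np.eye(n, dtype=bool)
    return float(diff[mask].mean())


def compute_contact_map(
    ensemble: ConformationEnsemble, selection: AtomSelection
) -> PairMatrix:
    """Distance-based contact map.

    D_ij is the mean over frames of the smallest inter-atomic distance
    between the selected atoms (typically backbone + Cβ) of residues i
    and j; the diagonal is zero.
    """
    topo = ensemble.topology
    n_res = topo.n_residues
    for r in range(n_res):
        if r not in selection.per_residue_groups:
            raise ValueError(
                f"residue {topo.residue_labels()[r]} has no atoms in selection"
            )
    # selection indices sorted by residue; contiguous blocks per residue
    res_order = sorted(selection.per_residue_groups)
    block_atoms = np.concatenate([selection.per_residue_groups[r] for r in res_order])
    sizes = [len(selection.per_residue_groups[r]) for r in res_order]
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    total = np.zeros((n_res, n_res))
    for f in range(ensemble.n_frames):
        atom_d = cdist(ensemble.frames[f, block_atoms], ensemble.frames[f, block_atoms])
        # reduce atom-level distances to per-residue-pair minima
        red = np.minimum.reduceat(atom_d, starts, axis=0)
        red = np.minimum.reduceat(red, starts, axis=1)
        total += red
    D = total / ensemble.n_frames
    np.fill_diagonal(D, 0.0)
    return PairMatrix("mean_min_distance", D, topo.residue_labels())


def combine_triangles(upper: PairMatrix, lower: PairMatrix) -> PairMatrix:
    """Display matrix with `upper`'s strict upper triangle and diagonal
    and `lower`'s strict lower triangle, the conventional side-by-side
    visual comparison of two symmetric matrices."""
    if upper.kind != lower.kind or upper.values.shape != lower.values.shape:
        raise ValueError("matrices must share kind and shape")
    out = np.triu(upper.values) + np.tril(lower.values, k=-1)
    return PairMatrix("combined_display", out, upper.residue_labels)


def stratify_sequence_separation(
    n_res: int, near_frac: float = 0.2, far_frac: float = 0.8
) -> StratumAssignment:
    """Label residue pairs close/middle/far by |i-j| relative to length.

    close: |i-j|/n_res < near_frac; far: > far_frac; ties fall to middle.
    """
    if n_res < 2:
        raise ValueError("need at least two residues")
    labels = {}
    for i in range(n_res):
        for j in range(i + 1, n_res):
            frac = (j - i) / n_res
            if frac < near_frac:
                labels[(i, j)] = "close"
            elif frac > far_frac:
                labels[(i, j)] = "far"
            else:
                labels[(i, j)] = "middle"
    return StratumAssignment("pair", labels)


def stratify_termini(n_res: int, terminal_len: int | None = None) -> StratumAssignment:
    """Label residues terminal/middle.

    Default terminal length is max(5, 10% of the chain) per terminus.
    """
    if terminal_len is None:
        terminal_len = max(5, round(0.1 * n_res))
    if terminal_len < 0:
        raise ValueError("terminal_len must be non-negative")
    if 2 * terminal_len >= n_res:
        raise ValueError(
            f"terminal_len {terminal_len} too large for {n_res} residues"
        )
    labels = {
        i: "terminal" if (i < terminal_len or i >= n_res - terminal_len) else "middle"
        for i in range(n_res)
    }
    return StratumAssignment("residue", labels)


def classify_interaction_pairs(
    topology: MolecularTopology,
    reference_map: PairMatrix,
    close_cutoff: float = 5.0,
    acidic: frozenset = ACIDIC,
    basic: frozenset = BASIC,
    aromatic: frozenset = AROMATIC,
    apolar: frozenset = APOLAR,
) -> StratumAssignment:
    """Classify close contacts by interaction chemistry.

    Pairs whose reference mean-minimum distance is below ``close_cutoff``
    are labelled polar_polar (one acidic + one basic residue: a salt
    bridge), pi_pi (both aromatic), non_polar (both apolar) or other.
    Pairs beyond the cutoff are excluded.
    """
    if reference_map.kind != "mean_min_distance":
        raise ValueError("reference_map must be a mean_min_distance matrix")
    names = [r.name for r in topology.residues]
    unknown = sorted({n for n in names if n not in _STANDARD_RESIDUES})
    if unknown:
        warnings.warn(
            f"unknown residue names labelled 'other': {', '.join(unknown)}",
            stacklevel=2,
        )
    labels = {}
    n = reference_map.n_res
    for i in range(n):
        for j in range(i + 1, n):
            if reference_map.values[i, j] >= close_cutoff:
                continue
            a, b = names[i], names[j]
            if (a in acidic and b in basic) or (a in basic and b in acidic):
                labels[(i, j)] = "polar_polar"
            elif a in aromatic and b in aromatic:
                labels[(i, j)] = "pi_pi"
            elif a in apolar and b in apolar:
                labels[(i, j)] = "non_polar"
            else:
                labels[(i, j)] = "other"
    return StratumAssignment("pair", labels)


def stratified_mae(
    m: PairMatrix, ref: PairMatrix, strata: StratumAssignment
) -> dict[str, float | None]:
    """Per-stratum MAE over unique unordered pairs (i < j).

    Strata with no pairs report None rather than zero.
    """
    if strata.level != "pair":
        raise ValueError("stratified_mae needs a pair-level stratum assignment")
    if m.values.shape != ref.values.shape:
        raise ValueError("matrix shapes differ")
    diff = np.abs(m.values - ref.values)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for (i, j), label in strata.labels.items():
        sums[label] = sums.get(label, 0.0) + diff[i, j]
        counts[label] = counts.get(label, 0) + 1
    return {
        label: (sums[label] / counts[label]) if counts[label] else None
        for label in sums
    }
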