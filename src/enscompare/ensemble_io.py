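"""Reading, writing, selecting and superposing conformational ensembles.

An ensemble is a fixed molecular topology plus a stack of coordinate
frames in ångström.  Multi-model PDB files are the native exchange
format; XTC/DCD trajectories (with a PDB topology) are read through
MDAnalysis, which converts nm-based formats to Å at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MolecularTopology",
    "ConformationEnsemble",
    "AtomSelection",
    "SuperpositionResult",
    "EnsembleFormatError",
    "read_multimodel_pdb",
    "read_trajectory",
    "write_multimodel_pdb",
    "concat_ensembles",
    "resolve_selection",
    "kabsch_superpose",
    "align_ensemble",
]

_HYDROGEN_NAMES = ("H", "D")


class EnsembleFormatError(ValueError):
    """Raised for malformed or internally inconsistent structure files."""


@dataclass(frozen=True)
class Residue:
    index: int          # original PDB residue number (label)
    name: str           # 3-letter code
    chain: str


@dataclass
class MolecularTopology:
    """Ordered residues and atoms shared by every frame of an ensemble.

    Residue positions used in all matrix outputs are 0-based positions in
    ``residues``; the original PDB residue numbers survive as labels.
    """

    residues: list[Residue]
    atom_names: list[str]
    atom_residue: np.ndarray      # per-atom 0-based residue position
    elements: list[str]

    def __post_init__(self) -> None:
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        if len(self.atom_names) != len(self.atom_residue):
            raise ValueError("atom_names and atom_residue lengths differ")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_labels(self) -> list[str]:
        return [f"{r.chain}:{r.name}{r.index}" for r in self.residues]

    def same_as(self, other: "MolecularTopology") -> int | None:
        """Return the first differing atom index, or None if identical."""
        if self.n_atoms != other.n_atoms:
            return min(self.n_atoms, other.n_atoms)
        for i, (a, b) in enumerate(zip(self.atom_names, other.atom_names)):
            ra = self.residues[self.atom_residue[i]]
            rb = other.residues[other.atom_residue[i]]
            if a != b or ra.name != rb.name:
                return i
        return None


@dataclass
class ConformationEnsemble:
    """A topology plus frames of shape (n_frames, n_atoms, 3) in Å."""

    topology: MolecularTopology
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class AtomSelection:
    """A resolved atom subset of a topology.

    ``per_residue_groups`` maps each selected residue position to the
    indices of its selected atoms, preserving topology order.
    """

    name: str
    indices: np.ndarray
    per_residue_groups: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return self.indices.size


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, proper (det +1)
    translation: np.ndarray   # 3-vector, Å
    fit_rmsd: float           # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB parsing

def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise EnsembleFormatError(
            f"unparseable ATOM record at line {lineno}: {line.rstrip()!r}"
        ) from exc
    if not element:
        element = _guess_element(name)
    return name, altloc, resname, chain, resid, icode, (x, y, z), occupancy, element


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_multimodel_pdb(path: str | Path) -> ConformationEnsemble:
    """Read a multi-model (or single-structure) PDB file as an ensemble.

    One frame per MODEL record; the topology is taken from the first
    model and every later model is validated against it.  The
    highest-occupancy alternate location is kept per atom; residues with
    insertion codes are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    models: list[list] = []
    current: list | None = None
    seen_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                seen_model_record = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if seen_model_record:
                        continue  # stray atoms between models
                    current = []
                    models.append(current)
                current.append(_parse_atom_line(line, lineno))
    if current is not None and seen_model_record and current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EnsembleFormatError(f"no ATOM records found in {path}")

    frames = []
    topology: MolecularTopology | None = None
    ref_keys: list[tuple] | None = None
    for model_no, atoms in enumerate(models, start=1):
        topo, coords, keys = _build_model(atoms, path)
        if topology is None:
            topology, ref_keys = topo, keys
        elif keys != ref_keys:
            raise EnsembleFormatError(
                f"model {model_no} of {path} does not match model 1 "
                f"({len(keys)} atoms vs {len(ref_keys)})"
            )
        frames.append(coords)
    return ConformationEnsemble(topology, np.array(frames))


def _build_model(atoms: list, path: Path):
    """Resolve altlocs/icodes and build topology + coordinates for one model."""
    # group altlocs: keep highest occupancy per (chain, resid, resname, name)
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    n_icode_skipped = 0
    for entry in atoms:
        name, altloc, resname, chain, resid, icode, xyz, occ, element = entry
        if icode:
            n_icode_skipped += 1
            continue
        key = (chain, resid, resname, name)
        if key not in best:
            best[key] = entry
            order.append(key)
        elif occ > best[key][7]:
            best[key] = entry
    if n_icode_skipped:
        warnings.warn(
            f"{path}: skipped {n_icode_skipped} insertion-coded atom records",
            stacklevel=3,
        )

    residues: list[Residue] = []
    res_pos: dict[tuple, int] = {}
    atom_names, elements, atom_res, coords = [], [], [], []
    for key in order:
        name, _alt, resname, chain, resid, _ic, xyz, _occ, element = best[key]
        rkey = (chain, resid, resname)
        if rkey not in res_pos:
            res_pos[rkey] = len(residues)
            residues.append(Residue(resid, resname, chain))
        atom_names.append(name)
        elements.append(element)
        atom_res.append(res_pos[rkey])
        coords.append(xyz)
    topo = MolecularTopology(residues, atom_names, np.array(atom_res), elements)
    return topo, np.array(coords, dtype=float), order


def write_multimodel_pdb(ensemble: ConformationEnsemble, path: str | Path) -> None:
    """Write an ensemble as a MODEL/ENDMDL multi-model PDB file."""
    topo = ensemble.topology
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 1
            for i, name in enumerate(topo.atom_names):
                res = topo.residues[topo.atom_residue[i]]
                x, y, z = ensemble.frames[f, i]
                pdb_name = name if len(name) == 4 else f" {name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {pdb_name}{'':1s}{res.name:>3s} "
                    f"{res.chain:1s}{res.index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {topo.elements[i]:>2s}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(topology_path: str | Path, trajectory_path: str | Path) -> ConformationEnsemble:
    """Read an XTC/DCD trajectory with a PDB topology.

    Coordinates come back in Å (MDAnalysis converts nm-based formats).
    """
    import MDAnalysis as mda

    template = read_multimodel_pdb(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path), str(trajectory_path))
    if u.atoms.n_atoms != template.n_atoms:
        raise EnsembleFormatError(
            f"topology has {template.n_atoms} atoms but trajectory frames "
            f"have {u.atoms.n_atoms}"
        )
    frames = np.array([u.atoms.positions.astype(float) for _ in u.trajectory])
    return ConformationEnsemble(template.topology, frames)


def concat_ensembles(parts: list[ConformationEnsemble]) -> ConformationEnsemble:
    """Concatenate ensembles sharing one topology, e.g. repeat trajectories."""
    if not parts:
        raise ValueError("no ensembles to concatenate")
    if len(parts) == 1:
        return parts[0]
    first = parts[0]
    for k, part in enumerate(parts[1:], start=2):
        diff = first.topology.same_as(part.topology)
        if diff is not None:
            raise ValueError(
                f"ensemble {k} topology differs from ensemble 1 at atom index {diff}"
            )
    return ConformationEnsemble(
        first.topology, np.concatenate([p.frames for p in parts], axis=0)
    )


# ---------------------------------------------------------------------------
# Selections

def resolve_selection(topology: MolecularTopology, name: str) -> AtomSelection:
    """Resolve a named atom selection against a topology.

    calpha       one CA per residue (error if a residue lacks one)
    backbone_cb  N, CA, C, O and CB where present (glycine has no CB)
    heavy        every non-hydrogen atom
    """
    names = np.array(topology.atom_names)
    if name == "calpha":
        mask = names == "CA"
    elif name == "backbone_cb":
        mask = np.isin(names, ("N", "CA", "C", "O", "CB"))
    elif name == "heavy":
        mask = np.array([e not in _HYDROGEN_NAMES for e in topology.elements])
    else:
        raise ValueError(f"unrecognized selection name: {name!r}")

    indices = np.flatnonzero(mask)
    groups: dict[int, np.ndarray] = {}
    for idx in indices:
        groups.setdefault(int(topology.atom_residue[idx]), []).append(int(idx))
    groups = {r: np.array(v) for r, v in groups.items()}

    if name == "calpha":
        missing = [
            topology.residue_labels()[r]
            for r in range(topology.n_residues)
            if r not in groups
        ]
        if missing:
            raise ValueError(f"residues lacking a CA atom: {', '.join(missing)}")
        extra = [r for r, v in groups.items() if len(v) != 1]
        if extra:
            raise ValueError(f"residues with multiple CA atoms at positions {extra}")
    return AtomSelection(name, indices, groups)


# ---------------------------------------------------------------------------
# Superposition

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Closed-form SVD solution with the reflection branch excluded, so the
    returned rotation is always proper.  Both inputs are (n, 3) with
    n >= 3 and must not be collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for superposition, got {n}")

    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    P = mobile - mob_center
    Q = reference - ref_center

    # collinear point sets leave a free spin about the common axis
    if np.linalg.matrix_rank(P, tol=1e-8 * max(1.0, np.abs(P).max())) < 2:
        raise ValueError("degenerate (rank-deficient) point configuration")

    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_center - R @ mob_center
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd)


def align_ensemble(
    ensemble: ConformationEnsemble,
    reference: np.ndarray,
    fit_selection: AtomSelection,
) -> ConformationEnsemble:
    """Superpose every frame onto a reference using the fit selection.

    Each frame gets its own rigid transform, computed on the selected
    atoms and applied to all atoms.  ``reference`` may be a full-topology
    coordinate array or just the selected atoms' coordinates.
    """
    reference = np.asarray(reference, dtype=float)
    sel = fit_selection.indices
    if reference.shape[0] == ensemble.n_atoms:
        ref_sel = reference[sel]
    elif reference.shape[0] == sel.size:
        ref_sel = reference
    else:
        raise ValueError(
            f"reference has {reference.shape[0]} atoms; expected "
            f"{ensemble.n_atoms} (full) or {sel.size} (selection)"
        )
    out = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        sup = kabsch_superpose(ensemble.frames[f, sel], ref_sel)
        out[f] = sup.apply(ensemble.frames[f])
    return ConformationEnsemble(ensemble.topology, out)
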