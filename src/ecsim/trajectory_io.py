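"""Reading MD conformations into a frame matrix and writing selection output.

Supported inputs: multi-model PDB (MODEL/ENDMDL blocks), XYZ trajectories
(repeated count/comment/atom-line blocks) and plain delimited matrices
(one frame per row, columns = flattened x,y,z per atom).  The matrix format
is the documented interchange for anything a vendor toolkit would be needed
for.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C")

FORMATS = ("pdb", "xyz", "matrix")

_SUFFIX_TO_FORMAT = {
    ".pdb": "pdb", ".ent": "pdb",
    ".xyz": "xyz",
    ".csv": "matrix", ".tsv": "matrix", ".txt": "matrix", ".mat": "matrix",
    ".dat": "matrix",
}


class TrajectoryError(ValueError):
    """Structured error for malformed trajectory input."""


@dataclass
class FrameMatrix:
    """Conformations as an N_frames x m matrix (m = 3 * n_atoms, Angstrom).

    Every frame must have the same atoms in the same order; each atom
    contributes a contiguous (x, y, z) triple to its row.
    """

    values: np.ndarray
    frame_ids: np.ndarray = None
    atom_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TrajectoryError("frame matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise TrajectoryError("frame matrix contains non-finite values")
        n, m = self.values.shape
        if m == 0 or m % 3 != 0:
            raise TrajectoryError(
                f"row length {m} is not a positive multiple of 3")
        if self.frame_ids is None:
            self.frame_ids = np.arange(n)
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        if self.frame_ids.shape != (n,):
            raise TrajectoryError("frame_ids length must equal N_frames")
        if not self.atom_labels:
            self.atom_labels = [(i + 1, "X") for i in range(m // 3)]
        if len(self.atom_labels) != m // 3:
            raise TrajectoryError("atom_labels length must equal n_atoms")
        self.atom_labels = [(int(r), str(a)) for r, a in self.atom_labels]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.values.shape[1] // 3

    def coordinates(self, i: int) -> np.ndarray:
        """Frame ``i`` reshaped to (n_atoms, 3)."""
        return self.values[i].reshape(-1, 3)


def _wanted_names(atom_selection):
    if atom_selection is None or atom_selection == "all":
        return None
    if atom_selection == "backbone":
        return set(BACKBONE_ATOMS)
    if isinstance(atom_selection, str):
        raise ValueError(f"unknown atom selection {atom_selection!r}")
    return {str(n).strip() for n in atom_selection}


def _check_consistent(per_frame, what="atoms"):
    """Enforce identical atom count/order across frames; name the offender."""
    if not per_frame:
        raise TrajectoryError("no frames found")
    ref = per_frame[0]
    for i, cur in enumerate(per_frame[1:], start=1):
        if len(cur) != len(ref):
            raise TrajectoryError(
                f"frame {i}: expected {len(ref)} {what}, found {len(cur)}")
        if cur != ref:
            raise TrajectoryError(
                f"frame {i}: atom names/order differ from frame 0")


def _read_pdb(path, atom_selection):
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise TrajectoryError("no MODEL/ATOM records found")
    wanted = _wanted_names(atom_selection)
    rows, labels_per_frame = [], []
    for model in range(1, n_models + 1):
        atoms = pdb.get_structure(model=model, altloc="all")
        # keep altLoc ' ' (stored as '') or 'A' only, for a deterministic set
        if "altloc_id" in atoms.get_annotation_categories():
            alt = atoms.altloc_id
            atoms = atoms[(alt == "") | (alt == " ") | (alt == "A") | (alt == ".")]
        names = [n.strip() for n in atoms.atom_name]
        keep = [i for i, n in enumerate(names) if wanted is None or n in wanted]
        if not keep:
            raise TrajectoryError(
                f"frame {model - 1}: atom selection matched no atoms")
        atoms = atoms[keep]
        labels = [(int(r), n.strip())
                  for r, n in zip(atoms.res_id, atoms.atom_name)]
        labels_per_frame.append(labels)
        rows.append(np.asarray(atoms.coord, dtype=float).ravel())
    _check_consistent(labels_per_frame)
    return np.vstack(rows), labels_per_frame[0]


def _read_xyz(path, atom_selection):
    wanted = _wanted_names(atom_selection)
    rows, labels_per_frame = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos, frame = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryError(
                f"frame {frame}: expected atom count, got {lines[pos]!r}")
        block = lines[pos + 2: pos + 2 + count]
        if len(block) < count:
            raise TrajectoryError(
                f"frame {frame}: expected {count} atoms, found {len(block)}")
        coords, labels = [], []
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryError(
                    f"frame {frame}: malformed atom line {line!r}")
            name = parts[0].strip()
            if wanted is not None and name not in wanted:
                continue
            try:
                coords.extend(float(x) for x in parts[1:4])
            except ValueError:
                raise TrajectoryError(
                    f"frame {frame}: non-numeric coordinate in {line!r}")
            labels.append((k + 1, name))
        if not labels:
            raise TrajectoryError(
                f"frame {frame}: atom selection matched no atoms")
        rows.append(np.asarray(coords))
        labels_per_frame.append(labels)
        pos += 2 + count
        frame += 1
    _check_consistent(labels_per_frame)
    return np.vstack(rows), labels_per_frame[0]


def _read_matrix(path, atom_selection):
    if atom_selection not in (None, "all"):
        raise ValueError("matrix input carries no atom names; "
                         "use atom_selection='all'")
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else ("\t" if "\t" in first else None)
    try:
        values = np.loadtxt(str(path), delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise TrajectoryError(f"non-numeric value in matrix file: {exc}")
    return values, None


def read_frames(path, format: str | None = None,
                atom_selection="all") -> FrameMatrix:
    """Read conformations from ``path`` into a :class:`FrameMatrix`.

    Parameters
    ----------
    format:
        One of ``pdb``, ``xyz``, ``matrix``; inferred from the file suffix
        when omitted.
    atom_selection:
        ``"all"``, ``"backbone"`` (atom names N, CA, C — the protein
        backbone convention) or an explicit list of atom names.  Atoms are
        kept in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = _SUFFIX_TO_FORMAT.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    reader = {"pdb": _read_pdb, "xyz": _read_xyz, "matrix": _read_matrix}[format]
    values, labels = reader(path, atom_selection)
    return FrameMatrix(values=values, atom_labels=labels or [])


def write_matrix(frames: FrameMatrix, path, delimiter=",") -> None:
    """Write a frame matrix in the delimited interchange format.

    Uses 17 significant digits so that float64 values round-trip bit-exactly.
    """
    np.savetxt(str(path), frames.values, fmt="%.17g", delimiter=delimiter)


def write_xyz(frames: FrameMatrix, path, comment="frame") -> None:
    """Write frames as a repeated-block XYZ trajectory."""
    with open(path, "w") as fh:
        for i in range(frames.n_frames):
            fh.write(f"{frames.n_atoms}\n{comment} {frames.frame_ids[i]}\n")
            for (res, name), xyz in zip(frames.atom_labels,
                                        frames.coordinates(i)):
                fh.write(f"{name} {xyz[0]:.17g} {xyz[1]:.17g} {xyz[2]:.17g}\n")


def write_selection(result, path) -> None:
    """Write a selection as TSV: rank, frame_id, similarity at that step.

    Ranks are 1-based; the medoid step has no prior-set similarity and is
    written as NA.  Byte output is deterministic for a fixed result.
    """
    order = list(result.order)
    if not order:
        raise ValueError("cannot write an empty selection")
    sims = list(result.step_similarity)
    buf = io.StringIO()
    buf.write("rank\tframe_id\tsimilarity\n")
    for rank, (frame, sim) in enumerate(zip(order, sims), start=1):
        text = "NA" if sim is None or np.isnan(sim) else format(sim, ".12g")
        buf.write(f"{rank}\t{frame}\t{text}\n")
    Path(path).write_text(buf.getvalue())
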