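"""Periodic water configurations: containers, I/O and unit conventions.

A configuration ("frame") is a set of oxygen and hydrogen coordinates in an
orthorhombic periodic box, optionally tagged with a state point (temperature
in K, molar density in mol/l) and a per-molecule scalar annotation such as a
dipole magnitude in Debye.

Units are fixed throughout the package: Å for length, K for temperature,
mol/l for molar density.  Molar density converts to number density in Å⁻³
via Avogadro's number: n = ρ · N_A · 10⁻²⁷ (1 litre = 10²⁷ Å³).

The canonical on-disk format is extended XYZ with the box encoded in the
``Lattice="..."`` comment-line key.  PDB (CRYST1 + ATOM) is accepted
read-only.  Only orthorhombic cells are supported; triclinic input is a
hard error.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

AVOGADRO = 6.02214076e23  # mol^-1, CODATA exact

__all__ = [
    "AVOGADRO",
    "BoxedFrame",
    "MoleculeTopology",
    "StatePointSeries",
    "molar_to_number_density",
    "number_to_molar_density",
    "box_edge_for",
    "wrap",
    "infer_topology",
    "read_frames",
    "write_frames",
]


def molar_to_number_density(molar_density: float) -> float:
    """Convert molar density (mol/l) to number density (Å⁻³)."""
    return molar_density * AVOGADRO * 1e-27


def number_to_molar_density(number_density: float) -> float:
    """Convert number density (Å⁻³) to molar density (mol/l)."""
    return number_density / (AVOGADRO * 1e-27)


def box_edge_for(n_molecules: int, molar_density: float) -> float:
    """Cubic box edge (Å) holding ``n_molecules`` at ``molar_density`` mol/l."""
    return float((n_molecules / molar_to_number_density(molar_density)) ** (1.0 / 3.0))


@dataclasses.dataclass
class BoxedFrame:
    """One periodic configuration of water molecules.

    Parameters
    ----------
    oxygen_positions : (N, 3) float array, Å
    hydrogen_positions : (2N, 3) float array, Å
        Hydrogens need not be ordered by molecule; use
        :func:`infer_topology` to recover the O–H assignment.
    box : (3,) float array, Å
        Orthorhombic edge lengths, all strictly positive.
    temperature : float or None, K
    molar_density : float or None, mol/l
    per_molecule_scalar : (N,) float array or None
        Optional annotation carried through the analysis (e.g. a dipole
        magnitude in Debye).  Never computed here.
    """

    oxygen_positions: np.ndarray
    hydrogen_positions: np.ndarray
    box: np.ndarray
    temperature: float | None = None
    molar_density: float | None = None
    per_molecule_scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.oxygen_positions = np.atleast_2d(np.asarray(self.oxygen_positions, dtype=float))
        self.hydrogen_positions = np.atleast_2d(np.asarray(self.hydrogen_positions, dtype=float))
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise ValueError(f"box edges must be strictly positive, got {self.box}")
        if self.oxygen_positions.shape[1] != 3 or self.hydrogen_positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3) arrays")
        if self.per_molecule_scalar is not None:
            self.per_molecule_scalar = np.asarray(self.per_molecule_scalar, dtype=float)
            if self.per_molecule_scalar.shape != (self.n_molecules,):
                raise ValueError("per_molecule_scalar must have one entry per molecule")

    @property
    def n_molecules(self) -> int:
        return self.oxygen_positions.shape[0]

    @property
    def volume(self) -> float:
        """Box volume in Å³."""
        return float(np.prod(self.box))

    @property
    def number_density(self) -> float:
        """Molecular number density N/V in Å⁻³."""
        return self.n_molecules / self.volume

    def check_molecular(self) -> None:
        """Raise unless the H count is twice the O count."""
        if self.hydrogen_positions.shape[0] != 2 * self.n_molecules:
            raise ValueError(
                f"molecular water requires 2 hydrogens per oxygen: "
                f"{self.n_molecules} O, {self.hydrogen_positions.shape[0]} H"
            )


@dataclasses.dataclass(frozen=True)
class MoleculeTopology:
    """Assignment of hydrogens to molecules: row i holds O i's two H indices."""

    hydrogen_indices: np.ndarray  # (N, 2) int

    @property
    def n_molecules(self) -> int:
        return self.hydrogen_indices.shape[0]


@dataclasses.dataclass
class StatePointSeries:
    """An ordered (temperature, value) series at fixed density, e.g. an isochore.

    Temperatures must be strictly increasing (hence unique).
    """

    temperatures: np.ndarray  # K
    values: np.ndarray
    label: str = ""
    errors: np.ndarray | None = None  # per-point 1-sigma error bars, optional

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.shape != self.values.shape:
            raise ValueError("temperatures and values must be equal-length 1-d arrays")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.temperatures.shape:
                raise ValueError("errors must match the series length")

    def __len__(self) -> int:
        return self.temperatures.size


def wrap(frame: BoxedFrame) -> BoxedFrame:
    """Reduce all coordinates into the primary cell [0, box edge).

    Minimum-image pair distances are unchanged; the operation is idempotent.
    """
    return dataclasses.replace(
        frame,
        oxygen_positions=np.mod(frame.oxygen_positions, frame.box),
        hydrogen_positions=np.mod(frame.hydrogen_positions, frame.box),
    )


def _min_image_delta(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = a - b
    return d - box * np.round(d / box)


def infer_topology(frame: BoxedFrame, oh_cutoff: float = 1.2) -> MoleculeTopology:
    """Assign each hydrogen to its nearest oxygen under minimum image.

    Fails (rather than returning a broken molecule) if any oxygen does not
    end up with exactly two hydrogens within ``oh_cutoff`` Å.
    """
    frame.check_molecular()
    o = frame.oxygen_positions
    h = frame.hydrogen_positions
    # (2N, N, 3) displacement tensor is fine at the N≈300 scale.
    delta = _min_image_delta(h[:, None, :], o[None, :, :], frame.box)
    dist = np.linalg.norm(delta, axis=-1)
    nearest = np.argmin(dist, axis=1)
    nearest_dist = dist[np.arange(h.shape[0]), nearest]

    stray = np.nonzero(nearest_dist >= oh_cutoff)[0]
    if stray.size:
        raise ValueError(
            f"hydrogens {stray.tolist()} are farther than {oh_cutoff} Å "
            "from every oxygen (dissociated input?)"
        )
    assignment = np.full((frame.n_molecules, 2), -1, dtype=int)
    counts = np.zeros(frame.n_molecules, dtype=int)
    for h_idx, o_idx in enumerate(nearest):
        if counts[o_idx] < 2:
            assignment[o_idx, counts[o_idx]] = h_idx
        counts[o_idx] += 1
    bad = np.nonzero(counts != 2)[0]
    if bad.size:
        raise ValueError(
            f"oxygens {bad.tolist()} have != 2 hydrogens within {oh_cutoff} Å "
            f"(counts {counts[bad].tolist()})"
        )
    return MoleculeTopology(hydrogen_indices=assignment)


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_KEYVAL_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KEYVAL_RE.finditer(comment)}


def _lattice_to_box(lattice: str, where: str) -> np.ndarray:
    cell = np.fromstring(lattice, sep=" ")
    if cell.size != 9:
        raise ValueError(f"{where}: Lattice must hold 9 numbers, got {cell.size}")
    cell = cell.reshape(3, 3)
    off = cell - np.diag(np.diag(cell))
    if np.any(np.abs(off) > 1e-8):
        raise ValueError(f"{where}: only orthorhombic (diagonal) lattices are supported")
    return np.diag(cell).copy()


def _read_extxyz(path: Path) -> list[BoxedFrame]:
    frames: list[BoxedFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame_idx}: bad atom-count line {lines[pos]!r}") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        keys = _parse_comment(comment)
        if "Lattice" not in keys:
            raise ValueError(f"frame {frame_idx}: no box (missing Lattice= in comment line)")
        box = _lattice_to_box(keys["Lattice"], f"frame {frame_idx}")

        o_rows: list[list[float]] = []
        h_rows: list[list[float]] = []
        scalars: list[float] = []
        for line in lines[pos + 2 : pos + 2 + natoms]:
            parts = line.split()
            elem = parts[0]
            xyz = [float(v) for v in parts[1:4]]
            if elem == "O":
                o_rows.append(xyz)
                if len(parts) > 4:
                    scalars.append(float(parts[4]))
            elif elem == "H":
                h_rows.append(xyz)
            else:
                raise ValueError(f"frame {frame_idx}: unsupported element {elem!r} (only O/H)")
        temperature = float(keys["Temperature"]) if "Temperature" in keys else None
        density = float(keys["MolarDensity"]) if "MolarDensity" in keys else None
        frames.append(
            BoxedFrame(
                oxygen_positions=np.array(o_rows),
                hydrogen_positions=np.array(h_rows) if h_rows else np.empty((0, 3)),
                box=box,
                temperature=temperature,
                molar_density=density,
                per_molecule_scalar=np.array(scalars) if len(scalars) == len(o_rows) and scalars else None,
            )
        )
        pos += 2 + natoms
        frame_idx += 1
    return frames


def write_frames(frames: Iterable[BoxedFrame], path: str | Path, precision: int = 8) -> None:
    """Write frames as extended XYZ (box in the ``Lattice`` comment key).

    Oxygens are written first, then hydrogens; an optional per-molecule
    scalar becomes a trailing column on the oxygen records.
    """
    path = Path(path)
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        for frame in frames:
            n = frame.n_molecules + frame.hydrogen_positions.shape[0]
            lx, ly, lz = frame.box
            comment = (
                f'Lattice="{lx:.8f} 0.0 0.0 0.0 {ly:.8f} 0.0 0.0 0.0 {lz:.8f}" '
                'Properties=species:S:1:pos:R:3'
            )
            if frame.per_molecule_scalar is not None:
                comment += ":scalar:R:1"
            if frame.temperature is not None:
                comment += f" Temperature={frame.temperature:g}"
            if frame.molar_density is not None:
                comment += f" MolarDensity={frame.molar_density:.6f}"
            fh.write(f"{n}\n{comment}\n")
            for i, row in enumerate(frame.oxygen_positions):
                line = "O " + " ".join(fmt.format(v) for v in row)
                if frame.per_molecule_scalar is not None:
                    line += " " + fmt.format(frame.per_molecule_scalar[i])
                fh.write(line + "\n")
            for row in frame.hydrogen_positions:
                fh.write("H " + " ".join(fmt.format(v) for v in row) + "\n")


def _read_pdb(path: Path) -> list[BoxedFrame]:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    frames: list[BoxedFrame] = []
    elements = np.array([name.strip()[0].upper() for name in u.atoms.names])
    bad = set(elements) - {"O", "H"}
    if bad:
        raise ValueError(f"unsupported elements in PDB: {sorted(bad)} (only O/H)")
    for i, ts in enumerate(u.trajectory):
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise ValueError(f"frame {i}: no box (missing or empty CRYST1 record)")
        if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
            raise ValueError(f"frame {i}: only orthorhombic cells supported, "
                             f"angles {ts.dimensions[3:]}")
        coords = u.atoms.positions.astype(float)
        frames.append(
            BoxedFrame(
                oxygen_positions=coords[elements == "O"],
                hydrogen_positions=coords[elements == "H"],
                box=ts.dimensions[:3].astype(float),
            )
        )
    return frames


def read_frames(path: str | Path, format: str | None = None) -> list[BoxedFrame]:
    """Read configurations from extended XYZ or PDB.

    ``format`` is ``"extxyz"`` or ``"pdb"``; inferred from the suffix when
    omitted.  Frames are returned in file order with coordinates in Å.
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() == ".pdb" else "extxyz"
    if format in ("extxyz", "extended-xyz", "xyz"):
        return _read_extxyz(path)
    if format == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unknown format {format!r} (use 'extxyz' or 'pdb')")
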