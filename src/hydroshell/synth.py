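"""Synthetic water configurations with known ground truth.

Four generators emulate the statistical structure the analysis assumes,
without any molecular dynamics:

* :func:`ideal_gas` — structureless configurations: oxygens uniform in the
  box, rigid monomers in random orientations.  The reference state in
  which the tetrahedrality Q averages zero.
* :func:`tetrahedral_lattice` — a diamond-cubic oxygen sublattice (the
  topology of cubic ice) with ice-like hydrogen placement and Gaussian
  thermal noise.  At zero noise every molecule has Q = 1 exactly.
* :func:`two_state_mixture` — well separated molecular clusters whose
  second coordination shell is either expanded ("LDA-like", after
  low-density amorphous ice at 51.86 mol/l) or collapsed with one
  interstitial neighbour ("HDA-like", after high-density amorphous ice at
  64.76 mol/l), with per-site ground-truth labels.
* :func:`motif_fixture` — a central molecule plus the minimal partner set
  realising one exact hydrogen-bond motif (free, D, …, DDAAA).

All generators are deterministic given their seed.  Monomers are rigid
with the gas-phase geometry r_OH = 0.96 Å, H–O–H = 104.5°; lattice
hydrogens sit on tetrahedral bond directions (H–O–H = 109.47°, the ice
geometry).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from .frames import (
    BoxedFrame,
    box_edge_for,
    molar_to_number_density,
    number_to_molar_density,
)

__all__ = [
    "GeneratorSpec",
    "generate",
    "ideal_gas",
    "tetrahedral_lattice",
    "two_state_mixture",
    "MixtureFrame",
    "motif_fixture",
    "R_OH",
    "HOH_ANGLE",
    "LDA_MOLAR_DENSITY",
    "HDA_MOLAR_DENSITY",
]

R_OH = 0.96  # Å, gas-phase O–H bond length
HOH_ANGLE = 104.5  # degrees, gas-phase bend angle

#: Experimental molar densities of the amorphous ices that anchor the
#: two-state templates (mol/l).
LDA_MOLAR_DENSITY = 51.86
HDA_MOLAR_DENSITY = 64.76

#: Stylised interstitial O–O distance of the HDA-like template (Å): between
#: the first shell and the hydrogen-bond cutoff, so the fifth neighbour of a
#: collapsed environment sits inside 3.5 Å.
HDA_INTERSTITIAL_R = 3.30

# Tetrahedral bond directions of the diamond lattice's A sublattice.
_TETRA_DIRS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclasses.dataclass
class GeneratorSpec:
    """Declarative description of one synthetic configuration."""

    kind: str  # ideal_gas | tetrahedral_lattice | two_state_mixture | motif_fixture
    n_molecules: int = 300
    molar_density: float = 55.3173  # mol/l (ambient water)
    sigma: float = 0.0  # Å, Gaussian thermal displacement
    fraction: float = 0.5  # LDA-like fraction for mixtures
    seed: int = 0
    motif: str = "DDAA"  # fixtures only

    def __post_init__(self) -> None:
        if self.molar_density <= 0:
            raise ValueError("density must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def generate(spec: GeneratorSpec):
    """Dispatch on ``spec.kind``; see the individual generators."""
    if spec.kind == "ideal_gas":
        return ideal_gas(spec.n_molecules, spec.molar_density, seed=spec.seed)
    if spec.kind == "tetrahedral_lattice":
        return tetrahedral_lattice(
            spec.n_molecules, spec.molar_density, sigma=spec.sigma, seed=spec.seed
        )
    if spec.kind == "two_state_mixture":
        return two_state_mixture(
            spec.n_molecules, fraction=spec.fraction, sigma=spec.sigma, seed=spec.seed
        )
    if spec.kind == "motif_fixture":
        return motif_fixture(spec.motif)
    raise ValueError(f"unknown generator kind {spec.kind!r}")


def _monomer_oh_vectors() -> np.ndarray:
    """The two O→H unit vectors of the reference monomer (bisector on +z)."""
    half = np.deg2rad(HOH_ANGLE / 2.0)
    return np.array(
        [[np.sin(half), 0.0, np.cos(half)], [-np.sin(half), 0.0, np.cos(half)]]
    )


def _random_hydrogens(o_pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two hydrogens per oxygen, rigid monomers in uniform random orientations."""
    n = o_pos.shape[0]
    rots = Rotation.random(n, random_state=rng)
    oh = _monomer_oh_vectors()  # (2, 3)
    h = np.empty((2 * n, 3))
    mats = rots.as_matrix()  # (n, 3, 3)
    h[0::2] = o_pos + R_OH * np.einsum("nij,j->ni", mats, oh[0])
    h[1::2] = o_pos + R_OH * np.einsum("nij,j->ni", mats, oh[1])
    return h


def ideal_gas(
    n_molecules: int = 300,
    molar_density: float = 55.3173,
    seed: int = 0,
    temperature: float | None = None,
) -> BoxedFrame:
    """Structureless configuration: uniform oxygens, random orientations."""
    rng = np.random.default_rng(seed)
    edge = box_edge_for(n_molecules, molar_density)
    box = np.full(3, edge)
    o = rng.uniform(0.0, edge, size=(n_molecules, 3))
    h = _random_hydrogens(o, rng)
    return BoxedFrame(
        oxygen_positions=o,
        hydrogen_positions=np.mod(h, box),
        box=box,
        temperature=temperature,
        molar_density=molar_density,
    )


def admissible_lattice_counts(limit: int = 4096) -> list[int]:
    """Molecule counts compatible with diamond-cubic replication (8·m³)."""
    counts = []
    m = 1
    while 8 * m**3 <= limit:
        counts.append(8 * m**3)
        m += 1
    return counts


def tetrahedral_lattice(
    n_molecules: int = 216,
    molar_density: float = LDA_MOLAR_DENSITY,
    sigma: float = 0.0,
    seed: int = 0,
    temperature: float | None = None,
) -> BoxedFrame:
    """Diamond-cubic ("ice-like") configuration with thermal noise.

    Oxygens occupy a diamond-cubic sublattice scaled to the requested
    density; each oxygen's two hydrogens point along two of its four bond
    directions, chosen at random per site (local motif statistics, not
    globally ice-rule-consistent).  Gaussian noise of width ``sigma`` is
    applied to every atom.  ``n_molecules`` must equal 8·m³.
    """
    m = round((n_molecules / 8) ** (1.0 / 3.0))
    if 8 * m**3 != n_molecules:
        raise ValueError(
            f"n_molecules={n_molecules} incompatible with diamond-cubic "
            f"replication; admissible counts: {admissible_lattice_counts()}"
        )
    rng = np.random.default_rng(seed)
    number_density = molar_to_number_density(molar_density)
    a = (8.0 / number_density) ** (1.0 / 3.0)  # conventional cell edge
    fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    cells = np.array([[i, j, k] for i in range(m) for j in range(m) for k in range(m)])
    sub_a = (cells[:, None, :] + fcc[None, :, :]).reshape(-1, 3)
    o_frac = np.concatenate([sub_a, sub_a + 0.25])  # B sublattice shifted ¼¼¼
    o = a * o_frac
    n = o.shape[0]
    # bond directions: +tetra for sublattice A, −tetra for B
    dirs = np.concatenate(
        [np.tile(_TETRA_DIRS, (n // 2, 1, 1)), np.tile(-_TETRA_DIRS, (n // 2, 1, 1))]
    )
    h = np.empty((2 * n, 3))
    for i in range(n):
        two = rng.choice(4, size=2, replace=False)
        h[2 * i] = o[i] + R_OH * dirs[i, two[0]]
        h[2 * i + 1] = o[i] + R_OH * dirs[i, two[1]]
    if sigma > 0:
        # rigid-molecule displacements: monomers translate as units, so the
        # O-H geometry (and hence topology inference) survives any sigma
        disp = rng.normal(0.0, sigma, size=o.shape)
        o = o + disp
        h = h + np.repeat(disp, 2, axis=0)
    box = np.full(3, a * m)
    return BoxedFrame(
        oxygen_positions=np.mod(o, box),
        hydrogen_positions=np.mod(h, box),
        box=box,
        temperature=temperature,
        molar_density=molar_density,
    )


# ---------------------------------------------------------------------------
# two-state mixture
# ---------------------------------------------------------------------------

def _template_radii() -> dict[str, float]:
    """Shell radii (Å) derived from the amorphous-ice anchor densities.

    The first shell is taken from the LDA-density diamond lattice (the
    incompressible shell); the second-shell radius is the lattice
    second-neighbour distance a/√2 at each anchor density.
    """
    a_lda = (8.0 / molar_to_number_density(LDA_MOLAR_DENSITY)) ** (1.0 / 3.0)
    a_hda = (8.0 / molar_to_number_density(HDA_MOLAR_DENSITY)) ** (1.0 / 3.0)
    return {
        "r_first": a_lda * np.sqrt(3.0) / 4.0,
        "r_second_lda": a_lda / np.sqrt(2.0),
        "r_second_hda": a_hda / np.sqrt(2.0),
        "r_interstitial": HDA_INTERSTITIAL_R,
    }


@dataclasses.dataclass
class MixtureFrame:
    """A two-state frame plus its ground truth.

    ``labels[i]`` ("LDA" or "HDA") is the true state of central site i,
    whose molecule index is ``center_indices[i]``.
    """

    frame: BoxedFrame
    labels: np.ndarray  # (n_centers,) str
    center_indices: np.ndarray  # (n_centers,) int


def two_state_mixture(
    n_molecules: int = 300,
    fraction: float = 0.5,
    sigma: float = 0.1,
    seed: int = 0,
    temperature: float | None = None,
    spacing: float = 12.0,
) -> MixtureFrame:
    """Mixture of expanded- and collapsed-second-shell local environments.

    ``n_molecules`` central sites are placed on a cubic grid of pitch
    ``spacing`` (wide enough that cluster environments do not interfere); a
    fraction ``fraction`` of them receive the LDA-like template (4 first
    shell + 6 second shell at the expanded radius, no interstitial) and
    the rest the HDA-like template (4 first shell + 1 interstitial inside
    3.5 Å + 6 second shell at the collapsed radius).  Gaussian noise
    ``sigma`` displaces every atom.  The frame's recorded molar density is
    the *resulting* one — the grid, not the density, is the control here.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    radii = _template_radii()
    m = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    edge = m * spacing
    grid = (np.array(
        [[i, j, k] for i in range(m) for j in range(m) for k in range(m)]
    )[:n_molecules] + 0.5) * spacing

    n_lda = int(round(fraction * n_molecules))
    labels = np.array(["HDA"] * n_molecules, dtype=object)
    labels[rng.permutation(n_molecules)[:n_lda]] = "LDA"

    second_dirs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    centers = []
    partners = []
    for i in range(n_molecules):
        rot = Rotation.random(random_state=rng).as_matrix()
        c = grid[i]
        centers.append(c)
        tet = _TETRA_DIRS @ rot.T
        partners.extend(c + radii["r_first"] * tet)
        if labels[i] == "LDA":
            r2 = radii["r_second_lda"]
        else:
            r2 = radii["r_second_hda"]
            partners.append(c - radii["r_interstitial"] * tet[0])
        partners.extend(c + r2 * (second_dirs @ rot.T))

    o = np.concatenate([np.array(centers), np.array(partners)])
    if sigma > 0:
        o = o + rng.normal(0.0, sigma, size=o.shape)
    h = _random_hydrogens(o, rng)
    box = np.full(3, edge)
    frame = BoxedFrame(
        oxygen_positions=np.mod(o, box),
        hydrogen_positions=np.mod(h, box),
        box=box,
        temperature=temperature,
        molar_density=number_to_molar_density(o.shape[0] / edge**3),
    )
    return MixtureFrame(
        frame=frame,
        labels=labels.astype(str),
        center_indices=np.arange(n_molecules),
    )


# ---------------------------------------------------------------------------
# motif fixtures
# ---------------------------------------------------------------------------

_VALID_MOTIFS = {"free", "D", "A", "DA", "DD", "AA", "DDA", "DAA", "DDAA", "DDAAA"}

_HB_ROO = 2.8  # Å, ideal donor–acceptor O–O separation


def _perp_unit(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = ref - np.dot(ref, u) * u
    return w / np.linalg.norm(w)


def motif_fixture(label: str, box_edge: float = 30.0) -> BoxedFrame:
    """Minimal cluster whose central molecule has exactly motif ``label``.

    The central molecule sits at the box centre (molecule index 0).  Each
    donated bond places an acceptor partner 2.8 Å along one of the central
    O–H directions (donor angle 0°); each accepted bond places a donor
    partner 2.8 Å along a lone-pair-like direction with one hydrogen
    pointing straight at the central oxygen.  Partner orientations are
    chosen so no spurious bonds arise.
    """
    if label not in _VALID_MOTIFS:
        raise ValueError(f"unknown motif label {label!r}; valid: {sorted(_VALID_MOTIFS)}")
    n_d = label.count("D")
    n_a = label.count("A")

    c = np.full(3, box_edge / 2.0)
    oh = _monomer_oh_vectors()  # h1, h2 with bisector +z
    # lone-pair-like directions below the molecular (x–z) plane, plus the
    # anti-bisector: pairwise far enough apart or orientation-protected
    half_t = np.deg2rad(109.47 / 2.0)
    lp = np.array(
        [
            [0.0, np.sin(half_t), -np.cos(half_t)],
            [0.0, -np.sin(half_t), -np.cos(half_t)],
            [0.0, 0.0, -1.0],
        ]
    )

    o_list = [c]
    h_list = [c + R_OH * oh[0], c + R_OH * oh[1]]

    cos_b = np.cos(np.deg2rad(HOH_ANGLE))
    sin_b = np.sin(np.deg2rad(HOH_ANGLE))
    for u in oh[:n_d]:  # acceptor partners: central donates along its O–H
        p = c + _HB_ROO * u
        w = _perp_unit(u)
        o_list.append(p)
        h_list.append(p + R_OH * u)  # points radially outward
        h_list.append(p + R_OH * (cos_b * u + sin_b * w))
    for u in lp[:n_a]:  # donor partners: one H aimed at the central oxygen
        p = c + _HB_ROO * u
        w = _perp_unit(u)
        o_list.append(p)
        h_list.append(p - R_OH * u)  # straight at the central O
        h_list.append(p + R_OH * (-cos_b * u + sin_b * w))
    return BoxedFrame(
        oxygen_positions=np.array(o_list),
        hydrogen_positions=np.array(h_list),
        box=np.full(3, box_edge),
    )
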