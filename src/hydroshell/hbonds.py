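"""Directed hydrogen-bond graphs and donor/acceptor motif classification.

A donor bond leaves a molecule through one of its hydrogens and ends on
another molecule's oxygen (the acceptor).  The default geometric criterion
is the field-standard one: O_d–O_a minimum-image distance < 3.5 Å and the
donor-centred angle between O_d→H and O_d→O_a < 30°, both strict
inequalities so counts are reproducible bit-for-bit.  Each hydrogen donates
at most one bond (no bifurcated donors): when several acceptors satisfy the
criterion the smallest angle wins, ties broken by molecule index.

Motifs label each molecule by its donor count n_D (≤ 2) and acceptor count
n_A: "DDAA" is the tetrahedral motif, "DDA"/"DAA" the three-bonded ones,
"DDAAA" the five-bonded species.  Acceptor counts above 3 are folded into
the 3-acceptor tail (and logged); molecules with no bonds are "free".
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .frames import BoxedFrame, MoleculeTopology, infer_topology

logger = logging.getLogger(__name__)

__all__ = [
    "HBGraph",
    "detect_hbonds",
    "classify_motifs",
    "MotifDistribution",
    "motif_populations",
    "asymmetry",
    "MOTIF_LABELS",
]

#: Canonical label order for reporting (donor count then acceptor count).
MOTIF_LABELS = ["free", "D", "A", "DA", "DD", "AA", "DDA", "DAA", "DDAA", "DDAAA"]

ROO_MAX = 3.5  # Å
ANGLE_MAX = 30.0  # degrees


@dataclasses.dataclass
class HBGraph:
    """Directed donor→acceptor bond graph for one frame.

    ``edges`` rows are (donor molecule, hydrogen index, acceptor molecule).
    Σ n_donor = Σ n_acceptor = number of edges, and no self-edges exist.
    """

    edges: np.ndarray  # (E, 3) int
    n_donor: np.ndarray  # (N,) int
    n_acceptor: np.ndarray  # (N,) int

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def detect_hbonds(
    frame: BoxedFrame,
    topology: MoleculeTopology | None = None,
    roo_max: float = ROO_MAX,
    angle_max: float = ANGLE_MAX,
    angle_convention: str = "donor-oo",
) -> HBGraph:
    """Geometric hydrogen-bond detection.

    ``angle_convention`` selects where the angle is measured:

    * ``"donor-oo"`` (default): angle at the donor oxygen between O_d→H
      and O_d→O_a.
    * ``"h-da"``: deviation from linearity at the hydrogen, i.e. the angle
      between O_d→H and H→O_a.

    Both thresholds are strict (< , not ≤).
    """
    if angle_convention not in ("donor-oo", "h-da"):
        raise ValueError(f"unknown angle convention {angle_convention!r}")
    if topology is None:
        topology = infer_topology(frame)
    n = frame.n_molecules
    o = frame.oxygen_positions
    h = frame.hydrogen_positions
    box = frame.box

    doo = o[:, None, :] - o[None, :, :]
    doo -= box * np.round(doo / box)
    roo = np.linalg.norm(doo, axis=-1)

    cos_max = np.cos(np.deg2rad(angle_max))
    edges: list[tuple[int, int, int]] = []
    for donor in range(n):
        cand = np.nonzero((roo[donor] < roo_max) & (np.arange(n) != donor))[0]
        if cand.size == 0:
            continue
        to_acc = -doo[donor, cand]  # O_d → O_a, minimum image
        to_acc_u = to_acc / np.linalg.norm(to_acc, axis=-1, keepdims=True)
        for h_idx in topology.hydrogen_indices[donor]:
            oh = h[h_idx] - o[donor]
            oh -= box * np.round(oh / box)
            if angle_convention == "donor-oo":
                cosang = to_acc_u @ (oh / np.linalg.norm(oh))
            else:  # h-da: angle between O_d→H and H→O_a
                ha = to_acc - oh
                ha_u = ha / np.linalg.norm(ha, axis=-1, keepdims=True)
                cosang = ha_u @ (oh / np.linalg.norm(oh))
            # strict inequality (angle < angle_max); the 1e-12 guard keeps
            # geometries at exactly the threshold out regardless of rounding
            ok = cosang - cos_max > 1e-12
            if not np.any(ok):
                continue
            # best (smallest) angle wins; stable argmax on cosang breaks
            # exact ties by ascending candidate (molecule) index
            best = cand[ok][int(np.argmax(cosang[ok]))]
            edges.append((donor, int(h_idx), int(best)))

    edge_arr = np.array(edges, dtype=int).reshape(-1, 3)
    n_donor = np.bincount(edge_arr[:, 0], minlength=n)
    n_acceptor = np.bincount(edge_arr[:, 2], minlength=n)
    return HBGraph(edges=edge_arr, n_donor=n_donor, n_acceptor=n_acceptor)


def classify_motifs(graph: HBGraph) -> list[str]:
    """Per-molecule motif label "D"×n_D + "A"×n_A; zero bonds → "free"."""
    n_over = int(np.count_nonzero(graph.n_acceptor > 3))
    if n_over:
        logger.info("classify_motifs: %d molecules with >3 acceptor bonds "
                    "folded into the 3-acceptor tail", n_over)
    labels = []
    for nd, na in zip(graph.n_donor, graph.n_acceptor):
        na = min(int(na), 3)
        nd = int(nd)
        labels.append("D" * nd + "A" * na if nd + na else "free")
    return labels


@dataclasses.dataclass
class MotifDistribution:
    """Normalised motif probabilities at one state point."""

    probabilities: dict[str, float]
    temperature: float | None = None
    molar_density: float | None = None
    n_samples: int = 0

    def p(self, label: str) -> float:
        return self.probabilities.get(label, 0.0)


def motif_populations(
    frames: Sequence[BoxedFrame],
    temperature: float | None = None,
    molar_density: float | None = None,
    **criterion,
) -> MotifDistribution:
    """Pooled motif frequencies over all molecules and frames.

    Extra keyword arguments (``roo_max``, ``angle_max``,
    ``angle_convention``) are forwarded to :func:`detect_hbonds`.
    """
    if not len(frames):
        raise ValueError("frames must be non-empty")
    counts: dict[str, int] = {}
    total = 0
    for frame in frames:
        graph = detect_hbonds(frame, **criterion)
        for label in classify_motifs(graph):
            counts[label] = counts.get(label, 0) + 1
            total += 1
    return MotifDistribution(
        probabilities={k: v / total for k, v in counts.items()},
        temperature=temperature,
        molar_density=molar_density,
        n_samples=total,
    )


def asymmetry(dist: MotifDistribution) -> float:
    """Donor/acceptor asymmetry P(DDA) − P(DAA).

    A positive value means an excess of double-donor three-bonded
    molecules; the population of the five-bonded DDAAA species
    (``dist.p("DDAAA")``) indicates the strength of the asymmetry.
    """
    return dist.p("DDA") - dist.p("DAA")
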