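"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorised minimum-image
arithmetic: distances are minimised explicitly over all 27 periodic images
so they can serve as an independent reference.
"""

import numpy as np
import pytest

from hydroshell import BoxedFrame

SHIFTS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


def brute_min_image(a, b, box):
    """Minimum |a - b + n·box| over the 27 neighbouring images."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    box = np.asarray(box, float)
    return float(np.linalg.norm(a - b + SHIFTS * box, axis=1).min())


def brute_distance_matrix(positions, box):
    n = len(positions)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = brute_min_image(positions[i], positions[j], box)
            out[i, j] = out[j, i] = d
    return out


def brute_neighbor_lists(positions, box, max_rank):
    """Per-molecule sorted (distance, index) lists; ties by smaller index."""
    n = len(positions)
    tables = []
    for i in range(n):
        pairs = sorted(
            (brute_min_image(positions[i], positions[j], box), j)
            for j in range(n)
            if j != i
        )
        tables.append(pairs[:max_rank])
    return tables


def brute_hbond_edges(frame, topology, roo_max=3.5, angle_max=30.0):
    """Independent donor→acceptor edge set (donor-centred O–O/O–H angle).

    Pure-python loops; each hydrogen keeps only its best-angle acceptor.
    """
    o = frame.oxygen_positions
    h = frame.hydrogen_positions
    box = frame.box
    n = frame.n_molecules
    edges = set()
    for donor in range(n):
        for h_idx in topology.hydrogen_indices[donor]:
            # minimum-image O->H vector via explicit image search
            best_img = min(
                (np.linalg.norm(h[h_idx] - o[donor] + s * box), tuple(s))
                for s in SHIFTS
            )[1]
            oh = h[h_idx] - o[donor] + np.array(best_img) * box
            best = None
            for acc in range(n):
                if acc == donor:
                    continue
                img = min(
                    (np.linalg.norm(o[acc] - o[donor] + s * box), tuple(s))
                    for s in SHIFTS
                )
                roo, shift = img
                if not roo < roo_max:
                    continue
                ooa = o[acc] - o[donor] + np.array(shift) * box
                cosang = np.dot(oh, ooa) / (np.linalg.norm(oh) * np.linalg.norm(ooa))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if not angle < angle_max:
                    continue
                if best is None or angle < best[0] - 1e-12:
                    best = (angle, acc)
            if best is not None:
                edges.add((donor, int(h_idx), best[1]))
    return edges


def cluster_frame(center, neighbor_offsets, box_edge=40.0):
    """An oxygen-only frame: one molecule at ``center`` plus offsets from it."""
    center = np.asarray(center, float)
    o = np.vstack([center, center + np.asarray(neighbor_offsets, float)])
    return BoxedFrame(
        oxygen_positions=o,
        hydrogen_positions=np.empty((0, 3)),
        box=np.full(3, box_edge),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
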