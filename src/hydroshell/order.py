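"""Per-molecule structural order parameters: tetrahedrality Q, LSI and d5.

Q measures first-shell orientational order over a molecule's four nearest
oxygens; it is 1 for a perfect tetrahedron and averages 0 over a
structureless (ideal-gas) shell.  The local structure index (LSI, Å²)
measures how cleanly the first and second coordination shells are
separated; d5 (Å), the distance to the fifth-nearest oxygen, tracks the
neighbour that fluctuates between the two shells and discriminates
low-density (d5 large) from high-density (d5 small) environments.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .frames import BoxedFrame
from .neighbors import NeighborTable

logger = logging.getLogger(__name__)

__all__ = [
    "tetrahedrality",
    "local_structure_index",
    "d5",
    "order_parameters",
    "build_order_table",
    "midpoint_split",
    "OrderParamSummary",
    "summarize",
]

#: Default first-shell cutoff for the LSI (Å), the conventional choice
#: separating first-shell from gap neighbours in water.
LSI_CUTOFF = 3.7


def tetrahedrality(frame: BoxedFrame, table: NeighborTable) -> np.ndarray:
    """Rescaled tetrahedral order parameter per molecule.

        Q_i = 1 − (3/8) Σ_{j<k≤4} (cos ψ_jk + 1/3)²

    where ψ_jk are the angles at oxygen i subtended by its four nearest
    oxygens (no distance cutoff), computed from minimum-image displacement
    vectors.  Q = 1 for ideal tetrahedral directions; the degenerate case
    of all four neighbours collinear with the centre gives Q = −3.
    """
    if table.max_rank < 4:
        raise ValueError("tetrahedrality needs a neighbour table with max_rank >= 4")
    o = frame.oxygen_positions
    nbr = o[table.indices[:, :4]]  # (N, 4, 3)
    vec = nbr - o[:, None, :]
    vec -= frame.box * np.round(vec / frame.box)
    vec /= np.linalg.norm(vec, axis=-1, keepdims=True)
    cosang = np.einsum("nij,nkj->nik", vec, vec)  # (N, 4, 4)
    j, k = np.triu_indices(4, k=1)
    return 1.0 - (3.0 / 8.0) * np.sum((cosang[:, j, k] + 1.0 / 3.0) ** 2, axis=1)


def local_structure_index(
    table: NeighborTable, cutoff: float = LSI_CUTOFF
) -> np.ndarray:
    """Local structure index per molecule, in Å².

    With a molecule's neighbour distances ordered
    r_1 < … < r_{n} < cutoff < r_{n+1}, the gap increments are
    Δ_j = r_{j+1} − r_j for j = 1…n, and the LSI is the mean squared
    deviation of the Δ's about their mean (population variance).  Large
    values mean a well separated first and second shell.

    Molecules with no neighbour inside the cutoff yield NaN (flagged
    missing, logged), never zero.  If any molecule's table is truncated
    before its first beyond-cutoff neighbour, the table is too short and a
    hard error demands a larger ``max_rank``.
    """
    dist = table.distances
    within = dist < cutoff
    n_in = within.sum(axis=1)
    if np.any(n_in >= table.max_rank):
        bad = np.nonzero(n_in >= table.max_rank)[0]
        raise ValueError(
            f"neighbour table truncated before the first beyond-cutoff "
            f"neighbour for molecules {bad.tolist()}; rebuild with larger max_rank"
        )
    out = np.full(table.n_molecules, np.nan)
    defined = n_in >= 1
    if np.any(~defined):
        logger.warning(
            "LSI undefined (no neighbour inside %.2f Å) for %d molecules",
            cutoff, int(np.count_nonzero(~defined)),
        )
    for i in np.nonzero(defined)[0]:
        n = n_in[i]
        deltas = np.diff(dist[i, : n + 1])  # includes the cutoff-crossing gap
        out[i] = np.mean((deltas - deltas.mean()) ** 2)
    return out


def d5(table: NeighborTable) -> np.ndarray:
    """Distance to the fifth-nearest oxygen, per molecule (Å)."""
    return table.rank(5)


def order_parameters(
    frame: BoxedFrame, table: NeighborTable, lsi_cutoff: float = LSI_CUTOFF
):
    """Per-molecule table of Q, LSI and d5 (plus any scalar annotation).

    Returns a pandas DataFrame with columns molecule, q, lsi, d5
    (and ``scalar`` when the frame carries a per-molecule annotation).
    """
    import pandas as pd

    data = {
        "molecule": np.arange(frame.n_molecules),
        "q": tetrahedrality(frame, table),
        "lsi": local_structure_index(table, cutoff=lsi_cutoff),
        "d5": d5(table),
    }
    if frame.per_molecule_scalar is not None:
        data["scalar"] = frame.per_molecule_scalar
    return pd.DataFrame(data)


def midpoint_split(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Split a bimodal sample into low/high modes by a midpoint threshold.

    Deterministic one-dimensional two-means locates the two mode centres
    (centroids start at the sample extremes, Lloyd iterations to
    convergence); the reported threshold is the point equidistant from the
    centres in units of each mode's spread — the plain midpoint when the
    spreads are equal, pulled toward the narrow mode otherwise (a midpoint
    of means is systematically biased toward the broader mode).  Used to
    assign molecules to the low-density-like (high d5/LSI) or
    high-density-like mode.  NaNs are excluded from the fit and classified
    False.

    Returns ``(is_high, threshold)``.
    """
    values = np.asarray(values, dtype=float)
    v = values[~np.isnan(values)]
    if v.size < 2:
        raise ValueError("need at least two finite values to split")
    lo, hi = float(v.min()), float(v.max())
    thr = 0.5 * (lo + hi)
    for _ in range(200):
        below, above = v[v <= thr], v[v > thr]
        if below.size == 0 or above.size == 0:
            break
        new_thr = 0.5 * (below.mean() + above.mean())
        if abs(new_thr - thr) < 1e-12:
            break
        thr = new_thr
    below, above = v[v <= thr], v[v > thr]
    if below.size and above.size:
        s_lo, s_hi = below.std(), above.std()
        if s_lo + s_hi > 0:
            thr = float(
                (below.mean() * s_hi + above.mean() * s_lo) / (s_lo + s_hi)
            )
    with np.errstate(invalid="ignore"):
        return values > thr, thr


def build_order_table(frames, lsi_cutoff: float = LSI_CUTOFF, max_rank: int = 30):
    """Stack per-molecule order parameters for many frames into one table.

    Adds a leading ``frame`` column to the :func:`order_parameters` output.
    """
    import pandas as pd

    from .neighbors import build_neighbor_table

    parts = []
    for i, frame in enumerate(frames):
        table = build_neighbor_table(frame, max_rank=min(max_rank, frame.n_molecules - 1))
        df = order_parameters(frame, table, lsi_cutoff=lsi_cutoff)
        df.insert(0, "frame", i)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


@dataclasses.dataclass
class OrderParamSummary:
    """Mean and standard error of one observable at one state point.

    Frames are treated as independent blocks: the SE is the standard
    deviation of per-frame means over √(frame count).  With a single frame
    the SE is undefined and reported as NaN, never zero.
    """

    observable: str
    temperature: float | None
    molar_density: float | None
    mean: float
    stderr: float
    n_frames: int
    n_dropped: int = 0  # flagged-missing values excluded from the average


def summarize(
    per_frame_values: list[np.ndarray],
    observable: str = "",
    temperature: float | None = None,
    molar_density: float | None = None,
) -> OrderParamSummary:
    """Frame-block mean and standard error of per-molecule values.

    NaN entries (flagged missing, e.g. undefined LSI) are excluded and
    counted; their count is logged.
    """
    if not per_frame_values:
        raise ValueError("per_frame_values must be non-empty")
    frame_means = []
    dropped = 0
    for vals in per_frame_values:
        vals = np.asarray(vals, dtype=float)
        ok = ~np.isnan(vals)
        dropped += int(np.count_nonzero(~ok))
        if not np.any(ok):
            raise ValueError("a frame has no defined values for this observable")
        frame_means.append(float(vals[ok].mean()))
    if dropped:
        logger.info("summarize(%s): %d flagged-missing values excluded", observable, dropped)
    frame_means = np.asarray(frame_means)
    n = frame_means.size
    stderr = float(frame_means.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return OrderParamSummary(
        observable=observable,
        temperature=temperature,
        molar_density=molar_density,
        mean=float(frame_means.mean()),
        stderr=stderr,
        n_frames=n,
        n_dropped=dropped,
    )
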