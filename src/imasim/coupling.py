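"""Bidirectional deformation transfer between the vessel mesh and the strand network.

Offsets are displacements from the rest configuration. Vessel-to-strand
transfer copies each paired vessel vertex's offset onto its strand point,
clamped in magnitude at λ_max with direction preserved. The reverse transfer
does the same while the coupling is engaged (β = 1, instrument in contact);
when disengaged (β = 0) the previously transferred vessel offsets decay
geometrically by a factor 0.8 per frame, giving smooth motion decay without
oscillation. Pairings are precomputed once on the rest pose — no spatial
queries during simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .anatomy import StrandNetwork
from .mesh_core import TriangleMesh

DECAY_FACTOR = 0.8

__all__ = ["CouplingMap", "build_coupling_map", "propagate_ima_to_strands",
           "propagate_fat_to_ima", "DECAY_FACTOR"]


@dataclass
class CouplingMap:
    """Precomputed (strand point ↔ vessel vertex) pairs plus the clamp λ_max."""

    strand_indices: np.ndarray
    ima_indices: np.ndarray
    lambda_max: float
    rest_distances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.strand_indices)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"strand_point": self.strand_indices,
                             "ima_vertex": self.ima_indices,
                             "rest_distance": self.rest_distances})


def build_coupling_map(network: StrandNetwork, ima_mesh: TriangleMesh,
                       lambda_max: float = 0.005) -> CouplingMap:
    """Pair each vessel-side strand endpoint with its nearest rest-pose vessel vertex."""
    if not network.strands or len(ima_mesh.vertices) == 0:
        raise ValueError("coupling requires a non-empty strand network and vessel mesh")
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    _, ends_b = network.endpoint_indices()
    tree = cKDTree(ima_mesh.vertices)
    pts = network.polyline.vertices[ends_b]
    dists, nearest = tree.query(pts)
    return CouplingMap(ends_b, nearest.astype(np.int64), float(lambda_max),
                       np.asarray(dists, dtype=float))


def _clamped_copy(offsets: np.ndarray, lam: float) -> np.ndarray:
    """û · min(|O|, λ_max) per row; a zero offset maps to zero."""
    offsets = np.asarray(offsets, dtype=float)
    mags = np.linalg.norm(offsets, axis=-1, keepdims=True)
    scale = np.where(mags > lam, lam / np.where(mags == 0, 1.0, mags), 1.0)
    return offsets * scale


def propagate_ima_to_strands(ima_offsets: np.ndarray, cmap: CouplingMap,
                             n_strand_points: int | None = None) -> np.ndarray:
    """Vessel → strand offset transfer: O_l,i = û_ima,j · min(|O_ima,j|, λ_max).

    Returns a full (n_strand_points, 3) offset array (zero off the map) when
    ``n_strand_points`` is given, else the per-pair offsets.
    """
    ima_offsets = np.asarray(ima_offsets, dtype=float)
    if not np.all(np.isfinite(ima_offsets)):
        raise ValueError("non-finite vessel offsets")
    transferred = _clamped_copy(ima_offsets[cmap.ima_indices], cmap.lambda_max)
    if n_strand_points is None:
        return transferred
    out = np.zeros((n_strand_points, 3))
    out[cmap.strand_indices] = transferred
    return out


def propagate_fat_to_ima(fat_offsets: np.ndarray, previous_ima_offsets: np.ndarray,
                         beta: int, cmap: CouplingMap) -> np.ndarray:
    """Strand → vessel transfer (β = 1) or 0.8× decay of the held offsets (β = 0).

    ``fat_offsets`` is indexed by strand point; the returned array is indexed
    by vessel vertex and has the shape of ``previous_ima_offsets``.
    """
    if beta not in (0, 1):
        raise ValueError("beta must be 0 or 1")
    prev = np.asarray(previous_ima_offsets, dtype=float)
    if beta == 0:
        return DECAY_FACTOR * prev
    out = np.zeros_like(prev)
    src = np.asarray(fat_offsets, dtype=float)[cmap.strand_indices]
    out[cmap.ima_indices] = _clamped_copy(src, cmap.lambda_max)
    return out
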