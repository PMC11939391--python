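"""Numba-compiled inner loops for the position-based-dynamics solver.

Constraint projection runs Gauss–Seidel in a fixed, deterministic order
(arrays are processed in storage order), so repeated runs are bit-identical.
All kernels operate in place on (N, 3) float64 position arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "dihedral_angle_k",
    "dihedral_gradients_k",
    "distance_sweep",
    "dihedral_sweep",
]


@njit(cache=True)
def _cross(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True)
def _norm(a):
    return np.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])


@njit(cache=True)
def dihedral_angle_k(p0, p1, p2, p3):
    """Signed dihedral angle about the shared edge p2→p3 of the two triangles
    (p0, p2, p3) and (p1, p3, p2).

    atan2((n1 × n2)·ê, n1·n2) with n1, n2 the unit triangle normals and ê the
    unit edge direction. Coplanar wings with same-facing normals give 0.
    Returns NaN for degenerate wings (normal magnitude < 1e-12).
    """
    e = p3 - p2
    n1 = _cross(p2 - p0, p3 - p0)
    n2 = _cross(p3 - p1, p2 - p1)
    m1 = _norm(n1)
    m2 = _norm(n2)
    me = _norm(e)
    if m1 < 1e-12 or m2 < 1e-12 or me < 1e-12:
        return np.nan
    n1 = n1 / m1
    n2 = n2 / m2
    ehat = e / me
    s = _cross(n1, n2) @ ehat
    c = n1 @ n2
    return np.arctan2(s, c)


@njit(cache=True)
def dihedral_gradients_k(p0, p1, p2, p3):
    """Analytic gradients (∂θ/∂p0..∂p3) of :func:`dihedral_angle_k`.

    Hinge-angle gradients of the discrete-shells form: with non-unit normals
    N1 = (p2−p0)×(p3−p0), N2 = (p3−p1)×(p2−p1) and edge e = p3−p2,

        ∂θ/∂p0 = −|e| N1/|N1|²
        ∂θ/∂p1 = −|e| N2/|N2|²
        ∂θ/∂p2 = −((p0−p3)·ê) N1/|N1|² − ((p1−p3)·ê) N2/|N2|²
        ∂θ/∂p3 = ((p0−p2)·ê) N1/|N1|² + ((p1−p2)·ê) N2/|N2|²

    The four gradients sum to zero (translation invariance), so projections
    along them conserve linear momentum for equal masses. Returns a (4, 3)
    array of zeros for degenerate wings.
    """
    grads = np.zeros((4, 3))
    e = p3 - p2
    me = _norm(e)
    n1 = _cross(p2 - p0, p3 - p0)
    n2 = _cross(p3 - p1, p2 - p1)
    m1sq = n1 @ n1
    m2sq = n2 @ n2
    if me < 1e-12 or m1sq < 1e-24 or m2sq < 1e-24:
        return grads
    ehat = e / me
    g1 = n1 / m1sq
    g2 = n2 / m2sq
    grads[0] = -me * g1
    grads[1] = -me * g2
    a02 = (p0 - p2) @ ehat
    a03 = (p0 - p3) @ ehat
    a12 = (p1 - p2) @ ehat
    a13 = (p1 - p3) @ ehat
    grads[2] = -a03 * g1 - a13 * g2
    grads[3] = a02 * g1 + a12 * g2
    return grads


@njit(cache=True)
def distance_sweep(positions, inv_mass, idx_i, idx_j, rest, k_eff):
    """One Gauss–Seidel pass over all distance constraints, in place.

    The correction for constraint C = |p_i − p_j| − d0 moves both particles
    along the inter-particle axis, weighted by inverse masses and scaled by
    the per-iteration stiffness k_eff. Coincident particles are skipped
    (gradient undefined); the caller may warn. Returns the number skipped.
    """
    skipped = 0
    for k in range(idx_i.shape[0]):
        i = idx_i[k]
        j = idx_j[k]
        wi = inv_mass[i]
        wj = inv_mass[j]
        wsum = wi + wj
        if wsum == 0.0:
            continue
        d0 = rest[k]
        dx = positions[i, 0] - positions[j, 0]
        dy = positions[i, 1] - positions[j, 1]
        dz = positions[i, 2] - positions[j, 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        if dist < 1e-12:
            skipped += 1
            continue
        scale = k_eff[k] * (dist - d0) / (dist * wsum)
        positions[i, 0] -= wi * scale * dx
        positions[i, 1] -= wi * scale * dy
        positions[i, 2] -= wi * scale * dz
        positions[j, 0] += wj * scale * dx
        positions[j, 1] += wj * scale * dy
        positions[j, 2] += wj * scale * dz
    return skipped


@njit(cache=True)
def dihedral_sweep(positions, inv_mass, quads, rest_angle, k_eff):
    """One Gauss–Seidel pass over all dihedral (bending) constraints, in place.

    C = wrap(θ − θ_rest); correction Δp_k = −k_eff · w_k C ∇_kθ / Σ w |∇θ|².
    Degenerate wings are skipped. Returns the number skipped.
    """
    skipped = 0
    for c in range(quads.shape[0]):
        i0 = quads[c, 0]
        i1 = quads[c, 1]
        i2 = quads[c, 2]
        i3 = quads[c, 3]
        p0 = positions[i0].copy()
        p1 = positions[i1].copy()
        p2 = positions[i2].copy()
        p3 = positions[i3].copy()
        theta = dihedral_angle_k(p0, p1, p2, p3)
        if np.isnan(theta):
            skipped += 1
            continue
        # wrap C into (-pi, pi] so the projection takes the short way round
        cval = theta - rest_angle[c]
        while cval > np.pi:
            cval -= 2.0 * np.pi
        while cval <= -np.pi:
            cval += 2.0 * np.pi
        grads = dihedral_gradients_k(p0, p1, p2, p3)
        denom = 0.0
        w = np.empty(4)
        w[0] = inv_mass[i0]
        w[1] = inv_mass[i1]
        w[2] = inv_mass[i2]
        w[3] = inv_mass[i3]
        for k in range(4):
            denom += w[k] * (grads[k] @ grads[k])
        if denom < 1e-18:
            skipped += 1
            continue
        lam = -cval / denom
        s = k_eff[c] * lam
        for k in range(4):
            idx = quads[c, k]
            positions[idx, 0] += s * w[k] * grads[k, 0]
            positions[idx, 1] += s * w[k] * grads[k, 1]
            positions[idx, 2] += s * w[k] * grads[k, 2]
    return skipped
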