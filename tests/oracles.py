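"""Independent numerical oracles used by the test suite.

These deliberately avoid the production code paths: element integrals
via Gaussian quadrature, convolution via the direct double sum.
"""

import numpy as np

# degree-2-exact 4-point rule for tetrahedra (barycentric)
_A, _B = 0.5854101966249685, 0.13819660112501052
TET_QP = np.array(
    [
        [_A, _B, _B, _B],
        [_B, _A, _B, _B],
        [_B, _B, _A, _B],
        [_B, _B, _B, _A],
    ]
)
TET_QW = np.full(4, 0.25)

# degree-2-exact 3-point edge-midpoint rule for triangles (barycentric)
TRI_QP = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
TRI_QW = np.full(3, 1.0 / 3.0)


def tet_volume(verts):
    v = verts[1:] - verts[0]
    return abs(np.linalg.det(v)) / 6.0


def tri_area(verts):
    return 0.5 * np.linalg.norm(np.cross(verts[1] - verts[0], verts[2] - verts[0]))


def quad_tet_mass(verts, c):
    V = tet_volume(verts)
    M = np.zeros((4, 4))
    for lam, w in zip(TET_QP, TET_QW):
        M += w * np.outer(lam, lam)
    return (V / c) * M


def quad_tet_stiffness(verts, D, mu_a):
    V = tet_volume(verts)
    # gradients via the oracle's own route: solve for barycentric planes
    A = np.column_stack([verts, np.ones(4)])
    grads = np.linalg.inv(A)[:3].T  # row i: gradient of basis i
    mass = np.zeros((4, 4))
    for lam, w in zip(TET_QP, TET_QW):
        mass += w * np.outer(lam, lam)
    return D * V * (grads @ grads.T) + mu_a * V * mass


def quad_face_boundary(verts, q):
    A = tri_area(verts)
    M = np.zeros((3, 3))
    for lam, w in zip(TRI_QP, TRI_QW):
        M += w * np.outer(lam, lam)
    return (A / (2.0 * q)) * M


def direct_convolve(a, b, dt):
    """O(T^2) sequential double sum: out[k] = dt * sum_j a[j] b[k-j]."""
    T = len(a)
    out = np.zeros(T)
    for k in range(T):
        acc = 0.0
        for j in range(k + 1):
            acc += a[j] * b[k - j]
        out[k] = dt * acc
    return out
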