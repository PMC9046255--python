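"""Internal-coordinate geometry: dihedral measurement and NeRF atom placement.

Shared by the PDB reader (C-beta imputation), the graph featurizer (phi/psi/
omega) and the synthetic chain builder, so that building a chain from stated
torsions and re-measuring them round-trips.
"""

from __future__ import annotations

import numpy as np


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle(s) p0-p1-p2-p3 in radians, IUPAC convention.

    Accepts (3,) vectors or (N, 3) stacks. The angle is in (-pi, pi]; looking
    down the p1->p2 axis, a clockwise rotation of p3 relative to p0 is
    positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    ang = -np.arctan2(y, x)
    # map -pi -> +pi so results live in (-pi, pi]
    return np.where(np.isclose(ang, -np.pi), np.pi, ang)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to the frame a-b-c.

    ``bond`` is |d-c| in Angstrom, ``angle`` the b-c-d bond angle and
    ``torsion`` the a-b-c-d dihedral, both in radians. Chirality follows the
    IUPAC torsion convention, i.e. ``dihedral(a, b, c, place_atom(...))``
    returns ``torsion``.
    """
    a, b, c = (np.asarray(p, dtype=np.float64) for p in (a, b, c))
    bc = c - b
    bc_n = np.linalg.norm(bc)
    if bc_n < 1e-10:
        raise ValueError("degenerate backbone geometry: coincident frame atoms")
    bc = bc / bc_n
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise ValueError("degenerate backbone geometry: collinear frame atoms")
    n = n / n_norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
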