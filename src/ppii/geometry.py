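"""Internal-coordinate geometry: torsion angles and backbone construction.

All angles are degrees in the half-open interval (-180, 180], IUPAC sign
convention for torsions.  Cartesian placement from internal coordinates uses
the standard natural-extension (NeRF) construction, so torsion ->
coordinates -> torsion round-trips close tightly.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

# Ideal backbone internal coordinates (angstroms / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

_COLLINEAR_TOL = 1e-10


def wrap_angle(deg):
    """Map an angle (or array of angles) in degrees into (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(deg, dtype=float), 360.0)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 about the p2-p3 axis, in degrees.

    Follows the IUPAC convention: looking down p2->p3, the angle is positive
    when p4 is rotated clockwise from p1.  Raises :class:`GeometryError` when
    three consecutive points are collinear (the torsion is undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.dot(n1, n1) < _COLLINEAR_TOL or np.dot(n2, n2) < _COLLINEAR_TOL:
        raise GeometryError("undefined dihedral: collinear points")
    b2n = b2 / np.linalg.norm(b2)
    m1 = np.cross(b2n, n1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def place_atom(a, b, c, bond_length: float, bond_angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place atom d so that |cd| = bond_length, angle(b,c,d) = bond_angle and
    dihedral(a,b,c,d) = torsion (NeRF extension step)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc_n = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_n)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise GeometryError("cannot place atom: reference atoms collinear")
    n = n / nn
    m = np.cross(n, bc_n)
    d_local = bond_length * np.array([
        -np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)
    ])
    return c + d_local[0] * bc_n + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omegas) -> dict[str, np.ndarray]:
    """Construct N/CA/C/O coordinates for a chain from backbone torsions.

    ``phis[0]`` and ``psis[-1]`` do not affect the backbone trace (they are
    undefined at the termini); ``psis[-1]`` still orients the final carbonyl
    oxygen.  Returns arrays of shape (n, 3) keyed by atom name.
    """
    phis = np.asarray(phis, dtype=float)
    psis = np.asarray(psis, dtype=float)
    omegas = np.asarray(omegas, dtype=float)
    n = len(phis)
    if not (len(psis) == n and len(omegas) == n):
        raise GeometryError("torsion lists must have equal length")
    if n < 2:
        raise GeometryError("a chain needs at least 2 residues")

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))

    # First residue in a canonical frame.
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, omegas[i - 1])
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phis[i])

    for i in range(n):
        # Carbonyl O antiperiplanar to the next N (torsion psi + 180).
        O[i] = place_atom(N[i], CA[i], C[i],
                          BOND_C_O, ANGLE_CA_C_O, wrap_angle(psis[i] + 180.0))
    return {"N": N, "CA": CA, "C": C, "O": O}
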