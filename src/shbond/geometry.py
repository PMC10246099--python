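"""Small 3D geometry helpers shared by the detection and fixture modules."""

from __future__ import annotations

import numpy as np

# idealized covalent bond lengths used when placing hydrogens, in Angstrom
OH_BOND = 0.96
NH_BOND = 1.01


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex ``b`` of the triangle a-b-c, in degrees."""
    u = unit(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    w = unit(np.asarray(c, dtype=float) - np.asarray(b, dtype=float))
    cos = float(np.clip(np.dot(u, w), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def perp_basis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to ``v``."""
    v = unit(np.asarray(v, dtype=float))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(v, ref))
    e2 = np.cross(v, e1)
    return e1, e2


def cone_direction(axis: np.ndarray, half_angle_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at ``half_angle_deg`` from ``axis`` at the given azimuth."""
    axis = unit(np.asarray(axis, dtype=float))
    e1, e2 = perp_basis(axis)
    phi = np.radians(half_angle_deg)
    psi = np.radians(azimuth_deg)
    return (
        np.cos(phi) * axis
        + np.sin(phi) * (np.cos(psi) * e1 + np.sin(psi) * e2)
    )


def best_cone_azimuth(axis: np.ndarray, half_angle_deg: float, target_dir: np.ndarray) -> float:
    """Azimuth (degrees) on the cone around ``axis`` pointing closest to ``target_dir``.

    The optimum is the projection of the target onto the plane normal to the
    axis; a target parallel to the axis leaves the azimuth free and 0 is
    returned.
    """
    axis = unit(np.asarray(axis, dtype=float))
    e1, e2 = perp_basis(axis)
    t = np.asarray(target_dir, dtype=float)
    x = float(np.dot(t, e1))
    y = float(np.dot(t, e2))
    if abs(x) < 1e-12 and abs(y) < 1e-12:
        return 0.0
    return float(np.degrees(np.arctan2(y, x)))


def hydrogen_for_theta(
    donor: np.ndarray, acceptor: np.ndarray, bond_length: float, theta_deg: float
) -> np.ndarray:
    """Place H on the donor so that the donor-H-acceptor angle equals ``theta_deg``.

    Solves the D-H-A triangle (|DH| = bond_length, |DA| = R, angle at H =
    theta) and puts H in a deterministic plane through the D-A axis. For
    theta = 180 the hydrogen is collinear with the heavy atoms.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    r = distance(donor, acceptor)
    theta = np.radians(theta_deg)
    # law of sines: angle at A subtends side DH
    sin_a = bond_length * np.sin(theta) / r
    if sin_a > 1.0:
        raise ValueError(
            f"no D-H-A triangle with R={r:.2f}, b={bond_length}, theta={theta_deg}"
        )
    ang_a = np.arcsin(sin_a)
    ang_d = np.pi - theta - ang_a  # angle at the donor between DA and DH
    axis = unit(acceptor - donor)
    e1, _ = perp_basis(axis)
    direction = np.cos(ang_d) * axis + np.sin(ang_d) * e1
    return donor + bond_length * direction
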