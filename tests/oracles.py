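"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's analytic formulas: geometry is
checked against explicit Cartesian coordinates and numerically computed
centre of mass / inertia, and torsion energies against direct evaluations
of the three closed forms.
"""

import math

import numpy as np


def threefold_group_coords(b_ax, b_xh, alpha_deg):
    """Explicit coordinates (nm) of anchor + center + 3 H, anchor at origin,
    axis along z, hydrogens at 120-degree azimuthal spacing."""
    a = math.radians(alpha_deg)
    z_h = b_ax + b_xh * math.cos(a)
    r_h = b_xh * math.sin(a)
    pts = [np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, b_ax])]
    for t in (0.0, 2 * math.pi / 3, 4 * math.pi / 3):
        pts.append(np.array([r_h * math.cos(t), r_h * math.sin(t), z_h]))
    return np.array(pts)


def mass_moments_numeric(b_ax, b_xh, alpha_deg, m_x, m_h):
    """(m_tot, z_com, I_axis) of the 4 massive particles (center + 3 H),
    computed from explicit coordinates and the full inertia sum about the
    anchor-center axis (the z axis through the origin)."""
    pts = threefold_group_coords(b_ax, b_xh, alpha_deg)[1:]  # drop anchor
    masses = np.array([m_x, m_h, m_h, m_h])
    m_tot = masses.sum()
    com = (masses[:, None] * pts).sum(axis=0) / m_tot
    i_axis = float((masses * (pts[:, 0] ** 2 + pts[:, 1] ** 2)).sum())
    return float(m_tot), float(com[2]), i_axis


def point_masses_moments(masses, positions):
    """(m_tot, z_com, I_axis about z) of arbitrary point masses."""
    masses = np.asarray(masses, dtype=float)
    positions = np.asarray(positions, dtype=float)
    m_tot = masses.sum()
    com = (masses[:, None] * positions).sum(axis=0) / m_tot
    i_axis = float((masses * (positions[:, 0] ** 2
                              + positions[:, 1] ** 2)).sum())
    return float(m_tot), float(com[2]), i_axis


def triangle_third_side(b1, b2, theta_deg):
    """Distance measured on explicitly constructed coordinates of a
    three-atom bend with arm lengths b1, b2 and included angle theta."""
    t = math.radians(theta_deg)
    p_a = np.array([b1, 0.0, 0.0])
    p_h = np.array([b2 * math.cos(t), b2 * math.sin(t), 0.0])
    return float(np.linalg.norm(p_a - p_h))


def v_proper(terms, phi_deg):
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    v = np.zeros_like(phi)
    for phase, k, n in terms:
        v = v + k * (1 + np.cos(n * phi - math.radians(phase)))
    return v


def v_rb(c, phi_deg):
    psi_cos = -np.cos(np.radians(np.asarray(phi_deg, dtype=float)))
    v = np.zeros_like(psi_cos)
    for m, cm in enumerate(c):
        v = v + cm * psi_cos ** m
    return v


def v_fourier(f, phi_deg):
    p = np.radians(np.asarray(phi_deg, dtype=float))
    return 0.5 * (f[0] * (1 + np.cos(p)) + f[1] * (1 - np.cos(2 * p))
                  + f[2] * (1 + np.cos(3 * p)) + f[3] * (1 - np.cos(4 * p)))
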