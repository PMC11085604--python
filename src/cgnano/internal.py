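"""Internal-coordinate kernels for the reduced chain representation.

Measures and differentiates the backbone virtual bond angles theta
(Ca-Ca-Ca), virtual dihedrals gamma (Ca-Ca-Ca-Ca) and the side-chain
placement angles alpha/beta, and rebuilds Cartesian coordinates from them
(natural-extension reference frame construction).

Conventions
-----------
* dihedrals signed, right-handed, in (-180, 180]; collinear quadruplets
  give NaN (undefined), never a silent zero
* alpha is the angle between the Ca->SC vector and the *outward* bisector
  of theta (the direction pointing away from the two backbone neighbours);
  beta is the azimuth of Ca->SC about that bisector, zero in the
  Ca(i-1)-Ca(i)-Ca(i+1) plane, positive toward the right-handed normal
  u x v with u = Ca(i-1)-Ca(i), v = Ca(i+1)-Ca(i).

All public angles are degrees; gradient routines work in radians
internally and return d(angle_rad)/d(position).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _cross(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _norm(v):
    return float(np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2]))


def _unit(v):
    n = _norm(v)
    if n < _EPS:
        raise ValueError("zero-length vector in internal-coordinate kernel")
    return v / n, n


def _unit_jac(v):
    """Unit vector and Jacobian d(vhat)/dv = (I - vhat vhat^T)/|v|."""
    vhat, n = _unit(v)
    return vhat, (np.eye(3) - np.outer(vhat, vhat)) / n


def _skew(v):
    return np.array([
        [0.0, -v[2], v[1]],
        [v[2], 0.0, -v[0]],
        [-v[1], v[0], 0.0],
    ])


def bond_angle(a, b, c):
    """Angle a-b-c in degrees, in [0, 180]."""
    u, _ = _unit(np.asarray(a, float) - b)
    v, _ = _unit(np.asarray(c, float) - b)
    return np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0)))


def bond_angle_grad(a, b, c):
    """Angle (radians) and gradients w.r.t. the three points.

    Returns (theta_rad, (ga, gb, gc)).  At exactly 0 or 180 degrees the
    gradient is undefined; zeros are returned there.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    u = a - b
    v = c - b
    uhat, lu = _unit(u)
    vhat, lv = _unit(v)
    cos_t = np.clip(uhat @ vhat, -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    if sin_t < 1e-9:
        z = np.zeros(3)
        return theta, (z, z.copy(), z.copy())
    ga = -(vhat - cos_t * uhat) / (lu * sin_t)
    gc = -(uhat - cos_t * vhat) / (lv * sin_t)
    gb = -(ga + gc)
    return theta, (ga, gb, gc)


def dihedral(a, b, c, d):
    """Signed dihedral a-b-c-d in degrees, (-180, 180]; NaN if degenerate."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    if _norm(n1) < 1e-9 or _norm(n2) < 1e-9:
        return float("nan")
    b2hat, _ = _unit(b2)
    y = _cross(n1, n2) @ b2hat
    x = n1 @ n2
    phi = np.degrees(np.arctan2(y, x))
    if phi <= -180.0:
        phi += 360.0
    return phi


def dihedral_grad(a, b, c, d):
    """Dihedral (radians) and gradients w.r.t. the four points."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    sq1 = n1 @ n1
    sq2 = n2 @ n2
    lb2 = _norm(b2)
    if sq1 < 1e-18 or sq2 < 1e-18:
        raise ValueError("degenerate (collinear) dihedral has no gradient")
    b2hat = b2 / lb2
    y = _cross(n1, n2) @ b2hat
    x = n1 @ n2
    phi = np.arctan2(y, x)
    ga = -lb2 / sq1 * n1
    gd = lb2 / sq2 * n2
    tg = (b1 @ b2) / (lb2 * lb2)
    th = (b3 @ b2) / (lb2 * lb2)
    gb = -(1.0 + tg) * ga + th * gd
    gc = -(ga + gb + gd)
    return phi, (ga, gb, gc, gd)


def _sc_frame(p, c, n):
    """Local side-chain frame at Ca(i).

    Returns (mhat, ehat, nhat): outward bisector, in-plane perpendicular,
    and plane normal unit(u x v).
    """
    uhat, _ = _unit(np.asarray(p, float) - c)
    vhat, _ = _unit(np.asarray(n, float) - c)
    q = _cross(uhat, vhat)
    if _norm(q) < 1e-9:
        raise ValueError("collinear backbone triple: side-chain frame undefined")
    mhat, _ = _unit(-(uhat + vhat))
    nhat, _ = _unit(q)
    ehat = _cross(nhat, mhat)
    return mhat, ehat, nhat


def measure_sc(p, c, n, s):
    """(alpha_deg, beta_deg, d) of side-chain site s in the frame at c."""
    mhat, ehat, nhat = _sc_frame(p, c, n)
    w = np.asarray(s, float) - c
    what, d = _unit(w)
    alpha = np.degrees(np.arccos(np.clip(what @ mhat, -1.0, 1.0)))
    beta = np.degrees(np.arctan2(what @ nhat, what @ ehat))
    return alpha, beta, d


def place_sc(p, c, n, d, alpha_deg, beta_deg):
    """Inverse of measure_sc: Cartesian side-chain position."""
    mhat, ehat, nhat = _sc_frame(p, c, n)
    al = np.radians(alpha_deg)
    be = np.radians(beta_deg)
    direction = (np.cos(al) * mhat
                 + np.sin(al) * (np.cos(be) * ehat + np.sin(be) * nhat))
    return np.asarray(c, float) + d * direction


def measure_sc_grad(p, c, n, s):
    """alpha, beta (radians) with gradients w.r.t. (p, c, n, s).

    Chain-rule through the unit-vector normalisations; gradients w.r.t. c
    follow from translation invariance.  Returns
    (alpha, beta, d, grads) with grads[key] arrays of shape (4, 3) for
    keys 'alpha', 'beta', 'd' ordered (p, c, n, s).
    """
    p, c, n, s = (np.asarray(x, float) for x in (p, c, n, s))
    u = p - c
    v = n - c
    w = s - c
    uhat, Ju = _unit_jac(u)
    vhat, Jv = _unit_jac(v)
    what, Jw = _unit_jac(w)
    d = _norm(w)

    m = -(uhat + vhat)
    mhat, Jm = _unit_jac(m)
    # d(mhat)/d(site): via d(m)/duhat = -I
    dm_dp = -Jm @ Ju
    dm_dn = -Jm @ Jv

    q = _cross(uhat, vhat)
    qhat, Jq = _unit_jac(q)
    # q = uhat x vhat: dq/duhat = -[vhat]x, dq/dvhat = [uhat]x
    dq_dp = Jq @ (-_skew(vhat)) @ Ju
    dq_dn = Jq @ _skew(uhat) @ Jv

    ehat = _cross(qhat, mhat)
    # de = -[mhat]x dqhat + [qhat]x dmhat
    de_dp = -_skew(mhat) @ dq_dp + _skew(qhat) @ dm_dp
    de_dn = -_skew(mhat) @ dq_dn + _skew(qhat) @ dm_dn

    cos_a = np.clip(what @ mhat, -1.0, 1.0)
    alpha = np.arccos(cos_a)
    sin_a = np.sqrt(max(1.0 - cos_a * cos_a, 0.0))

    # gradients of cos(alpha) = what . mhat
    dca_ds = Jw @ mhat
    dca_dp = dm_dp.T @ what
    dca_dn = dm_dn.T @ what
    dca_dc = -(dca_ds + dca_dp + dca_dn)

    if sin_a < 1e-9:
        g_alpha = np.zeros((4, 3))
    else:
        g_alpha = -np.array([dca_dp, dca_dc, dca_dn, dca_ds]) / sin_a

    # beta = atan2(y, x), y = what.qhat, x = what.ehat
    y = what @ qhat
    x = what @ ehat
    beta = np.arctan2(y, x)
    dy_ds = Jw @ qhat
    dy_dp = dq_dp.T @ what
    dy_dn = dq_dn.T @ what
    dy_dc = -(dy_ds + dy_dp + dy_dn)
    dx_ds = Jw @ ehat
    dx_dp = de_dp.T @ what
    dx_dn = de_dn.T @ what
    dx_dc = -(dx_ds + dx_dp + dx_dn)
    r2 = x * x + y * y
    if r2 < 1e-18:
        g_beta = np.zeros((4, 3))
    else:
        g_beta = (x * np.array([dy_dp, dy_dc, dy_dn, dy_ds])
                  - y * np.array([dx_dp, dx_dc, dx_dn, dx_ds])) / r2

    g_d = np.zeros((4, 3))
    g_d[3] = what
    g_d[1] = -what

    return alpha, beta, d, {"alpha": g_alpha, "beta": g_beta, "d": g_d}


def nerf_extend(a, b, c, d_len, theta_deg, gamma_deg):
    """Place the next chain point D given A, B, C and (d, theta, gamma).

    theta is the bond angle B-C-D and gamma the dihedral A-B-C-D (signed,
    same convention as :func:`dihedral`).  Exactly straight angles
    (theta == 180) extend collinearly and ignore gamma.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(theta_deg)
    bc, _ = _unit(c - b)
    ab = b - a
    q = _cross(ab, bc)
    if _norm(q) < 1e-9:
        # previous three points collinear: pick a deterministic normal
        ref = np.array([1.0, 0.0, 0.0])
        if abs(bc @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        q = _cross(ref, bc)
    nhat, _ = _unit(q)
    mhat = _cross(nhat, bc)
    gamma = 0.0 if np.isnan(gamma_deg) else np.radians(gamma_deg)
    direction = (np.cos(theta) * (-bc)
                 + np.sin(theta) * (np.cos(gamma) * mhat
                                    + np.sin(gamma) * nhat))
    return c + d_len * direction
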