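"""Closed-form magnetostatics of uniformly magnetized cuboid magnets.

The Coulombian (magnetic surface-charge) model gives the H field of a
uniformly magnetized cuboid in closed form: in the body frame, for
magnetization M along z, the field is a signed sum over the 8 corners of
arctangent terms (component parallel to M) and logarithm terms (transverse
components).  With X_i = x - x_i, Y_j = y - y_j, Z_k = z - z_k the corner
offsets and R_ijk the corner distances, s_ijk = (-1)^(i+j+k):

    H_x = -(M/4pi) sum s_ijk ln(Y_j + R_ijk)
    H_y = -(M/4pi) sum s_ijk ln(X_i + R_ijk)
    H_z =  (M/4pi) sum s_ijk atan2(X_i Y_j, Z_k R_ijk)      (exterior)

Inside the body the atan2 sum yields H_z + M (i.e. B_z/mu0), so M is
subtracted there.  A general magnetization direction is handled by cyclic
coordinate permutation and superposition; the spatial Jacobian dH_i/dx_j is
differentiated analytically, so exterior evaluations are exactly curl-free
and divergence-free up to rounding.

The magnet interior is modeled with relative permeability 1 (pure
Coulombian solution); the small material permeability of NdFeB (~1.05) is
recorded on the Magnet for provenance but not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import mu_0

from .errors import ConfigurationError, ParameterError

__all__ = [
    "MU0",
    "Magnet",
    "FieldSample",
    "ParticleProps",
    "cuboid_H",
    "grad_H",
    "cuboid_field",
    "total_field",
    "magnetophoretic_force",
    "protocol_layout",
    "grad_B_map",
]

MU0 = mu_0

#: remanent flux-density vector shared by all magnet protocols [T];
#: |B_r| = 1.2 T tilted in the sagittal (yz) plane.
DEFAULT_REMANENCE = (0.0, 0.771, 0.919)

_EDGE_EPS = 1e-9  # evaluation offset near log/edge singularities [m]


@dataclass(frozen=True)
class Magnet:
    """A uniformly magnetized cuboid permanent magnet.

    center / half_lengths are in metres; ``rotation`` maps body to world
    coordinates (columns are the body axes in the world frame); ``remanence``
    is the remanent flux density B_r in the *world* frame [T], so the
    magnetization vector is M = B_r / mu0.  ``mu_r`` is informational.
    """

    center: tuple
    half_lengths: tuple
    rotation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    remanence: tuple = DEFAULT_REMANENCE
    mu_r: float = 1.05

    def __post_init__(self):
        R = self.rotation_matrix
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ConfigurationError("magnet rotation matrix is not orthonormal")
        if np.linalg.norm(self.remanence) <= 0.0:
            raise ConfigurationError("magnet remanence must be non-zero")
        if np.any(np.asarray(self.half_lengths) <= 0.0):
            raise ConfigurationError("magnet half_lengths must be positive")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def magnetization(self) -> np.ndarray:
        """Magnetization vector M = B_r/mu0 in the world frame [A/m]."""
        return np.asarray(self.remanence, dtype=float) / MU0

    @property
    def volume(self) -> float:
        a, b, c = self.half_lengths
        return 8.0 * a * b * c

    @property
    def moment(self) -> np.ndarray:
        """Magnetic dipole moment m = M * V [A m^2]."""
        return self.magnetization * self.volume


@dataclass
class FieldSample:
    """Field evaluation at one or more points.

    H [A/m] and B [T] have shape (..., 3); the Jacobian J with entries
    J[..., i, j] = dH_i/dx_j has shape (..., 3, 3).  Outside all magnets
    B = mu0 H, J is symmetric (curl H = 0) and traceless (div H = 0).
    """

    H: np.ndarray
    B: np.ndarray
    J: np.ndarray
    flagged: np.ndarray = None  # points nudged off an edge singularity


@dataclass(frozen=True)
class ParticleProps:
    """Magnetite microparticle properties.

    Defaults describe the 7.5 um radius, 5200 kg/m^3 magnetite carriers
    used throughout: radius [m], density [kg/m^3], and (optionally) the
    magnetic susceptibility used by the exact force model.
    """

    radius: float = 7.5e-6
    density: float = 5200.0
    susceptibility: float | None = None

    def __post_init__(self):
        if self.radius <= 0.0:
            raise ParameterError("particle radius must be positive")
        if self.density <= 0.0:
            raise ParameterError("particle density must be positive")

    @property
    def volume(self) -> float:
        """Particle volume (4/3) pi R^3 [m^3]."""
        return 4.0 / 3.0 * np.pi * self.radius**3

    @property
    def mass(self) -> float:
        return self.density * self.volume


# -- core closed form --------------------------------------------------------


def _field_z_body(pts, half_lengths, M):
    """H and Jacobian for magnetization M along body z, body-frame points.

    pts: (N, 3).  Returns H (N, 3), J (N, 3, 3).
    """
    a, b, c = half_lengths
    x = pts[:, 0][:, None]
    y = pts[:, 1][:, None]
    z = pts[:, 2][:, None]
    X = x - np.array([-a, a])  # (N, 2)
    Y = y - np.array([-b, b])
    Z = z - np.array([-c, c])

    # corner tensors, shape (N, 2, 2, 2) indexed [n, i, j, k]
    Xc = X[:, :, None, None]
    Yc = Y[:, None, :, None]
    Zc = Z[:, None, None, :]
    R = np.sqrt(Xc**2 + Yc**2 + Zc**2)
    sign = np.array([-1.0, 1.0])
    S = sign[:, None, None] * sign[None, :, None] * sign[None, None, :]

    pref = M / (4.0 * np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnY = np.log(Yc + R)
        lnX = np.log(Xc + R)
        u = Xc * Yc
        v = Zc * R
        Hx = -pref * np.einsum("ijk,nijk->n", S, lnY)
        Hy = -pref * np.einsum("ijk,nijk->n", S, lnX)
        Hz = pref * np.einsum("ijk,nijk->n", S, np.arctan2(u, v))

        uv2 = u**2 + v**2
        dHx_dx = -pref * np.einsum("ijk,nijk->n", S, Xc / (R * (Yc + R)))
        dHx_dy = -pref * np.einsum("ijk,nijk->n", S, 1.0 / R)
        dHx_dz = -pref * np.einsum("ijk,nijk->n", S, Zc / (R * (Yc + R)))
        dHy_dy = -pref * np.einsum("ijk,nijk->n", S, Yc / (R * (Xc + R)))
        dHy_dz = -pref * np.einsum("ijk,nijk->n", S, Zc / (R * (Xc + R)))
        dHz_dx = pref * np.einsum(
            "ijk,nijk->n", S, Zc * Yc * (Yc**2 + Zc**2) / (R * uv2)
        )
        dHz_dy = pref * np.einsum(
            "ijk,nijk->n", S, Zc * Xc * (Xc**2 + Zc**2) / (R * uv2)
        )
        dHz_dz = -pref * np.einsum(
            "ijk,nijk->n", S, Xc * Yc * (R**2 + Zc**2) / (R * uv2)
        )

    # inside the body the arctan sum returns B_z/mu0 = H_z + M
    inside = (np.abs(x[:, 0]) < a) & (np.abs(y[:, 0]) < b) & (np.abs(z[:, 0]) < c)
    Hz = Hz - np.where(inside, M, 0.0)

    H = np.stack([Hx, Hy, Hz], axis=1)
    J = np.empty((pts.shape[0], 3, 3))
    J[:, 0, 0] = dHx_dx
    J[:, 0, 1] = dHx_dy
    J[:, 0, 2] = dHx_dz
    J[:, 1, 0] = dHx_dy  # dHy_dx equals dHx_dy term-by-term
    J[:, 1, 1] = dHy_dy
    J[:, 1, 2] = dHy_dz
    J[:, 2, 0] = dHz_dx
    J[:, 2, 1] = dHz_dy
    J[:, 2, 2] = dHz_dz
    return H, J


# cyclic permutations mapping each body axis onto the "z" of the closed form
_PERMS = {0: (1, 2, 0), 1: (2, 0, 1), 2: (0, 1, 2)}


def _field_body(pts, half_lengths, M_body):
    """H and J in the body frame for an arbitrary magnetization vector."""
    n = pts.shape[0]
    H = np.zeros((n, 3))
    J = np.zeros((n, 3, 3))
    hl = np.asarray(half_lengths, dtype=float)
    for axis in range(3):
        Ma = M_body[axis]
        if Ma == 0.0:
            continue
        p = _PERMS[axis]
        Hp, Jp = _field_z_body(pts[:, p], hl[list(p)], Ma)
        # scatter permuted components back: orig[p[i]] = tilde[i]
        H[:, p] += Hp
        for i in range(3):
            for j in range(3):
                J[:, p[i], p[j]] += Jp[:, i, j]
    return H, J


def cuboid_field(points, magnet: Magnet, _eps=_EDGE_EPS):
    """H [A/m] and Jacobian dH_i/dx_j [A/m^2] of one cuboid magnet.

    ``points`` may be a single 3-vector or an (..., 3) array, in world
    coordinates.  Points landing on a log/edge singularity are re-evaluated
    at an offset of ``_eps`` metres and flagged rather than raising, so a
    grazing particle trajectory cannot crash the tracer.
    Returns (H, J, flagged).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts2 = np.atleast_2d(pts).reshape(-1, 3)

    R = magnet.rotation_matrix
    M_body = R.T @ magnet.magnetization
    body = (pts2 - np.asarray(magnet.center, dtype=float)) @ R  # = R^T (p - c)

    H_b, J_b = _field_body(body, magnet.half_lengths, M_body)
    bad = ~(np.isfinite(H_b).all(axis=1) & np.isfinite(J_b).all(axis=(1, 2)))
    flagged = bad.copy()
    tries = 0
    while np.any(bad) and tries < 4:
        tries += 1
        shift = _eps * tries / np.sqrt(3.0)
        H_fix, J_fix = _field_body(
            body[bad] + shift, magnet.half_lengths, M_body
        )
        H_b[bad] = H_fix
        J_b[bad] = J_fix
        bad = ~(np.isfinite(H_b).all(axis=1) & np.isfinite(J_b).all(axis=(1, 2)))

    H = H_b @ R.T
    J = np.einsum("ab,nbc,dc->nad", R, J_b, R)

    shape = pts.shape[:-1]
    H = H.reshape(shape + (3,)) if not single else H[0]
    J = J.reshape(shape + (3, 3)) if not single else J[0]
    flagged = flagged.reshape(shape) if not single else bool(flagged[0])
    return H, J, flagged


def cuboid_H(point, magnet: Magnet) -> np.ndarray:
    """Magnetic field intensity H [A/m] of a single cuboid magnet."""
    return cuboid_field(point, magnet)[0]


def grad_H(point, magnet: Magnet) -> np.ndarray:
    """Analytic spatial Jacobian dH_i/dx_j [A/m^2] of a cuboid magnet."""
    return cuboid_field(point, magnet)[1]


def total_field(points, magnets) -> FieldSample:
    """Superposed field sample of a list of magnets; B = mu0 H (exterior)."""
    if not magnets:
        raise ConfigurationError("total_field requires a non-empty magnet list")
    H = J = flagged = None
    for m in magnets:
        Hi, Ji, fi = cuboid_field(points, m)
        if H is None:
            H, J, flagged = Hi, Ji, np.asarray(fi)
        else:
            H = H + Hi
            J = J + Ji
            flagged = flagged | np.asarray(fi)
    return FieldSample(H=H, B=MU0 * H, J=J, flagged=flagged)


# -- magnetophoretic force ---------------------------------------------------


def magnetophoretic_force(sample: FieldSample, props: ParticleProps,
                          mode: str = "high_chi") -> np.ndarray:
    """Magnetophoretic force on a magnetizable sphere, F = k mu0 V_p (H.grad)H.

    mode="exact" uses the Clausius-Mossotti-type factor k = 3 chi/(chi + 3)
    (requires props.susceptibility); mode="high_chi" is the saturating
    high-susceptibility limit k = 3, appropriate for magnetite carriers.
    (H.grad)H_i = sum_j H_j dH_i/dx_j = J @ H.
    """
    if mode == "exact":
        chi = props.susceptibility
        if chi is None:
            raise ParameterError("exact force mode requires props.susceptibility")
        if chi <= -3.0:
            raise ParameterError(
                f"susceptibility {chi} is at or below the chi = -3 pole"
            )
        factor = 3.0 * chi / (chi + 3.0)
    elif mode == "high_chi":
        factor = 3.0
    else:
        raise ParameterError(f"unknown force mode {mode!r}")
    JH = np.einsum("...ij,...j->...i", sample.J, sample.H)
    return MU0 * props.volume * factor * JH


# -- protocol layouts --------------------------------------------------------

# magnet 1: 1 x 1 x 4 cm bar; magnet 2: 5 x 3 x 0.2 cm flat plate
_BAR_HALF = (0.005, 0.005, 0.02)     # long axis along body z
_PLATE_HALF = (0.001, 0.025, 0.015)  # thin axis along body x (septum normal)

# body z (bar long axis) -> world y: rotation of -90 deg about x
_ROT_LONG_Y = ((1.0, 0.0, 0.0), (0.0, 0.0, 1.0), (0.0, -1.0, 0.0))
_ROT_IDENTITY = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


def protocol_layout(protocol: int, distance: float = 0.005,
                    center_yz=(0.015, 0.025),
                    remanence=DEFAULT_REMANENCE) -> list:
    """Magnet layout of one delivery protocol.

    The sagittal reference (septum) plane is x = 0 with the airway at x > 0;
    the magnet center sits at x = -distance (default 5 mm).  Protocol 1 is
    the 1x1x4 cm bar with its long axis along y (parallel to the septum,
    along the nose); protocol 2 is the same bar rotated 90 degrees about the
    septum normal (long axis along z); protocol 3 is the 5x3x0.2 cm flat
    plate lying flat against the septum.  The remanence vector is the same
    world-frame (0, 0.771, 0.919) T for every protocol.
    ``center_yz`` places the magnet center in the sagittal plane (default
    over the vestibule/valve area of the surrogate passage).
    """
    if protocol not in (1, 2, 3):
        raise ConfigurationError(f"protocol must be 1, 2 or 3, got {protocol!r}")
    center = (-float(distance), float(center_yz[0]), float(center_yz[1]))
    if protocol == 1:
        return [Magnet(center=center, half_lengths=_BAR_HALF,
                       rotation=_ROT_LONG_Y, remanence=tuple(remanence))]
    if protocol == 2:
        return [Magnet(center=center, half_lengths=_BAR_HALF,
                       rotation=_ROT_IDENTITY, remanence=tuple(remanence))]
    return [Magnet(center=center, half_lengths=_PLATE_HALF,
                   rotation=_ROT_IDENTITY, remanence=tuple(remanence))]


def grad_B_map(domain, magnets, x_offset: float = 0.005):
    """In-plane gradient-magnitude map |grad |B|| on the domain cell grid.

    Evaluates |B| at the cell centers of ``domain`` in the sagittal plane
    x = x_offset and differentiates numerically in (y, z).  Returns
    (y_coords, z_coords, gradB) with gradB of shape (ny, nz) [T/m].
    """
    y, z = domain.cell_centers()
    yy, zz = np.meshgrid(y, z, indexing="ij")
    pts = np.stack(
        [np.full(yy.size, x_offset), yy.ravel(), zz.ravel()], axis=1
    )
    sample = total_field(pts, magnets)
    Bmag = np.linalg.norm(sample.B, axis=1).reshape(yy.shape)
    gy, gz = np.gradient(Bmag, y, z)
    return y, z, np.hypot(gy, gz)
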