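"""Lagrangian tracing of magnetite microparticles in the sagittal plane.

Non-interacting spherical particles obey m_p dv_p/dt = F_f + F_m with
Stokes drag F_f = -6 pi eta R_p (v_p - v_f) and the magnetophoretic force
of the high-susceptibility limit (or the exact finite-chi form); coupling
is one-way (the airflow is never modified by the particles) and gravity is
neglected against drag at this particle size.  Motion is integrated with
the classical 4th-order Runge-Kutta scheme at a fixed step tied to the
particle relaxation time tau = 2 rho_p R_p^2 / (9 eta) ~ 3.4 ms, which is
short against the ~0.3 s transit time: the motion is overdamped, and the
particle velocity tracks v_f + F_m/(6 pi eta R_p).

Magnetic forces are evaluated in 3-D at the release plane x = dx (the
sagittal offset of the release line from the septum, where the magnets
sit on the far side); only the in-plane (y, z) force components drive the
2-D motion.

Particles terminate by DEPOSITED (first contact with a WALL or OLFACTORY
segment sticks; no rebound), ESCAPED (crossing the OUTLET - or back out of
the INLET), or SUSPENDED (still airborne at t_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import ConfigurationError, IntegrationError, ParameterError
from .geometry import Domain, RegionLabel
from .magnetics import ParticleProps, magnetophoretic_force, total_field

__all__ = [
    "ParticleStatus",
    "ParticleState",
    "ReleaseSpec",
    "TraceConfig",
    "drag_force",
    "relaxation_time",
    "step_rk4",
    "release_line",
    "default_release",
    "trace",
]


class ParticleStatus(Enum):
    IN_FLIGHT = "in_flight"
    DEPOSITED = "deposited"
    ESCAPED = "escaped"
    SUSPENDED = "suspended"


@dataclass
class ParticleState:
    """Kinematic state and fate of one particle (positions in metres)."""

    position: np.ndarray
    velocity: np.ndarray
    status: ParticleStatus = ParticleStatus.IN_FLIGHT
    time: float = 0.0
    region: RegionLabel | None = None  # label hit at termination
    particle_id: int = 0
    trajectory: np.ndarray | None = None  # decimated (k, 2) polyline


@dataclass(frozen=True)
class ReleaseSpec:
    """Line release: ``count`` particles equally spaced from ``start`` to
    ``end`` (endpoints included), released at rest.  ``x_offset`` is the
    sagittal distance of the release plane from the septum plane [m].
    If ``jitter_seed`` is set, positions get a uniform along-line jitter of
    up to half the inter-particle spacing."""

    count: int = 100
    start: tuple = (0.001, 0.0071)
    end: tuple = (0.009, 0.0071)
    x_offset: float = 0.005
    jitter_seed: int | None = None

    def __post_init__(self):
        if self.count < 1:
            raise ConfigurationError("release count must be >= 1")
        if np.allclose(self.start, self.end):
            raise ConfigurationError("release line must have positive length")


#: per-protocol release offsets [m]: (dz above the inlet, dx off the septum)
PROTOCOL_RELEASE_OFFSETS = {
    1: (0.0071, 0.0025),
    2: (0.0071, 0.0030),
    3: (0.0031, 0.0030),
}


@dataclass(frozen=True)
class TraceConfig:
    """Integration policy.

    ``dt`` overrides the default step tau/``dt_factor``; the stiffness
    guard requires dt <= tau/10.  ``t_max`` caps the simulated time per
    particle; survivors are reported SUSPENDED.  ``trajectory_stride`` > 0
    records every stride-th position.
    """

    dt: float | None = None
    dt_factor: float = 20.0
    t_max: float = 10.0
    trajectory_stride: int = 0
    force_mode: str = "high_chi"

    def resolve_dt(self, tau: float) -> float:
        dt = self.dt if self.dt is not None else tau / self.dt_factor
        if dt > tau / 10.0 + 1e-15:
            raise ConfigurationError(
                f"dt = {dt} violates the stiffness guard dt <= tau/10 = {tau / 10}"
            )
        return dt


def drag_force(v_p, v_f, props: ParticleProps, viscosity: float) -> np.ndarray:
    """Stokes drag F_f = -6 pi eta R_p (v_p - v_f) [N]; vectorized."""
    v_p = np.asarray(v_p, dtype=float)
    v_f = np.asarray(v_f, dtype=float)
    return -6.0 * np.pi * viscosity * props.radius * (v_p - v_f)


def relaxation_time(props: ParticleProps, viscosity: float) -> float:
    """Velocity relaxation time tau = m_p/(6 pi eta R_p) = 2 rho R^2/(9 eta)."""
    return 2.0 * props.density * props.radius**2 / (9.0 * viscosity)


def step_rk4(state: ParticleState, force_eval, dt: float,
             mass: float) -> ParticleState:
    """One classical RK4 step of dx/dt = v, dv/dt = force_eval(x, v)/m.

    ``force_eval(position, velocity)`` returns the total force [N].  Used
    directly in unit validations; :func:`trace` runs the same scheme
    vectorized over all particles.
    """
    if state.status is not ParticleStatus.IN_FLIGHT:
        raise IntegrationError("cannot step a terminal particle",
                               particle_id=state.particle_id, time=state.time)
    x, v = state.position, state.velocity

    def acc(px, pv):
        return np.asarray(force_eval(px, pv), dtype=float) / mass

    k1x, k1v = v, acc(x, v)
    k2x, k2v = v + 0.5 * dt * k1v, acc(x + 0.5 * dt * k1x, v + 0.5 * dt * k1v)
    k3x, k3v = v + 0.5 * dt * k2v, acc(x + 0.5 * dt * k2x, v + 0.5 * dt * k2v)
    k4x, k4v = v + dt * k3v, acc(x + dt * k3x, v + dt * k3v)
    xn = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    vn = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return replace(state, position=xn, velocity=vn, time=state.time + dt)


def release_line(spec: ReleaseSpec, domain: Domain | None = None) -> list:
    """Equally spaced line release at rest; deterministic without a seed.

    If a domain is given, every release point must lie in the fluid region.
    """
    a = np.asarray(spec.start, dtype=float)
    b = np.asarray(spec.end, dtype=float)
    n = spec.count
    if n == 1:
        pos = 0.5 * (a + b)[None, :]
    else:
        t = np.linspace(0.0, 1.0, n)[:, None]
        pos = a + t * (b - a)
    if spec.jitter_seed is not None and n > 1:
        rng = np.random.default_rng(spec.jitter_seed)
        spacing = np.linalg.norm(b - a) / (n - 1)
        unit = (b - a) / np.linalg.norm(b - a)
        pos = pos + (rng.uniform(-0.5, 0.5, n) * spacing)[:, None] * unit
    if domain is not None:
        inside = domain.contains(pos)
        if not np.all(inside):
            bad = np.nonzero(~inside)[0].tolist()
            raise ConfigurationError(
                f"release points at indices {bad} lie outside the fluid region"
            )
    return [
        ParticleState(position=pos[i].copy(), velocity=np.zeros(2),
                      particle_id=i)
        for i in range(n)
    ]


def default_release(domain: Domain, protocol: int, count: int = 100,
                    line_length: float = 0.015) -> ReleaseSpec:
    """Per-protocol release line on the surrogate.

    The line is horizontal at height dz above the inlet, centred on the
    inlet centreline, with the per-protocol sagittal offset dx; its length
    (nominally 1.5 cm, nearly the whole nostril) is clipped to fit the
    vestibule width of the surrogate.
    """
    if protocol not in PROTOCOL_RELEASE_OFFSETS:
        raise ConfigurationError(f"unknown protocol {protocol!r}")
    dz, dx = PROTOCOL_RELEASE_OFFSETS[protocol]
    inlet = domain.seg_label == RegionLabel.INLET
    pts = np.vstack([domain.seg_a[inlet], domain.seg_b[inlet]])
    y_lo, y_hi = pts[:, 0].min(), pts[:, 0].max()
    z0 = pts[:, 1].mean()
    margin = 1.5 * domain.grid_spacing
    half = min(line_length, (y_hi - y_lo) - 2 * margin) / 2.0
    y_mid = 0.5 * (y_lo + y_hi)
    return ReleaseSpec(count=count,
                       start=(y_mid - half, z0 + dz),
                       end=(y_mid + half, z0 + dz),
                       x_offset=dx)


# -- vectorized tracing ------------------------------------------------------


def _segment_crossings(p, q, a, b):
    """First boundary crossing of particle steps p->q against segments a->b.

    Returns (hit, s, seg_index): ``s`` is the fractional position of the
    first crossing along p->q.
    """
    r = q - p  # (N,2)
    s_ab = b - a  # (M,2)

    def cross(u, v):
        return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]

    ap = a[None, :, :] - p[:, None, :]  # (N,M,2)
    denom = cross(r[:, None, :], s_ab[None, :, :])  # (N,M)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross(ap, s_ab[None, :, :]) / denom      # along particle step
        u = cross(ap, r[:, None, :]) / denom         # along boundary segment
    valid = (np.abs(denom) > 1e-30) & (t >= -1e-12) & (t <= 1.0 + 1e-12) \
        & (u >= -1e-9) & (u <= 1.0 + 1e-9)
    t = np.where(valid, t, np.inf)
    seg = np.argmin(t, axis=1)
    tmin = t[np.arange(len(p)), seg]
    return np.isfinite(tmin), np.clip(tmin, 0.0, 1.0), seg


def trace(particles, flow, magnets, domain: Domain, props: ParticleProps,
          config: TraceConfig, x_offset: float = 0.005) -> list:
    """Advance all particles to a terminal state.

    ``magnets`` may be an empty list (magnet-free control).  The flow field
    is only read.  Returns new ParticleState objects (the inputs are not
    mutated); DEPOSITED + ESCAPED + SUSPENDED == len(particles).
    """
    eta = flow.params.viscosity
    tau = relaxation_time(props, eta)
    dt = config.resolve_dt(tau)
    mass = props.mass
    drag_k = 6.0 * np.pi * eta * props.radius

    n = len(particles)
    pos = np.array([p.position for p in particles], dtype=float)
    vel = np.array([p.velocity for p in particles], dtype=float)
    status = np.zeros(n, dtype=np.int8)  # 0 in-flight 1 deposited 2 escaped 3 susp
    region = np.full(n, -1, dtype=np.int64)
    t_end = np.zeros(n)

    wall_like = (domain.seg_label == RegionLabel.WALL) | (
        domain.seg_label == RegionLabel.OLFACTORY
    )

    def accel(x, v, active):
        vf = flow.sample(x)
        F = -drag_k * (v - vf)
        if magnets:
            pts3 = np.column_stack([np.full(len(x), x_offset), x])
            sample = total_field(pts3, magnets)
            Fm = magnetophoretic_force(sample, props, mode=config.force_mode)
            F = F + Fm[:, 1:]
        return F / mass

    n_steps = int(np.ceil(config.t_max / dt))
    record = config.trajectory_stride > 0
    traj = [[] for _ in range(n)] if record else None
    active = status == 0

    for step in range(n_steps):
        if not np.any(active):
            break
        x = pos[active]
        v = vel[active]
        k1v = accel(x, v, active)
        k1x = v
        k2v = accel(x + 0.5 * dt * k1x, v + 0.5 * dt * k1v, active)
        k2x = v + 0.5 * dt * k1v
        k3v = accel(x + 0.5 * dt * k2x, v + 0.5 * dt * k2v, active)
        k3x = v + 0.5 * dt * k2v
        k4v = accel(x + dt * k3x, v + dt * k3v, active)
        k4x = v + dt * k3v
        xn = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        vn = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)

        if not np.all(np.isfinite(xn)):
            bad = np.nonzero(active)[0][~np.isfinite(xn).all(axis=1)][0]
            raise IntegrationError(
                "non-finite particle state", particle_id=int(bad),
                time=(step + 1) * dt, position=pos[bad],
            )

        ids = np.nonzero(active)[0]
        now = (step + 1) * dt

        # first boundary crossing within this step
        hit, s, seg = _segment_crossings(x, xn, domain.seg_a, domain.seg_b)
        if np.any(hit):
            xi = x[hit] + s[hit, None] * (xn[hit] - x[hit])
            xn[hit] = xi
            lab = domain.seg_label[seg[hit]]
            gid = ids[hit]
            deposited = wall_like[seg[hit]]
            status[gid] = np.where(deposited, 1, 2)
            region[gid] = lab
            t_end[gid] = now - (1.0 - s[hit]) * dt

        # proximity capture: particle surface touches a wall segment
        rem = ~hit
        if np.any(rem):
            d, lab = domain.distance_to_boundary(xn[rem])
            touch = d <= props.radius
            if np.any(touch):
                gid = ids[rem][touch]
                lab_t = lab[touch]
                dep = (lab_t == RegionLabel.WALL) | (lab_t == RegionLabel.OLFACTORY)
                status[gid] = np.where(dep, 1, 2)
                region[gid] = lab_t
                t_end[gid] = now

        pos[active] = xn
        vel[active] = vn
        if record and step % config.trajectory_stride == 0:
            for i, gi in enumerate(ids):
                traj[gi].append(xn[i].copy())
        active = status == 0

    leftovers = status == 0
    status[leftovers] = 3
    t_end[leftovers] = n_steps * dt

    out = []
    for i, p in enumerate(particles):
        st = (ParticleStatus.DEPOSITED, ParticleStatus.ESCAPED,
              ParticleStatus.SUSPENDED)[status[i] - 1]
        out.append(ParticleState(
            position=pos[i], velocity=vel[i], status=st,
            time=float(t_end[i]),
            region=RegionLabel(int(region[i])) if region[i] >= 0 else None,
            particle_id=p.particle_id,
            trajectory=np.array(traj[i]) if record and traj[i] else None,
        ))
    return out
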