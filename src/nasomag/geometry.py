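"""Synthetic 2-D sagittal nasal-passage surrogate.

The real airway in magnetophoretic-delivery studies is segmented from a CT
head scan; this module generates an idealized stand-in: a channel in the
sagittal (y, z) plane that runs from a nostril inlet at the bottom, up
through a curved vestibule bend, posteriorly along a main passage under an
"olfactory" roof segment, and down a narrower nasopharynx limb to the
outlet.  Coordinates follow the patient convention: y anterior->posterior,
z inferior->superior; all lengths are in metres.

The boundary is a closed labeled polyline (INLET / OUTLET / OLFACTORY /
WALL); the interior is discretized on a uniform cell grid used by the flow
solver.  The olfactory segment is placed on the superior roof and sized so
that its share of the total wall length equals ``olfactory_fraction``
(about 8 % of the nasal surface is olfactory epithelium).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path as FilePath

import numpy as np
from matplotlib.path import Path as MplPath

from .errors import DomainError, ResolutionError, STLReadError

__all__ = [
    "RegionLabel",
    "SurrogateParams",
    "Domain",
    "build_surrogate",
    "channel_domain",
    "signed_distance",
    "read_stl",
]


class RegionLabel(IntEnum):
    """Boundary-region label.  Integer order encodes nearest-label priority
    (lower value wins a distance tie): OLFACTORY > WALL > INLET > OUTLET."""

    OLFACTORY = 0
    WALL = 1
    INLET = 2
    OUTLET = 3


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate nasal passage.

    inlet_width
        Width of the nostril/vestibule limb [m].  Chosen so the 2-D mean
        inlet speed matches the 0.5 m/s inhalation boundary condition (the
        3-D nostril area of 1.32e-4 m^2 cannot be honored in 2-D).
    passage_height, passage_length
        Inferior->superior and anterior->posterior extents of the model [m].
    passage_thickness
        Thickness of the superior (main) passage under the roof [m].
    outlet_width
        Width of the posterior nasopharynx limb [m]; narrower than the main
        passage so the flow accelerates toward the outlet, as in the airway.
    olfactory_fraction
        Fraction of the total wall length labeled OLFACTORY (default 0.08).
    bend_radius
        Fillet radius of the two interior bends [m].
    grid_spacing
        Uniform cell size of the solver grid [m]; must resolve the inlet by
        at least 8 cells.
    """

    inlet_width: float = 0.01
    passage_height: float = 0.05
    passage_length: float = 0.07
    passage_thickness: float = 0.012
    outlet_width: float = 0.006
    olfactory_fraction: float = 0.08
    bend_radius: float = 0.005
    grid_spacing: float = 8.0e-4

    def __post_init__(self):
        if not 0.0 < self.olfactory_fraction < 1.0:
            raise ValueError(
                f"olfactory_fraction must lie in (0, 1), got {self.olfactory_fraction}"
            )
        for name in (
            "inlet_width",
            "passage_height",
            "passage_length",
            "passage_thickness",
            "outlet_width",
            "bend_radius",
            "grid_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inlet_width / self.grid_spacing < 8.0 - 1e-12:
            raise ResolutionError(
                f"grid_spacing {self.grid_spacing} resolves inlet_width "
                f"{self.inlet_width} by fewer than 8 cells"
            )
        if self.passage_thickness + self.bend_radius >= self.passage_height:
            raise ValueError("passage_thickness + bend_radius must be < passage_height")
        block_w = self.passage_length - self.inlet_width - self.outlet_width
        if block_w <= 2 * self.bend_radius:
            raise ValueError("bend_radius too large for the interior septal block")


@dataclass
class Domain:
    """Labeled 2-D fluid domain on a uniform grid.

    ``seg_a``/``seg_b`` are the start/end points of the boundary polyline
    segments (closed loop), ``seg_label`` the per-segment RegionLabel codes.
    ``mask`` marks fluid cells; cell (i, j) has its center at
    ``origin + grid_spacing * (i + 0.5, j + 0.5)``.
    """

    seg_a: np.ndarray
    seg_b: np.ndarray
    seg_label: np.ndarray
    origin: np.ndarray
    grid_spacing: float
    mask: np.ndarray  # (ny, nz) bool, True = fluid
    _path: MplPath = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._path is None:
            # the polyline is stored in traversal order, so seg_a already
            # walks the closed loop
            self._path = MplPath(np.vstack([self.seg_a, self.seg_a[:1]]))

    # -- bookkeeping ---------------------------------------------------------

    @property
    def shape(self):
        return self.mask.shape

    @property
    def bbox(self):
        lo = self.origin
        hi = self.origin + self.grid_spacing * np.asarray(self.mask.shape)
        return lo, hi

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.seg_b - self.seg_a, axis=1)

    def wall_lengths(self) -> dict:
        """Total boundary length per RegionLabel [m]."""
        lengths = self.segment_lengths
        return {
            lab: float(lengths[self.seg_label == lab].sum()) for lab in RegionLabel
        }

    def olfactory_wall_fraction(self) -> float:
        """Realized OLFACTORY share of the wall length (inlet/outlet excluded)."""
        wl = self.wall_lengths()
        walls = wl[RegionLabel.OLFACTORY] + wl[RegionLabel.WALL]
        return wl[RegionLabel.OLFACTORY] / walls

    # -- geometric queries ---------------------------------------------------

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True for points strictly inside the fluid polygon."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self._path.contains_points(pts)

    def distance_to_boundary(self, points: np.ndarray):
        """Unsigned distance to the closest boundary segment and its label.

        Vectorized over points; does not raise for out-of-box points (used
        in the particle-tracing inner loop).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = _point_segment_distance(pts, self.seg_a, self.seg_b)
        dmin = d.min(axis=1)
        # priority tie-break within one part in 1e12 of the minimum
        tol = 1e-12 + 1e-12 * np.abs(dmin)
        candidate = d <= (dmin + tol)[:, None]
        ranked = np.where(candidate, self.seg_label[None, :], np.iinfo(np.int64).max)
        labels = ranked.min(axis=1)
        return dmin, labels

    def signed_distance(self, point) -> tuple[float, RegionLabel]:
        """Signed distance of a single point: negative inside the fluid.

        Raises DomainError if the point is outside the grid bounding box.
        """
        p = np.asarray(point, dtype=float)
        lo, hi = self.bbox
        if np.any(p < lo - 1e-12) or np.any(p > hi + 1e-12):
            raise DomainError(f"point {p} outside domain bounding box {lo}..{hi}")
        d, lab = self.distance_to_boundary(p[None, :])
        sign = -1.0 if self.contains(p[None, :])[0] else 1.0
        dist = float(d[0])
        if dist < 1e-12:  # on the boundary
            return 0.0, RegionLabel(int(lab[0]))
        return sign * dist, RegionLabel(int(lab[0]))

    def cell_centers(self):
        ny, nz = self.mask.shape
        y = self.origin[0] + self.grid_spacing * (np.arange(ny) + 0.5)
        z = self.origin[1] + self.grid_spacing * (np.arange(nz) + 0.5)
        return y, z

    # -- serialization -------------------------------------------------------

    def to_json(self, path):
        """Write a self-describing JSON record of the domain."""
        rec = {
            "format": "nasomag-domain",
            "version": 1,
            "grid_spacing": self.grid_spacing,
            "origin": self.origin.tolist(),
            "shape": list(self.mask.shape),
            "mask_rows": ["".join("1" if v else "0" for v in row) for row in self.mask],
            "segments": {
                "a": self.seg_a.tolist(),
                "b": self.seg_b.tolist(),
                "label": [RegionLabel(int(l)).name for l in self.seg_label],
            },
        }
        FilePath(path).write_text(json.dumps(rec))

    @classmethod
    def from_json(cls, path):
        rec = json.loads(FilePath(path).read_text())
        if rec.get("format") != "nasomag-domain":
            raise DomainError(f"{path} is not a nasomag domain file")
        mask = np.array(
            [[c == "1" for c in row] for row in rec["mask_rows"]], dtype=bool
        )
        return cls(
            seg_a=np.asarray(rec["segments"]["a"], dtype=float),
            seg_b=np.asarray(rec["segments"]["b"], dtype=float),
            seg_label=np.asarray(
                [RegionLabel[n] for n in rec["segments"]["label"]], dtype=np.int64
            ),
            origin=np.asarray(rec["origin"], dtype=float),
            grid_spacing=float(rec["grid_spacing"]),
            mask=mask,
        )


def signed_distance(domain: Domain, point):
    """Module-level convenience wrapper around :meth:`Domain.signed_distance`."""
    return domain.signed_distance(point)


# -- construction ------------------------------------------------------------


def _point_segment_distance(points, a, b):
    """Distances from N points to M segments, shape (N, M)."""
    ab = b - a  # (M,2)
    ap = points[:, None, :] - a[None, :, :]  # (N,M,2)
    denom = np.einsum("mi,mi->m", ab, ab)
    denom = np.where(denom == 0.0, 1.0, denom)
    t = np.clip(np.einsum("nmi,mi->nm", ap, ab) / denom, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=2)


def _arc_points(center, radius, theta0, theta1, n):
    th = np.linspace(theta0, theta1, n + 1)
    return np.stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)], axis=1
    )


def _polyline_to_domain(vertices, labels, grid_spacing, origin, shape):
    """Assemble a Domain from an ordered closed labeled vertex chain."""
    verts = np.asarray(vertices, dtype=float)
    seg_a = verts
    seg_b = np.roll(verts, -1, axis=0)
    seg_label = np.asarray(labels, dtype=np.int64)
    keep = np.linalg.norm(seg_b - seg_a, axis=1) > 1e-15
    seg_a, seg_b, seg_label = seg_a[keep], seg_b[keep], seg_label[keep]

    ny, nz = shape
    h = grid_spacing
    yc = origin[0] + h * (np.arange(ny) + 0.5)
    zc = origin[1] + h * (np.arange(nz) + 0.5)
    yy, zz = np.meshgrid(yc, zc, indexing="ij")
    path = MplPath(np.vstack([seg_a, seg_a[:1]]))
    mask = path.contains_points(
        np.column_stack([yy.ravel(), zz.ravel()])
    ).reshape(ny, nz)
    return Domain(
        seg_a=seg_a,
        seg_b=seg_b,
        seg_label=seg_label,
        origin=np.asarray(origin, dtype=float),
        grid_spacing=h,
        mask=mask,
        _path=path,
    )


def build_surrogate(params: SurrogateParams) -> Domain:
    """Build the n-shaped surrogate nasal passage.

    The fluid region is the union of three overlapping rectangles — the
    vestibule limb (anterior), the main passage band under the roof, and the
    nasopharynx limb (posterior) — with the two interior corners of the
    central septal block filleted at ``bend_radius``.  The olfactory segment
    sits on the roof, centered over the main passage, with length
    ``olfactory_fraction`` times the total wall length.  Construction is
    deterministic for fixed parameters.
    """
    W = params.inlet_width
    H = params.passage_height
    L = params.passage_length
    t = params.passage_thickness
    Wo = params.outlet_width
    r = params.bend_radius
    h = params.grid_spacing

    z_ceil = H - t  # top of the interior septal block

    # wall length is independent of where the olfactory segment sits
    wall_len = (
        2 * H                      # outer anterior + posterior walls
        + L                        # roof
        + 2 * (z_ceil - r)         # interior limb walls
        + math.pi * r              # two quarter-circle fillets
        + (L - W - Wo - 2 * r)     # interior ceiling
    )
    olf_len = params.olfactory_fraction * wall_len
    olf_mid = L / 2.0
    y0 = olf_mid - olf_len / 2.0
    y1 = olf_mid + olf_len / 2.0
    if y0 <= h or y1 >= L - h:
        raise ResolutionError(
            f"olfactory segment of length {olf_len:.4g} m does not fit on the "
            f"roof of length {L:.4g} m"
        )

    n_arc = max(8, int(math.ceil(math.pi * r / 2.0 / h)))

    verts: list[tuple[float, float]] = []
    labels: list[int] = []

    def add(points, label):
        # each point starts one segment toward the following point
        for p in points:
            verts.append((float(p[0]), float(p[1])))
            labels.append(int(label))

    add([(0.0, 0.0)], RegionLabel.WALL)               # anterior wall, upward
    add([(0.0, H)], RegionLabel.WALL)                 # roof, anterior part
    add([(y0, H)], RegionLabel.OLFACTORY)             # olfactory roof segment
    add([(y1, H)], RegionLabel.WALL)                  # roof, posterior part
    add([(L, H)], RegionLabel.WALL)                   # posterior wall, downward
    add([(L, 0.0)], RegionLabel.OUTLET)               # outlet (nasopharynx floor)
    add([(L - Wo, 0.0)], RegionLabel.WALL)            # interior posterior limb wall
    arc_r = _arc_points(
        (L - Wo - r, z_ceil - r), r, 0.0, math.pi / 2.0, n_arc
    )
    add(arc_r[:-1], RegionLabel.WALL)                 # posterior bend fillet
    add([arc_r[-1]], RegionLabel.WALL)                # interior ceiling
    arc_l = _arc_points(
        (W + r, z_ceil - r), r, math.pi / 2.0, math.pi, n_arc
    )
    add(arc_l[:-1], RegionLabel.WALL)                 # anterior bend fillet
    add([arc_l[-1]], RegionLabel.WALL)                # interior anterior limb wall
    add([(W, 0.0)], RegionLabel.INLET)                # inlet (nostril floor)
    # closing segment (W,0)->(0,0) carries the INLET label

    ny = int(round(L / h))
    nz = int(round(H / h))
    return _polyline_to_domain(verts, labels, h, (0.0, 0.0), (ny, nz))


def channel_domain(
    length: float = 0.03,
    width: float = 0.01,
    grid_spacing: float = 2.5e-4,
    olfactory_on_top: bool = False,
) -> Domain:
    """Straight 2-D channel fixture: inlet at y=0, outlet at y=length,
    no-slip walls at z=0 and z=width.  Used for plane-Poiseuille validation
    and as a minimal tracing arena."""
    Lc, Wc, h = length, width, grid_spacing
    top = RegionLabel.OLFACTORY if olfactory_on_top else RegionLabel.WALL
    verts = [(0.0, 0.0), (0.0, Wc), (Lc, Wc), (Lc, 0.0)]
    labels = [RegionLabel.INLET, top, RegionLabel.OUTLET, RegionLabel.WALL]
    ny = int(round(Lc / h))
    nz = int(round(Wc / h))
    return _polyline_to_domain(verts, labels, h, (0.0, 0.0), (ny, nz))


# -- STL ---------------------------------------------------------------------


def read_stl(path):
    """Read a triangulated surface in binary or ASCII STL format.

    Returns a ``trimesh.Trimesh``; the facet count is ``len(mesh.faces)``.
    No region labeling is performed.  Raises STLReadError on malformed input.
    """
    import trimesh

    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl")
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise STLReadError(f"could not parse STL file {path}: {exc}") from exc
    if not hasattr(mesh, "faces") or len(mesh.faces) == 0:
        raise STLReadError(f"STL file {path} contains no facets")
    return mesh
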