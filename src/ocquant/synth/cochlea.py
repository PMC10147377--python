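"""Synthetic 3D cochlear volumes with a planted efferent axon and puncta.

Renders a four-channel (axon/GFP, Syp, NPY, CALB2) 16-bit volume around a
known branched axon skeleton running along a straight tonotopic axis (the
unrolled cochlea — every published metric is along arc length, so
curvature adds nothing but harder ground truth).

Ground truth includes the SWC skeleton, every planted punctum (centroid,
radius, NPY status, CALB2-contact status) and the planted morphometrics
(branch-point count, stem position, tonotopic extent, turn direction).

Contact geometry is built to make the "proximity ≤ 0" rule unambiguous:
CALB2 tubes overlap their target punctum by about one voxel, while every
non-contact punctum keeps a surface gap of at least two voxels from all
tubes.  NPY⁺ puncta are wrapped by an NPY sphere slightly larger than the
punctum; NPY⁻ puncta have no NPY signal within two voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ..axon import AxonSkeleton, TonotopicAxis
from ..errors import ParameterError, PlacementError, ResolutionError
from ..image import ChannelImage

__all__ = ["CochleaSimParams", "CochleaGroundTruth", "generate_cochlea_volume"]


@dataclass
class CochleaSimParams:
    """Parameters of the cochlear volume simulation.

    Shapes are (Z, Y, X) voxels; all physical quantities in µm.  The
    tonotopic axis runs along +X with the base at low X.  ``turn_direction``
    orients the axon's terminal arbor from its stem ("apex", "base" or
    "bifurcated").
    """

    rng_seed: int = 0
    volume_shape: tuple[int, int, int] = (40, 72, 288)
    voxel_size: tuple[float, float, float] = (0.2, 0.2, 0.2)  # (z, y, x) µm
    axis_d0_percent: float = 20.0   # cochlear percent at x = 0
    axis_d1_percent: float = 40.0   # cochlear percent at x = X_max
    stem_frac: float = 0.35         # stem position along the axis [0, 1]
    n_branch_points: int = 3
    branch_length_um: float = 8.0
    turn_direction: str = "apex"
    axon_radius_um: float = 0.4
    n_puncta: int = 20
    puncta_radius_um: tuple[float, float] = (0.5, 0.05)  # mean, sd
    min_puncta_sep_um: float = 2.0
    fraction_npy: float = 0.5
    fraction_on_calb2: float = 0.5
    calb2_radius_um: float = 0.5
    background: float = 0.05
    noise_sd: float = 0.0
    amplitude: float = 10000.0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        for frac in (self.fraction_npy, self.fraction_on_calb2):
            if not 0 <= frac <= 1:
                raise ParameterError("fractions must lie in [0, 1]")
        if self.puncta_radius_um[0] <= 0 or self.axon_radius_um <= 0:
            raise ParameterError("radii must be positive")
        if self.puncta_radius_um[0] < max(self.voxel_size):
            raise ResolutionError(
                f"puncta radius {self.puncta_radius_um[0]} µm is below the "
                f"voxel size {max(self.voxel_size)} µm"
            )
        if self.turn_direction not in ("apex", "base", "bifurcated"):
            raise ParameterError(f"unknown turn_direction {self.turn_direction!r}")
        if self.n_puncta < 0 or self.n_branch_points < 0:
            raise ParameterError("counts must be >= 0")


@dataclass
class CochleaGroundTruth:
    """Planted truth for one simulated volume."""

    skeleton: AxonSkeleton
    axis: TonotopicAxis
    puncta: pd.DataFrame  # x/y/z_um, radius_um, npy_positive, on_calb2
    n_branch_points: int
    stem_percent: float
    turn_direction: str
    span_percent: float   # tonotopic extent of terminals+puncta, cochlear %


# ---------------------------------------------------------------------------
# skeleton construction
# ---------------------------------------------------------------------------

def _build_skeleton(
    params: CochleaSimParams, rng: np.random.Generator
) -> tuple[AxonSkeleton, list[tuple[np.ndarray, np.ndarray]]]:
    """Deterministic branched polyline tree; returns skeleton + segment list.

    The stem enters perpendicular to the tonotopic axis and turns into a
    trunk running along it; each branch point spawns a side branch offset
    in Y that then runs parallel to the trunk.  Node spacing is 1 µm.
    """
    vz, vy, vx = params.voxel_size
    nz, ny, nx = params.volume_shape
    ext_x, ext_y, ext_z = nx * vx, ny * vy, nz * vz
    y0, z0 = ext_y / 2, ext_z / 2
    x_stem = params.stem_frac * ext_x
    margin = 2.0

    # waypoints per unbranched path: list of (start, end) in µm (x, y, z)
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    entry = np.array([x_stem, y0 - min(6.0, y0 - margin), z0])
    junction = np.array([x_stem, y0, z0])
    segments.append((entry, junction))

    directions = {"apex": [1.0], "base": [-1.0], "bifurcated": [1.0, -1.0]}[
        params.turn_direction
    ]
    n_side = params.n_branch_points
    trunk_ends = []
    for k, sgn in enumerate(directions):
        if len(directions) == 1:
            n_here = n_side
        else:
            n_here = n_side - n_side // 2 if k == 0 else n_side // 2
        run = (n_here + 1) * params.branch_length_um
        run = min(run, (ext_x - margin - x_stem) if sgn > 0 else (x_stem - margin))
        end = junction + np.array([sgn * run, 0, 0])
        trunk_ends.append((junction, end, sgn, n_here))

    nodes: list[tuple[int, int, np.ndarray]] = []  # (id, parent, xyz)
    nid = 0

    def add_path(start: np.ndarray, end: np.ndarray, parent: int) -> int:
        """Append nodes along start→end (1 µm steps); return last node id."""
        nonlocal nid
        vec = end - start
        length = float(np.linalg.norm(vec))
        n_steps = max(1, int(np.ceil(length / 1.0)))
        prev = parent
        for s in range(1, n_steps + 1):
            nid += 1
            nodes.append((nid, prev, start + vec * (s / n_steps)))
            prev = nid
        return prev

    nid += 1
    nodes.append((nid, -1, entry))
    junction_id = add_path(entry, junction, 1)

    branch_ids = []
    for start, end, sgn, n_here in trunk_ends:
        vec = end - start
        prev = junction_id
        prev_pt = start
        for b in range(n_here):
            t = (b + 1) / (n_here + 1)
            bp_pt = start + vec * t
            prev = add_path(prev_pt, bp_pt, prev)
            branch_ids.append(prev)
            # side branch: offset in Y, then parallel to the trunk
            side_sgn = 1 if b % 2 == 0 else -1
            dy = min(4.0, (ext_y - margin - y0) if side_sgn > 0 else (y0 - margin))
            elbow = bp_pt + np.array([0, side_sgn * dy, 0])
            sid = add_path(bp_pt, elbow, prev)
            tip = elbow + np.array([sgn * params.branch_length_um * 0.6, 0, 0])
            tip[0] = np.clip(tip[0], margin, ext_x - margin)
            add_path(elbow, tip, sid)
            prev_pt = bp_pt
        add_path(prev_pt, end, prev)

    ids = np.array([n[0] for n in nodes])
    parents = np.array([n[1] for n in nodes])
    xyz = np.array([n[2] for n in nodes])
    radius = np.full(len(nodes), params.axon_radius_um)
    skel = AxonSkeleton(ids, parents, xyz, radius)
    return skel, segments


def _skeleton_distance_field(
    skel: AxonSkeleton, shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
) -> np.ndarray:
    """Distance (µm) from every voxel to the densely rasterized skeleton."""
    vz, vy, vx = voxel
    seed = np.ones(shape, bool)
    idx = {int(n): i for i, n in enumerate(skel.nodes)}
    step = 0.5 * min(voxel)
    for n, p in zip(skel.nodes, skel.parents):
        if p == -1:
            pts = skel.xyz[idx[int(n)]][None, :]
        else:
            a, b = skel.xyz[idx[int(p)]], skel.xyz[idx[int(n)]]
            k = max(2, int(np.ceil(np.linalg.norm(b - a) / step)))
            pts = a + (b - a) * np.linspace(0, 1, k)[:, None]
        zi = np.clip(np.round(pts[:, 2] / vz).astype(int), 0, shape[0] - 1)
        yi = np.clip(np.round(pts[:, 1] / vy).astype(int), 0, shape[1] - 1)
        xi = np.clip(np.round(pts[:, 0] / vx).astype(int), 0, shape[2] - 1)
        seed[zi, yi, xi] = False
    return ndi.distance_transform_edt(seed, sampling=voxel)


def _pick_calb2_contacts(
    rng: np.random.Generator,
    centers: list[np.ndarray],
    radii: np.ndarray,
    params: "CochleaSimParams",
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Choose which puncta touch a CALB2 tube and where the tubes go.

    Tubes run along Y at a contact punctum's X, offset in Z so the two
    surfaces overlap by ~1.5 voxels.  The assignment is redrawn until every
    non-contact punctum keeps a surface gap of at least two voxels from all
    tubes, keeping the planted flags geometrically unambiguous.
    """
    vz = params.voxel_size[0]
    nz = shape[0]
    n = len(centers)
    k = int(round(params.fraction_on_calb2 * n))
    if n == 0:
        return np.zeros(0, bool), []
    r_tube = params.calb2_radius_um
    clearance = 2.0 * max(params.voxel_size)

    # a tube for punctum i runs along Y at (x_i, z_t_i)
    z_t = np.empty(n)
    for i, (c, r) in enumerate(zip(centers, radii)):
        dz = r + r_tube - 1.5 * vz
        z_t[i] = c[2] + dz if c[2] + dz + r_tube < nz * vz - vz else c[2] - dz

    # puncta whose prospective tubes would graze the other punctum must
    # share a flag; union such pairs into components
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cj, rj = centers[j], radii[j]
            if np.hypot(cj[0] - centers[i][0], cj[2] - z_t[i]) - rj - r_tube \
                    < clearance:
                ri, rj_ = find(i), find(j)
                if ri != rj_:
                    parent[ri] = rj_

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    components = list(comps.values())

    # choose whole components whose sizes sum as close to k as possible
    best_flags, best_err = None, None
    for _ in range(200):
        order = rng.permutation(len(components))
        chosen: list[int] = []
        total = 0
        for ci in order:
            size = len(components[ci])
            if total + size <= k:
                chosen.extend(components[ci])
                total += size
            if total == k:
                break
        err = abs(total - k)
        if best_err is None or err < best_err:
            best_err = err
            best_flags = np.zeros(n, bool)
            best_flags[chosen] = True
        if best_err == 0:
            break
    flags = best_flags
    tubes = [(float(centers[i][0]), float(z_t[i]))
             for i in np.flatnonzero(flags)]
    return flags, tubes


def _sphere_mask(shape, voxel, center_um, radius_um) -> np.ndarray:
    vz, vy, vx = voxel
    zz, yy, xx = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    return (
        ((zz * vz - center_um[2]) ** 2)
        + ((yy * vy - center_um[1]) ** 2)
        + ((xx * vx - center_um[0]) ** 2)
    ) <= radius_um ** 2


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_cochlea_volume(
    params: CochleaSimParams,
) -> tuple[ChannelImage, np.ndarray, CochleaGroundTruth]:
    """Render one synthetic cochlear volume.

    Returns the four-channel image (``"gfp"``, ``"syp"``, ``"npy"``,
    ``"calb2"``, uint16), the boolean axon mask, and the ground truth.
    Deterministic under the seed.
    """
    rng = np.random.default_rng(params.rng_seed)
    shape = params.volume_shape
    voxel = params.voxel_size
    vz, vy, vx = voxel
    nz, ny, nx = shape

    skel, _ = _build_skeleton(params, rng)
    dist_axon = _skeleton_distance_field(skel, shape, voxel)
    axon_mask = dist_axon <= params.axon_radius_um

    axis = TonotopicAxis(
        p0=(0.0, ny * vy / 2, nz * vz / 2),
        p1=(nx * vx, ny * vy / 2, nz * vz / 2),
        d0_percent=params.axis_d0_percent,
        d1_percent=params.axis_d1_percent,
    )

    # ---- place puncta on the skeleton ---------------------------------
    idx = {int(n): i for i, n in enumerate(skel.nodes)}
    arcs = []  # candidate points on skeleton, away from the volume border
    for n, p in zip(skel.nodes, skel.parents):
        if p == -1:
            continue
        a, b = skel.xyz[idx[int(p)]], skel.xyz[idx[int(n)]]
        for t in np.linspace(0, 1, 4, endpoint=False):
            pt = a + (b - a) * t
            if (1.5 <= pt[0] <= nx * vx - 1.5 and 1.5 <= pt[1] <= ny * vy - 1.5
                    and 1.5 <= pt[2] <= nz * vz - 1.5):
                arcs.append(pt)
    arcs = np.array(arcs)
    if params.n_puncta > 0 and len(arcs) == 0:
        raise PlacementError("no admissible skeleton points for puncta")

    radii = np.clip(
        rng.normal(*params.puncta_radius_um, params.n_puncta),
        max(voxel), None,
    )
    min_sep = params.min_puncta_sep_um
    centers: list[np.ndarray] = []
    for _ in range(max(1, params.max_retries // 10) if params.n_puncta else 0):
        attempt: list[np.ndarray] = []
        for j in rng.permutation(len(arcs)):
            cand = arcs[j]
            if all(np.linalg.norm(cand - c) >= min_sep for c in attempt):
                attempt.append(cand)
                if len(attempt) == params.n_puncta:
                    break
        if len(attempt) > len(centers):
            centers = attempt
        if len(centers) == params.n_puncta:
            break
    if len(centers) < params.n_puncta:
        raise PlacementError(
            f"could only place {len(centers)}/{params.n_puncta} puncta at "
            f"separation {min_sep} µm; reduce n_puncta"
        )

    n = len(centers)
    npy_flags = np.zeros(n, bool)
    npy_flags[rng.permutation(n)[: int(round(params.fraction_npy * n))]] = True
    on_flags, tube_rows = _pick_calb2_contacts(
        rng, centers, radii, params, shape
    )

    # ---- render channels ----------------------------------------------
    gfp = np.where(axon_mask, 0.8, params.background)
    syp = np.full(shape, params.background)
    npy = np.full(shape, params.background)
    calb2 = np.full(shape, params.background)

    for i, (c, r) in enumerate(zip(centers, radii)):
        sph = _sphere_mask(shape, voxel, c, r)
        syp[sph & axon_mask] = 0.9  # Syp restricted to the axon tube
        if npy_flags[i]:
            npy[_sphere_mask(shape, voxel, c, r + 0.2)] = 0.85

    # CALB2 tubes along Y at each contact punctum, overlapping it slightly
    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    for tx, tz in tube_rows:
        tube = ((xx * vx - tx) ** 2 + (zz * vz - tz) ** 2) <= (
            params.calb2_radius_um ** 2
        )
        calb2 = np.where(np.broadcast_to(tube, shape), 0.9, calb2)

    if params.noise_sd > 0:
        gfp = gfp + rng.normal(0, params.noise_sd, shape)
        syp = syp + rng.normal(0, params.noise_sd, shape)
        npy = npy + rng.normal(0, params.noise_sd, shape)
        calb2 = calb2 + rng.normal(0, params.noise_sd, shape)

    def to_u16(a: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(a * params.amplitude), 0, 65535).astype(np.uint16)

    image = ChannelImage(
        data=np.stack([to_u16(gfp), to_u16(syp), to_u16(npy), to_u16(calb2)]),
        channels=["gfp", "syp", "npy", "calb2"],
        pixel_size=voxel,
    )

    centers_arr = np.array(centers) if centers else np.zeros((0, 3))
    puncta = pd.DataFrame(
        {
            "x_um": centers_arr[:, 0] if n else [],
            "y_um": centers_arr[:, 1] if n else [],
            "z_um": centers_arr[:, 2] if n else [],
            "radius_um": radii[:n],
            "npy_positive": npy_flags,
            "on_calb2": on_flags,
        }
    )

    extent_pts = [skel.terminal_xyz()]
    if n:
        extent_pts.append(centers_arr)
    d_vals = axis.percent_at(np.vstack(extent_pts))
    stem_pct = float(axis.percent_at(skel.root_xyz[None, :])[0])
    gt = CochleaGroundTruth(
        skeleton=skel,
        axis=axis,
        puncta=puncta,
        n_branch_points=len(skel.branch_points()),
        stem_percent=stem_pct,
        turn_direction=params.turn_direction,
        span_percent=float(d_vals.max() - d_vals.min()),
    )
    return image, axon_mask, gt
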