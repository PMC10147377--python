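"""3D efferent-axon reconstruction analysis for the cochlea.

Given a multi-channel confocal volume (axon/GFP, synaptophysin, NPY, CALB2),
an axon skeleton traced elsewhere (SWC), and a tonotopic axis annotation,
this module reproduces the quantification chain behind per-axon synaptic
morphometrics:

* mask the synaptic channels by the axon surface;
* detect synaptophysin puncta (smooth → threshold → 26-connected
  components → watershed split of blobs larger than ~1.6 µm);
* classify each punctum NPY⁺/NPY⁻ and On/Off-CALB2 by "proximity ≤ 0",
  i.e. voxel overlap or 26-connected adjacency with the respective surface;
* map positions to frequency through the cochlear place–frequency function
  ``F(kHz) = 10^((a − d)/b)`` with d the percent distance from the base;
* summarize each axon (stem frequency, tonotopic span, branch points,
  turn direction, densities, %NPY⁺, CALB2 selectivity) and run the Pearson
  correlation screen across axons.

All geometry is computed in physical µm; anisotropic voxels are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .errors import (
    ConfigError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "PlaceFrequencyMap",
    "TonotopicAxis",
    "AxonSkeleton",
    "AxonMetrics",
    "position_to_frequency",
    "frequency_to_position",
    "mask_channel_by_axon",
    "detect_puncta",
    "classify_npy",
    "classify_calb2",
    "puncta_frequencies",
    "skeleton_metrics",
    "correlate_metrics",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# place–frequency map and tonotopic axis
# ---------------------------------------------------------------------------

@dataclass
class PlaceFrequencyMap:
    """Mouse cochlear place–frequency function.

    ``F(kHz) = 10**((a - d) / b)`` with ``d`` the percent distance from the
    BASE (0 = basal/high-frequency end, 100 = apical/low-frequency end).
    Defaults a = 156.5, b = 82.5 give 78.96 kHz at the base and 4.84 kHz at
    the apex; both parameters are configurable for other species.
    """

    a: float = 156.5
    b: float = 82.5

    def frequency(self, d_percent_from_base) -> np.ndarray | float:
        d = np.asarray(d_percent_from_base, float)
        if np.any(d < 0) or np.any(d > 100):
            raise ParameterError("d must lie in [0, 100] percent")
        f = 10.0 ** ((self.a - d) / self.b)
        return float(f) if f.ndim == 0 else f

    def position(self, f_khz) -> np.ndarray | float:
        f = np.asarray(f_khz, float)
        if np.any(f <= 0):
            raise ParameterError("frequency must be positive")
        d = self.a - self.b * np.log10(f)
        return float(d) if d.ndim == 0 else d


def position_to_frequency(d_percent_from_base, pmap: PlaceFrequencyMap | None = None):
    """Percent-from-base cochlear position → frequency in kHz."""
    return (pmap or PlaceFrequencyMap()).frequency(d_percent_from_base)


def frequency_to_position(f_khz, pmap: PlaceFrequencyMap | None = None):
    """Frequency in kHz → percent distance from the cochlear base."""
    return (pmap or PlaceFrequencyMap()).position(f_khz)


@dataclass
class TonotopicAxis:
    """Straight tonotopic reference segment inside the imaged volume.

    ``p0``/``p1`` are the segment endpoints in µm, (x, y, z); they map to
    cochlear positions ``d0_percent``/``d1_percent`` (percent from base).
    Points are orthogonally projected onto the segment (clamped to it) and
    linearly interpolated to a percent position.
    """

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    d0_percent: float = 0.0
    d1_percent: float = 100.0

    def __post_init__(self) -> None:
        if np.allclose(self.p0, self.p1):
            raise ConfigError("axis endpoints coincide")

    def percent_at(self, points_um: np.ndarray) -> np.ndarray:
        """Percent-from-base position of (N, 3) points in µm."""
        p = np.atleast_2d(np.asarray(points_um, float))
        v = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        t = ((p - np.asarray(self.p0, float)) @ v) / float(v @ v)
        t = np.clip(t, 0.0, 1.0)
        return self.d0_percent + t * (self.d1_percent - self.d0_percent)

    def axial_coordinate(self, points_um: np.ndarray) -> np.ndarray:
        """Signed scalar coordinate (µm) along the base→apex direction."""
        p = np.atleast_2d(np.asarray(points_um, float))
        v = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        v = v / np.linalg.norm(v)
        if self.d1_percent < self.d0_percent:  # p1 is the basal end
            v = -v
        return (p - np.asarray(self.p0, float)) @ v


# ---------------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------------

@dataclass
class AxonSkeleton:
    """Rooted tree skeleton of one axon, in physical µm.

    ``nodes`` is an (N,) int array of SWC ids, ``parents`` the parent id per
    node (−1 for the single root), ``xyz`` an (N, 3) float array (x, y, z in
    µm) and ``radius`` the per-node radius.  The root is the entry point of
    the axon (the stem).
    """

    nodes: np.ndarray
    parents: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, int)
        self.parents = np.asarray(self.parents, int)
        self.xyz = np.asarray(self.xyz, float)
        self.radius = np.asarray(self.radius, float)
        if len(set(self.nodes.tolist())) != len(self.nodes):
            raise FormatError("duplicate node ids")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise FormatError(f"expected exactly one root, found {len(roots)}")
        idx = {int(n): i for i, n in enumerate(self.nodes)}
        g = nx.DiGraph()
        g.add_nodes_from(int(n) for n in self.nodes)
        for n, p in zip(self.nodes, self.parents):
            if p == -1:
                continue
            if int(p) not in idx:
                raise FormatError(f"node {int(n)} references missing parent {int(p)}")
            g.add_edge(int(p), int(n))
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError("skeleton contains a cycle")
        if not nx.is_weakly_connected(g):
            raise FormatError("skeleton is not a single connected tree")
        self._graph = g
        self._index = idx
        self._root = int(self.nodes[roots[0]])

    @property
    def root(self) -> int:
        return self._root

    @property
    def root_xyz(self) -> np.ndarray:
        return self.xyz[self._index[self._root]]

    def total_length(self) -> float:
        """Sum of parent→child segment lengths in µm."""
        length = 0.0
        for n, p in zip(self.nodes, self.parents):
            if p == -1:
                continue
            length += float(
                np.linalg.norm(self.xyz[self._index[int(n)]] -
                               self.xyz[self._index[int(p)]])
            )
        return length

    def branch_points(self) -> list[int]:
        """Node ids with two or more children."""
        return [n for n in self._graph.nodes if self._graph.out_degree(n) >= 2]

    def terminals(self) -> list[int]:
        """Leaf node ids (no children)."""
        return [n for n in self._graph.nodes if self._graph.out_degree(n) == 0]

    def terminal_xyz(self) -> np.ndarray:
        return np.array([self.xyz[self._index[t]] for t in self.terminals()])

    def branch_depth(self) -> int:
        """Maximum number of branch points on any root→terminal path."""
        bset = set(self.branch_points())
        best = 0
        for t in self.terminals():
            path = nx.shortest_path(self._graph, self._root, t)
            best = max(best, sum(1 for n in path if n in bset))
        return best

    def translated(self, offset_um) -> "AxonSkeleton":
        """Rigidly translated copy (µm offset, (x, y, z))."""
        return AxonSkeleton(self.nodes.copy(), self.parents.copy(),
                            self.xyz + np.asarray(offset_um, float),
                            self.radius.copy())


# ---------------------------------------------------------------------------
# channel masking and puncta detection
# ---------------------------------------------------------------------------

def mask_channel_by_axon(channel: np.ndarray, axon_mask: np.ndarray) -> np.ndarray:
    """Zero every voxel outside the axon surface mask."""
    channel = np.asarray(channel)
    axon_mask = np.asarray(axon_mask).astype(bool)
    if channel.shape != axon_mask.shape:
        raise ConfigError(
            f"channel shape {channel.shape} != mask shape {axon_mask.shape}"
        )
    return np.where(axon_mask, channel, 0)


def detect_puncta(
    masked_syp: np.ndarray,
    voxel_size: tuple[float, float, float],
    intensity_threshold: float,
    grain_um: float = 0.115,
    split_diameter_um: float = 1.6,
    min_voxels: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Detect presynaptic puncta in the axon-masked synaptophysin channel.

    Pipeline: Gaussian smoothing at the surface grain scale (``grain_um``;
    sub-voxel grains render as voxel-level smoothing) → absolute intensity
    threshold → 26-connected components → any component with equivalent
    spherical diameter above ``split_diameter_um`` is divided by a
    distance-transform watershed whose seeds are at least that far apart
    (a component yielding a single seed is bisected across its long axis).

    Parameters
    ----------
    masked_syp : (Z, Y, X) array
    voxel_size : (z, y, x) voxel edge lengths in µm.
    intensity_threshold : float
        Threshold on the smoothed intensity; >= 0.
    min_voxels : int
        Fragments below this size are discarded.

    Returns
    -------
    (label_volume, table) — an int32 punctum label volume and a DataFrame
    with ``punctum`` id, centroid in µm (x, y, z), voxel count, volume in
    µm³ and equivalent diameter in µm.  An all-zero input yields an empty
    table, not an error.
    """
    vol = np.asarray(masked_syp, float)
    if vol.ndim != 3:
        raise ParameterError(f"expected a 3D volume, got ndim={vol.ndim}")
    if intensity_threshold < 0:
        raise ParameterError("intensity threshold must be >= 0")
    vz, vy, vx = (float(v) for v in voxel_size)
    if min(vz, vy, vx) <= 0:
        raise ParameterError("voxel sizes must be positive")

    sigmas = tuple(grain_um / v for v in (vz, vy, vx))
    smoothed = ndi.gaussian_filter(vol, sigmas, mode="nearest")
    fg = smoothed > intensity_threshold
    if not fg.any():
        return np.zeros(vol.shape, np.int32), _empty_puncta_table()

    comps, _ = ndi.label(fg, structure=_STRUCT26)
    voxel_vol = vz * vy * vx
    out = np.zeros(vol.shape, np.int32)
    next_id = 1
    for cid, sl in enumerate(ndi.find_objects(comps), start=1):
        if sl is None:
            continue
        region = comps[sl] == cid
        eq_d = _equivalent_diameter(int(region.sum()) * voxel_vol)
        if eq_d > split_diameter_um:
            pieces = _split_component(region, (vz, vy, vx), split_diameter_um)
        else:
            pieces = region.astype(np.int32)
        for pid in np.unique(pieces):
            if pid == 0:
                continue
            piece = pieces == pid
            if piece.sum() < min_voxels:
                continue
            out[sl][piece] = next_id
            next_id += 1

    return out, _puncta_table(out, (vz, vy, vx))


def _equivalent_diameter(volume_um3: float) -> float:
    return float((6.0 * volume_um3 / np.pi) ** (1.0 / 3.0))


def _split_component(
    region: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_sep_um: float,
) -> np.ndarray:
    """Watershed-split one oversized component; fall back to a long-axis cut."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    dist = ndi.distance_transform_edt(region, sampling=voxel_size)
    min_dist_vox = max(1, int(np.ceil(min_sep_um / min(voxel_size))))
    peaks = peak_local_max(
        dist, min_distance=min_dist_vox, labels=region, exclude_border=False
    )
    if len(peaks) >= 2:
        # enforce physical seed separation >= min_sep_um
        kept: list[np.ndarray] = []
        scale = np.asarray(voxel_size)
        for pk in peaks:  # peaks come sorted by peak height
            if all(np.linalg.norm((pk - q) * scale) >= min_sep_um for q in kept):
                kept.append(pk)
        peaks = np.array(kept)
    if len(peaks) >= 2:
        markers = np.zeros(region.shape, np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        return watershed(-dist, markers, mask=region).astype(np.int32)

    # single interior maximum (e.g. a smooth prolate blob): cut across the
    # principal axis at the median so both halves keep >= 1 voxel
    coords = np.argwhere(region) * np.asarray(voxel_size)
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    cut = np.median(proj)
    labels = np.zeros(region.shape, np.int32)
    idx = np.argwhere(region)
    labels[tuple(idx.T)] = np.where(proj <= cut, 1, 2)
    return labels


def _empty_puncta_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["punctum", "x_um", "y_um", "z_um", "n_voxels",
                 "volume_um3", "eq_diameter_um"]
    )


def _puncta_table(labels: np.ndarray, voxel_size) -> pd.DataFrame:
    vz, vy, vx = voxel_size
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return _empty_puncta_table()
    centroids = np.array(ndi.center_of_mass(np.ones_like(labels), labels, ids))
    counts = ndi.sum_labels(np.ones_like(labels), labels, ids)
    voxel_vol = vz * vy * vx
    return pd.DataFrame(
        {
            "punctum": ids.astype(int),
            "x_um": centroids[:, 2] * vx,
            "y_um": centroids[:, 1] * vy,
            "z_um": centroids[:, 0] * vz,
            "n_voxels": counts.astype(int),
            "volume_um3": counts * voxel_vol,
            "eq_diameter_um": [_equivalent_diameter(c * voxel_vol) for c in counts],
        }
    )


# ---------------------------------------------------------------------------
# proximity classification
# ---------------------------------------------------------------------------

def _touches_surface(
    puncta_labels: np.ndarray,
    table: pd.DataFrame,
    surface_mask: np.ndarray,
) -> np.ndarray:
    """Proximity ≤ 0 per punctum: voxel overlap or 26-connected adjacency."""
    if puncta_labels.shape != surface_mask.shape:
        raise ConfigError("puncta and surface grids differ in shape")
    surface = np.asarray(surface_mask).astype(bool)
    # one-voxel 26-connected halo: overlap with it == touching or overlapping
    halo = ndi.binary_dilation(surface, structure=_STRUCT26)
    flags = np.zeros(len(table), dtype=bool)
    if not halo.any() or len(table) == 0:
        return flags
    touched = np.unique(puncta_labels[halo & (puncta_labels > 0)])
    return table["punctum"].isin(touched).to_numpy()


def classify_npy(
    puncta_labels: np.ndarray,
    table: pd.DataFrame,
    npy_mask: np.ndarray,
) -> pd.DataFrame:
    """Add ``npy_positive``: punctum touches/overlaps the NPY surface."""
    out = table.copy()
    out["npy_positive"] = _touches_surface(puncta_labels, table, npy_mask)
    return out


def classify_calb2(
    puncta_labels: np.ndarray,
    table: pd.DataFrame,
    calb2_mask: np.ndarray,
) -> pd.DataFrame:
    """Add ``on_calb2``: punctum directly contacts the CALB2 surface."""
    out = table.copy()
    out["on_calb2"] = _touches_surface(puncta_labels, table, calb2_mask)
    return out


def puncta_frequencies(
    table: pd.DataFrame,
    axis: TonotopicAxis,
    pmap: PlaceFrequencyMap | None = None,
) -> pd.DataFrame:
    """Add tonotopic position (``d_percent``) and ``freq_khz`` per punctum."""
    pmap = pmap or PlaceFrequencyMap()
    out = table.copy()
    if len(table) == 0:
        out["d_percent"] = pd.Series(dtype=float)
        out["freq_khz"] = pd.Series(dtype=float)
        return out
    pts = table[["x_um", "y_um", "z_um"]].to_numpy(float)
    d = axis.percent_at(pts)
    out["d_percent"] = d
    out["freq_khz"] = pmap.frequency(d)
    return out


# ---------------------------------------------------------------------------
# per-axon metrics and the correlation screen
# ---------------------------------------------------------------------------

@dataclass
class AxonMetrics:
    """Morphometric and synaptic summary of one reconstructed axon."""

    stem_freq_khz: float
    span_khz: float
    n_branch_points: int
    branch_depth: int
    total_length_um: float
    n_puncta: int
    pct_npy: float            # NaN when no puncta
    selectivity_calb2: float  # fraction On-CALB2; NaN when no puncta
    fiber_density_um_per_khz: float  # NaN when span is 0
    puncta_density_per_100um: float
    turn_direction: str       # "apex" | "base" | "bifurcated"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def skeleton_metrics(
    skeleton: AxonSkeleton,
    puncta: pd.DataFrame,
    axis: TonotopicAxis,
    pmap: PlaceFrequencyMap | None = None,
    span_source: str = "union",
    bifurcation_frac: float = 0.05,
) -> AxonMetrics:
    """Compute the per-axon metric panel.

    ``span_source`` selects which points bound the tonotopic span:
    ``"union"`` (terminals and puncta, the default), ``"puncta"`` or
    ``"terminals"``.  Turn direction compares the maximum terminal extent
    toward apex vs base from the stem along the tonotopic axis; the axon is
    called bifurcated when the minor extent exceeds ``bifurcation_frac`` of
    the summed extents.
    """
    pmap = pmap or PlaceFrequencyMap()
    if span_source not in ("union", "puncta", "terminals"):
        raise ParameterError(f"unknown span_source {span_source!r}")

    stem = skeleton.root_xyz
    stem_d = float(axis.percent_at(stem[None, :])[0])
    stem_freq = float(pmap.frequency(stem_d))

    term_xyz = skeleton.terminal_xyz()
    pts: list[np.ndarray] = []
    if span_source in ("union", "terminals") and len(term_xyz):
        pts.append(np.vstack([stem[None, :], term_xyz]))
    if span_source in ("union", "puncta") and len(puncta):
        pts.append(puncta[["x_um", "y_um", "z_um"]].to_numpy(float))
    if pts:
        d = axis.percent_at(np.vstack(pts))
        freqs = pmap.frequency(d)
        span = float(np.max(freqs) - np.min(freqs))
    else:
        span = 0.0

    n_puncta = int(len(puncta))
    pct_npy = (
        100.0 * float(puncta["npy_positive"].mean()) if n_puncta else float("nan")
    )
    selectivity = (
        float(puncta["on_calb2"].mean()) if n_puncta else float("nan")
    )
    length = skeleton.total_length()
    fiber_density = length / span if span > 0 else float("nan")
    puncta_density = 100.0 * n_puncta / length if length > 0 else float("nan")

    # signed extents along base→apex from the stem
    if len(term_xyz):
        coords = axis.axial_coordinate(term_xyz) - axis.axial_coordinate(
            stem[None, :]
        )[0]
        e_apex = float(max(coords.max(), 0.0))
        e_base = float(max(-coords.min(), 0.0))
    else:
        e_apex = e_base = 0.0
    total = e_apex + e_base
    if total == 0:
        turn = "apex"
    elif min(e_apex, e_base) > bifurcation_frac * total:
        turn = "bifurcated"
    else:
        turn = "apex" if e_apex >= e_base else "base"

    return AxonMetrics(
        stem_freq_khz=stem_freq,
        span_khz=span,
        n_branch_points=len(skeleton.branch_points()),
        branch_depth=skeleton.branch_depth(),
        total_length_um=length,
        n_puncta=n_puncta,
        pct_npy=pct_npy,
        selectivity_calb2=selectivity,
        fiber_density_um_per_khz=fiber_density,
        puncta_density_per_100um=puncta_density,
        turn_direction=turn,
    )


def correlate_metrics(
    axon_table: pd.DataFrame,
    x_field: str = "pct_npy",
    y_fields: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation screen of one metric against the others.

    Returns one row per y field with ``r`` and the two-sided t-based ``p``.
    No multiplicity correction is applied.  Raises if fewer than 3 axons or
    if the x field is constant.
    """
    if y_fields is None:
        y_fields = [
            c for c in axon_table.columns
            if c != x_field and pd.api.types.is_numeric_dtype(axon_table[c])
        ]
    x = axon_table[x_field].to_numpy(float)
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 axons, got {len(x)}")
    if np.ptp(x[~np.isnan(x)]) == 0:
        raise InsufficientDataError(f"x field {x_field!r} is constant")
    rows = []
    for yf in y_fields:
        y = axon_table[yf].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.ptp(y[ok]) == 0:
            rows.append({"y_field": yf, "n": int(ok.sum()),
                         "r": float("nan"), "p": float("nan")})
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"y_field": yf, "n": int(ok.sum()),
                     "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
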