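"""Synthetic LSO sections with a planted medial–lateral peptide gradient.

The generator emits a two-channel 16-bit section (soma marker + peptide),
an instance label image, and a ground-truth table, so the whole soma
quantification → gradient regression chain can be validated against known
parameters.

Model
-----
Somata are non-overlapping filled disks with Gaussian-jittered radii,
scattered inside an LSO-shaped polygon.  Each expressing soma adds a
peptide signal whose expected normalized intensity is
``intercept + slope * position`` (position = normalized medial–lateral
coordinate, 0 at the medial end); non-expressing somata add nothing.  The
peptide channel additionally carries a smooth random neuropil field
(low-pass-filtered noise) and per-pixel Gaussian noise; all intensities
are in normalized units and scaled by ``amplitude`` into 16-bit counts at
render time.  Decoy objects — normal-looking disks outside the polygon and
thin slivers inside it — exercise the curation rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from ..errors import GeometryError, ParameterError, PlacementError
from ..gradient import LsoAxis
from ..image import ChannelImage, SomaMask

__all__ = ["GradientSimParams", "LsoGroundTruth", "generate_lso_image",
           "default_lso_polygon"]


def default_lso_polygon(shape: tuple[int, int] = (512, 512),
                        n_vertices: int = 48) -> np.ndarray:
    """An S-curved, LSO-like closed polygon filling most of the frame.

    Vertices in (x, y) pixel coordinates.  The outline is an ellipse whose
    vertical center undulates along x, echoing the S shape of the nucleus.
    """
    h, w = shape
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    cx, cy = w / 2, h / 2
    rx, ry = 0.42 * w, 0.30 * h
    x = cx + rx * np.cos(t)
    y = cy + ry * np.sin(t) + 0.08 * h * np.sin(2 * np.pi * (x - cx) / w)
    return np.column_stack([x, y])


@dataclass
class GradientSimParams:
    """Parameters of the LSO gradient simulation.

    Intensities (``true_intercept``, ``neuropil_level``, ``noise_sd``...)
    are in normalized units where the brightest expected soma is ~1;
    ``amplitude`` converts them to 16-bit counts.  ``true_slope`` is
    normalized intensity per unit normalized medial–lateral position.
    """

    rng_seed: int = 0
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5  # µm/px
    lso_polygon: np.ndarray | None = None  # (x, y) vertices; default S-shape
    axis: LsoAxis | None = None  # default: horizontal through the polygon
    n_cells: int = 200
    soma_radius_px: tuple[float, float] = (6.0, 1.0)  # mean, sd
    true_slope: float = -0.6
    true_intercept: float = 1.0
    expressing_fraction: float = 1.0
    neuropil_level: float = 0.15
    neuropil_texture: float = 0.5   # relative sd of the smooth field
    neuropil_sigma_px: float = 40.0
    noise_sd: float = 0.05          # per-cell expression scatter, normalized units
    pixel_noise_sd: float = 0.02    # per-pixel read noise, normalized units
    soma_marker_level: float = 0.75
    amplitude: float = 10000.0      # normalized unit → 16-bit counts
    n_decoys_outside: int = 0
    n_decoys_misshapen: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_decoys_outside < 0 or self.n_decoys_misshapen < 0:
            raise ParameterError("object counts must be >= 0")
        if not 0 <= self.expressing_fraction <= 1:
            raise ParameterError("expressing_fraction must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if self.noise_sd < 0 or self.pixel_noise_sd < 0 or self.neuropil_level < 0:
            raise ParameterError("noise and background levels must be >= 0")
        if self.lso_polygon is None:
            self.lso_polygon = default_lso_polygon(self.image_shape)
        self.lso_polygon = np.asarray(self.lso_polygon, float)
        poly = Polygon(self.lso_polygon)
        if len(self.lso_polygon) < 3 or not poly.is_valid or poly.area == 0:
            raise GeometryError("lso_polygon is degenerate or self-intersecting")
        if not poly.is_simple:
            raise GeometryError("lso_polygon must be simple (non-self-intersecting)")
        if self.axis is None:
            xs, ys = self.lso_polygon[:, 0], self.lso_polygon[:, 1]
            ymid = float(ys.mean())
            self.axis = LsoAxis((float(xs.min()), ymid), (float(xs.max()), ymid))


@dataclass
class LsoGroundTruth:
    """Planted truth for one simulated section.

    ``cells`` has one row per emitted label — genuine somata first, then
    decoys (``decoy`` column: "" / "outside" / "sliver").  For genuine
    somata, ``expected_intensity`` is the expected *corrected* peptide
    intensity in normalized units (0 for non-expressing cells) and
    ``expected_soma_mean`` additionally includes the local neuropil field.
    """

    cells: pd.DataFrame
    true_slope: float
    true_intercept: float
    expressing_fraction: float
    amplitude: float


def _sample_positions(
    rng: np.random.Generator,
    polygon: Polygon,
    n: int,
    radii: np.ndarray,
    taken: list[tuple[float, float, float]],
    max_retries: int,
    inside: bool = True,
    margin: float = 2.0,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping disk centers (x, y, r)."""
    minx, miny, maxx, maxy = polygon.bounds
    placed: list[tuple[float, float, float]] = []
    prepared = prep(polygon)
    for r in radii:
        for attempt in range(max_retries):
            if inside:
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if not prepared.contains(Point(x, y)):
                    continue
                if polygon.exterior.distance(Point(x, y)) < r + 1:
                    continue
            else:
                # anywhere in the frame but clear of the polygon
                x = rng.uniform(0, maxx + (maxx - minx) * 0.1)
                y = rng.uniform(0, maxy + (maxy - miny) * 0.1)
                if polygon.distance(Point(x, y)) < r + 2:
                    continue
            ok = all(
                np.hypot(x - px, y - py) >= r + pr + margin
                for px, py, pr in taken + placed
            )
            if ok:
                placed.append((x, y, r))
                break
        else:
            raise PlacementError(
                f"could not place object after {max_retries} retries "
                f"({len(placed)}/{n} placed); reduce n_cells or radii"
            )
    return placed


def generate_lso_image(
    params: GradientSimParams,
) -> tuple[ChannelImage, SomaMask, LsoGroundTruth]:
    """Render one synthetic LSO section.

    Returns the two-channel image (channels ``"soma"`` and ``"peptide"``,
    uint16), the planted instance label mask, and the ground truth.
    Identical parameters (including the seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_shape
    polygon = Polygon(params.lso_polygon)

    mean_r, sd_r = params.soma_radius_px
    radii = np.clip(rng.normal(mean_r, sd_r, params.n_cells), 3.0, None)
    cells = _sample_positions(
        rng, polygon, params.n_cells, radii, [], params.max_retries
    )

    decoy_radii = np.clip(
        rng.normal(mean_r, sd_r, params.n_decoys_outside), 3.0, None
    )
    decoys_out = _sample_positions(
        rng, polygon, params.n_decoys_outside, decoy_radii,
        cells, params.max_retries, inside=False,
    )
    sliver_radii = np.clip(
        rng.normal(mean_r, sd_r, params.n_decoys_misshapen), 3.0, None
    )
    # place with the sliver's long half-axis so it cannot touch a soma
    slivers = _sample_positions(
        rng, polygon, params.n_decoys_misshapen, 3.2 * sliver_radii,
        cells + decoys_out, params.max_retries,
    )
    slivers = [(x, y, r / 3.2) for x, y, r in slivers]

    # ---- label image ---------------------------------------------------
    labels = np.zeros((h, w), np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    label_id = 0
    axis = params.axis
    v = np.asarray(axis.lateral) - np.asarray(axis.medial)
    denom = float(v @ v)

    expressing = np.zeros(params.n_cells, bool)
    n_expr = int(round(params.expressing_fraction * params.n_cells))
    if params.n_cells:
        expressing[rng.permutation(params.n_cells)[:n_expr]] = True

    scatter = rng.normal(0.0, params.noise_sd, params.n_cells)
    for i, (x, y, r) in enumerate(cells):
        label_id += 1
        disk = (xx - x) ** 2 + (yy - y) ** 2 <= r ** 2
        labels[disk] = label_id
        pos = float(np.clip(
            ((np.array([x, y]) - np.asarray(axis.medial)) @ v) / denom, 0, 1
        ))
        line = params.true_intercept + params.true_slope * pos
        # per-cell biological scatter around the gradient line
        e = max(line + scatter[i], 0.0) if expressing[i] else 0.0
        rows.append({
            "label": label_id, "x_px": x, "y_px": y, "radius_px": r,
            "position": pos, "line_intensity": max(line, 0.0) if expressing[i] else 0.0,
            "expected_intensity": e,
            "expressing": bool(expressing[i]), "decoy": "",
        })

    for x, y, r in decoys_out:
        label_id += 1
        disk = (xx - x) ** 2 + (yy - y) ** 2 <= r ** 2
        labels[disk] = label_id
        rows.append({
            "label": label_id, "x_px": x, "y_px": y, "radius_px": r,
            "position": np.nan, "line_intensity": 0.0, "expected_intensity": 0.0,
            "expressing": False, "decoy": "outside",
        })

    for x, y, r in slivers:
        label_id += 1
        ang = rng.uniform(0, np.pi)
        a, b = 3.2 * r, max(1.2, 0.25 * r)  # eccentricity ~0.997
        xr = (xx - x) * np.cos(ang) + (yy - y) * np.sin(ang)
        yr = -(xx - x) * np.sin(ang) + (yy - y) * np.cos(ang)
        sliver = (xr / a) ** 2 + (yr / b) ** 2 <= 1
        sliver &= labels == 0
        labels[sliver] = label_id
        rows.append({
            "label": label_id, "x_px": x, "y_px": y, "radius_px": r,
            "position": np.nan, "line_intensity": 0.0, "expected_intensity": 0.0,
            "expressing": False, "decoy": "sliver",
        })

    truth_cols = ["label", "x_px", "y_px", "radius_px", "position",
                  "line_intensity", "expected_intensity", "expressing", "decoy"]
    truth = pd.DataFrame(rows, columns=truth_cols)

    # ---- peptide channel ----------------------------------------------
    if params.neuropil_texture > 0 and params.neuropil_level > 0:
        raw_field = rng.standard_normal((h, w))
        smooth = ndi.gaussian_filter(raw_field, params.neuropil_sigma_px)
        smooth /= max(smooth.std(), 1e-12)
        fieldmap = params.neuropil_level * np.clip(
            1.0 + params.neuropil_texture * smooth, 0.0, None
        )
    else:
        fieldmap = np.full((h, w), params.neuropil_level)

    peptide = fieldmap.copy()
    soma_chan = np.full((h, w), 0.05)
    expected_soma_means = []
    for row in truth.itertuples():
        region = labels == row.label
        if row.decoy == "":
            peptide[region] += row.expected_intensity
            expected_soma_means.append(
                row.expected_intensity + float(fieldmap[region].mean())
            )
            soma_chan[region] = params.soma_marker_level
        else:
            expected_soma_means.append(float(fieldmap[region].mean())
                                       if region.any() else np.nan)
            soma_chan[region] = params.soma_marker_level
    truth["expected_soma_mean"] = expected_soma_means
    truth["expected_neuropil"] = [
        float(fieldmap[labels == lab].mean()) if (labels == lab).any() else np.nan
        for lab in truth["label"]
    ]

    if params.pixel_noise_sd > 0:
        peptide = peptide + rng.normal(0, params.pixel_noise_sd, (h, w))
        soma_chan = soma_chan + rng.normal(0, params.pixel_noise_sd, (h, w))

    def to_u16(a: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(a * params.amplitude), 0, 65535).astype(np.uint16)

    image = ChannelImage(
        data=np.stack([to_u16(soma_chan), to_u16(peptide)]),
        channels=["soma", "peptide"],
        pixel_size=(params.pixel_size, params.pixel_size),
    )
    mask = SomaMask(labels=labels, pixel_size=params.pixel_size)
    gt = LsoGroundTruth(
        cells=truth,
        true_slope=params.true_slope,
        true_intercept=params.true_intercept,
        expressing_fraction=params.expressing_fraction,
        amplitude=params.amplitude,
    )
    return image, mask, gt
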