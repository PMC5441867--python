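"""Chemogeography: distribution-pattern binning over collection sites and
spatial rendering of feature intensities onto a background map.

Every feature is reduced to a presence/absence bit-vector over the ordered
site list; bins keyed by these patterns form the nodes of an n-dimensional
hypercube graph whose edges connect patterns differing at exactly one site.
For map rendering, each sample gets a pixel coordinate (multiple samples at
one site are ringed around the site's anchor pixel) and a feature's
per-spot intensities, scaled 0-100% (optionally after a log transform), are
painted with the jet colormap and blended into the background in log-space
with a Gaussian distance falloff truncated at the spot radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import STUDY_SITES, SampleMetadata, ValidationError, provenance_line
from .diversity import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class GeoParams:
    site_list: tuple[str, ...] = STUDY_SITES
    bin_color_max: int = 10000
    colormap: str = "jet"  # jet | linear_grey
    intensity_scale: str = "logarithmic"  # logarithmic | linear
    spot_radius: float = 12.0
    falloff_sigma: float = 5.0

    def __post_init__(self) -> None:
        self.site_list = tuple(self.site_list)
        if not self.site_list or len(set(self.site_list)) != len(self.site_list):
            raise ValidationError("site_list must be non-empty and unique")
        if self.spot_radius <= 0:
            raise ValidationError("spot_radius must be > 0")
        if self.colormap not in ("jet", "linear_grey"):
            raise ValidationError("colormap must be 'jet' or 'linear_grey'")
        if self.intensity_scale not in ("logarithmic", "linear"):
            raise ValidationError("intensity_scale must be 'logarithmic' or 'linear'")


@dataclass
class DistributionBin:
    """A presence/absence pattern over the site list plus its features."""

    pattern: tuple[int, ...]
    feature_ids: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.feature_ids)

    @property
    def key(self) -> str:
        return "".join(map(str, self.pattern))


@dataclass
class SpatialMap:
    """Pixel geometry of the rendering canvas: spot placements per sample."""

    width: int
    height: int
    spots: pd.DataFrame  # columns: sample_id, x, y

    def __post_init__(self) -> None:
        if len(self.spots):
            x, y = self.spots["x"].values, self.spots["y"].values
            if (x < 0).any() or (x >= self.width).any() or (y < 0).any() or (y >= self.height).any():
                raise ValidationError("spot coordinates outside image bounds")


def bin_distribution_patterns(
    table: FeatureTable, geo: GeoParams | None = None
) -> list[DistributionBin]:
    """Assign every feature to its presence bit-vector over ``site_list``.

    All 2^n patterns are enumerated in the output (empty bins have count 0);
    samples at sites outside the list are dropped with a warning.  A feature
    absent from every listed site lands in the all-zero pattern's key but is
    not stored there (that bin holds no features by definition), so bin
    counts over non-empty patterns sum to the number of features detected at
    one or more listed sites.
    """
    geo = geo or GeoParams()
    sites = list(geo.site_list)
    n = len(sites)
    sample_site = {sid: table.site_of(sid) for sid in table.sample_ids}
    unknown = sorted({s for s in sample_site.values() if s not in sites})
    if unknown:
        warnings.warn(f"samples at sites outside site_list dropped: {unknown}", stacklevel=2)
    presence = table.presence()
    bins = {tuple(p): DistributionBin(pattern=tuple(p)) for p in _all_patterns(n)}
    for fid in table.feature_ids:
        row = presence.loc[fid]
        pattern = tuple(
            int(any(row[sid] for sid in table.sample_ids if sample_site[sid] == site))
            for site in sites
        )
        if any(pattern):
            bins[pattern].feature_ids.append(fid)
    return [bins[tuple(p)] for p in _all_patterns(n)]


def _all_patterns(n: int) -> list[tuple[int, ...]]:
    return [tuple((i >> (n - 1 - b)) & 1 for b in range(n)) for i in range(2**n)]


def build_bin_network(bins: list[DistributionBin], geo: GeoParams | None = None) -> nx.Graph:
    """Hypercube graph over all 2^n patterns.

    Nodes carry the feature count and a normalized color position
    min(count / bin_color_max, 1) for the white-to-red scale; edges connect
    patterns at Hamming distance 1 (n * 2^(n-1) edges in total).
    """
    geo = geo or GeoParams()
    n = len(bins[0].pattern)
    if len(bins) != 2**n:
        raise ValidationError("bins must enumerate all 2^n patterns")
    g = nx.Graph()
    for b in bins:
        g.add_node(
            b.key,
            count=b.count,
            color_position=min(b.count / geo.bin_color_max, 1.0),
            n_sites=int(sum(b.pattern)),
        )
    for b in bins:
        value = int(b.key, 2)
        for bit in range(n):
            neighbor = value ^ (1 << bit)
            if neighbor > value:
                g.add_edge(b.key, format(neighbor, f"0{n}b"))
    return g


def assign_spot_coordinates(
    metadata: list[SampleMetadata],
    site_pixel_lookup: dict[str, tuple[float, float]],
    geo: GeoParams | None = None,
    width: int = 640,
    height: int = 360,
) -> SpatialMap:
    """Deterministic pixel placement of samples on the background map.

    The first sample at a site (in sample_id sort order) sits on the site's
    anchor pixel; subsequent samples are placed on a ring of radius
    2 * spot_radius around it, in angular order.  Coordinates are clamped to
    the image bounds.
    """
    geo = geo or GeoParams()
    missing = sorted({m.site_code for m in metadata} - set(site_pixel_lookup))
    if missing:
        raise ValidationError(f"sites missing from pixel lookup: {missing}")
    by_site: dict[str, list[SampleMetadata]] = {}
    for m in sorted(metadata, key=lambda m: m.sample_id):
        by_site.setdefault(m.site_code, []).append(m)
    rows = []
    for site in sorted(by_site):
        anchor_x, anchor_y = site_pixel_lookup[site]
        members = by_site[site]
        for rank, m in enumerate(members):
            if rank == 0:
                x, y = anchor_x, anchor_y
            else:
                n_ring = len(members) - 1
                angle = 2 * np.pi * (rank - 1) / n_ring
                r = 2 * geo.spot_radius
                x = anchor_x + r * np.cos(angle)
                y = anchor_y + r * np.sin(angle)
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "x": float(np.clip(x, 0, width - 1)),
                    "y": float(np.clip(y, 0, height - 1)),
                }
            )
    spots = pd.DataFrame(rows, columns=["sample_id", "x", "y"])
    return SpatialMap(width=width, height=height, spots=spots)


def _colormap(name: str):
    import matplotlib

    if name == "jet":
        return matplotlib.colormaps["jet"]
    return matplotlib.colormaps["gray"]


def render_spatial_map(
    feature_id: str,
    table: FeatureTable,
    spatial: SpatialMap,
    geo: GeoParams | None = None,
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Paint one feature's spot intensities onto the background.

    Per-spot intensity is the sample abundance aggregated per spot, scaled
    to [0, 100] across spots (after log10(1 + x) when the intensity scale is
    logarithmic).  Each spot's color is jet(scaled / 100); a pixel at
    distance d from the spot center blends background and spot color in
    log-space with weight w = exp(-d^2 / (2 sigma^2)) for d <= spot_radius
    and 0 beyond, i.e. rendered = bg^(1-w) * color^w per channel (the
    log-combination identity, so w = 1 reproduces the spot color exactly).
    Pixels no spot reaches keep the background exactly.

    Returns (H x W x 3 float image in [0, 1], per-spot intensity table).
    """
    geo = geo or GeoParams()
    if feature_id not in table.matrix.index:
        raise ValidationError(f"unknown feature {feature_id}")
    if background is None:
        background = np.full((spatial.height, spatial.width, 3), 0.82)
    img = np.array(background, dtype=float, copy=True)

    abundances = table.matrix.loc[feature_id]
    spot_int = np.array(
        [float(abundances.get(sid, 0.0)) for sid in spatial.spots["sample_id"]]
    )
    raw = spot_int.copy()
    if not (spot_int > 0).any():
        warnings.warn(f"feature {feature_id} has zero intensity everywhere; background returned", stacklevel=2)
        report = spatial.spots.assign(raw_intensity=raw, scaled_intensity=0.0)
        return img, report
    if geo.intensity_scale == "logarithmic":
        spot_int = np.log10(1.0 + spot_int)
    scaled = 100.0 * spot_int / spot_int.max()

    cmap = _colormap(geo.colormap)
    yy, xx = np.mgrid[0 : spatial.height, 0 : spatial.width]
    for (_, spot), s in zip(spatial.spots.iterrows(), scaled):
        if s <= 0:
            continue
        color = np.asarray(cmap(s / 100.0)[:3])
        d2 = (xx - spot["x"]) ** 2 + (yy - spot["y"]) ** 2
        w = np.exp(-d2 / (2.0 * geo.falloff_sigma**2))
        w[d2 > geo.spot_radius**2] = 0.0
        mask = w > 0
        if not mask.any():
            continue
        wm = w[mask][:, None]
        bg = np.clip(img[mask], 0.0, 1.0)
        col = np.clip(color[None, :], 0.0, 1.0)
        img[mask] = bg ** (1.0 - wm) * col**wm
    report = spatial.spots.assign(raw_intensity=raw, scaled_intensity=scaled)
    return img, report


def save_map_png(
    img: np.ndarray, path: str | Path, seed: int | None = None, params: object = None
) -> Path:
    """Write a rendered map as PNG with provenance in a tEXt chunk."""
    from PIL import Image
    from PIL.PngImagePlugin import PngInfo

    data = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    info = PngInfo()
    info.add_text("provenance", provenance_line(seed, params))
    Image.fromarray(data).save(path, pnginfo=info)
    return Path(path)
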