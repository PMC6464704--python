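"""Threshold-and-particle quantification of lipopigment and lysosome signals.

Mirrors a fixed-threshold "analyze particles" workflow: a grey-level cutoff
(held identical across every image of a comparison) produces a binary mask;
8-connected components are filtered by pixel count and circularity
(4π·area/perimeter²); read-outs are percent area occupied by autofluorescent
lipopigment (AL) in vivo (whole image or per cortical-layer ROI) and, per
cultured cell, the percent of cytosolic area (soma minus nucleus) occupied
by AL or lysosomes.  Filter presets follow the quantification rules used for
these signals: AL puncta must comprise more than eight adjacent pixels with
circularity > 0.4; lysosomes must have circularity > 0.5 (to avoid counting
clusters as one unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as _sk_label
from skimage.measure import perimeter_crofton as _sk_perimeter_crofton
from skimage.measure import regionprops as _sk_regionprops

from .calcium import LineROI, extract_kymograph
from .calibration import PX_SIZE_UM
from .exceptions import ConfigError, DegenerateInputError, ParameterError

__all__ = [
    "ChannelImage",
    "ThresholdSpec",
    "Particle",
    "SomaQuant",
    "ColumnQuant",
    "AL_PRESET",
    "LYSOSOME_PRESET",
    "particle_perimeter",
    "threshold_mask",
    "find_particles",
    "quantify_soma",
    "percent_area_column",
    "line_scan",
]

#: AL punctum filter: more than eight adjacent pixels (size >= 9) and circularity > 0.4.
AL_PRESET = {"min_pixels": 9, "circ_min": 0.4, "circ_max": 1.0}
#: Lysosome filter: circularity > 0.5, no size floor.
LYSOSOME_PRESET = {"min_pixels": 1, "circ_min": 0.5, "circ_max": 1.0}


@dataclass
class ChannelImage:
    """One fluorescence channel as a 2-D array of arbitrary units."""

    pixels: np.ndarray
    channel: str = "generic"
    px_size: float = PX_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels: expected a 2-D image")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ParameterError("pixels: values must be finite and non-negative")


@dataclass
class ThresholdSpec:
    """Per-channel grey-level cutoffs, applied identically across a comparison set."""

    cutoffs: dict
    note: str = ""

    def cutoff(self, channel: str) -> float:
        try:
            return float(self.cutoffs[channel])
        except KeyError as exc:
            raise ConfigError(f"no threshold configured for channel '{channel}'") from exc


@dataclass
class Particle:
    """An 8-connected component that passed the filters."""

    label: int
    area: int  # px^2
    perimeter: float  # px
    circularity: float
    centroid: tuple[float, float]  # (row, col)
    coords: np.ndarray  # (n, 2) pixel coordinates

    def area_um2(self, px_size: float) -> float:
        return self.area * px_size**2


@dataclass
class SomaQuant:
    """Per-cell cytosolic quantification."""

    cytosol_area: int
    pct_al_area: float
    pct_lysosome_area: float
    n_al: int
    mean_lysosome_area: float
    al_positive: bool
    al_particles: list = field(default_factory=list)
    lysosome_particles: list = field(default_factory=list)


@dataclass
class ColumnQuant:
    """Percent AL area across a set of cortical-column images."""

    per_image_pct: list
    mean_pct: float
    per_layer_pct: dict = field(default_factory=dict)


def _as_pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ChannelImage) else np.asarray(img, dtype=float)


def threshold_mask(img, spec: ThresholdSpec, channel: str | None = None) -> np.ndarray:
    """Binary mask of pixels at or above the channel's configured cutoff."""
    if channel is None:
        channel = img.channel if isinstance(img, ChannelImage) else "generic"
    return _as_pixels(img) >= spec.cutoff(channel)


def particle_perimeter(mask: np.ndarray) -> float:
    """Boundary length of a component via the Crofton formula (4 directions).

    This estimator converges to the true boundary length as shapes are
    rasterized more finely, and it stays honest for 1-px-wide structures
    (whose boundary runs up one side and back down the other), which keeps
    the circularity filter able to reject thin-line artifacts.
    """
    return float(_sk_perimeter_crofton(np.asarray(mask, dtype=bool), directions=4))


def _circularity(area: float, perim: float) -> float:
    # Rasterization can overshoot 4πA/P² slightly above 1 for near-circular
    # shapes; clamp.  A component whose perimeter estimate is 0 is treated as
    # perfectly circular.
    if perim <= 0:
        return 1.0
    return float(min(4.0 * np.pi * area / perim**2, 1.0))


def find_particles(
    mask: np.ndarray,
    min_pixels: int = 1,
    circ_min: float = 0.0,
    circ_max: float = 1.0,
) -> list[Particle]:
    """8-connected components of a binary mask, filtered by size and circularity.

    ``min_pixels`` is inclusive (the AL preset's "more than eight adjacent
    pixels" maps to ``min_pixels=9``); circularity bounds are exclusive at
    the lower end, inclusive at the upper.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _sk_label(mask, connectivity=2)
    out: list[Particle] = []
    for rp in _sk_regionprops(labels):
        area = int(rp.area)
        perim = particle_perimeter(rp.image)
        circ = _circularity(area, perim)
        if area >= min_pixels and circ_min < circ <= circ_max:
            out.append(
                Particle(
                    label=int(rp.label),
                    area=area,
                    perimeter=perim,
                    circularity=circ,
                    centroid=tuple(map(float, rp.centroid)),
                    coords=rp.coords.copy(),
                )
            )
    return out


def quantify_soma(
    channels: dict,
    spec: ThresholdSpec,
    soma_roi: np.ndarray | None = None,
) -> SomaQuant:
    """Quantify AL and lysosome load within one cell's cytosol.

    Cytosolic area = soma-channel mask area minus nucleus-channel mask area,
    restricted to the soma ROI (the soma threshold mask itself when no
    explicit ROI polygon mask is given).  Percentages are particle areas
    (AL preset for AL, lysosome preset for lysosomes) over cytosolic area.
    """
    if "soma" not in channels or "nucleus" not in channels:
        raise ParameterError("channels: 'soma' and 'nucleus' channels are required")
    soma_mask = threshold_mask(channels["soma"], spec, "soma")
    if soma_roi is not None:
        soma_mask = soma_mask & np.asarray(soma_roi, dtype=bool)
    nucleus_mask = threshold_mask(channels["nucleus"], spec, "nucleus") & soma_mask
    cytosol = soma_mask & ~nucleus_mask
    cytosol_area = int(cytosol.sum())
    if cytosol_area <= 0:
        raise DegenerateInputError("cytosolic area <= 0 (nucleus covers the soma)")

    def channel_particles(name: str, preset: dict) -> list[Particle]:
        if name not in channels:
            return []
        m = threshold_mask(channels[name], spec, name) & soma_mask
        return find_particles(m, **preset)

    al = channel_particles("al", AL_PRESET)
    lys = channel_particles("lysosome", LYSOSOME_PRESET)
    al_area = sum(p.area for p in al)
    lys_area = sum(p.area for p in lys)
    return SomaQuant(
        cytosol_area=cytosol_area,
        pct_al_area=100.0 * al_area / cytosol_area,
        pct_lysosome_area=100.0 * lys_area / cytosol_area,
        n_al=len(al),
        mean_lysosome_area=float(np.mean([p.area for p in lys])) if lys else 0.0,
        al_positive=len(al) >= 1,
        al_particles=al,
        lysosome_particles=lys,
    )


def percent_area_column(
    images: list,
    spec: ThresholdSpec,
    layer_rois: dict | None = None,
    channel: str = "al",
) -> ColumnQuant:
    """Percent area occupied by thresholded AL signal across an image set.

    Per image: 100 x (mask pixels)/(image pixels); the set mean is the
    per-column value.  When rectangular layer ROIs ``{name: (r0, c0, r1, c1)}``
    are given, a per-layer percentage (pooled over images) is also computed.
    Overlapping layer ROIs trigger a geometry warning.
    """
    if not images:
        raise ParameterError("images: empty image set")
    per_image = []
    masks = []
    for img in images:
        m = threshold_mask(img, spec, channel)
        masks.append(m)
        per_image.append(100.0 * m.sum() / m.size)

    per_layer: dict = {}
    if layer_rois:
        shape = masks[0].shape
        cover = np.zeros(shape, dtype=int)
        for name, (r0, c0, r1, c1) in layer_rois.items():
            cover[r0:r1, c0:c1] += 1
            hits = sum(int(m[r0:r1, c0:c1].sum()) for m in masks)
            total = (r1 - r0) * (c1 - c0) * len(masks)
            per_layer[name] = 100.0 * hits / total if total else 0.0
        if np.any(cover > 1):
            warnings.warn("layer ROIs overlap", stacklevel=2)

    return ColumnQuant(
        per_image_pct=per_image,
        mean_pct=float(np.mean(per_image)),
        per_layer_pct=per_layer,
    )


def line_scan(channels: dict, roi: LineROI) -> pd.DataFrame:
    """Per-channel intensity profiles along one width-1 line ROI.

    All channels are sampled along the identical arc-length positions, so the
    returned table has one aligned row per position with a column per channel.
    """
    roi1 = LineROI(points=roi.points, width_px=1)
    out = {}
    for name, img in channels.items():
        px = _as_pixels(img)
        kymo = extract_kymograph(px[None, :, :], roi1)
        out[name] = kymo.values[0]
    df = pd.DataFrame(out)
    df.insert(0, "position_px", np.arange(len(df)))
    return df
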