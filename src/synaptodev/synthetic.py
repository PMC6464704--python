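"""Seeded synthetic-data generators with ground truth.

Every input the analysis stages consume can be generated here with a known
latent state: biexponentially decaying evoked currents, 2-D dendrite movies
with point-source or spatially diffusing calcium transients, multi-channel
soma images with lipopigment/lysosome puncta of known geometry, and
plate-reader viability tables.  Each generator takes one seed, draws all
randomness from a single ``numpy.random.default_rng`` instance (no global
state), and returns a :class:`GroundTruth` record of every latent quantity,
so regeneration with the same seed is bit-exact.

Truth quantities are computed by construction (pixel counts, event lists)
or with third-party primitives, never by calling the analysis modules they
are meant to validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.measure import perimeter_crofton as _sk_perimeter_crofton

from .calcium import LineROI
from .epsc import EPSCTrace
from .exceptions import ParameterError, PlacementError

__all__ = [
    "EPSCSimParams",
    "CalciumSimParams",
    "SomaSimParams",
    "PlateSimParams",
    "GroundTruth",
    "gen_epsc",
    "gen_calcium_movie",
    "gen_soma_image",
    "gen_plate",
]


@dataclass
class GroundTruth:
    """Latent state of one generated dataset (serializable alongside it)."""

    generator: str
    params: dict
    latent: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return {"generator": self.generator, "params": _clean(self.params), "latent": _clean(self.latent)}


# ---------------------------------------------------------------------------
# evoked EPSC traces


@dataclass
class EPSCSimParams:
    """Generative parameters for an evoked NMDAR-EPSC.

    The decay is the biexponential A_f e^(-t/tau_fast) + A_s e^(-t/tau_slow);
    onset is shaped by a multiplicative (1 - e^(-t/rise_tau)) rise filter
    (``rise_tau = 0`` gives an instantaneous step onset).  Units: amplitudes
    pA, time constants ms, sample_rate kHz, noise SD pA.
    """

    amp_fast: float = 50.0
    amp_slow: float = 50.0
    tau_fast: float = 50.0
    tau_slow: float = 300.0
    rise_tau: float = 2.0
    sample_rate: float = 10.0
    duration: float = 1500.0
    stim_onset: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ParameterError("tau_fast/tau_slow: time constants must be > 0")
        if self.tau_fast >= self.tau_slow:
            raise ParameterError("tau_fast: must be < tau_slow")
        if self.amp_fast < 0 or self.amp_slow < 0:
            raise ParameterError("amp_fast/amp_slow: amplitudes must be >= 0")
        if self.amp_fast == 0 and self.amp_slow == 0:
            raise ParameterError("amp_fast/amp_slow: at least one amplitude must be > 0")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate: must be > 0")
        if self.rise_tau < 0:
            raise ParameterError("rise_tau: must be >= 0")
        if not (0 <= self.stim_onset < self.duration):
            raise ParameterError("stim_onset: must lie within the sweep duration")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd: must be >= 0")


def gen_epsc(params: EPSCSimParams) -> tuple[EPSCTrace, GroundTruth]:
    """Simulate one evoked NMDAR-EPSC sweep.

    Current is zero (plus noise) before ``stim_onset``; afterwards it follows
    rise(t') x [A_f e^(-t'/tau_fast) + A_s e^(-t'/tau_slow)] with
    t' = t - stim_onset, plus white Gaussian noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate  # ms
    tp = t - params.stim_onset
    post = tp >= 0
    decay = params.amp_fast * np.exp(-np.maximum(tp, 0) / params.tau_fast) + (
        params.amp_slow * np.exp(-np.maximum(tp, 0) / params.tau_slow)
    )
    if params.rise_tau > 0:
        rise = 1.0 - np.exp(-np.maximum(tp, 0) / params.rise_tau)
    else:
        rise = np.ones_like(t)
    current = np.where(post, rise * decay, 0.0)
    if params.noise_sd > 0:
        current = current + rng.normal(0.0, params.noise_sd, size=n)

    noiseless = np.where(post, rise * decay, 0.0)
    ipk = int(np.argmax(noiseless))
    truth = GroundTruth(
        generator="gen_epsc",
        params=asdict(params),
        latent={
            "true_tau_w": (
                params.tau_fast * params.amp_fast + params.tau_slow * params.amp_slow
            )
            / (params.amp_fast + params.amp_slow),
            "true_frac_fast": params.amp_fast / (params.amp_fast + params.amp_slow),
            "noiseless_peak_time_ms": float(t[ipk]),
            "noiseless_peak_pa": float(noiseless[ipk]),
        },
    )
    return EPSCTrace(t, current, params.stim_onset), truth


# ---------------------------------------------------------------------------
# calcium movies


@dataclass
class CalciumSimParams:
    """Generative parameters for a dendrite calcium movie.

    A horizontal dendrite band of constant baseline fluorescence runs along
    the frame; each transient multiplies the band by (1 + a·g(x)·h(t)) with a
    spatial Gaussian g of SD ``spatial_sigma`` px at the site and an
    exponential temporal kernel h of decay ``decay_tau`` frames.  Small
    ``spatial_sigma`` emulates compartmentalized (spine-restricted) signals,
    large values the diffuse influxes that spread through the shaft.  Event
    streams are Bernoulli per frame at ``transient_rate``/500; a shared
    stream is mixed in with weight ``common_drive`` to create synchrony.
    """

    n_frames: int = 600
    fps: float = 7.0
    px_size: float = 10.0 / 65.0
    roi_length: int = 300
    n_sites: int = 3
    site_positions: list[int] | None = None
    transient_rate: float = 5.0  # events per 500 frames per site
    amplitude: float = 1.0  # peak ΔF/F0 of one event
    spatial_sigma: float = 3.0  # px
    decay_tau: float = 4.0  # frames
    common_drive: float = 0.0
    baseline_f0: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0
    band_halfwidth: int = 4  # dendrite half-thickness, px
    frame_height: int = 24
    background: float = 10.0

    def validate(self) -> None:
        if self.n_frames <= 0:
            raise ParameterError("n_frames: must be > 0")
        if self.fps <= 0 or self.px_size <= 0:
            raise ParameterError("fps/px_size: must be > 0")
        if self.n_sites == 0 and self.transient_rate > 0:
            raise ParameterError("n_sites: zero sites with transient_rate > 0")
        if not (0.0 <= self.common_drive <= 1.0):
            raise ParameterError("common_drive: must be in [0, 1]")
        if self.site_positions is not None:
            if len(self.site_positions) != self.n_sites:
                raise ParameterError("site_positions: length must equal n_sites")
            for p in self.site_positions:
                if not (0 <= p < self.roi_length):
                    raise ParameterError("site_positions: must lie in [0, roi_length)")
        if self.baseline_f0 <= 0:
            raise ParameterError("baseline_f0: must be > 0")
        if self.transient_rate < 0 or self.noise_sd < 0 or self.amplitude < 0:
            raise ParameterError("transient_rate/noise_sd/amplitude: must be >= 0")
        if self.spatial_sigma <= 0 or self.decay_tau <= 0:
            raise ParameterError("spatial_sigma/decay_tau: must be > 0")


def _default_sites(params: CalciumSimParams) -> np.ndarray:
    margin = max(10, int(3 * params.spatial_sigma))
    usable = params.roi_length - 2 * margin
    if params.n_sites == 1:
        return np.array([params.roi_length // 2])
    return np.round(margin + np.arange(params.n_sites) * usable / (params.n_sites - 1)).astype(int)


def gen_calcium_movie(
    params: CalciumSimParams,
) -> tuple[np.ndarray, LineROI, GroundTruth]:
    """Simulate a dendrite movie with known transients.

    Returns the movie as a float (frames, H, W) stack, a :class:`LineROI`
    traced along the dendrite midline wide enough to cover the band, and the
    truth record listing every event (site index, onset frame, amplitude)
    plus the site positions.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sites = (
        np.asarray(params.site_positions, dtype=int)
        if params.site_positions is not None
        else _default_sites(params)
    )

    p_event = params.transient_rate / 500.0
    n_f, n_s = params.n_frames, params.n_sites
    # Draw all three streams unconditionally so runs with different
    # common_drive but the same seed share one underlying event universe
    # (a monotone coupling in common_drive).
    shared = rng.random(n_f) < p_event
    indep = rng.random((n_s, n_f)) < p_event
    coins = rng.random((n_s, n_f)) < params.common_drive
    event_streams = np.where(coins, shared[None, :], indep) if n_s else indep

    # Per-site multiplicative signal s_i(t), then spatial spread along x.
    kernel_len = int(np.ceil(6 * params.decay_tau)) + 1
    kernel = np.exp(-np.arange(kernel_len) / params.decay_tau)
    x = np.arange(params.roi_length)
    signal = np.zeros((n_f, params.roi_length))
    events = []
    for i in range(n_s):
        onsets = np.nonzero(event_streams[i])[0]
        if len(onsets) == 0:
            continue
        impulse = np.zeros(n_f)
        impulse[onsets] = params.amplitude
        tcourse = np.convolve(impulse, kernel)[:n_f]
        g = np.exp(-((x - sites[i]) ** 2) / (2 * params.spatial_sigma**2))
        signal += np.outer(tcourse, g)
        events.extend(
            {"site": int(i), "onset": int(o), "amplitude": float(params.amplitude)}
            for o in onsets
        )

    h = params.frame_height
    y0 = h // 2
    band = slice(y0 - params.band_halfwidth, y0 + params.band_halfwidth + 1)
    base = np.full((h, params.roi_length), params.background)
    base[band] = params.baseline_f0
    movie = np.broadcast_to(base, (n_f, h, params.roi_length)).copy()
    movie[:, band, :] = params.baseline_f0 * (1.0 + signal[:, None, :])
    if params.noise_sd > 0:
        movie = movie + rng.normal(0.0, params.noise_sd, size=movie.shape)

    roi = LineROI(
        points=[(0.0, float(y0)), (float(params.roi_length - 1), float(y0))],
        width_px=2 * params.band_halfwidth + 1,
    )
    truth = GroundTruth(
        generator="gen_calcium_movie",
        params=asdict(params),
        latent={
            "site_positions": sites,
            "events": sorted(events, key=lambda e: (e["site"], e["onset"])),
            "dendrite_row": y0,
            "band_halfwidth": params.band_halfwidth,
        },
    )
    return movie, roi, truth


# ---------------------------------------------------------------------------
# soma images


@dataclass
class SomaSimParams:
    """Generative parameters for a four-channel soma image.

    Channels emulate lysosome (LAMP-2), soma (MAP2), nucleus (DAPI) and
    autofluorescent-lipopigment (AL) signals.  AL puncta are rasterized discs
    with an optional sinusoidal boundary perturbation (``al_irregularity``)
    that lowers circularity; lysosomes are plain discs.
    """

    image_size: int = 256
    n_al: int = 5
    al_radius_range: tuple[float, float] = (3.0, 6.0)
    al_irregularity: float = 0.0
    n_lysosomes: int = 8
    lys_radius_range: tuple[float, float] = (2.0, 4.0)
    soma_mask_radius: int = 100
    nucleus_radius: int = 35
    channel_intensities: dict | None = None
    background: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_al < 0 or self.n_lysosomes < 0:
            raise ParameterError("n_al/n_lysosomes: counts must be >= 0")
        if self.nucleus_radius >= self.soma_mask_radius:
            raise ParameterError("nucleus_radius: nucleus must fit inside the soma")
        for name, rng_ in (("al_radius_range", self.al_radius_range), ("lys_radius_range", self.lys_radius_range)):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ParameterError(f"{name}: radii must be positive and ordered")
        if self.soma_mask_radius <= 0 or self.image_size <= 2 * self.soma_mask_radius:
            raise ParameterError("soma_mask_radius: soma must fit inside the image")


_DEFAULT_INTENSITIES = {"lysosome": 200.0, "soma": 100.0, "nucleus": 150.0, "al": 180.0}


def _disc_mask(size: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _blob_mask(
    size: int, cx: float, cy: float, radius: float, irregularity: float, rng: np.random.Generator
) -> np.ndarray:
    """Disc with radius modulated by a random sinusoid around the boundary."""
    if irregularity <= 0:
        return _disc_mask(size, cx, cy, radius)
    k = int(rng.integers(3, 7))
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    theta = np.arctan2(dy, dx)
    r_theta = radius * (1.0 + irregularity * np.sin(k * theta + phase))
    return dx**2 + dy**2 <= r_theta**2


def gen_soma_image(params: SomaSimParams) -> tuple[dict, GroundTruth]:
    """Simulate a single-cell, four-channel image with known puncta.

    Returns ``channels`` as a dict of 2-D float arrays keyed
    ``{"lysosome", "soma", "nucleus", "al"}`` and a truth record with each
    particle's pixel count, circularity (4π·area/perimeter², computed on the
    particle's own rasterized mask) and centroid, plus the true percent of
    cytosolic area covered by AL.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    intens = dict(_DEFAULT_INTENSITIES)
    if params.channel_intensities:
        intens.update(params.channel_intensities)
    c = size / 2.0

    soma_mask = _disc_mask(size, c, c, params.soma_mask_radius)
    nucleus_mask = _disc_mask(size, c, c, params.nucleus_radius)
    cytosol_mask = soma_mask & ~nucleus_mask

    def place_puncta(n: int, radius_range, irregularity: float, occupied: list) -> list[dict]:
        placed = []
        for _ in range(n):
            for _attempt in range(500):
                r = rng.uniform(*radius_range)
                rho = rng.uniform(params.nucleus_radius + r + 2, params.soma_mask_radius - r - 2)
                ang = rng.uniform(0, 2 * np.pi)
                cx, cy = c + rho * np.cos(ang), c + rho * np.sin(ang)
                max_r = r * (1.0 + irregularity)
                if all(
                    np.hypot(cx - q["cx"], cy - q["cy"]) > max_r + q["max_r"] + 3 for q in occupied
                ):
                    mask = _blob_mask(size, cx, cy, r, irregularity, rng)
                    if not mask.any():
                        continue
                    placed.append({"cx": cx, "cy": cy, "r": r, "max_r": max_r, "mask": mask})
                    occupied.append(placed[-1])
                    break
            else:
                raise PlacementError("could not place punctum inside soma after 500 retries")
        return placed

    occupied: list = []
    al_puncta = place_puncta(params.n_al, params.al_radius_range, params.al_irregularity, occupied)
    lys_puncta = place_puncta(params.n_lysosomes, params.lys_radius_range, 0.0, occupied)

    def render(puncta: list[dict], level: float) -> np.ndarray:
        img = np.full((size, size), params.background)
        for p in puncta:
            img[p["mask"]] = level
        return img

    channels = {
        "soma": np.where(soma_mask, intens["soma"], params.background),
        "nucleus": np.where(nucleus_mask, intens["nucleus"], params.background),
        "al": render(al_puncta, intens["al"]),
        "lysosome": render(lys_puncta, intens["lysosome"]),
    }

    def particle_truth(p: dict) -> dict:
        # Crofton-formula boundary length, computed directly on the particle's
        # own rasterized mask (not through the analysis module) so truth stays
        # an independent oracle while sharing the 4πA/P² definition.
        area = int(p["mask"].sum())
        perim = float(_sk_perimeter_crofton(p["mask"], directions=4))
        circ = min(4 * np.pi * area / perim**2, 1.0) if perim > 0 else 1.0
        ys, xs = np.nonzero(p["mask"])
        return {
            "area_px": area,
            "circularity": circ,
            "centroid": (float(ys.mean()), float(xs.mean())),
            "radius": p["r"],
        }

    al_area_in_cytosol = int(sum((p["mask"] & cytosol_mask).sum() for p in al_puncta))
    truth = GroundTruth(
        generator="gen_soma_image",
        params={**asdict(params), "channel_intensities": intens},
        latent={
            "al_particles": [particle_truth(p) for p in al_puncta],
            "lysosome_particles": [particle_truth(p) for p in lys_puncta],
            "cytosol_area_px": int(cytosol_mask.sum()),
            "soma_area_px": int(soma_mask.sum()),
            "nucleus_area_px": int(nucleus_mask.sum()),
            "true_pct_al_area": 100.0 * al_area_in_cytosol / cytosol_mask.sum(),
        },
    )
    return channels, truth


# ---------------------------------------------------------------------------
# plate-reader tables


@dataclass
class PlateSimParams:
    """Generative parameters for a viability plate-reader table."""

    conditions: tuple[str, ...] = ("vehicle", "NMDA_10uM", "NMDA_100uM", "NMDA_300uM")
    true_viability: dict | None = None
    vehicle_mean: float = 1000.0
    cv: float = 0.05
    n_wells: int = 4
    vehicle_label: str = "vehicle"
    seed: int = 0

    def validate(self) -> None:
        if self.vehicle_label not in self.conditions:
            raise ParameterError("conditions: vehicle condition must be present")
        if self.cv < 0:
            raise ParameterError("cv: must be >= 0")
        if self.n_wells < 1:
            raise ParameterError("n_wells: must be >= 1")
        viab = self.viability_map()
        for cond, v in viab.items():
            if v < 0:
                raise ParameterError(f"true_viability[{cond}]: must be >= 0")

    def viability_map(self) -> dict:
        if self.true_viability is not None:
            viab = dict(self.true_viability)
        else:
            viab = {"vehicle": 1.0, "NMDA_10uM": 0.93, "NMDA_100uM": 0.65, "NMDA_300uM": 0.40}
        for cond in self.conditions:
            viab.setdefault(cond, 1.0)
        viab.setdefault(self.vehicle_label, 1.0)
        return viab


def gen_plate(params: PlateSimParams):
    """Simulate a per-well fluorescence table.

    Each well reads ``vehicle_mean x true_viability x (1 + eps)`` with
    ``eps ~ Normal(0, cv)``, seeded.  Returns a pandas DataFrame with columns
    ``well, condition, fluorescence`` and the truth record.
    """
    import pandas as pd

    params.validate()
    rng = np.random.default_rng(params.seed)
    viab = params.viability_map()
    rows = []
    for cond in params.conditions:
        for w in range(params.n_wells):
            noise = rng.normal(0.0, params.cv) if params.cv > 0 else 0.0
            rows.append(
                {
                    "well": f"{cond}_{w}",
                    "condition": cond,
                    "fluorescence": params.vehicle_mean * viab[cond] * (1.0 + noise),
                }
            )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        generator="gen_plate",
        params=asdict(params),
        latent={"true_viability": viab, "vehicle_label": params.vehicle_label},
    )
    return table, truth
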