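"""Spatial and temporal calibration constants for the imaging pipeline.

The live-imaging rig records dendritic GCaMP3 movies at ~7 frames/s with a
pixel scale in which a 65-pixel span corresponds to 10 μm.  Both constants are
used as defaults throughout the calcium pipeline and can be overridden per
dataset.
"""

#: Default pixel size, μm per pixel (65 px ≡ 10 μm).
PX_SIZE_UM: float = 10.0 / 65.0

#: Default acquisition rate, frames per second.
FPS: float = 7.0

#: Default frequency-normalization window, frames.
FREQ_WINDOW_FRAMES: int = 500


def px_to_um(pixels: float, px_size: float = PX_SIZE_UM) -> float:
    """Convert a pixel span to micrometres."""
    return float(pixels) * px_size


def frames_to_seconds(frames: float, fps: float = FPS) -> float:
    """Convert a frame count to seconds at the acquisition rate."""
    return float(frames) / fps
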