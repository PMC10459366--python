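"""Motion-informed enhancement of time-lapse frames.

A moving insect is often nearly invisible in a single still image of
dense vegetation, but it is the only thing that changes between three
consecutive time-lapse frames.  The enhancement embeds that temporal
signal into an ordinary RGB image so downstream detectors need no
architectural changes:

* each frame is converted to grayscale (BT.601 luma) and blurred with a
  small Gaussian kernel, giving B_{k-1}, B_k, B_{k+1};
* the three-frame motion likelihood is the per-pixel sum of absolute
  neighbour differences, L3 = |B_k - B_{k-1}| + |B_{k+1} - B_k|;
* the enhanced image M keeps the green channel (vegetation) untouched,
  stores L3 in the red channel, and folds the original red into the
  blue channel:  Mr = L3 (clamped to 255), Mg = Ig, Mb = (Ir + Ib) / 2.

A static scene therefore renders with a black red channel, while a
moving insect lights up red at its current position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from scipy import ndimage

from .sequence_io import Frame, TimeLapseSequence, _round_half_up

#: BT.601 luma weights for R, G, B
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def default_sigma(kernel_size: int) -> float:
    """Kernel-size-derived Gaussian sigma: 0.3*((k-1)/2 - 1) + 0.8.

    Gives 1.1 for the default 5x5 kernel.
    """
    return 0.3 * ((kernel_size - 1) / 2 - 1) + 0.8


@dataclass
class EnhanceParams:
    """Parameters of the enhancement stage.

    kernel_size : odd Gaussian kernel side in pixels (default 5).
    sigma : Gaussian sigma; defaults to the kernel-size-derived value.
    endpoint_policy : "skip" drops the first/last frame of a run (no
        temporal neighbour on one side); "pad" duplicates the terminal
        frame so the missing-side difference is zero.
    """

    kernel_size: int = 5
    sigma: float | None = None
    endpoint_policy: str = "skip"

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and >= 1, got {self.kernel_size}")
        if self.sigma is None:
            self.sigma = default_sigma(self.kernel_size)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.endpoint_policy not in ("skip", "pad"):
            raise ValueError(f"unknown endpoint_policy {self.endpoint_policy!r}")


@dataclass
class BlurredGray:
    """Grayscale + Gaussian-blurred frame, kept in floating point."""

    values: np.ndarray
    timestamp: datetime
    frame_id: str


@dataclass
class MotionLikelihood:
    """Per-pixel three-frame motion likelihood (non-negative reals)."""

    values: np.ndarray
    timestamp: datetime
    frame_id: str


@dataclass
class EnhancedFrame:
    """Motion-enhanced RGB image for the centre frame of a triple."""

    image: np.ndarray
    timestamp: datetime
    frame_id: str
    source_ids: tuple[str, str, str] = ("", "", "")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    @property
    def motion_channel(self) -> np.ndarray:
        return self.image[:, :, 0]


def _gaussian_kernel1d(kernel_size: int, sigma: float) -> np.ndarray:
    radius = (kernel_size - 1) // 2
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def luma(image: np.ndarray) -> np.ndarray:
    """BT.601 grayscale of an RGB image, in floating point."""
    img = np.asarray(image, dtype=float)
    return (LUMA_WEIGHTS[0] * img[:, :, 0]
            + LUMA_WEIGHTS[1] * img[:, :, 1]
            + LUMA_WEIGHTS[2] * img[:, :, 2])


def to_gray_blur(frame: Frame, kernel_size: int = 5, sigma: float | None = None) -> BlurredGray:
    """Grayscale (BT.601) then blur with a truncated Gaussian kernel.

    The blur is a separable 2-D convolution with reflective border
    handling; no intermediate rounding is applied.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if sigma is None:
        sigma = default_sigma(kernel_size)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    gray = luma(frame.image)
    if kernel_size > 1:
        k = _gaussian_kernel1d(kernel_size, sigma)
        gray = ndimage.correlate1d(gray, k, axis=0, mode="reflect")
        gray = ndimage.correlate1d(gray, k, axis=1, mode="reflect")
    return BlurredGray(values=gray, timestamp=frame.timestamp, frame_id=frame.frame_id)


def motion_likelihood(b_prev: BlurredGray, b_k: BlurredGray, b_next: BlurredGray) -> MotionLikelihood:
    """Three-frame motion likelihood |B_k - B_{k-1}| + |B_{k+1} - B_k|."""
    if b_prev.values.shape != b_k.values.shape or b_k.values.shape != b_next.values.shape:
        raise ValueError("blurred frames have mismatched shapes")
    if not (b_prev.timestamp < b_k.timestamp < b_next.timestamp):
        # padded triples duplicate the terminal frame; allow equal stamps there
        if not (b_prev.timestamp <= b_k.timestamp <= b_next.timestamp):
            raise ValueError("timestamps must be non-decreasing across the triple")
    values = np.abs(b_k.values - b_prev.values) + np.abs(b_next.values - b_k.values)
    return MotionLikelihood(values=values, timestamp=b_k.timestamp, frame_id=b_k.frame_id)


def enhance(i_prev: Frame, i_k: Frame, i_next: Frame,
            params: EnhanceParams | None = None) -> EnhancedFrame:
    """Build the motion-enhanced image for the centre frame of a triple.

    Channel mapping: Mr = clamp(round(L3), 0, 255); Mg = Ig bitwise;
    Mb = round((Ir + Ib)/2).  All arithmetic is floating point with a
    single round-half-away-from-zero at the 8-bit export.
    """
    params = params or EnhanceParams()
    if i_prev.shape != i_k.shape or i_k.shape != i_next.shape:
        raise ValueError("frames have mismatched shapes")
    blurred = [to_gray_blur(f, params.kernel_size, params.sigma)
               for f in (i_prev, i_k, i_next)]
    l3 = motion_likelihood(*blurred).values
    mr = np.clip(_round_half_up(l3), 0, 255).astype(np.uint8)
    mg = i_k.image[:, :, 1]
    mb = np.clip(
        _round_half_up(0.5 * i_k.image[:, :, 2].astype(float)
                       + 0.5 * i_k.image[:, :, 0].astype(float)),
        0, 255,
    ).astype(np.uint8)
    return EnhancedFrame(
        image=np.stack([mr, mg, mb], axis=2),
        timestamp=i_k.timestamp,
        frame_id=i_k.frame_id,
        source_ids=(i_prev.frame_id, i_k.frame_id, i_next.frame_id),
    )


def grayscale_reference(i_k: Frame) -> EnhancedFrame:
    """Motion-free control: the red channel holds the frame's own luma.

    Used as the ablation counterpart of :func:`enhance` — identical
    green/blue mapping but no temporal information — so the value of
    the motion channel can be measured in isolation.
    """
    mr = np.clip(_round_half_up(luma(i_k.image)), 0, 255).astype(np.uint8)
    mg = i_k.image[:, :, 1]
    mb = np.clip(
        _round_half_up(0.5 * i_k.image[:, :, 2].astype(float)
                       + 0.5 * i_k.image[:, :, 0].astype(float)),
        0, 255,
    ).astype(np.uint8)
    return EnhancedFrame(
        image=np.stack([mr, mg, mb], axis=2),
        timestamp=i_k.timestamp,
        frame_id=i_k.frame_id,
        source_ids=(i_k.frame_id, i_k.frame_id, i_k.frame_id),
    )


def enhance_sequence(run: TimeLapseSequence,
                     params: EnhanceParams | None = None) -> list[EnhancedFrame]:
    """Enhance every frame of one consecutive run.

    Interior frame k is enhanced from the triple (k-1, k, k+1).  The
    endpoint policy decides what happens at the run boundaries: "skip"
    yields n-2 outputs (none for a run shorter than 3), "pad" yields n
    outputs by duplicating the terminal frames.
    """
    params = params or EnhanceParams()
    if len(run) == 0:
        raise ValueError("cannot enhance an empty run")
    frames = run.frames
    out: list[EnhancedFrame] = []
    if params.endpoint_policy == "pad":
        padded = [frames[0]] + frames + [frames[-1]]
    else:
        padded = frames
    for k in range(1, len(padded) - 1):
        out.append(enhance(padded[k - 1], padded[k], padded[k + 1], params))
    return out


def grayscale_reference_sequence(run: TimeLapseSequence,
                                 params: EnhanceParams | None = None) -> list[EnhancedFrame]:
    """Ablation control aligned with :func:`enhance_sequence` frame ids."""
    params = params or EnhanceParams()
    if len(run) == 0:
        raise ValueError("cannot process an empty run")
    frames = run.frames if params.endpoint_policy == "pad" else run.frames[1:-1]
    return [grayscale_reference(f) for f in frames]
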