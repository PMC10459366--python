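"""Detection stage: motion-blob baseline and external-detector adapter.

The package deliberately keeps the detector pluggable.  Production use
feeds the enhanced frames to a trained CNN detector and reads its
output back through :func:`run_external_detections`; for end-to-end
testing without any learned model, :func:`detect_motion_blobs` provides
a classical baseline that thresholds the motion channel of an enhanced
frame and reports connected components as detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from skimage import measure, morphology

from .enhancement import EnhancedFrame
from .sequence_io import BoundingBox, Detection, read_detections_csv

logger = logging.getLogger(__name__)


@dataclass
class BaselineParams:
    """Motion-blob baseline parameters.

    threshold : motion-channel intensity above which a pixel counts as
        moving, in (0, 255].
    min_area / max_area : connected-component area band, in pixels.
    open_radius : disk radius of a denoising morphological opening
        (0 disables it).
    merge_gap : components closer than this many pixels are merged into
        one detection (0 disables merging).
    """

    threshold: float = 130.0
    min_area: int = 4
    max_area: int = 5000
    open_radius: int = 0
    merge_gap: int = 0

    def __post_init__(self):
        if not (0 < self.threshold <= 255):
            raise ValueError("threshold must lie in (0, 255]")
        if self.min_area < 1 or self.min_area > self.max_area:
            raise ValueError("need 1 <= min_area <= max_area")
        if self.open_radius < 0 or self.merge_gap < 0:
            raise ValueError("open_radius and merge_gap must be >= 0")


def detect_motion_blobs(frame: EnhancedFrame,
                        params: BaselineParams | None = None) -> list[Detection]:
    """Detect bright blobs in the motion (red) channel of an enhanced frame.

    Pipeline: binarise Mr at ``threshold``; optional morphological
    opening; 8-connected component labelling (optionally on a dilated
    mask so nearby fragments merge); components with area within
    [min_area, max_area] become detections.  Confidence is the mean
    motion intensity inside the component normalised by 255, and output
    order is deterministic (ymin, then xmin).
    """
    params = params or BaselineParams()
    mr = frame.motion_channel.astype(float)
    mask = mr >= params.threshold
    if params.open_radius > 0:
        mask = morphology.binary_opening(mask, morphology.disk(params.open_radius))
    if not mask.any():
        return []
    if params.merge_gap > 0:
        label_mask = morphology.dilation(mask, morphology.disk(params.merge_gap))
    else:
        label_mask = mask
    labels = measure.label(label_mask, connectivity=2)
    detections: list[Detection] = []
    for region in measure.regionprops(labels):
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        keep = mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
        area = rr.size
        if area < params.min_area or area > params.max_area:
            continue
        box = BoundingBox(
            xmin=float(cc.min()), ymin=float(rr.min()),
            xmax=float(cc.max()) + 1.0, ymax=float(rr.max()) + 1.0,
        )
        confidence = min(1.0, float(mr[rr, cc].mean()) / 255.0)
        detections.append(
            Detection(frame_id=frame.frame_id, box=box, confidence=confidence,
                      class_id=0, timestamp=frame.timestamp)
        )
    detections.sort(key=lambda d: (d.box.ymin, d.box.xmin))
    return detections


def detect_sequence(frames: Iterable[EnhancedFrame],
                    params: BaselineParams | None = None) -> list[Detection]:
    """Run the blob baseline over many enhanced frames."""
    out: list[Detection] = []
    for f in frames:
        out.extend(detect_motion_blobs(f, params))
    return out


def run_external_detections(
    detections_csv: str | Path,
    frame_ids: Iterable[str],
) -> Mapping[str, list[Detection]]:
    """Group an external detector's CSV output by frame id.

    Every requested frame id maps to a (possibly empty) list; rows
    referencing unknown frame ids are logged and dropped.
    """
    frame_ids = list(frame_ids)
    grouped: dict[str, list[Detection]] = {fid: [] for fid in frame_ids}
    known = set(frame_ids)
    orphans = 0
    for det in read_detections_csv(detections_csv):
        if det.frame_id in known:
            grouped[det.frame_id].append(det)
        else:
            orphans += 1
            logger.warning("detection references unknown frame_id %r", det.frame_id)
    if orphans:
        logger.warning("%d detection row(s) referenced unknown frames", orphans)
    return grouped
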