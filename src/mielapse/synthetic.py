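"""Synthetic time-lapse scenes with ground truth.

Emulates the structure of greenhouse pollinator-monitoring recordings:
a static, green-dominant vegetation background with a few brightly
coloured flowers, over which small dark insect blobs move between
frames.  Scenes are rendered at quarter scale (480 x 270) by default,
which preserves the small-object regime (insects 6-20 px across) while
keeping whole benchmarks cheap to generate.

Two nuisance factors of real field recordings are modelled explicitly:
a global per-frame brightness jitter (automatic exposure) and a small
rigid sway of the flower layer (wind).  Everything is a pure function
of the configuration and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from scipy import ndimage
from skimage import draw

from .sequence_io import (
    Annotation,
    BoundingBox,
    Frame,
    TimeLapseSequence,
    save_sequence,
    write_yolo_annotations,
)


@dataclass
class BackgroundConfig:
    """Vegetation background model.

    A smooth green texture (Gaussian-filtered noise) with elliptical
    "flowers" in pink/orange/red hues; ``illumination_jitter`` is the
    std of a per-frame global brightness multiplier and ``sway_px`` the
    amplitude of the flower layer's per-frame rigid shift.
    """

    texture_scale: float = 8.0
    n_flowers: int = 12
    flower_colors: tuple[tuple[int, int, int], ...] = (
        (230, 120, 180),  # pink
        (240, 140, 60),   # orange
        (220, 60, 70),    # red
    )
    flower_radius_px: tuple[int, int] = (8, 20)
    base_color: tuple[int, int, int] = (70, 160, 60)
    texture_amplitude: float = 12.0
    illumination_jitter: float = 0.02
    sway_px: float = 1.0


@dataclass
class SceneConfig:
    """Full configuration of one synthetic camera site."""

    width: int = 480
    height: int = 270
    n_frames: int = 20
    interval_s: float = 30.0
    n_insects: int = 1
    insect_size_px: tuple[int, int] = (6, 20)
    insect_color: tuple[int, int, int] = (25, 20, 15)
    insect_color_jitter: float = 10.0
    step_px: tuple[float, float] = (15.0, 40.0)
    presence_prob: float = 0.9
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    seed: int = 0
    start_time: datetime = field(default_factory=lambda: datetime(2022, 6, 1, 8, 0, 0))
    camera_id: str = "SYN-0"

    def __post_init__(self):
        if self.width < 1 or self.height < 1 or self.n_frames < 0:
            raise ValueError("dimensions and frame count must be positive")
        if not (0.0 <= self.presence_prob <= 1.0):
            raise ValueError("presence_prob must lie in [0, 1]")
        if self.insect_size_px[1] >= min(self.width, self.height):
            raise ValueError("insect larger than frame")


def load_scene_config(path: str | Path) -> SceneConfig:
    """Build a SceneConfig from a YAML (or JSON) mapping mirroring its fields.

    A nested ``background`` mapping configures BackgroundConfig;
    ``start_time`` accepts an ISO 8601 string.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of SceneConfig fields")
    if "background" in data:
        data["background"] = BackgroundConfig(**{
            k: tuple(tuple(c) for c in v) if k == "flower_colors" else
            tuple(v) if isinstance(v, list) else v
            for k, v in data["background"].items()
        })
    for key in ("insect_size_px", "insect_color", "step_px"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    if isinstance(data.get("start_time"), str):
        data["start_time"] = datetime.fromisoformat(data["start_time"])
    return SceneConfig(**data)


@dataclass
class SyntheticSite:
    """One generated site: sequence plus per-frame ground truth."""

    site_id: str
    config: SceneConfig
    sequence: TimeLapseSequence
    annotations: dict[str, list[Annotation]]

    @property
    def n_annotations(self) -> int:
        return sum(len(a) for a in self.annotations.values())


def _render_background_layers(config: SceneConfig, rng: np.random.Generator):
    """Base green texture and a separate flower RGBA layer."""
    bg = config.background
    h, w = config.height, config.width
    base = np.empty((h, w, 3), dtype=float)
    noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), bg.texture_scale)
    scale = noise.std() or 1.0
    noise = noise / scale
    for c, v in enumerate(bg.base_color):
        base[:, :, c] = v + bg.texture_amplitude * noise * (1.0 if c == 1 else 0.4)
    base = np.clip(base, 0, 255)

    flower_rgb = np.zeros((h, w, 3), dtype=float)
    flower_mask = np.zeros((h, w), dtype=bool)
    for _ in range(bg.n_flowers):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = rng.uniform(*bg.flower_radius_px)
        rx = rng.uniform(*bg.flower_radius_px)
        color = bg.flower_colors[rng.integers(len(bg.flower_colors))]
        rr, cc = draw.ellipse(cy, cx, ry, rx, shape=(h, w))
        flower_mask[rr, cc] = True
        for c in range(3):
            flower_rgb[rr, cc, c] = color[c] + rng.normal(0, 6)
    return base, np.clip(flower_rgb, 0, 255), flower_mask


def _composite(base, flower_rgb, flower_mask, shift=(0, 0), gain=1.0):
    img = base.copy()
    if flower_mask.any():
        mask = ndimage.shift(flower_mask.astype(float), shift, order=0) > 0.5
        rgb = ndimage.shift(flower_rgb, (*shift, 0), order=0)
        img[mask] = rgb[mask]
    return np.clip(img * gain, 0, 255)


def generate_background(config: SceneConfig, seed: int | None = None) -> Frame:
    """Render the static background only (no insects, no nuisance)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base, flower_rgb, flower_mask = _render_background_layers(config, rng)
    img = _composite(base, flower_rgb, flower_mask)
    return Frame(
        image=np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8),
        timestamp=config.start_time,
        frame_id="background",
    )


class _Insect:
    """Seeded random-walk blob with a fixed ellipse footprint."""

    def __init__(self, config: SceneConfig, rng: np.random.Generator):
        lo, hi = config.insect_size_px
        self.rx = rng.uniform(lo, hi) / 2.0
        self.ry = self.rx * rng.uniform(0.6, 1.0)
        margin_x = self.rx + 2
        margin_y = self.ry + 2
        self.x = rng.uniform(margin_x, config.width - margin_x)
        self.y = rng.uniform(margin_y, config.height - margin_y)
        self.color = np.array(config.insect_color, dtype=float)
        self.jitter = config.insect_color_jitter
        self._cfg = config

    def step(self, rng: np.random.Generator) -> None:
        cfg = self._cfg
        for _ in range(20):
            angle = rng.uniform(0, 2 * math.pi)
            dist = rng.uniform(*cfg.step_px)
            nx = self.x + dist * math.cos(angle)
            ny = self.y + dist * math.sin(angle)
            if (self.rx + 1 <= nx <= cfg.width - self.rx - 1
                    and self.ry + 1 <= ny <= cfg.height - self.ry - 1):
                self.x, self.y = nx, ny
                return
        # cornered: reflect towards the centre
        self.x = min(max(self.x, self.rx + 1), cfg.width - self.rx - 1)
        self.y = min(max(self.y, self.ry + 1), cfg.height - self.ry - 1)

    def render(self, img: np.ndarray, rng: np.random.Generator) -> BoundingBox | None:
        rr, cc = draw.ellipse(self.y, self.x, self.ry, self.rx, shape=img.shape[:2])
        if rr.size == 0:
            return None
        texture = rng.normal(0, self.jitter, size=(rr.size, 3))
        img[rr, cc] = np.clip(self.color[None, :] + texture, 0, 255)
        return BoundingBox(
            xmin=float(cc.min()), ymin=float(rr.min()),
            xmax=float(cc.max()) + 1.0, ymax=float(rr.max()) + 1.0,
        )


def generate_sequence(config: SceneConfig) -> tuple[TimeLapseSequence, dict[str, list[Annotation]]]:
    """Generate one site's frames and per-frame ground-truth boxes.

    The background is static up to the configured nuisance factors;
    each insect follows a seeded random walk and, when visible, yields
    one annotation whose box tightly encloses its painted pixels.
    Fully reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    base, flower_rgb, flower_mask = _render_background_layers(config, rng)
    insects = [_Insect(config, rng) for _ in range(config.n_insects)]
    bg = config.background

    frames: list[Frame] = []
    annotations: dict[str, list[Annotation]] = {}
    for k in range(config.n_frames):
        ts = config.start_time + timedelta(seconds=k * config.interval_s)
        frame_id = ts.strftime("%Y%m%d-%H%M%S")
        gain = 1.0 + (rng.normal(0, bg.illumination_jitter) if bg.illumination_jitter > 0 else 0.0)
        if bg.sway_px > 0:
            shift = (rng.integers(-round(bg.sway_px), round(bg.sway_px) + 1),
                     rng.integers(-round(bg.sway_px), round(bg.sway_px) + 1))
        else:
            shift = (0, 0)
        img = _composite(base, flower_rgb, flower_mask, shift=shift, gain=gain)
        anns: list[Annotation] = []
        for insect in insects:
            if k > 0:
                insect.step(rng)
            visible = rng.uniform() < config.presence_prob
            if visible:
                box = insect.render(img, rng)
                if box is not None:
                    anns.append(Annotation(frame_id=frame_id, box=box, class_id=0))
        frames.append(Frame(
            image=np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8),
            timestamp=ts, frame_id=frame_id,
        ))
        annotations[frame_id] = anns
    seq = TimeLapseSequence(frames=frames, camera_id=config.camera_id,
                            nominal_interval_s=config.interval_s)
    return seq, annotations


def generate_benchmark(
    config: SceneConfig,
    n_sites: int = 7,
    ratio_range: tuple[float, float] = (0.01, 0.15),
) -> list[SyntheticSite]:
    """Generate a multi-site benchmark with varying insect prevalence.

    Each site gets an independent child seed of ``config.seed`` and an
    insect presence probability drawn uniformly from ``ratio_range``,
    mirroring real deployments where the fraction of insect-bearing
    frames varies widely between cameras.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    master = np.random.default_rng(config.seed)
    sites: list[SyntheticSite] = []
    for i in range(n_sites):
        site_seed = int(master.integers(0, 2**31 - 1))
        ratio = float(master.uniform(*ratio_range))
        site_id = f"SYN-{i}"
        site_cfg = replace(config, seed=site_seed, presence_prob=ratio,
                           camera_id=site_id)
        seq, anns = generate_sequence(site_cfg)
        sites.append(SyntheticSite(site_id=site_id, config=site_cfg,
                                   sequence=seq, annotations=anns))
    return sites


def write_benchmark(sites: Iterable[SyntheticSite], out_dir: str | Path) -> Path:
    """Write a benchmark to disk in the formats the pipeline consumes.

    Layout: ``<site>/images/*.png``, ``<site>/labels/*.txt`` and a
    ``manifest.csv`` with columns site_id, frame_dir, label_dir.
    """
    out_dir = Path(out_dir)
    rows = ["site_id,frame_dir,label_dir"]
    for site in sites:
        frame_dir = out_dir / site.site_id / "images"
        label_dir = out_dir / site.site_id / "labels"
        label_dir.mkdir(parents=True, exist_ok=True)
        save_sequence(site.sequence, frame_dir)
        h, w = site.sequence.shape
        for frame_id, anns in site.annotations.items():
            write_yolo_annotations(anns, w, h, label_dir / f"{frame_id}.txt")
        rows.append(f"{site.site_id},{frame_dir},{label_dir}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
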