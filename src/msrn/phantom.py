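"""Synthetic OCT B-scan phantoms with known labels and lesion coordinates.

Each phantom is a curved, bright, multi-layer retinal band over a dark
background, multiplied by a smoothed gamma-distributed speckle field (the
multiplicative interference noise characteristic of coherent imaging).
Three lesion types can be injected, echoing the appearance of the real
pathologies:

* **AMD** — drusen: smooth dome-shaped bumps lifting the lowest bright
  layer (the RPE), with moderate-intensity deposit material beneath;
* **ERM** — a thin bright membrane hugging or floating just above the
  inner retinal surface (1-3 px thick at the native 512 side, so it is
  barely resolvable after aggressive downscaling but clear at fine scale);
* **ME** — dark elliptical fluid cavities inside the band.

Lesions are sampled independently per class with configurable marginal
probabilities; the defaults approximate the reference prevalences
(AMD 0.22, ERM 0.28, ME 0.11), so multi-disease co-occurrence arises
naturally.  Every draw flows through one ``numpy.random.Generator``:
a given (config, seed) pair is byte-reproducible.

This is a test phantom, not a physical OCT simulation: there is no A-scan
optics model, shadowing, or vendor post-processing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .labels import CLASS_NAMES, MultiHotLabel
from .training import DatasetManifest, MANIFEST_COLUMNS

# geometry defaults below are in pixels at the native 512 side and are
# rescaled proportionally for other sides


@dataclass(frozen=True)
class PhantomConfig:
    side: int = 512
    background_level: float = 0.05
    # retinal band geometry (px at side=512)
    surface_row: float = 160.0
    surface_curvature: float = 45.0
    nfl_thickness: float = 10.0
    inner_thickness: float = 70.0
    onl_thickness: float = 35.0
    rpe_thickness: float = 13.0
    # layer intensities
    nfl_level: float = 0.85
    inner_level: float = 0.55
    onl_level: float = 0.38
    rpe_level: float = 0.95
    # speckle
    speckle_contrast: float = 0.35
    speckle_grain: float = 1.2
    # lesion marginal probabilities (independent Bernoulli draws)
    p_amd: float = 0.22
    p_erm: float = 0.28
    p_me: float = 0.11
    # lesion size ranges (px at side=512)
    drusen_height: tuple[float, float] = (14.0, 38.0)
    drusen_width: tuple[float, float] = (20.0, 45.0)
    erm_thickness: tuple[float, float] = (1.0, 3.0)
    erm_gap: tuple[float, float] = (2.0, 10.0)
    cavity_rx: tuple[float, float] = (22.0, 60.0)
    cavity_ry: tuple[float, float] = (10.0, 28.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_amd", "p_erm", "p_me"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("nfl_thickness", "inner_thickness", "onl_thickness",
                     "rpe_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.side < 32:
            raise ValueError("side must be at least 32")

    @property
    def scale(self) -> float:
        return self.side / 512.0


@dataclass
class PhantomSample:
    image: np.ndarray  # (side, side) float32 in [0, 1]
    label: MultiHotLabel
    lesion_boxes: list  # (class_name, (x0, y0, x1, y1)) in pixel coords
    patient_id: str = ""
    eye_id: str = ""

    def __post_init__(self) -> None:
        present = {name for name, _ in self.lesion_boxes}
        for name in ("amd", "erm", "me"):
            if bool(getattr(self.label, name)) != (name in present):
                raise ValueError(f"label/lesion inconsistency for class {name}")
        if bool(self.label.normal) != (len(self.lesion_boxes) == 0):
            raise ValueError("normal label inconsistent with lesion boxes")


def _band_geometry(cfg: PhantomConfig, rng: np.random.Generator):
    """Per-column layer boundary rows (float arrays of length side)."""
    s, sc = cfg.side, cfg.scale
    x = np.arange(s)
    center = rng.uniform(0.35, 0.65) * s
    curvature = cfg.surface_curvature * sc * rng.uniform(0.6, 1.4)
    tilt = rng.uniform(-0.06, 0.06)
    top = (cfg.surface_row * sc + rng.uniform(-20, 20) * sc
           + curvature * ((x - center) / s) ** 2 * 4.0 + tilt * (x - s / 2))
    b1 = top + cfg.nfl_thickness * sc
    b2 = b1 + cfg.inner_thickness * sc
    b3 = b2 + cfg.onl_thickness * sc
    b4 = b3 + cfg.rpe_thickness * sc
    return top, b1, b2, b3, b4


def _inject_drusen(cfg, rng, top_rpe, n_max=3):
    """Return (elevation array per column, bounding boxes)."""
    s, sc = cfg.side, cfg.scale
    x = np.arange(s)
    n = rng.integers(1, n_max + 1)
    elevation = np.zeros(s)
    boxes = []
    for _ in range(n):
        h = rng.uniform(*cfg.drusen_height) * sc
        w = rng.uniform(*cfg.drusen_width) * sc
        cx = rng.uniform(0.15, 0.85) * s
        bump = h * np.exp(-0.5 * ((x - cx) / w) ** 2)
        elevation = np.maximum(elevation, bump)
        span = np.flatnonzero(bump > 1.5 * sc)
        if len(span) == 0:
            span = np.array([int(cx)])
        x0, x1 = int(span[0]), int(span[-1]) + 1
        y_top = top_rpe[x0:x1] - bump[x0:x1]
        y_bot = top_rpe[x0:x1] + cfg.rpe_thickness * sc
        boxes.append(("amd", (x0, int(max(0, y_top.min())), x1, int(y_bot.max()) + 1)))
    return elevation, boxes


def _inject_erm(cfg, rng, top):
    s, sc = cfg.side, cfg.scale
    th = rng.uniform(*cfg.erm_thickness) * sc
    gap = rng.uniform(*cfg.erm_gap) * sc
    x0 = int(rng.uniform(0.05, 0.35) * s)
    x1 = int(rng.uniform(0.65, 0.95) * s)
    y_mem = top[x0:x1] - gap
    box = ("erm", (x0, int(max(0, y_mem.min() - th)), x1, int(y_mem.max()) + 2))
    return (x0, x1, y_mem, max(th, 1.0)), box


def _inject_cavities(cfg, rng, b1, b3, n_max=3):
    s, sc = cfg.side, cfg.scale
    n = rng.integers(1, n_max + 1)
    cavities, boxes = [], []
    for _ in range(n):
        rx = rng.uniform(*cfg.cavity_rx) * sc
        ry = rng.uniform(*cfg.cavity_ry) * sc
        cx = rng.uniform(0.15, 0.85) * s
        col = int(np.clip(cx, 0, s - 1))
        lo = b1[col] + ry + 2 * sc
        hi = b3[col] - ry - 2 * sc
        if hi <= lo:  # band too thin for this cavity; shrink it
            ry = max(3.0 * sc, (b3[col] - b1[col]) / 4)
            lo, hi = b1[col] + ry, b3[col] - ry
        cy = rng.uniform(lo, max(hi, lo + 1e-6))
        cavities.append((cx, cy, rx, ry))
        boxes.append(("me", (int(cx - rx), int(cy - ry), int(cx + rx) + 1,
                             int(cy + ry) + 1)))
    return cavities, boxes


def generate_phantom(config: PhantomConfig,
                     rng: np.random.Generator | None = None) -> PhantomSample:
    """Render one phantom B-scan with its ground-truth label and boxes."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s, sc = config.side, config.scale
    has_amd = rng.random() < config.p_amd
    has_erm = rng.random() < config.p_erm
    has_me = rng.random() < config.p_me

    top, b1, b2, b3, b4 = _band_geometry(config, rng)
    rows = np.arange(s)[:, None].astype(np.float64)

    elevation = np.zeros(s)
    boxes: list = []
    if has_amd:
        elevation, amd_boxes = _inject_drusen(config, rng, b3)
        boxes.extend(amd_boxes)
    rpe_top = b3 - elevation
    rpe_bot = rpe_top + config.rpe_thickness * sc

    img = np.full((s, s), config.background_level, dtype=np.float64)
    img[(rows >= top) & (rows < b1)] = config.nfl_level
    img[(rows >= b1) & (rows < b2)] = config.inner_level
    img[(rows >= b2) & (rows < rpe_top)] = config.onl_level
    img[(rows >= rpe_top) & (rows < rpe_bot)] = config.rpe_level
    # deposit material between an elevated RPE and its original bed
    deposit = (rows >= rpe_bot) & (rows < b4) & (elevation > 0)
    img[deposit] = 0.5

    if has_me:
        cavities, me_boxes = _inject_cavities(config, rng, b1, b3)
        boxes.extend(me_boxes)
        cols = np.arange(s)[None, :]
        inside_band = (rows >= b1) & (rows < b3)
        for cx, cy, rx, ry in cavities:
            ell = ((cols - cx) / rx) ** 2 + ((rows - cy) / ry) ** 2 <= 1.0
            img[ell & inside_band] = config.background_level * 1.2

    if has_erm:
        (x0, x1, y_mem, th), erm_box = _inject_erm(config, rng, top)
        boxes.append(erm_box)
        cols = np.arange(x0, x1)[None, :]
        seg = (rows >= y_mem[None, :]) & (rows < (y_mem + th)[None, :])
        img[:, x0:x1][seg] = 0.9

    # multiplicative speckle: gamma field with unit mean, smoothed grain
    shape = 1.0 / max(config.speckle_contrast, 1e-3) ** 2
    speckle = rng.gamma(shape, 1.0 / shape, size=(s, s))
    if config.speckle_grain > 0:
        speckle = ndimage.gaussian_filter(speckle, config.speckle_grain * sc)
        speckle /= speckle.mean()
    img = np.clip(img * speckle, 0.0, 1.0).astype(np.float32)

    label = MultiHotLabel.from_diseases(amd=int(has_amd), erm=int(has_erm),
                                        me=int(has_me))
    return PhantomSample(image=img, label=label, lesion_boxes=boxes)


def generate_samples(n: int, config: PhantomConfig,
                     frames_per_patient: int = 8) -> list[PhantomSample]:
    """n phantoms from one seeded stream, patients in consecutive blocks."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(config.seed)
    samples = []
    for i in range(n):
        s = generate_phantom(config, rng)
        pid = i // frames_per_patient
        s.patient_id = f"P{pid:05d}"
        s.eye_id = "OD" if pid % 2 == 0 else "OS"
        samples.append(s)
    return samples


def generate_dataset(n: int, config: PhantomConfig, out_dir,
                     frames_per_patient: int = 8) -> DatasetManifest:
    """Write n phantom PNGs + manifest CSV + lesion-box JSON side-car."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, config, frames_per_patient)
    records, all_boxes = [], {}
    for i, s in enumerate(samples):
        name = f"phantom_{i:05d}.png"
        arr8 = np.round(s.image * 255.0).astype(np.uint8)
        Image.fromarray(arr8, mode="L").save(out_dir / name)
        records.append({
            "path": name, "amd": s.label.amd, "erm": s.label.erm,
            "me": s.label.me, "normal": s.label.normal,
            "patient_id": s.patient_id,
        })
        all_boxes[name] = [{"class": c, "box": list(b)} for c, b in s.lesion_boxes]
    manifest = DatasetManifest(pd.DataFrame.from_records(records,
                                                         columns=MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv")
    with open(out_dir / "lesion_boxes.json", "w") as fh:
        json.dump(all_boxes, fh, indent=0)
    with open(out_dir / "generator_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
    return manifest
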