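"""Seeded synthetic microscopy scenes: paired bright-field z-stacks,
fluorescent targets and ground-truth instance/state maps.

The generator emulates the statistical structure the translation method
relies on, not the optics of a real microscope:

* **Healthy nuclei** are smooth-interior ellipses with soft edges and a
  mild intensity gradient — low internal variance in fluorescence.
* **Apoptotic nuclei** are clusters of 3–8 small bright fragments inside
  an elliptical footprint with ≥1 px dark gaps (karyorrhexis) — high
  internal variance; iterated Gaussian smoothing can reconnect the
  fragments into one blob, which is what the ground-truth pipeline needs.
* **Bright-field** shows low-contrast cell bodies larger than their
  nuclei (edge rings), while the nuclei themselves are nearly invisible
  at focus; their phase-like contrast reverses sign through focus, so
  off-focus slices carry most of the nucleus signal and a full z-stack is
  genuinely more informative than the center slice alone. Slices are
  blurred in proportion to their defocus distance and carry additive
  Gaussian noise.
* Occasional **touching nuclei pairs** exercise the watershed split, and
  an optional "necrotic-like" attenuation flag renders a nucleus very
  faint in both modalities (qualitative tests only).

Every scene is a pure function of its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .preprocessing import BACKGROUND, NucleusInstanceMap

logger = logging.getLogger(__name__)

__all__ = [
    "SceneConfig",
    "ScenePair",
    "generate_scene",
    "fluorescent_stack",
    "generate_dataset",
    "split_counts",
    "desk_scene_config",
]

#: default train:validation:test proportions
SPLIT_RATIO = (66, 12, 8)


@dataclass
class SceneConfig:
    """All knobs of one synthetic scene; the seed fully determines it."""

    height: int = 256
    width: int = 256
    n_healthy: int = 6
    n_apoptotic: int = 4
    n_slices: int = 13
    slice_spacing_um: float = 0.3
    focus_slice: int | None = None  # defaults to the center slice
    defocus_sigma_per_um: float = 1.2  # blur σ (px) per μm of defocus
    base_blur_sigma: float = 0.5
    noise_sd: float = 0.02
    nucleus_radius_range: tuple[float, float] = (12.0, 18.0)
    fragment_count_range: tuple[int, int] = (3, 8)
    fragment_radius_range: tuple[float, float] = (2.5, 4.0)
    touching_pair_prob: float = 0.25
    cell_body_scale: float = 1.8
    nucleus_contrast: float = 0.12   # peak bright-field amplitude of nuclei
    cell_edge_contrast: float = 0.06
    necrotic_like_prob: float = 0.0
    placement_retries: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_healthy < 0 or self.n_apoptotic < 0:
            raise ValueError("nucleus counts must be non-negative")

    @property
    def focus(self) -> int:
        return self.n_slices // 2 if self.focus_slice is None else self.focus_slice


@dataclass
class ScenePair:
    """One paired scene; arrays are float64 unless noted."""

    bright_field: np.ndarray        # (S, H, W) in [0, 1]
    fluorescent_target: np.ndarray  # (2, H, W) in [0, 1]: healthy, apoptotic
    class_mask: np.ndarray          # (H, W) in {0, 1, 2}
    instances: NucleusInstanceMap   # true labels + states
    config: SceneConfig
    requested: tuple[int, int] = (0, 0)
    placed: tuple[int, int] = (0, 0)
    necrotic_like: tuple[int, ...] = ()

    @property
    def n_nuclei(self) -> int:
        return self.instances.n_instances


def _ellipse(h, w, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / rx
    v = (-st * dx + ct * dy) / ry
    return u * u + v * v <= 1.0


def _soft(mask: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    return ndi.gaussian_filter(mask.astype(float), sigma)


def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator):
    """Sample nucleus geometry with a retry budget; returns a list of dicts."""
    h, w = cfg.height, cfg.width
    lo, hi = cfg.nucleus_radius_range
    states = ["healthy"] * cfg.n_healthy + ["apoptotic"] * cfg.n_apoptotic
    rng.shuffle(states)
    nuclei = []
    for state in states:
        ry, rx = rng.uniform(lo, hi, size=2)
        r = max(ry, rx)
        placed = False
        for _ in range(cfg.placement_retries):
            if nuclei and rng.random() < cfg.touching_pair_prob:
                anchor = nuclei[rng.integers(len(nuclei))]
                ang = rng.uniform(0, 2 * np.pi)
                dist = 0.95 * (max(anchor["ry"], anchor["rx"]) + r)
                cy = anchor["cy"] + dist * np.sin(ang)
                cx = anchor["cx"] + dist * np.cos(ang)
                min_sep_scale = 0.0  # intentionally touching
            else:
                cy = rng.uniform(r + 2, h - r - 2)
                cx = rng.uniform(r + 2, w - r - 2)
                min_sep_scale = 1.15
            if not (r + 1 <= cy <= h - r - 1 and r + 1 <= cx <= w - r - 1):
                continue
            ok = True
            for other in nuclei:
                d = np.hypot(cy - other["cy"], cx - other["cx"])
                sep = min_sep_scale * (max(other["ry"], other["rx"]) + r)
                if d < max(sep, 0.9 * (max(other["ry"], other["rx"]) + r)):
                    ok = False
                    break
            if ok:
                nuclei.append(dict(cy=cy, cx=cx, ry=ry, rx=rx,
                                   theta=rng.uniform(0, np.pi), state=state))
                placed = True
                break
        if not placed:
            logger.warning("nucleus placement retry budget exhausted; scene has "
                           "fewer nuclei than requested")
    return nuclei


def _fragments(nuc, cfg: SceneConfig, rng: np.random.Generator):
    """Fragment centers/radii inside the parent ellipse, ≥1 px gaps."""
    k = int(rng.integers(cfg.fragment_count_range[0], cfg.fragment_count_range[1] + 1))
    frags = []
    for _ in range(k):
        for _ in range(40):
            fr = rng.uniform(*cfg.fragment_radius_range)
            rad = rng.uniform(0, 0.75)
            ang = rng.uniform(0, 2 * np.pi)
            fy = nuc["cy"] + rad * nuc["ry"] * np.sin(ang)
            fx = nuc["cx"] + rad * nuc["rx"] * np.cos(ang)
            if all(np.hypot(fy - o[0], fx - o[1]) >= fr + o[2] + 1.0 for o in frags):
                frags.append((fy, fx, fr))
                break
    return frags


def generate_scene(config: SceneConfig | None = None, **overrides) -> ScenePair:
    """Render one scene deterministically from ``config.seed``."""
    cfg = replace(config or SceneConfig(), **overrides) if (config or overrides) \
        else SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    nuclei = _place_nuclei(cfg, rng)

    labels = np.zeros((h, w), dtype=np.int64)
    states: dict[int, str] = {}
    fluor = np.zeros((h, w))
    granular = np.zeros((h, w))   # fragment structure (bright-field texture cue)
    smooth_sig = np.zeros((h, w))  # intact-nucleus structure
    necrotic: list[int] = []
    label = 0
    for nuc in nuclei:
        label += 1
        atten = 1.0
        if cfg.necrotic_like_prob and rng.random() < cfg.necrotic_like_prob:
            atten = 0.15
            necrotic.append(label)
        if nuc["state"] == "healthy":
            foot = _ellipse(h, w, nuc["cy"], nuc["cx"], nuc["ry"], nuc["rx"],
                            nuc["theta"])
            # intact chromatin: uniform moderate brightness, mild gradient
            base = rng.uniform(0.6, 0.72)
            grad = (np.mgrid[0:h, 0:w][0] - nuc["cy"]) / max(h, w)
            intensity = _soft(foot, 0.7) * (base + 0.05 * grad) * atten
            smooth_sig += _soft(foot, 1.5)
        else:
            # condensed fragments: bright spots with dark gaps between them
            foot = np.zeros((h, w), dtype=bool)
            intensity = np.zeros((h, w))
            for fy, fx, fr in _fragments(nuc, cfg, rng):
                fm = _ellipse(h, w, fy, fx, fr, fr, 0.0)
                foot |= fm
                intensity += _soft(fm, 0.5) * rng.uniform(0.85, 1.0) * atten
            granular += _soft(foot.astype(float), 0.8)
        region = foot & (labels == 0)
        if not region.any():
            label -= 1
            if label + 1 in states:  # pragma: no cover - defensive
                del states[label + 1]
            continue
        labels[region] = label
        states[label] = nuc["state"]
        fluor = np.maximum(fluor, np.clip(intensity, 0, 1))
        nuc["label"] = label
        nuc["atten"] = atten

    instances = NucleusInstanceMap(labels, states)
    class_mask = instances.class_map()
    target = np.stack([
        fluor * instances.state_mask("healthy"),
        fluor * instances.state_mask("apoptotic"),
    ])

    # ---------------------------------------------------------- bright-field
    yy, xx = np.mgrid[0:h, 0:w]
    illum = 0.55 + 0.04 * (xx / w - 0.5) + 0.03 * (yy / h - 0.5)
    cell_sig = np.zeros((h, w))
    for nuc in nuclei:
        if "label" not in nuc:
            continue
        body = _ellipse(h, w, nuc["cy"], nuc["cx"],
                        cfg.cell_body_scale * nuc["ry"],
                        cfg.cell_body_scale * nuc["rx"], nuc["theta"])
        soft = _soft(body, 2.0)
        ring = 4.0 * soft * (1.0 - soft)  # edge band of the cell body
        cell_sig += cfg.cell_edge_contrast * (0.3 * soft - ring) * nuc.get("atten", 1.0)

    focus = cfg.focus
    stack = np.empty((cfg.n_slices, h, w))
    for z in range(cfg.n_slices):
        dz_um = (z - focus) * cfg.slice_spacing_um
        # phase-like contrast: zero at focus, opposite signs above/below
        amp = cfg.nucleus_contrast * np.tanh(dz_um / 0.45)
        plane = illum + cell_sig + amp * (smooth_sig - 1.6 * granular)
        sigma = cfg.base_blur_sigma + cfg.defocus_sigma_per_um * abs(dz_um)
        plane = ndi.gaussian_filter(plane, sigma)
        plane = plane + rng.normal(0.0, cfg.noise_sd, size=(h, w))
        stack[z] = plane
    stack = np.clip(stack, 0.0, 1.0)

    placed_h = sum(1 for s in states.values() if s == "healthy")
    placed_a = sum(1 for s in states.values() if s == "apoptotic")
    return ScenePair(stack, target, class_mask, instances, cfg,
                     requested=(cfg.n_healthy, cfg.n_apoptotic),
                     placed=(placed_h, placed_a),
                     necrotic_like=tuple(necrotic))


def fluorescent_stack(scene: ScenePair, n_slices: int = 24,
                      spacing_um: float = 0.3, gain: float = 1000.0,
                      psf_growth_per_um: float = 0.5) -> np.ndarray:
    """Emulated raw fluorescent z-stack for the preparation pipeline.

    The in-focus structure is the scene's combined fluorescence; slices
    away from the center are defocus-blurred (confocal optical sectioning
    keeps the blur growth modest) and attenuated, with a dim baseline and
    detector noise, in arbitrary detector units.
    """
    cfg = scene.config
    rng = np.random.default_rng(cfg.seed + 77_000_003)
    structure = scene.fluorescent_target.sum(axis=0)
    focus = n_slices // 2
    out = np.empty((n_slices, *structure.shape))
    for z in range(n_slices):
        dz_um = abs(z - focus) * spacing_um
        sigma = 0.4 + psf_growth_per_um * dz_um
        plane = ndi.gaussian_filter(structure, sigma)
        plane = gain * (0.02 + plane * (1.0 / (1.0 + 0.25 * dz_um)))
        out[z] = plane + rng.normal(0, 0.01 * gain, size=plane.shape)
    return np.clip(out, 0.0, None)


def split_counts(n_scenes: int, ratio: tuple[int, int, int] = SPLIT_RATIO):
    """Proportional train/val/test sizes (test and val at least 1)."""
    if n_scenes < 3:
        raise ValueError("need at least 3 scenes to form train/val/test splits")
    total = sum(ratio)
    n_test = max(1, round(n_scenes * ratio[2] / total))
    n_val = max(1, round(n_scenes * ratio[1] / total))
    n_train = n_scenes - n_val - n_test
    if n_train < 1:
        raise ValueError(f"{n_scenes} scenes leave no training scenes")
    return n_train, n_val, n_test


@dataclass
class SyntheticDataset:
    scenes: list[ScenePair]
    split: dict[str, list[int]]
    seeds: list[int]

    def subset(self, name: str) -> list[ScenePair]:
        return [self.scenes[i] for i in self.split[name]]


def generate_dataset(n_scenes: int, config: SceneConfig | None = None) -> SyntheticDataset:
    """Generate ``n_scenes`` seeded scenes with a deterministic
    train/validation/test assignment in 66:12:8 proportions."""
    cfg = config or SceneConfig()
    seeds = [int((cfg.seed * 100_003 + 7 * i + 1) % (2**31 - 1)) for i in range(n_scenes)]
    scenes = [generate_scene(replace(cfg, seed=s)) for s in seeds]
    n_train, n_val, n_test = split_counts(n_scenes)
    order = np.random.default_rng(cfg.seed).permutation(n_scenes)
    split = {
        "train": sorted(int(i) for i in order[:n_train]),
        "val": sorted(int(i) for i in order[n_train:n_train + n_val]),
        "test": sorted(int(i) for i in order[n_train + n_val:]),
    }
    return SyntheticDataset(scenes, split, seeds)


def desk_scene_config(seed: int = 0, size: int = 64) -> SceneConfig:
    """Desk-scale scene: small canvas, few nuclei, radii scaled to fit."""
    return SceneConfig(
        height=size, width=size, n_healthy=3, n_apoptotic=2,
        nucleus_radius_range=(5.0, 8.0), fragment_radius_range=(1.5, 2.5),
        touching_pair_prob=0.15, seed=seed,
    )
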