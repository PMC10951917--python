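"""Ground-truth preparation: raw fluorescent z-stacks → training targets.

The pipeline distils a 24-slice Hoechst z-stack into (i) a 2-channel
fluorescent target (healthy / apoptotic), (ii) a 3-class mask and
(iii) per-nucleus health states:

1.  optional resize; per-slice min–max normalization to 8-bit range;
2.  maximum-intensity projection along z;
3.  CLAHE (clip limit 2, 8×8 tile grid), then 4 passes of Gaussian
    smoothing (reconnects karyorrhexis fragments of one nucleus) and 12
    passes of 3×3 median filtering (removes salt-and-pepper noise);
4.  Otsu threshold → nuclei foreground; distance transform, local-maximum
    markers, marker-controlled watershed → one label per nucleus;
5.  per-nucleus intensity standard deviation on the maximum image; a 1-D
    Otsu split assigns the high-variance group to "apoptotic" (fragmented)
    and the low-variance group to "healthy", with a manual-override table
    for curator corrections;
6.  the two state masks applied to the CLAHE'd center slice give the
    2-channel target; bright-field stacks are min–max normalized and
    concatenated along z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters, transform
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

HEALTHY, APOPTOTIC, BACKGROUND = 0, 1, 2
STATE_NAMES = {HEALTHY: "healthy", APOPTOTIC: "apoptotic"}

__all__ = [
    "HEALTHY", "APOPTOTIC", "BACKGROUND",
    "PreprocessConfig", "NucleusInstanceMap", "TrainingSample",
    "resize_image", "normalize_and_project", "enhance_and_denoise",
    "segment_instances", "classify_states", "build_training_sample",
    "prepare_sample",
]


@dataclass
class PreprocessConfig:
    """Tunables of the preparation pipeline (pixel units).

    clahe_clip of 2 follows the 256-bin convention (cap = clip/256 of the
    tile histogram); clahe_tiles is the number of tiles per image side.
    peak_min_distance / peak_rel_threshold govern watershed marker
    selection on the distance map.
    """

    resize_to: tuple[int, int] | None = None
    clahe_clip: float = 2.0
    clahe_tiles: int = 8
    gaussian_sigma: float = 1.0
    gaussian_passes: int = 4
    median_size: int = 3
    median_passes: int = 12
    peak_min_distance: int = 7
    peak_rel_threshold: float = 0.3


@dataclass
class NucleusInstanceMap:
    """Integer-labelled nucleus map (0 = background) with per-label states."""

    labels: np.ndarray
    states: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValueError("instance labels must be contiguous 1..K")

    @property
    def n_instances(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def state_mask(self, state: str) -> np.ndarray:
        """Boolean union of all instances with the given state."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for lbl, s in self.states.items():
            if s == state:
                out |= self.labels == lbl
        return out

    def class_map(self) -> np.ndarray:
        """Per-pixel {0: healthy, 1: apoptotic, 2: background} map."""
        out = np.full(self.labels.shape, BACKGROUND, dtype=np.int64)
        out[self.state_mask("healthy")] = HEALTHY
        out[self.state_mask("apoptotic")] = APOPTOTIC
        return out


@dataclass
class TrainingSample:
    """One paired training example, all float arrays in [0, 1]."""

    bright_field: np.ndarray  # (S, H, W)
    target: np.ndarray        # (2, H, W): healthy, apoptotic
    class_mask: np.ndarray    # (H, W) in {0, 1, 2}


def resize_image(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return transform.resize(img, shape, preserve_range=True, anti_aliasing=True)


def minmax_rescale(img: np.ndarray, out_max: float = 255.0) -> np.ndarray:
    """Min–max normalize one image to [0, out_max]; flat images map to zero."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        logger.warning("flat image in min–max normalization; mapped to zeros")
        return np.zeros_like(img)
    return (img - lo) * (out_max / (hi - lo))


def normalize_and_project(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice min–max normalization to [0, 255] + max-intensity projection."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a (S,H,W) stack, got shape {stack.shape}")
    normalized = np.stack([minmax_rescale(s) for s in stack])
    return normalized, normalized.max(axis=0)


def apply_clahe(img: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    cfg = config or PreprocessConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.max() <= img.min():
        return img.copy()
    h, w = img.shape
    kernel = (max(1, h // cfg.clahe_tiles), max(1, w // cfg.clahe_tiles))
    out = exposure.equalize_adapthist(
        np.clip(img / 255.0, 0.0, 1.0), kernel_size=kernel,
        clip_limit=cfg.clahe_clip / 256.0,
    )
    return out * 255.0


def enhance_and_denoise(img: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """CLAHE, then iterated Gaussian smoothing and median filtering."""
    cfg = config or PreprocessConfig()
    out = apply_clahe(img, cfg)
    for _ in range(cfg.gaussian_passes):
        out = ndi.gaussian_filter(out, cfg.gaussian_sigma, mode="nearest")
    for _ in range(cfg.median_passes):
        out = ndi.median_filter(out, size=cfg.median_size, mode="nearest")
    return np.clip(out, 0.0, 255.0)


def segment_instances(img: np.ndarray,
                      config: PreprocessConfig | None = None) -> NucleusInstanceMap:
    """Otsu foreground split into nuclei by marker-controlled watershed.

    Markers are distance-map local maxima at least ``peak_min_distance``
    apart and above ``peak_rel_threshold`` of the maximum distance;
    8-connectivity throughout. Foreground components the peaks miss get
    their own label, so the labels tile the Otsu mask exactly.
    """
    cfg = config or PreprocessConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.max() == img.min():
        return NucleusInstanceMap(np.zeros(img.shape, dtype=np.int64))
    mask = img > filters.threshold_otsu(img)
    if not mask.any():
        return NucleusInstanceMap(np.zeros(img.shape, dtype=np.int64))
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist,
        min_distance=cfg.peak_min_distance,
        threshold_abs=cfg.peak_rel_threshold * dist.max(),
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int64)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    struct8 = np.ones((3, 3), bool)
    if markers.max() == 0:
        labels, _ = ndi.label(mask, structure=struct8)
    else:
        labels = watershed(-dist, markers, mask=mask, connectivity=2)
        # components without a marker stay 0 inside the mask: label them too
        orphan = mask & (labels == 0)
        if orphan.any():
            extra, n_extra = ndi.label(orphan, structure=struct8)
            labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    # make labels contiguous 1..K
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int64)
    remap[present] = np.arange(1, len(present) + 1)
    return NucleusInstanceMap(remap[labels])


def instance_stds(instances: NucleusInstanceMap, max_image: np.ndarray) -> dict[int, float]:
    img = np.asarray(max_image, dtype=np.float64)
    return {
        lbl: float(img[instances.labels == lbl].std())
        for lbl in range(1, instances.n_instances + 1)
    }


def classify_states(instances: NucleusInstanceMap, max_image: np.ndarray,
                    overrides: dict[int, str] | None = None) -> NucleusInstanceMap:
    """Assign health states by a 1-D Otsu split of per-nucleus intensity std.

    Fragmented (apoptotic) nuclei have higher internal intensity variance
    than intact smooth ones, so the higher-std Otsu group is labelled
    apoptotic. A single nucleus, or identical stds, cannot be split: all
    are assigned healthy with a warning (the early-timepoint convention).
    ``overrides`` maps labels to states and replicates manual curation.
    """
    k = instances.n_instances
    states: dict[int, str] = {}
    if k:
        stds = instance_stds(instances, max_image)
        values = np.array([stds[l] for l in range(1, k + 1)])
        if k == 1 or np.allclose(values, values[0]):
            logger.warning(
                "cannot Otsu-split %d nucleus/nuclei with indistinguishable "
                "intensity std; all assigned healthy", k
            )
            states = {l: "healthy" for l in range(1, k + 1)}
        else:
            thresh = filters.threshold_otsu(values)
            states = {
                l: "apoptotic" if stds[l] > thresh else "healthy"
                for l in range(1, k + 1)
            }
    for lbl, state in (overrides or {}).items():
        if state not in ("healthy", "apoptotic"):
            raise ValueError(f"override state must be healthy/apoptotic, got {state!r}")
        states[lbl] = state
    return NucleusInstanceMap(instances.labels.copy(), states)


def build_training_sample(center_slice: np.ndarray, instances: NucleusInstanceMap,
                          bf_stack: np.ndarray) -> TrainingSample:
    """Split the CLAHE'd center slice into per-state channels; normalize
    the bright-field stack. The two target channels have disjoint support."""
    if not instances.states and instances.n_instances:
        raise ValueError("instances must have states assigned (run classify_states)")
    center = np.asarray(center_slice, dtype=np.float64) / 255.0
    target = np.stack([
        center * instances.state_mask("healthy"),
        center * instances.state_mask("apoptotic"),
    ])
    bf = np.asarray(bf_stack, dtype=np.float64)
    bright = np.stack([minmax_rescale(s, out_max=1.0) for s in bf])
    return TrainingSample(bright, target, instances.class_map())


def prepare_sample(fluor_stack: np.ndarray, bf_stack: np.ndarray,
                   config: PreprocessConfig | None = None,
                   overrides: dict[int, str] | None = None):
    """Full pipeline: raw stacks → (TrainingSample, instances, max_image)."""
    cfg = config or PreprocessConfig()
    fluor = np.asarray(fluor_stack, dtype=np.float64)
    if cfg.resize_to is not None:
        fluor = np.stack([resize_image(s, cfg.resize_to) for s in fluor])
        bf_stack = np.stack([resize_image(s, cfg.resize_to) for s in bf_stack])
    _, max_image = normalize_and_project(fluor)
    denoised = enhance_and_denoise(max_image, cfg)
    instances = segment_instances(denoised, cfg)
    instances = classify_states(instances, max_image, overrides)
    center = apply_clahe(
        minmax_rescale(fluor[fluor.shape[0] // 2]), cfg
    )
    sample = build_training_sample(center, instances, bf_stack)
    return sample, instances, max_image
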