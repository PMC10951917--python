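"""Nucleus-level detection/classification scoring and the slice-count
experiment harness.

Detection scoring compares the predicted 3-class mask against a
ground-truth instance map: predicted nuclei are 8-connected components
of the argmax foreground, matched one-to-one to truth instances by
maximal overlap (intersection-over-truth ≥ a threshold, default 0.3).
Unmatched predictions are false positives (rate over the number of
detections), unmatched truths are false negatives (rate over the number
of truth nuclei), and matched pairs are scored by the component's
majority predicted class against the true state. Raw counts are kept on
the report so any normalization convention can be recomputed.

The slice-count harness extracts centered sub-stacks from 13-slice
bright-field stacks — either contiguous slices at the native 0.3 μm
separation (growing depth) or wider separations chosen to keep a fixed
3.6 μm total depth — and trains/evaluates an identical model per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .preprocessing import APOPTOTIC, BACKGROUND, HEALTHY, NucleusInstanceMap

__all__ = [
    "DetectionReport",
    "score_detection",
    "SliceExperimentSpec",
    "substack_indices",
    "slice_experiment",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DetectionReport:
    """Confusion summary of nucleus detection + state classification."""

    n_true: int
    n_detected: int
    n_matched: int
    n_correct: int
    n_h_to_a: int
    n_a_to_h: int
    n_false_positive: int
    n_false_negative: int

    @property
    def accuracy(self) -> float:
        """Correctly detected-and-classified fraction of truth nuclei
        (1 for an empty scene with no detections)."""
        return self.n_correct / self.n_true if self.n_true else 1.0

    @property
    def false_positive_rate(self) -> float:
        return self.n_false_positive / self.n_detected if self.n_detected else 0.0

    @property
    def false_negative_rate(self) -> float:
        return self.n_false_negative / self.n_true if self.n_true else 0.0

    @property
    def h_to_a_rate(self) -> float:
        return self.n_h_to_a / self.n_true if self.n_true else 0.0

    @property
    def a_to_h_rate(self) -> float:
        return self.n_a_to_h / self.n_true if self.n_true else 0.0

    @property
    def misclassification_rate(self) -> float:
        return self.h_to_a_rate + self.a_to_h_rate

    def as_dict(self) -> dict:
        return {
            "n_true": self.n_true, "n_detected": self.n_detected,
            "n_matched": self.n_matched, "accuracy": self.accuracy,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
            "misclassification_rate": self.misclassification_rate,
            "h_to_a_rate": self.h_to_a_rate, "a_to_h_rate": self.a_to_h_rate,
        }


def _predicted_instances(pred_classes: np.ndarray):
    """8-connected components of the non-background argmax, with their
    majority class."""
    fg = pred_classes != BACKGROUND
    labels, n = ndi.label(fg, structure=_STRUCT8)
    comps = []
    for lbl in range(1, n + 1):
        m = labels == lbl
        classes = pred_classes[m]
        cls = HEALTHY if (classes == HEALTHY).sum() >= (classes == APOPTOTIC).sum() \
            else APOPTOTIC
        comps.append((m, cls))
    return comps


def score_detection(pred_mask: np.ndarray, truth: NucleusInstanceMap,
                    overlap_threshold: float = 0.3) -> DetectionReport:
    """Score a predicted mask against truth instances.

    ``pred_mask`` is a (3,H,W) probability map (argmax is taken) or an
    (H,W) class map in {0,1,2}.
    """
    pred_mask = np.asarray(pred_mask)
    if pred_mask.ndim == 3:
        classes = pred_mask.argmax(axis=0)
    else:
        classes = pred_mask.astype(np.int64)
    if classes.shape != truth.labels.shape:
        raise ValueError("prediction and truth shapes differ")
    comps = _predicted_instances(classes)
    n_true = truth.n_instances
    state_code = {"healthy": HEALTHY, "apoptotic": APOPTOTIC}
    # overlap fractions (intersection over truth area)
    pairs = []
    for ci, (m, _) in enumerate(comps):
        hits = truth.labels[m]
        hits = hits[hits > 0]
        if hits.size == 0:
            continue
        for lbl in np.unique(hits):
            frac = (hits == lbl).sum() / (truth.labels == lbl).sum()
            if frac >= overlap_threshold:
                pairs.append((frac, ci, int(lbl)))
    # greedy one-to-one matching by descending overlap
    pairs.sort(key=lambda t: -t[0])
    used_c: set[int] = set()
    used_t: set[int] = set()
    n_correct = n_h_to_a = n_a_to_h = 0
    for _, ci, lbl in pairs:
        if ci in used_c or lbl in used_t:
            continue
        used_c.add(ci)
        used_t.add(lbl)
        true_state = truth.states.get(lbl)
        pred_cls = comps[ci][1]
        if pred_cls == state_code.get(true_state):
            n_correct += 1
        elif true_state == "healthy":
            n_h_to_a += 1
        else:
            n_a_to_h += 1
    n_matched = len(used_t)
    return DetectionReport(
        n_true=n_true, n_detected=len(comps), n_matched=n_matched,
        n_correct=n_correct, n_h_to_a=n_h_to_a, n_a_to_h=n_a_to_h,
        n_false_positive=len(comps) - len(used_c),
        n_false_negative=n_true - n_matched,
    )


def nucleus_report(pred_mask: np.ndarray) -> list[dict]:
    """Per-nucleus rows (label, state, area, centroid) for the argmax mask."""
    pred_mask = np.asarray(pred_mask)
    classes = pred_mask.argmax(axis=0) if pred_mask.ndim == 3 else pred_mask
    rows = []
    for i, (m, cls) in enumerate(_predicted_instances(classes), start=1):
        ys, xs = np.nonzero(m)
        rows.append({
            "label": i,
            "state": "healthy" if cls == HEALTHY else "apoptotic",
            "area": int(m.sum()),
            "centroid_y": round(float(ys.mean()), 2),
            "centroid_x": round(float(xs.mean()), 2),
        })
    return rows


# ------------------------------------------------------------ slice counts
@dataclass
class SliceExperimentSpec:
    """Arms of the slice-count experiment.

    mode "fixed_separation" keeps the native inter-slice separation (the
    stack depth grows with the slice count); "fixed_depth" widens the
    separation so every arm spans the full source-stack depth. Slice
    counts must be odd so all arms share the same middle layer.
    """

    slice_counts: tuple[int, ...] = (1, 3, 5, 7)
    mode: str = "fixed_separation"
    separation_um: float = 0.3
    source_slices: int = 13
    source_spacing_um: float = 0.3

    def __post_init__(self):
        if any(c % 2 == 0 for c in self.slice_counts):
            raise ValueError("slice counts must be odd (same middle layer)")
        if self.mode not in ("fixed_separation", "fixed_depth"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def source_depth_um(self) -> float:
        return (self.source_slices - 1) * self.source_spacing_um


def substack_indices(n_slices: int, spec: SliceExperimentSpec) -> list[int]:
    """Centered source-slice indices for one arm; nearest-slice rounding
    (with a warning) when the requested separation is off the grid."""
    import logging

    center = spec.source_slices // 2
    if n_slices == 1:
        return [center]
    if spec.mode == "fixed_separation":
        sep_um = spec.separation_um
    else:
        sep_um = spec.source_depth_um / (n_slices - 1)
    step = sep_um / spec.source_spacing_um
    if abs(step - round(step)) > 1e-9:
        logging.getLogger(__name__).warning(
            "separation %.3g μm is not on the %.3g μm slice grid; "
            "rounding to the nearest slice", sep_um, spec.source_spacing_um)
    half = (n_slices - 1) // 2
    idx = [center + int(round(k * step)) for k in range(-half, half + 1)]
    if idx[0] < 0 or idx[-1] >= spec.source_slices:
        raise ValueError(
            f"{n_slices} slices at {sep_um:.3g} μm exceed the source stack")
    return idx


def slice_experiment(spec: SliceExperimentSpec, dataset, *, gen_config=None,
                     train_config=None, loss_config=None, epochs: int = 10) -> pd.DataFrame:
    """Train and evaluate one identical model per arm; returns a table of
    test-split MAE/SSIM/PSNR per slice count."""
    from .generator import GeneratorConfig
    from .training import TranslationGAN, scene_to_sample

    scenes = dataset.scenes
    split = dataset.split
    rows = []
    for n in spec.slice_counts:
        idx = substack_indices(n, spec)
        samples = []
        for sc in scenes:
            s = scene_to_sample(sc)
            samples.append(type(s)(s.bright_field[idx], s.target, s.class_mask))
        base = gen_config or GeneratorConfig()
        gcfg = replace(base, input_slices=n)
        model = TranslationGAN((samples, split), gcfg,
                               loss_config=loss_config, train_config=train_config)
        result = model.fit(epochs=epochs)
        model.generator.load_state_dict(result.best_state)
        test_metrics = model.validate("test")
        depth = 0.0 if n == 1 else (idx[-1] - idx[0]) * spec.source_spacing_um
        rows.append({"n_slices": n, "mode": spec.mode,
                     "separation_um": 0.0 if n == 1 else
                     (idx[1] - idx[0]) * spec.source_spacing_um,
                     "depth_um": depth, **test_metrics})
    return pd.DataFrame(rows)
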