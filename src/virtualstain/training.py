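"""Adversarial training: augmentation, alternating optimization,
cross-validation fold rotation and checkpointing.

:class:`TranslationGAN` is the model object: it owns the generator, the
patch discriminator and the dataset split; :meth:`TranslationGAN.fit`
runs the alternating Adam optimization (one discriminator step per
generator step, β = (0.5, 0.999), two-time-scale learning rates) and
returns a :class:`TrainingResult` carrying the per-epoch loss/metric
history, the best-validation checkpoint and a ``summary()`` table.

Each epoch every training sample is augmented with random flips,
90°-multiple rotations (mask-safe — no interpolation) and a random crop;
the train/validation folds are reshuffled every ``fold_rotation_period``
epochs while the test split never moves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autograd import Tensor
from .discriminator import DiscriminatorConfig, PatchDiscriminator
from .generator import Generator, GeneratorConfig, build_generator
from .losses import (LossConfig, adversarial_losses, conventional_loss,
                     mask_loss, mask_weight, metrics, total_generator_loss)
from .nn import Adam
from .preprocessing import TrainingSample
from .synthetic import ScenePair, SyntheticDataset

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "augment", "TranslationGAN", "TrainingResult", "train"]


@dataclass
class TrainConfig:
    """Optimization settings (desk-scale defaults)."""

    batch_size: int = 8
    epochs: int = 50
    lr_G: float = 1e-4
    lr_D: float = 4e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    crop_size: int | None = None  # None → no crop (full frames)
    flip_prob: float = 0.5
    fold_rotation_period: int = 50
    validate_every: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _transform(arr: np.ndarray, flip_h: bool, flip_v: bool, k: int,
               top: int, left: int, crop: int | None) -> np.ndarray:
    """Apply one geometric transform to the trailing two axes."""
    if flip_h:
        arr = arr[..., :, ::-1]
    if flip_v:
        arr = arr[..., ::-1, :]
    arr = np.rot90(arr, k, axes=(-2, -1))
    if crop is not None:
        arr = arr[..., top : top + crop, left : left + crop]
    return np.ascontiguousarray(arr)


def augment(sample: TrainingSample, seed: int, crop_size: int | None = None,
            flip_prob: float = 0.5) -> TrainingSample:
    """Random flips and 90°-multiple rotations, then a random crop.

    The identical geometric transform is applied to the bright-field
    stack, the target channels and the class mask, so pixel classes move
    with their pixels.
    """
    rng = np.random.default_rng(seed)
    h, w = sample.class_mask.shape
    if crop_size is not None and (crop_size > h or crop_size > w):
        raise ValueError(f"crop_size {crop_size} exceeds sample size {h}x{w}")
    flip_h = rng.random() < flip_prob
    flip_v = rng.random() < flip_prob
    k = int(rng.integers(0, 4))
    if crop_size is not None:
        # rotation by odd k swaps H/W; with square crops only the valid
        # offset ranges matter, computed on the post-rotation shape
        hh, ww = (w, h) if k % 2 else (h, w)
        top = int(rng.integers(0, hh - crop_size + 1))
        left = int(rng.integers(0, ww - crop_size + 1))
    else:
        top = left = 0
    args = (flip_h, flip_v, k, top, left, crop_size)
    return TrainingSample(
        _transform(sample.bright_field, *args),
        _transform(sample.target, *args),
        _transform(sample.class_mask, *args),
    )


def scene_to_sample(scene: ScenePair) -> TrainingSample:
    return TrainingSample(scene.bright_field, scene.fluorescent_target,
                          scene.class_mask)


@dataclass
class TrainingResult:
    """Fit artifacts: history, best checkpoint and evaluation helpers."""

    history: pd.DataFrame
    generator: Generator
    discriminator: PatchDiscriminator
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_mae: float
    gen_config: GeneratorConfig
    diverged: bool = False

    def summary(self) -> str:
        h = self.history
        lines = [
            "Bright-field → fluorescence translation GAN",
            "=" * 46,
            f"variant            {self.gen_config.variant}",
            f"placement code     {self.gen_config.placement}",
            f"attention modules  {self.generator.n_attention_modules}",
            f"parameters (G)     {self.generator.n_parameters():,}",
            f"epochs run         {len(h)}",
            f"best epoch         {self.best_epoch}",
            f"best val MAE       {self.best_val_mae:.4f}",
        ]
        if len(h):
            last = h.iloc[-1]
            lines += [
                f"final loss_D       {last['loss_D']:.4f}",
                f"final loss_G       {last['loss_G']:.4f}",
            ]
            if np.isfinite(last.get("val_ssim", np.nan)):
                lines.append(f"final val SSIM     {last['val_ssim']:.4f}")
                lines.append(f"final val PSNR     {last['val_psnr']:.2f} dB")
        if self.diverged:
            lines.append("WARNING: run aborted on non-finite loss; "
                         "best checkpoint retained")
        return "\n".join(lines)

    def restore_best(self) -> Generator:
        """Load the best-validation parameters into the generator."""
        self.generator.load_state_dict(self.best_state)
        return self.generator

    def save(self, path):
        """Persist the best-validation generator + its config (.npz)."""
        save_checkpoint(path, self.gen_config, self.best_state)

    def plot_history(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
        self.history.plot(x="epoch", y=["loss_D", "loss_G_adv"], ax=axes[0])
        axes[0].set_ylabel("adversarial loss")
        self.history.plot(x="epoch", y="val_mae", ax=axes[1])
        axes[1].set_ylabel("validation MAE")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class TranslationGAN:
    """Conditional GAN fitted to paired bright-field/fluorescence scenes.

    Parameters
    ----------
    dataset : :class:`~virtualstain.synthetic.SyntheticDataset`, or a
        ``(samples, split)`` pair where ``samples`` is a list of
        :class:`~virtualstain.preprocessing.TrainingSample` and ``split``
        maps "train"/"val"/"test" to index lists.
    gen_config, disc_config, loss_config, train_config : module configs;
        omitted ones take their defaults, with the discriminator sized to
        match the generator's slices and output channels.
    """

    def __init__(self, dataset, gen_config: GeneratorConfig | None = None,
                 disc_config: DiscriminatorConfig | None = None,
                 loss_config: LossConfig | None = None,
                 train_config: TrainConfig | None = None):
        if isinstance(dataset, SyntheticDataset):
            self.samples = [scene_to_sample(s) for s in dataset.scenes]
            self.split = {k: list(v) for k, v in dataset.split.items()}
        else:
            samples, split = dataset
            self.samples = list(samples)
            self.split = {k: list(v) for k, v in split.items()}
        if not self.split.get("train"):
            raise ValueError("training split is empty")
        s = self.samples[0].bright_field.shape[0]
        self.gen_config = gen_config or GeneratorConfig(input_slices=s)
        self.disc_config = disc_config or DiscriminatorConfig(
            input_slices=self.gen_config.input_slices,
            image_channels=self.gen_config.out_channels,
            base_channels=max(8, self.gen_config.base_channels // 2),
            seed=self.gen_config.seed + 1,
        )
        self.loss_config = loss_config or LossConfig()
        self.train_config = train_config or TrainConfig()
        self.generator = build_generator(self.gen_config)
        self.discriminator = PatchDiscriminator(self.disc_config)

    # ------------------------------------------------------------- internals
    def _target_for_variant(self, target: np.ndarray) -> np.ndarray:
        if self.gen_config.out_channels == 1:
            return target.max(axis=0, keepdims=True)
        return target

    def _batch(self, idx: list[int], rng: np.random.Generator):
        cfg = self.train_config
        xs, ys, ls = [], [], []
        for i in idx:
            aug = augment(self.samples[i], int(rng.integers(2**31 - 1)),
                          cfg.crop_size, cfg.flip_prob)
            xs.append(aug.bright_field)
            # targets keep the dark background at 0 (inside the Tanh range);
            # the gated product vanishes exactly where the mask says background
            ys.append(self._target_for_variant(aug.target))
            ls.append(aug.class_mask)
        return np.stack(xs), np.stack(ys), np.stack(ls)

    def _rotate_folds(self, rng: np.random.Generator):
        pool = sorted(self.split["train"] + self.split.get("val", []))
        n_val = len(self.split.get("val", []))
        order = rng.permutation(len(pool))
        pool = [pool[i] for i in order]
        self.split["val"] = sorted(pool[:n_val])
        self.split["train"] = sorted(pool[n_val:])
        test = set(self.split.get("test", []))
        assert not test & set(self.split["train"] + self.split["val"]), \
            "fold rotation leaked a test scene"

    def validate(self, subset: str = "val") -> dict[str, float]:
        """Mean MAE/SSIM/PSNR over a split, on the [0, 1] intensity scale."""
        idx = self.split.get(subset, [])
        if not idx:
            return {"mae": np.nan, "ssim": np.nan, "psnr": np.nan}
        self.generator.eval()
        rows = []
        for i in idx:
            s = self.samples[i]
            out = self.generator(Tensor(s.bright_field[None]))
            rows.append(metrics(out.translation.data[0],
                                self._target_for_variant(s.target),
                                data_range=1.0))
        self.generator.train()
        return {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}

    # ------------------------------------------------------------------ fit
    def fit(self, epochs: int | None = None, verbose: bool = False) -> TrainingResult:
        cfg = self.train_config
        n_epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed)
        fold_rng = np.random.default_rng(cfg.seed + 1)
        g, d = self.generator, self.discriminator
        opt_g = Adam(g.parameters(), lr=cfg.lr_G, betas=cfg.adam_betas)
        opt_d = Adam(d.parameters(), lr=cfg.lr_D, betas=cfg.adam_betas)
        rows = []
        best_state = g.state_dict()
        best_epoch, best_val = -1, np.inf
        diverged = False
        for epoch in range(n_epochs):
            if epoch and cfg.fold_rotation_period and \
                    epoch % cfg.fold_rotation_period == 0:
                self._rotate_folds(fold_rng)
            order = rng.permutation(self.split["train"])
            ep = {"loss_D": [], "loss_G_adv": [], "loss_conv": [], "loss_mask": []}
            for start in range(0, len(order), cfg.batch_size):
                idx = [int(i) for i in order[start : start + cfg.batch_size]]
                x, y, labels = self._batch(idx, rng)
                xt, yt = Tensor(x), Tensor(y)
                out = g(xt)
                # --- discriminator step (generator output detached)
                d.zero_grad()
                real_scores = d(xt, yt)
                fake_scores = d(xt, out.translation.detach())
                loss_d, _ = adversarial_losses(real_scores, fake_scores)
                loss_d.backward()
                opt_d.step()
                # --- generator step (one D step per G step)
                g.zero_grad()
                d.zero_grad()
                fake_scores = d(xt, out.translation)
                _, loss_g_adv = adversarial_losses(
                    Tensor(real_scores.data), fake_scores)
                conv = conventional_loss(out.translation, yt, self.loss_config)
                if out.mask is not None:
                    lmask = mask_loss(out.mask, labels)
                else:
                    lmask = Tensor(0.0)
                loss_g = total_generator_loss(loss_g_adv, conv, lmask, epoch,
                                              self.loss_config)
                loss_g.backward()
                opt_g.step()
                vals = (float(loss_d.data), float(loss_g_adv.data),
                        float(conv.data), float(lmask.data))
                if not all(np.isfinite(v) for v in vals):
                    logger.error("non-finite loss at epoch %d; aborting with "
                                 "last good checkpoint", epoch)
                    diverged = True
                    break
                for k, v in zip(ep, vals):
                    ep[k].append(v)
            if diverged:
                break
            row = {"epoch": epoch,
                   **{k: float(np.mean(v)) if v else np.nan for k, v in ep.items()},
                   "mask_weight": mask_weight(epoch, self.loss_config)}
            row["loss_G"] = (row["loss_G_adv"]
                             + self.loss_config.lambda_conv * row["loss_conv"]
                             + row["mask_weight"] * row["loss_mask"])
            if epoch % cfg.validate_every == 0 or epoch == n_epochs - 1:
                val = self.validate()
                row.update({f"val_{k}": v for k, v in val.items()})
                if np.isfinite(val["mae"]) and val["mae"] < best_val:
                    best_val, best_epoch = val["mae"], epoch
                    best_state = g.state_dict()
            rows.append(row)
            if verbose:
                logger.info("epoch %d: %s", epoch,
                            {k: round(v, 4) for k, v in row.items() if k != "epoch"})
        if best_epoch < 0:
            best_state, best_epoch = g.state_dict(), len(rows) - 1
        history = pd.DataFrame(rows)
        return TrainingResult(history, g, d, best_state, best_epoch,
                              float(best_val), self.gen_config, diverged)


def train(dataset, g_config=None, d_config=None, l_config=None,
          t_config=None, **fit_kwargs) -> TrainingResult:
    """Functional wrapper: build a :class:`TranslationGAN` and fit it."""
    model = TranslationGAN(dataset, g_config, d_config, l_config, t_config)
    return model.fit(**fit_kwargs)


def save_checkpoint(path, gen_config: GeneratorConfig, state: dict[str, np.ndarray]):
    import dataclasses
    import json

    meta = json.dumps(dataclasses.asdict(gen_config))
    np.savez_compressed(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **state)


def load_generator(path) -> Generator:
    """Rebuild a generator from a checkpoint written by
    :func:`save_checkpoint` / :meth:`TrainingResult.save`."""
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__config__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    meta["placement"] = str(meta["placement"])
    for key in ("adam_betas",):
        meta.pop(key, None)
    cfg = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in meta.items()})
    g = build_generator(cfg)
    g.load_state_dict(state)
    return g
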