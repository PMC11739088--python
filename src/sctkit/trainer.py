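"""Cycle-GAN training orchestration and MR -> synthetic-CT inference.

Optimisation follows the adversarial-translation conventions: Adam
(beta1 = 0.5), batch size 1, generators updated first on the combined
bidirectional objective, then each discriminator on its least-squares loss
against a 50-image replay pool of past fakes.  The learning rate is constant
(1e-4) for the first 30 epochs, then decays linearly to exactly zero at the
final epoch.

Four ablation arms select the generator variant and the structural loss:
``baseline`` (residual generator, no MIND), ``swin_only`` (attention
generator, no MIND), ``mind_only`` (residual generator + MIND), ``proposed``
(attention generator + MIND).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import ImageGrid, Modality
from .mind import MINDConfig
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    build_discriminator,
    build_generator,
    save_checkpoint,
)
from .nn import Adam, Tensor
from .nn.functional import mind_loss_t
from .objective import LossReport, LossWeights, adversarial_losses, cycle_loss, identity_loss, total_losses
from .preprocess import mr_to_net, net_to_ct
from . import preprocess

__all__ = ["ARMS", "TrainConfig", "TrainResult", "lr_at_epoch", "ImagePool",
           "train", "synthesize", "naive_affine_sct"]

# arm -> (generator variant, use_mind)
ARMS: Dict[str, Tuple[str, bool]] = {
    "baseline": ("resnet_baseline", False),
    "swin_only": ("swin_unetr_2d", False),
    "mind_only": ("resnet_baseline", True),
    "proposed": ("swin_unetr_2d", True),
}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr: float = 1e-4
    decay_start_epoch: int = 30
    image_size: int = 256
    batch_size: int = 1
    seed: int = 0
    pool_size: int = 50
    arm: str = "proposed"
    weights: LossWeights = field(default_factory=LossWeights)
    # capacity knobs (paper-scale defaults; see desk() for the test preset)
    embed_dim: int = 24
    depths: Tuple[int, ...] = (2, 2, 2)
    heads: Tuple[int, ...] = (2, 4, 8)
    window_size: int = 4
    base_width: int = 16
    n_res_blocks: int = 4
    disc_width: int = 16
    checkpoint_every: int = 0  # 0: final checkpoint only

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {sorted(ARMS)}")
        if not (0 < self.decay_start_epoch < self.epochs):
            raise ValueError("require 0 < decay_start_epoch < epochs")
        if self.lr <= 0:
            raise ValueError("lr must be positive")

    @property
    def generator_variant(self) -> str:
        return ARMS[self.arm][0]

    @property
    def use_mind(self) -> bool:
        return ARMS[self.arm][1]

    def generator_spec(self) -> GeneratorSpec:
        return GeneratorSpec(
            variant=self.generator_variant,
            embed_dim=self.embed_dim,
            depths=self.depths,
            heads=self.heads,
            window_size=self.window_size,
            base_width=self.base_width,
            n_res_blocks=self.n_res_blocks,
        )

    def discriminator_spec(self) -> DiscriminatorSpec:
        return DiscriminatorSpec(base_width=self.disc_width)

    @classmethod
    def desk(cls, arm: str = "proposed", epochs: int = 10, seed: int = 0, **kw) -> "TrainConfig":
        """Small-capacity preset for 64x64 phantom runs on one CPU."""
        defaults = dict(
            epochs=epochs, decay_start_epoch=max(1, min(3, epochs - 1)), image_size=64,
            seed=seed, arm=arm, embed_dim=24, depths=(2, 2, 2), heads=(2, 4, 8),
            window_size=4, base_width=8, n_res_blocks=2, disc_width=8,
        )
        defaults.update(kw)
        return cls(**defaults)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate for a 1-based epoch: constant through the decay-start
    epoch, then linear to exactly 0 at the final epoch."""
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside 1..{cfg.epochs}")
    if epoch <= cfg.decay_start_epoch:
        return cfg.lr
    return cfg.lr * (cfg.epochs - epoch) / (cfg.epochs - cfg.decay_start_epoch)


class ImagePool:
    """Replay pool of past generated images for discriminator updates: once
    full, each query swaps with a stored fake half of the time."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.images: List[np.ndarray] = []

    def query(self, img: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return img
        if len(self.images) < self.size:
            self.images.append(img.copy())
            return img
        if self.rng.random() < 0.5:
            k = int(self.rng.integers(0, self.size))
            out = self.images[k]
            self.images[k] = img.copy()
            return out
        return img


@dataclass
class TrainResult:
    G_mr2ct: object
    G_ct2mr: object
    D_ct: object
    D_mr: object
    history: pd.DataFrame       # one LossReport row per iteration
    epoch_means: pd.DataFrame   # LossReport means per epoch
    config: TrainConfig


def _to_batch(arr: np.ndarray) -> Tensor:
    return Tensor(arr.astype(np.float32)[None, None])


def train(
    cfg: TrainConfig,
    mr_set: Sequence[np.ndarray],
    ct_set: Sequence[np.ndarray],
    out_dir: Optional[str | Path] = None,
    mind_cfg: MINDConfig = MINDConfig(),
) -> TrainResult:
    """Train the bidirectional translation GAN on unpaired, [-1, 1]-scaled
    2D arrays.  Fixed seed gives a reproducible loss trajectory on a fixed
    machine.  Raises on empty sets or non-finite losses."""
    if len(mr_set) == 0 or len(ct_set) == 0:
        raise ValueError("mr_set and ct_set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    w = cfg.weights
    gen_spec = cfg.generator_spec()
    disc_spec = cfg.discriminator_spec()
    G_A = build_generator(gen_spec, seed=cfg.seed * 4 + 1)   # MR -> CT
    G_B = build_generator(gen_spec, seed=cfg.seed * 4 + 2)   # CT -> MR
    D_ct = build_discriminator(disc_spec, seed=cfg.seed * 4 + 3)
    D_mr = build_discriminator(disc_spec, seed=cfg.seed * 4 + 4)

    opt_G = Adam(G_A.parameters() + G_B.parameters(), lr=cfg.lr)
    opt_D = Adam(D_ct.parameters() + D_mr.parameters(), lr=cfg.lr)
    pool_ct = ImagePool(cfg.pool_size, np.random.default_rng(cfg.seed + 101))
    pool_mr = ImagePool(cfg.pool_size, np.random.default_rng(cfg.seed + 102))

    n_iter = min(len(mr_set), len(ct_set))
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_at_epoch(cfg, epoch)
        opt_G.lr = lr
        opt_D.lr = lr
        order_mr = rng.permutation(len(mr_set))[:n_iter]
        order_ct = rng.permutation(len(ct_set))[:n_iter]
        for i_mr, i_ct in zip(order_mr, order_ct):
            mr = _to_batch(mr_set[i_mr])
            ct = _to_batch(ct_set[i_ct])

            # ---- generators -------------------------------------------------
            fake_ct = G_A(mr)
            rec_mr = G_B(fake_ct)
            fake_mr = G_B(ct)
            rec_ct = G_A(fake_mr)
            idt_ct = G_A(ct)
            idt_mr = G_B(mr)

            adv_g_mr2ct, _ = adversarial_losses(Tensor(0.0), D_ct(fake_ct), w)
            adv_g_ct2mr, _ = adversarial_losses(Tensor(0.0), D_mr(fake_mr), w)
            cyc_mr = cycle_loss(mr, rec_mr, w)
            cyc_ct = cycle_loss(ct, rec_ct, w)
            idt_ct_l = identity_loss(ct, idt_ct, w)
            idt_mr_l = identity_loss(mr, idt_mr, w)
            total = adv_g_mr2ct + adv_g_ct2mr + cyc_mr + cyc_ct + idt_ct_l + idt_mr_l
            if cfg.use_mind:
                mind_sct = w.lambda_mind * mind_loss_t(mr, fake_ct, mind_cfg)
                mind_smr = w.lambda_mind * mind_loss_t(ct, fake_mr, mind_cfg)
                total = total + mind_sct + mind_smr
            else:
                mind_sct = mind_smr = Tensor(0.0)

            opt_G.zero_grad()
            total.backward()
            opt_G.step()

            # ---- discriminators (replay pool, detached fakes) ---------------
            opt_D.zero_grad()
            pooled_ct = pool_ct.query(fake_ct.data[0, 0])
            pooled_mr = pool_mr.query(fake_mr.data[0, 0])
            _, l_d_ct = adversarial_losses(D_ct(ct), D_ct(_to_batch(pooled_ct)), w)
            _, l_d_mr = adversarial_losses(D_mr(mr), D_mr(_to_batch(pooled_mr)), w)
            (l_d_ct + l_d_mr).backward()
            opt_D.step()

            report = total_losses(
                adv_G_mr2ct=adv_g_mr2ct.item(),
                adv_G_ct2mr=adv_g_ct2mr.item(),
                adv_D_ct=l_d_ct.item(),
                adv_D_mr=l_d_mr.item(),
                cycle_mr=cyc_mr.item(),
                cycle_ct=cyc_ct.item(),
                idt_ct=idt_ct_l.item(),
                idt_mr=idt_mr_l.item(),
                mind_sct=mind_sct.item(),
                mind_smr=mind_smr.item(),
                use_mind=cfg.use_mind,
            )
            if not np.isfinite(report.total_sct + report.total_smr + report.adv_D_ct + report.adv_D_mr):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={lr:.2e}): {report.as_dict()}"
                )
            rows.append({"epoch": epoch, **report.as_dict()})

        if out_dir is not None and cfg.checkpoint_every and epoch % cfg.checkpoint_every == 0:
            _save(out_dir, f"checkpoint_epoch{epoch:03d}.npz", G_A, G_B, D_ct, D_mr, gen_spec, disc_spec, cfg, epoch)

    history = pd.DataFrame(rows)
    epoch_means = history.groupby("epoch").mean().reset_index()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        history.to_csv(out_dir / "training_log.csv", index=False)
        _save(out_dir, "checkpoint_final.npz", G_A, G_B, D_ct, D_mr, gen_spec, disc_spec, cfg, cfg.epochs)
    return TrainResult(G_A, G_B, D_ct, D_mr, history, epoch_means, cfg)


def _save(out_dir, name, G_A, G_B, D_ct, D_mr, gen_spec, disc_spec, cfg, epoch) -> None:
    save_checkpoint(
        Path(out_dir) / name,
        models={"G_mr2ct": G_A, "G_ct2mr": G_B, "D_ct": D_ct, "D_mr": D_mr},
        specs={"G_mr2ct": gen_spec, "G_ct2mr": gen_spec, "D_ct": disc_spec, "D_mr": disc_spec},
        meta={"epoch": epoch, "arm": cfg.arm, "seed": cfg.seed},
    )


def synthesize(generator, mr: ImageGrid, already_scaled: bool = False) -> ImageGrid:
    """Run the MR -> CT generator on a preprocessed MR slice and return a
    synthetic CT in HU (fixed inverse affine; values within [-1024, 3071])."""
    arr = np.asarray(mr.values, dtype=np.float32) if already_scaled else mr_to_net(mr).astype(np.float32)
    out = generator(_to_batch(arr)).data[0, 0]
    return ImageGrid(net_to_ct(out), mr.spacing_mm, Modality.SCT)


def naive_affine_sct(mr: ImageGrid) -> ImageGrid:
    """Affine-rescaled MR pushed into the HU range: the no-learning baseline
    a trained generator must beat."""
    return ImageGrid(net_to_ct(mr_to_net(mr)), mr.spacing_mm, Modality.SCT)
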