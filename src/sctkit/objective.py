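"""The loss system of the translation GAN.

Least-squares adversarial losses (targets 1 for real, 0 for fake), L1 cycle
consistency, L1 identity, and the MIND structural term, combined per
direction as

    L_sCT = L_G(MR->CT) + L_cycle(MR) + L_idt(CT) + L_mind(sCT)
    L_sMR = L_G(CT->MR) + L_cycle(CT) + L_idt(MR) + L_mind(sMR)

with weights lambda_D = 0.5, lambda_G = 1, lambda_cycle = 10, lambda_idt = 5
and a unit MIND weight by default.  Every term is a mean over pixels (and
batch), which keeps the weights scale-free across image sizes.

All loss functions are generic over numpy arrays and autodiff tensors: they
only use arithmetic, ``abs`` and ``mean``, which both provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

__all__ = ["LossWeights", "LossReport", "adversarial_losses", "cycle_loss",
           "identity_loss", "total_losses"]


@dataclass(frozen=True)
class LossWeights:
    lambda_G: float = 1.0
    lambda_D: float = 0.5
    lambda_cycle: float = 10.0
    lambda_idt: float = 5.0
    lambda_mind: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass
class LossReport:
    """Per-term scalars for one iteration (or an epoch mean).  The totals
    are exact sums of their components."""

    adv_G_mr2ct: float = 0.0
    adv_G_ct2mr: float = 0.0
    adv_D_ct: float = 0.0
    adv_D_mr: float = 0.0
    cycle_mr: float = 0.0
    cycle_ct: float = 0.0
    idt_ct: float = 0.0
    idt_mr: float = 0.0
    mind_sct: float = 0.0
    mind_smr: float = 0.0
    total_sct: float = 0.0
    total_smr: float = 0.0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _abs(x):
    return x.abs() if hasattr(x, "abs") else np.abs(x)


def _mean(x):
    return x.mean()


def _check_shapes(a, b, what: str) -> None:
    if getattr(a, "shape", None) != getattr(b, "shape", None):
        raise ValueError(f"{what}: operands must share a grid, got {a.shape} vs {b.shape}")


def adversarial_losses(d_real, d_fake, w: LossWeights = LossWeights()):
    """Least-squares adversarial terms from discriminator score maps.

    Returns ``(L_G, L_D)``: the generator wants D(fake) near 1; the
    discriminator wants D(real) near 1 and D(fake) near 0, at half weight.
    """
    l_g = w.lambda_G * _mean((d_fake - 1.0) ** 2)
    l_d = w.lambda_D * (_mean(d_fake**2) + _mean((d_real - 1.0) ** 2))
    return l_g, l_d


def cycle_loss(original, reconstructed, w: LossWeights = LossWeights()):
    """Weighted L1 between an image and its round-trip reconstruction."""
    _check_shapes(original, reconstructed, "cycle_loss")
    return w.lambda_cycle * _mean(_abs(original - reconstructed))


def identity_loss(real, same_domain_output, w: LossWeights = LossWeights()):
    """Weighted L1 penalty for a generator altering an image already in its
    own target domain."""
    _check_shapes(real, same_domain_output, "identity_loss")
    return w.lambda_idt * _mean(_abs(real - same_domain_output))


def total_losses(
    adv_G_mr2ct: float,
    adv_G_ct2mr: float,
    adv_D_ct: float,
    adv_D_mr: float,
    cycle_mr: float,
    cycle_ct: float,
    idt_ct: float,
    idt_mr: float,
    mind_sct: float = 0.0,
    mind_smr: float = 0.0,
    use_mind: bool = True,
) -> LossReport:
    """Assemble a :class:`LossReport`; totals are bit-exact sums of their
    parts, with the MIND terms included iff ``use_mind``."""
    m_sct = mind_sct if use_mind else 0.0
    m_smr = mind_smr if use_mind else 0.0
    return LossReport(
        adv_G_mr2ct=adv_G_mr2ct,
        adv_G_ct2mr=adv_G_ct2mr,
        adv_D_ct=adv_D_ct,
        adv_D_mr=adv_D_mr,
        cycle_mr=cycle_mr,
        cycle_ct=cycle_ct,
        idt_ct=idt_ct,
        idt_mr=idt_mr,
        mind_sct=m_sct,
        mind_smr=m_smr,
        total_sct=adv_G_mr2ct + cycle_mr + idt_ct + m_sct,
        total_smr=adv_G_ct2mr + cycle_ct + idt_mr + m_smr,
    )
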