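"""Iterative self-training for the segmenter.

Semi-supervised dataset growth: a model trained on a small manually
labeled seed set predicts masks for unlabeled images; a *corrector*
(ground truth in tests, a human in practice) fixes the predictions, the
corrected pairs join the labeled set, and the model is retrained. Repeating
this grows a robust training set from a handful of manual annotations.

The corrector is just a callable ``(image, predicted_mask) -> mask``, so
the "manual validation and correction" step is fully pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import CircleROI, WellImage
from .segmentation import SegMask, SegModel, iou, predict, train_segmenter

__all__ = ["LabeledItem", "SelfTrainState", "self_train", "correction_effort"]

Corrector = Callable[[WellImage, SegMask], SegMask]


@dataclass
class LabeledItem:
    """One labeled pair with provenance of where its mask came from."""

    image: WellImage
    mask: SegMask
    provenance: str  # "manual" or "corrected_prediction"
    round_added: int = 0
    model_fingerprint: str | None = None
    pixels_corrected_frac: float | None = None


@dataclass
class SelfTrainState:
    """Bookkeeping for the self-training loop."""

    round: int = 0
    labeled: list[LabeledItem] = field(default_factory=list)
    pool: list[WellImage] = field(default_factory=list)
    history: list[float] = field(default_factory=list)  # validation IoU per round


def _validation_iou(
    model: SegModel,
    validation: Sequence[tuple[WellImage, SegMask]],
    roi: CircleROI,
) -> float:
    scores = [iou(predict(model, img, roi), msk) for img, msk in validation]
    return float(np.mean(scores))


def self_train(
    initial: Sequence[tuple[WellImage, SegMask]],
    pool: Sequence[WellImage],
    validation: Sequence[tuple[WellImage, SegMask]],
    corrector: Corrector,
    roi: CircleROI,
    rounds: int = 3,
    batch: int = 20,
    seed: int = 0,
) -> tuple[SegModel, SelfTrainState]:
    """Run the self-training loop and return the final model plus state.

    Each round: train on the current labeled set, predict on ``batch``
    pool images (consumed in a seeded random order), apply the corrector,
    move the corrected pairs into the labeled set, and record validation
    IoU. Deterministic for a fixed seed and deterministic corrector.
    """
    if len(initial) == 0:
        raise ValueError("initial labeled set must be non-empty")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)

    state = SelfTrainState(
        labeled=[LabeledItem(img, msk, "manual") for img, msk in initial],
        pool=list(pool),
    )
    order = list(rng.permutation(len(state.pool)))
    queue = [state.pool[i] for i in order]
    model: SegModel | None = None

    for rnd in range(1, rounds + 1):
        pairs = [(it.image, it.mask) for it in state.labeled]
        model = train_segmenter(pairs, seed=int(rng.integers(0, 2**31 - 1)))
        fingerprint = model.training_manifest["dataset_fingerprint"]

        take = queue[:batch]
        queue = queue[batch:]
        for img in take:
            draft = predict(model, img, roi)
            corrected = corrector(img, draft)
            if corrected.shape != draft.shape:
                raise ValueError("corrector returned a shape-mismatched mask")
            flipped = float(np.mean(corrected.pixels != draft.pixels))
            state.labeled.append(
                LabeledItem(
                    image=img,
                    mask=corrected,
                    provenance="corrected_prediction",
                    round_added=rnd,
                    model_fingerprint=fingerprint,
                    pixels_corrected_frac=flipped,
                )
            )
        state.pool = list(queue)
        state.round = rnd
        state.history.append(_validation_iou(model, validation, roi))

    assert model is not None
    return model, state


def correction_effort(state: SelfTrainState) -> list[float]:
    """Mean fraction of pixels the corrector flipped, per round.

    A falling trend means later models need less fixing — the quantity
    behind the claim that self-training cuts manual annotation effort.
    """
    if state.round < 1:
        raise ValueError("state has no completed rounds")
    out = []
    for rnd in range(1, state.round + 1):
        fracs = [
            it.pixels_corrected_frac
            for it in state.labeled
            if it.round_added == rnd and it.pixels_corrected_frac is not None
        ]
        out.append(float(np.mean(fracs)) if fracs else 0.0)
    return out
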