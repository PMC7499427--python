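"""Patch preparation and balanced-epoch augmentation.

Training inputs are 24x24 crops of the stored 32x32 patches: cropping
admits translation by up to 4 pixels either side of center in each axis
without any interpolation, and the 8 elements of the dihedral group of the
square (4 rotations x optional reflection) supply orientation variants.
Every augmentation is therefore an exact pixel rearrangement — no new
values are ever created.

Class balance within a training epoch is restored by oversampling with
replacement: benign patches by a factor of 2 and malignant patches by a
factor of ~6 (the malignant class being roughly a third of the cohort),
each sampled patch receiving an independently drawn random augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .records import PATCH_SIZE

CROP_SIZE = 24
MAX_OFFSET = PATCH_SIZE - CROP_SIZE  # 8


@dataclass(frozen=True)
class AugmentationSpec:
    """One geometric augmentation: crop offset + dihedral element.

    ``dx``/``dy`` position the 24x24 window inside the 32x32 patch
    (0..8; 4 is the centered crop). ``rotation_quarter_turns`` (0..3) and
    ``reflect`` index the 8 elements of the dihedral group D4.
    """

    dx: int = MAX_OFFSET // 2
    dy: int = MAX_OFFSET // 2
    rotation_quarter_turns: int = 0
    reflect: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.dx <= MAX_OFFSET and 0 <= self.dy <= MAX_OFFSET):
            raise ValueError(f"crop offsets must lie in 0..{MAX_OFFSET}, got ({self.dx}, {self.dy})")
        if self.rotation_quarter_turns not in (0, 1, 2, 3):
            raise ValueError(f"rotation_quarter_turns must be in 0..3, got {self.rotation_quarter_turns}")


@dataclass(frozen=True)
class EpochSamplingPlan:
    """Per-epoch oversampling factors (benign x2, malignant x~6)."""

    benign_oversample_factor: float = 2.0
    malignant_oversample_factor: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.benign_oversample_factor < 1 or self.malignant_oversample_factor < 1:
            raise ValueError("oversample factors must be >= 1")

    @classmethod
    def exact_balance(cls, n_benign: int, n_malignant: int, seed: int = 0) -> "EpochSamplingPlan":
        """Benign x2 with the malignant factor chosen so expected class
        counts are exactly equal (2 * n_benign / n_malignant)."""
        if n_benign < 1 or n_malignant < 1:
            raise ValueError("need at least one patch of each class")
        return cls(2.0, 2.0 * n_benign / n_malignant, seed)


def apply_augmentation(patch_32: np.ndarray, spec: AugmentationSpec) -> np.ndarray:
    """Crop to 24x24 at (dy, dx), then rotate/reflect. Pure rearrangement."""
    patch_32 = np.asarray(patch_32)
    if patch_32.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"expected a {PATCH_SIZE}x{PATCH_SIZE} patch, got shape {patch_32.shape}")
    if not np.all(np.isfinite(patch_32)):
        raise ValueError("patch contains non-finite values")
    window = patch_32[spec.dy : spec.dy + CROP_SIZE, spec.dx : spec.dx + CROP_SIZE]
    out = np.rot90(window, k=spec.rotation_quarter_turns)
    if spec.reflect:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def center_crop(patch_32: np.ndarray) -> np.ndarray:
    """The untouched central 24x24 window (inference-time input)."""
    return apply_augmentation(patch_32, AugmentationSpec())


def enumerate_augmentations() -> list[AugmentationSpec]:
    """All distinct (dx, dy, rotation, reflect) tuples: 9 x 9 x 8 = 648."""
    return [
        AugmentationSpec(dx=dx, dy=dy, rotation_quarter_turns=rot, reflect=bool(refl))
        for dx in range(MAX_OFFSET + 1)
        for dy in range(MAX_OFFSET + 1)
        for rot in range(4)
        for refl in (0, 1)
    ]


def random_augmentation(rng: np.random.Generator) -> AugmentationSpec:
    return AugmentationSpec(
        dx=int(rng.integers(0, MAX_OFFSET + 1)),
        dy=int(rng.integers(0, MAX_OFFSET + 1)),
        rotation_quarter_turns=int(rng.integers(0, 4)),
        reflect=bool(rng.integers(0, 2)),
    )


def balanced_epoch(
    patches: Sequence[np.ndarray],
    labels: Sequence[int],
    plan: EpochSamplingPlan,
    rng: np.random.Generator | None = None,
) -> Iterator[tuple[np.ndarray, int]]:
    """Yield one epoch of oversampled, randomly augmented (patch, label).

    Epoch size is ``round(n_benign*f_b + n_malignant*f_m)``; the class of
    each slot is multinomial with probabilities proportional to the class
    expectations, and patches are drawn with replacement within class, so
    realized class counts fluctuate around ``n_class * factor``.  Pass a
    persistent ``rng`` to get a fresh, reproducible draw every epoch.
    """
    labels_arr = np.asarray(labels, dtype=int)
    if len(patches) != labels_arr.size:
        raise ValueError("patches and labels length mismatch")
    benign_idx = np.flatnonzero(labels_arr == 0)
    malignant_idx = np.flatnonzero(labels_arr == 1)
    if benign_idx.size == 0 or malignant_idx.size == 0:
        raise ValueError(
            "balanced_epoch needs both classes present "
            f"(benign={benign_idx.size}, malignant={malignant_idx.size})"
        )
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    expect_b = benign_idx.size * plan.benign_oversample_factor
    expect_m = malignant_idx.size * plan.malignant_oversample_factor
    total = int(round(expect_b + expect_m))
    n_mal = rng.binomial(total, expect_m / (expect_b + expect_m))
    chosen = np.concatenate(
        [
            rng.choice(benign_idx, size=total - n_mal, replace=True),
            rng.choice(malignant_idx, size=n_mal, replace=True),
        ]
    )
    rng.shuffle(chosen)
    for i in chosen:
        spec = random_augmentation(rng)
        yield apply_augmentation(patches[i], spec), int(labels_arr[i])
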