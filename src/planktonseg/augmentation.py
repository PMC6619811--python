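"""Rarity-aware geometric augmentation and contrast-level dataset expansion.

Rare taxa never yield enough crops for balanced training, so existing ROIs
are expanded by rotations/mirrors whose count grows with class rarity:

* euphausiids (rare): 90° CW and 180° rotation + up/down mirror → 3 extra
  variants per ROI;
* chaetognatha and medusae (rarer): the above + left/right mirror → 4;
* fish larvae (rarest): the above + a widened-dynamic-range contrast
  variant → 5.

A second expansion renders every training crop at several background
boundary parameters δ (default {3.1, 3.3, 3.5, 3.7, 3.9}), i.e. the
background-suppression transform evaluated at each level, emulating
different imaging conditions.  2048 training crops × 5 levels gives 10,240
training samples per class; the test split (512 per class) stays raw.

Variants inherit the base ROI's identity, so train/test independence is
enforced at the *base* level: no augmented descendant of a test ROI can
appear in training.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .enhancement import apply_background_transform
from .image_io import DatasetManifest, ManifestRecord

__all__ = [
    "AugOp",
    "AugmentationRecipe",
    "ContrastLevelSet",
    "LabeledSample",
    "DEFAULT_RECIPES",
    "CLASS_LABELS",
    "apply_op",
    "apply_rarity_recipe",
    "apply_contrast_levels",
    "build_training_set",
]

CLASS_LABELS = (
    "chaetognatha", "copepoda", "medusae", "euphausiids",
    "fish_larvae", "limacina", "other",
)


class AugOp(str, enum.Enum):
    ROT90_CW = "rot90cw"
    ROT180_CW = "rot180"
    MIRROR_UD = "mirror_ud"
    MIRROR_LR = "mirror_lr"
    CONTRAST_WIDEN = "contrast_widen"


@dataclass(frozen=True)
class AugmentationRecipe:
    name: str
    ops: tuple[AugOp, ...]
    applies_to: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("recipe has no ops")
        if len(set(self.ops)) != len(self.ops):
            raise ValueError("recipe repeats an op")


DEFAULT_RECIPES: dict[str, AugmentationRecipe] = {
    "euphausiids": AugmentationRecipe(
        "euphausiid-threefold",
        (AugOp.ROT90_CW, AugOp.ROT180_CW, AugOp.MIRROR_UD),
        frozenset({"euphausiids"}),
    ),
    "chaetognatha": AugmentationRecipe(
        "chaetognath-fourfold",
        (AugOp.ROT90_CW, AugOp.ROT180_CW, AugOp.MIRROR_UD, AugOp.MIRROR_LR),
        frozenset({"chaetognatha"}),
    ),
    "medusae": AugmentationRecipe(
        "medusa-fourfold",
        (AugOp.ROT90_CW, AugOp.ROT180_CW, AugOp.MIRROR_UD, AugOp.MIRROR_LR),
        frozenset({"medusae"}),
    ),
    "fish_larvae": AugmentationRecipe(
        "fish-larva-fivefold",
        (AugOp.ROT90_CW, AugOp.ROT180_CW, AugOp.MIRROR_UD, AugOp.MIRROR_LR,
         AugOp.CONTRAST_WIDEN),
        frozenset({"fish_larvae"}),
    ),
}


@dataclass(frozen=True)
class ContrastLevelSet:
    deltas: tuple[float, ...] = (3.1, 3.3, 3.5, 3.7, 3.9)

    def __post_init__(self) -> None:
        for d in self.deltas:
            if not (3.0 <= d <= 4.0):
                raise ValueError(f"delta {d} outside [3, 4]")


@dataclass(frozen=True)
class LabeledSample:
    """A labeled crop (optionally with its target mask) and its provenance.

    ``base_id`` identifies the un-augmented source ROI; every augmented
    variant keeps the base_id so split independence can be audited.
    """

    crop: np.ndarray
    label: str
    sample_id: str
    base_id: str
    mask: np.ndarray | None = None
    tags: tuple[str, ...] = ()
    i_max: int = 255


def _contrast_widen(crop: np.ndarray, i_max: int) -> np.ndarray:
    """Linear rescale of the crop onto the full [0, i_max] dynamic range."""
    c = crop.astype(np.float64)
    lo, hi = c.min(), c.max()
    if hi == lo:
        return crop.copy()
    out = (c - lo) * (i_max / (hi - lo))
    return np.clip(np.floor(out + 0.5), 0, i_max).astype(crop.dtype)


def apply_op(sample: LabeledSample, op: AugOp) -> LabeledSample:
    """Apply one geometric/contrast op; masks transform alongside crops."""
    crop, mask = sample.crop, sample.mask
    if op is AugOp.ROT90_CW:
        crop = np.rot90(crop, k=-1).copy()
        mask = None if mask is None else np.rot90(mask, k=-1).copy()
    elif op is AugOp.ROT180_CW:
        crop = np.rot90(crop, k=2).copy()
        mask = None if mask is None else np.rot90(mask, k=2).copy()
    elif op is AugOp.MIRROR_UD:
        crop = np.flipud(crop).copy()
        mask = None if mask is None else np.flipud(mask).copy()
    elif op is AugOp.MIRROR_LR:
        crop = np.fliplr(crop).copy()
        mask = None if mask is None else np.fliplr(mask).copy()
    elif op is AugOp.CONTRAST_WIDEN:
        crop = _contrast_widen(crop, sample.i_max)
    else:  # pragma: no cover
        raise ValueError(f"unknown op {op}")
    return dc_replace(
        sample,
        crop=crop,
        mask=mask,
        sample_id=f"{sample.sample_id}+{op.value}",
        tags=sample.tags + (op.value,),
    )


def apply_rarity_recipe(sample: LabeledSample,
                        recipe: AugmentationRecipe) -> list[LabeledSample]:
    """One new sample per recipe op (the original is not returned)."""
    if sample.label not in recipe.applies_to:
        raise ValueError(
            f"recipe {recipe.name!r} does not apply to class {sample.label!r}"
        )
    return [apply_op(sample, op) for op in recipe.ops]


def apply_contrast_levels(samples: list[LabeledSample],
                          levels: ContrastLevelSet = ContrastLevelSet(),
                          allow_maskless: bool = False) -> list[LabeledSample]:
    """Render every sample at every δ level (len(samples)·len(levels) outputs).

    The contrast adjustment is the background-suppression grayscale
    transform evaluated at each δ, which needs the target mask.  With
    ``allow_maskless`` a plain linear contrast stretch toward the level's
    strength is substituted for samples without masks.
    """
    out: list[LabeledSample] = []
    for s in samples:
        if s.mask is None and not allow_maskless:
            raise ValueError(f"sample {s.sample_id} has no mask")
        for d in levels.deltas:
            if s.mask is not None:
                crop = apply_background_transform(s.crop, s.mask, d, i_max=s.i_max)
            else:
                # fallback: stretch intensities by the same (delta-3) gain
                crop = np.clip(np.floor(
                    s.crop.astype(np.float64) * (1.0 + (d - 3.0)) + 0.5),
                    0, s.i_max).astype(s.crop.dtype)
            out.append(dc_replace(
                s, crop=crop,
                sample_id=f"{s.sample_id}@d{d:g}",
                tags=s.tags + (f"delta={d:g}",),
            ))
    return out


def build_training_set(samples: list[LabeledSample],
                       recipes: dict[str, AugmentationRecipe] | None = None,
                       levels: ContrastLevelSet | None = None,
                       train_per_class: int = 2048,
                       test_per_class: int = 512,
                       seed: int = 0) -> tuple[list[LabeledSample], list[LabeledSample], DatasetManifest]:
    """Build a balanced, split-independent train/test sample set.

    Base ROIs are first partitioned into train/test pools per class (seeded
    uniform choice), the rarity recipe for the class (if any) expands the
    train pool, a seeded subsample trims each class to exactly
    ``train_per_class`` / ``test_per_class``, and optional contrast levels
    multiply the train split afterwards.  Augmented variants of a base ROI
    never straddle splits.  Raises with per-class deficits if the pools
    cannot reach the targets.
    """
    if recipes is None:
        recipes = DEFAULT_RECIPES
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)

    train: list[LabeledSample] = []
    test: list[LabeledSample] = []
    deficits: list[str] = []
    for label in sorted(by_class):
        pool = sorted(by_class[label], key=lambda s: s.sample_id)
        if len(pool) < test_per_class + 1:
            deficits.append(f"{label}: only {len(pool)} base ROIs for "
                            f"{test_per_class} test + >=1 train")
            continue
        idx = rng.permutation(len(pool))
        test_pool = [pool[i] for i in idx[:test_per_class]]
        train_pool = [pool[i] for i in idx[test_per_class:]]
        recipe = recipes.get(label)
        expanded = list(train_pool)
        if recipe is not None:
            for s in train_pool:
                expanded.extend(apply_rarity_recipe(s, recipe))
        if len(expanded) < train_per_class:
            deficits.append(f"{label}: {len(expanded)} post-recipe train "
                            f"samples < target {train_per_class}")
            continue
        pick = rng.choice(len(expanded), size=train_per_class, replace=False)
        chosen = [expanded[i] for i in sorted(pick)]
        if levels is not None:
            chosen = apply_contrast_levels(chosen, levels, allow_maskless=True)
        train.extend(chosen)
        test.extend(test_pool)
    if deficits:
        raise ValueError("insufficient samples after augmentation: " + "; ".join(deficits))

    manifest = DatasetManifest()
    for split, items in (("train", train), ("test", test)):
        for s in items:
            manifest.append(ManifestRecord(
                path=f"{split}/{s.label}/{s.sample_id}.png",
                frame_id="", roi_id=s.base_id, class_label=s.label,
                split=split, augmentation_tag="|".join(s.tags),
            ))
    manifest.validate()
    return train, test, manifest
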