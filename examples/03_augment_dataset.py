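"""Rarity recipes and contrast-level expansion arithmetic.

Each rare class multiplies its ROIs by rotations/mirrors (3, 4 or 5 extra
variants depending on rarity), then every training crop is re-rendered at
five background boundary parameters delta, multiplying the set by 5.
"""

from planktonseg import DEFAULT_RECIPES, apply_rarity_recipe, apply_contrast_levels
from planktonseg.synthetic import make_labeled_dataset

samples, _ = make_labeled_dataset(
    {"euphausiids": 1, "chaetognatha": 1, "fish_larvae": 1}, seed=0)
for s in samples:
    variants = apply_rarity_recipe(s, DEFAULT_RECIPES[s.label])
    ops = ", ".join(v.tags[-1] for v in variants)
    print(f"{s.label:>13}: +{len(variants)} variants ({ops})")

base, _ = make_labeled_dataset({"copepoda": 8}, seed=1)
expanded = apply_contrast_levels(base)
print(f"{len(base)} crops x 5 contrast levels -> {len(expanded)} training samples")
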