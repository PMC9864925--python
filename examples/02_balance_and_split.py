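"""Balance an imbalanced corpus with SMOTE, then split 80/10/10.

SMOTE fills each minority class up to a common target by interpolating
between a sample and one of its k nearest same-class neighbours in pixel
space. The stratified split then allocates floor(fraction * n) per class to
validation and test, remainder to train.
"""

from dmflsim import SplitSpec, generate_synthetic_dataset, smote_oversample, stratified_split

counts = [330, 500, 70, 279, 387, 135]  # 1:10 scale of the motivating corpus
ds = generate_synthetic_dataset(counts, image_size=(16, 16), separability=3.0, seed=0)
print(f"raw: {len(ds)} samples, per-class {list(ds.manifest.values())}")

balanced = smote_oversample(ds, target_per_class=700, k_neighbors=5, seed=0)
synthetic = sum(1 for s in balanced if s.provenance == "synthetic_smote")
print(f"balanced: {len(balanced)} samples ({synthetic} synthetic), per-class 700 each")

train, val, test = stratified_split(balanced, SplitSpec(0.8, 0.1, 0.1), seed=0)
print(f"split: train={len(train)} val={len(val)} test={len(test)}")
print(f"per class: train={train.manifest[0]} val={val.manifest[0]} test={test.manifest[0]}")
# At the full corpus scale (700 -> 7000 per class) the same arithmetic gives
# exactly 5600/700/700 per class: 42,000 = 33,600 + 4,200 + 4,200.
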