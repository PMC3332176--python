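"""Statistical region merging at different granularities.

The complexity parameter Q controls the merge bound: small Q merges
aggressively into few regions, large Q preserves detail.  The darkest
region is scored as lesion for ROC comparison with the fuzzy methods.
"""

from dermseg import evaluation, synthetic
from dermseg.srm import srm_lesion_score, srm_segment

image, mask = synthetic.generate(synthetic.LesionSpec(noise_sigma=5.0, seed=4))

for q in (1, 32, 256):
    labels, means, sizes = srm_segment(image, q=q)
    score = srm_lesion_score(labels, means)
    auc = evaluation.roc_curve(score, mask.astype(int)).auc
    print(f"Q = {q:3d}: {labels.max() + 1:4d} regions, lesion AUC {auc:.4f}")
print("\nMore regions (larger Q) refine the partition; the AUC stays high as")
print("long as the lesion is isolated in its own dark region(s).")
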