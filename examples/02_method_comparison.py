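"""Compare the three segmentation backends on a batch of noisy phantoms.

Runs Otsu, k-means and fuzzy c-means on the same 10 phantom slices and
prints per-tissue mean Dice plus paired Wilcoxon p-values against Otsu.
"""

from slicefat.anatomy import (
    apply_abdominal_mask,
    build_abdominal_mask,
    delineate_vat_sat,
)
from slicefat.metrics import evaluate_compartments
from slicefat.phantom import PhantomSpec, generate_slice_phantom
from slicefat.pipeline import compare_methods
from slicefat.preprocess import preprocess_slice
from slicefat.segment import SegmentationConfig, segment

reports = []
for seed in range(10):
    image, truth, _, _ = generate_slice_phantom(
        PhantomSpec(noise_sd=0.05, seed=seed)
    )
    pre = preprocess_slice(image)
    abdominal = build_abdominal_mask(image)
    ref = {"sat": truth.sat, "vat": truth.vat, "tat": truth.tat}
    for method in ("otsu", "kmeans", "fcm"):
        seg = segment(pre, SegmentationConfig(method=method, seed=seed))
        comps = delineate_vat_sat(apply_abdominal_mask(seg.mask, abdominal))
        pred = {"sat": comps.sat, "vat": comps.vat, "tat": comps.tat}
        reports.append(
            evaluate_compartments(pred, ref, method=method, case_id=f"c{seed}")
        )

table = compare_methods(reports)
print(table.to_string(index=False))
# Each row is one (method, tissue): mean +/- SD Dice and Hausdorff over the
# 10 phantoms, with the Wilcoxon signed-rank p-value of that method's Dice
# against Otsu (p = 1 for Otsu itself).
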