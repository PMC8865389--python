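"""Constrained soft labels for non-ROI tissue slices of a pT1a slide.

A slide diagnosed pT1a (category 3 of 4) carries slices without a region of
interest; clinically those slices can only show *lower* categories. Starting
from two soft label vectors, the diagnostic constraint zeroes categories
>= 3 and renormalizes the rest.
"""

import numpy as np

from scaleformer import LabelVector, baseline_labels, constrain_label

for raw in ([0.46, 0.39, 0.08, 0.07], [0.21, 0.54, 0.10, 0.15]):
    y_hat = LabelVector(np.array(raw), kind="soft")
    y_tilde = constrain_label(y_hat, k=3)
    print(f"soft {raw} -> constrained {np.round(y_tilde.probs, 2).tolist()}")

print("\nBaseline schemes for the same slide (class 3, epsilon = 0.1):")
print("  hard                :", baseline_labels(3, "hard").probs.tolist())
print("  smoothed            :", np.round(baseline_labels(3, "smoothed").probs, 3).tolist())
print(
    "  constrained smoothed:",
    baseline_labels(3, "constrained_smoothed", has_roi=False).probs.tolist(),
)
# The constrained vectors put all mass on MMD/MIS: a slice without the
# diagnostic region cannot itself be invasive melanoma.
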