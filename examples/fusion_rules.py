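"""The three multi-view fusion rules on a hand-made voxel.

Three orthogonal networks each produce a probability that a voxel is lumen.
Majority voting binarizes each view first; averaging combines the raw
probabilities; the combined rule trusts unanimous views outright and falls
back to the average where the views disagree.
"""

import numpy as np

from mvseg import Volume, average_probs, combined_fusion, majority_vote

def prob(p):
    return Volume(np.full((1, 1, 1), p, np.float32), (1, 1, 1), role="probability")

def label(v):
    return Volume(np.full((1, 1, 1), v, np.uint8), (1, 1, 1), role="label")

thresholds = [0.4, 0.45, 0.4]  # per-view validated binarization thresholds

for p_ax, p_sag, p_cor in [(0.9, 0.8, 0.7), (0.1, 0.2, 0.05), (0.9, 0.6, 0.3)]:
    votes = [label(int(p >= t)) for p, t in zip((p_ax, p_sag, p_cor), thresholds)]
    maj = majority_vote(votes).data.item()
    avg = average_probs([prob(p_ax), prob(p_sag), prob(p_cor)]).data.item()
    comb = combined_fusion(
        [prob(p_ax), prob(p_sag), prob(p_cor)], thresholds
    ).data.item()
    print(
        f"views ({p_ax}, {p_sag}, {p_cor}) -> "
        f"majority {maj}, average {avg:.3f}, combined {comb:.3f}"
    )
# Unanimous views give combined exactly 1 or 0; the disagreement case
# (0.9, 0.6, 0.3) falls back to the plain average, 0.6.
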