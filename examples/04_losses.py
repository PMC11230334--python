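"""The three training objectives on worked numbers.

BCE sums -[y log p + (1-y) log(1-p)]; WBCE multiplies the positive
(minority, eligible) term by beta; the contrastive loss acts on the cosine
similarity d_w of the two branch encodings with a squared hinge at the
margin.
"""

from trialmatch import bce, contrastive, cosine_similarity, default_beta, wbce

print(f"bce(y=1, p=0.5)            = {bce([1.0], [0.5]):.4f}   (-ln 0.5)")
print(f"bce(y=[1,0], p=[0.5,0.5])  = {bce([1.0, 0.0], [0.5, 0.5]):.4f}   (sum over the batch)")
print(f"wbce(y=1, p=0.5, beta=2)   = {wbce([1.0], [0.5], beta=2.0):.4f}   (positive term doubled)")
print(f"wbce(y=0, p=0.5, beta=2)   = {wbce([0.0], [0.5], beta=2.0):.4f}   (beta leaves negatives alone)")

beta = default_beta([1] * 50 + [0] * 130)
print(f"default beta on a 50/130 cohort = {beta:.2f}   (N_fail / N_success)")

print(f"contrastive(y=0, d_w=0.5)  = {contrastive([0.0], [0.5]):.4f}   (push dissimilar pairs to 0)")
print(f"contrastive(y=1, d_w=0.2)  = {contrastive([1.0], [0.2]):.4f}   (hinge: (1 - 0.2)^2)")

print(f"cosine([1,0], [0,1])       = {cosine_similarity([1.0, 0.0], [0.0, 1.0]):.1f}")
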