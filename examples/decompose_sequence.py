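"""Decompose one synthetic feature-sequence class into canonical coefficients.

Builds an order-4 cross-time monomial dictionary for a short (I=6) sequence,
fits the canonical model from sample moments, and demonstrates the two
defining properties of the construction: the extracted coefficients are
exactly uncorrelated over the training sample, and the first-component
expansion reconstructs every realization from its coefficients.
"""

import numpy as np

from canondx import (
    ClassSpec,
    MomentTable,
    build_canonical_model,
    build_dictionary,
    extract_coefficients,
    reconstruct_first_component,
    select_decision_coefficients,
    simulate_class,
    standardize,
)

ts = simulate_class(ClassSpec("demo", alpha=0.4, beta=0.2), I=6, L=500, seed=42)
_, (std,) = standardize(ts)

order = build_dictionary(I=6, N=4)
model = build_canonical_model(MomentTable(std), order)

P = extract_coefficients(model, std.values)
G = P.T @ P / P.shape[0]
max_cross = np.abs(G - np.diag(np.diag(G))).max()

rec = reconstruct_first_component(model, P)
rec_err = np.abs(rec - std.values).max()

print(f"dictionary size (I=6, N=4): {order.size} monomials")
print(f"non-degenerate coefficients: {model.active.size}")
print(f"max |cross-moment| between distinct coefficients: {max_cross:.2e}")
print(f"max reconstruction error over the training set:   {rec_err:.2e}")
print("decision coefficients (last monomial of each block):")
for mon in select_decision_coefficients(model):
    print(f"  block {mon.nu}: {mon}")
print(
    "\nA cross-moment near machine precision means the dictionary's "
    "sequential orthogonalization has whitened the sequence; the "
    "reconstruction error near 1e-15 shows the coefficient map is lossless."
)
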