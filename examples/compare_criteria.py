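"""Compare the linear, polynomial and nonlinear decision criteria.

Generates the quadratic-coupling benchmark — two classes with identical
means and variances that differ only in the sign of a third-order lag-1
coupling — trains all three criteria, and prints the per-class
percent-correct table.  A second-order (linear) model cannot represent the
difference between these classes, so its accuracy stays near chance; the
higher-order criteria see the coupling.
"""

from canondx import BenchmarkConfig, make_benchmark, run_benchmark, second_order_report

cfg = BenchmarkConfig(kind="quadratic_coupling", seed=7)
train, _ = make_benchmark(cfg)

print("second-order match between the two classes (should be exact):")
print(second_order_report(train).to_string(index=False))

table = run_benchmark(cfg)
print("\npercent correct on 500 held-out draws per class:")
print(table.round(1).to_string())
print(
    "\nThe linear criterion hovers near the 50% chance level because the "
    "class difference is purely third-order; the single-time polynomial "
    "and the full cross-time nonlinear criteria both exceed it."
)
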