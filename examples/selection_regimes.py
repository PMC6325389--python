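"""Truncation-selection constants for typical preselection percentages.

Keeping the top p% of candidates on a normally distributed EBV defines a
truncation point x, a selection intensity i, and a variance reduction
k = i(i - x) of the criterion among the survivors.  k is what erodes
genetic variance in a preselected reference population.
"""

from refpop import variance_reduction

print(f"{'kept %':>7} {'x':>9} {'i':>8} {'k':>8}")
for percent in (5, 30, 70, 90, 100):
    r = variance_reduction(percent / 100.0)
    print(f"{percent:>7} {r.x:>9.4f} {r.i:>8.4f} {r.k:>8.4f}")

print()
print("Keeping only the top 5% removes", f"{variance_reduction(0.05).k:.1%}",
      "of the variance of the selection criterion; keeping 90% removes only",
      f"{variance_reduction(0.90).k:.1%}.")
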