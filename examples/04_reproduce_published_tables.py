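"""Recompute the published worked-example numbers.

The source study's patient data were never deposited, but its summary
tables over-determine the per-marker 2x2 tables: the printed sensitivity
and specificity on the complete-case denominators (pre-treatment 43 dead /
24 alive, post-treatment 44 / 28) pin down every cell count, from which
PPV, NPV, the univariate odds ratios and their Wald intervals all follow.
This harness recomputes each one and compares against the printed value
under the two-decimal truncation display rule.
"""

from ppsn import reproduce_worked_examples

checks = reproduce_worked_examples()
n_pass = sum(c["pass"] for c in checks)
print(f"{'target':<36}{'expected':>10}{'actual':>10}  status")
for c in checks:
    status = "ok" if c["pass"] else f"FAIL (delta {c['delta']:+.4g})"
    print(f"{c['target']:<36}{c['expected']:>10}{c['actual']:>10}  {status}")
print(f"\n{n_pass}/{len(checks)} published values reproduced exactly")
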