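"""Quantify epistasis as the energy gap of multipoint mutants.

For random combinations of mutations, the gap is the energy of the
multipoint mutant minus the sum of its constituent single-mutation ddG
values: zero on an additive landscape, large and positive when a planted
incompatible pair is present.
"""

import numpy as np

from htfunclib.energy import ddg_scan, epistasis_gap, generate_landscape
from htfunclib.genotypes import Mutation

reference = {p: "A" for p in range(1, 7)}
allowed = {p: set("GSW") for p in reference}
contacts = [(p, q) for p in reference for q in reference if p < q]
oracle = generate_landscape(
    reference, allowed, contacts,
    field_scale=1.0, coupling_scale=0.3,
    n_incompatible_pairs=2, incompatible_penalty=10.0, seed=3,
)
scan = ddg_scan(oracle, reference, allowed)

rng = np.random.default_rng(0)
combos = []
for _ in range(500):
    positions = rng.choice(list(reference), size=3, replace=False)
    combos.append(
        [Mutation(int(p), "A", rng.choice(list("GSW"))) for p in positions]
    )
gaps, summary = epistasis_gap(oracle, combos, scan)

print(f"{len(gaps)} random 3-mutation combinations")
print(
    "gap quartiles: "
    f"q1={summary['q1']:+.2f}  median={summary['median']:+.2f}  "
    f"q3={summary['q3']:+.2f}"
)
print(f"whiskers (1.5*IQR): [{summary['whisker_low']:+.2f}, {summary['whisker_high']:+.2f}]")
print(f"combinations with gap > 5 (hit a planted pair): {(gaps > 5).sum()}")
print(
    "\nMost combinations sit near zero (mild pairwise couplings); the heavy\n"
    "right tail is produced by the planted incompatible pairs."
)
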