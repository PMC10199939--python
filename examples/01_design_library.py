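"""Design an epistasis-aware combinatorial library on a synthetic landscape.

Generates a fully synthetic demo system (toy barrel structure, homolog
alignment, pairwise energy landscape with two planted incompatible mutation
pairs), runs the full design pipeline, and compares the neural-net-enriched
library with the space passing only per-mutation filters.
"""

import json
import tempfile
from pathlib import Path

from htfunclib.pipeline import RunConfig, make_fixture, run_design

workdir = Path(tempfile.mkdtemp(prefix="htfl_design_"))
truth = make_fixture("design-demo", seed=7, out_dir=workdir)
config = RunConfig.from_yaml(workdir / "config.yaml")
library, report = run_design(config, workdir / "out")

print("planted incompatible pairs:", truth["planted_pairs"])
print("selected library (position -> allowed identities):")
for pos in sorted(library.allowed):
    print(f"  {pos}: {''.join(sorted(library.allowed[pos]))}")
for name in ("enriched", "filtered"):
    r = report[name]
    print(
        f"{name:>8s} space: {r['space_size']:>5d} genotypes, "
        f"mean energy {r['mean_energy']:+.2f}, "
        f"{100 * r['fraction_below_reference']:.0f}% below reference"
    )
print(
    "\nThe enriched space should score far better than the filtered one: the\n"
    "network demotes mutations that only fail in combination, so at least one\n"
    "member of each planted pair is excluded from the library."
)
print("artifacts written under", workdir / "out")
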