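"""Model a genotype-phenotype map with sequence-only features.

Builds the feature table (identities, mutation counts, conservation and
accessibility changes), trains the two-stage gradient-boosted classifier
(functional vs. not, then fluorescence channel), and fits an additive
logistic-regression allele-preference logo.
"""

import numpy as np

from htfunclib.epinnet import SiteNeighborhood
from htfunclib.genotypes import Genotype
from htfunclib.profiles import Alignment, build_pssm
from htfunclib.seqfunc import build_features, logistic_logo, two_stage_classify

rng = np.random.default_rng(0)
reference = {1: "A", 2: "C", 3: "Y"}
pssm = build_pssm(
    Alignment(("ACY", "ACY", "GCY", "AWY", "SCY"), tuple("rabcd"), 0)
)
neighborhoods = [SiteNeighborhood(1, (1, 2)), SiteNeighborhood(3, (3,))]

# synthetic truth: position-1 identity decides the phenotype
label_map = {"G": "nonfunctional", "A": "GFP", "S": "AmCyan"}
genotypes, labels = [], []
for _ in range(800):
    ids = {1: rng.choice(["A", "G", "S"]), 2: rng.choice(["C", "W"]),
           3: rng.choice(["Y", "M"])}
    genotypes.append(Genotype.from_mapping(ids))
    labels.append(label_map[ids[1]])

features = build_features(genotypes, reference, pssm, neighborhoods)
print(f"feature table: {features.shape[0]} genotypes x {features.shape[1]} features")

result = two_stage_classify(features, labels, seed=0)
print(f"stage-1 balanced accuracy (functional vs. not): {result.stage1_balanced_accuracy:.2f}")
print(f"stage-2 accuracy (channel among functional): {result.stage2_accuracy:.2f}")
print("top features:", result.feature_importance.head(3)["feature"].tolist())

binary = [int(l != "nonfunctional") for l in labels]
logo = logistic_logo(genotypes, binary, l2_C=0.5)
print("\nallele-preference logo (delta-log2 odds, mean-centered by site):")
print(logo.round(2).to_string())
print(
    "\nPosition 1 carries all the signal: G is strongly disfavoured while A\n"
    "and S are favoured; the other positions' coefficients are ~0."
)
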