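# Methods

This note documents the models, numerical choices and limitations behind
`htfunclib`, in the order the pipeline runs.

## Conservation profile

The PSSM is a per-position log₂-odds score against a background
distribution q:

    score(p, a) = log2( (n_pa + m·q_a) / ((N_p + m)·q_a) )

with n_pa the count of amino acid a in the alignment column mapped to
ungapped reference position p, N_p the non-gap count, and m a
background-proportional pseudocount mass (default 1). The background
defaults to uniform (q_a = 1/20). Columns aligned to reference gaps are
dropped; columns with no residues score 0 with a logged warning. Scores are
kept as floats and the conservation filter (default threshold −2 bits,
strict >) is applied to the float value; the reference identity is always
retained regardless of score. With fixed m the scores of *observed*
identities converge as the alignment grows (asserted within 0.2 bits on a
2×-replicated toy alignment); exact invariance under row duplication holds
when m is scaled with the number of rows. Secondary-structure segmentation
of the alignment is not reproduced; whole-alignment column statistics are
used.

ΔPSSM of a genotype is the per-position score difference (mutant −
reference); the sum, and the mean and max **over the mutated positions**,
are reported (the mean/max over all designed positions would be diluted by
structural zeros at unmutated positions).

## Pocket and neighborhoods

Structures are parsed with gemmi; hydrogens are discarded and altlocs
resolved to highest occupancy. All distances use heavy atoms. A candidate
residue is a *contact* of a center when at least two of its heavy atoms
each lie within the cutoff (default 6 Å) of some heavy atom of the center —
a per-residue criterion that is symmetric under a shared `min_atom_pairs`,
so proximal neighborhoods overlap. The ligand shell uses any-atom distance
to any ligand heavy atom (default 8 Å, boundary inclusive). Manual
neighborhood pruning is supported as a per-center exclusion list in the
configuration; pruning a center is an error. Positions are addressed as
(chain, author residue number).

Solvent accessibility is computed by sphere sampling (a deterministic
Fibonacci lattice of 960 points per atom, probe 1.4 Å, van der Waals radii
C 1.70 / N 1.55 / O 1.52 / S 1.80 Å), validated against the closed-form
area of an isolated sphere. Relative accessibility divides by tabulated
per-amino-acid theoretical maxima (Tien et al. 2013); relative SASA < 0.2
is the default burial call. The ΔSASA classifier feature uses differences
of the tabulated maxima directly (an identity-swap proxy that requires no
remodeling).

## Energy oracle and synthetic landscape

Everything downstream consumes energies through an oracle returning one
scalar per genotype with the reference gauged to 0, so external ΔΔG tables
can be used without absolute-energy alignment. The synthetic landscape is a
pairwise (Potts-like) model

    E(g) = Σ_p h_p(a_p) + Σ_{p<q} J_pq(a_p, a_q)

with h and J vanishing on reference identities, fields and couplings drawn
from zero-mean Gaussians, couplings restricted to contacting position
pairs, and n planted (position-pair, identity-pair) combinations receiving
a large positive penalty — the model of energetically incompatible mutation
pairs the design method is meant to purge. All draws are seeded; the
planted pairs are recorded for test oracles only.

The single-mutation ΔΔG filter retains mutations with ΔΔG ≤ threshold
(boundary inclusive). The automatic threshold selection takes the largest
grid value whose implied total Σ_k Π_{p∈k}(1 + m_p(t)) over neighborhoods k
stays strictly under the budget (default 10⁶); a per-neighborhood variant
of the bound is available as a configuration switch. The epistasis gap of a
mutation combination is ΔΔG(combo) − Σ ΔΔG(single); on the pairwise
landscape this equals the sum of the active couplings exactly, which the
tests verify by brute force.

## EpiNNet training and library selection

Neighborhood spaces below 10⁴ designs are fully enumerated; larger ones are
sampled uniformly without replacement at 10% (seeded; rejection sampling
with deduplication above 10⁷). Labels per neighborhood: energy strictly
below the reference → success (1); the ⌈n/2⌉ highest-energy designs →
failure (0); the remainder is discarded as undetermined. When both rules
match (possible when most of a neighborhood beats the reference) the
success rule wins, as "better than reference" is the primary definition;
consequently the fail count equals ⌈n/2⌉ only when the two rules are
disjoint, and that is the case in which the partition property is asserted.

Labelled designs are embedded into the full designed-position space
(reference identity outside the neighborhood), one-hot encoded over the
per-position allowed sets, pooled across neighborhoods, and split 80/20
(unstratified). The classifier is a single-hidden-layer perceptron with
hidden width equal to the number of designed positions, trained up to 2000
iterations with a fixed seed. Each tolerated single mutation is then scored
as the predicted success probability of (reference + mutation); ties are
broken by lower ΔΔG, then position, then alphabetical identity, making the
ranking deterministic.

Library selection adds mutations in rank order, recomputing the space size
Π_p(1 + m_p) after each addition, and stops at the first addition reaching
the target (that mutation included; a target of 1 returns the
reference-only library). The default target is 4×10⁶ ("several million" is
the stated experimental limit; the exact value is a user parameter).
Validation scores the enriched and the filtered space with the oracle —
exhaustively up to 10⁴ genotypes, otherwise by seeded sampling — and
reports mean/median energy and the fraction strictly below the reference.

A note on what is learnable: with binary success/fail labels the network
identifies the *selection boundary* (which mutations belong in the library
at a given size), not a total order among mutations far from that boundary.
On additive landscapes the selected library coincides with the one built by
sorting on ΔΔG (asserted as set equivalence); near-zero-ΔΔG mutations sit
on the label boundary and their rank is genuinely undetermined.

## Sequencing analysis

Enrichment is the read-frequency ratio (sorted/total_sorted) /
(presorted/total_presorted), invariant to rescaling either sample.
Genotypes found only in the sorted sample get +∞ and are called enriched
(the presorted pool undersamples a large library; minimum sorted support
defaults to 1 read and is configurable). A gate is hit when enrichment
strictly exceeds the threshold (default 1); labels combine gates as one
gate's name, `both`, or `nonfunctional`.

The functional fraction versus mutation count n is fit to

    F(n) = exp(−A·n − B·n(n−1)/2) = exp(−α·n − β·n²),

with robustness A = α + β ≥ 0 and epistasis B = 2β ≥ 0 — the unique
mapping under which the two forms coincide for all n (note n(n−1)/2 =
(n²−n)/2, so α = A − B/2). The fit is constrained nonlinear least squares
on linear F (not log F) so near-zero fractions carry no infinite weight.
Noiseless data are recovered to 10⁻⁶; pure-exponential data yield B ≤ 10⁻⁶.

Classifier features are sequence-only: per-position identity
(categorical), total mutation count, per-neighborhood (and optional
user-defined area) mutation counts, per-position ΔPSSM / ΔSASA /
category-change flag, and the mean and max of each per-position block over
the mutated positions. Amino-acid categories: aliphatic {A,V,L,I,M},
aromatic {F,W,Y,H}, polar {S,T,N,Q,C}, positive {K,R}, negative {D,E},
special {G,P}. Zero-variance features are pruned with a logged list. The
two-stage classifier (gradient-boosted trees by default, pluggable) first
separates functional from non-functional, then classifies the channel on
stage-1 positives only; stage-1 accuracy is reported on a class-balanced
held-out set obtained by subsampling majority classes to the minority
count.

Allele-preference logos come from an L2-penalized one-hot additive
logistic regression (C = 0.5 by default, or cross-validated over a
log-spaced grid), optionally restricted to genotypes within a Hamming
radius of a set of center genotypes; natural-log coefficients are converted
to log₂ and mean-centered within each position over the identities observed
there (unobserved identities are reported as 0).

## Evolutionary model and visualization

The substitution rate uses the standard origin-fixation form
rate(S) = S/(1 − e^(−S)) with rate(0) = 1 by continuous extension,
satisfying rate(S)/rate(−S) = e^S. (The alternative sign convention
S/(1 − e^S) is inconsistent with a neutral rate of 1 and with detailed
balance, and is not used.) With binary fitness f and S_ij = c(f_j − f_i),
the chain is reversible with π_i ∝ e^(c·f_i); c is calibrated in closed
form, c = ln(target/(1−target) · N_nonf/N_func), and the tests verify the
target occupancy through the left null vector of Q rather than the formula.
For very negative S the rate is evaluated as |S|e^S/(1 − e^S) to avoid
overflow.

Diffusion coordinates solve the π-symmetrized eigenproblem
D^{1/2} Q D^{−1/2} (dense symmetric solver below 5000 genotypes, Lanczos
above; both agree to 10⁻⁶ on desk-scale spaces). Axis k is
u_k/√(−λ_k) with u_k the k-th subdominant right eigenvector normalized
under the π-weighted inner product, sign-fixed so the largest-magnitude
entry is positive. The exact two-state case (λ₁ = −2, coordinates ±1/√2,
squared distance 2 = commute time) anchors the scaling. Region logos
partition (functional) genotypes by intervals along one axis and report
per-position amino-acid frequency matrices (rows sum to 1; empty regions
are emitted as zeros with a warning) as plain TSV consumable by any logo
plotter.

## Synthetic study conditions

The design demo emulates the study conditions at desk scale: 6 designed
positions on a 10-residue toy ring around a central ligand, a 61-row
alignment planting ~3 alternate identities per designed column at ~20%
frequency each (so the −2-bit filter admits ~4 identities per position, a
4096-genotype filtered space), Gaussian fields of scale 1.0, couplings of
scale 0.25, two planted incompatible pairs with penalty +10 (≥8× the field
scale), and a library target of 100 (~2% of the filtered space, mirroring
a several-million target out of 10¹⁹ at full scale). The counts demo
plants per-gate enrichment with 4× frequency margins on a 16-genotype
space; the two-island demo defines two 8-genotype functional islands whose
single-substitution paths must pass through non-functional intermediates.

What the synthetic landscape does **not** emulate: backbone-mediated
(indirect) epistasis beyond pairwise terms, energy-function error,
experimental noise in sorting and sequencing, and read-count
overdispersion. Passing tests therefore demonstrate the correctness and
internal consistency of the machinery — filters, labeling, training,
selection, and the evolutionary model — not the accuracy of any particular
atomistic energy function on real proteins.

## Known limitations

- The energy oracle returns a single scalar per genotype; per-residue
  energy decompositions are out of scope.
- Neighborhood subsampling assumes the index space fits 64-bit integers.
- The landscape visualization enumerates the genotype space and is capped
  at desk scale (2×10⁵ genotypes in the pipeline entry point); the full
  10⁷-design library of a real campaign is out of reach of a dense
  eigensolve and would need the iterative path plus label subsampling.
- Homolog retrieval, clustering and alignment construction are inputs, not
  features; the alignment must be pre-computed.
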