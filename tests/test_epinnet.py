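import math

import numpy as np
import pandas as pd
import pytest

from htfunclib.energy import ddg_scan, generate_landscape
from htfunclib.epinnet import (
    GenotypeEncoder,
    LibraryDefinition,
    NeighborhoodSample,
    SiteNeighborhood,
    UNDETERMINED,
    assemble_dataset,
    enumerate_neighborhood,
    enumerate_space,
    label_designs,
    neighborhood_space_size,
    rank_mutations,
    sample_space,
    select_ddg_threshold,
    select_library,
    space_size,
    train_epinnet,
    validate_spaces,
)
from htfunclib.genotypes import Genotype, Mutation

REF = {1: "A", 2: "C", 3: "D"}


def make_sample(nbhd, genotypes, energies):
    return NeighborhoodSample(nbhd, genotypes, np.asarray(energies, float))


class TestSelectThreshold:
    def test_brute_force_size_agreement(self, chain_neighborhoods):
        scan = pd.DataFrame(
            {
                "position": [1, 1, 2, 3],
                "from_aa": ["A", "A", "C", "D"],
                "to_aa": ["G", "S", "W", "H"],
                "ddg": [0.5, 1.5, 0.5, 1.5],
            }
        )
        # at t=1.0: mutations {1:G, 2:W}; neighborhood spaces by direct product:
        # n1 over {1,2}: 2*2=4; n2 over {2,1,3}: 2*2*1=4; n3 over {3,2}: 1*2=2
        t, table = select_ddg_threshold(chain_neighborhoods, scan, [1.0, 2.0], 11)
        assert t == 1.0
        assert table.loc[table["threshold"] == 1.0, "total"].item() == 10
        assert table.loc[table["threshold"] == 2.0, "total"].item() == 6 + 12 + 4

    def test_all_thresholds_under_bound_picks_max(self, chain_neighborhoods):
        scan = pd.DataFrame(
            {"position": [1], "from_aa": ["A"], "to_aa": ["G"], "ddg": [0.5]}
        )
        t, _ = select_ddg_threshold(chain_neighborhoods, scan, [1.0, 2.0, 3.0], 10**6)
        assert t == 3.0

    def test_no_threshold_under_bound_falls_back_to_smallest(self, chain_neighborhoods):
        scan = pd.DataFrame(
            {
                "position": [1] * 5,
                "from_aa": ["A"] * 5,
                "to_aa": list("GSWHK"),
                "ddg": [0.1] * 5,
            }
        )
        t, _ = select_ddg_threshold(chain_neighborhoods, scan, [1.0, 2.0], max_total=2)
        assert t == 1.0


class TestEnumerate:
    def test_full_enumeration_below_limit(self):
        nbhd = SiteNeighborhood(1, (1, 2, 3))
        genos = enumerate_neighborhood(nbhd, {1: {"G"}, 2: {"W"}, 3: {"H"}}, REF)
        assert len(genos) == 8
        assert len(set(genos)) == 8

    def test_subsampling_fraction_and_distinctness(self):
        nbhd = SiteNeighborhood(1, (1, 2, 3))
        muts = {1: set("GSWHKMNP"), 2: set("GSWHKMNP"), 3: set("GSWHKMNP")}
        genos = enumerate_neighborhood(
            nbhd, muts, REF, full_limit=100, sample_fraction=0.1, seed=4
        )
        assert len(genos) == math.ceil(0.1 * 9**3)
        assert len(set(genos)) == len(genos)

    def test_same_seed_reproducible(self):
        nbhd = SiteNeighborhood(1, (1, 2))
        muts = {1: set("GSWHKMNP"), 2: set("GSWHKMNP")}
        a = enumerate_neighborhood(nbhd, muts, REF, full_limit=10, seed=9)
        b = enumerate_neighborhood(nbhd, muts, REF, full_limit=10, seed=9)
        assert a == b

    def test_non_member_positions_stay_reference(self):
        nbhd = SiteNeighborhood(1, (1,))
        genos = enumerate_neighborhood(nbhd, {1: {"G"}, 3: {"H"}}, REF)
        assert {g.identity(3) for g in genos} == {"D"}


class TestLabelDesigns:
    def test_worked_example_partition(self):
        nbhd = SiteNeighborhood(1, (1,))
        genos = [Genotype.from_mapping(REF)] * 6
        sample = make_sample(nbhd, genos, [-2, -1, 0, 1, 2, 3])
        labels = label_designs(sample, reference_energy=0.0)
        assert labels.tolist() == [1, 1, UNDETERMINED, 0, 0, 0]

    def test_success_rule_wins_when_all_beat_reference(self):
        nbhd = SiteNeighborhood(1, (1,))
        sample = make_sample(nbhd, [Genotype.from_mapping(REF)] * 4, [-4, -3, -2, -1])
        assert label_designs(sample, 0.0).tolist() == [1, 1, 1, 1]

    def test_single_worse_design_fails(self):
        nbhd = SiteNeighborhood(1, (1,))
        sample = make_sample(nbhd, [Genotype.from_mapping(REF)], [5.0])
        assert label_designs(sample, 0.0).tolist() == [0]

    @pytest.mark.parametrize("n", [1, 2, 5, 8, 11])
    def test_fail_count_is_half_rounded_up_when_rules_disjoint(self, n, rng):
        # all energies above the reference: the success rule never overlaps
        nbhd = SiteNeighborhood(1, (1,))
        energies = rng.uniform(0.5, 5.0, size=n)
        labels = label_designs(make_sample(nbhd, [Genotype.from_mapping(REF)] * n, energies), 0.0)
        assert (labels == 0).sum() == math.ceil(n / 2)
        assert (labels == 1).sum() + (labels == 0).sum() + (labels == UNDETERMINED).sum() == n


class TestAssembleAndEncode:
    def test_encode_decode_round_trip(self):
        enc = GenotypeEncoder({1: {"G"}, 2: {"W"}, 3: {"H"}}, REF)
        g = Genotype.from_mapping({1: "G", 2: "C", 3: "H"})
        row = enc.encode([g])[0]
        assert row.sum() == 3  # exactly one active column per position
        assert enc.decode(row) == g

    def test_pooling_concatenates_neighborhood_rows(self):
        n1, n2 = SiteNeighborhood(1, (1,)), SiteNeighborhood(2, (2,))
        g = Genotype.from_mapping(REF)
        s1 = make_sample(n1, [g] * 4, [-1, -2, 1, 2])
        s2 = make_sample(n2, [g] * 4, [-1, -2, 1, 2])
        ds = assemble_dataset([s1, s2], {1: {"G"}, 2: {"W"}}, REF)
        assert len(ds.y) == 8  # no undetermined rows in this construction
        assert set(ds.provenance) == {1, 2}

    def test_embedding_keeps_reference_at_non_member_positions(self):
        n1 = SiteNeighborhood(1, (1,))
        g = Genotype.from_mapping({**REF, 1: "G"})
        ds = assemble_dataset(
            [make_sample(n1, [g, g], [-1.0, 1.0])], {1: {"G"}}, REF
        )
        decoded = ds.encoder.decode(ds.X[0])
        assert decoded.identity(2) == "C" and decoded.identity(3) == "D"


def _separable_dataset(seed=0, n=400):
    """Success iff mutation 1G absent; balanced, linearly separable."""
    rng = np.random.default_rng(seed)
    allowed = {1: {"G"}, 2: {"W"}, 3: {"H"}}
    enc_ref = dict(REF)
    genos, labels = [], []
    for _ in range(n):
        ids = {
            p: rng.choice([enc_ref[p], list(allowed[p])[0]]) for p in enc_ref
        }
        genos.append(Genotype.from_mapping(ids))
        labels.append(0 if ids[1] == "G" else 1)
    nbhd = SiteNeighborhood(1, (1, 2, 3))
    sample = NeighborhoodSample(nbhd, genos, np.zeros(n))
    from htfunclib.epinnet import GenotypeEncoder, TrainingDataset

    enc = GenotypeEncoder(allowed, enc_ref)
    return TrainingDataset(
        enc.encode(genos), np.array(labels), np.full(n, 1), enc
    )


class TestTrainAndRank:
    def test_separable_data_reaches_perfect_holdout(self):
        model = train_epinnet(_separable_dataset(), seed=0)
        assert model.holdout_accuracy == 1.0

    def test_shuffled_labels_score_near_chance(self):
        ds = _separable_dataset(seed=1)
        rng = np.random.default_rng(1)
        ds.y = rng.permutation(ds.y)
        model = train_epinnet(ds, seed=1)
        assert 0.3 < model.holdout_accuracy < 0.7

    def test_same_seed_same_scores(self):
        ds = _separable_dataset()
        m1 = train_epinnet(ds, seed=5)
        m2 = train_epinnet(ds, seed=5)
        g = [Genotype.from_mapping({**REF, 2: "W"})]
        assert m1.success_probability(g)[0] == m2.success_probability(g)[0]

    def test_single_class_rejected(self):
        ds = _separable_dataset()
        ds.y = np.ones_like(ds.y)
        with pytest.raises(ValueError, match="both"):
            train_epinnet(ds)

    def test_additive_landscape_ranking_matches_ddg_order(self):
        # on an additive landscape the network's single-mutation scores must
        # reproduce the brute-force ddg sort; field terms are well separated
        # from 0 so no mutation sits on the success boundary
        reference = {i: "A" for i in range(1, 5)}
        allowed = {i: set("GSW") for i in reference}
        field_values = [-3.0, -2.4, -1.8, -1.2, -0.9, -0.6,
                        0.6, 0.9, 1.2, 1.8, 2.4, 3.0]
        base = generate_landscape(
            reference, allowed, contacts=[(1, 2), (2, 3), (3, 4)],
            field_scale=2.0, coupling_scale=0.0, seed=11,
        )
        from htfunclib.energy import SyntheticLandscape

        ls = SyntheticLandscape(
            reference=base.reference,
            allowed=base.allowed,
            fields=dict(zip(sorted(base.fields), field_values)),
            couplings={},
            planted_pairs=(),
            seed=11,
        )
        scan = ddg_scan(ls, reference, allowed)
        nbhds = [
            SiteNeighborhood(1, (1, 2)),
            SiteNeighborhood(2, (2, 1, 3)),
            SiteNeighborhood(3, (3, 2, 4)),
            SiteNeighborhood(4, (4, 3)),
        ]
        muts = {p: set("GSW") for p in reference}
        samples = []
        for nb in nbhds:
            genos = enumerate_neighborhood(nb, muts, reference, seed=0)
            samples.append(
                make_sample(nb, genos, [ls.energy(g) for g in genos])
            )
        ds = assemble_dataset(samples, muts, reference)
        model = train_epinnet(ds, seed=0)
        ranked = rank_mutations(model, muts, reference, scan)
        ranked_muts = [m for m, _ in ranked]
        lut = {
            (int(r["position"]), r["to_aa"]): float(r["ddg"])
            for _, r in scan.iterrows()
        }
        # every stabilizing mutation (success on the reference background)
        # must outrank every destabilizing one; with binary labels only the
        # selection boundary is learnable, not the within-group order
        negative = {m for m in ranked_muts if lut[(m.position, m.to_aa)] < 0}
        k = len(negative)
        assert set(ranked_muts[:k]) == negative

        # selection equivalence: the library built from the EpiNNet ranking
        # equals the library built from the brute-force ddg sort
        by_ddg = sorted(ranked_muts, key=lambda m: lut[(m.position, m.to_aa)])
        target = space_size(
            {
                p: {reference[p]} | {m.to_aa for m in negative if m.position == p}
                for p in reference
            }
        )
        lib_nn, _ = select_library(ranked, reference, target)
        lib_ddg, _ = select_library(
            [(m, 0.0) for m in by_ddg], reference, target
        )
        assert lib_nn.allowed == lib_ddg.allowed


class TestSelectLibrary:
    def _ranked(self):
        return [
            (Mutation(1, "A", "G"), 0.9),
            (Mutation(1, "A", "S"), 0.8),
            (Mutation(2, "C", "W"), 0.7),
            (Mutation(2, "C", "H"), 0.6),
        ]

    def test_stops_at_first_addition_reaching_target(self):
        lib, trace = select_library(self._ranked(), {1: "A", 2: "C"}, target_size=6)
        # sizes along the path: 2, 3, 6 -> stops at the 3rd addition
        assert [s for _, s in trace] == [2, 3, 6]
        assert space_size(lib) == 6

    def test_target_one_gives_reference_only_library(self):
        lib, trace = select_library(self._ranked(), {1: "A", 2: "C"}, target_size=1)
        assert space_size(lib) == 1
        assert trace == []

    def test_trace_strictly_increasing(self):
        _, trace = select_library(self._ranked(), {1: "A", 2: "C"}, target_size=100)
        sizes = [s for _, s in trace]
        assert sizes == sorted(sizes) and len(set(sizes)) == len(sizes)

    def test_exhausted_ranking_returns_everything(self):
        lib, trace = select_library(self._ranked(), {1: "A", 2: "C"}, target_size=10**9)
        assert space_size(lib) == 9  # (1+2) * (1+2): every ranked mutation added
        assert len(trace) == 4


class TestSpaceSize:
    def test_reference_only_space_is_one(self):
        lib = LibraryDefinition({1: frozenset("A")}, {1: "A"})
        assert space_size(lib) == 1

    def test_product_arithmetic(self):
        assert space_size({1: "AGS", 2: "CWHK"}) == 12

    def test_twenty_identities_at_27_positions_rounds_to_1e35(self):
        size = space_size({p: set("ACDEFGHIKLMNPQRSTVWY") for p in range(27)})
        assert size == 20**27
        assert round(math.log10(size)) == 35


class TestSampling:
    def test_reference_only_library_samples_reference(self, additive_landscape):
        ref = additive_landscape.reference
        lib = LibraryDefinition({p: frozenset(ref[p]) for p in ref}, dict(ref))
        report = validate_spaces(additive_landscape, lib, lib, n=50, seed=0)
        assert report["enriched"]["fraction_below_reference"] == 0.0
        assert report["enriched"]["mean_energy"] == 0.0

    def test_same_seed_identical_report(self, additive_landscape):
        ref = additive_landscape.reference
        lib = LibraryDefinition(
            {p: frozenset({ref[p]} | set(additive_landscape.allowed[p])) for p in ref},
            dict(ref),
        )
        r1 = validate_spaces(additive_landscape, lib, lib, n=100, seed=3,
                             exhaustive_limit=1)
        r2 = validate_spaces(additive_landscape, lib, lib, n=100, seed=3,
                             exhaustive_limit=1)
        assert r1 == r2

    def test_enumerate_space_covers_product_exactly(self):
        lib = LibraryDefinition(
            {1: frozenset("AG"), 2: frozenset("CW")}, {1: "A", 2: "C"}
        )
        genos = enumerate_space(lib)
        assert len(genos) == 4 and len(set(genos)) == 4

    def test_sample_space_draws_within_allowed(self):
        lib = LibraryDefinition(
            {1: frozenset("AG"), 2: frozenset("CW")}, {1: "A", 2: "C"}
        )
        for g in sample_space(lib, 25, seed=1):
            assert g.identity(1) in "AG" and g.identity(2) in "CW"
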