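"""Synthetic species trees, gene trees, alignments and exact-profile datasets."""

import pytest

from orthosignal.clans import ClanStatus, check_clans, clan_status, filter_orthogroups
from orthosignal.infometrics import rcfv, saturation
from orthosignal.synthetic import (
    ProfileError,
    SyntheticSpec,
    construct_profile_dataset,
    profile_clans,
    simulate_alignment,
    simulate_gene_trees,
    simulate_species_tree,
)


class TestSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(clan_sizes={"A": 2, "B": 1})
        with pytest.raises(ValueError):
            SyntheticSpec(violation_rate=1.5)
        with pytest.raises(ValueError):
            SyntheticSpec(gamma_shape=0.0)

    def test_clan_definitions_cover_all_taxa(self):
        spec = SyntheticSpec()
        clans = spec.clans()
        total = sum(len(c.taxa) for c in clans)
        assert total == sum(spec.clan_sizes.values())


class TestSpeciesTree:
    def test_every_clan_recovered_by_construction(self):
        spec = SyntheticSpec(seed=4)
        tree = simulate_species_tree(spec)
        assert len(tree.leaves) == sum(spec.clan_sizes.values())
        for clan in spec.clans():
            expected = (
                ClanStatus.RECOVERED if clan.countable else ClanStatus.INSUFFICIENT
            )
            assert clan_status(tree, clan) is expected

    def test_seed_reproducible(self):
        spec = SyntheticSpec(seed=9)
        assert (
            simulate_species_tree(spec).to_newick()
            == simulate_species_tree(SyntheticSpec(seed=9)).to_newick()
        )

    def test_stem_stretch_lengthens_fast_clan_stem(self):
        base = simulate_species_tree(SyntheticSpec(seed=2, stem_stretch=1.0))
        long = simulate_species_tree(SyntheticSpec(seed=2, stem_stretch=20.0))
        assert long.total_length() > base.total_length()


class TestGeneTrees:
    def test_no_violations_when_rate_zero(self):
        spec = SyntheticSpec(seed=1, n_orthogroups=30, violation_rate=0.0)
        species = simulate_species_tree(spec)
        trees, truth = simulate_gene_trees(species, spec)
        assert (truth.moves == "").all()
        report = check_clans(trees, spec.clans())
        for (og, name), status in report.statuses.items():
            assert status is not ClanStatus.VIOLATED

    def test_full_dropout_makes_clan_insufficient(self):
        spec = SyntheticSpec(
            seed=1, n_orthogroups=10, violation_rate=0.0, dropout={"Porifera": 1.0}
        )
        species = simulate_species_tree(spec)
        trees, truth = simulate_gene_trees(species, spec)
        clan = [c for c in spec.clans() if c.name == "Porifera"][0]
        for tree in trees.values():
            assert clan_status(tree, clan) is ClanStatus.INSUFFICIENT

    def test_truth_table_matches_recomputed_statuses(self):
        spec = SyntheticSpec(seed=8, n_orthogroups=60, violation_rate=0.5)
        species = simulate_species_tree(spec)
        trees, truth = simulate_gene_trees(species, spec)
        report = check_clans(trees, spec.clans())
        for _, row in truth.iterrows():
            recorded = set(row.violated_clans.split(";")) if row.violated_clans else set()
            detected = {
                c.name
                for c in spec.clans()
                if report.statuses[(row.orthogroup, c.name)] is ClanStatus.VIOLATED
            }
            assert recorded <= detected
            if not row.moves:
                assert not detected

    def test_seed_reproducible(self):
        spec = SyntheticSpec(seed=3, n_orthogroups=10)
        species = simulate_species_tree(spec)
        t1, truth1 = simulate_gene_trees(species, spec)
        t2, truth2 = simulate_gene_trees(species, spec)
        assert [t.to_newick() for t in t1.values()] == [t.to_newick() for t in t2.values()]
        assert truth1.equals(truth2)


class TestAlignments:
    def test_zero_length_tree_gives_identical_sequences(self):
        spec = SyntheticSpec(seed=5, aln_length=(50, 50))
        species = simulate_species_tree(spec)
        flat = species.scale_lengths(0.0)
        aln = simulate_alignment(flat, spec, seed=2)
        assert len({aln[t] for t in aln.taxa}) == 1

    def test_seed_reproducible(self):
        spec = SyntheticSpec(seed=5, aln_length=(80, 120))
        species = simulate_species_tree(spec)
        a = simulate_alignment(species, spec, seed=6)
        b = simulate_alignment(species, spec, seed=6)
        assert a == b

    def test_length_within_requested_range(self):
        spec = SyntheticSpec(seed=5, aln_length=(100, 150))
        species = simulate_species_tree(spec)
        aln = simulate_alignment(species, spec, seed=1)
        assert 100 <= aln.length <= 150

    def test_composition_shift_raises_rcfv(self):
        # paired seeds: same tree, same per-site rates, only the shift differs
        n_increase = 0
        for i in range(20):
            base = SyntheticSpec(seed=100 + i, aln_length=(400, 400), violation_rate=0.0)
            shifted = SyntheticSpec(
                seed=100 + i, aln_length=(400, 400), violation_rate=0.0, comp_shift=0.5
            )
            tree = simulate_species_tree(base)
            a0 = simulate_alignment(tree, base, seed=500 + i)
            a1 = simulate_alignment(tree, shifted, seed=500 + i)
            n_increase += rcfv(a1) > rcfv(a0)
        assert n_increase >= 16

    def test_doubling_branch_lengths_lowers_saturation_slope(self):
        spec = SyntheticSpec(seed=13, aln_length=(600, 600), branch_scale=0.3)
        tree = simulate_species_tree(spec)
        doubled = tree.scale_lengths(2.0)
        s_short = saturation(tree, simulate_alignment(tree, spec, seed=21))
        s_long = saturation(doubled, simulate_alignment(doubled, spec, seed=21))
        assert s_long < s_short

    def test_gap_injection_reduces_occupancy(self):
        spec = SyntheticSpec(seed=5, aln_length=(200, 200), gap_fraction=0.3)
        species = simulate_species_tree(spec)
        aln = simulate_alignment(species, spec, seed=2)
        gap_frac = sum(aln[t].count("-") for t in aln.taxa) / (
            len(aln.taxa) * aln.length
        )
        assert 0.2 < gap_frac < 0.4


class TestProfileConstruction:
    def test_single_tree_with_requested_count(self):
        clans = profile_clans()
        trees = construct_profile_dataset({3: 1}, clans, seed=1)
        report = check_clans(trees, clans)
        assert list(report.n_recovered.values()) == [3]

    def test_histograms_realized_exactly(self):
        clans = profile_clans()
        request = {5: 2, 4: 3, 3: 4, 2: 5, 1: 6, 0: 7}
        trees = construct_profile_dataset(request, clans, seed=2)
        hist = check_clans(trees, clans).histogram()
        assert {n: c for n, c in hist.items() if c} == request

    def test_infeasible_count_rejected(self):
        with pytest.raises(ProfileError):
            construct_profile_dataset({6: 1}, profile_clans(), seed=1)

    def test_seed_reproducible(self):
        clans = profile_clans()
        t1 = construct_profile_dataset({2: 3}, clans, seed=7)
        t2 = construct_profile_dataset({2: 3}, clans, seed=7)
        assert [t.to_newick() for t in t1.values()] == [t.to_newick() for t in t2.values()]

    def test_filtering_threshold_on_constructed_profile(self):
        clans = profile_clans()
        trees = construct_profile_dataset({4: 2, 3: 3, 2: 4}, clans, seed=3)
        report = check_clans(trees, clans)
        assert len(filter_orthogroups(report, 3)) == 5
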