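"""Coalescent simulator, region generator, and planted-event fixtures."""

import dendropy
import numpy as np
import pytest

from conftest import random_orf_locus
from denovogene.orf import detect_disablers, infer_enablers, project_cds, scan_orfs, Orf
from denovogene.popgen import (
    harmonic_number,
    nucleotide_diversity,
    segsite_distribution,
    watterson_theta,
)
from denovogene.simulate import (
    AncestralLocus,
    PlantedEventSpec,
    evolve_orthologs,
    make_screen_fixture,
    sample_segregating_counts,
    simulate_coalescent,
    simulate_popgen_region,
)


class TestSimulateCoalescent:
    def test_deterministic_given_seed(self):
        a = simulate_coalescent(12, 3.0, seed=42)
        b = simulate_coalescent(12, 3.0, seed=42)
        assert a == b
        c = simulate_coalescent(12, 3.0, seed=43)
        assert a != c

    def test_derived_counts_strictly_polymorphic(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = simulate_coalescent(8, 4.0, rng=rng)
            for pos, count in s.sites:
                assert 0 < count < 8
                assert 0.0 <= pos < 1.0

    def test_positions_distinct(self):
        s = simulate_coalescent(30, 20.0, seed=5)
        positions = [p for p, _ in s.sites]
        assert len(set(positions)) == len(positions)

    def test_pairwise_tmrca_mean(self):
        """For n=2 the tree length is 2*T2 with E[T2] = 1 (units of 2N)."""
        rng = np.random.default_rng(11)
        totals = np.array(
            [simulate_coalescent(2, 0.1, rng=rng).total_tree_length for _ in range(20000)]
        )
        tmrca = totals / 2.0
        se = tmrca.std(ddof=1) / np.sqrt(len(tmrca))
        assert abs(tmrca.mean() - 1.0) < 3 * se

    def test_mean_segregating_sites_matches_watterson(self):
        rng = np.random.default_rng(13)
        n, theta, reps = 20, 5.0, 5000
        counts = np.array(
            [simulate_coalescent(n, theta, rng=rng).n_segregating for _ in range(reps)]
        )
        expected = theta * harmonic_number(n - 1)
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - expected) < 3 * se

    def test_vectorised_counts_match_full_simulator(self):
        """The topology-free S sampler and the full simulator agree in law."""
        n, theta, reps = 10, 2.0, 8000
        rng = np.random.default_rng(17)
        full = np.array(
            [simulate_coalescent(n, theta, rng=rng).n_segregating for _ in range(reps)]
        )
        fast = sample_segregating_counts(n, theta, reps, np.random.default_rng(18))
        # compare means and the low quantiles of the two distributions
        se = np.sqrt(full.var(ddof=1) / reps + fast.var(ddof=1) / reps)
        assert abs(full.mean() - fast.mean()) < 3 * se
        for s in (0, 2, 5):
            pf = (full <= s).mean()
            pv = (fast <= s).mean()
            se_p = np.sqrt(pf * (1 - pf) / reps + pv * (1 - pv) / reps) + 1e-9
            assert abs(pf - pv) < 3 * se_p

    def test_agrees_with_msprime_oracle(self):
        """Cross-check mean S against an independent coalescent implementation."""
        import msprime

        n, theta, reps = 10, 2.0, 4000
        rng = np.random.default_rng(19)
        ours = np.array(
            [simulate_coalescent(n, theta, rng=rng).n_segregating for _ in range(reps)]
        )
        ts_reps = msprime.sim_ancestry(
            samples=n, ploidy=1, sequence_length=1, num_replicates=reps,
            random_seed=23,
        )
        theirs = np.array(
            [
                msprime.sim_mutations(
                    ts, rate=theta / 2, random_seed=i + 1, discrete_genome=False
                ).num_sites
                for i, ts in enumerate(ts_reps)
            ]
        )
        se = np.sqrt(ours.var(ddof=1) / reps + theirs.var(ddof=1) / reps)
        assert abs(ours.mean() - theirs.mean()) < 3 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_coalescent(1, 1.0)
        with pytest.raises(ValueError):
            simulate_coalescent(5, 0.0)


class TestSimulatePopgenRegion:
    def test_zero_rate_classes_have_no_snps(self):
        recs = simulate_popgen_region(
            {"a": 100, "b": 200}, {"a": 0.0, "b": 0.0}, 10, seed=1
        )
        assert recs == []

    def test_reference_shaped_schema_feeds_report(self):
        from denovogene.popgen import per_class_report

        lengths = {"CDS_syn": 151, "CDS_nonsyn": 434, "UTR5": 263,
                   "UTR3": 1177, "intron": 830, "flank": 1000}
        rates = {cls: 1e-3 for cls in lengths}
        recs = simulate_popgen_region(lengths, rates, 180, seed=3)
        report = per_class_report(recs, lengths, 180)
        assert len(report.rows) == 6

    def test_positions_fall_in_class_blocks(self):
        lengths = {"a": 50, "b": 70}
        recs = simulate_popgen_region(lengths, {"a": 0.05, "b": 0.05}, 20, seed=9)
        for r in recs:
            if r.site_class == "a":
                assert 0 <= r.position < 50
            else:
                assert 50 <= r.position < 120

    def test_estimator_recovery_small(self):
        """Mean Watterson estimate over replicates tracks the generating rate."""
        n, rate, l, reps = 20, 2e-3, 800, 2000
        rng = np.random.default_rng(29)
        thetas = np.empty(reps)
        for i in range(reps):
            recs = simulate_popgen_region({"x": l}, {"x": rate}, n, rng=rng)
            thetas[i] = watterson_theta(len(recs), l, n)
        se = thetas.std(ddof=1) / np.sqrt(reps)
        assert abs(thetas.mean() - rate) < 3 * se


def _primate_fixture(rng, events, background=0.01, n_codons=120, junctions=None):
    tree = dendropy.Tree.get(
        data="(((human,chimp),gorilla),(orangutan,rhesus));", schema="newick"
    )
    seq, start = random_orf_locus(rng, n_codons)
    locus = AncestralLocus(
        seq=seq, orf_start=start, orf_codons=n_codons, junctions=junctions or {}
    )
    seed = int(rng.integers(2**31))
    return evolve_orthologs(
        tree, locus, events, background_rate=background, seed=seed, reference="human"
    ), start, n_codons, tree


class TestEvolveOrthologs:
    def test_no_background_no_events_rows_identical(self, rng):
        fx, *_ = _primate_fixture(rng, [], background=0.0)
        assert len(set(fx.alignment.rows)) == 1

    def test_conflicting_events_rejected(self, rng):
        events = [
            PlantedEventSpec("chimp", "premature_stop", 10),
            PlantedEventSpec("chimp", "substitution", 10, "AAA"),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            _primate_fixture(rng, events)

    def test_planted_stop_recovered(self, rng):
        events = [PlantedEventSpec("chimp", "premature_stop", 28, "TAG")]
        fx, start, n_codons, _ = _primate_fixture(rng, events)
        orf = scan_orfs(fx.alignment.ungapped("human"), 50)[0]
        proj = project_cds(fx.alignment, orf)
        calls = detect_disablers(proj)
        assert [(e.kind, e.codon_index) for e in calls["chimp"]] == [
            ("premature_stop", 28)
        ]
        assert fx.truth.disablers["chimp"] == (("premature_stop", 28),)

    def test_clade_event_inherited_by_all_leaves_below(self, rng):
        events = [
            PlantedEventSpec(("orangutan", "rhesus"), "premature_stop", 15, "TGA")
        ]
        fx, start, n_codons, _ = _primate_fixture(rng, events)
        orf = scan_orfs(fx.alignment.ungapped("human"), 50)[0]
        calls = detect_disablers(project_cds(fx.alignment, orf))
        for sp in ("orangutan", "rhesus"):
            assert (("premature_stop", 15)) in [
                (e.kind, e.codon_index) for e in calls[sp]
            ]
        assert calls["gorilla"] == []

    def test_enabler_scenario_recovered(self, rng):
        events = [
            PlantedEventSpec("root", "premature_stop", 28, "TAG"),
            PlantedEventSpec("human", "substitution", 28, "TGG"),
            PlantedEventSpec("root", "frameshift_indel", 106, "+G"),
            PlantedEventSpec("human", "frameshift_indel", 106, "-1"),
        ]
        fx, start, n_codons, _ = _primate_fixture(rng, events)
        aln = fx.alignment
        orf = scan_orfs(aln.ungapped("human"), 50)[0]
        proj = project_cds(aln, orf)
        found = {(e.codon_index, e.removes) for e in infer_enablers(aln, proj, "human")}
        assert found == {(28, "premature_stop"), (106, "frameshift")}
        assert set(fx.truth.enablers) == found
        assert detect_disablers(proj)["human"] == []

    def test_junction_gain_state_truth(self, rng):
        seq = "A" * 30 + "CA" + "T" * 10 + "AG" + "A" * 30
        tree = dendropy.Tree.get(
            data="(((human,chimp),gorilla),(orangutan,rhesus));", schema="newick"
        )
        locus = AncestralLocus(seq=seq, junctions={"j1": (30, 42)})
        fx = evolve_orthologs(
            tree,
            locus,
            [PlantedEventSpec(("human", "chimp"), "junction_gain", "j1")],
            background_rate=0.02,
            seed=31,
            reference="human",
        )
        states = fx.truth.junction_states["j1"]
        assert states["human"] == states["chimp"] == "present_canonical"
        assert states["rhesus"] == "present_noncanonical"
        assert fx.truth.junction_gain_branch["j1"] == frozenset({"human", "chimp"})

    def test_background_never_creates_frame_relevant_changes(self, rng):
        """High background rate, no events: every species stays disabler-free."""
        fx, start, n_codons, _ = _primate_fixture(rng, [], background=0.08)
        orf = scan_orfs(fx.alignment.ungapped("human"), 50)[0]
        assert (orf.start, orf.n_codons) == (start, n_codons)
        calls = detect_disablers(project_cds(fx.alignment, orf))
        assert all(evs == [] for evs in calls.values())


class TestMakeScreenFixture:
    def test_reproducible(self):
        a = make_screen_fixture(seed=4)
        b = make_screen_fixture(seed=4)
        assert a.truth == b.truth
        assert [g.gene_id for g in a.genes] == [g.gene_id for g in b.genes]

    def test_truth_is_planted_subset(self):
        fx = make_screen_fixture(seed=8)
        assert 1 <= len(fx.truth) <= 3
        ids = {g.gene_id for g in fx.genes}
        assert set(fx.truth) <= ids

    def test_all_homolog_flags_false_empties_screen(self):
        from denovogene.screen import GeneAnnotation, screen_candidates

        fx = make_screen_fixture(seed=12)
        ann = {gid: GeneAnnotation(a.orf_complete, False) for gid, a in fx.annotations.items()}
        assert screen_candidates(fx.genes, fx.gwas, fx.linkage, ann) == []
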