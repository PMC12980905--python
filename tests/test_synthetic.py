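"""Synthetic cohort generator: scenario invariants, read model, truth replay."""

import numpy as np
import pandas as pd
import pytest

from crcrelapse import cnphylo, signatures, synthetic, variants
from crcrelapse.synthetic import (MET_SAMPLES, RELAPSE_SAMPLES,
                                  simulate_clone_tree, simulate_reads)


class TestCloneTree:
    def test_shared_scenario_minimal_tree(self):
        tree = simulate_clone_tree(4, "shared", seed=1)
        rc = tree.relapsing_clone
        met_phi = tree.phi.loc[rc, list(MET_SAMPLES)]
        assert (met_phi > 0).sum() == 1
        assert met_phi.max() >= 0.15
        assert (tree.phi.loc[rc, list(RELAPSE_SAMPLES)] >= 0.3).all()

    def test_branchoff_lineages_share_only_primary_resident_ancestors(self):
        tree = simulate_clone_tree(6, "private_branchoff", seed=7)
        rc = tree.relapsing_clone
        met_clones = [c for c in tree.clones
                      if (tree.phi.loc[c, list(MET_SAMPLES)] > 0).any()
                      and tree.phi.loc[c, "P_A"] == 0]
        rc_ancestors = set(tree.ancestors(rc))
        for mc in met_clones:
            common = rc_ancestors & ({mc} | set(tree.ancestors(mc)))
            for anc in common:
                assert tree.phi.loc[anc, "P_A"] > 0  # primary-resident

    def test_private_sequential_liver_ancestor(self):
        tree = simulate_clone_tree(5, "private_sequential", seed=2)
        rc = tree.relapsing_clone
        liver = list(MET_SAMPLES) + list(RELAPSE_SAMPLES)
        anc_ok = any((tree.phi.loc[a, liver] > 0).all()
                     and tree.phi.loc[a, "P_A"] == 0
                     for a in tree.ancestors(rc))
        assert anc_ok
        assert (tree.phi.loc[rc, list(MET_SAMPLES)] == 0).all()

    @pytest.mark.parametrize("scenario", synthetic.SCENARIOS)
    def test_invariants_hold_across_sizes_and_seeds(self, scenario):
        for n_clones, seed in [(4, 1), (6, 5), (9, 11)]:
            tree = simulate_clone_tree(n_clones, scenario, seed)
            tree.validate()  # raises on any ISA/scenario violation

    def test_determinism(self):
        a = simulate_clone_tree(6, "shared", seed=9)
        b = simulate_clone_tree(6, "shared", seed=9)
        pd.testing.assert_frame_equal(a.phi, b.phi)
        assert a.parent == b.parent

    def test_errors(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            simulate_clone_tree(5, "bogus", seed=1)
        with pytest.raises(ValueError, match="n_clones"):
            simulate_clone_tree(3, "shared", seed=1)


class TestReadModel:
    def test_zero_phi_gives_zero_alt(self):
        for seed in range(5):
            _, alt = simulate_reads(0.0, 0.8, 2, 1, 450, seed)
            assert alt == 0

    def test_monte_carlo_mean_matches_closed_form(self):
        # phi=1, rho=1, CN=2, m=1 => xi = 0.5
        rng = np.random.default_rng(0)
        vafs = []
        for _ in range(10_000):
            d, a = simulate_reads(1.0, 1.0, 2, 1, 100, rng)
            vafs.append(a / d)
        se = np.std(vafs) / np.sqrt(len(vafs))
        assert abs(np.mean(vafs) - 0.5) < 3 * se + 1e-12

    def test_expected_vaf_direct_substitution(self):
        assert synthetic.expected_vaf(1.0, 0.5, 2, 1) == pytest.approx(0.25)

    def test_inconsistent_combination_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            synthetic.expected_vaf(1.0, 1.0, 1, 4)


class TestFfpeArtifacts:
    def test_rate_zero_leaves_table_unchanged(self, shared_sim):
        t = shared_sim.table
        assert synthetic.inject_ffpe_artifacts(t, 0, seed=1) is t

    def test_negative_rate_rejected(self, shared_sim):
        with pytest.raises(ValueError):
            synthetic.inject_ffpe_artifacts(shared_sim.table, -1, seed=1)

    def test_artifacts_absent_from_all_liver_samples(self, shared_sim):
        t = shared_sim.table
        art = t.muts.index[t.muts["is_artifact"]]
        assert len(art) == 20
        assert (t.alt.loc[art, t.liver_samples()] == 0).all().all()

    def test_decon_filter_removes_exactly_the_injected_artifacts(self):
        # controlled fixture: every real mutation passes the filter
        from conftest import full_cover_segments, make_table
        alt = np.zeros((5, 8), dtype=int)
        alt[:, 1:7] = 60  # present in all liver samples
        depth = np.full((5, 8), 450)
        t = make_table(alt, depth)
        t.muts["is_artifact"] = False
        injected = synthetic.inject_ffpe_artifacts(t, 20, seed=5)
        segs = full_cover_segments()
        kept = variants.select_deconvolution_input(injected, segs)
        removed = set(injected.muts.index) - set(kept.muts.index)
        assert removed == set(injected.muts.index[injected.muts["is_artifact"]])


class TestCnProfiles:
    def test_wgd_doubles_parent_profile_before_other_events(self):
        tree = simulate_clone_tree(5, "shared", seed=4)
        synthetic.simulate_cn_profiles(tree, 12, wgd_on_relapse_branch=True,
                                       seed=2, relapse_gain_chrom=None)
        rc = tree.relapsing_clone
        parent = tree.profiles[tree.parent[rc]]
        events = tree.branch_events[rc]
        assert events[0].direction == "wgd"
        replay = cnphylo.apply_events(parent, events[:1])
        assert (replay.major == 2 * parent.major).all()
        assert (replay.minor == 2 * parent.minor).all()

    def test_truth_events_replay_to_each_clone_profile(self):
        tree = simulate_clone_tree(7, "private_sequential", seed=6)
        synthetic.simulate_cn_profiles(tree, 16, seed=3)
        for clone in tree.clones:
            chain = []
            node = clone
            lineage_order = []
            while node != 0:
                lineage_order.append(node)
                node = tree.parent[node]
            for anc in reversed(lineage_order):
                chain.extend(tree.branch_events[anc])
            germ = cnphylo.diploid_profile("g", tree.profiles[clone].chroms)
            replay = cnphylo.apply_events(germ, chain)
            assert (replay.major == tree.profiles[clone].major).all()
            assert (replay.minor == tree.profiles[clone].minor).all()

    def test_branch_without_events_inherits_parent_profile(self):
        tree = simulate_clone_tree(8, "shared", seed=12)
        synthetic.simulate_cn_profiles(tree, 12, seed=8,
                                       relapse_gain_chrom=None)
        quiet = [c for c in tree.clones if not tree.branch_events[c]
                 and tree.parent[c] != 0]
        for c in quiet:
            p = tree.parent[c]
            assert (tree.profiles[c].major == tree.profiles[p].major).all()
            assert (tree.profiles[c].minor == tree.profiles[p].minor).all()


class TestSignatureMixture:
    def test_single_signature_frequencies(self, catalog):
        n = 96_000
        counts = synthetic.simulate_signature_mixture(
            {"clock_a": 1.0}, catalog, n, seed=1)
        p = catalog["clock_a"].to_numpy()
        freq = counts.to_numpy() / n
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(freq - p) <= 3 * se + 1e-9).mean() > 0.97
        assert counts.sum() == n

    def test_zero_mutations_gives_zero_vector(self, catalog):
        counts = synthetic.simulate_signature_mixture(
            {"flat": 1.0}, catalog, 0, seed=1)
        assert counts.sum() == 0

    def test_unnormalizable_exposures_rejected(self, catalog):
        with pytest.raises(ValueError, match="normalizable"):
            synthetic.simulate_signature_mixture({"flat": 0.0}, catalog,
                                                 10, seed=1)

    def test_mixture_recovered_by_refitting(self, catalog):
        counts = synthetic.simulate_signature_mixture(
            {"clock_a": 0.6, "fivefu": 0.4}, catalog, 1000, seed=2)
        fit = signatures.refit_exposures(counts.to_numpy(), catalog)
        recon = catalog.to_numpy() @ fit.exposures.to_numpy()
        truth = catalog.to_numpy() @ np.array([0.6, 0.0, 0.4, 0.0]) * 1000
        assert signatures.cosine_similarity(recon, truth) >= 0.95


class TestExpressionSimulation:
    def test_absent_genes_rejected(self):
        from crcrelapse.expression import GeneSet
        gs = GeneSet("bad", ("NOT_A_GENE",))
        with pytest.raises(ValueError, match="absent genes"):
            synthetic.simulate_expression(50, {"s1": "a"}, {gs: {"a": 1.0}},
                                          None, seed=1)

    def test_determinism(self):
        kw = dict(n_genes=100, groups={"s1": "a", "s2": "b"},
                  shifted_sets=None, cms_mixture={"s1": {"CMS1": 1.0}},
                  seed=42)
        a = synthetic.simulate_expression(**kw)
        b = synthetic.simulate_expression(**kw)
        pd.testing.assert_frame_equal(a.expr.values, b.expr.values)


class TestCohort:
    def test_patient_determinism_byte_identical(self):
        a = synthetic.simulate_patient("X", "private_branchoff", seed=17)
        b = synthetic.simulate_patient("X", "private_branchoff", seed=17)
        pd.testing.assert_frame_equal(a.table.alt, b.table.alt)
        pd.testing.assert_frame_equal(a.table.depth, b.table.depth)
        pd.testing.assert_frame_equal(a.segments, b.segments)
        pd.testing.assert_frame_equal(a.tree.phi, b.tree.phi)

    def test_cohort_structure_and_writers_round_trip(self, tmp_path):
        cohort = synthetic.simulate_cohort(3, seed=5)
        assert [p.scenario for p in cohort.patients] == list(synthetic.SCENARIOS)
        outdir = tmp_path / "cohort"
        synthetic.write_cohort(cohort, str(outdir))
        p = cohort.patients[0]
        back = variants.read_vcf(str(outdir / f"{p.patient}.vcf"),
                                 p.table.meta)
        order = back.muts.index
        pd.testing.assert_frame_equal(back.alt, p.table.alt.loc[order])
        purity = pd.read_csv(outdir / "purity.tsv", sep="\t")
        assert len(purity) == sum(len(q.table.samples)
                                  for q in cohort.patients)
        segs = pd.read_csv(outdir / "segments.tsv", sep="\t")
        assert {"sample", "chrom", "start", "end", "major", "minor"} <= \
            set(segs.columns)
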