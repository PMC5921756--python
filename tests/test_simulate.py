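import numpy as np
import pandas as pd
import pytest

from famkit import cre, genome, phylo, proteins, qpcr, simulate
from famkit.errors import FamkitError
from famkit.model import Motif
from famkit.phylo import TreeNode
from famkit.proteins import ACTIVATOR_QSL, DBD_ONLY, FULL, TRUNCATED_III_ONLY

CAACA = Motif("RAV1AAT", "CAACA")
AUXRE = Motif("AuxRe1", "TGTCTC")


class TestGenPromoters:
    def test_seed_determinism(self):
        a = simulate.gen_promoters(n=5, length=400, seed=1)
        b = simulate.gen_promoters(n=5, length=400, seed=1)
        assert [r.seq for r in a.sequences] == [r.seq for r in b.sequences]
        c = simulate.gen_promoters(n=5, length=400, seed=2)
        assert [r.seq for r in a.sequences] != [r.seq for r in c.sequences]

    def test_realized_gc_near_target(self):
        promoters = simulate.gen_promoters(n=23, length=1500, gc=0.28, seed=3)
        seqs = "".join(r.seq for r in promoters.sequences)
        n = len(seqs)
        gc = sum(seqs.count(b) for b in "GC") / n
        sd = (0.28 * 0.72 / n) ** 0.5
        assert abs(gc - 0.28) < 3 * sd

    def test_planted_copies_recovered_in_window(self):
        n = 10
        promoters = simulate.gen_promoters(
            n=n, length=1500, plant={AUXRE: (2, (-600, -400))}, seed=4
        )
        in_window = 0
        for rec in promoters.sequences:
            starts = cre.scan_promoter(rec.seq, AUXRE)
            rel = cre.tss_relative_positions(starts, len(rec.seq), promoters.length)
            in_window += sum(1 for p in rel if -600 <= p <= -400)
        assert in_window >= 2 * n

    def test_infeasible_planting_rejected(self):
        with pytest.raises(FamkitError):
            simulate.gen_promoters(n=2, length=1500, plant={AUXRE: (10, (-30, -1))}, seed=5)

    def test_null_mean_matches_bernoulli_expectation(self):
        # cross-validation of the generator against the closed-form model
        totals = []
        for seed in range(200):
            promoters = simulate.gen_promoters(n=4, length=300, gc=0.28, seed=seed)
            totals.append(sum(len(cre.scan_promoter(r.seq, CAACA)) for r in promoters.sequences))
        totals = np.array(totals)
        expected = cre.expected_occurrences(CAACA, cre.BackgroundModel(0.28), [300] * 4)
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - expected) < 3 * se


class TestGenProteinFamily:
    SCHEDULE = {FULL: 15, TRUNCATED_III_ONLY: 3, DBD_ONLY: 6}

    def test_schedule_recovered_exactly(self):
        records, annotations = simulate.gen_protein_family(self.SCHEDULE, n_activators=7, seed=6)
        assert len(records) == 24
        classes = [proteins.classify_architecture(annotations[r.id]) for r in records]
        assert classes.count(FULL) == 15
        assert classes.count(TRUNCATED_III_ONLY) == 3
        assert classes.count(DBD_ONLY) == 6
        truncated = sum(1 for c in classes if c != FULL)
        assert truncated / len(classes) * 100 == pytest.approx(37.5)

    def test_roles_recover_activator_count(self):
        records, annotations = simulate.gen_protein_family(self.SCHEDULE, n_activators=7, seed=7)
        background = proteins.mean_background(r.seq for r in records)
        roles = []
        for rec in records:
            arch = proteins.classify_architecture(annotations[rec.id])
            mr = proteins.extract_mr(rec.seq, annotations[rec.id])
            roles.append(proteins.classify_regulatory_role(mr, arch, background, rec.id).role)
        assert roles.count(ACTIVATOR_QSL) == 7
        assert round(proteins.activator_repressor_ratio(roles), 2) == 0.41

    def test_length_implies_architecture(self):
        records, annotations = simulate.gen_protein_family(self.SCHEDULE, n_activators=7, seed=8)
        for rec in records:
            arch = proteins.classify_architecture(annotations[rec.id])
            if len(rec.seq) < 670:
                assert arch == DBD_ONLY
            if len(rec.seq) > 725:
                assert arch == FULL

    def test_all_q_profile_makes_all_activators(self):
        records, annotations = simulate.gen_protein_family(
            {FULL: 4}, n_activators=4, seed=9,
            mr_profiles={"activator_qsl": {"Q": 1.0}},
        )
        background = proteins.mean_background(r.seq for r in records)
        for rec in records:
            mr = proteins.extract_mr(rec.seq, annotations[rec.id])
            role = proteins.classify_regulatory_role(mr, FULL, background, rec.id).role
            assert role == ACTIVATOR_QSL

    def test_bad_profile_rejected(self):
        with pytest.raises(FamkitError):
            simulate.gen_protein_family({FULL: 1}, seed=10, mr_profiles={"activator_qsl": {"Q": 0.5}})

    def test_seed_determinism(self):
        a, _ = simulate.gen_protein_family(self.SCHEDULE, n_activators=7, seed=11)
        b, _ = simulate.gen_protein_family(self.SCHEDULE, n_activators=7, seed=11)
        assert [r.seq for r in a] == [r.seq for r in b]


def four_taxon_tree(internal=0.3):
    t = TreeNode
    left = t(children=[(t(name="a"), 0.1), (t(name="b"), 0.15)])
    right = t(children=[(t(name="c"), 0.12), (t(name="d"), 0.2)])
    return t(children=[(left, internal / 2), (right, internal / 2)])


class TestGenAlignmentOnTree:
    def test_zero_length_branches_identical_sequences(self):
        t = TreeNode
        root = t(children=[(t(name="a"), 0.0), (t(name="b"), 0.0), (t(name="c"), 0.0)])
        aln = simulate.gen_alignment_on_tree(root, length=200, seed=12)
        assert len(set(aln.rows)) == 1
        assert phylo.p_distance(aln, "a", "b") == 0.0

    def test_topology_recovery_high_rate(self):
        hits = 0
        for seed in range(20):
            aln = simulate.gen_alignment_on_tree(four_taxon_tree(), length=5000, seed=seed)
            tree = phylo.nj_tree(phylo.distance_matrix(aln))
            sides = {frozenset(s) for s in tree.bipartitions()}
            if frozenset({"a", "b"}) in sides or frozenset({"c", "d"}) in sides:
                hits += 1
        assert hits >= 19

    def test_corrected_distance_tracks_path_length(self):
        aln = simulate.gen_alignment_on_tree(four_taxon_tree(internal=0.3), length=10_000, seed=13)
        dm = phylo.distance_matrix(aln)
        i, j = dm.taxa.index("a"), dm.taxa.index("c")
        # a->root (0.1 + 0.15) then root->c (0.15 + 0.12)
        true_path = 0.1 + 0.15 + 0.15 + 0.12
        assert abs(dm.d[i, j] - true_path) / true_path < 0.10

    def test_nonbinary_tree_rejected(self):
        t = TreeNode
        bad = t(children=[(t(name="a"), 0.1), (t(name="b"), 0.1),
                          (t(name="c"), 0.1), (t(name="d"), 0.1)])
        with pytest.raises(FamkitError):
            simulate.gen_alignment_on_tree(bad, length=10, seed=14)

    def test_seed_determinism(self):
        a = simulate.gen_alignment_on_tree(four_taxon_tree(), length=100, seed=15)
        b = simulate.gen_alignment_on_tree(four_taxon_tree(), length=100, seed=15)
        assert a.rows == b.rows


class TestGenCqTable:
    def truth(self):
        return pd.DataFrame(
            {"t1": [1.0, 2.0, 0.25], "t2": [1.0, 1.0, 8.0]},
            index=["cal", "s1", "s2"],
        )

    def test_noiseless_inversion_is_exact(self):
        eff = {a: 1.0 for a in ["r1", "t1", "t2"]}
        table = simulate.gen_cq_table(self.truth(), ["r1"], eff, "cal",
                                      replicate_sd=0.0, replicates=2, seed=16)
        result = qpcr.nrq(table, eff, ["r1"], "cal")
        assert np.allclose(result.nrq.values, self.truth().values)

    def test_loading_offsets_cancel(self):
        eff = {a: 0.9 for a in ["r1", "r2", "t1", "t2"]}
        table = simulate.gen_cq_table(self.truth(), ["r1", "r2"], eff, "cal",
                                      replicate_sd=0.0, replicates=1, seed=17,
                                      sample_load_sd=1.0)
        result = qpcr.nrq(table, eff, ["r1", "r2"], "cal")
        assert np.allclose(result.nrq.values, self.truth().values, rtol=1e-8)

    def test_cq_above_cycle_limit_not_detected(self):
        truth = pd.DataFrame({"t1": [1.0, 2.0 ** -40]}, index=["cal", "low"])
        eff = {"r1": 1.0, "t1": 1.0}
        table = simulate.gen_cq_table(truth, ["r1"], eff, "cal", base_cq=24.0, seed=18)
        low = table.data.query("sample == 'low' and assay == 't1'")
        assert low["cq"].isna().all()

    def test_seed_determinism(self):
        eff = {a: 1.0 for a in ["r1", "t1", "t2"]}
        a = simulate.gen_cq_table(self.truth(), ["r1"], eff, "cal", replicate_sd=0.2, seed=19)
        b = simulate.gen_cq_table(self.truth(), ["r1"], eff, "cal", replicate_sd=0.2, seed=19)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestGenKaksPairs:
    def test_fixed_ratio_construction(self):
        pairs = simulate.gen_kaks_pairs(50, components=((1.0, 0.19),), seed=20)
        summary = genome.duplication_summary(pairs)
        assert summary.mean_ratio == pytest.approx(0.19, abs=1e-9)

    def test_ks_endpoints_date_to_printed_span(self):
        for ks, mya in [(0.59, 48.36), (1.64, 134.43)]:
            assert genome.divergence_time(ks) == pytest.approx(mya, abs=0.01)
        pairs = simulate.gen_kaks_pairs(500, ks_range=(0.59, 1.64), seed=21)
        times = [p.time_mya for p in pairs]
        assert min(times) >= 48.3 and max(times) <= 134.5

    def test_mixture_positive_fraction(self):
        pairs = simulate.gen_kaks_pairs(
            2000, components=((0.9, 0.2), (0.1, 1.3)), seed=22
        )
        positive = sum(1 for p in pairs if p.mode == "positive")
        assert positive / len(pairs) == pytest.approx(0.10, abs=0.03)

    def test_seed_determinism(self):
        a = simulate.gen_kaks_pairs(10, seed=23)
        b = simulate.gen_kaks_pairs(10, seed=23)
        assert a == b
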