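import numpy as np
import pytest
from scipy import stats

from afpcompare import codon_usage as cu
from afpcompare import dotplot as dp
from afpcompare import helix_features as hf
from afpcompare import synthetic_data as sd
from afpcompare.seqio import RegionKind, extract_region, translate


class TestMaturePeptide:
    def test_layout_and_features(self, rng):
        pep = sd.make_mature_peptide(sd.SyntheticConfig(n_repeats=3), rng)
        assert len(pep.seq) == 5 + 3 * 11
        rep = hf.build_report(pep)
        assert rep.thr_period.best_phase == sd.TRUE_PHASE
        assert rep.n_cap == hf.NCap(1, 3)
        assert len(rep.salt_bridges) >= 1
        assert rep.ala_mol_percent > 50

    def test_single_repeat_still_capped(self, rng):
        pep = sd.make_mature_peptide(sd.SyntheticConfig(n_repeats=1), rng)
        assert pep.seq.startswith("MDAPA")
        assert hf.ala_mol_percent(pep) > 50

    def test_always_ala_rich(self, rng):
        cfg = sd.SyntheticConfig(thr_substitution_rate=0.2)
        for _ in range(200):
            assert hf.ala_mol_percent(sd.make_mature_peptide(cfg, rng)) > 50

    @pytest.mark.parametrize("sub_rate", [0.0, 0.1, 0.25])
    def test_phase_recovered_below_substitution_ceiling(self, sub_rate):
        cfg = sd.SyntheticConfig(thr_substitution_rate=sub_rate)
        rng = np.random.default_rng(7)
        recovered = 0
        for _ in range(200):
            pep = sd.make_mature_peptide(cfg, rng)
            tp = hf.thr_periodicity(pep)
            recovered += tp.best_phase == sd.TRUE_PHASE
        assert recovered / 200 >= 0.95

    def test_default_score_at_least_point_eight(self):
        rng = np.random.default_rng(13)
        cfg = sd.SyntheticConfig()
        for _ in range(100):
            tp = hf.thr_periodicity(sd.make_mature_peptide(cfg, rng))
            assert tp.score >= 0.8


class TestBackTranslate:
    def test_pure_gcg_bias(self, rng):
        pep = sd.make_mature_peptide(sd.SyntheticConfig(), rng)
        nt = sd.back_translate(pep, (0, 0, 0, 1), rng)
        codons = {nt[i : i + 3] for i in range(0, len(nt), 3)}
        ala_codons_used = codons & set(sd.ALA_CODONS)
        assert ala_codons_used == {"GCG"}

    def test_round_trip_translation(self, rng):
        for _ in range(10):
            pep = sd.make_mature_peptide(
                sd.SyntheticConfig(thr_substitution_rate=0.2), rng
            )
            nt = sd.back_translate(pep, (0.1, 0.2, 0.3, 0.4), rng)
            assert translate(nt).seq == pep.seq

    def test_law_of_large_numbers(self):
        rng = np.random.default_rng(5)
        from afpcompare.seqio import ProteinRecord

        pep = ProteinRecord(id="polyA", seq="A" * 10000, provenance="direct")
        bias = (0.1, 0.1, 0.1, 0.7)
        nt = sd.back_translate(pep, bias, rng)
        prof = cu.ala_profile(cu.count_codons(nt))
        for got, want in zip(prof.fractions, bias):
            assert abs(got - want) < 0.02


class TestMakeFamily:
    def test_deterministic(self):
        cfg = sd.SyntheticConfig(seed=42)
        recs1, truth1 = sd.make_family(cfg)
        recs2, truth2 = sd.make_family(cfg)
        assert [r.seq for r in recs1] == [r.seq for r in recs2]
        assert [r.regions for r in recs1] == [r.regions for r in recs2]
        assert truth1.events == truth2.events

    def test_zero_rates_give_identical_paralogs(self):
        cfg = sd.SyntheticConfig(seed=3, point_mut_rate=0, indel_rate=0, repeat_cnv_prob=0)
        recs, truth = sd.make_family(cfg)
        assert all(r.seq == truth.ancestor_seq for r in recs)
        assert all(evs == [] for evs in truth.events.values())

    def test_event_log_replays_byte_exactly(self):
        recs, truth = sd.make_family(sd.SyntheticConfig(seed=8, repeat_cnv_prob=0.9))
        for rec in recs:
            seq, regs = sd.apply_events(
                truth.ancestor_seq, truth.ancestor_regions, truth.events[rec.id]
            )
            assert seq == rec.seq
            assert regs == rec.regions

    def test_utr_identity_above_ninety(self):
        recs, _ = sd.make_family(sd.SyntheticConfig(seed=17))
        utrs = [extract_region(r, RegionKind.FIVE_PRIME_UTR) for r in recs]
        idents = [
            cu.pairwise_identity(a, b)
            for i, a in enumerate(utrs)
            for b in utrs[i + 1 :]
        ]
        assert np.mean(idents) > 90

    def test_paralogs_stay_translatable(self):
        recs, _ = sd.make_family(sd.SyntheticConfig(seed=23, point_mut_rate=0.05))
        for rec in recs:
            pep = translate(extract_region(rec, RegionKind.MATURE_CDS))
            assert len(pep.seq) > 10

    def test_repeat_cnv_changes_length_in_whole_repeat_units(self):
        cfg = sd.SyntheticConfig(
            seed=2, point_mut_rate=0, indel_rate=0, repeat_cnv_prob=1.0
        )
        recs, truth = sd.make_family(cfg)
        anc_cds_len = sum(
            len(r) for r in truth.ancestor_regions if r.kind == RegionKind.MATURE_CDS
        )
        diffs = {
            len(extract_region(r, RegionKind.MATURE_CDS)) - anc_cds_len for r in recs
        }
        assert diffs <= {-33, 0, 33}
        assert diffs & {-33, 33}

    def test_introns_annotated_when_requested(self):
        recs, _ = sd.make_family(sd.SyntheticConfig(seed=4, n_introns=2))
        for rec in recs:
            assert sum(1 for r in rec.regions if r.kind == RegionKind.INTRON) == 2


class TestConvergentGroups:
    def _cfgs(self, n=4, seed=100):
        return [
            sd.SyntheticConfig(
                seed=seed + i,
                scenario="convergent",
                ala_bias=tuple(np.eye(4)[i % 4] * 0.6 + 0.1),
            )
            for i in range(n)
        ]

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="at least 2"):
            sd.make_convergent_groups(self._cfgs(1))

    def test_requires_convergent_scenario(self):
        with pytest.raises(ValueError, match="convergent"):
            sd.make_convergent_groups(
                [sd.SyntheticConfig(seed=1), sd.SyntheticConfig(seed=2)]
            )

    def test_group_profiles_recover_biases(self):
        cfgs = self._cfgs(4)
        groups = sd.make_convergent_groups(cfgs)
        for cfg, (recs, _) in zip(cfgs, groups.values()):
            tables = [
                cu.count_codons(
                    cu.trim_partial_codons(extract_region(r, RegionKind.MATURE_CDS))
                )
                for r in recs
            ]
            prof = cu.ala_profile(tables)
            assert int(np.argmax(prof.fractions)) == int(np.argmax(cfg.ala_bias))

    def test_same_seed_different_bias_same_peptide_layout(self):
        a = sd.SyntheticConfig(seed=9, scenario="convergent", ala_bias=(0.7, 0.1, 0.1, 0.1))
        b = sd.SyntheticConfig(seed=9, scenario="convergent", ala_bias=(0.1, 0.1, 0.1, 0.7))
        groups = sd.make_convergent_groups([a, b])
        (ra, _), (rb, _) = groups.values()
        pa = translate(extract_region(ra[0], RegionKind.MATURE_CDS))
        pb = translate(extract_region(rb[0], RegionKind.MATURE_CDS))
        assert pa.seq == pb.seq
        assert extract_region(ra[0], RegionKind.MATURE_CDS) != extract_region(
            rb[0], RegionKind.MATURE_CDS
        )

    def test_cross_group_utr_similarity_negligible(self):
        groups = sd.make_convergent_groups(self._cfgs(3, seed=300))
        reps = [max(recs, key=lambda r: len(r.seq)) for recs, _ in groups.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                res = dp.compute_dotplot(
                    reps[i].seq, reps[j].seq, dp.DotplotParams(12, 9)
                )
                score = dp.utr_similarity_score(
                    res, reps[i].regions, reps[j].regions
                )
                assert score < 0.05


class TestBackgroundGenes:
    def test_pooled_profile_prefers_gcc(self):
        rng = np.random.default_rng(11)
        genes = sd.make_background_genes(sd.SyntheticConfig(), 20, rng, codon_len_range=(50, 150))
        tables = [
            cu.count_codons(cu.trim_partial_codons(extract_region(g, RegionKind.MATURE_CDS)))
            for g in genes
        ]
        prof = cu.ala_profile(tables)
        assert int(np.argmax(prof.fractions)) == 1  # GCC

    def test_single_gene_valid(self):
        genes = sd.make_background_genes(
            sd.SyntheticConfig(), 1, np.random.default_rng(0)
        )
        assert len(genes) == 1
        assert genes[0].regions[0].kind == RegionKind.MATURE_CDS

    def test_deterministic(self):
        g1 = sd.make_background_genes(sd.SyntheticConfig(), 3, np.random.default_rng(4))
        g2 = sd.make_background_genes(sd.SyntheticConfig(), 3, np.random.default_rng(4))
        assert [g.seq for g in g1] == [g.seq for g in g2]

    def test_survive_curation_by_construction(self):
        rng = np.random.default_rng(6)
        genes = sd.make_background_genes(
            sd.SyntheticConfig(), 10, rng, codon_len_range=(50, 120)
        )
        assert len(cu.curate_background(genes)) == 10


def test_homologous_scores_stochastically_dominate_convergent():
    """UTR similarity separates the two evolutionary scenarios sharply."""
    homol, conv = [], []
    for k in range(12):
        recs, _ = sd.make_family(sd.SyntheticConfig(seed=1000 + k, n_paralogs=2))
        a, b = recs
        res = dp.compute_dotplot(a.seq, b.seq, dp.DotplotParams(10, 9))
        homol.append(dp.utr_similarity_score(res, a.regions, b.regions))

        cfg_a = sd.SyntheticConfig(
            seed=2000 + 2 * k, scenario="convergent", ala_bias=(0.7, 0.1, 0.1, 0.1)
        )
        cfg_b = sd.SyntheticConfig(
            seed=2001 + 2 * k, scenario="convergent", ala_bias=(0.1, 0.1, 0.1, 0.7)
        )
        groups = sd.make_convergent_groups([cfg_a, cfg_b])
        (ra, _), (rb, _) = groups.values()
        res = dp.compute_dotplot(ra[0].seq, rb[0].seq, dp.DotplotParams(12, 9))
        conv.append(dp.utr_similarity_score(res, ra[0].regions, rb[0].regions))
    u = stats.mannwhitneyu(homol, conv, alternative="greater")
    assert u.pvalue < 1e-4
    assert min(homol) > max(conv)
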