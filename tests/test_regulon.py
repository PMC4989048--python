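"""Motif scanning, rank aggregation, AUC recovery and evidence integration."""

import numpy as np
import pandas as pd
import pytest
from math import comb
from hypothesis import given, settings, strategies as st

from phenosubnet import regulon as rg
from phenosubnet.synthio import simulate_regulon_evidence

UNIFORM = np.full(4, 0.25)


def consensus_pwm(consensus: str, p: float = 0.85):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        pwm[i, idx[b]] = p
    return pwm


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestPromoterScore:
    def test_hitless_sequence_scores_zero(self):
        pwm = consensus_pwm("ACGTACGT")
        assert rg.score_promoter(pwm, UNIFORM, "CCCCCCCCCCCCCCCCCC") == 0.0

    def test_planted_consensus_raises_score(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        background_seq = "".join(rng.choice(list(bases), 300))
        consensus = "ACGTTGCA"
        pwm = consensus_pwm(consensus)
        planted = background_seq[:100] + consensus + background_seq[108:]
        lo_max = np.log2(np.max(pwm, axis=1) / 0.25).sum()
        s_planted = rg.score_promoter(pwm, UNIFORM, planted)
        s_plain = rg.score_promoter(pwm, UNIFORM, background_seq)
        assert s_planted >= lo_max - 1e-9
        assert s_planted > s_plain

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 200))
        seq = seq[:50] + "ACGTTGCA" + seq[58:]
        pwm = consensus_pwm("ACGTTGCA")
        assert rg.score_promoter(pwm, UNIFORM, seq) == pytest.approx(
            rg.score_promoter(pwm, UNIFORM, revcomp(seq)))

    def test_short_sequence_scores_zero(self):
        assert rg.score_promoter(consensus_pwm("ACGTACGT"), UNIFORM, "ACG") == 0.0

    def test_batch_matches_scalar_path(self):
        rng = np.random.default_rng(2)
        seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), 150)) for i in range(20)}
        pwm = consensus_pwm("TTGACGCA")
        batch = rg.score_promoters(pwm, UNIFORM, seqs)
        for g, seq in seqs.items():
            assert batch[g] == pytest.approx(rg.score_promoter(pwm, UNIFORM, seq))


class TestRanking:
    def test_distinct_scores_are_permutation(self):
        ranks = rg.rank_genes_per_species({"a": 3.0, "b": 1.0, "c": 2.0})
        assert sorted(ranks) == [1.0, 2.0, 3.0]
        assert ranks["a"] == 1 and ranks["b"] == 3 and ranks["c"] == 2

    def test_ties_get_average_rank(self):
        ranks = rg.rank_genes_per_species({"a": 5.0, "b": 5.0, "c": 1.0})
        assert ranks["a"] == ranks["b"] == 1.5


class TestAggregateRanks:
    def test_single_list_reduces_to_uniform_cdf(self):
        ranking = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0})
        rho = rg.aggregate_ranks([ranking])
        assert rho["a"] == pytest.approx(0.2)

    def test_unanimous_top_gene_has_smallest_rho(self):
        rankings = []
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        for _ in range(4):
            others = rng.permutation(genes[1:]).tolist()
            order = ["g0"] + others
            rankings.append(pd.Series({g: i + 1.0 for i, g in enumerate(order)}))
        rho = rg.aggregate_ranks(rankings)
        assert rho.index[0] == "g0"

    def test_matches_binomial_sum_order_statistic_oracle(self):
        # P(U_(k) <= x) = sum_{j>=k} C(L,j) x^j (1-x)^(L-j): independent oracle
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(5)]
        rankings = []
        for _ in range(3):
            order = rng.permutation(genes)
            rankings.append(pd.Series({g: i + 1.0 for i, g in enumerate(order)}))
        rho = rg.aggregate_ranks(rankings)
        L = 3
        for g in genes:
            r = sorted(rankings[j][g] / len(genes) for j in range(L))
            best = min(
                sum(comb(L, j) * r[k] ** j * (1 - r[k]) ** (L - j)
                    for j in range(k + 1, L + 1))
                for k in range(L)
            )
            assert rho[g] == pytest.approx(min(1.0, L * best), abs=1e-12)

    def test_missing_genes_penalised_with_unit_rank(self):
        r1 = pd.Series({"a": 1.0, "b": 2.0})
        r2 = pd.Series({"a": 1.0})
        rho = rg.aggregate_ranks([r1, r2], genes=["a", "b"])
        assert rho["a"] < rho["b"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rg.aggregate_ranks([])


class TestAucRecovery:
    def test_hand_enumerated_case(self):
        ranking = [f"g{i}" for i in range(20)]
        auc = rg.auc_recovery(ranking, {"g0", "g1"}, top_fraction=0.5)
        assert auc == pytest.approx(0.95)

    def test_set_outside_top_fraction_scores_zero(self):
        ranking = [f"g{i}" for i in range(100)]
        assert rg.auc_recovery(ranking, {"g90", "g95"}, 0.03) == 0.0

    def test_saturated_top_attains_maximum(self):
        ranking = [f"g{i}" for i in range(100)]
        members = {f"g{i}" for i in range(3)}
        auc = rg.auc_recovery(ranking, members, 0.03)
        x, s = 3, 3
        best = sum(min(i + 1, s) for i in range(x)) / (x * s)
        assert auc == pytest.approx(best)

    @given(st.integers(min_value=0, max_value=18))
    @settings(max_examples=20, deadline=None)
    def test_promoting_a_member_never_decreases_auc(self, pos):
        ranking = [f"g{i}" for i in range(20)]
        members = {"g10", "g15"}
        base = rg.auc_recovery(ranking, members, 0.5)
        promoted = list(ranking)
        promoted.remove("g15")
        promoted.insert(min(pos, 15), "g15")
        if promoted.index("g15") <= ranking.index("g15"):
            assert rg.auc_recovery(promoted, members, 0.5) >= base - 1e-12


class TestZScores:
    def test_equal_aucs_give_zero(self):
        out = rg.motif_zscores({"m1": 0.5, "m2": 0.5, "m3": 0.5})
        assert all(e.z_score == 0 and not e.passes for e in out)

    def test_z_boundary_is_inclusive(self):
        assert rg.MotifEnrichment("m", 0.5, 3.0).passes
        assert not rg.MotifEnrichment("m", 0.5, np.nextafter(3.0, 0.0)).passes
        # and the z formula itself matches direct mean/sd arithmetic
        aucs = {f"m{i}": 0.1 for i in range(11)}
        aucs["hi"] = 0.9
        vals = np.array(list(aucs.values()))
        expect = (0.9 - vals.mean()) / vals.std(ddof=1)
        hi = next(e for e in rg.motif_zscores(aucs) if e.motif_id == "hi")
        assert hi.z_score == pytest.approx(expect)
        assert hi.passes == (expect >= 3.0)

    def test_single_outlier_is_the_only_pass(self):
        # the collection must be large enough for z = 3 to be attainable:
        # the largest possible z among n values is (n-1)/sqrt(n)
        aucs = {f"m{i:02d}": 0.1 for i in range(15)}
        aucs["big"] = 0.9
        out = rg.motif_zscores(aucs)
        passes = [e.motif_id for e in out if e.passes]
        assert passes == ["big"]


class TestTextMining:
    def test_zero_overlap_gives_unit_p(self):
        res = rg.textmining_channel({"tf": {"a", "b"}}, {"c", "d"},
                                    {"a", "b", "c", "d", "e"})
        assert res["tf"][0] == pytest.approx(1.0)

    def test_saturated_universe_gives_unit_p(self):
        u = {"a", "b", "c"}
        res = rg.textmining_channel({"tf": set(u)}, set(u), u)
        assert res["tf"][0] == pytest.approx(1.0)

    def test_exact_combinatorial_value(self):
        universe = {f"u{i}" for i in range(10)}
        targets = {f"u{i}" for i in range(5)}
        res = rg.textmining_channel({"tf": targets}, targets, universe)
        assert res["tf"][0] == pytest.approx(1 / comb(10, 5), rel=1e-12)

    def test_matches_enumeration_on_small_universe(self):
        universe = {f"u{i}" for i in range(8)}
        targets = {f"u{i}" for i in range(4)}
        degs = {f"u{i}" for i in range(2, 6)}
        p = rg.textmining_channel({"tf": targets}, degs, universe)["tf"][0]
        k_obs = len(targets & degs)
        brute = sum(comb(4, k) * comb(4, 4 - k) for k in range(k_obs, 5)) / comb(8, 4)
        assert p == pytest.approx(brute, rel=1e-12)


class TestChannelsOnPlantedBundle:
    def test_all_planted_tfs_selected(self, planted_bundle):
        bundle, truth = planted_bundle
        outcomes = rg.evaluate_evidence(bundle)
        selected = rg.integrate_evidence(outcomes)
        assert set(truth.regulons) <= set(selected)

    def test_two_channel_rule(self):
        def outcome(tf, motif_z, chip_z, tm_q):
            return rg.ChannelOutcome(
                tf=tf,
                motif=rg.MotifEnrichment(tf, 0.5, motif_z),
                chip=rg.MotifEnrichment(tf, 0.5, chip_z),
                textmining_p=tm_q, textmining_q=tm_q,
                coexpression=rg.MotifEnrichment(tf, 0.5, 0.0),
            )
        outcomes = {
            "both": outcome("both", 3.5, 3.1, 0.5),
            "tm_only": outcome("tm_only", 0.0, 0.0, 0.01),
            "none": outcome("none", 1.0, 2.9, 0.2),
        }
        assert rg.integrate_evidence(outcomes) == ["both"]

    def test_target_recovery_and_tf_edges(self, planted_bundle):
        bundle, truth = planted_bundle
        outcomes = rg.evaluate_evidence(bundle)
        regulons = rg.build_regulons(outcomes, bundle)
        by_tf = {r.tf: r for r in regulons}
        for tf, targets in truth.regulons.items():
            recovered = by_tf[tf].targets
            assert recovered <= bundle.degs
            assert len(recovered & targets) / len(targets) >= 0.6
        union = set().union(*(r.targets for r in regulons))
        assert len(union) <= len(bundle.degs)

    def test_recover_targets_respects_top_fraction(self):
        ranking = [f"g{i}" for i in range(100)]
        degs = {"g1", "g50"}
        got = rg.recover_targets("tf", ranking, degs, top_fraction=0.03)
        assert got == {"g1"}

    def test_coexpression_constant_column_cannot_pass(self):
        coexpr = pd.DataFrame(0.5, index=[f"tf{i}" for i in range(5)],
                              columns=[f"g{i}" for i in range(50)])
        out = rg.coexpression_channel(coexpr, {"g1", "g2"}, 0.1)
        assert all(not e.passes for e in out)


class TestPathwayOverlap:
    def test_disjoint_sets_unit_p(self):
        regs = [rg.Regulon(tf="t", channels=["chip"], targets={"a", "b"})]
        assert rg.tf_pathway_overlap(regs, {"c", "d"},
                                     {"a", "b", "c", "d", "e"}) == pytest.approx(1.0)

    def test_complete_containment_combinatorial(self):
        universe = {f"u{i}" for i in range(10)}
        targets = {f"u{i}" for i in range(4)}
        regs = [rg.Regulon(tf="t", channels=["chip"], targets=targets)]
        p = rg.tf_pathway_overlap(regs, targets, universe)
        assert p == pytest.approx(1 / comb(10, 4), rel=1e-12)

    def test_planted_overlap_is_extreme(self, study):
        universe = set(study.evidence.genes)
        targets = set().union(*study.truth.regulons.values())
        regs = [rg.Regulon(tf="t", channels=["chip"], targets=targets)]
        p = rg.tf_pathway_overlap(regs, targets | {"G0999"}, universe)
        assert p < 1e-6

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            rg.tf_pathway_overlap([], set(), set())
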