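"""GTR+I+G simulator, planting operators and pruning likelihoods."""

import dendropy
import numpy as np
import pytest

from cladesig.errors import PlantSpecError, TaxaError
from cladesig.nhs_scan import CladePartition, find_nhs
from cladesig.seq_data import AlignedSeqSet
from cladesig.synthetic_data import (
    SENTINEL_LNL,
    GTREigen,
    IntronPlant,
    ModelParams,
    PlantedNHS,
    SimConfig,
    evaluate_planted_recovery,
    gamma_category_rates,
    mixture_rate_classes,
    planted_pairing_map,
    rate_matrix,
    simulate_alignment,
    simulate_sitelh,
    sitewise_loglik,
    study_config,
)


class TestModelParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParams(freqs=(0.5, 0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            ModelParams(r_ct=-1)
        with pytest.raises(ValueError):
            ModelParams(p_inv=1.0)

    def test_published_freqs_renormalised(self):
        p = ModelParams.ssu_gtr_ig()
        assert sum(p.freqs) == pytest.approx(1.0, abs=1e-12)
        assert p.p_inv == 0.6009 and p.gamma_shape == 0.6856

    def test_rate_matrix_normalised(self):
        for params in (ModelParams.jc(), ModelParams.ssu_gtr_ig()):
            Q = rate_matrix(params)
            pi = np.asarray(params.freqs)
            assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
            assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)
            # detailed balance (reversibility)
            assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    def test_gamma_rates_mean_one(self):
        r = gamma_category_rates(0.6856, 4)
        assert r.mean() == pytest.approx(1.0)
        assert (np.diff(r) > 0).all()

    def test_mixture_mean_one(self):
        rates, weights = mixture_rate_classes(ModelParams.ssu_gtr_ig())
        assert (rates * weights).sum() == pytest.approx(1.0)
        assert rates[0] == 0.0 and weights[0] == pytest.approx(0.6009)

    def test_transition_rows_stochastic(self):
        eig = GTREigen(ModelParams.ssu_gtr_ig())
        for t in (0.0, 0.01, 0.5, 5.0):
            P = eig.transition(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert (P >= 0).all()


class TestSimulateAlignment:
    def test_zero_length_branches_identical_sequences(self):
        cfg = SimConfig(newick="(a:0,b:0,c:0);", params=ModelParams.jc(),
                        n_sites=200, seed=1)
        aln, _ = simulate_alignment(cfg)
        assert len(set(aln.seqs)) == 1

    def test_seed_determinism(self):
        cfg = study_config(5, n_sites=600, intron_length=40)
        a1, l1 = simulate_alignment(cfg)
        a2, l2 = simulate_alignment(cfg)
        assert a1.seqs == a2.seqs and a1.ids == a2.ids
        assert l1.equals(l2)

    def test_jc_divergence_matches_closed_form(self):
        t = 0.5
        cfg = SimConfig(newick=f"(a:{t / 2},b:{t / 2});",
                        params=ModelParams.jc(), n_sites=50000, seed=2)
        aln, _ = simulate_alignment(cfg)
        pdiff = np.mean(
            np.array(list(aln.seqs[0])) != np.array(list(aln.seqs[1]))
        )
        expect = 0.75 * (1 - np.exp(-4 * t / 3))
        se = np.sqrt(expect * (1 - expect) / 50000)
        assert abs(pdiff - expect) < 3 * se

    def test_stationary_frequencies_at_long_branch(self):
        params = ModelParams.ssu_gtr_ig()
        cfg = SimConfig(newick="(a:0.01,b:20);", params=params,
                        n_sites=100000, seed=3)
        aln, _ = simulate_alignment(cfg)
        chars = np.array(list(aln.seq_of("b")))
        for base, pi in zip("ACGT", params.freqs):
            obs = np.mean(chars == base)
            se = np.sqrt(pi * (1 - pi) / 100000)
            assert abs(obs - pi) < 4 * se

    def test_elevated_ct_rate_raises_transition_share(self):
        """C<->T exchangeability at its fitted value (5.25) versus 1 should
        visibly raise the share of C/T differences between two taxa."""
        def ct_share(r_ct, seed):
            params = ModelParams(r_ct=r_ct)
            cfg = SimConfig(newick="(a:0.2,b:0.2);", params=params,
                            n_sites=40000, seed=seed)
            aln, _ = simulate_alignment(cfg)
            a = np.array(list(aln.seqs[0]))
            b = np.array(list(aln.seqs[1]))
            diff = a != b
            ct = diff & (((a == "C") & (b == "T")) | ((a == "T") & (b == "C")))
            return ct.sum() / diff.sum()

        assert ct_share(5.2526, 4) > ct_share(1.0, 4) + 0.05

    def test_invalid_newick(self):
        with pytest.raises(TaxaError):
            simulate_alignment(
                SimConfig(newick="((a:1,b:1;", params=ModelParams.jc(),
                          n_sites=10, seed=0)
            )


class TestPlanting:
    def test_planted_columns_become_nhs(self):
        cfg = study_config(21)
        aln, ledger = simulate_alignment(cfg)
        scores = evaluate_planted_recovery(aln, ledger, cfg)
        assert scores == {"recall": 1.0, "precision": 1.0, "class_accuracy": 1.0}

    def test_homoplasy_breaks_planted_column(self):
        cfg = study_config(22, homoplasy_rate=1.0)
        aln, ledger = simulate_alignment(cfg)
        part = CladePartition(aln.clade_of)
        pm = planted_pairing_map(cfg)
        broken = ledger[(ledger["kind"] == "nhs") & ledger["broken"]]
        assert len(broken) > 0
        for row in broken.itertuples():
            cols = {r.column for r in find_nhs(aln, part, (row.clade,), pm)}
            assert int(row.column) not in cols

    def test_overlapping_planted_columns_rejected(self):
        cfg = SimConfig(
            newick="(a:0.1,b:0.1);", params=ModelParams.jc(), n_sites=20,
            seed=0, clade_of={"a": "A", "b": "B"},
            planted_nhs=[
                PlantedNHS(clade="A", column=5, state_in="A"),
                PlantedNHS(clade="A", column=5, state_in="C"),
            ],
        )
        with pytest.raises(PlantSpecError):
            simulate_alignment(cfg)

    def test_outside_equals_inside_rejected(self):
        cfg = SimConfig(
            newick="(a:0.1,b:0.1);", params=ModelParams.jc(), n_sites=20,
            seed=0, clade_of={"a": "A", "b": "B"},
            planted_nhs=[PlantedNHS(clade="A", column=3, state_in="A",
                                    outside_state="A")],
        )
        with pytest.raises(PlantSpecError):
            simulate_alignment(cfg)

    def test_intron_block_written(self):
        carriers = frozenset({"a"})
        cfg = SimConfig(
            newick="(a:0.1,b:0.1);", params=ModelParams.jc(), n_sites=50,
            seed=0, intron=IntronPlant(carriers=carriers, start=11, length=10),
        )
        aln, ledger = simulate_alignment(cfg)
        assert "-" not in aln.seq_of("a")
        assert aln.seq_of("b")[10:20] == "-" * 10
        assert ledger.iloc[0]["kind"] == "intron"


class TestSitewiseLoglik:
    def test_jc_pairwise_closed_form(self):
        aln = AlignedSeqSet(ids=["a", "b"], seqs=["AAAA", "AACG"])
        t = 0.5
        lnl = sitewise_loglik(aln, f"(a:{t / 2},b:{t / 2});", ModelParams.jc())
        match = 0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3))
        mismatch = 0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3))
        np.testing.assert_allclose(
            lnl, [np.log(match)] * 2 + [np.log(mismatch)] * 2, atol=1e-10
        )

    def test_zero_distance_identical_and_sentinel(self):
        aln = AlignedSeqSet(ids=["a", "b"], seqs=["AA", "AC"])
        lnl = sitewise_loglik(aln, "(a:0,b:0);", ModelParams.jc())
        assert lnl[0] == pytest.approx(np.log(0.25), abs=1e-12)
        assert lnl[1] == SENTINEL_LNL

    def test_gap_treated_as_missing(self):
        aln = AlignedSeqSet(ids=["a", "b"], seqs=["A-", "AN"])
        lnl = sitewise_loglik(aln, "(a:0.1,b:0.1);", ModelParams.jc())
        # column 2: both missing -> likelihood 1 under each state mix = sum pi
        assert lnl[1] == pytest.approx(0.0, abs=1e-10)

    def test_reroot_invariance(self):
        cfg = study_config(31, n_sites=400, intron_length=40)
        aln, _ = simulate_alignment(cfg)
        params = ModelParams.ssu_gtr_ig()
        tr = dendropy.Tree.get(data=cfg.newick, schema="newick",
                               preserve_underscores=True)
        l1 = sitewise_loglik(aln, tr, params)
        node = tr.find_node_with_taxon_label("E1").parent_node
        tr.reroot_at_node(node, update_bipartitions=False)
        l2 = sitewise_loglik(aln, tr, params)
        assert abs(l1.sum() - l2.sum()) < 1e-8

    def test_taxon_order_invariance(self):
        cfg = study_config(32, n_sites=300, intron_length=40)
        aln, _ = simulate_alignment(cfg)
        rev = AlignedSeqSet(ids=list(reversed(aln.ids)),
                            seqs=list(reversed(aln.seqs)))
        params = ModelParams.ssu_gtr_ig()
        assert abs(
            sitewise_loglik(aln, cfg.newick, params).sum()
            - sitewise_loglik(rev, cfg.newick, params).sum()
        ) < 1e-8

    def test_taxon_mismatch(self):
        aln = AlignedSeqSet(ids=["a", "b"], seqs=["AA", "AC"])
        with pytest.raises(TaxaError):
            sitewise_loglik(aln, "(a:0.1,x:0.1);", ModelParams.jc())


class TestSimulateSitelh:
    def test_exchangeable_null_shape(self):
        S = simulate_sitelh(3, 100, seed=1)
        assert S.n_trees == 3 and S.n_sites == 100

    def test_offset_separates_totals(self):
        S = simulate_sitelh(2, 5000, offsets=[0.5, 0.0], noise_sd=0.1, seed=2)
        assert S.totals[0] > S.totals[1]

    def test_seed_determinism(self):
        a = simulate_sitelh(2, 50, seed=9)
        b = simulate_sitelh(2, 50, seed=9)
        np.testing.assert_array_equal(a.L, b.L)
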