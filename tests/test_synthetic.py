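"""Synthetic generators: reproducibility, planted structure, toy fixtures."""

import numpy as np
import pytest
from scipy import stats

from crisprattn.encoding import encode_dimers
from crisprattn.errors import ValidationError
from crisprattn.synthetic import (
    OffTargetSimConfig,
    OnTargetSimConfig,
    gen_offtarget,
    gen_ontarget,
    latent_activity,
)


class TestOffTarget:
    def test_seed_for_seed_reproducible(self):
        a = gen_offtarget(OffTargetSimConfig(n_guides=5, decoys_per_guide=10, seed=9))
        b = gen_offtarget(OffTargetSimConfig(n_guides=5, decoys_per_guide=10, seed=9))
        assert [(p.sgrna_seq, p.dna_seq, p.score) for p in a.pairs] == [
            (p.sgrna_seq, p.dna_seq, p.score) for p in b.pairs
        ]

    def test_zero_mismatch_zero_noise_is_maximal(self):
        cfg = OffTargetSimConfig(n_guides=4, decoys_per_guide=20, noise_sd=0.0, seed=1)
        sim = gen_offtarget(cfg)
        perfect = [p.score for p in sim.pairs if p.n_mismatches == 0]
        assert perfect and all(s == pytest.approx(100.0) for s in perfect)
        assert max(p.score for p in sim.pairs) <= 100.0

    def test_position_weight_ordering(self):
        w = np.zeros(20)
        w[10] = 2.0
        assert latent_activity(w, [10]) < latent_activity(w, [0])

    def test_labeling_count(self):
        sim = gen_offtarget(OffTargetSimConfig(n_guides=50, decoys_per_guide=80, seed=0))
        labels = np.array([p.label for p in sim.pairs])
        assert labels.sum() == round(0.2 * 4000)

    def test_mismatch_counts_within_bound(self):
        sim = gen_offtarget(OffTargetSimConfig(n_guides=10, decoys_per_guide=30, seed=2))
        assert all(p.n_mismatches <= 6 for p in sim.pairs)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            OffTargetSimConfig(n_guides=0)
        with pytest.raises(ValidationError):
            OffTargetSimConfig(position_weights=-np.ones(20))


class TestOnTarget:
    def test_seed_for_seed_reproducible(self):
        a = gen_ontarget(OnTargetSimConfig(n_guides=20, seed=4))
        b = gen_ontarget(OnTargetSimConfig(n_guides=20, seed=4))
        assert [(r.seq, r.efficiency, r.gene_id) for r in a.records] == [
            (r.seq, r.efficiency, r.gene_id) for r in b.records
        ]

    def test_zero_gene_effect_decorrelates_netexpress(self):
        sim = gen_ontarget(
            OnTargetSimConfig(n_guides=400, gene_effect_via_network=0.0, seed=5)
        )
        ne = np.array([r.netexpress for r in sim.records])
        eff = np.array([r.efficiency for r in sim.records])
        observed = abs(stats.spearmanr(ne, eff).statistic)
        # permutation null for |spearman| at this n
        rng = np.random.default_rng(0)
        null = [
            abs(stats.spearmanr(ne, rng.permutation(eff)).statistic) for _ in range(200)
        ]
        assert observed < np.quantile(null, 0.99)

    def test_noiseless_single_position_signal_recomputes_exactly(self):
        effects = np.zeros((33, 16))
        effects[18] = np.linspace(-1, 1, 16)
        cfg = OnTargetSimConfig(
            n_guides=30, dimer_effects=effects, gene_effect_via_network=0.0,
            noise_sd=0.0, seed=6,
        )
        sim = gen_ontarget(cfg)
        for r in sim.records:
            tok = encode_dimers(r.seq).tokens[18]
            assert r.efficiency == pytest.approx(effects[18, tok])

    def test_identical_expression_gives_identical_efficiencies(self):
        cfg = OnTargetSimConfig(
            n_guides=25, shared_expression=True, noise_sd=0.0, seed=7
        )
        sim = gen_ontarget(cfg)
        by_seq = {}
        for r in sim.records:
            by_seq.setdefault(r.seq, []).append(r.efficiency)
        assert all(len(set(v)) == 1 for v in by_seq.values())

    def test_cross_cell_line_discordance_with_distinct_expression(self):
        sim = gen_ontarget(OnTargetSimConfig(n_guides=200, seed=8))
        eff = {}
        for r in sim.records:
            eff.setdefault(r.cell_line, []).append(r.efficiency)
        rho = stats.spearmanr(eff["CL1"], eff["CL2"]).statistic
        assert 0.1 < rho < 0.99  # correlated via the shared sequence term, not identical


class TestToyFixtures:
    def test_network_hand_sums(self, toy):
        from crisprattn.netexpress import compute_all

        scores = compute_all(toy.network, toy.expression)
        for gene, expected in toy.expected_netexpress.items():
            assert scores[gene].score == pytest.approx(expected)

    def test_guide_encodes_to_documented_dimers(self, toy):
        from crisprattn.encoding import dimer_name

        ts = encode_dimers(toy.guides[0].seq)
        assert [dimer_name(t, rna=True) for t in ts.tokens] == ["AU", "UG", "GC", "CU"]

    def test_perfect_pair_match_tokens_only(self, toy):
        from crisprattn.encoding import MATCH_TOKENS, encode_base_pairs

        assert set(encode_base_pairs(toy.perfect_pair).tokens.tolist()) <= MATCH_TOKENS
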