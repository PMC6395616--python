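"""NG86 Ka/Ks counting and Ks mixture decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_ng86
from paleofrac.molevol import (
    batch_ng86,
    block_ks,
    classify_blocks_by_ks,
    encode_cds,
    fit_ks_mixture,
    ks_mixture_bic,
    ng86_kaks,
)
from paleofrac.synthetic_data import CodonProcess, codons_to_seq, simulate_cds_pairs, to64

SENSE_CODONS = [
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
]


def random_cds(rng, n_codons):
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))


class TestNg86:
    def test_identical_sequences_zero(self):
        r = ng86_kaks("TTGAAACCC", "TTGAAACCC")
        assert (r.ka, r.ks) == (0.0, 0.0)

    def test_phe_synonymous_single_difference(self):
        r = ng86_kaks("TTT", "TTC")
        assert r.syn_diffs == pytest.approx(1.0)
        assert r.nonsyn_diffs == pytest.approx(0.0)

    def test_two_codon_toy_matches_oracle(self):
        a, b = "TTGAAA", "AGAAAA"
        r = ng86_kaks(a, b)
        ka_o, ks_o = oracle_ng86(a, b)
        assert r.ka == pytest.approx(ka_o, abs=1e-12)
        assert r.ks == pytest.approx(ks_o, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            a, b = random_cds(rng, n), random_cds(rng, n)
            r = ng86_kaks(a, b)
            ka_o, ks_o = oracle_ng86(a, b)
            for got, want in ((r.ka, ka_o), (r.ks, ks_o)):
                if math.isinf(want):
                    assert math.isinf(got)
                else:
                    assert got == pytest.approx(want, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_cds(rng, 6), random_cds(rng, 6)
        r1, r2 = ng86_kaks(a, b), ng86_kaks(b, a)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12) or (
            math.isinf(r1.ks) and math.isinf(r2.ks)
        )
        assert r1.ka == pytest.approx(r2.ka, abs=1e-12) or (
            math.isinf(r1.ka) and math.isinf(r2.ka)
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ng86_kaks("TTT", "TTTAAA")

    def test_stop_codons_dropped_pairwise(self):
        r = ng86_kaks("TTTTAA", "TTCAAA")  # second codon is a stop in seq a
        assert r.n_codons == 1

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        pairs = [(random_cds(rng, 40), random_cds(rng, 40)) for _ in range(10)]
        arr_a = np.stack([encode_cds(a) for a, _ in pairs])
        arr_b = np.stack([encode_cds(b) for _, b in pairs])
        res = batch_ng86(arr_a, arr_b)
        for k, (a, b) in enumerate(pairs):
            r = ng86_kaks(a, b)
            if math.isfinite(r.ks):
                assert res["ks"][k] == pytest.approx(r.ks, abs=1e-12)
            if math.isfinite(r.ka):
                assert res["ka"][k] == pytest.approx(r.ka, abs=1e-12)

    def test_dnds_ratio_recovered_from_simulation(self):
        """Sequences evolved at dN/dS = 0.2 estimate a ratio near 0.2."""
        pairs = simulate_cds_pairs(60, 400, dnds=0.2, ks_target=0.35, seed=9)
        ratios = [ng86_kaks(a, b).ratio for a, b in pairs]
        ratios = [r for r in ratios if math.isfinite(r)]
        assert abs(float(np.mean(ratios)) - 0.2) < 0.05

    def test_neutral_process_ratio_near_one(self):
        pairs = simulate_cds_pairs(30, 500, dnds=1.0, ks_target=0.4, seed=9)
        ratios = [ng86_kaks(a, b).ratio for a, b in pairs]
        assert abs(float(np.mean(ratios)) - 1.0) < 0.08

    def test_ks_calibration_hits_target(self):
        for target in (0.2, 0.4, 1.0):
            pairs = simulate_cds_pairs(40, 500, dnds=0.3, ks_target=target, seed=4)
            ks = [ng86_kaks(a, b).ks for a, b in pairs]
            assert float(np.mean(ks)) == pytest.approx(target, rel=0.12)


class TestBlockKs:
    class _B:
        def __init__(self, pairs):
            self.pairs = pairs
            self.median_ks = None

    class _P:
        def __init__(self, a, b):
            self.gene_a, self.gene_b = a, b

    def test_median_of_finite_values(self):
        b = self._B([self._P("a", str(i)) for i in range(3)])
        ks = {("a", "0"): 0.1, ("a", "1"): 0.3, ("a", "2"): 0.5}
        assert block_ks(b, ks) == pytest.approx(0.3)

    def test_saturated_pairs_excluded(self):
        b = self._B([self._P("a", "0"), self._P("a", "1")])
        assert block_ks(b, {("a", "0"): 0.2, ("a", "1"): math.inf}) == pytest.approx(0.2)

    def test_all_saturated_flags_block(self):
        b = self._B([self._P("a", "0")])
        assert block_ks(b, {("a", "0"): math.inf}) is None
        assert b.median_ks is None


class TestKsMixture:
    def draws(self, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        comp = rng.random(n) < 0.55
        return np.where(comp, rng.normal(0.40, 0.08, n), rng.normal(1.37, 0.20, n))

    def test_single_component_recovers_sample_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.05, 400)
        m = fit_ks_mixture(x, k=1, seed=0)
        assert m.means[0] == pytest.approx(float(x[(x > 0) & (x <= 3)].mean()), abs=1e-6)

    def test_two_component_recovery_within_003(self):
        m = fit_ks_mixture(self.draws(), k=2, seed=0)
        assert abs(m.means[0] - 0.40) < 0.03
        assert abs(m.means[1] - 1.37) < 0.03
        assert abs(m.weights[0] - 0.55) < 0.05

    def test_loglik_monotone_nondecreasing(self):
        m = fit_ks_mixture(self.draws(1000, 3), k=2, seed=0)
        h = np.array(m.loglik_history)
        assert (np.diff(h) >= -1e-8).all()

    def test_k2_loglik_at_least_k1(self):
        x = self.draws(2000, 5)
        m1 = fit_ks_mixture(x, k=1, seed=0)
        m2 = fit_ks_mixture(x, k=2, seed=0)
        assert m2.loglik >= m1.loglik - 1e-6

    def test_agrees_with_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = self.draws(4000, 11)
        m = fit_ks_mixture(x, k=2, seed=0)
        ref = sklearn.GaussianMixture(2, random_state=0, n_init=3).fit(
            x[(x > 0) & (x <= 3)].reshape(-1, 1)
        )
        ref_means = np.sort(ref.means_.ravel())
        assert np.allclose(m.means, ref_means, atol=0.02)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            fit_ks_mixture([0.4] * 15, k=2)

    def test_bic_prefers_two_components_on_bimodal_data(self):
        bic = ks_mixture_bic(self.draws(3000, 7), k_range=(1, 2, 3))
        assert bic[2] < bic[1]


class TestClassifyBlocks:
    class _B:
        def __init__(self, ks):
            self.median_ks = ks

    def test_posterior_rule_at_component_means(self):
        m = fit_ks_mixture(TestKsMixture().draws(), k=2, seed=0)
        recent, ancient = classify_blocks_by_ks([self._B(0.40), self._B(1.37)], m)
        assert [b.median_ks for b in recent] == [0.40]
        assert [b.median_ks for b in ancient] == [1.37]

    def test_hard_interval_mode(self):
        m = fit_ks_mixture(TestKsMixture().draws(), k=2, seed=0)
        recent, ancient = classify_blocks_by_ks(
            [self._B(0.9), self._B(1.2)], m, ks_interval=(1.0, 2.0)
        )
        assert len(recent) == 1 and len(ancient) == 1

    def test_blocks_without_ks_excluded(self):
        m = fit_ks_mixture(TestKsMixture().draws(), k=2, seed=0)
        recent, ancient = classify_blocks_by_ks([self._B(None)], m)
        assert recent == [] and ancient == []

    def test_planted_labels_recovered_with_separated_peaks(self):
        rng = np.random.default_rng(2)
        truth = rng.random(400) < 0.6
        ks = np.where(truth, rng.normal(0.4, 0.08, 400), rng.normal(1.37, 0.2, 400))
        m = fit_ks_mixture(ks, k=2, seed=0)
        blocks = [self._B(float(v)) for v in ks]
        recent, ancient = classify_blocks_by_ks(blocks, m)
        recent_set = {id(b) for b in recent}
        correct = sum(
            1
            for b, t in zip(blocks, truth)
            if (id(b) in recent_set) == bool(t)
        )
        assert correct / len(blocks) >= 0.95
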