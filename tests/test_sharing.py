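"""Sharing statistics, model predictions, and the Pgen mixture fit."""

import numpy as np
import pytest

from tcrshare.germline import build_model, tiny_demo_model
from tcrshare.model import GermlineSegment, RecombinationModel, generate_repertoire
from tcrshare.repertoire import Clonotype, Repertoire
from tcrshare.sharing import (
    coincidental_shared_pgen_reference,
    fit_pgen_mixture,
    normalized_sharing,
    pgen_distribution_of_shared,
    predict_sharing_inframe_weighted,
    predict_sharing_mc,
    sharing_vs_abundance,
)


def _rep(donor, seqs, counts=None, chain="alpha"):
    counts = counts or [1] * len(seqs)
    return Repertoire(donor, chain, [Clonotype(s, c) for s, c in zip(seqs, counts)])


class TestNormalizedSharing:
    def test_definition(self):
        r1 = _rep("a", ["AAAA", "CCCC", "GGGG"])
        r2 = _rep("b", ["AAAA", "CCCC", "TTTT", "ACGT"])
        res = normalized_sharing(r1, r2)
        assert res.shared == 2
        assert res.normalized == pytest.approx(2 / 12)
        assert res.sd == pytest.approx(np.sqrt(2) / 12)

    def test_disjoint_sets(self):
        res = normalized_sharing(_rep("a", ["AAAA"]), _rep("b", ["CCCC"]))
        assert res.normalized == 0.0 and res.sd == 0.0

    def test_identity_case(self):
        r = _rep("a", ["AAAA", "CCCC", "GGGG"])
        res = normalized_sharing(r, r)
        assert res.shared == 3
        assert res.normalized == pytest.approx(1 / 3)

    def test_count_rescaling_invariance(self):
        seqs1, seqs2 = ["AAAA", "CCCC"], ["AAAA", "GGGG"]
        a = normalized_sharing(_rep("a", seqs1, [1, 1]), _rep("b", seqs2, [1, 1]))
        b = normalized_sharing(_rep("a", seqs1, [90, 7]), _rep("b", seqs2, [3, 50]))
        assert a.normalized == b.normalized

    def test_chain_mismatch_rejected(self):
        with pytest.raises(ValueError, match="chain"):
            normalized_sharing(
                _rep("a", ["AAAA"], chain="alpha"), _rep("b", ["AAAA"], chain="beta")
            )


class TestPredictSharingMC:
    def test_full_universe_limit(self):
        # the 5-sequence universe of the demo model is saturated: overlap 5/25
        m0 = tiny_demo_model()
        pred, sd = predict_sharing_mc(m0, m0, 5, 5, frame_filter=None, replicates=5, rng_seed=1)
        assert pred == pytest.approx(0.2)
        assert sd == 0.0

    def test_symmetry_under_swap(self):
        m0 = tiny_demo_model()
        a = predict_sharing_mc(m0, m0, 3, 4, frame_filter=None, replicates=6, rng_seed=5)
        b = predict_sharing_mc(m0, m0, 4, 3, frame_filter=None, replicates=6, rng_seed=5)
        assert a[0] == pytest.approx(b[0], rel=0.3)

    def test_disjoint_germlines_share_nothing(self):
        ma = RecombinationModel(
            "VJ",
            [GermlineSegment("V0", "V", "AAAA"), GermlineSegment("J0", "J", "AAAA")],
            {("V0", "J0"): 1.0}, {"V0": [1.0]}, {"J0": [1.0]}, p_ins=[1.0],
        )
        mb = RecombinationModel(
            "VJ",
            [GermlineSegment("V0", "V", "CCCC"), GermlineSegment("J0", "J", "CCCC")],
            {("V0", "J0"): 1.0}, {"V0": [1.0]}, {"J0": [1.0]}, p_ins=[1.0],
        )
        pred, _ = predict_sharing_mc(ma, mb, 1, 1, frame_filter=None, replicates=3, rng_seed=0)
        assert pred == 0.0

    def test_unsatisfiable_filter_errors(self):
        det = RecombinationModel(
            "VJ",
            [GermlineSegment("V0", "V", "AAA"), GermlineSegment("J0", "J", "AAA")],
            {("V0", "J0"): 1.0}, {"V0": [1.0]}, {"J0": [1.0]}, p_ins=[1.0],
        )
        with pytest.raises(RuntimeError):
            predict_sharing_mc(det, det, 1, 1, frame_filter="out_of_frame",
                               replicates=2, rng_seed=0, )


class TestQWeightedSharing:
    def test_single_term(self):
        assert predict_sharing_inframe_weighted(
            {"AAA"}, {"AAA": 2.0}, {"AAA"}, {"AAA": 0.5}
        ) == pytest.approx(1.0)

    def test_reduces_to_unweighted_with_unit_q(self):
        rng = np.random.default_rng(0)
        pool = ["".join("ACGT"[i] for i in rng.integers(0, 4, 6)) for _ in range(60)]
        s1 = set(rng.choice(pool, 25, replace=False))
        s2 = set(rng.choice(pool, 30, replace=False))
        q = {s: 1.0 for s in pool}
        weighted = predict_sharing_inframe_weighted(s1, q, s2, q)
        assert weighted == pytest.approx(len(s1 & s2) / (len(s1) * len(s2)))

    def test_arithmetic(self):
        s1 = {"AAA", "CCC"}
        s2 = {"AAA", "CCC"}
        q1 = {"AAA": 1.0, "CCC": 3.0}
        q2 = {"AAA": 1.0, "CCC": 1.0}
        assert predict_sharing_inframe_weighted(s1, q1, s2, q2) == pytest.approx(1.0)

    def test_missing_q_named(self):
        with pytest.raises(KeyError, match="AAA"):
            predict_sharing_inframe_weighted({"AAA"}, {}, {"AAA"}, {"AAA": 1.0})


class TestPgenHistograms:
    BINS = np.arange(-12, 0.1, 1.0)

    def test_single_sequence_unit_mass(self, m0):
        hist, n_zero = pgen_distribution_of_shared(["CAGTT"], m0, self.BINS)
        assert n_zero == 0
        # log10(0.1) = -1 falls in the bin [-2, -1)... upper edge convention
        assert hist.sum() == pytest.approx(1.0)
        assert hist[np.digitize(np.log10(0.1), self.BINS) - 1] == pytest.approx(1.0)

    def test_zero_pgen_goes_to_sentinel(self, m0):
        hist, n_zero = pgen_distribution_of_shared(["CAGTT", "GGGG"], m0, self.BINS)
        assert n_zero == 1

    def test_empty_set_rejected(self, m0):
        with pytest.raises(ValueError):
            pgen_distribution_of_shared([], m0, self.BINS)

    def test_toy_universe_concentration(self, m0):
        reps = [s for s, _ in generate_repertoire(m0, 400, 3)]
        hist, _ = pgen_distribution_of_shared(reps, m0, np.arange(-2, 0.01, 0.25))
        # mass only at log10(0.6) and log10(0.1)
        assert hist.sum() == pytest.approx(1.0)
        occupied = np.flatnonzero(hist)
        assert len(occupied) == 2

    def test_coincidental_reference_deterministic_and_shifted(self):
        model = build_model("alpha")
        bins = np.arange(-14, -1.9, 0.5)
        h1, _ = coincidental_shared_pgen_reference(model, 1500, 1500, replicates=4, rng_seed=8, bins=bins)
        h2, _ = coincidental_shared_pgen_reference(model, 1500, 1500, replicates=4, rng_seed=8, bins=bins)
        assert np.array_equal(h1, h2)
        # stochastic dominance: shared sequences have higher Pgen than
        # generic generated sequences
        rng = np.random.default_rng(1)
        gen = [s for s, _ in generate_repertoire(model, 1500, 2)]
        logp = [np.log10(model.pgen(s)) for s in gen]
        gen_hist, _ = np.histogram(logp, bins=bins)
        gen_cdf = np.cumsum(gen_hist / gen_hist.sum())
        shared_cdf = np.cumsum(h1)
        assert (shared_cdf <= gen_cdf + 0.05).all()
        assert shared_cdf.mean() < gen_cdf.mean()


class TestMixtureFit:
    @staticmethod
    def _components():
        edges = np.linspace(-14, 0, 57)
        centers = (edges[:-1] + edges[1:]) / 2
        reg = np.exp(-0.5 * ((centers + 4) / 1.0) ** 2)
        coi = np.exp(-0.5 * ((centers + 9) / 1.2) ** 2)
        return reg / reg.sum(), coi / coi.sum()

    def test_pure_components(self):
        reg, coi = self._components()
        assert fit_pgen_mixture(coi * 1e4, reg, coi, n_boot=20).w == pytest.approx(0.0, abs=1e-3)
        assert fit_pgen_mixture(reg * 1e4, reg, coi, n_boot=20).w == pytest.approx(1.0, abs=1e-3)

    def test_recovery_at_operating_point(self):
        reg, coi = self._components()
        rng = np.random.default_rng(3)
        obs = rng.multinomial(100_000, 0.18 * reg + 0.82 * coi).astype(float)
        fit = fit_pgen_mixture(obs, reg, coi, n_boot=100, rng_seed=5)
        assert 0.16 <= fit.w <= 0.20
        assert fit.sd < 0.02

    def test_mismatched_bins_rejected(self):
        reg, coi = self._components()
        with pytest.raises(ValueError):
            fit_pgen_mixture(reg[:-1], reg, coi)


class TestSharingVsAbundance:
    def test_group_a_sharing_dominates(self):
        # clonesets made entirely of germline-matchable (group A)
        # sequences are lower-diversity, hence share more than group B
        model = build_model("alpha")
        rng = np.random.default_rng(4)
        pool_a, pool_b = [], []
        while len(pool_a) < 500 or len(pool_b) < 500:
            s, _ = model.sample(rng)
            (pool_a if model.is_zero_insertion_consistent(s) else pool_b).append(s)
        rep_a1 = _rep("a1", list(dict.fromkeys(pool_a))[:400])
        rep_a2 = _rep("a2", list(dict.fromkeys(pool_a))[100:480])
        rep_b1 = _rep("b1", list(dict.fromkeys(pool_b))[:400])
        rep_b2 = _rep("b2", list(dict.fromkeys(pool_b))[100:480])
        curve_a = sharing_vs_abundance(rep_a1, rep_a2, model, [200, 300], replicates=4, rng_seed=1)
        curve_b = sharing_vs_abundance(rep_b1, rep_b2, model, [200, 300], replicates=4, rng_seed=1)
        assert all(a.f0 > 0.95 for a in curve_a.classes)
        assert all(b.f0 < 0.05 for b in curve_b.classes)
        for ca, cb in zip(curve_a.classes, curve_b.classes):
            assert ca.predicted > cb.predicted

    def test_class_validation(self):
        model = tiny_demo_model()
        r = _rep("a", ["CATT", "CAGTT"])
        with pytest.raises(ValueError):
            sharing_vs_abundance(r, r, model, [5])
        with pytest.raises(ValueError):
            sharing_vs_abundance(r, r, model, [2, 2])
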