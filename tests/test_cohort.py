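"""Synthetic cohort generator: mechanisms and statistical signatures."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from tcrshare.cohort import (
    CohortConfig,
    DonorSpec,
    default_models,
    simulate_adult,
    simulate_aging_series,
    simulate_cord_blood,
    simulate_q_factors,
    simulate_twin_pair,
)
from tcrshare.insertions import insertion_posterior_mean
from tcrshare.repertoire import frame_subset, rank_clonotypes
from tcrshare.sharing import coincidental_shared_pgen_reference, normalized_sharing


@pytest.fixture(scope="module")
def beta_models():
    return default_models("beta")


@pytest.fixture(scope="module")
def alpha_models():
    return default_models("alpha")


def _f0(model, clones):
    return float(np.mean([model.is_zero_insertion_consistent(c.cdr3_nt) for c in clones]))


def _two_prop_z(p1, n1, p2, n2):
    p = (p1 * n1 + p2 * n2) / (n1 + n2)
    se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    return (p1 - p2) / se


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fetal_fraction": 1.2},
            {"twin_transfer": -0.1},
            {"fetal_decay_rate": -1.0},
            {"fetal_advantage": 0.5},
            {"zipf_exponent": 0.0},
            {"out_of_frame_fraction": {"beta": 1.5}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_tdt_plus_model_rejected_as_tdt_minus(self, beta_models):
        _, tp = beta_models
        with pytest.raises(ValueError, match="P_ins"):
            simulate_cord_blood(tp, tp, CohortConfig(n_clones=10))


class TestCordBlood:
    def test_deterministic_given_seed(self, beta_models):
        cfg = CohortConfig(n_clones=1500, seed=4)
        r1 = simulate_cord_blood(*beta_models, cfg)
        r2 = simulate_cord_blood(*beta_models, cfg)
        assert [(c.cdr3_nt, c.count) for c in r1.clonotypes] == [
            (c.cdr3_nt, c.count) for c in r2.clonotypes
        ]

    def test_out_of_frame_fraction_matches_config(self, beta_models):
        cfg = CohortConfig(n_clones=4000, seed=6)
        rep = simulate_cord_blood(*beta_models, cfg)
        frac = np.mean([c.frame == "out_of_frame" for c in rep.clonotypes])
        assert frac == pytest.approx(0.03, abs=0.012)

    def test_no_fetal_component_is_flat(self, beta_models):
        cfg = CohortConfig(n_clones=6000, fetal_fraction=0.0, fetal_advantage=1.0, seed=8)
        rep = simulate_cord_blood(*beta_models, cfg)
        ranked = rank_clonotypes(rep)
        _, tp = beta_models
        top, bottom = _f0(tp, ranked[:1500]), _f0(tp, ranked[-1500:])
        assert abs(_two_prop_z(top, 1500, bottom, 1500)) < 3.0

    def test_pure_fetal_is_fully_zero_insertion(self, beta_models):
        tm, _ = beta_models
        cfg = CohortConfig(n_clones=1200, fetal_fraction=1.0, seed=9)
        rep = simulate_cord_blood(*beta_models, cfg)
        assert all(tm.is_zero_insertion_consistent(c.cdr3_nt) for c in rep.clonotypes)

    def test_abundance_enrichment_of_zero_insertions(self, beta_models):
        # the core cord-blood signature: fetal size advantage makes the
        # top abundance bin far richer in germline-matchable clones
        _, tp = beta_models
        cfg = CohortConfig(n_clones=60_000, fetal_fraction=0.3, fetal_advantage=10.0, seed=10)
        rep = simulate_cord_blood(*beta_models, cfg)
        ranked = rank_clonotypes(rep)
        top, bottom = _f0(tp, ranked[:3000]), _f0(tp, ranked[-3000:])
        assert _two_prop_z(top, 3000, bottom, 3000) > 5.0


class TestAdult:
    def test_newborn_naive_matches_cord_statistics(self, beta_models):
        _, tp = beta_models
        cfg = CohortConfig(n_clones=8000, seed=12)
        cord = simulate_cord_blood(*beta_models, cfg)
        naive0 = simulate_adult(DonorSpec("n0", 0.0, "naive", "beta"), beta_models, cfg)
        f_cord = _f0(tp, rank_clonotypes(cord)[:2000])
        f_naive = _f0(tp, rank_clonotypes(naive0)[:2000])
        assert abs(_two_prop_z(f_cord, 2000, f_naive, 2000)) < 3.0

    def test_no_decay_means_age_independent_fraction(self, beta_models):
        _, tp = beta_models
        cfg = CohortConfig(n_clones=8000, fetal_decay_rate=0.0, seed=13)
        f0s = []
        for age in (5.0, 70.0):
            rep = simulate_adult(DonorSpec(f"a{age}", age, "naive", "beta"), beta_models, cfg)
            f0s.append(_f0(tp, rank_clonotypes(rep)[:2000]))
        assert abs(_two_prop_z(f0s[0], 2000, f0s[1], 2000)) < 3.0

    def test_decay_reduces_fetal_enrichment_with_age(self, beta_models):
        _, tp = beta_models
        cfg = CohortConfig(n_clones=8000, seed=14)
        young = simulate_adult(DonorSpec("y", 10.0, "naive", "beta"), beta_models, cfg)
        old = simulate_adult(DonorSpec("o", 75.0, "naive", "beta"), beta_models, cfg)
        fy = _f0(tp, rank_clonotypes(young)[:2000])
        fo = _f0(tp, rank_clonotypes(old)[:2000])
        assert _two_prop_z(fy, 2000, fo, 2000) > 3.0

    def test_memory_sizes_independent_of_insertions(self, beta_models):
        # no rank/insertion correlation in memory: clonal expansion resets
        # sizes, erasing the fetal abundance structure
        _, tp = beta_models
        n_sig = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = CohortConfig(n_clones=600, seed=100 + seed)
            rep = simulate_adult(DonorSpec("m", 40.0, "memory", "beta"), beta_models, cfg)
            ranked = rank_clonotypes(rep)
            means = [insertion_posterior_mean(tp, c.cdr3_nt) for c in ranked]
            ok = [(r, m) for r, m in enumerate(means) if m is not None]
            rho = spearmanr([r for r, _ in ok], [m for _, m in ok])
            if rho.pvalue < 0.01:
                n_sig += 1
        assert n_sig <= 2, f"{n_sig}/{n_seeds} seeds showed rank-insertion correlation"


class TestTwins:
    def _pair(self, cfg, models, age=25.0):
        s1 = DonorSpec("T1", age, "PBMC", "alpha", twin_partner="T2")
        s2 = DonorSpec("T2", age, "PBMC", "alpha", twin_partner="T1")
        return simulate_twin_pair(s1, s2, models, cfg)

    def test_full_transfer_at_birth_shares_all_fetal_clones(self, alpha_models):
        cfg = CohortConfig(n_clones=2000, twin_transfer=1.0, seed=15)
        r1, r2 = self._pair(cfg, alpha_models, age=0.0)
        tm, _ = alpha_models
        n_f = int(round(cfg.fetal_fraction * cfg.n_clones))
        shared = r1.keyset() & r2.keyset()
        # all 2 * n_f fetal-era clones (TdT- and cord TdT+) are shared
        assert len(shared) >= 2 * n_f

    def test_no_transfer_matches_coincidental_sharing(self, alpha_models):
        # tau = 0 twins are just two independent donors: their sharing
        # stays within sampling error of an unrelated simulated pair
        vals = {0.0: [], None: []}
        for i, tau in enumerate([0.0, 0.0, 0.0]):
            cfg = CohortConfig(n_clones=4000, twin_transfer=tau, seed=200 + i)
            r1, r2 = self._pair(cfg, alpha_models)
            o1, o2 = frame_subset(r1, "out_of_frame"), frame_subset(r2, "out_of_frame")
            vals[0.0].append(normalized_sharing(o1, o2).normalized)
        for i in range(3):
            cfg = CohortConfig(n_clones=4000, twin_transfer=0.0, seed=300 + i)
            a = simulate_adult(DonorSpec("U1", 25.0, "PBMC", "alpha"), alpha_models, cfg)
            b = simulate_adult(DonorSpec("U2", 25.0, "PBMC", "alpha"), alpha_models, cfg)
            oa, ob = frame_subset(a, "out_of_frame"), frame_subset(b, "out_of_frame")
            vals[None].append(normalized_sharing(oa, ob).normalized)
        twin0 = np.mean(vals[0.0])
        unrel = np.mean(vals[None])
        spread = np.std(vals[0.0] + vals[None], ddof=1)
        assert abs(twin0 - unrel) < 2.0 * spread

    def test_transferred_clones_include_low_pgen_sequences(self, alpha_models):
        _, tp = alpha_models
        cfg = CohortConfig(n_clones=6000, twin_transfer=0.5, seed=16)
        r1, r2 = self._pair(cfg, alpha_models, age=5.0)
        o1, o2 = frame_subset(r1, "out_of_frame"), frame_subset(r2, "out_of_frame")
        shared = o1.keyset() & o2.keyset()
        logp_shared = np.array(
            [np.log10(p) for s in shared if (p := tp.pgen(s)) > 0]
        )
        hist, edges = coincidental_shared_pgen_reference(
            tp, 800, 800, replicates=6, rng_seed=2
        )
        # 1st percentile of the coincidental-sharing distribution
        cdf = np.cumsum(hist)
        cut = edges[np.searchsorted(cdf, 0.01) + 1]
        assert (logp_shared < cut).any()


@pytest.fixture(scope="module")
def q_rep(alpha_models):
    cfg = CohortConfig(n_clones=3000, seed=17)
    return simulate_adult(DonorSpec("q", 30.0, "PBMC", "alpha"), alpha_models, cfg)


class TestQFactors:
    @pytest.fixture
    def rep(self, q_rep):
        return q_rep

    def test_degenerate_sigma_gives_unit_q(self, rep):
        q = simulate_q_factors(rep, sigma=0.0, rng_seed=1)
        assert q and all(v == 1.0 for v in q.values())

    def test_deterministic_per_sequence_and_seed(self, rep):
        q1 = simulate_q_factors(rep, sigma=0.5, rng_seed=2)
        q2 = simulate_q_factors(rep, sigma=0.5, rng_seed=2)
        assert q1 == q2
        q3 = simulate_q_factors(rep, sigma=0.5, rng_seed=3)
        assert q1 != q3

    def test_median_near_one(self, rep):
        q = simulate_q_factors(rep, sigma=0.5, rng_seed=4)
        med = float(np.median(list(q.values())))
        assert 0.9 <= med <= 1.1


class TestAgingSeriesGeneration:
    def test_out_of_frame_free_parameters_recovered(self):
        # noiseless series must reproduce the generating curve exactly
        from tcrshare.aging import AgingObservation, fit_decay_models

        params = (0.004, 0.017, 0.027, 0.68, 0.015)
        table = simulate_aging_series(np.linspace(5, 85, 30), params, noise_sd=0.0)
        obs = [AgingObservation(r.donor, r.age, r.Z, r.N) for r in table.itertuples()]
        fit = fit_decay_models(obs)
        assert fit.b == pytest.approx(0.027, abs=1e-6)
        assert fit.b_naive == pytest.approx(0.015, abs=1e-6)
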