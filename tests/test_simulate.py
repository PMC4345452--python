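"""Society simulator: demography, Hamilton allocation, ledger emission."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from kinflows import (
    AgeSchedule,
    SocietyConfig,
    TransferPolicy,
    allocate_transfers,
    emit_ledger,
    family_net_matrix,
    individual_net_matrix,
    net_production_profile,
    simulate_pedigree,
    simulate_society,
)
from kinflows.simulate import ConfigError


class TestHamiltonAllocation:
    """Closed-form checks of the marginal-utility transfer kernel."""

    def two_agent(self, r, avail=(3000.0, 1000.0), curvature=1.0):
        rmat = np.array([[0.0, r], [r, 0.0]])
        pol = TransferPolicy(
            curvature=curvature, gift_granularity=0.01, kin_floor=0.0
        )
        return allocate_transfers(np.array(avail), np.ones(2), rmat, pol)

    def test_log_utility_interior_optimum(self):
        # r * (3000 - t) = 1000 + t  =>  t = 500 / 1.5
        g = self.two_agent(0.5)
        assert g[0, 1] == pytest.approx(1000.0 / 3.0, abs=0.5)

    def test_r_zero_no_transfer(self):
        assert self.two_agent(0.0).sum() == 0.0

    def test_r_one_equalizes(self):
        g = self.two_agent(1.0)
        assert g[0, 1] == pytest.approx(1000.0, abs=0.5)

    def test_conserves_calories(self):
        rng = np.random.default_rng(3)
        avail = rng.uniform(500, 6000, 8)
        w = rng.uniform(1, 5, 8)
        r = rng.uniform(0, 0.5, (8, 8))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        g = allocate_transfers(avail.copy(), w, r, TransferPolicy(kin_floor=0.0))
        final = avail + g.sum(axis=0) - g.sum(axis=1)
        assert final.sum() == pytest.approx(avail.sum())
        assert (g >= 0).all()

    def test_non_concave_utility_rejected(self):
        with pytest.raises(ConfigError, match="concav"):
            TransferPolicy(curvature=0.0)

    def test_kin_floor_blocks_distant_kin(self):
        # steep curvature lets r = 0.05 trade when the floor is disabled,
        # while the default floor screens such distant kin out entirely
        g = self.two_agent(0.05, curvature=5.0)
        pol = TransferPolicy(curvature=5.0, gift_granularity=0.01)  # floor 0.1
        rmat = np.array([[0.0, 0.05], [0.05, 0.0]])
        g2 = allocate_transfers(np.array([3000.0, 1000.0]), np.ones(2), rmat, pol)
        assert g[0, 1] > 0
        assert g2.sum() == 0.0


class TestPedigreeGeneration:
    def test_deterministic_given_seed(self, small_cfg):
        p1 = simulate_pedigree(small_cfg)
        p2 = simulate_pedigree(small_cfg)
        pd.testing.assert_frame_equal(p1.to_frame(), p2.to_frame())

    def test_founders_only_with_zero_fertility(self):
        cfg = SocietyConfig(
            n_communities=1, families_per_community=1, mean_children=0.0, study_days=0
        )
        ped = simulate_pedigree(cfg)
        assert len(ped) == 2
        assert all(ped.mother(i) is None for i in ped.ids)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ConfigError):
            SocietyConfig(n_communities=0)
        with pytest.raises(ConfigError):
            SocietyConfig(families_per_community=0)

    def test_required_dyad_types_present(self, small_society):
        run, _ = small_society
        ped = run.ped
        from kinflows import DyadCategory

        for comm, fams in ped.communities().items():
            fams = [f for f in fams if ped.family_members(f)]
            cats = set()
            for a in range(len(fams)):
                for b in range(a + 1, len(fams)):
                    cats.add(ped.classify_family_dyad(fams[a], fams[b], ref_year=run.cfg.study_year))
            assert DyadCategory.PARENT_OFFSPRING in cats
            assert DyadCategory.NON_KIN in cats

    def test_unknown_config_keys_listed(self):
        with pytest.raises(ConfigError, match="typo_key"):
            SocietyConfig.from_dict({"typo_key": 1, "another_bad": 2})

    def test_yaml_round_trip(self, tmp_path, small_cfg):
        path = tmp_path / "cfg.yaml"
        small_cfg.to_yaml(path)
        back = SocietyConfig.from_yaml(path)
        assert back == small_cfg
        assert back.config_hash() == small_cfg.config_hash()


class TestDailyEconomy:
    def test_calories_conserved_every_day(self, small_society):
        run, _ = small_society
        intake = run.intake()
        np.testing.assert_allclose(
            run.production.sum(axis=0), intake.sum(axis=0), rtol=1e-9
        )

    @pytest.fixture(scope="class")
    def observed_society(self):
        cfg = SocietyConfig(
            n_communities=2,
            families_per_community=20,
            study_days=90,
            seed=22,
            interviews_per_week=7,
            recall_days=1,
        )
        run = simulate_society(cfg)
        return cfg, run, emit_ledger(run)

    def test_life_course_shape(self, observed_society):
        """Individual net production: deficit childhood, surplus prime age."""
        cfg, run, ledger = observed_society
        prof = net_production_profile(ledger, run.ped, "individual", ref_year=cfg.study_year)
        xover = cfg.schedule.crossover_age("M")
        assert 15 < xover < 25
        young = prof[prof["age_hi"] <= 15]
        prime = prof[(prof["age_lo"] >= 30) & (prof["age_hi"] <= 60)]
        assert (young["mean"] < 0).all()
        assert prime["mean"].mean() > 0

    def test_family_budget_shape(self, observed_society):
        """Young families run deficits; older families run surpluses."""
        cfg, run, ledger = observed_society
        prof = net_production_profile(ledger, run.ped, "family", ref_year=cfg.study_year)
        young = prof[prof["age_hi"] <= 45]["mean"].mean()
        old = prof[prof["age_lo"] >= 45]["mean"].mean()
        assert young < 0 < old

    def test_null_policy_ignores_relatedness(self):
        """Random gifting produces non-kin flows; Hamilton policy does not."""
        base = SocietyConfig(n_communities=1, families_per_community=10, study_days=30, seed=5)
        null = dataclasses.replace(
            base, policy=TransferPolicy(kin_weighting=False, need_directed=False)
        )
        run_k = simulate_society(base)
        run_n = simulate_society(null)
        fi = {f: k for k, f in enumerate(run_n.fam_ids)}
        rbar = run_n.fam_relatedness.to_numpy()

        def nonkin_kcal(run):
            tot = 0.0
            for row in run.gifts.itertuples():
                if run.fam_relatedness.loc[row.donor_fam, row.recip_fam] == 0:
                    tot += row.kcal
            return tot

        assert nonkin_kcal(run_k) == 0.0
        assert nonkin_kcal(run_n) > 0.0


class TestLedgerEmission:
    def test_full_sampling_exact_totals(self):
        cfg = SocietyConfig(
            n_communities=1, families_per_community=8, study_days=20, seed=11,
            interviews_per_week=7, recall_days=1, reporting_noise_sd=0.0,
        )
        run = simulate_society(cfg)
        ledger = emit_ledger(run)
        assert ledger.records["kcal"].sum() == pytest.approx(run.production.sum(), rel=1e-9)
        # family net matrix equals the simulator's true flows exactly
        T = individual_net_matrix(ledger)
        Tf = family_net_matrix(T, run.ped)
        truth = run.true_family_net()
        for a, fa in enumerate(Tf.ids):
            for b, fb in enumerate(Tf.ids):
                if Tf.days[a, b] > 0:
                    assert Tf.values[a, b] == pytest.approx(truth.loc[fa, fb], abs=1e-6)

    def test_zero_length_study_empty_ledger(self, tmp_path):
        cfg = SocietyConfig(n_communities=1, families_per_community=6, study_days=0, seed=2)
        run = simulate_society(cfg)
        ledger = emit_ledger(run)
        assert len(ledger.records) == 0
        ledger.write(tmp_path / "led")
        from kinflows import SharingLedger

        back = SharingLedger.read(tmp_path / "led")
        assert len(back.records) == 0 and back.study_days == 0

    def test_interview_sampling_unbiased(self):
        """Across seeds, sparsely sampled dyad rates match the truth on
        average (within 3 Monte-Carlo s.e.)."""
        errors = []
        for seed in range(60):
            cfg = SocietyConfig(
                n_communities=1, families_per_community=6, study_days=30, seed=seed,
                interviews_per_week=2, recall_days=2,
            )
            run = simulate_society(cfg)
            truth = run.true_family_net()
            ledger = emit_ledger(run)
            T = individual_net_matrix(ledger)
            Tf = family_net_matrix(T, run.ped)
            for a in range(len(Tf.ids)):
                for b in range(a + 1, len(Tf.ids)):
                    if Tf.days[a, b] > 0:
                        errors.append(
                            Tf.values[a, b] - truth.loc[Tf.ids[a], Tf.ids[b]]
                        )
        errors = np.array(errors)
        se = errors.std(ddof=1) / np.sqrt(len(errors))
        assert abs(errors.mean()) <= 3 * se

    def test_reporting_noise_perturbs_kcal(self):
        cfg = SocietyConfig(
            n_communities=1, families_per_community=6, study_days=10, seed=3,
            interviews_per_week=7, recall_days=1, reporting_noise_sd=0.3,
        )
        run = simulate_society(cfg)
        noisy = emit_ledger(run)
        assert noisy.records["kcal"].sum() != pytest.approx(run.production.sum(), rel=1e-6)
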