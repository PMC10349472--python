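"""Ground-truth generators: growth curves, secretion effects, assay kinetics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from mbrtwin.mass_balance import ParameterError
from mbrtwin.synthetic_data import (
    DEFAULT_SIGNAL_PEPTIDE_MEANS,
    GrowthModelConfig,
    SecretionEffectConfig,
    make_replicate_design,
    simulate_assay_kinetics,
    simulate_batch_growth,
    simulate_secretion,
)


def backscatter(ts: pd.DataFrame) -> pd.DataFrame:
    return ts[ts["channel"] == "backscatter"].reset_index(drop=True)


class TestGrowthModel:
    def test_initial_sample_is_calibrated_inoculum(self):
        cfg = GrowthModelConfig(od0=0.1, gain_au_per_od=3.2, offset_au=0.7,
                                noise_sd_au=0.0)
        ts = backscatter(simulate_batch_growth(cfg, duration_h=1.0))
        assert ts["value"].iloc[0] == pytest.approx(3.2 * 0.1 + 0.7)

    def test_stop_time_closed_form_matches_ode_oracle(self):
        cfg = GrowthModelConfig(mu_max=0.3, lag_h=0.0, od0=0.1,
                                substrate_g_per_L=10.0, yield_od_per_g=2.0,
                                noise_sd_au=0.0)
        # independent oracle: integrate dOD/dt = mu*OD with substrate depletion
        def rhs(t, z):
            od, s = z
            dod = cfg.mu_max * od if s > 0 else 0.0
            return [dod, -dod / cfg.yield_od_per_g]

        sol = solve_ivp(rhs, [0, 20], [cfg.od0, cfg.substrate_g_per_L],
                        max_step=1e-3, t_eval=[5.0, 10.0, 17.0, 19.0])
        assert np.allclose(sol.y[0], [cfg.od_at(t) for t in sol.t], rtol=1e-3)
        assert cfg.t_stop_h == pytest.approx(math.log(20.1 / 0.1) / 0.3)
        assert cfg.t_stop_h == pytest.approx(17.68, abs=0.01)

    def test_series_constant_after_stop(self):
        cfg = GrowthModelConfig(mu_max=0.3, lag_h=0.0, noise_sd_au=0.0,
                                cycle_min=4.0)
        ts = backscatter(simulate_batch_growth(cfg, duration_h=cfg.t_stop_h + 2))
        after = ts[ts["time_h"] > cfg.t_stop_h]["value"]
        assert after.nunique() == 1

    def test_grid_counting(self):
        cfg = GrowthModelConfig(cycle_min=4.0, noise_sd_au=0.0)
        ts = backscatter(simulate_batch_growth(cfg, duration_h=1.0))
        assert len(ts) == 16  # t = 0, 4, ..., 60 min inclusive
        assert ts["time_h"].iloc[-1] == pytest.approx(1.0)

    def test_noiseless_curve_monotone_until_stop(self):
        cfg = GrowthModelConfig(noise_sd_au=0.0, cycle_min=13.0)
        ts = backscatter(simulate_batch_growth(cfg, duration_h=cfg.t_stop_h + 1))
        assert (np.diff(ts["value"]) >= -1e-12).all()

    def test_fixed_seed_reproducible(self):
        cfg = GrowthModelConfig(seed=11)
        a = simulate_batch_growth(cfg, duration_h=5.0, well="B02")
        b = simulate_batch_growth(cfg, duration_h=5.0, well="B02")
        pd.testing.assert_frame_equal(a, b)

    def test_aux_channels_are_smooth_placeholders(self):
        cfg = GrowthModelConfig(noise_sd_au=0.0)
        ts = simulate_batch_growth(cfg, duration_h=5.0, include_aux_channels=True)
        assert set(ts["channel"].unique()) == {"backscatter", "pH", "DO"}

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            GrowthModelConfig(mu_max=-0.1)
        with pytest.raises(ParameterError):
            simulate_batch_growth(GrowthModelConfig(), duration_h=0.0)


class TestSecretion:
    def design(self, **kw):
        kw.setdefault("strains", list(DEFAULT_SIGNAL_PEPTIDE_MEANS))
        kw.setdefault("iptg_levels", [250.0, 500.0])
        return make_replicate_design(**kw)

    def test_design_row_count(self):
        # 12 strains x 2 IPTG x 3 biological x 2 technical replicates
        assert len(self.design()) == 144

    def test_zero_noise_reproduces_cell_means(self):
        cfg = SecretionEffectConfig(
            strain_means={"A": 1.0, "B": 2.0},
            iptg_effect={250.0: 0.1, 500.0: -0.2},
            batch_sd=0.0, bio_sd=0.0, tech_sd=0.0,
        )
        table = simulate_secretion(
            self.design(strains=["A", "B"]), cfg
        )
        for row in table.itertuples():
            assert row.activity_U_per_mL == pytest.approx(
                cfg.expected(row.strain, row.iptg_uM)
            )

    def test_batch_effect_shared_within_batch(self):
        cfg = SecretionEffectConfig(strain_means={"A": 1.0},
                                    batch_sd=0.3, bio_sd=0.0, tech_sd=0.0)
        table = simulate_secretion(
            self.design(strains=["A"], iptg_levels=[250.0], strategy="spread"),
            cfg,
        )
        per_batch = table.groupby("batch")["activity_U_per_mL"].nunique()
        assert (per_batch == 1).all()
        assert table.groupby("batch")["activity_U_per_mL"].first().nunique() == 3

    def test_between_batch_variance_converges_to_batch_sd(self):
        rows = [
            {"strain": "A", "iptg_uM": 250.0, "batch": f"b{b:02d}",
             "bio_rep": r, "tech_rep": 1}
            for b in range(60) for r in range(1, 5)
        ]
        cfg = SecretionEffectConfig(strain_means={"A": 5.0}, batch_sd=0.3,
                                    bio_sd=0.05, tech_sd=0.0, seed=3)
        table = simulate_secretion(pd.DataFrame(rows), cfg)
        batch_means = table.groupby("batch")["activity_U_per_mL"].mean()
        # Var(batch mean) = batch_sd^2 + bio_sd^2/4; CLT bound over 60 batches
        expected = 0.3**2 + 0.05**2 / 4
        se = expected * math.sqrt(2 / 59)
        assert abs(batch_means.var(ddof=1) - expected) < 3 * se

    def test_unknown_strain_rejected_and_clamping_flagged(self):
        with pytest.raises(KeyError):
            simulate_secretion(self.design(strains=["nope"]),
                               SecretionEffectConfig(strain_means={"A": 1.0}))
        cfg = SecretionEffectConfig(strain_means={"A": 0.0}, batch_sd=1.0,
                                    bio_sd=0.0, tech_sd=0.0, seed=2)
        table = simulate_secretion(
            self.design(strains=["A"], iptg_levels=[250.0], n_bio=6,
                        strategy="spread", ), cfg)
        assert (table["activity_U_per_mL"] >= 0).all()
        # with mean 0 and unit batch SD, about half the draws get clamped
        assert table["clamped"].any()

    def test_same_plate_design_confines_cells_to_one_batch(self):
        same = self.design(strategy="same_plate")
        assert (same.groupby(["strain", "iptg_uM"])["batch"].nunique() == 1).all()
        spread = self.design(strategy="spread")
        assert (spread.groupby(["strain", "iptg_uM"])["batch"].nunique() == 3).all()


class TestAssayKinetics:
    def test_zero_activity_is_flat(self):
        kin = simulate_assay_kinetics(0.0, m_standard=10.0, DF=2.0)
        assert kin["absorbance"].nunique() == 1

    def test_slope_matches_activity_relation(self):
        # EA=0.1 U/mL, m=10 a.u./mM, DF=2 -> 0.5 a.u./min
        kin = simulate_assay_kinetics(0.1, m_standard=10.0, DF=2.0,
                                      read_interval_min=1.0, n_reads=5)
        slopes = np.diff(kin["absorbance"]) / np.diff(kin["time_min"])
        assert np.allclose(slopes, 0.5)
        kin2 = simulate_assay_kinetics(0.1, m_standard=10.0, DF=2.0,
                                       read_interval_min=1.0, n_reads=5,
                                       blank_au=0.0)
        assert kin2["absorbance"].iloc[0] == 0.0

    def test_first_read_is_blank(self):
        kin = simulate_assay_kinetics(0.3, m_standard=8.0, DF=1.0, blank_au=0.07)
        assert kin["absorbance"].iloc[0] == pytest.approx(0.07)

    def test_invalid_standard_slope_rejected(self):
        with pytest.raises(ParameterError):
            simulate_assay_kinetics(0.1, m_standard=0.0, DF=1.0)
        with pytest.raises(ParameterError):
            simulate_assay_kinetics(0.1, m_standard=1.0, DF=0.5)
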