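import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acepep.energetics import (
    BOLTZMANN_KCAL,
    BindingEnergyModel,
    assemble_binding_free_energy,
    interaction_entropy,
    mean_components,
    nonpolar_solvation,
)
from acepep.reference import ROUNDING_OUTLIERS, load_binding_energies
from acepep.synthetic import EnergySeriesConfig, gen_energy_series

KT300 = BOLTZMANN_KCAL * 300.0


class TestNonpolarSolvation:
    @pytest.mark.parametrize(
        "sasa,expected", [(600.0, 3.00), (0.0, 0.00), (568.0, 2.84)]
    )
    def test_gamma_sasa_plus_beta(self, sasa, expected):
        assert nonpolar_solvation(sasa) == pytest.approx(expected)

    def test_custom_coefficients(self):
        assert nonpolar_solvation(100.0, gamma=0.01, beta=0.5) == pytest.approx(1.5)

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_solvation(-1.0)

    def test_vectorized(self):
        np.testing.assert_allclose(
            nonpolar_solvation(np.array([0.0, 600.0])), [0.0, 3.0]
        )


class TestMeanComponents:
    def test_constant_frames(self):
        frames = pd.DataFrame(
            {"e_vdw": [-10.0] * 5, "e_ele": [-20.0] * 5,
             "g_gb": [15.0] * 5, "g_np": [-2.0] * 5}
        )
        means = mean_components(frames)
        assert means["e_vdw"] == -10.0 and means["g_np"] == -2.0

    def test_two_frame_average(self):
        frames = pd.DataFrame(
            {"e_vdw": [-10.0, -12.0], "e_ele": [0.0, 0.0],
             "g_gb": [0.0, 0.0], "g_np": [0.0, 0.0]}
        )
        assert mean_components(frames)["e_vdw"] == pytest.approx(-11.0)

    def test_gaussian_recovery_within_clt_band(self):
        cfg = EnergySeriesConfig(seed=5, n_frames=100)
        frames = gen_energy_series(cfg)
        means = mean_components(frames)
        for comp, mu in cfg.component_means.items():
            band = 3 * cfg.component_sds[comp] / math.sqrt(100)
            assert abs(means[comp] - mu) < band

    def test_empty_and_missing_column_rejected(self):
        with pytest.raises(ValueError):
            mean_components(pd.DataFrame())
        with pytest.raises(ValueError):
            mean_components(pd.DataFrame({"e_vdw": [1.0]}))


class TestInteractionEntropy:
    def test_constant_series_exactly_zero(self):
        assert interaction_entropy(np.full(100, -79.84)) == 0.0

    def test_two_frame_closed_form_log_cosh(self):
        # symmetric two-point series {+e, -e}: IE = kT ln cosh(e/kT)
        e = 0.59616  # beta * e = 1 at 300 K
        expected = KT300 * math.log(math.cosh(e / KT300))
        assert interaction_entropy(np.array([e, -e])) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.2586, abs=5e-4)

    def test_gaussian_cumulant_limit(self):
        rng = np.random.default_rng(99)
        sigma = 1.0
        ie = interaction_entropy(rng.normal(0.0, sigma, 200_000))
        assert ie == pytest.approx(sigma**2 / (2 * KT300), rel=0.03)

    def test_large_fluctuations_do_not_overflow(self):
        # beta * dE ~ 500: naive exp would overflow double precision
        ie = interaction_entropy(np.array([300.0, -300.0]))
        assert np.isfinite(ie) and ie > 0

    @given(
        shift=st.floats(-1e4, 1e4),
        seed=st.integers(0, 1000),
    )
    def test_invariant_under_additive_shift(self, shift, seed):
        e = np.random.default_rng(seed).normal(0, 2.0, 50)
        assert interaction_entropy(e + shift) == pytest.approx(
            interaction_entropy(e), abs=1e-8
        )

    @given(seed=st.integers(0, 10_000))
    def test_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(rng.uniform(-100, 0), rng.uniform(0.01, 5.0),
                       rng.integers(2, 200))
        assert interaction_entropy(e) >= 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            interaction_entropy(np.array([1.0]))
        with pytest.raises(ValueError):
            interaction_entropy(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            interaction_entropy(np.array([1.0, 2.0]), temperature=0.0)


class TestAssembly:
    def test_all_zero_components(self):
        e = assemble_binding_free_energy(
            {"e_vdw": 0, "e_ele": 0, "g_gb": 0, "g_np": 0}, 0.0
        )
        assert e.d_h == 0.0 and e.d_gbind == 0.0

    def test_negative_entropy_penalty_rejected(self):
        with pytest.raises(ValueError):
            assemble_binding_free_energy(
                {"e_vdw": -1, "e_ele": 0, "g_gb": 0, "g_np": 0}, -0.5
            )

    @pytest.mark.parametrize(
        "complex_id,dh,dgbind",
        [("ACE-WFSW", -41.56, -21.70), ("ACE-YYWK", -29.72, -18.27)],
    )
    def test_published_worked_examples(self, complex_id, dh, dgbind):
        table = load_binding_energies().set_index("complex")
        row = table.loc[complex_id]
        energy = assemble_binding_free_energy(
            {"e_vdw": row.e_vdw, "e_ele": row.e_ele,
             "g_gb": row.g_gb, "g_np": row.g_np},
            row.minus_tds, complex_id,
        )
        assert energy.d_h == pytest.approx(dh, abs=0.02)
        assert energy.d_gbind == pytest.approx(dgbind, abs=0.02)

    def test_all_reference_rows_round_trip(self):
        """Component sums reproduce the printed dH/dG_bind to the printed
        rounding, except the one documented outlier row."""
        for _, row in load_binding_energies().iterrows():
            tol = ROUNDING_OUTLIERS.get(row["complex"], 0.02)
            energy = assemble_binding_free_energy(
                {"e_vdw": row.e_vdw, "e_ele": row.e_ele,
                 "g_gb": row.g_gb, "g_np": row.g_np},
                row.minus_tds,
            )
            assert energy.d_h == pytest.approx(row.dh, abs=tol)
            assert energy.d_gbind == pytest.approx(row.dg_bind, abs=tol)
            assert row.minus_tds > 0

    def test_gas_and_solvation_partitions(self):
        e = assemble_binding_free_energy(
            {"e_vdw": -36.32, "e_ele": -43.52, "g_gb": 41.12, "g_np": -2.84},
            19.86,
        )
        assert e.d_ggas == pytest.approx(-79.84)
        assert e.d_gsolv == pytest.approx(38.28)
        assert e.d_h == pytest.approx(e.d_ggas + e.d_gsolv)


class TestBindingEnergyModel:
    def test_zero_noise_reproduces_configured_means(self):
        cfg = EnergySeriesConfig(
            seed=1, n_frames=200,
            component_sds={k: 0.0 for k in ("e_vdw", "e_ele", "g_gb", "g_np")},
            e_int_sd=0.0,
        )
        results = BindingEnergyModel(gen_energy_series(cfg)).fit()
        assert results.energy.d_h == pytest.approx(-41.56, abs=1e-9)
        assert results.energy.minus_t_ds == 0.0
        assert results.energy.d_gbind == pytest.approx(-41.56, abs=1e-9)

    def test_frame_subsampling_counts(self):
        frames = gen_energy_series(EnergySeriesConfig(seed=2, n_frames=10_000))
        results = BindingEnergyModel(frames).fit(
            n_frames_enthalpy=100, n_frames_entropy=10_000
        )
        assert results.n_frames_enthalpy == 100
        assert results.n_frames_entropy == 10_000

    def test_sasa_column_converted(self):
        frames = pd.DataFrame(
            {"e_vdw": [-10.0, -10.0], "e_ele": [0.0, 0.0], "g_gb": [0.0, 0.0],
             "sasa": [600.0, 600.0], "e_int": [-10.0, -10.0]}
        )
        results = BindingEnergyModel(frames).fit()
        assert results.energy.d_gnp == pytest.approx(3.0)

    def test_summary_mentions_key_terms(self):
        frames = gen_energy_series(EnergySeriesConfig(seed=3, n_frames=500,
                                                      complex_id="toy"))
        text = BindingEnergyModel(frames, complex_id="toy").fit().summary()
        for token in ("dG_bind", "-T dS", "dE_vdW", "toy"):
            assert token in text

    def test_requires_interaction_energy_column(self):
        frames = pd.DataFrame(
            {"e_vdw": [0.0, 0.0], "e_ele": [0.0, 0.0], "g_gb": [0.0, 0.0],
             "g_np": [0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            BindingEnergyModel(frames)
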