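"""Shared-ASV mask, ratio statistic and the linear POC-flux model."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phytoflux import fluxmodel, pigments, trophic

import _oracles as oracles
from conftest import (lineage, random_counts, random_trap_metadata,
                      taxonomy_frame)


@pytest.fixture(scope="module")
def ratio_setup():
    """Counts with known pigment groups: d* diatoms, h* hacrobia, o* others."""
    tax = taxonomy_frame({
        "d1": lineage(division="Ochrophyta", class_="Bacillariophyta"),
        "d2": lineage(division="Ochrophyta", class_="Bacillariophyta"),
        "h1": lineage(division="Haptophyta", class_="Prymnesiophyceae"),
        "o1": lineage(division="Dinoflagellata", class_="Dinophyceae"),
        "o2": lineage(division="Chlorophyta", class_="Mamiellophyceae"),
    })
    return pigments.assign_pigment_groups(trophic.classify_trophic(tax))


class TestSharedMask:
    def test_surface_and_sink_intersection(self):
        counts = pd.DataFrame(
            [[1, 1, 0], [1, 0, 1], [0, 0, 1]],
            index=["su", "b1", "p1"], columns=["shared", "surfonly", "deep"])
        samples = pd.DataFrame.from_dict({
            "su": dict(basin="NP", sample_type="surface", deployment=1,
                       platform="", depth_m=5.0, particle_class="none",
                       light_level=""),
            "b1": dict(basin="NP", sample_type="bulk_trap", deployment=1,
                       platform="STT-1", depth_m=100.0, particle_class="none",
                       light_level=""),
            "p1": dict(basin="NP", sample_type="particle", deployment=1,
                       platform="STT-1", depth_m=100.0,
                       particle_class="short_pellet", light_level="")},
            orient="index")
        mask = fluxmodel.build_shared_mask(counts, samples, "NP")
        assert mask == {"shared"}  # particle-only and surface-only excluded

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_intersection(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_counts(rng, n_samples=12, n_asvs=20, density=0.4)
        samples = random_trap_metadata(rng, counts.index)
        for basin in ("NP", "NA"):
            brute = oracles.pools_brute(counts, samples, basin)
            expect = brute["surface"] & (brute["bulk"] | brute["particle"])
            if not expect:
                with pytest.raises(ValueError):
                    fluxmodel.build_shared_mask(counts, samples, basin)
            else:
                assert fluxmodel.build_shared_mask(counts, samples, basin) == expect


class TestRatioStatistic:
    def test_arithmetic_example(self, ratio_setup):
        counts = pd.DataFrame([[20, 10, 10, 15, 5]], index=["b"],
                              columns=["d1", "d2", "h1", "o1", "o2"])
        x = fluxmodel.ratio_statistic(counts, ratio_setup,
                                      set(counts.columns))
        assert x["b"] == pytest.approx(2.0)  # (20+10+10)/(15+5)

    def test_no_numerator_reads_gives_zero(self, ratio_setup):
        counts = pd.DataFrame([[0, 0, 0, 6, 4]], index=["b"],
                              columns=["d1", "d2", "h1", "o1", "o2"])
        x = fluxmodel.ratio_statistic(counts, ratio_setup, set(counts.columns))
        assert x["b"] == 0.0

    def test_zero_denominator_yields_nan_and_log(self, ratio_setup, caplog):
        counts = pd.DataFrame([[3, 0, 1, 0, 0]], index=["b"],
                              columns=["d1", "d2", "h1", "o1", "o2"])
        with caplog.at_level(logging.WARNING):
            x = fluxmodel.ratio_statistic(counts, ratio_setup,
                                          set(counts.columns))
        assert np.isnan(x["b"])
        assert any("zero-denominator" in r.message for r in caplog.records)

    def test_alternative_numerator_groups(self, ratio_setup):
        counts = pd.DataFrame([[20, 10, 10, 15, 5]], index=["b"],
                              columns=["d1", "d2", "h1", "o1", "o2"])
        x = fluxmodel.ratio_statistic(counts, ratio_setup, set(counts.columns),
                                      numerator_groups=("diatoms",))
        assert x["b"] == pytest.approx(30 / 30)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_asv_level_brute_force(self, seed, ratio_setup):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.integers(0, 30, size=(6, 5)),
                              index=[f"s{i}" for i in range(6)],
                              columns=["d1", "d2", "h1", "o1", "o2"])
        mask = {c for c in counts.columns if rng.random() < 0.8}
        if not mask:
            mask = {"d1", "o1"}
        x = fluxmodel.ratio_statistic(counts, ratio_setup, mask)
        groups = ratio_setup["pigment_group"].to_dict()
        for s in counts.index:
            expect = oracles.ratio_brute(counts.loc[s].to_dict(), groups,
                                         mask, {"diatoms", "hacrobia"})
            if np.isnan(expect):
                assert np.isnan(x[s])
            else:
                assert x[s] == pytest.approx(expect, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.integers(1, 10_000))
    def test_scale_invariance(self, ratio_setup, k):
        counts = pd.DataFrame([[20, 10, 10, 15, 5]], index=["b"],
                              columns=["d1", "d2", "h1", "o1", "o2"])
        x1 = fluxmodel.ratio_statistic(counts, ratio_setup, set(counts.columns))
        xk = fluxmodel.ratio_statistic(counts * k, ratio_setup,
                                       set(counts.columns))
        assert xk["b"] == pytest.approx(x1["b"], rel=1e-12)

    def test_full_mask_equals_unmasked_statistic(self, classified):
        ds, _, tax, photo = classified
        bulk = photo.loc[ds.samples.loc[photo.index, "sample_type"] == "bulk_trap"]
        x_masked = fluxmodel.ratio_statistic(bulk, tax, set(photo.columns))
        groups = tax.loc[bulk.columns, "pigment_group"]
        num = bulk.loc[:, groups.isin(["diatoms", "hacrobia"]).to_numpy()].sum(axis=1)
        den = bulk.loc[:, ~groups.isin(["diatoms", "hacrobia"]).to_numpy()].sum(axis=1)
        np.testing.assert_allclose(x_masked.to_numpy(), (num / den).to_numpy())


class TestFit:
    def _ratio_df(self, x, y, basin="NP"):
        n = len(x)
        return pd.DataFrame({
            "basin": [basin] * n, "deployment": [1] * n, "depth_m": 100.0,
            "platform": ["STT-1"] * n, "x": x, "poc_flux": y,
            "flux_uncertainty": 0.1},
            index=[f"b{i:02d}" for i in range(n)])

    def test_exact_line_recovered(self):
        x = np.array([0.0, 0.5, 1.0, 2.0])
        m = fluxmodel.fit_flux_model(self._ratio_df(x, 2 * x + 1))
        assert m.slope == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert m.r_squared == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            fluxmodel.fit_flux_model(self._ratio_df([1, 2], [1, 2]))

    def test_constant_ratio_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fluxmodel.fit_flux_model(self._ratio_df([1, 1, 1], [1, 2, 3]))

    def test_null_slope_p_values_are_uniformly_distributed(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            x = rng.uniform(0, 2, size=30)
            y = rng.normal(1.0, 0.5, size=30)  # independent of x
            pvals.append(fluxmodel.fit_flux_model(self._ratio_df(x, y)).p_value)
        pvals = np.array(pvals)
        assert abs((pvals < 0.05).mean() - 0.05) < 0.05
        assert abs(pvals.mean() - 0.5) < 0.08

    def test_r_squared_consistent_with_residuals(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 2, size=40)
        y = 3.4 * x + 0.47 + rng.normal(0, 0.5, size=40)
        m = fluxmodel.fit_flux_model(self._ratio_df(x, y))
        resid = y - m.predict(x)
        expect = 1 - resid.var() / y.var()
        assert m.r_squared == pytest.approx(expect, abs=1e-9)


class TestPredict:
    def test_zero_ratio_predicts_intercept(self):
        m = fluxmodel.FluxModel(3.4, 0.47, 1.0, 0.0, 0.1, 0.1, 10)
        assert fluxmodel.predict_flux(m, [0.0])[0] == pytest.approx(0.47)

    def test_affine_identity(self):
        m = fluxmodel.FluxModel(2.5, 0.3, 1.0, 0.0, 0.1, 0.1, 10)
        ya, yb, yab = m.predict([1.0])[0], m.predict([2.0])[0], m.predict([3.0])[0]
        assert ya + yb - m.intercept == pytest.approx(yab)

    def test_negative_prediction_warns_but_returns(self, caplog):
        m = fluxmodel.FluxModel(3.4, 0.47, 1.0, 0.0, 0.1, 0.1, 10)
        with caplog.at_level(logging.WARNING):
            y = m.predict([-1.0])
        assert y[0] < 0
        assert any("negative" in r.message for r in caplog.records)


class TestDepthProfile:
    def test_monotone_ratio_gives_monotone_modeled_profile(self):
        x = np.array([2.0, 1.5, 1.0, 0.5, 0.2])
        df = pd.DataFrame({
            "basin": "NA", "deployment": 1,
            "depth_m": [95.0, 145.0, 195.0, 330.0, 500.0],
            "platform": "STT-1", "x": x, "poc_flux": 3.4 * x + 0.47,
            "flux_uncertainty": 0.1}, index=[f"b{i}" for i in range(5)])
        m = fluxmodel.fit_flux_model(df)
        prof = fluxmodel.depth_profile(m, df)
        assert (np.diff(prof["modeled_flux"].to_numpy()) < 0).all()
        assert list(prof["depth_m"]) == sorted(prof["depth_m"])

    def test_stt_only_filter(self):
        df = pd.DataFrame({
            "basin": "NP", "deployment": 1, "depth_m": [95.0, 95.0, 195.0],
            "platform": ["STT-95", "NBST-95", "STT-195"],
            "x": [1.0, 1.1, 0.9], "poc_flux": [3.0, 3.1, 2.9],
            "flux_uncertainty": 0.1}, index=["a", "b", "c"])
        m = fluxmodel.FluxModel(3.4, 0.47, 1.0, 0.0, 0.1, 0.1, 10)
        prof = fluxmodel.depth_profile(m, df, stt_only=True)
        assert set(prof["platform"]) == {"STT-95", "STT-195"}
        both = fluxmodel.depth_profile(m, df, stt_only=False)
        assert len(both) == 3

    def test_rmse_matches_injected_noise_level(self, classified):
        ds, gt, tax, photo = classified
        ratio = fluxmodel.make_ratio_samples(photo, tax, ds.samples, ds.flux)
        m = fluxmodel.fit_flux_model(ratio)
        prof = fluxmodel.depth_profile(m, ratio, stt_only=False)
        rmse = np.sqrt(np.mean(
            (prof["measured_flux"] - prof["modeled_flux"]) ** 2))
        noise_sd = gt.flux_law[2]
        assert 0.55 * noise_sd < rmse < 1.45 * noise_sd


class TestWeightedFit:
    def test_uniform_weights_reproduce_ols(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 2, size=25)
        y = 3.4 * x + 0.47 + rng.normal(0, 0.5, size=25)
        df = pd.DataFrame({"basin": "NP", "deployment": 1, "depth_m": 100.0,
                           "platform": "STT-1", "x": x, "poc_flux": y,
                           "flux_uncertainty": 0.5},
                          index=[f"b{i}" for i in range(25)])
        ols = fluxmodel.fit_flux_model(df)
        wls = fluxmodel.fit_flux_model(df, weighted=True)
        assert wls.slope == pytest.approx(ols.slope, rel=1e-9)
        assert wls.intercept == pytest.approx(ols.intercept, rel=1e-9)
        assert wls.stderr == pytest.approx(ols.stderr, rel=1e-9)
        assert wls.p_value == pytest.approx(ols.p_value, rel=1e-6)

    def test_zero_uncertainty_rejected(self):
        df = pd.DataFrame({"basin": "NP", "deployment": 1, "depth_m": 100.0,
                           "platform": "STT-1", "x": [0.0, 1.0, 2.0],
                           "poc_flux": [1.0, 2.0, 3.0],
                           "flux_uncertainty": [0.1, 0.0, 0.1]},
                          index=["a", "b", "c"])
        with pytest.raises(ValueError, match="positive"):
            fluxmodel.fit_flux_model(df, weighted=True)
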