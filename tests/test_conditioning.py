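import numpy as np
import pytest

from pestmap import (
    AreaGrid,
    BanRegistry,
    CountryCorrection,
    GMRegistry,
    GridSpec,
    RawGlobalAPR,
    RegionMask,
    apply_bans,
    apply_gm_conditioning,
    country_masses,
    correction_ratios,
    faostat_condition,
    impute_missing_rc,
    project_estimates,
)


@pytest.fixture
def geo(small_spec, two_region_mask):
    areas = AreaGrid(small_spec, {"Corn": np.full(small_spec.shape, 10.0)})
    return small_spec, two_region_mask, areas


def flat_apr(spec, high=2.0, low=1.0, ai="glyphosate", crop="Corn"):
    return RawGlobalAPR(
        ai=ai, crop=crop, high=np.full(spec.shape, float(high)), low=np.full(spec.shape, float(low))
    )


class TestBans:
    def test_empty_registry_identity(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec)
        out = apply_bans(apr, BanRegistry(), mask)
        assert np.array_equal(out.high, apr.high)

    def test_banned_country_mass_zero_elsewhere_bit_identical(self, geo):
        spec, mask, areas = geo
        apr = flat_apr(spec)
        out = apply_bans(apr, BanRegistry(banned={(1, "glyphosate")}), mask)
        inside = mask.labels == 1
        assert np.all(out.high[inside] == 0.0) and np.all(out.low[inside] == 0.0)
        assert np.array_equal(out.high[~inside], apr.high[~inside])
        masses = country_masses([out], areas, mask)
        assert masses[1] == 0.0

    def test_unknown_country_rejected(self, geo):
        spec, mask, _ = geo
        with pytest.raises(ValueError, match="unknown countries"):
            apply_bans(flat_apr(spec), BanRegistry(banned={(7, "glyphosate")}), mask)


class TestGMConditioning:
    def test_empty_registry_identity(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec)
        out = apply_gm_conditioning(apr, GMRegistry(), 2.0, 1.0, BanRegistry(), mask)
        assert np.array_equal(out.high, apr.high)

    def test_non_gm_ingredient_untouched(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec, ai="atrazine")
        gm = GMRegistry(approvals={(1, "Corn", "glyphosate")})
        out = apply_gm_conditioning(apr, gm, 2.0, 1.0, BanRegistry(), mask)
        assert np.array_equal(out.high, apr.high)

    def test_thirty_percent_rule_in_non_approving_country(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec, high=5.0, low=4.0)
        gm = GMRegistry(approvals={(0, "Corn", "glyphosate")})  # country 1 not approving
        out = apply_gm_conditioning(
            apr, gm, usa_apr_high=2.0, usa_apr_low=1.0, bans=BanRegistry(), countries=mask,
            reference_country=0, dominant_crops={"Corn"},
        )
        inside = mask.labels == 1
        assert np.allclose(out.high[inside], 0.6)
        assert np.allclose(out.low[inside], 0.3)
        # reference country untouched
        assert np.array_equal(out.high[mask.labels == 0], apr.high[mask.labels == 0])

    def test_approving_country_capped_at_reference(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec, high=5.0, low=0.5)
        gm = GMRegistry(approvals={(1, "Corn", "glyphosate")})
        out = apply_gm_conditioning(
            apr, gm, usa_apr_high=2.0, usa_apr_low=1.0, bans=BanRegistry(), countries=mask,
            reference_country=0, dominant_crops={"Corn"},
        )
        inside = mask.labels == 1
        assert np.allclose(out.high[inside], 2.0)  # capped
        assert np.allclose(out.low[inside], 0.5)  # below cap, kept

    def test_ban_wins_over_gm(self, geo):
        spec, mask, _ = geo
        bans = BanRegistry(banned={(1, "glyphosate")})
        apr = apply_bans(flat_apr(spec), bans, mask)
        gm = GMRegistry(approvals={(0, "Corn", "glyphosate")})
        out = apply_gm_conditioning(
            apr, gm, 2.0, 1.0, bans=bans, countries=mask, reference_country=0,
            dominant_crops={"Corn"},
        )
        assert np.all(out.high[mask.labels == 1] == 0.0)

    def test_aggregated_gm_crop_rejected(self, geo):
        spec, mask, _ = geo
        gm = GMRegistry(approvals={(1, "VegFru", "glyphosate")})
        apr = flat_apr(spec, crop="VegFru")
        with pytest.raises(ValueError, match="non-dominant"):
            apply_gm_conditioning(
                apr, gm, 2.0, 1.0, BanRegistry(), mask, dominant_crops={"Corn"}
            )


class TestCountryMasses:
    def test_unit_conversion(self, small_spec):
        # uniform 1 kg/ha on 1000 ha in one country -> 1 tonne
        mask = RegionMask(labels=np.zeros(small_spec.shape, dtype=int))
        n = small_spec.n_rows * small_spec.n_cols
        areas = AreaGrid(small_spec, {"Corn": np.full(small_spec.shape, 1000.0 / n)})
        apr = flat_apr(small_spec, high=1.0, low=1.0)
        masses = country_masses([apr], areas, mask)
        assert masses[0] == pytest.approx(1.0)

    def test_country_split_additive(self, geo):
        spec, mask, areas = geo
        apr = flat_apr(spec)
        split = country_masses([apr], areas, mask)
        whole = country_masses([apr], areas, RegionMask(labels=np.zeros(spec.shape, int)))
        assert split[0] + split[1] == pytest.approx(whole[0])

    def test_exact_world_masses_match_truth(self, exact_world):
        bundle = exact_world
        aprs = [
            RawGlobalAPR(ai=ai, crop=crop, high=g, low=g.copy())
            for (ai, crop), g in bundle.true_apr.items()
        ]
        masses = country_masses(aprs, bundle.crop_areas, bundle.country_mask)
        for c, m in masses.items():
            assert m == pytest.approx(bundle.faostat_totals[c], rel=1e-9)


class TestCorrectionRatios:
    def test_reported_ratio(self):
        corr = correction_ratios({0: 5.0, 1: 2.0}, {0: 10.0})
        assert corr[0].r_c == pytest.approx(2.0)
        assert corr[0].source == "reported"
        assert 1 not in corr

    def test_neighbor_mean_imputation(self):
        base = {
            0: CountryCorrection(0, 1.0, 2.0, 2.0, "reported"),
            1: CountryCorrection(1, 1.0, 1.0, 1.0, "reported"),
        }
        out = impute_missing_rc(base, [0, 1, 2], {2: {0, 1}, 0: {2}, 1: {2}})
        assert out[2].r_c == pytest.approx(1.5)
        assert out[2].source == "neighbor-imputed"

    def test_island_falls_back_to_global_mean(self):
        base = {0: CountryCorrection(0, 1.0, 3.0, 3.0, "reported")}
        log = []
        out = impute_missing_rc(base, [0, 9], {9: set()}, log=log)
        assert out[9].r_c == pytest.approx(3.0)
        assert out[9].source == "global-fallback"
        assert "global fallback" in log[0]

    def test_nothing_reported_is_an_error(self):
        with pytest.raises(ValueError, match="no country"):
            impute_missing_rc({}, [0], {})


class TestFaostatConditioning:
    def test_reciprocal_ratio_leaves_country_unchanged(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec)
        corr = {1: CountryCorrection(1, 1.0, None, r_c=1.0 / 0.842, source="reported")}
        out = faostat_condition(apr, corr, f_m=0.842, usa_ratio=10.0, countries=mask)
        assert np.allclose(out.high[mask.labels == 1], apr.high[mask.labels == 1])

    def test_reference_ratio_caps_large_corrections(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec, high=2.0, low=1.0)
        corr = {1: CountryCorrection(1, 1.0, None, r_c=10.0, source="reported")}
        out = faostat_condition(apr, corr, f_m=1.0, usa_ratio=3.0, countries=mask)
        assert np.allclose(out.high[mask.labels == 1], 2.0 * 3.0)
        assert np.allclose(out.low[mask.labels == 1], 1.0 * 3.0)

    def test_reference_country_exempt(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec)
        corr = {0: CountryCorrection(0, 1.0, None, r_c=5.0, source="reported")}
        out = faostat_condition(apr, corr, f_m=1.0, usa_ratio=None, countries=mask)
        assert np.array_equal(out.high, apr.high)

    def test_undefined_cap_logged_and_omitted(self, geo):
        spec, mask, _ = geo
        apr = flat_apr(spec)
        corr = {1: CountryCorrection(1, 1.0, None, r_c=2.0, source="reported")}
        log = []
        out = faostat_condition(apr, corr, f_m=0.5, usa_ratio=None, countries=mask, log=log)
        assert np.allclose(out.high[mask.labels == 1], 2.0 * 1.0)  # 0.5 * 2.0 * high
        assert "cap omitted" in log[0]


class TestProjection:
    def test_unit_prefactor_identity(self, small_spec):
        apr = flat_apr(small_spec)
        final = project_estimates(apr, {2015: 1.0, 2020: 1.0, 2025: 1.0})
        assert np.array_equal(final.high(2020), apr.high)

    def test_halving_prefactor(self, small_spec):
        apr = flat_apr(small_spec)
        final = project_estimates(apr, {2015: 1.0, 2020: 0.5, 2025: 0.25})
        assert np.allclose(final.high(2020), 1.0)
        assert np.allclose(final.low(2025), 0.25)

    def test_banned_zero_stays_zero(self, geo):
        spec, mask, _ = geo
        apr = apply_bans(flat_apr(spec), BanRegistry(banned={(1, "glyphosate")}), mask)
        final = project_estimates(apr, {2015: 1.0, 2020: 2.0, 2025: 3.0})
        for year in (2015, 2020, 2025):
            assert np.all(final.high(year)[mask.labels == 1] == 0.0)

    def test_missing_prefactor_skipped_and_logged(self, small_spec):
        log = []
        final = project_estimates(flat_apr(small_spec), {2015: 1.0, 2020: 1.2}, log=log)
        assert 2025 not in final.grids
        assert any("no prefactor" in line for line in log)


class TestOrderAndMonotonicity:
    def test_high_ge_low_through_all_stages(self, geo):
        spec, mask, areas = geo
        rng = np.random.default_rng(12)
        apr = RawGlobalAPR(
            ai="glyphosate", crop="Corn",
            high=rng.uniform(1, 3, spec.shape), low=rng.uniform(0, 1, spec.shape),
        )
        bans = BanRegistry(banned={(1, "glyphosate")})
        step = apply_bans(apr, bans, mask)
        assert np.all(step.high >= step.low)
        gm = GMRegistry(approvals={(0, "Corn", "glyphosate")})
        step = apply_gm_conditioning(
            step, gm, 2.0, 1.0, bans, mask, reference_country=0, dominant_crops={"Corn"}
        )
        assert np.all(step.high >= step.low)
        corr = {1: CountryCorrection(1, 1.0, None, 1.7, "reported")}
        step = faostat_condition(step, corr, f_m=0.9, usa_ratio=2.0, countries=mask)
        assert np.all(step.high >= step.low)
        final = project_estimates(step, {2015: 1.0, 2020: 0.7, 2025: 1.4})
        for year in (2015, 2020, 2025):
            assert np.all(final.high(year) >= final.low(year))
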