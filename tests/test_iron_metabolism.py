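"""Right-hand sides of the iron compartments and derived observables."""

import numpy as np
import pytest

from ferropoiesis import iron_metabolism as iron
from ferropoiesis.erythropoiesis import ErythroidChain
from ferropoiesis.iron_metabolism import ObservableError
from ferropoiesis.state import layout_for, reference_state


class TestPlasmaIron:
    @pytest.mark.parametrize("trfl, ntbi, k, expected", [
        (0.0, 0.0, 2.0, 0.0),
        (1.0, 1.0, 2.0, 3.0),
        (1.0, 1.0, 0.4, 1.4),
    ])
    def test_linear_form(self, trfl, ntbi, k, expected):
        assert iron.plasma_iron(trfl, ntbi, k) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            iron.plasma_iron(-1.0, 0.0, 1.0)


class TestIntestinalDelay:
    def test_fixed_point_under_constant_input(self):
        c_star = 7.0 / 2.0
        assert iron.intestinal_delay_rhs(c_star, 7.0, 2.0) == pytest.approx(0.0)

    def test_exponential_decay_closed_form(self):
        # with no input, dC/dt = -delay*C so C(t) = C0*exp(-delay*t)
        c0, delay = 5.0, 2.0
        for t in (0.1, 0.5, 1.0):
            c = c0 * np.exp(-delay * t)
            assert iron.intestinal_delay_rhs(c, 0.0, delay) == pytest.approx(
                -delay * c)

    def test_empty_compartment_with_no_input_is_stationary(self):
        assert iron.intestinal_delay_rhs(0.0, 0.0, 2.0) == 0.0


class TestEnterocytes:
    def test_half_saturation(self, params):
        p = params.iron
        d = params.require_derived()
        rhs = iron.enterocyte_rhs(0.0, p.Fe_intest_max, 1.0, p, d.k_intest)
        assert rhs == pytest.approx(d.k_intest / 2.0)

    def test_saturation_ceiling(self, params):
        p = params.iron
        d = params.require_derived()
        rhs = iron.enterocyte_rhs(0.0, 1e12, 1.0, p, d.k_intest)
        assert rhs == pytest.approx(d.k_intest, rel=1e-9)

    def test_empty_everything_is_stationary(self, params):
        assert iron.enterocyte_rhs(0.0, 0.0, 1.0, params.iron,
                                   params.require_derived().k_intest) == 0.0


class TestNtbi:
    def test_injection_is_additive(self, params):
        base = iron.ntbi_rhs(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, params)
        dosed = iron.ntbi_rhs(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 5.0, params)
        assert dosed - base == pytest.approx(5.0)

    def test_loading_dominates_at_large_trfu(self, params):
        rhs = iron.ntbi_rhs(1.0, 1.0, 1.0, 1.0, 1.0, 1e9, 1.0, 0.0, params)
        assert rhs < -1e6


class TestStorage:
    def test_steady_state_zero(self):
        assert iron.storage_rhs(1.0, 1.0, 1.0, 0.02) == pytest.approx(0.0)

    def test_sign_follows_plasma_excess(self):
        assert iron.storage_rhs(1.0, 2.0, 1.0, 0.02) > 0
        assert iron.storage_rhs(1.0, 0.5, 1.0, 0.02) < 0

    def test_high_ferroportin_drains_stores(self):
        # haemochromatosis: elevated ferroportin mobilises storage iron
        assert iron.storage_rhs(1.0, 1.0, 2.0, 0.02) < iron.storage_rhs(
            1.0, 1.0, 1.0, 0.02)


class TestTransferrin:
    def test_marrow_drain_when_demand_doubles(self, params):
        at_rest = iron.trfl_rhs(1.0, 1.0, 1.0, 1.0, params)
        assert at_rest == pytest.approx(0.0, abs=1e-12)
        assert iron.trfl_rhs(1.0, 1.0, 1.0, 2.0, params) < 0

    def test_trfl_zero_without_iron(self, params):
        one = params.with_updates({"iron.alpha": 1.0})
        assert iron.trfl_rhs(0.0, 1.0, 0.0, 1.0, one) == pytest.approx(0.0)

    def test_trfu_production_linear_in_ztrf(self, params):
        lo = iron.trfu_rhs(1.0, 1.0, 1.0, 1.0, 1.0, params)
        hi = iron.trfu_rhs(1.0, 1.0, 1.0, 1.0, 1.5, params)
        assert hi - lo == pytest.approx(0.5 * params.iron.k_TRFu)

    def test_trfu_pure_decay_without_sources(self, params):
        # no NTBI, no loaded transferrin, no marrow flux: pure degradation
        rhs = iron.trfu_rhs(2.0, 0.0, 0.0, 0.0, 1.0, params)
        assert rhs == pytest.approx(-params.require_derived().d_TRFu * 2.0)


class TestErythroidIronChain:
    def test_chain_length_mismatch_is_error(self, params):
        chain = ErythroidChain.from_params(params.cells)
        with pytest.raises(ValueError, match="does not match"):
            iron.erythroid_iron_rhs(np.ones(5), 1.0, 1.0, 1.0, 2.0,
                                    params.cells, chain)

    def test_stationary_at_reference(self, params):
        chain = ErythroidChain.from_params(params.cells)
        fe = np.ones(chain.n_ages + 3)
        d = iron.erythroid_iron_rhs(fe, 1.0, 1.0, 1.0, params.iron.alpha,
                                    params.cells, chain)
        np.testing.assert_allclose(d, 0.0, atol=1e-14)

    def test_no_transferrin_drains_chain(self, params):
        chain = ErythroidChain.from_params(params.cells)
        fe = np.ones(chain.n_ages + 3)
        d = iron.erythroid_iron_rhs(fe, 1.0, 1.0, 0.0, params.iron.alpha,
                                    params.cells, chain)
        assert d[0] < 0 and np.all(d[1:] <= 1e-14)

    def test_steady_influx_equals_death_outflux(self, params):
        # total erythroid iron is conserved at the fixed point
        chain = ErythroidChain.from_params(params.cells)
        fe = np.ones(chain.n_ages + 3)
        out = float(chain.w_out @ fe[2:])
        influx = 1.0 * 1.0 ** params.iron.alpha
        assert influx == pytest.approx(out)


class TestRecycling:
    def test_stationary_at_reference(self, params):
        assert iron.recycling_rhs(1.0, 1.0, 1.0, params) == pytest.approx(
            0.0, abs=1e-12)

    def test_total_loss_means_no_influx(self, params):
        lossy = params.with_updates({"iron.d_Fe": 1.0})
        rhs = iron.recycling_rhs(0.0, 5.0, 1.0, lossy)
        assert rhs == 0.0

    def test_ferroportin_block_accumulates_recycling_iron(self, params):
        # inflammation: lowered Zferro traps iron in macrophages
        assert iron.recycling_rhs(1.0, 1.0, 0.5, params) > 0


class TestObservables:
    def test_reference_state_maps_to_clinical_normals(self, params):
        obs = iron.observables(reference_state(params), params)
        br = params.bridges
        assert obs["HB"] == pytest.approx(params.references.HB_nor)
        assert obs["TSAT"] == pytest.approx(0.5)
        assert obs["TRF"] == pytest.approx(1.0)
        assert obs["serum_iron"] == pytest.approx(br.serum_iron_ref_ug_dl)
        assert obs["ferritin"] == pytest.approx(br.ferritin_ref_ug_l)
        assert obs["RBC"] == pytest.approx(br.rbc_nor_10e6_ul)
        assert obs["HCT"] == pytest.approx(br.hct_nor)

    def test_tsat_extremes(self, params):
        lay = layout_for(params)
        y = reference_state(params)
        y[lay.TRFl] = 0.0
        assert iron.observables(y, params)["TSAT"] == pytest.approx(0.0)
        y[lay.TRFl] = 1.0
        y[lay.TRFu] = 1.0
        assert iron.observables(y, params)["TSAT"] == pytest.approx(0.5)

    def test_tsat_undefined_without_transferrin(self, params):
        lay = layout_for(params)
        y = reference_state(params)
        y[lay.TRFl] = y[lay.TRFu] = 0.0
        with pytest.raises(ObservableError, match="TSAT"):
            iron.observables(y, params)

    def test_hb_neglects_reticulocyte_iron(self, params):
        lay = layout_for(params)
        y = reference_state(params)
        y[lay.Fe_RET] = 5.0
        assert iron.observables(y, params)["HB"] == pytest.approx(
            params.references.HB_nor)
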