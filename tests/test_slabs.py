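"""Slab stack construction: bilayer geometry, insertion models, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perimem import materials as M
from perimem import slabs as S
from perimem.reflectivity import abeles_reflectivity

H2O = M.SolventContrast(0.0)
D2O95 = M.SolventContrast(0.95)


class TestSubstrate:
    def test_full_coverage_oxide_is_pure_sio2(self):
        slabs = S.build_substrate(S.SubstrateParams(14, 1.0, 3, 5), H2O)
        assert slabs[0].sld == pytest.approx(M.SLD_SIO2)

    def test_partial_coverage_is_volume_mix(self):
        slabs = S.build_substrate(S.SubstrateParams(14, 0.75, 3, 5), H2O)
        expected = 0.75 * M.SLD_SIO2 + 0.25 * M.SLD_H2O
        assert slabs[0].sld == pytest.approx(expected, rel=1e-12)

    def test_zero_hydration_layer_omitted(self):
        slabs = S.build_substrate(S.SubstrateParams(14, 0.75, 3, 0.0), H2O)
        assert [s.name for s in slabs] == ["oxide"]

    def test_hydration_layer_is_pure_solvent(self):
        slabs = S.build_substrate(S.SubstrateParams(14, 0.75, 3, 5), D2O95)
        assert slabs[1].sld == pytest.approx(D2O95.sld)
        assert slabs[1].solvent_fraction == 1.0


class TestBilayer:
    def test_dry_bilayer_limit(self):
        """No hydration water: pure-moiety SLDs and closed-form thickness."""
        bp = S.BilayerParams(60.0, 0.0, 0.0, 5.0, 3.0, 0.0)
        slabs = S.build_bilayer(bp, S.DMPC_DMPG_11, H2O)
        lipid = S.DMPC_DMPG_11
        v_head, v_tail = (
            lipid.head.molecular_volume,
            lipid.tail.molecular_volume,
        )
        total = sum(s.thickness for s in slabs)
        assert total == pytest.approx(2 * (v_head + v_tail) / 60.0, rel=1e-12)
        assert slabs[0].sld == pytest.approx(lipid.head.sld_at(H2O))
        assert slabs[1].sld == pytest.approx(lipid.tail.sld_at(H2O))

    def test_doubling_apm_halves_thicknesses(self):
        bp1 = S.BilayerParams(apm=50.0, waters_per_head=3, waters_per_tail=4)
        bp2 = S.BilayerParams(apm=100.0, waters_per_head=3, waters_per_tail=4)
        t1 = [s.thickness for s in S.build_bilayer(bp1, S.DMPC_DMPG_11, H2O)]
        t2 = [s.thickness for s in S.build_bilayer(bp2, S.DMPC_DMPG_11, H2O)]
        assert np.allclose(np.array(t2), 0.5 * np.array(t1))

    def test_reference_bilayer_thickness_in_physical_range(self):
        """APM 60 Å², 3 waters/head, 4/tail: total thickness consistent with
        the ~4-5 nm bilayers seen in imaging (closed-form oracle)."""
        bp = S.BilayerParams(60.0, 3.0, 4.0, 5.0, 3.0, 0.0)
        slabs = S.build_bilayer(bp, S.DMPC_DMPG_11, H2O)
        lipid = S.DMPC_DMPG_11
        v_w = M.WATER.molecular_volume
        expected = (
            2
            * (
                (lipid.head.molecular_volume + 3 * v_w)
                + (lipid.tail.molecular_volume + 4 * v_w)
            )
            / 60.0
        )
        total = sum(s.thickness for s in slabs)
        assert total == pytest.approx(expected, rel=1e-12)
        assert 38.0 < total < 48.0

    def test_invalid_apm_rejected(self):
        with pytest.raises(ValueError):
            S.BilayerParams(apm=0.0)

    @given(
        apm=st.floats(40.0, 80.0),
        nh=st.floats(0.0, 20.0),
        nt=st.floats(0.0, 25.0),
        f=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_volume_conservation_everywhere(self, apm, nh, nt, f):
        """Component volume fractions sum to one in every slab, for every
        insertion model and parameter draw."""
        bp = S.BilayerParams(apm, nh, nt, 5.0, 3.0, 2.0)
        pp = S.ProteinParams(80.0, 0.3, 3.0, f, 0.5 * f)
        for model in S.InsertionModel:
            stack = S.build_stack(
                S.SubstrateParams(), bp, S.DMPC_DMPG_11, D2O95, pp, model
            )
            for slab in stack.slabs:
                assert sum(slab.fractions.values()) == pytest.approx(
                    1.0, abs=1e-9
                )
                assert all(v >= -1e-12 for v in slab.fractions.values())


class TestInsertionModels:
    def _stacks(self, model, pp, contrast=D2O95):
        return S.build_stack(
            S.SubstrateParams(),
            S.BilayerParams(45.0, 10.0, 17.0, 8.0, 4.0, 11.0),
            S.DMPC_DMPG_11,
            contrast,
            pp,
            model,
        )

    def test_zero_insertion_reduces_to_m1(self, q_grid):
        pp0 = S.ProteinParams(84.0, 0.26, 3.0, 0.0, 0.0)
        R1 = abeles_reflectivity(q_grid, self._stacks(S.InsertionModel.M1, pp0))
        for model in (
            S.InsertionModel.M2,
            S.InsertionModel.M3,
            S.InsertionModel.M4,
        ):
            R = abeles_reflectivity(q_grid, self._stacks(model, pp0))
            assert np.allclose(R, R1, rtol=1e-12)

    def test_m1_zero_coverage_is_reflectivity_equivalent_to_bare_bilayer(
        self, q_grid
    ):
        sub = S.SubstrateParams()
        bp = S.BilayerParams(45.0, 10.0, 17.0, 8.0, 4.0, 11.0)
        outer = float(np.hypot(bp.global_roughness, bp.local_outer_roughness))
        pp = S.ProteinParams(84.0, 0.0, outer, 0.0)
        with_layer = S.build_stack(
            sub, bp, S.DMPC_DMPG_11, D2O95, pp, S.InsertionModel.M1
        )
        bare = S.build_stack(sub, bp, S.DMPC_DMPG_11, D2O95)
        R1 = abeles_reflectivity(q_grid, with_layer)
        R0 = abeles_reflectivity(q_grid, bare)
        assert np.allclose(R1, R0, rtol=1e-10)

    def test_m3_books_39_percent_lipid_displacement(self):
        pp = S.ProteinParams(84.0, 0.26, 3.0, 0.39)
        stack = self._stacks(S.InsertionModel.M3, pp)
        by_name = {s.name: s for s in stack.slabs}
        outer_tails = by_name["outer-tails"]
        inner_tails = by_name["inner-tails"]
        # protein volume equals 39% of the original lipid volume
        phi_lipid_0 = inner_tails.fractions["lipid_tail"]
        assert outer_tails.fractions["protein"] == pytest.approx(
            0.39 * phi_lipid_0, rel=1e-12
        )
        assert outer_tails.fractions["lipid_tail"] == pytest.approx(
            0.61 * phi_lipid_0, rel=1e-12
        )
        assert "protein" not in inner_tails.fractions

    def test_m2_displaces_only_outer_head_water(self):
        pp = S.ProteinParams(84.0, 0.26, 3.0, 0.5)
        stack = self._stacks(S.InsertionModel.M2, pp)
        by_name = {s.name: s for s in stack.slabs}
        assert "protein" in by_name["outer-heads"].fractions
        assert "protein" not in by_name["outer-tails"].fractions
        # lipid content untouched
        assert by_name["outer-heads"].fractions["lipid_head"] == pytest.approx(
            by_name["inner-heads"].fractions["lipid_head"]
        )

    def test_overdisplacement_raises(self):
        bilayer = S.build_bilayer(
            S.BilayerParams(), S.DMPC_DMPG_11, D2O95
        )
        class Overfull:
            # bypasses ProteinParams validation to request 150% displacement
            layer_thickness = 84.0
            layer_coverage = 0.26
            layer_roughness = 3.0
            fraction_in_outer_leaflet = 1.5
            fraction_in_inner_leaflet = 0.0

        with pytest.raises(S.InfeasibleModelError):
            S.apply_insertion(
                S.InsertionModel.M3, bilayer, Overfull(), 2e-6, D2O95
            )

    def test_contrast_changes_only_solvent_containing_slabs(self):
        """Switching f_D2O rescales solvated slab SLDs but never geometry."""
        pp = S.ProteinParams(84.0, 0.26, 3.0, 0.39)
        s_h2o = self._stacks(S.InsertionModel.M3, pp, M.SolventContrast(0.0))
        s_d2o = self._stacks(S.InsertionModel.M3, pp, D2O95)
        assert np.allclose(s_h2o.thicknesses(), s_d2o.thicknesses())
        assert np.allclose(s_h2o.roughnesses(), s_d2o.roughnesses())
        for a, b in zip(s_h2o.slabs, s_d2o.slabs):
            solvated = (
                a.fractions.get("water", 0) + a.fractions.get("solvent", 0)
            ) > 0
            labile = a.fractions.get("lipid_head", 0) > 0  # PG OH exchange
            if not solvated and not labile and "protein" not in a.fractions:
                assert a.sld == pytest.approx(b.sld)


class TestSldProfile:
    def test_sharp_limit_is_piecewise_constant(self):
        slabs = (S.Slab(20.0, 3e-6, 0.0), S.Slab(30.0, 1e-6, 0.0))
        stack = S.SlabStack(slabs, fronting_sld=2e-6, backing_sld=6e-6)
        z = np.array([-5.0, 10.0, 35.0, 60.0])
        rho = S.sld_profile(stack, z)
        assert np.allclose(rho, [2e-6, 3e-6, 1e-6, 6e-6])

    @pytest.mark.filterwarnings("ignore:roughness")
    def test_far_field_equals_fronting_and_backing(self, bilayer_alone_stack):
        z = np.array([-500.0, 1500.0])
        rho = S.sld_profile(bilayer_alone_stack, z)
        assert rho[0] == pytest.approx(bilayer_alone_stack.fronting_sld)
        assert rho[1] == pytest.approx(bilayer_alone_stack.backing_sld)

    def test_integral_invariant_under_roughness(self):
        """Total scattering material is conserved when interfaces broaden
        (numeric quadrature oracle)."""
        z = np.linspace(-150.0, 250.0, 8001)

        def area(rough):
            slabs = (S.Slab(20.0, 3e-6, rough), S.Slab(30.0, 0.5e-6, rough))
            stack = S.SlabStack(
                slabs, fronting_sld=2e-6, backing_sld=6e-6,
                backing_roughness=rough,
            )
            rho = S.sld_profile(stack, z)
            return np.trapezoid(rho - stack.backing_sld, z)

        # closed form: sum over media of (rho - backing) * extent in window
        expected = (2e-6 - 6e-6) * 150 + (3e-6 - 6e-6) * 20 + (0.5e-6 - 6e-6) * 30
        assert area(5.0) == pytest.approx(area(12.0), rel=1e-6)
        assert area(5.0) == pytest.approx(expected, rel=1e-6)
        # the sharp limit agrees to trapezoid-rule accuracy at the steps
        assert area(0.0) == pytest.approx(expected, rel=2e-4)

    def test_excess_roughness_warns_but_computes(self):
        slabs = (S.Slab(5.0, 3e-6, 12.0), S.Slab(30.0, 1e-6, 2.0))
        stack = S.SlabStack(slabs, fronting_sld=2e-6, backing_sld=6e-6)
        with pytest.warns(UserWarning, match="roughness"):
            rho = S.sld_profile(stack, np.linspace(-10, 50, 50))
        assert np.all(np.isfinite(rho))


class TestLipidMixing:
    def test_mole_fraction_average(self):
        mix = S.mix_lipids([S.DMPC, S.DMPG], [0.5, 0.5])
        assert mix.head.molecular_volume == pytest.approx(
            0.5
            * (
                S.DMPC.head.molecular_volume
                + S.DMPG.head.molecular_volume
            )
        )
        assert mix.tail.scattering_length == pytest.approx(
            S.DMPC.tail.scattering_length
        )

    def test_d54_tails_differ_only_in_scattering_length(self):
        assert (
            S.D54_DMPC_DMPG_11.tail.molecular_volume
            == S.DMPC_DMPG_11.tail.molecular_volume
        )
        assert (
            S.D54_DMPC_DMPG_11.tail.scattering_length
            > S.DMPC_DMPG_11.tail.scattering_length
        )
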