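"""Co-refinement: recovery, determinism, bootstrap, model selection,
time-resolved fitting.  Problems are kept small (coarse q grids, few free
parameters) so each fit runs in seconds."""

import numpy as np
import pytest

from perimem.corefine import (
    bootstrap,
    corefine,
    fit_time_series,
    select_model,
)
from perimem.slabs import (
    BilayerParams,
    D54_DMPC_DMPG_11,
    InsertionModel,
    ProteinParams,
    SubstrateParams,
)
from perimem.synthetic import NRScenario, gen_nr, scenario

SMALL_DE = dict(popsize=8, maxiter=80, tol=1e-4)

TRUTH_FIX = {
    "oxide_thickness": 14.0,
    "oxide_coverage": 0.75,
    "oxide_roughness": 3.0,
    "hydration_thickness": 5.0,
    "global_roughness": 8.0,
    "inner_roughness": 4.0,
    "outer_roughness": 11.0,
    "waters_per_head": 10.0,
    "waters_per_tail": 17.0,
}


def _protein_scenario(model, **kw):
    return NRScenario(
        substrate=SubstrateParams(14.0, 0.75, 3.0, 5.0),
        bilayer=BilayerParams(45.0, 10.0, 17.0, 8.0, 4.0, 11.0),
        protein=ProteinParams(84.0, 0.26, 3.0, 0.39, 0.15),
        insertion_model=model,
        noise_fraction=0.0,
        n_q=60,
        **kw,
    )


class TestNoiselessRecovery:
    @pytest.mark.parametrize("model", list(InsertionModel), ids=lambda m: m.name)
    def test_every_insertion_model_recovers_truth(self, model):
        """Noiseless self-generated data return the generating parameters
        to relative 1e-3 for all four insertion hypotheses."""
        sc = _protein_scenario(model)
        data = gen_nr(sc, seed=0)
        vary = ["apm", "mbp_thickness", "mbp_coverage"]
        if model in (InsertionModel.M2, InsertionModel.M3, InsertionModel.M4):
            vary.append("insert_outer")
        if model is InsertionModel.M4:
            vary.append("insert_inner")
        fix = dict(TRUTH_FIX)
        fix["mbp_roughness"] = 3.0
        res = corefine(
            data, model=model, vary=vary, fix=fix, seed=0,
            de_options=SMALL_DE,
        )
        assert res.success
        assert res.values["apm"] == pytest.approx(45.0, rel=1e-3)
        assert res.values["mbp_thickness"] == pytest.approx(84.0, rel=1e-3)
        assert res.values["mbp_coverage"] == pytest.approx(0.26, rel=1e-3)
        if "insert_outer" in vary:
            assert res.values["insert_outer"] == pytest.approx(0.39, rel=1e-3)
        if "insert_inner" in vary:
            assert res.values["insert_inner"] == pytest.approx(0.15, rel=1e-3)
        assert res.chi2 / res.n_points < 1e-8

    def test_bilayer_alone_hydration_parameters(self):
        """Noiseless three-contrast data from the protein-free truth return
        APM 60 Å², 3 waters/head and 4 waters/tail."""
        sc = scenario("bilayer-alone-h", noise_fraction=0.0, n_q=60)
        data = gen_nr(sc, seed=0)
        res = corefine(
            data,
            vary=["apm", "waters_per_head", "waters_per_tail"],
            fix={"oxide_thickness": 14.0, "oxide_coverage": 0.75,
                 "oxide_roughness": 3.0, "hydration_thickness": 5.0,
                 "global_roughness": 5.0, "inner_roughness": 3.0,
                 "outer_roughness": 0.0},
            seed=0,
            de_options=SMALL_DE,
        )
        assert res.values["apm"] == pytest.approx(60.0, rel=1e-3)
        assert res.values["waters_per_head"] == pytest.approx(3.0, rel=1e-3)
        assert res.values["waters_per_tail"] == pytest.approx(4.0, rel=1e-3)

    def test_all_fixed_returns_inputs_and_forward_chi2(self):
        sc = _protein_scenario(InsertionModel.M3, contrasts=(0.95,))
        data = gen_nr(sc, seed=0)
        fix = dict(TRUTH_FIX, apm=45.0, mbp_thickness=84.0,
                   mbp_coverage=0.26, mbp_roughness=3.0, insert_outer=0.39)
        res = corefine(data, model=InsertionModel.M3, vary=[], fix=fix)
        assert res.varied == ()
        assert res.values["apm"] == 45.0
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)


class TestDeterminism:
    def test_corefine_bit_reproducible_with_seed(self):
        sc = scenario("bilayer-alone-h", n_q=50)
        data = gen_nr(sc, seed=3)
        kwargs = dict(
            vary=["apm", "waters_per_tail"],
            fix={k: v for k, v in TRUTH_FIX.items()
                 if k not in ("waters_per_tail",)} | {
                     "global_roughness": 5.0, "inner_roughness": 3.0,
                     "outer_roughness": 0.0, "waters_per_head": 3.0},
            seed=42,
            de_options=dict(popsize=6, maxiter=30, tol=0.01),
        )
        r1 = corefine(data, **kwargs)
        r2 = corefine(data, **kwargs)
        assert r1.values == r2.values
        assert r1.chi2 == r2.chi2

    def test_bootstrap_reproducible_and_order_invariant(self):
        sc = scenario("bilayer-alone-h", n_q=50)
        data = gen_nr(sc, seed=3)
        fix = dict(TRUTH_FIX)
        fix.update(global_roughness=5.0, inner_roughness=3.0,
                   outer_roughness=0.0, waters_per_head=3.0,
                   waters_per_tail=4.0)
        res = corefine(data, vary=["apm"], fix=fix, seed=0,
                       global_stage=False)
        i1 = bootstrap(res, n_resamples=25, seed=7)
        res_perm = corefine([data[2], data[0], data[1]], vary=["apm"],
                            fix=fix, seed=0, global_stage=False)
        i2 = bootstrap(res_perm, n_resamples=25, seed=7)
        i3 = bootstrap(res, n_resamples=25, seed=7)
        assert i1 == i3  # bit-reproducible
        assert i1["apm"] == pytest.approx(i2["apm"], rel=1e-9)  # order-free


class TestBootstrap:
    def _fit_apm(self, data, seed=0):
        fix = dict(TRUTH_FIX)
        fix.update(global_roughness=5.0, inner_roughness=3.0,
                   outer_roughness=0.0, waters_per_head=3.0,
                   waters_per_tail=4.0)
        return corefine(data, vary=["apm"], fix=fix, seed=seed,
                        global_stage=False)

    def test_interval_width_vanishes_with_noise(self):
        """sigma_R -> 0 (noiseless data, floor-level sigma): interval
        width collapses."""
        data = gen_nr(scenario("bilayer-alone-h", noise_fraction=0.0,
                               n_q=50), seed=0)
        res = self._fit_apm(data)
        lo, hi = bootstrap(res, n_resamples=25, seed=1)["apm"]
        assert hi - lo < 0.05

    def test_small_resample_count_warns(self):
        data = gen_nr(scenario("bilayer-alone-h", n_q=50), seed=0)
        res = self._fit_apm(data)
        with pytest.warns(UserWarning, match="n_resamples"):
            bootstrap(res, n_resamples=10, seed=1)

    def test_more_contrasts_tighten_intervals(self):
        """Adding solvent contrasts never widens the bootstrap interval
        (information monotonicity at fixed truth)."""
        data3 = gen_nr(scenario("bilayer-alone-h", n_q=50), seed=5)
        res3 = self._fit_apm(data3)
        w3 = np.diff(bootstrap(res3, n_resamples=40, seed=2)["apm"])[0]
        res1 = self._fit_apm(data3[:1])
        w1 = np.diff(bootstrap(res1, n_resamples=40, seed=2)["apm"])[0]
        assert w3 <= w1


class TestModelSelection:
    def test_m1_truth_prefers_m1_by_parsimony(self):
        """Data generated with a pure surface layer: M2-M4 collapse to zero
        insertion and tie; the fewest-parameter model wins."""
        sc = NRScenario(
            substrate=SubstrateParams(14.0, 0.75, 3.0, 5.0),
            bilayer=BilayerParams(45.0, 10.0, 17.0, 8.0, 4.0, 11.0),
            protein=ProteinParams(84.0, 0.26, 3.0, 0.0, 0.0),
            insertion_model=InsertionModel.M1,
            noise_fraction=0.0,
            n_q=50,
        )
        data = gen_nr(sc, seed=0)
        fix = dict(TRUTH_FIX, apm=45.0, mbp_roughness=3.0)
        ranking = select_model(
            data, fix=fix, seed=0,
            de_options=dict(popsize=6, maxiter=40, tol=1e-3),
        )
        assert ranking.best is InsertionModel.M1
        chis = [ranking.results[m].chi2 / ranking.results[m].n_points
                for m in InsertionModel]
        assert max(chis) < 0.05  # all four fit the degenerate data


class TestTimeSeries:
    def test_scripted_association_trajectory(self):
        """Slices scripted surface-adsorption -> headgroup penetration ->
        full outer-leaflet insertion: the fitted layer thins while the
        inserted fraction grows, and the repeated endpoint flags steady
        state."""
        substrate = dict(oxide_thickness=10.0, oxide_coverage=0.9,
                         oxide_roughness=3.0, hydration_thickness=25.0)
        bilayer = BilayerParams(52.0, 10.0, 17.0, 22.0, 5.0, 0.0)
        sub = SubstrateParams(10.0, 0.9, 3.0, 25.0)

        def snap(model, thick, cov, insert):
            return NRScenario(
                substrate=sub, bilayer=bilayer,
                protein=ProteinParams(thick, cov, 10.0, insert),
                insertion_model=model, lipid=D54_DMPC_DMPG_11,
                contrasts=(0.0,), noise_fraction=0.0, n_q=60,
            )

        script = [
            snap(InsertionModel.M1, 70.0, 0.50, 0.0),
            snap(InsertionModel.M2, 60.0, 0.50, 0.25),
            snap(InsertionModel.M3, 50.0, 0.50, 0.44),
            snap(InsertionModel.M3, 50.0, 0.50, 0.44),
            snap(InsertionModel.M3, 50.0, 0.50, 0.44),
        ]
        slices = [gen_nr(s, seed=0)[0] for s in script]
        models = [s.insertion_model for s in script]
        fix = dict(apm=52.0, waters_per_head=10.0, waters_per_tail=17.0,
                   global_roughness=22.0, inner_roughness=5.0,
                   outer_roughness=0.0, mbp_roughness=10.0)
        results, steady = fit_time_series(
            slices, models, substrate=substrate, lipid=D54_DMPC_DMPG_11,
            vary=["mbp_thickness", "mbp_coverage", "insert_outer"],
            fix=fix, seed=0, steady_bootstrap_n=20,
            de_options=dict(popsize=6, maxiter=50, tol=1e-3),
        )
        thick = [r.values["mbp_thickness"] for r in results]
        insert = [r.values.get("insert_outer", 0.0) for r in results]
        assert thick[0] > thick[1] > thick[2]
        assert insert[2] > insert[1] > insert[0]
        assert insert[2] == pytest.approx(0.44, rel=1e-2)
        assert steady[0] is False
        assert steady[3] and steady[4]

    def test_identical_slices_flag_immediately(self):
        sc = _protein_scenario(InsertionModel.M3, contrasts=(0.95,))
        ds = gen_nr(sc, seed=0)[0]
        substrate = dict(oxide_thickness=14.0, oxide_coverage=0.75,
                         oxide_roughness=3.0, hydration_thickness=5.0)
        fix = {k: v for k, v in TRUTH_FIX.items()
               if k not in substrate} | dict(apm=45.0, mbp_roughness=3.0)
        results, steady = fit_time_series(
            [ds, ds, ds], InsertionModel.M3, substrate=substrate,
            vary=["mbp_thickness", "mbp_coverage"], fix=fix, seed=0,
            steady_bootstrap_n=20,
            de_options=dict(popsize=6, maxiter=40, tol=1e-3),
        )
        assert results[0].values == results[1].values == results[2].values
        assert steady == [False, True, True]
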