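"""Simultaneous multi-contrast fitting of the slab model.

A single physical parameter set — substrate, bilayer and (optionally)
protein parameters — is refined against several reflectivity curves of the
same sample measured at different solvent contrasts.  Contrast variation is
what breaks the degeneracies of a single curve: the substrate and bilayer
parameters are shared across all contrasts, while only the solvent SLD
differs between datasets.

Optimisation is a two-stage scheme: a bounded global differential-evolution
search (seeded, hence reproducible) followed by a local trust-region
least-squares polish.  Uncertainties come from a parametric bootstrap:
synthetic replicates are drawn point-wise from Normal(R_model, sigma_R),
refitted, and the central 68% of the refitted values quoted per parameter.

The competing insertion hypotheses M1–M4 are compared by fitting each from
identical starting conditions and ranking by total chi-squared, with a
parsimony tie-break: within a reduced-chi-squared margin of 0.05 the model
with fewer free parameters wins (M2–M4 all contain M1 as a special case, so
without the tie-break the richer models would never lose).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import optimize

from .reflectivity import NRDataset, smeared_reflectivity
from .slabs import (
    BilayerParams,
    InsertionModel,
    Lipid,
    ProteinParams,
    SubstrateParams,
    build_stack,
    DMPC_DMPG_11,
)

#: Default parameter bounds (units: Å, Å², fractions).  Starting values are
#: the midpoints of these intervals.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "oxide_thickness": (5.0, 25.0),
    "oxide_coverage": (0.5, 1.0),
    "oxide_roughness": (0.0, 10.0),
    "hydration_thickness": (0.0, 40.0),
    "apm": (40.0, 80.0),
    "waters_per_head": (0.0, 20.0),
    "waters_per_tail": (0.0, 25.0),
    "global_roughness": (0.0, 30.0),
    "inner_roughness": (0.0, 15.0),
    "outer_roughness": (0.0, 15.0),
    "insert_outer": (0.0, 1.0),
    "insert_inner": (0.0, 1.0),
    "mbp_thickness": (0.0, 150.0),
    "mbp_coverage": (0.0, 1.0),
    "mbp_roughness": (0.0, 20.0),
}

SUBSTRATE_PARAMS = (
    "oxide_thickness",
    "oxide_coverage",
    "oxide_roughness",
    "hydration_thickness",
)
BILAYER_PARAMS = (
    "apm",
    "waters_per_head",
    "waters_per_tail",
    "global_roughness",
    "inner_roughness",
    "outer_roughness",
)

_MODEL_PROTEIN_PARAMS = {
    InsertionModel.M1: ("mbp_thickness", "mbp_coverage", "mbp_roughness"),
    InsertionModel.M2: (
        "mbp_thickness",
        "mbp_coverage",
        "mbp_roughness",
        "insert_outer",
    ),
    InsertionModel.M3: (
        "mbp_thickness",
        "mbp_coverage",
        "mbp_roughness",
        "insert_outer",
    ),
    InsertionModel.M4: (
        "mbp_thickness",
        "mbp_coverage",
        "mbp_roughness",
        "insert_outer",
        "insert_inner",
    ),
}


def protein_param_names(model: InsertionModel) -> tuple[str, ...]:
    return _MODEL_PROTEIN_PARAMS[model]


@dataclass
class SlabFitModel:
    """Maps a flat parameter dictionary onto per-contrast slab stacks."""

    lipid: Lipid = DMPC_DMPG_11
    insertion_model: InsertionModel | None = None
    labile_fraction_exchanged: float = 0.9

    def param_names(self) -> tuple[str, ...]:
        names = SUBSTRATE_PARAMS + BILAYER_PARAMS
        if self.insertion_model is not None:
            names = names + protein_param_names(self.insertion_model)
        return names

    def default_params(
        self,
        vary: list[str] | None = None,
        fix: dict[str, float] | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
    ) -> lmfit.Parameters:
        """Build an lmfit parameter set: midpoint starts within bounds.

        ``vary`` restricts which parameters float (default: all of them);
        ``fix`` pins named parameters at given values.
        """
        bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
        fix = fix or {}
        params = lmfit.Parameters()
        for name in self.param_names():
            lo, hi = bounds[name]
            if name in fix:
                value = float(fix[name])
                params.add(name, value=value, vary=False)
            else:
                varies = vary is None or name in vary
                params.add(
                    name, value=0.5 * (lo + hi), min=lo, max=hi, vary=varies
                )
        return params

    def stack(self, values: dict, contrast):
        sub = SubstrateParams(
            oxide_thickness=values["oxide_thickness"],
            oxide_coverage=values["oxide_coverage"],
            oxide_roughness=values["oxide_roughness"],
            hydration_layer_thickness=values["hydration_thickness"],
        )
        bp = BilayerParams(
            apm=values["apm"],
            waters_per_head=values["waters_per_head"],
            waters_per_tail=values["waters_per_tail"],
            global_roughness=values["global_roughness"],
            local_inner_roughness=values["inner_roughness"],
            local_outer_roughness=values["outer_roughness"],
        )
        if self.insertion_model is None:
            return build_stack(sub, bp, self.lipid, contrast)
        pp = ProteinParams(
            layer_thickness=values["mbp_thickness"],
            layer_coverage=values["mbp_coverage"],
            layer_roughness=values["mbp_roughness"],
            fraction_in_outer_leaflet=values.get("insert_outer", 0.0),
            fraction_in_inner_leaflet=values.get("insert_inner", 0.0),
        )
        return build_stack(
            sub,
            bp,
            self.lipid,
            contrast,
            protein=pp,
            model=self.insertion_model,
            labile_fraction_exchanged=self.labile_fraction_exchanged,
        )


@dataclass
class CorefinementProblem:
    """Datasets plus the fit model that maps parameters onto them."""

    datasets: list[NRDataset]
    fit_model: SlabFitModel

    def residuals(self, params) -> np.ndarray:
        values = (
            params.valuesdict() if hasattr(params, "valuesdict") else params
        )
        out = []
        for ds in self.datasets:
            stack = self.fit_model.stack(values, ds.contrast)
            model = smeared_reflectivity(ds.q, stack, ds.sigma_q)
            out.append((model - ds.R) / ds.sigma_R)
        return np.concatenate(out)

    def chi2_per_dataset(self, params) -> list[float]:
        values = (
            params.valuesdict() if hasattr(params, "valuesdict") else params
        )
        out = []
        for ds in self.datasets:
            stack = self.fit_model.stack(values, ds.contrast)
            model = smeared_reflectivity(ds.q, stack, ds.sigma_q)
            out.append(float(np.sum(((model - ds.R) / ds.sigma_R) ** 2)))
        return out

    @property
    def n_points(self) -> int:
        return sum(len(ds) for ds in self.datasets)


@dataclass
class CorefinementResult:
    """Best-fit values, goodness of fit and convergence metadata."""

    values: dict[str, float]
    stderr: dict[str, float]
    chi2: float
    chi2_per_dataset: list[float]
    n_points: int
    varied: tuple[str, ...]
    insertion_model: InsertionModel | None
    seed: int | None
    success: bool
    nfev: int
    message: str = ""
    problem: CorefinementProblem | None = field(default=None, repr=False)
    params: lmfit.Parameters | None = field(default=None, repr=False)
    bootstrap_intervals: dict | None = field(default=None, repr=False)

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.n_points - len(self.varied), 1)
        return self.chi2 / dof

    @property
    def n_varied(self) -> int:
        return len(self.varied)


DEFAULT_DE_OPTIONS = dict(
    popsize=15,
    maxiter=300,
    tol=0.01,
    mutation=(0.5, 1.0),
    recombination=0.7,
    init="sobol",
    polish=False,
    updating="deferred",
)


def corefine(
    datasets: list[NRDataset],
    model: InsertionModel | None = None,
    lipid: Lipid = DMPC_DMPG_11,
    params: lmfit.Parameters | None = None,
    vary: list[str] | None = None,
    fix: dict[str, float] | None = None,
    seed: int = 0,
    global_stage: bool = True,
    de_options: dict | None = None,
    labile_fraction_exchanged: float = 0.9,
) -> CorefinementResult:
    """Co-refine one parameter set against several contrast datasets.

    All parameters are shared across the supplied datasets (which therefore
    must belong to one sample in one condition); only the solvent contrast
    differs per dataset.  ``fix`` pins parameters (e.g. substrate values
    carried over from a protein-free fit); ``vary`` whitelists the floating
    ones.  With ``global_stage`` a seeded differential-evolution search
    precedes the least-squares polish; without it only the polish runs from
    the supplied starting values.

    Non-convergence is reported through ``success``/``message`` on the
    result rather than raised.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    fit_model = SlabFitModel(
        lipid=lipid,
        insertion_model=model,
        labile_fraction_exchanged=labile_fraction_exchanged,
    )
    problem = CorefinementProblem(list(datasets), fit_model)
    if params is None:
        params = fit_model.default_params(vary=vary, fix=fix)
    else:
        params = params.copy()

    varied = tuple(n for n in params if params[n].vary)
    values = dict(params.valuesdict())
    nfev = 0
    message = ""
    success = True
    stderr: dict[str, float] = {}

    if varied:
        x0 = np.array([params[n].value for n in varied])
        lo = np.array([params[n].min for n in varied])
        hi = np.array([params[n].max for n in varied])

        def residual_vec(x):
            trial = dict(values)
            trial.update(zip(varied, x))
            return problem.residuals(trial)

        def cost(x):
            r = residual_vec(x)
            return float(r @ r)

        if global_stage:
            de_kws = {**DEFAULT_DE_OPTIONS, **(de_options or {})}
            de_kws["seed"] = seed
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                de_res = optimize.differential_evolution(
                    cost, bounds=list(zip(lo, hi)), **de_kws
                )
            x0 = np.clip(de_res.x, lo, hi)
            nfev += int(de_res.nfev)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ls = optimize.least_squares(
                residual_vec,
                x0,
                bounds=(lo, hi),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        values.update(zip(varied, ls.x))
        for n, v in zip(varied, ls.x):
            params[n].value = float(v)
        nfev += int(ls.nfev)
        success = bool(ls.success)
        message = str(ls.message)
        # sigma-normalised residuals: covariance = (J^T J)^-1
        try:
            cov = np.linalg.pinv(ls.jac.T @ ls.jac)
            stderr = dict(zip(varied, np.sqrt(np.abs(np.diag(cov)))))
        except np.linalg.LinAlgError:
            stderr = {n: np.nan for n in varied}

    chi2_parts = problem.chi2_per_dataset(values)
    return CorefinementResult(
        values=values,
        stderr=stderr,
        chi2=float(sum(chi2_parts)),
        chi2_per_dataset=chi2_parts,
        n_points=problem.n_points,
        varied=varied,
        insertion_model=model,
        seed=seed,
        success=success,
        nfev=nfev,
        message=message,
        problem=problem,
        params=params,
    )


def _dataset_seed(base_seed: int, ds: NRDataset) -> int:
    """Content-derived RNG seed so bootstrap draws do not depend on the
    order in which datasets are supplied."""
    payload = np.round(ds.q, 10).tobytes() + np.round(ds.R, 12).tobytes()
    crc = zlib.crc32(payload + bytes(f"{ds.contrast.f_D2O:.6f}", "ascii"))
    return (int(base_seed) * 1000003 + crc) % (2**31 - 1)


def bootstrap(
    result: CorefinementResult,
    n_resamples: int = 100,
    seed: int = 0,
    method: str = "parametric",
    interval: float = 0.68,
) -> dict[str, tuple[float, float]]:
    """Parameter uncertainty intervals by Monte-Carlo resampling.

    Each resample draws a synthetic replicate of every dataset — point-wise
    Normal(R_model, sigma_R) for the default parametric scheme, or the
    model curve plus resampled observed residuals for ``method='residual'``
    — and refits it locally from the best values.  The quoted interval per
    parameter is the central ``interval`` mass of the refitted values.

    Results are stored on ``result.bootstrap_intervals`` and returned.
    """
    if result.problem is None or result.params is None:
        raise ValueError("result must carry its problem (fit via corefine)")
    if n_resamples < 20:
        warnings.warn(
            f"n_resamples={n_resamples} < 20: intervals will be unstable",
            stacklevel=2,
        )
    problem = result.problem
    values = result.values

    # model curves and per-dataset deterministic RNG streams
    curves = []
    for ds in problem.datasets:
        stack = problem.fit_model.stack(values, ds.contrast)
        curves.append(smeared_reflectivity(ds.q, stack, ds.sigma_q))

    varied = result.varied
    x_best = np.array([values[n] for n in varied])
    lo = np.array([result.params[n].min for n in varied])
    hi = np.array([result.params[n].max for n in varied])

    samples = {n: [] for n in varied}
    for i in range(n_resamples):
        boot_datasets = []
        for ds, model_R in zip(problem.datasets, curves):
            rng = np.random.default_rng(
                (_dataset_seed(seed, ds) + 7919 * i) % (2**31 - 1)
            )
            if method == "parametric":
                R_star = rng.normal(model_R, ds.sigma_R)
            elif method == "residual":
                resid = ds.R - model_R
                R_star = model_R + rng.choice(resid, size=resid.size)
            else:
                raise ValueError(f"unknown bootstrap method {method!r}")
            boot_datasets.append(
                NRDataset(
                    q=ds.q,
                    R=np.clip(R_star, 0.0, None),
                    sigma_R=ds.sigma_R,
                    sigma_q=ds.sigma_q,
                    contrast=ds.contrast,
                    label=ds.label,
                )
            )
        boot_problem = CorefinementProblem(boot_datasets, problem.fit_model)

        def residual_vec(x):
            trial = dict(values)
            trial.update(zip(varied, x))
            return boot_problem.residuals(trial)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.least_squares(
                residual_vec, x_best, bounds=(lo, hi)
            )
        for n, v in zip(varied, res.x):
            samples[n].append(float(v))

    alpha = 0.5 * (1.0 - interval)
    intervals = {
        n: (
            float(np.quantile(samples[n], alpha)),
            float(np.quantile(samples[n], 1.0 - alpha)),
        )
        for n in result.varied
    }
    result.bootstrap_intervals = {
        "intervals": intervals,
        "samples": {n: np.asarray(v) for n, v in samples.items()},
        "n_resamples": n_resamples,
        "seed": seed,
        "method": method,
    }
    return intervals


@dataclass
class ModelRanking:
    """Outcome of fitting all candidate insertion models."""

    results: dict[InsertionModel, CorefinementResult]
    ranking: list[InsertionModel]
    parsimony_margin: float

    @property
    def best(self) -> InsertionModel:
        return self.ranking[0]


def select_model(
    datasets: list[NRDataset],
    candidates: tuple[InsertionModel, ...] = tuple(InsertionModel),
    parsimony_margin: float = 0.05,
    **corefine_kwargs,
) -> ModelRanking:
    """Fit each candidate insertion model from identical starting
    conditions and rank them.

    Ranking is by total chi-squared, except that any model whose reduced
    chi-squared lies within ``parsimony_margin`` of the best is considered
    statistically tied, and ties resolve to fewer free parameters (then to
    the simpler model identity).
    """
    results = {
        m: corefine(datasets, model=m, **corefine_kwargs) for m in candidates
    }
    n = sum(len(ds) for ds in datasets)
    best_chi2 = min(r.chi2 for r in results.values())

    order = list(InsertionModel)

    def sort_key(m: InsertionModel):
        r = results[m]
        tied = (r.chi2 - best_chi2) / n < parsimony_margin
        if tied:
            return (0, r.n_varied, order.index(m))
        return (1, r.chi2, order.index(m))

    ranking = sorted(results, key=sort_key)
    return ModelRanking(
        results=results, ranking=ranking, parsimony_margin=parsimony_margin
    )


def fit_time_series(
    slices: list[NRDataset],
    models,
    substrate: dict[str, float],
    lipid: Lipid = DMPC_DMPG_11,
    seed: int = 0,
    vary: list[str] | None = None,
    fix: dict[str, float] | None = None,
    steady_bootstrap_n: int = 25,
    **corefine_kwargs,
) -> tuple[list[CorefinementResult], list[bool]]:
    """Fit a sequence of single-contrast time slices.

    Substrate parameters are frozen (typically from the protein-free fit);
    bilayer and protein parameters float per slice.  ``models`` is either
    one insertion model for all slices or one per slice.  A slice is
    flagged as steady state when every floating parameter moved from the
    previous slice by less than one bootstrap sigma (half the central-68%
    interval of the previous slice's parametric bootstrap).

    Returns (per-slice results, per-slice steady-state flags); the first
    slice is never flagged.
    """
    if isinstance(models, InsertionModel) or models is None:
        models = [models] * len(slices)
    if len(models) != len(slices):
        raise ValueError("need one insertion model per slice")

    all_fix = {**substrate, **(fix or {})}
    results: list[CorefinementResult] = []
    steady: list[bool] = []
    prev_sigma: dict[str, float] | None = None
    for ds, model in zip(slices, models):
        res = corefine(
            [ds],
            model=model,
            lipid=lipid,
            vary=vary,
            fix=all_fix,
            seed=seed,
            **corefine_kwargs,
        )
        flag = False
        if results:
            prev = results[-1]
            shared = [n for n in res.varied if n in prev.values]
            if prev_sigma is None:
                intervals = bootstrap(
                    prev, n_resamples=steady_bootstrap_n, seed=seed
                )
                prev_sigma = {
                    n: 0.5 * (hi - lo) for n, (lo, hi) in intervals.items()
                }
            flag = all(
                abs(res.values[n] - prev.values[n])
                <= prev_sigma.get(n, 0.0) + 1e-12
                for n in shared
            )
        results.append(res)
        if flag:
            prev_sigma = prev_sigma  # steady: keep the same reference sigma
        else:
            prev_sigma = None
        steady.append(flag)
    return results, steady
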