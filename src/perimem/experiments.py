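"""Canned parameter-recovery experiments on synthetic data.

These functions wire the generators and the co-refinement engine together
into the standard self-consistency studies for this pipeline: generate
three-contrast reflectivity from a known truth, refit it blind (midpoint
starting values, global + local optimisation), and compare the recovered
parameters with the generating ones.  They are used both by the test suite
and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .corefine import (
    BILAYER_PARAMS,
    SUBSTRATE_PARAMS,
    CorefinementResult,
    ModelRanking,
    bootstrap,
    corefine,
    protein_param_names,
    select_model,
)
from .slabs import InsertionModel
from .synthetic import NRScenario, gen_nr, scenario


def recover_bilayer_alone(
    seed: int = 0,
    noise_fraction: float = 0.03,
    n_q: int = 150,
    de_options: dict | None = None,
) -> CorefinementResult:
    """Generate the protein-free bilayer at three contrasts and refit it.

    All ten substrate + bilayer parameters float, shared across the three
    contrasts; starting values are midpoints of the default bounds.
    """
    sc = scenario(
        "bilayer-alone-h", noise_fraction=noise_fraction, n_q=n_q
    )
    data = gen_nr(sc, seed=seed)
    vary = list(SUBSTRATE_PARAMS + BILAYER_PARAMS)
    return corefine(
        data,
        model=None,
        lipid=sc.lipid,
        vary=vary,
        seed=seed,
        de_options=de_options,
    )


def recover_with_protein(
    seed: int = 0,
    scenario_name: str = "with-rmbp-h-M3",
    noise_fraction: float = 0.03,
    n_q: int = 150,
    de_options: dict | None = None,
) -> CorefinementResult:
    """Generate the with-protein condition (insertion model M3) at three
    contrasts and refit the full 14-parameter model."""
    sc = scenario(scenario_name, noise_fraction=noise_fraction, n_q=n_q)
    data = gen_nr(sc, seed=seed)
    vary = list(
        SUBSTRATE_PARAMS
        + BILAYER_PARAMS
        + protein_param_names(sc.insertion_model)
    )
    return corefine(
        data,
        model=sc.insertion_model,
        lipid=sc.lipid,
        vary=vary,
        seed=seed,
        de_options=de_options,
    )


def model_selection_replicates(
    n_replicates: int = 20,
    seed: int = 0,
    noise_fraction: float = 0.03,
    n_q: int = 40,
    de_options: dict | None = None,
) -> tuple[list[InsertionModel], list[ModelRanking]]:
    """Repeat the insertion-model comparison on independent noise draws.

    Data are generated under M3 (hydrogenated with-protein truth); for each
    replicate all four candidate models are fitted from identical midpoint
    starting conditions with the substrate pinned at the protein-free
    values (as carried over from a bilayer-alone fit in practice) and
    bilayer + protein parameters floating.  Returns the winning model per
    replicate and the full rankings.
    """
    sc = scenario(
        "with-rmbp-h-M3", noise_fraction=noise_fraction, n_q=n_q
    )
    fix = {
        "oxide_thickness": sc.substrate.oxide_thickness,
        "oxide_coverage": sc.substrate.oxide_coverage,
        "oxide_roughness": sc.substrate.oxide_roughness,
        "hydration_thickness": sc.substrate.hydration_layer_thickness,
    }
    de_options = de_options or dict(popsize=6, maxiter=40, tol=0.02)
    winners = []
    rankings = []
    for i in range(n_replicates):
        rep_seed = (seed * 10007 + i) % (2**31 - 1)
        data = gen_nr(sc, seed=rep_seed)
        ranking = select_model(
            data,
            lipid=sc.lipid,
            fix=fix,
            seed=rep_seed,
            de_options=de_options,
        )
        winners.append(ranking.best)
        rankings.append(ranking)
    return winners, rankings


def bootstrap_coverage(
    n_outer: int = 50,
    n_resamples: int = 29,
    seed: int = 0,
    noise_fraction: float = 0.03,
    n_q: int = 60,
    vary: tuple[str, ...] = ("apm",),
    param: str = "apm",
) -> float:
    """Empirical coverage of the central-68% bootstrap interval.

    Nested Monte Carlo: ``n_outer`` independent noisy datasets are drawn
    from a fixed truth, each is fitted (local refinement of the floating
    parameters from truth-neighbouring starting values) and bootstrapped,
    and the fraction of intervals containing the generating truth is
    returned.  Under a well-calibrated interval this fraction should sit
    near 0.68.
    """
    sc = scenario(
        "bilayer-alone-h", noise_fraction=noise_fraction, n_q=n_q
    )
    truth = {
        "oxide_thickness": sc.substrate.oxide_thickness,
        "oxide_coverage": sc.substrate.oxide_coverage,
        "oxide_roughness": sc.substrate.oxide_roughness,
        "hydration_thickness": sc.substrate.hydration_layer_thickness,
        "apm": sc.bilayer.apm,
        "waters_per_head": sc.bilayer.waters_per_head,
        "waters_per_tail": sc.bilayer.waters_per_tail,
        "global_roughness": sc.bilayer.global_roughness,
        "inner_roughness": sc.bilayer.local_inner_roughness,
        "outer_roughness": sc.bilayer.local_outer_roughness,
    }
    fix = {k: v for k, v in truth.items() if k not in vary}
    true_value = truth[param]

    hits = 0
    for i in range(n_outer):
        rep_seed = (seed * 20011 + i) % (2**31 - 1)
        data = gen_nr(sc, seed=rep_seed)
        res = corefine(
            data,
            lipid=sc.lipid,
            vary=list(vary),
            fix=fix,
            seed=rep_seed,
            global_stage=False,
        )
        intervals = bootstrap(res, n_resamples=n_resamples, seed=rep_seed)
        lo, hi = intervals[param]
        if lo <= true_value <= hi:
            hits += 1
    return hits / n_outer
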