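"""Synthetic measurement generators for the whole pipeline.

Every input the analysis stages consume can be generated here with the
statistical structure the analyses assume, so the package is exercisable
end-to-end without instrument data:

* three-contrast specular reflectivity of a supported DMPC:DMPG bilayer on
  silicon, with or without a bound protein layer, resolution-smeared and
  carrying per-point uncertainty and resolution columns;
* dose-response titrations and one-phase association sensorgrams mimicking
  an SPR lipid-capture experiment;
* a 1-D small-angle diffraction curve with a lamellar Bragg peak on a
  power-law background.

All generators are pure functions of (scenario, seed).  Default noise for
reflectivity is 3% fractional Gaussian with a 1e-7 floor on the quoted
sigma — counting statistics are instrument-specific, and this level keeps
parameter recovery discriminating without being trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binding import Sensorgram, dose_response
from .materials import SolventContrast
from .reflectivity import NRDataset, smeared_reflectivity
from .slabs import (
    BilayerParams,
    D54_DMPC_DMPG_11,
    DMPC_DMPG_11,
    InsertionModel,
    Lipid,
    ProteinParams,
    SubstrateParams,
    build_stack,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Contrast scheme of the reflectometry design: ~95% D2O, silicon-matched
#: water (38:62 D2O:H2O), and pure H2O.
DEFAULT_CONTRASTS = (0.95, 0.38, 0.0)


@dataclass(frozen=True)
class NRScenario:
    """Truth parameters and measurement design for synthetic reflectivity."""

    substrate: SubstrateParams = SubstrateParams()
    bilayer: BilayerParams = BilayerParams()
    protein: ProteinParams | None = None
    insertion_model: InsertionModel | None = None
    lipid: Lipid = DMPC_DMPG_11
    contrasts: tuple = DEFAULT_CONTRASTS
    q_min: float = 0.008
    q_max: float = 0.3
    n_q: int = 150
    dq_over_q: float = 0.05  # FWHM fractional resolution
    noise_fraction: float = 0.03
    sigma_R_floor: float = 1e-7
    labile_fraction_exchanged: float = 0.9

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")

    def stack(self, contrast: SolventContrast):
        return build_stack(
            self.substrate,
            self.bilayer,
            self.lipid,
            contrast,
            protein=self.protein,
            model=self.insertion_model,
            labile_fraction_exchanged=self.labile_fraction_exchanged,
        )


#: Truth parameter sets for the three canonical measurement conditions of a
#: DMPC:DMPG (1:1) bilayer on silicon: the hydrogenated bilayer alone, the
#: hydrogenated bilayer with protein fully inserted in the outer leaflet
#: (model M3), and the tail-perdeuterated analogue of the latter.
NAMED_SCENARIOS: dict[str, NRScenario] = {
    "bilayer-alone-h": NRScenario(
        substrate=SubstrateParams(14.0, 0.75, 3.0, 5.0),
        bilayer=BilayerParams(60.0, 3.0, 4.0, 5.0, 3.0, 0.0),
        lipid=DMPC_DMPG_11,
    ),
    "with-rmbp-h-M3": NRScenario(
        substrate=SubstrateParams(14.0, 0.75, 3.0, 5.0),
        bilayer=BilayerParams(45.0, 10.0, 17.0, 8.0, 4.0, 11.0),
        protein=ProteinParams(84.0, 0.26, 3.0, 0.39),
        insertion_model=InsertionModel.M3,
        lipid=DMPC_DMPG_11,
    ),
    "with-rmbp-d-M3": NRScenario(
        substrate=SubstrateParams(10.0, 0.90, 3.0, 25.0),
        bilayer=BilayerParams(52.0, 10.0, 17.0, 22.0, 5.0, 0.0),
        protein=ProteinParams(75.0, 0.23, 10.0, 0.44),
        insertion_model=InsertionModel.M3,
        lipid=D54_DMPC_DMPG_11,
    ),
}


def gen_nr(scenario: NRScenario, seed: int = 0) -> list[NRDataset]:
    """Generate one resolution-smeared, noisy reflectivity dataset per
    contrast in the scenario.

    The noise model is multiplicative Gaussian: R_obs = R (1 + f eps),
    eps ~ N(0, 1), with the quoted sigma_R = max(f R, floor).  Zero noise
    returns the forward model exactly (sigma columns keep the same form so
    downstream fits remain defined).
    """
    q = np.logspace(
        np.log10(scenario.q_min), np.log10(scenario.q_max), scenario.n_q
    )
    sigma_q = scenario.dq_over_q * q * FWHM_TO_SIGMA
    rng = np.random.default_rng(seed)
    datasets = []
    for f in scenario.contrasts:
        contrast = SolventContrast(f)
        stack = scenario.stack(contrast)
        R = smeared_reflectivity(q, stack, sigma_q)
        sigma_R = np.maximum(
            scenario.noise_fraction * R, scenario.sigma_R_floor
        )
        if scenario.noise_fraction > 0:
            R_obs = R * (
                1.0 + scenario.noise_fraction * rng.standard_normal(q.size)
            )
            R_obs = np.clip(R_obs, 0.0, None)
        else:
            R_obs = R
        datasets.append(
            NRDataset(
                q=q,
                R=R_obs,
                sigma_R=sigma_R,
                sigma_q=sigma_q,
                contrast=contrast,
                label=f"fD2O={f:.2f}",
            )
        )
    return datasets


@dataclass(frozen=True)
class SPRScenario:
    """Truth parameters for synthetic dose-response and kinetics data.

    Default dose-response truth is the saturated lipid-capture titration
    (R_hi 7624 RU, R_lo 85.57 RU, A1 455.5 nM, A2 3.061); kinetic truth
    follows a pseudo-first-order scheme k_obs = k_on c + k_off with slow
    dissociation, consistent with effectively irreversible binding.
    """

    R_hi: float = 7624.0
    R_lo: float = 85.57
    A1: float = 455.5
    A2: float = 3.061
    conc_min: float = 20.0  # nM
    conc_max: float = 2000.0
    n_concentrations: int = 12
    replicates: int = 2
    response_noise: float = 50.0  # RU, additive
    k_on: float = 1.0e-4  # nM⁻¹ s⁻¹
    k_off: float = 1.0e-3  # s⁻¹
    window: float = 180.0  # s of association phase
    #: extra seconds of buffer wash after the association phase; the
    #: response stays flat there (effectively irreversible binding)
    dissociation_window: float = 0.0
    dt: float = 1.0
    sensorgram_noise: float = 10.0  # RU
    #: bias multiplier applied to k_obs below 500 nM; 1.0 disables the
    #: two-regime behaviour that distinguishes the two fitting sets
    low_conc_bias: float = 1.0


def gen_spr(
    scenario: SPRScenario, seed: int = 0
) -> tuple[pd.DataFrame, list[Sensorgram]]:
    """Generate a titration table and per-concentration sensorgrams.

    The titration is sampled in duplicate (per ``replicates``) at
    log-spaced concentrations; sensorgrams follow one-phase association
    with k_obs = k_on c + k_off (optionally biased below 500 nM to emulate
    the deviation from pseudo-first-order behaviour seen at low surface
    saturation).
    """
    rng = np.random.default_rng(seed)
    concs = np.logspace(
        np.log10(scenario.conc_min),
        np.log10(scenario.conc_max),
        scenario.n_concentrations,
    )
    rows = []
    for c in concs:
        r_true = dose_response(
            c, scenario.R_hi, scenario.R_lo, scenario.A1, scenario.A2
        )
        for rep in range(scenario.replicates):
            noise = (
                rng.normal(0.0, scenario.response_noise)
                if scenario.response_noise > 0
                else 0.0
            )
            rows.append(
                {"concentration": c, "response": r_true + noise, "replicate": rep}
            )
    titration = pd.DataFrame(rows)

    t = np.arange(
        0.0,
        scenario.window + scenario.dissociation_window + scenario.dt,
        scenario.dt,
    )
    sensorgrams = []
    for c in concs:
        k_obs = scenario.k_on * c + scenario.k_off
        if c < 500.0:
            k_obs *= scenario.low_conc_bias
        plateau = dose_response(
            c, scenario.R_hi, scenario.R_lo, scenario.A1, scenario.A2
        )
        y = plateau * (1.0 - np.exp(-k_obs * np.minimum(t, scenario.window)))
        if scenario.sensorgram_noise > 0:
            y = y + rng.normal(0.0, scenario.sensorgram_noise, t.size)
        sensorgrams.append(Sensorgram(time=t, response=y, concentration=c))
    return titration, sensorgrams


@dataclass(frozen=True)
class SAXDScenario:
    """Truth parameters for a lamellar diffraction curve.

    Defaults place the first-order Bragg peak at the 80 Å repeat of a
    protein-stacked DMPC:DMPG multilayer, on a power-law (s^-2) vesicle
    background, with an optional weak second order at twice the position.
    """

    d_spacing: float = 80.0  # Å
    peak_width: float = 0.004  # Gaussian sigma, Å⁻¹
    peak_amplitude: float = 30.0
    second_order_amplitude: float = 0.0
    background_amplitude: float = 0.01
    background_exponent: float = 2.0
    background_constant: float = 1.0
    noise_scale: float = 0.05  # Poisson-like: sigma = scale * sqrt(I)
    s_min: float = 0.02
    s_max: float = 0.25
    n_points: int = 400

    def __post_init__(self) -> None:
        if self.d_spacing <= 0:
            raise ValueError("d_spacing must be > 0")


def gen_saxd(scenario: SAXDScenario, seed: int = 0) -> pd.DataFrame:
    """Generate an (s, I) diffraction curve with a lamellar peak.

    Zero ``peak_amplitude`` produces the protein-free control: background
    only, for which peak detection must return the no-peak verdict.
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(scenario.s_min, scenario.s_max, scenario.n_points)
    s0 = 2.0 * np.pi / scenario.d_spacing
    intensity = (
        scenario.background_amplitude * s ** (-scenario.background_exponent)
        + scenario.background_constant
    )
    intensity = intensity + scenario.peak_amplitude * np.exp(
        -0.5 * ((s - s0) / scenario.peak_width) ** 2
    )
    if scenario.second_order_amplitude > 0:
        intensity = intensity + scenario.second_order_amplitude * np.exp(
            -0.5 * ((s - 2 * s0) / scenario.peak_width) ** 2
        )
    if scenario.noise_scale > 0:
        intensity = intensity + rng.normal(
            0.0, scenario.noise_scale * np.sqrt(np.abs(intensity))
        )
    return pd.DataFrame({"s": s, "I": intensity})


@dataclass(frozen=True)
class ScenarioConfig:
    """Bundle of truth configurations for a full synthetic study."""

    nr: NRScenario = field(default_factory=lambda: NAMED_SCENARIOS["bilayer-alone-h"])
    spr: SPRScenario = SPRScenario()
    saxd: SAXDScenario = SAXDScenario()
    seed: int = 0

    def generate(self):
        return {
            "nr": gen_nr(self.nr, self.seed),
            "spr": gen_spr(self.spr, self.seed + 1),
            "saxd": gen_saxd(self.saxd, self.seed + 2),
        }


def scenario(name: str, **overrides) -> NRScenario:
    """Fetch a named reflectivity scenario, optionally overriding fields."""
    base = NAMED_SCENARIOS[name]
    return replace(base, **overrides) if overrides else base
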