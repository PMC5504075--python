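"""Scattering-length-density bookkeeping for neutron contrast variation.

Every interfacial layer in a specular neutron reflectometry model is
characterised by its coherent scattering length density (SLD),

    rho = sum_i b_i / V   [Å⁻²],

the sum of bound coherent scattering lengths of the atoms in a molecular
unit divided by the volume that unit occupies.  Because hydrogen
(b = −3.74 fm) and deuterium (b = +6.67 fm) differ so strongly, the SLD of
any hydrogen-containing component depends on the D2O fraction of the
solvent, both through direct solvent mixing and through exchange of labile
(O–H, N–H) hydrogens.  This module holds the material constants and the
mixing rules used by the slab model.

Units: scattering lengths in femtometres (1 fm = 1e-5 Å), molecular volumes
in Å³, SLDs in Å⁻² (so typical values are a few 1e-6).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import yaml

FM_TO_ANG = 1.0e-5  # 1 fm expressed in Å

#: Bound coherent scattering lengths, fm (Sears neutron data tables).
COHERENT_B = {
    "H": -3.7390,
    "D": 6.6710,
    "C": 6.6460,
    "N": 9.3600,
    "O": 5.8030,
    "P": 5.1300,
    "Si": 4.1491,
    "Na": 3.6300,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple molecular formula such as ``'C10H18NO8P'``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in COHERENT_B:
            raise ValueError(f"unknown element {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_scattering_length(formula: str) -> float:
    """Summed bound coherent scattering length of a formula, in fm."""
    return sum(COHERENT_B[el] * n for el, n in parse_formula(formula).items())


class InvalidMaterialError(ValueError):
    """Raised for materials that cannot yield a finite SLD."""


@dataclass(frozen=True)
class Material:
    """A chemical species with a coherent scattering length and a volume.

    Parameters
    ----------
    name : str
        Label used in registries and reports.
    scattering_length : float
        Sum of bound coherent scattering lengths over the formula unit, fm.
    molecular_volume : float
        Volume of the formula unit, Å³.  Must be positive.
    labile_H : int
        Number of hydrogens that exchange with solvent (O–H, N–H).  In a
        D2O-containing solvent a fraction of these carry the deuterium
        scattering length instead of the hydrogen one.
    total_H : int or None
        Total hydrogen count, if known; used only to validate ``labile_H``.
    """

    name: str
    scattering_length: float
    molecular_volume: float
    labile_H: int = 0
    total_H: int | None = None

    def __post_init__(self) -> None:
        if not self.molecular_volume > 0:
            raise InvalidMaterialError(
                f"{self.name}: molecular_volume must be > 0, "
                f"got {self.molecular_volume}"
            )
        if self.labile_H < 0:
            raise InvalidMaterialError(f"{self.name}: labile_H must be >= 0")
        if self.total_H is not None and self.labile_H > self.total_H:
            raise InvalidMaterialError(
                f"{self.name}: labile_H ({self.labile_H}) exceeds total H "
                f"count ({self.total_H})"
            )

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: str,
        molecular_volume: float,
        labile_H: int = 0,
    ) -> "Material":
        counts = parse_formula(formula)
        return cls(
            name=name,
            scattering_length=sum(
                COHERENT_B[el] * n for el, n in counts.items()
            ),
            molecular_volume=molecular_volume,
            labile_H=labile_H,
            total_H=counts.get("H", 0) + counts.get("D", 0),
        )

    @property
    def sld(self) -> float:
        """SLD of the material with all labile H protonated, Å⁻²."""
        return self.scattering_length * FM_TO_ANG / self.molecular_volume

    def sld_at(
        self, contrast: "SolventContrast", exchange_fraction: float = 1.0
    ) -> float:
        """SLD after labile-H exchange with a D2O/H2O solvent.

        Each labile hydrogen is replaced by deuterium with probability
        ``f_D2O * exchange_fraction`` (ideal exchange with the solvent's
        deuterium pool).
        """
        if not 0.0 <= exchange_fraction <= 1.0:
            raise ValueError("exchange_fraction must lie in [0, 1]")
        extra = (
            self.labile_H
            * contrast.f_D2O
            * exchange_fraction
            * (COHERENT_B["D"] - COHERENT_B["H"])
        )
        return (
            (self.scattering_length + extra)
            * FM_TO_ANG
            / self.molecular_volume
        )


# -- built-in materials ------------------------------------------------------
# Volumes: water 29.9 Å³ (H2O) / 30.1 Å³ (D2O, slightly larger molar volume);
# crystalline Si 20.0 Å³ per atom; amorphous SiO2 at density 2.2 g/cm³;
# PC headgroup (phosphocholine + glycerol backbone + carbonyls) 320 Å³ and
# PG headgroup 289 Å³; a pair of myristoyl (C14) chains 720 Å³.  Head/tail
# volumes are literature values for fluid-phase lipids and are configurable.

WATER = Material.from_formula("H2O", "H2O", 29.9)
HEAVY_WATER = Material.from_formula("D2O", "D2O", 30.1)
SILICON = Material("Si", COHERENT_B["Si"], 20.0)
SILICON_OXIDE = Material.from_formula("SiO2", "SiO2", 45.4)

#: PC headgroup: C10H18NO8P, no exchangeable H.
PC_HEAD = Material.from_formula("PC-head", "C10H18NO8P", 320.0)
#: PG headgroup: C8H12O10P with the two glycerol hydroxyls exchangeable.
PG_HEAD = Material.from_formula("PG-head", "C8H12O10P", 289.0, labile_H=2)
#: Two hydrogenated myristoyl chains (2 × C13H27).
DM_TAILS = Material.from_formula("C14-tails", "C26H54", 720.0)
#: Tail-perdeuterated (d54) myristoyl chains: the 54 tail H become D.
DM_TAILS_D54 = Material.from_formula("d54-C14-tails", "C26D54", 720.0)

SLD_H2O = WATER.sld
SLD_D2O = HEAVY_WATER.sld
SLD_SI = SILICON.sld
SLD_SIO2 = SILICON_OXIDE.sld

#: Hydrogenated-protein SLD in pure H2O and in pure D2O with all labile
#: hydrogens exchanged.  Sequence-specific values would shift these by a few
#: percent; they are exposed in the materials registry for that reason.
PROTEIN_SLD_H2O = 1.8e-6
PROTEIN_SLD_D2O = 3.1e-6


@dataclass(frozen=True)
class SolventContrast:
    """A D2O/H2O mixture identified by its D2O volume fraction."""

    f_D2O: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_D2O <= 1.0:
            raise ValueError(
                f"f_D2O must lie in [0, 1], got {self.f_D2O}"
            )

    @property
    def sld(self) -> float:
        return solvent_sld(self.f_D2O)


def component_sld(material: Material) -> float:
    """SLD of a material, Å⁻² (``scattering_length / molecular_volume``)."""
    return material.sld


def solvent_sld(f_D2O: float) -> float:
    """SLD of a D2O/H2O mixture by linear volume-fraction mixing."""
    if not 0.0 <= f_D2O <= 1.0:
        raise ValueError(f"f_D2O must lie in [0, 1], got {f_D2O}")
    return f_D2O * SLD_D2O + (1.0 - f_D2O) * SLD_H2O


class NoMatchError(ValueError):
    """Raised when a target SLD is outside the water contrast range."""


def contrast_match_fraction(target_sld: float) -> float:
    """D2O volume fraction whose solvent SLD equals ``target_sld``.

    Exact inverse of :func:`solvent_sld`; e.g. matching crystalline silicon
    gives the classic silicon-matched water at 38% D2O.
    """
    lo, hi = min(SLD_H2O, SLD_D2O), max(SLD_H2O, SLD_D2O)
    if not lo <= target_sld <= hi:
        raise NoMatchError(
            f"target SLD {target_sld:.3e} outside water range "
            f"[{lo:.3e}, {hi:.3e}]"
        )
    return (target_sld - SLD_H2O) / (SLD_D2O - SLD_H2O)


def protein_sld(
    f_D2O: float,
    labile_fraction_exchanged: float = 0.9,
    sld_h2o: float = PROTEIN_SLD_H2O,
    sld_d2o: float = PROTEIN_SLD_D2O,
) -> float:
    """Protein SLD in a given solvent contrast.

    Interpolates between the protein-in-H2O SLD and the fully exchanged
    protein-in-D2O SLD in proportion to the solvent deuterium fraction and
    the fraction of labile sites that actually exchange (buried amides do
    not; 0.9 is a common working default).
    """
    if not 0.0 <= f_D2O <= 1.0:
        raise ValueError("f_D2O must lie in [0, 1]")
    if not 0.0 <= labile_fraction_exchanged <= 1.0:
        raise ValueError("labile_fraction_exchanged must lie in [0, 1]")
    return sld_h2o + f_D2O * labile_fraction_exchanged * (sld_d2o - sld_h2o)


def mix_sld(slds, volume_fractions) -> float:
    """Volume-fraction weighted SLD of a composite (additivity rule)."""
    total = sum(volume_fractions)
    if not abs(total - 1.0) < 1e-9:
        raise ValueError(f"volume fractions must sum to 1, got {total}")
    return sum(s * f for s, f in zip(slds, volume_fractions))


# -- registry ----------------------------------------------------------------

DEFAULT_MATERIALS: dict[str, Material] = {
    m.name: m
    for m in (
        WATER,
        HEAVY_WATER,
        SILICON,
        SILICON_OXIDE,
        PC_HEAD,
        PG_HEAD,
        DM_TAILS,
        DM_TAILS_D54,
    )
}


def load_materials(path) -> dict[str, Material]:
    """Load a materials registry from YAML.

    Each entry maps a name to ``{formula: ... | b: <fm>, volume: <Å³>,
    labile_H: <int>}``.  Entries override the built-in registry.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    registry = dict(DEFAULT_MATERIALS)
    for name, entry in raw.items():
        volume = float(entry["volume"])
        if "formula" in entry:
            mat = Material.from_formula(
                name, entry["formula"], volume, int(entry.get("labile_H", 0))
            )
        else:
            mat = Material(
                name, float(entry["b"]), volume, int(entry.get("labile_H", 0))
            )
        registry[name] = mat
    return registry
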