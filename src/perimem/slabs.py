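"""Interfacial slab stacks for a supported lipid bilayer with bound protein.

The interface is described front-to-back as

    Si | oxide | hydration water | inner heads | inner tails |
       outer tails | outer heads | [protein layer] | bulk solvent,

each slab carrying a thickness, an SLD, a roughness for its front (substrate
side) interface and an explicit per-component volume bookkeeping.  The
bilayer itself is parameterised physically rather than as free slabs: the
area per lipid molecule (APM) and the head/tail molecular volumes fix the
slab thicknesses,

    t_head = (V_head + n_head * V_water) / APM
    t_tail = (V_tail + n_tail * V_water) / APM   (per leaflet),

where ``n_head``/``n_tail`` are the numbers of water molecules housed with
each lipid headgroup and tail region.  Slab SLDs follow from the volume
fractions of lipid moiety, water and protein.  Hydration water exchanges
with the bulk, so it scatters with the solvent SLD.

Four competing insertion hypotheses for a peripheral protein are encoded as
models M1–M4: a surface layer only (M1); a surface layer plus penetration of
the outer headgroups displacing their water (M2); a surface layer plus full
insertion into the outer leaflet displacing lipid (M3); and insertion into
both leaflets (M4).  M2–M4 reduce exactly to M1 when their insertion
fractions are zero.

Roughness rule: a single "global" roughness applies to every bilayer
interface; separate "local" inner and outer roughnesses add in quadrature at
the inner head/hydration and outer head/solvent (or head/protein) interfaces.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .materials import (
    Material,
    SolventContrast,
    PC_HEAD,
    PG_HEAD,
    DM_TAILS,
    DM_TAILS_D54,
    SILICON_OXIDE,
    SLD_SI,
    WATER,
    protein_sld,
)

VOLUME_TOL = 1e-9


class InfeasibleModelError(ValueError):
    """Raised when an insertion model requests more lipid displacement than
    the leaflet contains."""


@dataclass(frozen=True)
class SubstrateParams:
    """Silicon oxide + interfacial hydration layer parameters (Å, fractions)."""

    oxide_thickness: float = 14.0
    oxide_coverage: float = 0.75
    oxide_roughness: float = 3.0
    hydration_layer_thickness: float = 5.0

    def __post_init__(self) -> None:
        if self.oxide_thickness < 0 or self.hydration_layer_thickness < 0:
            raise ValueError("thicknesses must be >= 0")
        if not 0.0 <= self.oxide_coverage <= 1.0:
            raise ValueError("oxide_coverage must lie in [0, 1]")
        if self.oxide_roughness < 0:
            raise ValueError("roughness must be >= 0")


@dataclass(frozen=True)
class BilayerParams:
    """Five-parameter bilayer description plus roughnesses.

    apm : area per lipid molecule, Å².
    waters_per_head / waters_per_tail : water molecules housed with each
        lipid headgroup / tail region.
    global_roughness : applied to every bilayer interface, Å.
    local_inner_roughness / local_outer_roughness : added in quadrature at
        the inner and outer head/solvent interfaces, Å.
    """

    apm: float = 60.0
    waters_per_head: float = 3.0
    waters_per_tail: float = 4.0
    global_roughness: float = 5.0
    local_inner_roughness: float = 3.0
    local_outer_roughness: float = 0.0

    def __post_init__(self) -> None:
        if not self.apm > 0:
            raise ValueError(f"apm must be > 0, got {self.apm}")
        if self.waters_per_head < 0 or self.waters_per_tail < 0:
            raise ValueError("water counts must be >= 0")
        if min(
            self.global_roughness,
            self.local_inner_roughness,
            self.local_outer_roughness,
        ) < 0:
            raise ValueError("roughnesses must be >= 0")


@dataclass(frozen=True)
class ProteinParams:
    """Peripheral protein layer and insertion parameters."""

    layer_thickness: float = 84.0
    layer_coverage: float = 0.26
    layer_roughness: float = 3.0
    fraction_in_outer_leaflet: float = 0.39
    fraction_in_inner_leaflet: float = 0.0

    def __post_init__(self) -> None:
        if self.layer_thickness < 0:
            raise ValueError("layer_thickness must be >= 0")
        for name in (
            "layer_coverage",
            "fraction_in_outer_leaflet",
            "fraction_in_inner_leaflet",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.layer_roughness < 0:
            raise ValueError("layer_roughness must be >= 0")


class InsertionModel(enum.Enum):
    """The four insertion hypotheses for the membrane-bound protein."""

    M1 = "surface layer only"
    M2 = "surface layer + outer headgroup penetration"
    M3 = "surface layer + full outer leaflet insertion"
    M4 = "surface layer + insertion into both leaflets"

    @property
    def n_protein_params(self) -> int:
        """Number of free protein parameters the model introduces."""
        return {"M1": 3, "M2": 4, "M3": 4, "M4": 5}[self.name]


@dataclass(frozen=True)
class Lipid:
    """A lipid split into a headgroup and a tail-region material."""

    name: str
    head: Material
    tail: Material


DMPC = Lipid("DMPC", PC_HEAD, DM_TAILS)
DMPG = Lipid("DMPG", PG_HEAD, DM_TAILS)
D54_DMPC = Lipid("d54-DMPC", PC_HEAD, DM_TAILS_D54)
D54_DMPG = Lipid("d54-DMPG", PG_HEAD, DM_TAILS_D54)


def mix_lipids(lipids, mole_fractions, name="mix") -> Lipid:
    """Mole-fraction average of several lipids into one effective species.

    The bilayer model fits a single APM, so a 1:1 mixture is treated as one
    lipid with averaged head/tail scattering lengths and volumes.
    """
    fracs = np.asarray(mole_fractions, dtype=float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("mole fractions must sum to 1")

    def _avg(parts):
        return Material(
            name=f"{name}-{parts[0].name}",
            scattering_length=float(
                sum(f * p.scattering_length for f, p in zip(fracs, parts))
            ),
            molecular_volume=float(
                sum(f * p.molecular_volume for f, p in zip(fracs, parts))
            ),
            labile_H=float(sum(f * p.labile_H for f, p in zip(fracs, parts))),
        )

    return Lipid(
        name,
        _avg([lp.head for lp in lipids]),
        _avg([lp.tail for lp in lipids]),
    )


DMPC_DMPG_11 = mix_lipids([DMPC, DMPG], [0.5, 0.5], name="DMPC:DMPG(1:1)")
D54_DMPC_DMPG_11 = mix_lipids(
    [D54_DMPC, D54_DMPG], [0.5, 0.5], name="d54-DMPC:d54-DMPG(1:1)"
)


@dataclass(frozen=True)
class Slab:
    """One homogeneous layer.

    ``roughness`` is the r.m.s. roughness of the slab's *front* interface
    (towards the substrate).  ``fractions`` records the volume bookkeeping
    (lipid_head / lipid_tail / water / protein / solvent) which must sum
    to one.
    """

    thickness: float
    sld: float
    roughness: float = 0.0
    name: str = ""
    fractions: dict = field(default_factory=lambda: {"solvent": 1.0})

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"slab {self.name}: thickness must be >= 0")
        if self.roughness < 0:
            raise ValueError(f"slab {self.name}: roughness must be >= 0")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > VOLUME_TOL:
            raise ValueError(
                f"slab {self.name}: component volume fractions sum to "
                f"{total!r}, not 1"
            )
        if any(f < -VOLUME_TOL for f in self.fractions.values()):
            raise ValueError(
                f"slab {self.name}: negative component fraction in "
                f"{self.fractions}"
            )

    @property
    def solvent_fraction(self) -> float:
        return self.fractions.get("solvent", 0.0)


@dataclass(frozen=True)
class SlabStack:
    """Ordered slabs between a semi-infinite fronting and backing medium."""

    slabs: tuple
    fronting_sld: float = SLD_SI
    backing_sld: float = 0.0
    backing_roughness: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "slabs", tuple(self.slabs))

    @property
    def total_thickness(self) -> float:
        return sum(s.thickness for s in self.slabs)

    def slds(self) -> np.ndarray:
        """SLD of every medium, fronting to backing."""
        return np.array(
            [self.fronting_sld]
            + [s.sld for s in self.slabs]
            + [self.backing_sld]
        )

    def thicknesses(self) -> np.ndarray:
        return np.array([s.thickness for s in self.slabs])

    def roughnesses(self) -> np.ndarray:
        """Roughness of each interface, front interface of slab i first."""
        return np.array(
            [s.roughness for s in self.slabs] + [self.backing_roughness]
        )


def _quad(a: float, b: float) -> float:
    return float(np.hypot(a, b))


def _mixed_slab(name, thickness, roughness, fractions, slds) -> Slab:
    """Slab whose SLD is the volume-fraction weighted mean of components."""
    sld = sum(fractions[k] * slds[k] for k in fractions)
    return Slab(
        thickness=thickness,
        sld=sld,
        roughness=roughness,
        name=name,
        fractions=dict(fractions),
    )


def build_substrate(
    sub: SubstrateParams,
    solvent: SolventContrast,
    oxide: Material = SILICON_OXIDE,
) -> list[Slab]:
    """Oxide slab (coverage-weighted SiO2/solvent mix) + pure-solvent
    hydration slab.  A zero-thickness hydration layer is omitted."""
    slabs = [
        _mixed_slab(
            "oxide",
            sub.oxide_thickness,
            sub.oxide_roughness,
            {"oxide": sub.oxide_coverage, "solvent": 1 - sub.oxide_coverage},
            {"oxide": oxide.sld, "solvent": solvent.sld},
        )
    ]
    if sub.hydration_layer_thickness > 0:
        slabs.append(
            Slab(
                thickness=sub.hydration_layer_thickness,
                sld=solvent.sld,
                roughness=sub.oxide_roughness,
                name="hydration",
                fractions={"solvent": 1.0},
            )
        )
    return slabs


def build_bilayer(
    bp: BilayerParams,
    lipid: Lipid,
    solvent: SolventContrast,
    water: Material = WATER,
) -> list[Slab]:
    """Four bilayer slabs: inner heads, inner tails, outer tails, outer heads.

    Water housed in the slabs exchanges freely with the bulk, so it is
    booked as 'water' but scatters with the solvent SLD.
    """
    v_w = water.molecular_volume
    v_head = lipid.head.molecular_volume
    v_tail = lipid.tail.molecular_volume

    t_head = (v_head + bp.waters_per_head * v_w) / bp.apm
    t_tail = (v_tail + bp.waters_per_tail * v_w) / bp.apm

    phi_head = v_head / (v_head + bp.waters_per_head * v_w)
    phi_tail = v_tail / (v_tail + bp.waters_per_tail * v_w)

    sld_head = lipid.head.sld_at(solvent)
    sld_tail = lipid.tail.sld_at(solvent)
    slds = {
        "lipid_head": sld_head,
        "lipid_tail": sld_tail,
        "water": solvent.sld,
    }

    g = bp.global_roughness
    inner_rough = _quad(g, bp.local_inner_roughness)
    return [
        _mixed_slab(
            "inner-heads",
            t_head,
            inner_rough,
            {"lipid_head": phi_head, "water": 1 - phi_head},
            slds,
        ),
        _mixed_slab(
            "inner-tails",
            t_tail,
            g,
            {"lipid_tail": phi_tail, "water": 1 - phi_tail},
            slds,
        ),
        _mixed_slab(
            "outer-tails",
            t_tail,
            g,
            {"lipid_tail": phi_tail, "water": 1 - phi_tail},
            slds,
        ),
        _mixed_slab(
            "outer-heads",
            t_head,
            g,
            {"lipid_head": phi_head, "water": 1 - phi_head},
            slds,
        ),
    ]


def apply_insertion(
    model: InsertionModel,
    bilayer: list[Slab],
    pp: ProteinParams,
    protein_sld_at_contrast: float,
    solvent: SolventContrast,
    bp: BilayerParams | None = None,
) -> list[Slab]:
    """Apply one of the four insertion hypotheses to a bilayer fragment.

    Returns the bilayer slabs (modified according to the model) plus the
    surface protein layer.  The surface layer has solvent fraction
    ``1 - layer_coverage`` and front-interface roughness equal to the
    global+local-outer roughness of the bilayer it sits on; its back
    (protein/solvent) interface roughness is ``layer_roughness`` and is
    applied by the stack assembler.
    """
    if len(bilayer) != 4:
        raise ValueError("bilayer fragment must have exactly 4 slabs")
    inner_heads, inner_tails, outer_tails, outer_heads = bilayer

    def rebuilt(slab: Slab, component: str, fraction: float) -> Slab:
        if fraction > 1 + VOLUME_TOL:
            raise InfeasibleModelError(
                f"requested displacement of {fraction:.2%} of {component} "
                f"in slab {slab.name!r} exceeds the available volume"
            )
        fraction = min(fraction, 1.0)
        avail = slab.fractions.get(component, 0.0)
        moved = avail * fraction
        fractions = dict(slab.fractions)
        fractions[component] = avail - moved
        fractions["protein"] = fractions.get("protein", 0.0) + moved
        sld = slab.sld + moved * (
            protein_sld_at_contrast - _component_sld(slab, component, solvent)
        )
        return replace(slab, fractions=fractions, sld=sld)

    if model is InsertionModel.M2:
        outer_heads = rebuilt(
            outer_heads, "water", pp.fraction_in_outer_leaflet
        )
    elif model is InsertionModel.M3:
        outer_tails = rebuilt(
            outer_tails, "lipid_tail", pp.fraction_in_outer_leaflet
        )
        outer_heads = rebuilt(
            outer_heads, "lipid_head", pp.fraction_in_outer_leaflet
        )
    elif model is InsertionModel.M4:
        outer_tails = rebuilt(
            outer_tails, "lipid_tail", pp.fraction_in_outer_leaflet
        )
        outer_heads = rebuilt(
            outer_heads, "lipid_head", pp.fraction_in_outer_leaflet
        )
        inner_tails = rebuilt(
            inner_tails, "lipid_tail", pp.fraction_in_inner_leaflet
        )
        inner_heads = rebuilt(
            inner_heads, "lipid_head", pp.fraction_in_inner_leaflet
        )
    elif model is not InsertionModel.M1:
        raise ValueError(f"unknown insertion model {model!r}")

    surface = _mixed_slab(
        "protein-layer",
        pp.layer_thickness,
        outer_heads.roughness if bp is None else _quad(
            bp.global_roughness, bp.local_outer_roughness
        ),
        {"protein": pp.layer_coverage, "solvent": 1 - pp.layer_coverage},
        {"protein": protein_sld_at_contrast, "solvent": solvent.sld},
    )
    return [inner_heads, inner_tails, outer_tails, outer_heads, surface]


def _component_sld(slab: Slab, component: str, solvent: SolventContrast) -> float:
    """SLD of one booked component inside a slab."""
    if component in ("water", "solvent"):
        return solvent.sld
    # lipid moiety SLD is recoverable from the mixing identity:
    # slab.sld = sum_k phi_k * sld_k with the other components known.
    known = {"water": solvent.sld, "solvent": solvent.sld}
    other = sum(
        f * known[k] for k, f in slab.fractions.items() if k in known
    )
    phi = slab.fractions.get(component, 0.0)
    if phi <= 0:
        return 0.0
    residual = slab.sld - other
    # residual may include protein already inserted; exclude it
    prot = slab.fractions.get("protein", 0.0)
    if prot > 0:
        raise ValueError("cannot displace from a slab already holding protein")
    return residual / phi


def build_stack(
    sub: SubstrateParams,
    bp: BilayerParams,
    lipid: Lipid,
    solvent: SolventContrast,
    protein: ProteinParams | None = None,
    model: InsertionModel | None = None,
    labile_fraction_exchanged: float = 0.9,
    fronting_sld: float = SLD_SI,
) -> SlabStack:
    """Assemble the full Si / oxide / hydration / bilayer [/ protein] stack."""
    slabs = build_substrate(sub, solvent)
    bilayer = build_bilayer(bp, lipid, solvent)
    # local-inner roughness acts at the hydration/inner-head interface and is
    # already set by build_bilayer on the inner-head slab front interface.
    outer_rough = _quad(bp.global_roughness, bp.local_outer_roughness)
    if protein is not None:
        if model is None:
            raise ValueError("an InsertionModel is required with protein")
        sld_p = protein_sld(solvent.f_D2O, labile_fraction_exchanged)
        fragment = apply_insertion(model, bilayer, protein, sld_p, solvent, bp)
        slabs += fragment
        backing_rough = protein.layer_roughness
    else:
        slabs += bilayer
        backing_rough = outer_rough
    return SlabStack(
        slabs=tuple(slabs),
        fronting_sld=fronting_sld,
        backing_sld=solvent.sld,
        backing_roughness=backing_rough,
    )


def sld_profile(stack: SlabStack, z: np.ndarray) -> np.ndarray:
    """Error-function-broadened SLD depth profile.

    z = 0 is the fronting/first-slab interface, positive towards the
    solvent.  Far-field values equal the fronting and backing SLDs.  A
    roughness larger than an adjacent slab thickness is physically dubious;
    the profile is still computed but a warning is issued.
    """
    z = np.asarray(z, dtype=float)
    slds = stack.slds()
    thick = stack.thicknesses()
    rough = stack.roughnesses()

    z_if = np.concatenate([[0.0], np.cumsum(thick)])
    for i, s in enumerate(stack.slabs):
        adj = [s.thickness]
        if i > 0:
            adj.append(stack.slabs[i - 1].thickness)
        if s.roughness > min(adj) and s.roughness > 0:
            warnings.warn(
                f"roughness {s.roughness:.1f} Å at interface {i} exceeds an "
                "adjacent slab thickness; profile may be unphysical",
                stacklevel=2,
            )

    profile = np.full_like(z, slds[0], dtype=float)
    for i in range(len(z_if)):
        step = slds[i + 1] - slds[i]
        sigma = rough[i]
        if sigma > 0:
            profile += step * 0.5 * (1 + erf((z - z_if[i]) / (np.sqrt(2) * sigma)))
        else:
            profile += step * (z >= z_if[i])
    return profile
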