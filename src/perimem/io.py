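"""Readers and writers for the plain-text formats the pipeline consumes.

Reflectivity files are the conventional reduced 4-column tables
(q [Å⁻¹], R, dR, dq) with ``#`` comment headers; the solvent D2O fraction
is carried in the header so a directory of files is self-describing.
Titrations, sensorgrams and diffraction curves are 2–3 column delimited
text.  Both whitespace- and comma-delimited input are accepted.
"""

from __future__ import annotations

import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .materials import SolventContrast
from .reflectivity import NRDataset
from .slabs import (
    BilayerParams,
    D54_DMPC_DMPG_11,
    DMPC_DMPG_11,
    InsertionModel,
    ProteinParams,
    SubstrateParams,
)
from .synthetic import NAMED_SCENARIOS, NRScenario

LIPID_REGISTRY = {
    "DMPC:DMPG": DMPC_DMPG_11,
    "d54-DMPC:d54-DMPG": D54_DMPC_DMPG_11,
}

_FD2O_RE = re.compile(r"f_?D2O\s*[=:]\s*([0-9.]+)", re.IGNORECASE)


def _read_table(path, n_cols_min: int) -> np.ndarray:
    """Read a delimited numeric table, accepting whitespace or commas."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[-1] else None
    data = np.genfromtxt(
        Path(path), comments="#", delimiter=delimiter, dtype=float
    )
    data = np.atleast_2d(data)
    if data.shape[1] < n_cols_min:
        raise ValueError(
            f"{path}: expected at least {n_cols_min} columns, "
            f"got {data.shape[1]}"
        )
    return data


def write_nr(dataset: NRDataset, path) -> None:
    """Write a reflectivity dataset as a 4-column text file."""
    header = (
        f"q R dR dq\n"
        f"f_D2O = {dataset.contrast.f_D2O:.4f}\n"
        f"label = {dataset.label}"
    )
    np.savetxt(
        path,
        np.column_stack(
            [dataset.q, dataset.R, dataset.sigma_R, dataset.sigma_q]
        ),
        header=header,
        fmt="%.8e",
    )


def read_nr(path, f_D2O: float | None = None, label: str = "") -> NRDataset:
    """Read a 4-column reflectivity file.

    The solvent D2O fraction is taken from an ``f_D2O = <x>`` header line
    unless given explicitly.
    """
    if f_D2O is None:
        for line in Path(path).read_text().splitlines():
            if not line.lstrip().startswith("#"):
                break
            m = _FD2O_RE.search(line)
            if m:
                f_D2O = float(m.group(1))
                break
        if f_D2O is None:
            raise ValueError(
                f"{path}: no f_D2O header line; pass f_D2O explicitly"
            )
    data = _read_table(path, 4)
    return NRDataset(
        q=data[:, 0],
        R=data[:, 1],
        sigma_R=data[:, 2],
        sigma_q=data[:, 3],
        contrast=SolventContrast(f_D2O),
        label=label or Path(path).stem,
    )


def read_titration(path) -> pd.DataFrame:
    """Read a 2-column (concentration [nM], response [RU]) titration."""
    data = _read_table(path, 2)
    return pd.DataFrame(
        {"concentration": data[:, 0], "response": data[:, 1]}
    )


def read_curve(path) -> pd.DataFrame:
    """Read a generic 2-column (x, y) curve: sensorgram or diffraction."""
    data = _read_table(path, 2)
    return pd.DataFrame({"x": data[:, 0], "y": data[:, 1]})


def write_frame(frame: pd.DataFrame, path, header: str = "") -> None:
    np.savetxt(
        path,
        frame.to_numpy(),
        header=(header or " ".join(frame.columns)),
        fmt="%.8e",
    )


# -- scenario serialisation --------------------------------------------------


def scenario_from_dict(cfg: dict) -> NRScenario:
    """Build a reflectivity scenario from a YAML-style mapping.

    Either ``scenario: <name>`` referencing a named truth set (with
    optional field overrides) or a fully explicit description with
    ``substrate``/``bilayer``/``protein``/``insertion_model``/``lipid``.
    """
    cfg = dict(cfg)
    name = cfg.pop("scenario", None)
    base = NAMED_SCENARIOS[name] if name else NRScenario()
    kwargs: dict = {}
    if "substrate" in cfg:
        kwargs["substrate"] = SubstrateParams(**cfg.pop("substrate"))
    if "bilayer" in cfg:
        kwargs["bilayer"] = BilayerParams(**cfg.pop("bilayer"))
    if "protein" in cfg:
        protein = cfg.pop("protein")
        kwargs["protein"] = (
            ProteinParams(**protein) if protein is not None else None
        )
    if "insertion_model" in cfg:
        m = cfg.pop("insertion_model")
        kwargs["insertion_model"] = (
            InsertionModel[m] if isinstance(m, str) else m
        )
    if "lipid" in cfg:
        kwargs["lipid"] = LIPID_REGISTRY[cfg.pop("lipid")]
    if "contrasts" in cfg:
        kwargs["contrasts"] = tuple(cfg.pop("contrasts"))
    for key in (
        "q_min",
        "q_max",
        "n_q",
        "dq_over_q",
        "noise_fraction",
        "sigma_R_floor",
        "labile_fraction_exchanged",
    ):
        if key in cfg:
            kwargs[key] = cfg.pop(key)
    if cfg:
        raise ValueError(f"unknown scenario keys: {sorted(cfg)}")
    from dataclasses import replace

    return replace(base, **kwargs)


def load_scenario(path) -> NRScenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh) or {})


def scenario_to_dict(sc: NRScenario) -> dict:
    out = {
        "substrate": asdict(sc.substrate),
        "bilayer": asdict(sc.bilayer),
        "protein": asdict(sc.protein) if sc.protein else None,
        "insertion_model": (
            sc.insertion_model.name if sc.insertion_model else None
        ),
        "lipid": next(
            (k for k, v in LIPID_REGISTRY.items() if v is sc.lipid),
            sc.lipid.name,
        ),
        "contrasts": list(sc.contrasts),
        "q_min": sc.q_min,
        "q_max": sc.q_max,
        "n_q": sc.n_q,
        "dq_over_q": sc.dq_over_q,
        "noise_fraction": sc.noise_fraction,
    }
    return out
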