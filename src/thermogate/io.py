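"""CSV/JSON dialects for traces, relations and model parameter sets.

CSV columns follow the conventions used at the bench: temperatures in
°C at file interfaces (kelvin in memory), currents in pA, concentrations
molar.  Model parameter JSON documents carry explicit unit annotations
and a schema version; the loader validates positivity on construction.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .dose_voltage import DoseResponse
from .gating import AllostericModel, ThermoTransition
from .noise import SweepEnsemble
from .thermo import ITRelation, PoTRelation

MODEL_SCHEMA_VERSION = 1

__all__ = [
    "read_it_csv", "write_it_csv",
    "read_pot_csv", "write_pot_csv",
    "read_dose_csv", "write_dose_csv",
    "read_sweeps_csv", "write_sweeps_csv",
    "load_model_json", "save_model_json", "load_preset",
]


def read_it_csv(path) -> ITRelation:
    """Read an I-T relation CSV: columns T_celsius, I_pA[, voltage_mV]."""
    df = pd.read_csv(path)
    v = float(df["voltage_mV"].iloc[0]) if "voltage_mV" in df else 90.0
    return ITRelation(T=celsius_to_kelvin(df["T_celsius"].to_numpy()),
                      I=df["I_pA"].to_numpy(), voltage=v,
                      condition=str(Path(path).stem))


def write_it_csv(rel: ITRelation, path) -> None:
    pd.DataFrame({
        "T_celsius": kelvin_to_celsius(rel.T),
        "I_pA": rel.I,
        "voltage_mV": rel.voltage,
    }).to_csv(path, index=False)


def read_pot_csv(path) -> PoTRelation:
    """Read a P_o-T relation CSV: columns T_celsius, Po[, sem]."""
    df = pd.read_csv(path)
    sem = df["sem"].to_numpy() if "sem" in df else None
    return PoTRelation(T=celsius_to_kelvin(df["T_celsius"].to_numpy()),
                       Po=df["Po"].to_numpy(), sem=sem,
                       condition=str(Path(path).stem))


def write_pot_csv(rel: PoTRelation, path) -> None:
    cols = {"T_celsius": kelvin_to_celsius(rel.T), "Po": rel.Po}
    if rel.sem is not None:
        cols["sem"] = rel.sem
    pd.DataFrame(cols).to_csv(path, index=False)


def read_dose_csv(path) -> DoseResponse:
    """Read a dose-response CSV: columns conc_M, response[, sem]."""
    df = pd.read_csv(path)
    sem = df["sem"].to_numpy() if "sem" in df else None
    return DoseResponse(conc=df["conc_M"].to_numpy(),
                        response=df["response"].to_numpy(), sem=sem)


def write_dose_csv(dr: DoseResponse, path) -> None:
    cols = {"conc_M": dr.conc, "response": dr.response}
    if dr.sem is not None:
        cols["sem"] = dr.sem
    pd.DataFrame(cols).to_csv(path, index=False)


def read_sweeps_csv(path, sample_interval: float | None = None
                    ) -> SweepEnsemble:
    """Read a sweep ensemble CSV: column time_s plus one column per sweep."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    sweeps = df.drop(columns=["time_s"]).to_numpy().T
    dt = sample_interval if sample_interval is not None else \
        float(np.median(np.diff(t)))
    return SweepEnsemble(sweeps=sweeps, sample_interval=dt)


def write_sweeps_csv(ens: SweepEnsemble, path) -> None:
    n = ens.sweeps.shape[1]
    cols = {"time_s": np.arange(n) * ens.sample_interval}
    for j, sw in enumerate(ens.sweeps):
        cols[f"sweep_{j:03d}"] = sw
    pd.DataFrame(cols).to_csv(path, index=False)


def _transition_to_dict(tr: ThermoTransition) -> dict:
    d = {"dH0_kcal_per_mol": tr.dH0, "dS0_kcal_per_mol_K": tr.dS0}
    if tr.dCp:
        d["dCp_kcal_per_mol_K"] = tr.dCp
        d["T0_K"] = tr.T0
    return d


def _transition_from_dict(d: dict) -> ThermoTransition:
    return ThermoTransition(dH0=d["dH0_kcal_per_mol"],
                            dS0=d["dS0_kcal_per_mol_K"],
                            dCp=d.get("dCp_kcal_per_mol_K", 0.0),
                            T0=d.get("T0_K"))


def save_model_json(model: AllostericModel, path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "L": model.L,
        "J1": _transition_to_dict(model.J1),
        "J2": _transition_to_dict(model.J2),
        "D": model.D, "E": model.E,
        "K1_prime_per_M": model.K1_prime,
        "F": model.F, "G": model.G, "H": model.H,
        "coop_exponent": model.coop_exponent,
    }
    if model.K2_prime is not None:
        doc["K2_prime_per_M"] = model.K2_prime
        doc["caps_couplings"] = {"c_L": model.c_L, "c_J1": model.c_J1,
                                 "c_J2": model.c_J2, "c_Na": model.c_Na}
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model_json(source) -> AllostericModel:
    """Load a model parameter JSON (path, str or already-parsed dict)."""
    if isinstance(source, dict):
        doc = source
    else:
        doc = json.loads(Path(source).read_text())
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    kwargs = dict(
        L=doc["L"],
        J1=_transition_from_dict(doc["J1"]),
        J2=_transition_from_dict(doc["J2"]),
        D=doc.get("D", 1.0), E=doc.get("E", 1.0),
        K1_prime=doc.get("K1_prime_per_M", 1.0),
        F=doc.get("F", 1.0), G=doc.get("G", 1.0), H=doc.get("H", 1.0),
        coop_exponent=doc.get("coop_exponent", 1.5),
    )
    if "K2_prime_per_M" in doc:
        kwargs["K2_prime"] = doc["K2_prime_per_M"]
        kwargs.update(doc.get("caps_couplings", {}))
    return AllostericModel(**kwargs)


def load_preset(name: str = "model_i_illustrative") -> AllostericModel:
    """Load a packaged illustrative parameter preset by name."""
    ref = resources.files("thermogate").joinpath(f"presets/{name}.json")
    return load_model_json(json.loads(ref.read_text()))
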