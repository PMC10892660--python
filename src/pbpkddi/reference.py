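"""Bundled reference PK tables: the printed study summaries used as evaluation inputs."""

from __future__ import annotations

import importlib.resources
import io

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    text = (importlib.resources.files("pbpkddi") / "data" / "observed" / name).read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def load_pk_parameters() -> pd.DataFrame:
    """Long-format table of observed and model-predicted PK parameter summaries."""
    return _read("pk_parameters.csv")


def load_predobs_ratios() -> pd.DataFrame:
    """Per-study predicted/observed Cmax and AUC_inf ratios with per-study MRD."""
    return _read("predobs_ratios.csv")


def load_gmfe_reference() -> pd.DataFrame:
    """Reported GMFE per species x compound x parameter."""
    return _read("gmfe_reference.csv")


def pk_value(species: str, compound: str, study: str, role: str, parameter: str) -> float:
    df = load_pk_parameters()
    row = df[
        (df.species == species)
        & (df.compound == compound)
        & (df.study == study)
        & (df.role == role)
        & (df.parameter == parameter)
    ]
    if len(row) != 1:
        raise KeyError(f"no unique reference value for {(species, compound, study, role, parameter)}")
    return float(row.value.iloc[0])
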