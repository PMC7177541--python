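"""Loaders for packaged reference data.

Everything here is small, plain-text and versioned with the package:
the Musashi-1 IDR construct, the Kyte-Doolittle hydropathy scale, a
random-coil backbone chemical-shift reference table, average residue
masses, and human-proteome-like background amino-acid frequencies.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

from .records import ProteinRecord, read_fasta

__all__ = [
    "musashi1_idr",
    "kyte_doolittle_values",
    "random_coil_table",
    "residue_masses",
    "background_frequencies",
]


def _data_path(name: str):
    return resources.files("idrkit.data").joinpath(name)


@lru_cache(maxsize=None)
def musashi1_idr() -> ProteinRecord:
    """The Musashi-1 C-terminal IDR construct (UniProt O43347, residues 194-362).

    This 169-residue region carries the eight-alanine tract (residues
    274-281) and the two transient helices (~208-218 and ~270-284) that the
    rest of the package's defaults refer to.
    """
    with resources.as_file(_data_path("musashi1_idr.fasta")) as p:
        return read_fasta(p, numbering_offset=194)[0]


@lru_cache(maxsize=None)
def kyte_doolittle_values() -> dict[str, float]:
    """Kyte-Doolittle hydropathy index per canonical residue."""
    payload = json.loads(_data_path("kyte_doolittle.json").read_text())
    return {k: float(v) for k, v in payload["values"].items()}


@lru_cache(maxsize=None)
def random_coil_table() -> pd.DataFrame:
    """Random-coil chemical-shift references, indexed by residue letter.

    Columns ``CA``, ``CB``, ``C`` in ppm; glycine CB is NaN.
    """
    with resources.as_file(_data_path("random_coil_shifts.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", na_values=["NA"])
    return df.set_index("residue")


@lru_cache(maxsize=None)
def residue_masses() -> dict[str, float]:
    """Average residue masses (Da; amino acid minus one water)."""
    with resources.as_file(_data_path("residue_masses.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return dict(zip(df["residue"], df["mass_da"].astype(float)))


@lru_cache(maxsize=None)
def background_frequencies() -> dict[str, float]:
    """Human-proteome-like background residue frequencies (normalized)."""
    with resources.as_file(_data_path("aa_frequencies.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    total = df["frequency"].sum()
    return {r: float(f) / total for r, f in zip(df["residue"], df["frequency"])}
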