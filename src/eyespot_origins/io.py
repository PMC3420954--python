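"""Delimited-text readers and writers for the pipeline's data files.

Formats are deliberately plain: a two-column character table
(``taxon<TAB>state`` with ``NA`` for missing), a four-column onset table
(``gene, compartment, stage, expression``), a three-column model-constraint
table (``model_name, node_spec, state``), and a three-column complexity
table (``species, n_genes, n_rings``).  Comment lines start with ``#``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_character",
    "write_character",
    "read_onset",
    "write_onset",
    "read_complexity",
]


def read_character(path) -> dict[str, int]:
    """Read ``taxon, state`` delimited text; ``NA``/blank means missing."""
    df = pd.read_csv(
        path, sep=None, engine="python", comment="#", header=None,
        names=["taxon", "state"], dtype={"taxon": str}, skipinitialspace=True,
    )
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        taxon = str(row["taxon"]).strip()
        state = row["state"]
        if pd.isna(state) or str(state).strip().upper() in ("NA", ""):
            continue
        state = int(float(state))
        if state not in (0, 1):
            raise ValueError(f"taxon {taxon!r}: state must be 0, 1 or NA, got {state}")
        out[taxon] = state
    if not out:
        raise ValueError(f"no scored taxa found in {path}")
    return out


def write_character(char: dict[str, int], path, all_taxa=None) -> None:
    taxa = list(all_taxa) if all_taxa is not None else sorted(char)
    with open(path, "w") as fh:
        for t in taxa:
            st = char.get(t)
            fh.write(f"{t}\t{'NA' if st is None else int(st)}\n")


ONSET_COLUMNS = ["gene", "compartment", "stage", "expression"]


def read_onset(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in ONSET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"onset table {path} lacks columns: {missing}")
    df = df[ONSET_COLUMNS].copy()
    df["stage"] = df["stage"].astype(float)
    df["expression"] = df["expression"].astype(int)
    if not np.isin(df["expression"], (0, 1)).all():
        raise ValueError("expression must be binary 0/1")
    return df


def write_onset(df: pd.DataFrame, path) -> None:
    df[ONSET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_complexity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    for col in ("species", "n_genes", "n_rings"):
        if col not in df.columns:
            raise ValueError(f"complexity table {path} lacks column {col!r}")
    return df
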