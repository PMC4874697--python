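"""Readers and writers for trees, character matrices and family tables.

Trees are Newick (branch lengths in Myr, named tips), read and written with
dendropy.  Character matrices are delimited text with a ``taxon`` column and
``c1..cK`` columns in {0, 1, NA}; NEXUS Characters blocks are also accepted.
"""

from __future__ import annotations

import os
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .likelihood import AnnotatedTree
from .trait_space import StateSpace, encode_combination

__all__ = [
    "read_tree",
    "write_tree",
    "read_char_matrix",
    "write_char_matrix",
    "annotate",
    "states_to_matrix",
    "read_family_table",
    "write_family_table",
]


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    """Read a rooted Newick tree (first tree in the file)."""
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def _read_nexus_chars(path: str) -> pd.DataFrame:
    mat = dendropy.StandardCharacterMatrix.get(path=path, schema="nexus")
    rows = {}
    n_chars = None
    for taxon in mat:
        symbols = [str(c.symbol) for c in mat[taxon]]
        n_chars = len(symbols)
        rows[taxon.label] = symbols
    cols = [f"c{i + 1}" for i in range(n_chars or 0)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df = df.replace({"?": pd.NA, "-": pd.NA})
    df.index.name = "taxon"
    return df


def read_char_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tip-by-character matrix.

    CSV/TSV with header ``taxon,c1,...,cK`` (values 0/1/NA), or a NEXUS file
    (by ``.nex``/``.nexus`` extension).  Returns a DataFrame indexed by taxon
    with nullable-integer character columns.
    """
    p = str(path)
    if p.lower().endswith((".nex", ".nexus")):
        df = _read_nexus_chars(p)
    else:
        sep = "\t" if p.lower().endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(p, sep=sep, dtype=str)
        if "taxon" not in df.columns:
            raise ValueError("character matrix must have a 'taxon' column")
        df = df.set_index("taxon")
    for col in df.columns:
        vals = df[col].astype("string")
        ok = vals.isna() | vals.isin(["0", "1", "NA"])
        if not ok.all():
            bad = vals[~ok].unique().tolist()
            raise ValueError(f"column {col}: character states must be 0/1/NA, "
                             f"got {bad}")
        df[col] = vals.replace({"NA": pd.NA}).astype("Int64")
    return df


def write_char_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df.copy()
    out.index.name = "taxon"
    out.astype("Int64").to_csv(str(path), na_rep="NA")


def annotate(tree: dendropy.Tree, chars: pd.DataFrame,
             space: StateSpace | None = None,
             drop_unscored: bool = True) -> AnnotatedTree:
    """Join a tree with a character matrix into an :class:`AnnotatedTree`.

    Tip combinations are encoded to state indices; tips with any missing
    character are treated as unscored and, by default, dropped (mirroring a
    pipeline that analyses only fully scored species).
    """
    k = chars.shape[1]
    space = space or StateSpace(k)
    if space.n_chars != k:
        raise ValueError("character matrix width does not match state space")
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = labels - set(chars.index)
    if missing:
        raise ValueError(f"{len(missing)} tips lack character data, e.g. "
                         f"{sorted(missing)[:3]}")
    states: dict[str, int | None] = {}
    for lab in labels:
        row = chars.loc[lab]
        if row.isna().any():
            states[lab] = None
        else:
            states[lab] = encode_combination([int(v) for v in row], space)
    atree = AnnotatedTree(tree, states)
    if drop_unscored:
        atree = atree.drop_unscored()
    return atree


def states_to_matrix(tip_states: Mapping[str, int], space: StateSpace
                     ) -> pd.DataFrame:
    """Decode tip state indices back to a 0/1 character DataFrame."""
    cols = [f"c{i + 1}" for i in range(space.n_chars)]
    rows = {lab: space.decode(s) for lab, s in tip_states.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "taxon"
    return df.astype("Int64")


def read_family_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a ``family,richness`` CSV."""
    df = pd.read_csv(str(path))
    if not {"family", "richness"} <= set(df.columns):
        raise ValueError("family table must have 'family' and 'richness' columns")
    df["richness"] = df["richness"].astype(int)
    if (df["richness"] < 1).any():
        raise ValueError("family richness must be >= 1")
    return df


def write_family_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["family", "richness"]].to_csv(str(path), index=False)
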