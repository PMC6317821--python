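"""Differential-expression summary-table parsing and queries.

The RNA-seq comparison of fly heads is published as a small printed table:
annotation symbol, gene name, fold change and p-value.  Fold changes use the
signed reciprocal convention common in such summaries: +x means x-fold
up-regulation, -x means x-fold down-regulation (linear expression ratio 1/x),
so valid magnitudes never fall strictly inside (-1, 1).  p-values may be in
scientific notation, and a printed p of exactly 0 is preserved as 0 and sorts
below any positive p.  Missing gene names are printed as "-" and kept as-is.

A verbatim copy of the printed 20-row table ships with the package and is
available via :func:`load_reference_table`.
"""

from __future__ import annotations

import io
import warnings
from importlib import resources

import numpy as np
import pandas as pd

COLUMNS = ["annotation", "gene_name", "fold_change", "p_value"]


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    bad_fc = df["fold_change"].abs() < 1
    if bad_fc.any():
        raise ValueError(
            "fold changes in (-1, 1) are invalid under the signed reciprocal "
            f"convention: {df.loc[bad_fc, 'annotation'].tolist()}")
    bad_p = (df["p_value"] < 0) | (df["p_value"] > 1)
    if bad_p.any():
        raise ValueError(
            f"p-values outside [0, 1]: {df.loc[bad_p, 'annotation'].tolist()}")
    dups = df["annotation"][df["annotation"].duplicated()]
    if len(dups):
        warnings.warn(f"duplicate annotation keys: {sorted(set(dups))}")
    return df


def parse_de_table(source) -> pd.DataFrame:
    """Parse a DE summary table from a path, file object or literal text.

    Accepts tab- or comma-separated input with a header row; the four columns
    are taken in order (annotation, gene name, fold change, p-value)
    regardless of their header spellings.
    """
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=None, engine="python", dtype=str,
                     keep_default_na=False, na_values=[""])
    if df.shape[1] < 4:
        raise ValueError("expected at least 4 columns")
    df = df.iloc[:, :4].copy()
    df.columns = COLUMNS
    df["annotation"] = df["annotation"].astype(str)
    df["gene_name"] = df["gene_name"].astype(str)
    try:
        # python's float() is correctly rounded, so serialize/parse cycles
        # are bit-stable
        df["fold_change"] = df["fold_change"].map(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed fold change: {exc}") from exc
    df["p_value"] = df["p_value"].map(float)
    return _validate(df.reset_index(drop=True))


def write_de_table(df: pd.DataFrame, path_or_buf=None, sep: str = "\t"):
    """Serialize a parsed table; round-trips through :func:`parse_de_table`.

    Floats are written with ``repr`` so parse -> write -> parse is bit-exact.
    """
    return df.to_csv(path_or_buf, sep=sep, index=False,
                     float_format=lambda v: repr(float(v)))


def rank_and_filter(df: pd.DataFrame, min_abs_fold: float = 1.0,
                    max_p: float = 1.0, direction: str = "up") -> pd.DataFrame:
    """Filter by |fold change| and p, then sort by regulation strength.

    ``direction='up'`` keeps up-regulated rows sorted by descending fold
    change; ``'down'`` keeps down-regulated rows sorted ascending (strongest
    down-regulation first); ``'both'`` keeps all rows sorted by descending
    |fold change|.  Ties break by p-value (ascending, 0 first) then gene
    name, so repeated calls are order-stable.
    """
    if direction not in {"up", "down", "both"}:
        raise ValueError("direction must be 'up', 'down' or 'both'")
    out = df[(df["fold_change"].abs() >= min_abs_fold)
             & (df["p_value"] <= max_p)].copy()
    if direction == "up":
        out = out[out["fold_change"] > 0]
        out = out.sort_values(["fold_change", "p_value", "gene_name"],
                              ascending=[False, True, True], kind="mergesort")
    elif direction == "down":
        out = out[out["fold_change"] < 0]
        out = out.sort_values(["fold_change", "p_value", "gene_name"],
                              ascending=[True, True, True], kind="mergesort")
    else:
        out["_abs"] = out["fold_change"].abs()
        out = out.sort_values(["_abs", "p_value", "gene_name"],
                              ascending=[False, True, True], kind="mergesort")
        out = out.drop(columns="_abs")
    return out.reset_index(drop=True)


def to_linear_ratio(fold_change):
    """Convert signed reciprocal fold changes to linear expression ratios.

    +x maps to x, -x maps to 1/x; magnitudes below 1 are invalid.
    """
    fc = np.asarray(fold_change, dtype=float)
    if np.any(np.abs(fc) < 1):
        raise ValueError("fold-change magnitudes must be >= 1")
    out = np.where(fc > 0, fc, -1.0 / fc)
    return float(out) if np.ndim(fold_change) == 0 else out


def load_reference_table() -> pd.DataFrame:
    """The packaged 20-row head-transcriptome DE table, parsed."""
    ref = resources.files("somnarch").joinpath("data/head_de_table.tsv")
    return parse_de_table(io.StringIO(ref.read_text()))
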