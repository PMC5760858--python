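"""Reading and writing abundance tables and trait tables.

Two abundance dialects are supported:

* ``plain`` — a TSV whose first column is the protein id ("GENE|GROUPID")
  and remaining columns are samples.
* ``maxquant`` — a MaxQuant ``proteinGroups.txt``-style TSV: samples live in
  ``LFQ intensity <sample>`` columns, and rows flagged in ``Reverse`` or
  ``Potential contaminant`` are decoys/contaminants and are dropped.

In both dialects a stored value of 0 means "not quantified" and becomes
missing (NaN) in memory, following MaxQuant LFQ conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleTraits, ValidationError

LFQ_PREFIX = "LFQ intensity "


class FormatError(ValueError):
    """Raised when an input file does not match the declared dialect."""


def read_abundance(path, dialect: str = "plain") -> AbundanceMatrix:
    """Read a raw abundance table; zeros become missing, stage is ``raw``."""
    if dialect == "plain":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
    elif dialect == "maxquant":
        raw = pd.read_csv(path, sep="\t", dtype={"Reverse": str, "Potential contaminant": str})
        lfq_cols = [c for c in raw.columns if c.startswith(LFQ_PREFIX)]
        if not lfq_cols:
            raise FormatError(f"no '{LFQ_PREFIX}<sample>' columns in {path}")
        id_col = "Protein IDs" if "Protein IDs" in raw.columns else raw.columns[0]
        keep = pd.Series(True, index=raw.index)
        for flag in ("Reverse", "Potential contaminant"):
            if flag in raw.columns:
                keep &= raw[flag].fillna("").str.strip() != "+"
        raw = raw.loc[keep]
        df = raw.set_index(id_col)[lfq_cols]
        df.index = df.index.astype(str)
        df.columns = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate protein id: {dup!r}")
    values = df.astype(float).replace(0.0, np.nan)
    return AbundanceMatrix(values=values, stage="raw", scale="intensity")


def write_abundance(m: AbundanceMatrix, path, dialect: str = "plain") -> None:
    """Write an abundance table; missing entries are stored as 0."""
    out = m.values.fillna(0.0)
    if dialect == "plain":
        out.to_csv(path, sep="\t", index_label="Protein")
    elif dialect == "maxquant":
        df = out.copy()
        df.columns = [LFQ_PREFIX + c for c in df.columns]
        df.insert(0, "Protein IDs", df.index)
        df["Reverse"] = ""
        df["Potential contaminant"] = ""
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_traits(path) -> SampleTraits:
    table = pd.read_csv(path, index_col=0)
    table.index = table.index.astype(str)
    return SampleTraits(table)


def write_traits(traits: SampleTraits, path) -> None:
    traits.table.to_csv(path, index_label="sample")


def numeric_traits(traits: SampleTraits, columns=("group", "pTDP_score", "TDP_LFQ")) -> pd.DataFrame:
    """Numeric trait submatrix for module-trait correlation."""
    cols = [c for c in columns if c in traits.table.columns]
    if not cols:
        raise ValidationError("no numeric trait columns available")
    return traits.table[cols].astype(float)
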