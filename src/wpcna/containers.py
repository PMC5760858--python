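"""Core data containers shared across the pipeline.

The central object is :class:`AbundanceMatrix`, a proteins x samples table of
label-free quantification (LFQ) values with an explicit processing ``stage``
tag, so downstream operations can assert they receive input at the right point
of the preprocessing chain (raw -> filtered -> imputed -> regressed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("raw", "filtered", "imputed", "regressed")

#: Ordinal coding of the clinical groups, matching the trait heatmap legend
#: (0 control, 1 ALS, 2 ALS/FTD, 3 FTD).
GROUP_NAMES = ("control", "ALS", "ALSFTD", "FTD")

TRAIT_COLUMNS = ("group", "age", "sex", "PMI", "pTDP_score", "TDP_LFQ", "C9_status")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance table.

    Parameters
    ----------
    values
        DataFrame indexed by protein id ("GENE|GROUPID" convention), columns
        are sample ids. ``NaN`` marks missing quantifications. Values are on
        the raw intensity scale until :func:`wpcna.preprocess.log2_transform`
        is applied (tracked by ``scale``).
    stage
        One of ``raw``, ``filtered``, ``imputed``, ``regressed``.
    scale
        ``"intensity"`` or ``"log2"``.
    """

    values: pd.DataFrame
    stage: str = "raw"
    scale: str = "intensity"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.scale not in ("intensity", "log2"):
            raise ValidationError(f"scale must be 'intensity' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate protein id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if self.stage in ("imputed", "regressed") and self.values.isna().any().any():
            raise ValidationError(f"stage={self.stage!r} forbids missing entries")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def with_values(self, values: pd.DataFrame, *, stage: str | None = None,
                    scale: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(values=values,
                               stage=self.stage if stage is None else stage,
                               scale=self.scale if scale is None else scale)

    def copy(self) -> "AbundanceMatrix":
        return replace(self, values=self.values.copy())


@dataclass
class SampleTraits:
    """Per-sample clinical/pathological traits.

    ``group`` is ordinal 0-3 (control, ALS, ALS/FTD, FTD); ``pTDP_score`` is
    the ordinal 0-3 phosphorylated TDP-43 burden rating; ``sex`` is 0/1;
    ``C9_status`` is one of ``pos``/``neg``/``unknown``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample id in traits")
        missing = [c for c in ("group", "age", "sex", "PMI") if c not in t.columns]
        if missing:
            raise ValidationError(f"traits table missing columns: {missing}")
        if not t["group"].isin([0, 1, 2, 3]).all():
            raise ValidationError("group must be ordinal 0-3")
        if "pTDP_score" in t.columns and not t["pTDP_score"].dropna().isin([0, 1, 2, 3]).all():
            raise ValidationError("pTDP_score must be ordinal 0-3")
        if "C9_status" in t.columns:
            bad = set(t["C9_status"].dropna()) - {"pos", "neg", "unknown"}
            if bad:
                raise ValidationError(f"invalid C9_status values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, sample_ids) -> "SampleTraits":
        """Subset/reorder rows to ``sample_ids`` (raises if any are absent)."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"traits missing samples: {missing[:5]}")
        return SampleTraits(self.table.loc[list(sample_ids)].copy())

    def group_labels(self) -> pd.Series:
        return self.table["group"].astype(int)


@dataclass
class OutlierReport:
    """Record of the iterative connectivity-based sample removal.

    ``iterations`` holds one table per pass with columns ``sample``, ``Z.K``
    and ``removed``; ``retained`` is the final sample list.
    """

    iterations: list[pd.DataFrame] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tab in enumerate(self.iterations):
            tab = tab.copy()
            tab.insert(0, "iteration", i)
            rows.append(tab)
        if not rows:
            return pd.DataFrame(columns=["iteration", "sample", "Z.K", "removed"])
        return pd.concat(rows, ignore_index=True)
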