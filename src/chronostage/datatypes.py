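"""Shared containers and metadata conventions.

Expression data travel through the pipeline as a :class:`pandas.DataFrame`
with probe identifiers on the index and sample identifiers on the columns,
holding log2-scale intensities.  Presence calls use the same axes with
boolean values.  Sample metadata are a DataFrame with one row per sample and
the columns in :data:`META_COLUMNS`; :class:`SampleInfo` is the typed view of
a single row.

A *condition* is a unique combination of concentration, exposure regime and
harvest time -- the unit at which the experimental design has biological
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Metadata column order used by every reader/writer in the package.
META_COLUMNS = ["sample_id", "concentration_uM", "regime", "harvest_h", "replicate"]

#: Columns whose unique combinations define a replicate condition.
CONDITION_COLUMNS = ["concentration_uM", "regime", "harvest_h"]

#: Recognised exposure regimes.  ``washoutN`` means the toxicant was removed
#: at N hours; ``shamN`` is the matching unexposed culture subjected to the
#: same wash procedure.
REGIMES = ("continuous", "washout2", "washout8", "sham2", "sham8")

#: Hour at which the medium is exchanged, per regime (None = never).
WASHOUT_TIME = {
    "continuous": None,
    "washout2": 2.0,
    "washout8": 8.0,
    "sham2": 2.0,
    "sham8": 8.0,
}


@dataclass(frozen=True)
class SampleInfo:
    """Design coordinates of a single sample."""

    sample_id: str
    concentration_uM: float
    regime: str
    harvest_h: float
    replicate: int

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        wash = WASHOUT_TIME[self.regime]
        if wash is not None and self.harvest_h < wash:
            raise ValueError(
                f"sample {self.sample_id}: harvest {self.harvest_h} h precedes "
                f"the {self.regime} washout at {wash} h"
            )


def samples_to_frame(samples: Iterable[SampleInfo]) -> pd.DataFrame:
    """Convert SampleInfo records to the canonical metadata DataFrame."""
    rows = [
        (s.sample_id, s.concentration_uM, s.regime, s.harvest_h, s.replicate)
        for s in samples
    ]
    return pd.DataFrame(rows, columns=META_COLUMNS)


def frame_to_samples(metadata: pd.DataFrame) -> list[SampleInfo]:
    """Typed view of a metadata DataFrame."""
    return [
        SampleInfo(
            sample_id=str(r.sample_id),
            concentration_uM=float(r.concentration_uM),
            regime=str(r.regime),
            harvest_h=float(r.harvest_h),
            replicate=int(r.replicate),
        )
        for r in metadata.itertuples(index=False)
    ]


def validate_matrix(matrix: pd.DataFrame) -> None:
    """Check the ExpressionMatrix invariants: unique axes, finite values."""
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe identifiers: {dup[:5]}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def indexed_metadata(metadata: pd.DataFrame, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Return metadata indexed by sample_id, checking coverage of *matrix*.

    Raises ``ValueError`` naming any matrix sample that lacks metadata.
    """
    missing = [c for c in META_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks columns {missing}")
    meta = metadata.set_index("sample_id", drop=False)
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dup[:5]}")
    if matrix is not None:
        absent = [s for s in matrix.columns if s not in meta.index]
        if absent:
            raise ValueError(f"samples without metadata: {absent[:10]}")
        meta = meta.loc[list(matrix.columns)]
    return meta


def condition_groups(metadata: pd.DataFrame) -> dict[tuple, list[str]]:
    """Map each condition (concentration, regime, harvest) to its sample ids."""
    meta = metadata if "sample_id" in metadata.columns else metadata.reset_index()
    out: dict[tuple, list[str]] = {}
    for key, grp in meta.groupby(CONDITION_COLUMNS, sort=True):
        out[key] = list(grp["sample_id"])
    return out


def harvest_grid(metadata: pd.DataFrame) -> list[float]:
    """Sorted unique harvest times present in the metadata."""
    return sorted(float(h) for h in pd.unique(metadata["harvest_h"]))


def select_samples(
    metadata: pd.DataFrame,
    *,
    concentration: float | Sequence[float] | None = None,
    regime: str | Sequence[str] | None = None,
    harvest: float | Sequence[float] | None = None,
) -> list[str]:
    """Sample ids matching the given design coordinates (None = any)."""
    meta = metadata if "sample_id" in metadata.columns else metadata.reset_index()
    mask = pd.Series(True, index=meta.index)

    def _match(col: str, value) -> pd.Series:
        if isinstance(value, (str, int, float)):
            value = [value]
        return meta[col].isin(list(value))

    if concentration is not None:
        mask &= _match("concentration_uM", concentration)
    if regime is not None:
        mask &= _match("regime", regime)
    if harvest is not None:
        mask &= _match("harvest_h", harvest)
    return list(meta.loc[mask, "sample_id"])
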