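"""Spectral-count matrices and their sample metadata.

A :class:`SpectralCountMatrix` holds a proteins x samples table of spectral
counts (raw counts are integers; after flooring and bait normalization the
values are positive reals) together with one :class:`SampleMeta` per column.
Samples are either tagged purifications (they name a bait protein and a
condition such as ``WT`` or ``fcp1-1``) or no-tag controls capturing
nonspecific background binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one purification sample.

    No-tag controls have ``bait_protein=None``; tagged samples must name a
    bait present in the matrix they annotate.
    """

    sample_id: str
    condition: str
    is_no_tag: bool = False
    bait_protein: str | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.is_no_tag and self.bait_protein is not None:
            raise ValidationError(
                f"no-tag sample {self.sample_id!r} must not name a bait"
            )
        if not self.is_no_tag and self.bait_protein is None:
            raise ValidationError(
                f"tagged sample {self.sample_id!r} must name a bait protein"
            )


@dataclass
class SpectralCountMatrix:
    """Proteins x samples spectral-count table plus sample metadata."""

    values: pd.DataFrame  # index: protein ids, columns: sample ids
    samples: Sequence[SampleMeta]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in metadata")
        if list(self.values.columns) != ids:
            raise ValidationError(
                "matrix columns do not match sample sheet: "
                f"{list(self.values.columns)} vs {ids}"
            )
        if self.values.index.has_duplicates:
            # duplicate protein IDs are permitted on input; they are the
            # raw material of collapse_duplicates, but must be distinct rows
            raise ValidationError("matrix index contains identical row labels")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite spectral counts")
        if (vals < 0).any():
            raise ValidationError("negative spectral counts")
        for s in self.samples:
            if not s.is_no_tag and s.bait_protein not in self.values.index:
                raise ValidationError(
                    f"bait {s.bait_protein!r} of sample {s.sample_id!r} "
                    "absent from matrix"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def sample_ids(self, *, tagged: bool | None = None,
                   condition: str | None = None) -> list[str]:
        """Sample ids, optionally restricted by tag status and condition."""
        out = []
        for s in self.samples:
            if tagged is True and s.is_no_tag:
                continue
            if tagged is False and not s.is_no_tag:
                continue
            if condition is not None and s.condition != condition:
                continue
            out.append(s.sample_id)
        return out

    @property
    def tagged_conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if not s.is_no_tag:
                seen.setdefault(s.condition, None)
        return list(seen)

    @property
    def bait_proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if s.bait_protein is not None:
                seen.setdefault(s.bait_protein, None)
        return list(seen)

    def require_no_tag(self) -> list[str]:
        ids = self.sample_ids(tagged=False)
        if not ids:
            raise ConfigurationError("no no-tag control samples present")
        return ids

    def require_condition(self, condition: str) -> list[str]:
        ids = self.sample_ids(tagged=True, condition=condition)
        if not ids:
            raise ConfigurationError(
                f"no tagged samples for condition {condition!r}"
            )
        return ids

    # -- derived matrices --------------------------------------------------

    def with_values(self, values: pd.DataFrame) -> "SpectralCountMatrix":
        return SpectralCountMatrix(values=values, samples=self.samples)

    def subset(self, protein_ids: Iterable[str]) -> "SpectralCountMatrix":
        keep = [p for p in self.values.index if p in set(protein_ids)]
        return self.with_values(self.values.loc[keep])

    def mean_over(self, sample_ids: Sequence[str]) -> pd.Series:
        return self.values[list(sample_ids)].mean(axis=1)
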