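"""Shared data containers: spectra sets and composition tables.

A :class:`SpectraSet` holds a samples × channels intensity matrix together
with its spectral axis (Raman shift in cm⁻¹ or wavelength in nm), a modality
tag, and per-row sample/replicate identifiers.  A :class:`CompositionTable`
holds per-sample proportional fatty-acid contents (% of total FA) plus total
fat (% of sample).  Both round-trip to plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MODALITIES = ("raman", "nir_reflectance", "nir_absorbance")

FAT_COLUMN = "fat"


@dataclass
class SpectraSet:
    """Samples × channels intensity matrix with axis and identifiers.

    Parameters
    ----------
    intensities : ndarray, shape (n_spectra, n_channels)
    axis : ndarray, shape (n_channels,)
        Strictly increasing spectral axis (cm⁻¹ for Raman, nm for NIR).
    modality : {"raman", "nir_reflectance", "nir_absorbance"}
    sample_ids : sequence of str
        One per row; replicates of the same physical sample share an id.
    replicate_ids : sequence of str
        One per row; distinguishes replicate measurements of a sample.
    provenance : list of str
        Ordered record of the processing steps applied so far.
    """

    intensities: np.ndarray
    axis: np.ndarray
    modality: str
    sample_ids: list[str]
    replicate_ids: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.replicate_ids = [str(r) for r in self.replicate_ids]
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (samples × channels)")
        n, p = self.intensities.shape
        if self.axis.shape != (p,):
            raise ValueError(
                f"axis length {self.axis.shape} does not match channel count {p}"
            )
        if p > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if len(self.sample_ids) != n or len(self.replicate_ids) != n:
            raise ValueError("sample_ids/replicate_ids must have one entry per spectrum")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def unique_samples(self) -> list[str]:
        """Sample ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(s, None)
        return list(seen)

    def with_intensities(self, intensities: np.ndarray, *, modality: str | None = None,
                         step: str | None = None) -> "SpectraSet":
        """Copy with new intensities (same shape) and an appended provenance step."""
        prov = list(self.provenance) + ([step] if step else [])
        return replace(
            self,
            intensities=np.asarray(intensities, dtype=float),
            modality=modality or self.modality,
            sample_ids=list(self.sample_ids),
            replicate_ids=list(self.replicate_ids),
            provenance=prov,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=[f"{v:g}" for v in self.axis])
        df.insert(0, "replicate_id", self.replicate_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, modality: str) -> "SpectraSet":
        df = pd.read_csv(path)
        axis = np.array([float(c) for c in df.columns[2:]])
        return cls(
            intensities=df.iloc[:, 2:].to_numpy(dtype=float),
            axis=axis,
            modality=modality,
            sample_ids=df["sample_id"].astype(str).tolist(),
            replicate_ids=df["replicate_id"].astype(str).tolist(),
        )


@dataclass
class CompositionTable:
    """Per-sample proportional FA contents (% of total FA) and fat (% of sample)."""

    values: pd.DataFrame  # columns = FA names, index = sample ids
    fat: pd.Series        # % of sample, same index

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.fat = pd.Series(self.fat, dtype=float).reindex(self.values.index)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FA contents must be nonnegative")
        bad = self.fat[(self.fat <= 0) | (self.fat > 100)]
        if len(bad):
            raise ValueError(f"fat must lie in (0, 100]; offending samples: {list(bad.index[:5])}")

    @property
    def fa_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out[FAT_COLUMN] = self.fat
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompositionTable":
        df = pd.read_csv(path, index_col="sample_id")
        if FAT_COLUMN not in df.columns:
            raise ValueError(f"composition CSV must contain a '{FAT_COLUMN}' column")
        return cls(values=df.drop(columns=[FAT_COLUMN]), fat=df[FAT_COLUMN])

    @classmethod
    def from_arrays(cls, fa_names: Sequence[str], values: np.ndarray, fat: np.ndarray,
                    sample_ids: Sequence[str] | None = None) -> "CompositionTable":
        values = np.asarray(values, dtype=float)
        if sample_ids is None:
            sample_ids = [f"S{i:04d}" for i in range(values.shape[0])]
        df = pd.DataFrame(values, columns=list(fa_names), index=list(sample_ids))
        return cls(values=df, fat=pd.Series(np.asarray(fat, dtype=float), index=list(sample_ids)))
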