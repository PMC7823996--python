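"""Core in-memory containers shared across the pipeline.

A :class:`FeatureTable` is the central object: a feature × sample intensity
matrix (pandas DataFrame) plus feature metadata (m/z, optional retention time,
annotations) and sample metadata (time in hours, replicate, blank flag).
A :class:`Spectrum` is one sample's centroided peak list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "FeatureTable"]


@dataclass
class Spectrum:
    """One sample's centroided peak list.

    Parameters
    ----------
    sample_id : str
        Unique sample identifier.
    mz : ndarray
        Peak m/z values in Da, sorted ascending, all within (0, 2000).
    intensity : ndarray
        Non-negative peak intensities (arbitrary units), same length as mz.
    polarity : str
        Ionization polarity, ``"+"`` or ``"-"``.
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "-"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"mz and intensity lengths differ: {self.mz.size} vs {self.intensity.size}"
            )
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities are not allowed")
        if self.mz.size and (self.mz.min() <= 0 or self.mz.max() >= 2000):
            raise ValueError("m/z values must lie within (0, 2000)")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")

    def __len__(self) -> int:
        return int(self.mz.size)

    def with_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "Spectrum":
        """Return a copy of this spectrum with a replacement peak list."""
        return Spectrum(self.sample_id, mz, intensity, self.polarity)


@dataclass
class FeatureTable:
    """Feature × sample intensity matrix with metadata.

    Attributes
    ----------
    values : DataFrame
        Intensities; index = feature ids, columns = sample ids.
    feature_meta : DataFrame
        Indexed by feature id; must contain an ``mz`` column, may carry
        ``rt`` and annotation columns.
    sample_meta : DataFrame
        Indexed by sample id; must contain ``time_h`` (float, NaN for blanks),
        ``replicate`` (int) and ``is_blank`` (bool) columns.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.feature_meta.index):
            raise ValueError("values index and feature_meta index must match")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("values columns and sample_meta index must match")
        if "mz" not in self.feature_meta.columns:
            raise ValueError("feature_meta must contain an 'mz' column")
        for col in ("time_h", "replicate", "is_blank"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta must contain a '{col}' column")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def blank_ids(self) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["is_blank"].astype(bool)])

    @property
    def cell_ids(self) -> list[str]:
        return list(self.sample_meta.index[~self.sample_meta["is_blank"].astype(bool)])

    @property
    def time_points(self) -> list[float]:
        t = self.sample_meta.loc[self.cell_ids, "time_h"]
        return sorted(set(float(x) for x in t))

    def samples_at(self, time_h: float) -> list[str]:
        """Sample ids of non-blank samples taken at a given time point."""
        meta = self.sample_meta
        mask = (~meta["is_blank"].astype(bool)) & (meta["time_h"] == time_h)
        return list(meta.index[mask])

    def drop_blanks(self) -> "FeatureTable":
        """Return the table restricted to non-blank samples."""
        keep = self.cell_ids
        return FeatureTable(
            self.values[keep].copy(),
            self.feature_meta.copy(),
            self.sample_meta.loc[keep].copy(),
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        """Return the table restricted to the given feature ids (order kept)."""
        ids = list(feature_ids)
        return FeatureTable(
            self.values.loc[ids].copy(),
            self.feature_meta.loc[ids].copy(),
            self.sample_meta.copy(),
        )

    def with_values(self, values: pd.DataFrame) -> "FeatureTable":
        """Return a copy with a replacement intensity matrix (same shape/labels)."""
        return FeatureTable(values, self.feature_meta.copy(), self.sample_meta.copy())
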