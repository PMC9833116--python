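"""Feature-table container for untargeted LC-MS intensity data.

A :class:`FeatureTable` couples a samples x features intensity matrix with
feature metadata (m/z, retention time, ionisation mode) and sample metadata
(subject, burn/control condition, time fraction, QC flag, tissue weight).
It is the common currency of the discriminant and lipidomics pipelines.

On disk a table is a pair of plain CSV files: a tidy long-format intensity
file (feature_id, mz, rt_s, ion_mode, sample_id, intensity) and a
sample-metadata file (sample_id, subject, condition, fraction, is_qc,
weight_mg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]

#: canonical sample-metadata columns, in on-disk order
SAMPLE_COLUMNS = ["subject", "condition", "fraction", "is_qc", "weight_mg"]


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with metadata on both axes.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Non-negative intensities, index = sample ids, columns = feature ids.
    features : pandas.DataFrame
        Indexed by feature id with columns ``mz`` (Da), ``rt_s`` (seconds)
        and ``ion_mode`` (``"+"`` or ``"-"``).
    samples : pandas.DataFrame
        Indexed by sample id with columns ``subject``, ``condition``
        (``"burn"`` / ``"control"``; empty for QC), ``fraction`` (time
        fraction index, nullable), ``is_qc`` (bool) and ``weight_mg``
        (nullable float).
    """

    intensities: pd.DataFrame
    features: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.samples.index):
            raise ValueError("intensity rows and sample metadata do not align")
        if not self.intensities.columns.equals(self.features.index):
            raise ValueError("intensity columns and feature metadata do not align")
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite")
        non_qc = self.samples.loc[~self.samples["is_qc"].astype(bool)]
        if non_qc["condition"].isna().any():
            raise ValueError("every non-QC sample needs a condition label")

    # -- convenience views ------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def qc_mask(self) -> np.ndarray:
        return self.samples["is_qc"].to_numpy(dtype=bool)

    def biological(self) -> "FeatureTable":
        """Return the table restricted to non-QC samples."""
        keep = ~self.qc_mask
        return self.subset_samples(self.samples.index[keep])

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(
            intensities=self.intensities.loc[sample_ids],
            features=self.features,
            samples=self.samples.loc[sample_ids],
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            intensities=self.intensities[list(feature_ids)],
            features=self.features.loc[list(feature_ids)],
            samples=self.samples,
        )

    def with_intensities(self, values: np.ndarray) -> "FeatureTable":
        """Return a copy whose intensity values are replaced (same axes)."""
        new = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.intensities.index,
            columns=self.intensities.columns,
        )
        return FeatureTable(intensities=new, features=self.features, samples=self.samples)

    # -- I/O --------------------------------------------------------------

    def to_csv(self, intensity_path: str | Path, sample_path: str | Path) -> None:
        """Write tidy long-format intensities and sample metadata CSVs."""
        long = (
            self.intensities.stack()
            .rename("intensity")
            .rename_axis(["sample_id", "feature_id"])
            .reset_index()
        )
        long = long.merge(
            self.features.rename_axis("feature_id").reset_index(), on="feature_id"
        )
        long = long[["feature_id", "mz", "rt_s", "ion_mode", "sample_id", "intensity"]]
        long.to_csv(intensity_path, index=False)
        meta = self.samples.rename_axis("sample_id").reset_index()
        meta[["sample_id"] + SAMPLE_COLUMNS].to_csv(sample_path, index=False)

    @classmethod
    def from_csv(cls, intensity_path: str | Path, sample_path: str | Path) -> "FeatureTable":
        long = pd.read_csv(intensity_path)
        meta = pd.read_csv(sample_path).set_index("sample_id")
        meta["is_qc"] = meta["is_qc"].astype(bool)
        if meta["condition"].dtype == object:
            meta["condition"] = meta["condition"].where(meta["condition"].notna())
        wide = long.pivot(index="sample_id", columns="feature_id", values="intensity")
        dup = long.duplicated(["sample_id", "feature_id"])
        if dup.any():
            raise ValueError("duplicate (sample, feature) cells in intensity CSV")
        features = (
            long[["feature_id", "mz", "rt_s", "ion_mode"]]
            .drop_duplicates("feature_id")
            .set_index("feature_id")
        )
        # preserve first-appearance order of features and the metadata sample order
        order = long["feature_id"].drop_duplicates().tolist()
        wide = wide.loc[meta.index, order]
        return cls(intensities=wide, features=features.loc[order], samples=meta)
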