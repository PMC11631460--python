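"""Core containers for tiled peptide-array differential-binding analysis.

Conventions used throughout the package:

* Protein coordinates are 1-based and inclusive.  A probe is a 16-mer
  whose ``start`` is the protein position of its first residue; the probe
  covers ``[start, start + 15]``.
* ``tiling`` is the amino-acid step between consecutive probes of the same
  protein (1, 2 or 4 a.a. on the arrays this package models).
* Epitope identifiers are ``Protein_FirstProbe_LastProbe`` where the two
  numbers are the start coordinates of the first and last member probes.
* Sample labels are ``negative`` (control / pre-treatment sera) and
  ``positive`` (experimental / post-treatment sera).  All probe-level
  statistics are computed per positive sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

NEGATIVE = "negative"
POSITIVE = "positive"

PEPTIDE_LENGTH = 16

Layer = Literal["global", "differential", "combined", "adjusted"]
Level = Literal["probe", "epitope", "protein"]


class DegenerateDataError(ValueError):
    """Raised when the input matrix cannot support the requested statistic."""


@dataclass
class ProbeDataset:
    """A normalized probe-intensity matrix with sample labels and probe metadata.

    Parameters
    ----------
    intensities
        Probes x samples matrix of normalized signal (rows indexed by
        ``probe_id``, columns by sample id).  No missing values.
    sample_labels
        Series mapping sample id -> ``"negative"`` / ``"positive"``.
    probe_meta
        DataFrame indexed by ``probe_id`` with columns ``protein_id``,
        ``start`` (1-based), ``tiling`` and optionally ``sequence``.
    """

    intensities: pd.DataFrame
    sample_labels: pd.Series
    probe_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        labels = set(self.sample_labels.unique())
        unknown = labels - {NEGATIVE, POSITIVE}
        if unknown:
            raise ValueError(f"unknown sample labels: {sorted(unknown)}")
        missing = [s for s in self.intensities.columns if s not in self.sample_labels.index]
        if missing:
            raise ValueError(f"samples absent from the sample sheet: {missing}")
        if not self.negative_samples:
            raise ValueError("at least one negative sample is required")
        if not self.positive_samples:
            raise ValueError("at least one positive sample is required")
        if self.intensities.isna().any().any():
            raise ValueError("intensity matrix contains missing values")
        missing_meta = self.intensities.index.difference(self.probe_meta.index)
        if len(missing_meta):
            raise ValueError(
                f"{len(missing_meta)} probes lack metadata, e.g. {list(missing_meta[:5])}"
            )
        for col in ("protein_id", "start", "tiling"):
            if col not in self.probe_meta.columns:
                raise ValueError(f"probe metadata misses required column {col!r}")
        meta = self.probe_meta.loc[self.intensities.index]
        dup = meta.groupby("protein_id")["start"].apply(lambda s: s.duplicated().any())
        if dup.any():
            bad = list(dup.index[dup])
            raise ValueError(f"duplicate probe start positions within proteins: {bad[:5]}")

    # -- convenience ------------------------------------------------------

    @property
    def negative_samples(self) -> list[str]:
        idx = self.sample_labels.index[self.sample_labels == NEGATIVE]
        return [s for s in self.intensities.columns if s in set(idx)]

    @property
    def positive_samples(self) -> list[str]:
        idx = self.sample_labels.index[self.sample_labels == POSITIVE]
        return [s for s in self.intensities.columns if s in set(idx)]

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    def protein_probe_order(self) -> pd.DataFrame:
        """Probe metadata with a ``rank`` column: positional order within protein.

        Rank adjacency (not a fixed coordinate offset) defines "consecutive"
        probes, which keeps mixed 2/4-a.a. tilings consistent.
        """
        meta = self.probe_meta.loc[self.probe_ids, ["protein_id", "start", "tiling"]].copy()
        meta = meta.sort_values(["protein_id", "start"], kind="mergesort")
        meta["rank"] = meta.groupby("protein_id").cumcount()
        return meta


@dataclass
class PValueTable:
    """Probes (or features) x positive-samples matrix of p-values for one layer."""

    layer: Layer
    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and ((v < 0).any() or (v > 1).any()):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class StatParams:
    """Probe-level significance parameters.

    ``global_sd_shift`` shifts the global one-sided z-test in units of the
    pooled SD; ``diff_abs_shift`` shifts the differential one-sided t-test on
    the normalized scale (a shift of 1 is a 2-fold change for log2 data).
    """

    global_sd_shift: float = 6.0
    diff_abs_shift: float = 1.0
    p_adj_cutoff: float = 0.05
    use_global: bool = True
    use_differential: bool = True
    one_hit_filter: bool = True
    bh_scope: Literal["per_sample", "matrix"] = "per_sample"

    def __post_init__(self) -> None:
        if not (self.use_global or self.use_differential):
            raise ValueError("at least one of use_global/use_differential must be enabled")
        if self.global_sd_shift < 0 or self.diff_abs_shift < 0:
            raise ValueError("shifts must be non-negative")
        if not (0 < self.p_adj_cutoff < 1):
            raise ValueError("p_adj_cutoff must lie in (0, 1)")


@dataclass
class CallMatrix:
    """Boolean features x positive-samples call matrix at an adjusted-p cutoff."""

    calls: pd.DataFrame
    cutoff: float
    level: Level = "probe"


@dataclass
class KofN:
    feature_id: str
    k: int
    n: int

    @property
    def fraction(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class Epitope:
    """A contiguous block of adjacent probes on one protein.

    ``first`` and ``last`` are the start coordinates (1-based) of the first
    and last member probes; the covered amino-acid interval of a 16-mer block
    is ``[first, last + 15]``.
    """

    protein_id: str
    first: int
    last: int
    member_probes: tuple[str, ...]

    @property
    def epitope_id(self) -> str:
        return f"{self.protein_id}_{self.first}_{self.last}"

    @property
    def n_probes(self) -> int:
        return len(self.member_probes)

    @property
    def covered_interval(self) -> tuple[int, int]:
        return (self.first, self.last + PEPTIDE_LENGTH - 1)


def parse_epitope_id(epitope_id: str) -> tuple[str, int, int]:
    """Split ``Protein_First_Last`` into its parts (protein ids may contain '_')."""
    protein, first, last = epitope_id.rsplit("_", 2)
    return protein, int(first), int(last)


@dataclass
class SegmentationConfig:
    method: Literal["unique", "hclust", "skater"] = "hclust"
    distance: Literal["binary_hamming", "zscore_euclidean"] = "binary_hamming"

    def __post_init__(self) -> None:
        if self.method not in ("unique", "hclust", "skater"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.distance not in ("binary_hamming", "zscore_euclidean"):
            raise ValueError(f"unknown distance mode {self.distance!r}")


@dataclass
class LevelResults:
    """Per-sample p-values, calls and K-of-N summaries for one feature level."""

    level: Level
    raw: pd.DataFrame
    adjusted: pd.DataFrame
    calls: CallMatrix
    k_of_n: list[KofN] = field(default_factory=list)
    feature_meta: pd.DataFrame | None = None

    def k_of_n_frame(self) -> pd.DataFrame:
        rows = [(x.feature_id, x.k, x.n, 100.0 * x.fraction) for x in self.k_of_n]
        return pd.DataFrame(rows, columns=["feature_id", "k", "n", "percent_called"]).set_index(
            "feature_id"
        )


def k_of_n_from_calls(calls: pd.DataFrame) -> list[KofN]:
    n = calls.shape[1]
    return [KofN(str(fid), int(row.sum()), n) for fid, row in calls.iterrows()]
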