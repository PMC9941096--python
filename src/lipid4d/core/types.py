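"""Domain types for 4D lipidomics data.

Every detected ion carries four descriptors: m/z [Da], retention time
[min], collision cross section [Å²], and (optionally) an MS/MS
spectrum. Types here are deliberately small value objects validated at
construction; tabular containers wrap pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

POLARITIES = ("positive", "negative")

PROV_PRIMARY = "primary"
PROV_RECURSIVE = "recursive"
PROV_MISSING = "missing"


class FormatError(ValueError):
    """A file does not conform to its declared text format."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


def _check_polarity(polarity: str) -> str:
    if polarity not in POLARITIES:
        raise ValidationError(
            f"polarity must be one of {POLARITIES}, got {polarity!r}"
        )
    return polarity


@dataclass(frozen=True)
class Feature4D:
    """One detected ion in one analysis run."""

    mz: float
    rt: float
    ccs: float
    area: float
    polarity: str
    spectrum_id: Optional[str] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"mz must be > 0, got {self.mz}")
        if not self.rt >= 0:
            raise ValidationError(f"rt must be >= 0, got {self.rt}")
        if not self.ccs > 0:
            raise ValidationError(f"ccs must be > 0, got {self.ccs}")
        if not self.area >= 0:
            raise ValidationError(f"area must be >= 0, got {self.area}")
        _check_polarity(self.polarity)

    def with_sample(self, sample_id: str) -> "Feature4D":
        return replace(self, sample_id=sample_id)


class Spectrum:
    """A centroided peak list with strictly increasing m/z."""

    __slots__ = ("peaks", "precursor_mz", "polarity")

    def __init__(
        self,
        peaks: Iterable[tuple[float, float]] | np.ndarray,
        precursor_mz: Optional[float] = None,
        polarity: Optional[str] = None,
    ) -> None:
        arr = np.asarray(list(peaks) if not isinstance(peaks, np.ndarray) else peaks,
                         dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
            raise ValidationError("spectrum needs at least one (mz, intensity) peak")
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        if np.any(np.diff(arr[:, 0]) <= 0):
            raise ValidationError("peak m/z values must be strictly increasing")
        if np.any(arr[:, 1] < 0):
            raise ValidationError("peak intensities must be >= 0")
        self.peaks = arr
        self.precursor_mz = precursor_mz
        if polarity is not None:
            _check_polarity(polarity)
        self.polarity = polarity

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]

    def total_intensity(self) -> float:
        return float(self.peaks[:, 1].sum())

    def __len__(self) -> int:
        return self.peaks.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.peaks, other.peaks)
            and self.precursor_mz == other.precursor_mz
            and self.polarity == other.polarity
        )

    def __repr__(self) -> str:
        return (f"Spectrum(n_peaks={len(self)}, precursor_mz={self.precursor_mz},"
                f" polarity={self.polarity})")


@dataclass(frozen=True)
class LibraryEntry:
    """One analyte-list record: identity plus expected 4D coordinates."""

    name: str
    lipid_class: str
    adduct: str
    polarity: str
    expected_mz: float
    expected_rt: float
    expected_ccs: float
    neutral_mass: Optional[float] = None
    formula: Optional[str] = None
    spectrum_id: Optional[str] = None
    is_istd: bool = False

    def __post_init__(self) -> None:
        if not self.expected_mz > 0:
            raise ValidationError(f"expected_mz must be > 0, got {self.expected_mz}")
        if not self.expected_rt >= 0:
            raise ValidationError(f"expected_rt must be >= 0, got {self.expected_rt}")
        if not self.expected_ccs > 0:
            raise ValidationError(f"expected_ccs must be > 0, got {self.expected_ccs}")
        _check_polarity(self.polarity)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.name, self.adduct, self.polarity)


@dataclass(frozen=True)
class ToleranceSet:
    """Per-dimension match tolerances (Chebyshev box).

    Exactly one of ``d_mz_abs`` / ``d_mz_ppm`` is active: setting
    ``d_mz_ppm`` switches the m/z test to a ppm window around the
    reference m/z. The m/z test is strict (<); RT and CCS are
    inclusive (<=).
    """

    d_mz_abs: Optional[float] = 0.002
    d_mz_ppm: Optional[float] = None
    d_rt: float = 0.1
    d_ccs: float = 0.2

    def __post_init__(self) -> None:
        if (self.d_mz_abs is None) == (self.d_mz_ppm is None):
            raise ValidationError("exactly one of d_mz_abs / d_mz_ppm must be set")
        active = self.d_mz_abs if self.d_mz_abs is not None else self.d_mz_ppm
        for label, v in (("d_mz", active), ("d_rt", self.d_rt), ("d_ccs", self.d_ccs)):
            if not v > 0:
                raise ValidationError(f"{label} must be strictly positive, got {v}")

    def mz_window(self, ref_mz: float) -> float:
        """Half-width of the m/z window around ``ref_mz`` [Da]."""
        if self.d_mz_abs is not None:
            return self.d_mz_abs
        return ref_mz * self.d_mz_ppm * 1e-6

    def contains(
        self,
        ref_mz: float, ref_rt: float, ref_ccs: float,
        mz: float, rt: float, ccs: float,
    ) -> bool:
        return (
            abs(mz - ref_mz) < self.mz_window(ref_mz)
            and abs(rt - ref_rt) <= self.d_rt
            and abs(ccs - ref_ccs) <= self.d_ccs
        )

    def normalized_distance(
        self,
        ref_mz: float, ref_rt: float, ref_ccs: float,
        mz: float, rt: float, ccs: float,
    ) -> float:
        """Chebyshev distance with each axis scaled by its tolerance."""
        return max(
            abs(mz - ref_mz) / self.mz_window(ref_mz),
            abs(rt - ref_rt) / self.d_rt,
            abs(ccs - ref_ccs) / self.d_ccs,
        )


@dataclass
class BucketTable:
    """Cross-sample aligned features.

    ``buckets`` holds consensus coordinates (columns mz, rt, ccs),
    ``values`` a bucket x sample peak-area matrix (NaN where missing),
    ``provenance`` a same-shaped matrix of {primary, recursive,
    missing}. ``members`` optionally maps bucket id -> sample id ->
    the member Feature4D.
    """

    buckets: pd.DataFrame
    values: pd.DataFrame
    provenance: pd.DataFrame
    polarity: str = "negative"
    members: Optional[dict] = None
    annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        _check_polarity(self.polarity)
        if not self.values.index.equals(self.provenance.index) or not (
            self.values.columns.equals(self.provenance.columns)
        ):
            raise ValidationError("values and provenance must share shape and labels")
        if not self.values.index.equals(self.buckets.index):
            raise ValidationError("values rows must match bucket records")
        present = self.provenance.to_numpy() != PROV_MISSING
        vals = self.values.to_numpy(dtype=float)
        if np.any(present & ~(vals >= 0)):
            raise ValidationError("present values must be >= 0")
        if np.any(~present & ~np.isnan(vals)):
            raise ValidationError("missing cells must hold NaN")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_buckets(self) -> int:
        return len(self.buckets)

    def presence_counts(self) -> pd.DataFrame:
        """Per bucket: number of primary and primary+recursive values."""
        prov = self.provenance
        primary = (prov == PROV_PRIMARY).sum(axis=1)
        filled = primary + (prov == PROV_RECURSIVE).sum(axis=1)
        return pd.DataFrame({"n_primary": primary, "n_filled": filled})

    def subset(self, bucket_ids: Iterable) -> "BucketTable":
        idx = pd.Index(bucket_ids)
        members = None
        if self.members is not None:
            members = {b: self.members[b] for b in idx if b in self.members}
        annotations = None
        if self.annotations is not None:
            annotations = self.annotations.loc[
                self.annotations.index.intersection(idx)
            ].copy()
        return BucketTable(
            buckets=self.buckets.loc[idx].copy(),
            values=self.values.loc[idx].copy(),
            provenance=self.provenance.loc[idx].copy(),
            polarity=self.polarity,
            members=members,
            annotations=annotations,
        )

    def copy(self) -> "BucketTable":
        return self.subset(self.buckets.index)


@dataclass
class StudyDesign:
    """Sample-level factors: individual, matrix, time point, dilution,
    batch role, and nominal concentration for calibration points."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "batch_role")
    OPTIONAL = ("individual", "matrix", "time_point", "dilution_volume",
                "nominal_conc")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"study design missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in design: {dups}")
        is_cal = df["batch_role"].astype(str).str.startswith("calibration_point")
        if is_cal.any() and df.loc[is_cal, "nominal_conc"].isna().any():
            raise ValidationError("calibration points must carry nominal_conc")
        df = df.set_index("sample_id", drop=False)
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def check_covers(self, sample_ids: Iterable[str]) -> None:
        missing = sorted(set(sample_ids) - set(self.sample_ids))
        if missing:
            raise ValidationError(
                f"samples absent from study design: {missing}"
            )

    def samples_with_role(self, role: str) -> pd.DataFrame:
        return self.table[self.table["batch_role"] == role]

    def dilution_map(self) -> Mapping[str, float]:
        """sample_id -> dilution volume for samples that carry one."""
        sub = self.table.dropna(subset=["dilution_volume"])
        return dict(zip(sub["sample_id"], sub["dilution_volume"].astype(float)))
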