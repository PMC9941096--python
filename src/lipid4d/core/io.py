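"""Readers and writers for the plain-text interchange formats.

Feature tables, analyte lists, and study designs are delimited text
(tab preferred, comma accepted — the delimiter is sniffed from the
header line). Spectra are NIST-style MSP (read/write) and MGF
(read-only). Bucket tables round-trip as a values TSV plus a
provenance side-file and a bucket-coordinate TSV.
"""

from __future__ import annotations

import os
import re
from typing import Optional

import numpy as np
import pandas as pd

from lipid4d.core.types import (
    PROV_MISSING,
    BucketTable,
    Feature4D,
    FormatError,
    LibraryEntry,
    Spectrum,
    StudyDesign,
    ValidationError,
)

_FEATURE_COLS = ("mz", "rt", "ccs", "area")
_ENTRY_COLS = (
    "name", "lipid_class", "adduct", "polarity", "neutral_mass",
    "expected_mz", "expected_rt", "expected_ccs", "formula",
    "spectrum_id", "is_istd",
)


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_delimited(path: str) -> pd.DataFrame:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _float_cell(raw: str, column: str, row: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise FormatError(
            f"row {row}: cannot parse {column}={raw!r} as a number"
        ) from None


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(path: str, polarity: str) -> list[Feature4D]:
    """Parse a delimited feature table into Feature4D records, in file order."""
    df = _read_delimited(path)
    for col in _FEATURE_COLS:
        if col not in df.columns:
            raise FormatError(f"feature table {path} missing column {col!r}")
    features = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        vals = {c: _float_cell(rec[c], c, i) for c in _FEATURE_COLS}
        if vals["area"] < 0:
            raise ValidationError(f"row {i}: negative area {vals['area']}")
        features.append(Feature4D(
            mz=vals["mz"], rt=vals["rt"], ccs=vals["ccs"], area=vals["area"],
            polarity=polarity,
            spectrum_id=rec.get("spectrum_id") or None,
            sample_id=rec.get("sample_id") or None,
        ))
    return features


def write_feature_table(features: list[Feature4D], path: str) -> None:
    rows = [
        {
            "mz": f"{f.mz:.6f}", "rt": f"{f.rt:.6f}", "ccs": f"{f.ccs:.6f}",
            "area": f"{f.area:.6f}",
            "spectrum_id": f.spectrum_id or "", "sample_id": f.sample_id or "",
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=["mz", "rt", "ccs", "area", "spectrum_id",
                                "sample_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spectra


def read_msp(path: str) -> dict[str, Spectrum]:
    """Parse NIST-style MSP records keyed by Name; peaks sorted ascending."""
    store: dict[str, Spectrum] = {}
    name: Optional[str] = None
    precursor: Optional[float] = None
    polarity: Optional[str] = None
    declared: Optional[int] = None
    peaks: list[tuple[float, float]] = []

    def flush() -> None:
        nonlocal name, precursor, polarity, declared, peaks
        if name is None:
            return
        if declared is not None and declared != len(peaks):
            raise FormatError(
                f"MSP record {name!r} declares {declared} peaks but lists {len(peaks)}"
            )
        if not peaks:
            raise FormatError(f"MSP record {name!r} has no peaks")
        store[name] = Spectrum(peaks, precursor_mz=precursor, polarity=polarity)
        name, precursor, polarity, declared, peaks = None, None, None, None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                flush()
                continue
            m = re.match(r"(?i)^name\s*:\s*(.+)$", line)
            if m:
                flush()
                name = m.group(1).strip()
                continue
            m = re.match(r"(?i)^precursormz\s*:\s*(\S+)$", line)
            if m:
                precursor = float(m.group(1))
                continue
            m = re.match(r"(?i)^(ion[_ ]?mode|polarity)\s*:\s*(\S+)$", line)
            if m:
                token = m.group(2).lower()
                polarity = {"p": "positive", "n": "negative"}.get(
                    token[0], token if token in ("positive", "negative") else None
                )
                continue
            m = re.match(r"(?i)^num\s*peaks\s*:\s*(\d+)$", line)
            if m:
                declared = int(m.group(1))
                continue
            if ":" in line and not line[0].isdigit():
                continue  # unrecognised metadata field
            parts = line.replace(";", " ").split()
            if len(parts) >= 2:
                peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return store


def write_msp(store: dict[str, Spectrum], path: str) -> None:
    with open(path, "w") as fh:
        for name, sp in store.items():
            fh.write(f"Name: {name}\n")
            if sp.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {sp.precursor_mz:.6f}\n")
            if sp.polarity is not None:
                fh.write(f"Ion_mode: {sp.polarity[0].upper()}\n")
            fh.write(f"Num Peaks: {len(sp)}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("\n")


def read_mgf(path: str) -> dict[str, Spectrum]:
    """Read-only MGF convenience; spectra keyed by TITLE."""
    store: dict[str, Spectrum] = {}
    in_block = False
    title: Optional[str] = None
    precursor: Optional[float] = None
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "BEGIN IONS":
                in_block, title, precursor, peaks = True, None, None, []
            elif line == "END IONS":
                if not peaks:
                    raise FormatError(f"MGF record {title!r} has no peaks")
                key = title if title is not None else f"spectrum_{len(store)}"
                store[key] = Spectrum(peaks, precursor_mz=precursor)
                in_block = False
            elif in_block:
                if line.startswith("TITLE="):
                    title = line[6:].strip()
                elif line.startswith("PEPMASS="):
                    precursor = float(line[8:].split()[0])
                elif "=" not in line and line:
                    parts = line.split()
                    if len(parts) >= 2:
                        peaks.append((float(parts[0]), float(parts[1])))
    return store


# ---------------------------------------------------------------------------
# analyte lists


def read_analyte_list(path: str) -> list[LibraryEntry]:
    df = _read_delimited(path)
    for col in ("name", "lipid_class", "adduct", "polarity", "expected_mz",
                "expected_rt", "expected_ccs"):
        if col not in df.columns:
            raise FormatError(f"analyte list {path} missing column {col!r}")
    entries: list[LibraryEntry] = []
    seen: set[tuple[str, str, str]] = set()
    polarities: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=2):
        entry = LibraryEntry(
            name=rec["name"],
            lipid_class=rec["lipid_class"],
            adduct=rec["adduct"],
            polarity=rec["polarity"],
            expected_mz=_float_cell(rec["expected_mz"], "expected_mz", i),
            expected_rt=_float_cell(rec["expected_rt"], "expected_rt", i),
            expected_ccs=_float_cell(rec["expected_ccs"], "expected_ccs", i),
            neutral_mass=(_float_cell(rec["neutral_mass"], "neutral_mass", i)
                          if rec.get("neutral_mass") else None),
            formula=rec.get("formula") or None,
            spectrum_id=rec.get("spectrum_id") or None,
            is_istd=str(rec.get("is_istd", "")).strip().lower()
            in ("1", "true", "yes"),
        )
        if entry.key in seen:
            raise ValidationError(f"duplicate analyte key {entry.key}")
        seen.add(entry.key)
        polarities.add(entry.polarity)
        entries.append(entry)
    if len(polarities) > 1:
        raise ValidationError(
            f"analyte list mixes polarities {sorted(polarities)}; one per file"
        )
    return entries


def write_analyte_list(entries: list[LibraryEntry], path: str) -> None:
    rows = []
    for e in entries:
        rows.append({
            "name": e.name, "lipid_class": e.lipid_class, "adduct": e.adduct,
            "polarity": e.polarity,
            "neutral_mass": f"{e.neutral_mass:.6f}" if e.neutral_mass else "",
            "expected_mz": f"{e.expected_mz:.6f}",
            "expected_rt": f"{e.expected_rt:.6f}",
            "expected_ccs": f"{e.expected_ccs:.6f}",
            "formula": e.formula or "",
            "spectrum_id": e.spectrum_id or "",
            "is_istd": "true" if e.is_istd else "false",
        })
    pd.DataFrame(rows, columns=list(_ENTRY_COLS)).to_csv(path, sep="\t",
                                                         index=False)


# ---------------------------------------------------------------------------
# study designs


def read_study_design(path: str) -> StudyDesign:
    df = _read_delimited(path)
    for col in ("dilution_volume", "nominal_conc"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].where(df[col] != ""))
    return StudyDesign(df)


def write_study_design(design: StudyDesign, path: str) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bucket tables


def write_bucket_table(table: BucketTable, prefix: str) -> None:
    """Write <prefix>.values.tsv, <prefix>.provenance.tsv, <prefix>.buckets.tsv."""
    table.values.to_csv(f"{prefix}.values.tsv", sep="\t",
                        index_label="bucket_id")
    table.provenance.to_csv(f"{prefix}.provenance.tsv", sep="\t",
                            index_label="bucket_id")
    meta = table.buckets.copy()
    meta.insert(0, "polarity", table.polarity)
    meta.to_csv(f"{prefix}.buckets.tsv", sep="\t", index_label="bucket_id")
    if table.annotations is not None:
        table.annotations.to_csv(f"{prefix}.annotations.tsv", sep="\t",
                                 index_label="bucket_id")


def read_bucket_table(prefix: str) -> BucketTable:
    values = pd.read_csv(f"{prefix}.values.tsv", sep="\t",
                         index_col="bucket_id")
    provenance = pd.read_csv(f"{prefix}.provenance.tsv", sep="\t",
                             index_col="bucket_id",
                             keep_default_na=False)
    meta = pd.read_csv(f"{prefix}.buckets.tsv", sep="\t", index_col="bucket_id")
    polarity = str(meta["polarity"].iloc[0]) if len(meta) else "negative"
    buckets = meta.drop(columns=["polarity"], errors="ignore")
    values = values.where(provenance != PROV_MISSING, np.nan)
    annotations = None
    ann_path = f"{prefix}.annotations.tsv"
    if os.path.exists(ann_path):
        annotations = pd.read_csv(ann_path, sep="\t", index_col="bucket_id")
    return BucketTable(buckets=buckets, values=values, provenance=provenance,
                       polarity=polarity, annotations=annotations)
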