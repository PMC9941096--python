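"""Building and extending the 4D reference library from replicate
standard runs.

Expected coordinates of a library entry are arithmetic means over the
replicate observations of the standard; the reference MS/MS spectrum
is taken from a single designated replicate (default: the one with
the highest total fragment intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from lipid4d.core import (
    LibraryEntry,
    Spectrum,
    ToleranceSet,
    ValidationError,
)


@dataclass
class StandardRunSet:
    """Replicate observations of one purchased standard."""

    name: str
    lipid_class: str
    adduct: str
    polarity: str
    observations: Sequence[tuple[float, float, float]]  # (mz, rt, ccs)
    spectra: Sequence[Optional[Spectrum]] = field(default_factory=list)
    reference_index: Optional[int] = None
    neutral_mass: Optional[float] = None
    formula: Optional[str] = None
    is_istd: bool = False

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise ValidationError(
                f"standard {self.name!r}: at least one replicate required"
            )
        if self.spectra and len(self.spectra) != len(self.observations):
            raise ValidationError(
                f"standard {self.name!r}: one spectrum slot per replicate"
            )


def choose_reference_spectrum(run_set: StandardRunSet) -> Optional[int]:
    """Index of the replicate whose MS/MS is stored with the entry.

    Explicit ``reference_index`` wins; otherwise the replicate with the
    highest total fragment intensity is used.
    """
    if run_set.reference_index is not None:
        return run_set.reference_index
    best, best_tic = None, -1.0
    for i, sp in enumerate(run_set.spectra):
        if sp is None:
            continue
        tic = sp.total_intensity()
        if tic > best_tic:
            best, best_tic = i, tic
    return best


def build_entry(run_set: StandardRunSet,
                spectrum_id: Optional[str] = None) -> LibraryEntry:
    """Average replicate coordinates into one library entry."""
    n = len(run_set.observations)
    mz = sum(o[0] for o in run_set.observations) / n
    rt = sum(o[1] for o in run_set.observations) / n
    ccs = sum(o[2] for o in run_set.observations) / n
    ref = choose_reference_spectrum(run_set)
    if spectrum_id is None and ref is not None:
        spectrum_id = f"{run_set.name}|{run_set.adduct}"
    return LibraryEntry(
        name=run_set.name,
        lipid_class=run_set.lipid_class,
        adduct=run_set.adduct,
        polarity=run_set.polarity,
        expected_mz=mz,
        expected_rt=rt,
        expected_ccs=ccs,
        neutral_mass=run_set.neutral_mass,
        formula=run_set.formula,
        spectrum_id=spectrum_id if ref is not None or spectrum_id else None,
        is_istd=run_set.is_istd,
    )


@dataclass
class MergeReport:
    appended: list[LibraryEntry] = field(default_factory=list)
    deduplicated: list[LibraryEntry] = field(default_factory=list)
    collisions: list[tuple[LibraryEntry, LibraryEntry]] = field(
        default_factory=list)


def _same_box(a: LibraryEntry, b: LibraryEntry, tol: ToleranceSet) -> bool:
    return a.adduct == b.adduct and tol.contains(
        a.expected_mz, a.expected_rt, a.expected_ccs,
        b.expected_mz, b.expected_rt, b.expected_ccs,
    )


def merge_curated(
    library: Sequence[LibraryEntry],
    new_entries: Sequence[LibraryEntry],
    tolerances: ToleranceSet | None = None,
) -> tuple[list[LibraryEntry], MergeReport]:
    """Merge curated additions into an existing library.

    A new entry matching an existing one in adduct and 4D coordinates
    AND name is dropped (existing kept). Same-coordinates but
    different-name pairs are both kept and flagged as collisions for
    manual curation.
    """
    tol = tolerances or ToleranceSet()
    merged = list(library)
    pols = {e.polarity for e in merged} | {e.polarity for e in new_entries}
    if len(pols) > 1:
        raise ValidationError(f"cross-polarity merge: {sorted(pols)}")
    report = MergeReport()
    for cand in new_entries:
        dup = None
        for existing in merged:
            if _same_box(existing, cand, tol):
                if existing.name == cand.name:
                    dup = existing
                    break
                report.collisions.append((existing, cand))
        if dup is not None:
            report.deduplicated.append(cand)
        else:
            merged.append(cand)
            report.appended.append(cand)
    return merged, report
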