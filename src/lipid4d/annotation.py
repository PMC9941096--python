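"""4D library annotation with banded confidence scoring.

Each candidate match is scored per dimension — precursor mass (ppm),
RT, CCS, optional isotope pattern, and optional MS/MS spectral match —
with sub-scores of 1 inside the tight band decaying linearly to 0 at
the loose band, and hard rejection beyond it. The composite score is
the unweighted mean of the available sub-scores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from lipid4d.core import (
    BucketTable,
    LibraryEntry,
    Spectrum,
    ValidationError,
)

TIER_FULL = "full_4D"
TIER_NO_MS2 = "no_MS2"
TIER_REJECTED = "rejected"


@dataclass(frozen=True)
class ScoreBands:
    """Tight/loose acceptance bands per scoring dimension."""

    ppm_tight: float = 1.0
    ppm_loose: float = 3.0
    rt_tight: float = 0.1
    rt_loose: float = 0.5
    ccs_tight: float = 0.2
    ccs_loose: float = 1.5
    ms2_good: float = 900.0
    ms2_cutoff: float = 500.0
    use_rt: bool = True
    use_ccs: bool = True

    def __post_init__(self) -> None:
        for t, l, lab in ((self.ppm_tight, self.ppm_loose, "ppm"),
                          (self.rt_tight, self.rt_loose, "rt"),
                          (self.ccs_tight, self.ccs_loose, "ccs")):
            if not 0 < t < l:
                raise ValidationError(f"{lab}: need 0 < tight < loose, got {t}, {l}")
        if not 0 <= self.ms2_cutoff <= self.ms2_good <= 1000:
            raise ValidationError(
                f"need 0 <= ms2_cutoff <= ms2_good <= 1000, got "
                f"{self.ms2_cutoff}, {self.ms2_good}"
            )


@dataclass
class Annotation:
    bucket_id: object
    entry: LibraryEntry
    ppm: float
    d_rt: float
    d_ccs: float
    sub_scores: dict[str, float]
    ms2_score: Optional[float]
    composite: float
    tier: str
    spectral_components: Optional[tuple[float, float, float]] = None


# ---------------------------------------------------------------------------
# spectral match


@dataclass(frozen=True)
class SpectralWeights:
    """Weights combining fit, reverse fit, and purity into [0, 1000]."""

    fit: float = 0.5
    reverse_fit: float = 0.3
    purity: float = 0.2


def _pair_peaks(query: Spectrum, reference: Spectrum,
                window: float) -> list[tuple[int, int]]:
    """Greedy nearest-m/z pairing within the window, one-to-one."""
    cand = []
    for i, qmz in enumerate(query.mz):
        for j, rmz in enumerate(reference.mz):
            d = abs(qmz - rmz)
            if d <= window:
                cand.append((d, i, j))
    pairs, used_q, used_r = [], set(), set()
    for _, i, j in sorted(cand):
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        pairs.append((i, j))
    return pairs


def spectral_score(
    query: Spectrum,
    reference: Spectrum,
    match_window_da: float = 0.01,
    weights: SpectralWeights | None = None,
) -> tuple[float, float, float, float]:
    """Return (fit, reverse_fit, purity, combined).

    fit: cosine over the union of peaks with square-root intensities;
    reverse_fit: the same cosine restricted to reference peaks;
    purity: fraction of total query intensity carried by matched peaks;
    combined: 1000 * weighted sum (default 0.5/0.3/0.2).
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValidationError("spectral_score requires non-empty spectra")
    if match_window_da <= 0:
        raise ValidationError("match_window_da must be > 0")
    w = weights or SpectralWeights()
    pairs = _pair_peaks(query, reference, match_window_da)
    matched_q = {i for i, _ in pairs}
    matched_r = {j for _, j in pairs}

    sq = np.sqrt(query.intensity)
    sr = np.sqrt(reference.intensity)

    # union vectors: one coordinate per matched pair + each unmatched peak
    qv, rv = [], []
    for i, j in pairs:
        qv.append(sq[i])
        rv.append(sr[j])
    for i in range(len(query)):
        if i not in matched_q:
            qv.append(sq[i])
            rv.append(0.0)
    for j in range(len(reference)):
        if j not in matched_r:
            qv.append(0.0)
            rv.append(sr[j])
    fit = _cosine(np.array(qv), np.array(rv))

    # reference-restricted vectors
    q_by_r = {j: sq[i] for i, j in pairs}
    rq = np.array([q_by_r.get(j, 0.0) for j in range(len(reference))])
    reverse_fit = _cosine(rq, sr)

    total_q = float(query.intensity.sum())
    purity = (
        float(sum(query.intensity[i] for i in matched_q)) / total_q
        if total_q > 0 else 0.0
    )
    combined = 1000.0 * (w.fit * fit + w.reverse_fit * reverse_fit
                         + w.purity * purity)
    return fit, reverse_fit, purity, combined


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# isotope pattern

# (abundance of A, A+1, A+2) per element, terrestrial averages
_ISOTOPES: dict[str, tuple[float, float, float]] = {
    "C": (0.9893, 0.0107, 0.0),
    "H": (0.999885, 0.000115, 0.0),
    "N": (0.99636, 0.00364, 0.0),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0, 0.0, 0.0),
    "S": (0.9499, 0.0075, 0.0425),
    "Na": (1.0, 0.0, 0.0),
    "Cl": (0.7576, 0.0, 0.2424),
    "K": (0.932581, 0.000117, 0.067302),
    "D": (1.0, 0.0, 0.0),  # enriched deuterium in labeled standards
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if not m.group(0):
            break
        sym, num = m.group(1), m.group(2)
        if sym not in _ISOTOPES:
            raise ValidationError(f"unknown element {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValidationError(f"cannot parse formula {formula!r}")
    return counts


def predicted_isotope_ratios(formula: str, n_extra: int = 2) -> np.ndarray:
    """Relative abundances of M+1.., M+n relative to M, by elementwise
    convolution of per-atom isotope distributions."""
    counts = parse_formula(formula)
    dist = np.array([1.0])
    for sym, n in counts.items():
        atom = np.array(_ISOTOPES[sym][: n_extra + 1])
        for _ in range(n):
            dist = np.convolve(dist, atom)[: n_extra + 1]
    if dist[0] <= 0:
        raise ValidationError(f"degenerate isotope distribution for {formula!r}")
    return dist[1: n_extra + 1] / dist[0]


def isotope_score(
    observed_ratios: Optional[Sequence[float]],
    formula: str,
) -> Optional[float]:
    """Score observed M+1/M (and optionally M+2/M) against prediction.

    Returns ``None`` when no isotope peaks were observed; otherwise
    max(0, 1 - mean relative deviation).
    """
    if observed_ratios is None or len(observed_ratios) == 0:
        return None
    predicted = predicted_isotope_ratios(formula, n_extra=len(observed_ratios))
    obs = np.asarray(observed_ratios, dtype=float)
    rel = np.abs(obs - predicted) / np.where(predicted > 0, predicted, 1.0)
    return float(max(0.0, 1.0 - rel.mean()))


# ---------------------------------------------------------------------------
# banded scoring


def _band_score(dev: float, tight: float, loose: float) -> Optional[float]:
    """1 inside tight, linear decay to 0 at loose, None beyond loose."""
    if dev <= tight:
        return 1.0
    if dev <= loose:
        return (loose - dev) / (loose - tight)
    return None


def score_annotation(
    bucket_id,
    bucket_mz: float,
    bucket_rt: float,
    bucket_ccs: float,
    entry: LibraryEntry,
    bands: ScoreBands | None = None,
    query_spectrum: Optional[Spectrum] = None,
    reference_spectrum: Optional[Spectrum] = None,
    observed_isotope_ratios: Optional[Sequence[float]] = None,
    spectral_weights: SpectralWeights | None = None,
) -> Annotation:
    """Score one bucket against one library entry."""
    bands = bands or ScoreBands()
    ppm = abs(bucket_mz - entry.expected_mz) / entry.expected_mz * 1e6
    d_rt = abs(bucket_rt - entry.expected_rt)
    d_ccs = abs(bucket_ccs - entry.expected_ccs)

    sub: dict[str, float] = {}
    rejected = False

    s = _band_score(ppm, bands.ppm_tight, bands.ppm_loose)
    if s is None:
        rejected = True
    else:
        sub["mass"] = s
    if bands.use_rt:
        s = _band_score(d_rt, bands.rt_tight, bands.rt_loose)
        if s is None:
            rejected = True
        else:
            sub["rt"] = s
    if bands.use_ccs:
        s = _band_score(d_ccs, bands.ccs_tight, bands.ccs_loose)
        if s is None:
            rejected = True
        else:
            sub["ccs"] = s

    ms2_score: Optional[float] = None
    components = None
    if query_spectrum is not None and reference_spectrum is not None:
        fit, rfit, purity, combined = spectral_score(
            query_spectrum, reference_spectrum, weights=spectral_weights)
        components = (fit, rfit, purity)
        ms2_score = combined
        if combined < bands.ms2_cutoff:
            rejected = True
        else:
            sub["ms2"] = min(1.0, (combined - bands.ms2_cutoff)
                             / (1000.0 - bands.ms2_cutoff))

    if entry.formula is not None:
        iso = isotope_score(observed_isotope_ratios, entry.formula)
        if iso is not None:
            sub["isotope"] = iso

    if rejected:
        tier = TIER_REJECTED
        composite = 0.0
    else:
        composite = float(np.mean(list(sub.values()))) if sub else 0.0
        tier = TIER_FULL if "ms2" in sub else TIER_NO_MS2
    return Annotation(
        bucket_id=bucket_id, entry=entry, ppm=ppm, d_rt=d_rt, d_ccs=d_ccs,
        sub_scores=sub, ms2_score=ms2_score, composite=composite, tier=tier,
        spectral_components=components,
    )


def annotate_table(
    table: BucketTable,
    library: Sequence[LibraryEntry],
    bands: ScoreBands | None = None,
    spectra: Optional[Mapping[str, Spectrum]] = None,
    query_spectra: Optional[Mapping[object, Spectrum]] = None,
    isotope_ratios: Optional[Mapping[object, Sequence[float]]] = None,
    spectral_weights: SpectralWeights | None = None,
) -> tuple[BucketTable, pd.DataFrame]:
    """Annotate every bucket with its best-scoring library entry.

    Candidates are entries passing every loose band (and the MS/MS
    cutoff when both spectra exist); the highest composite wins, ties
    broken by higher ms2 score, then smaller ppm, then smaller RT
    deviation. Buckets with more than one accepted candidate are
    flagged for curation.
    """
    bands = bands or ScoreBands()
    if len(library) == 0:
        raise ValidationError("annotate_table requires a non-empty library")
    pols = {e.polarity for e in library}
    if pols != {table.polarity}:
        raise ValidationError(
            f"library polarity {sorted(pols)} does not match table "
            f"{table.polarity!r}"
        )
    spectra = spectra or {}
    query_spectra = query_spectra or {}
    isotope_ratios = isotope_ratios or {}

    rows = []
    for bid, b in table.buckets.iterrows():
        accepted: list[Annotation] = []
        for entry in library:
            ref = spectra.get(entry.spectrum_id) if entry.spectrum_id else None
            ann = score_annotation(
                bid, b["mz"], b["rt"], b["ccs"], entry, bands,
                query_spectrum=query_spectra.get(bid),
                reference_spectrum=ref,
                observed_isotope_ratios=isotope_ratios.get(bid),
                spectral_weights=spectral_weights,
            )
            if ann.tier != TIER_REJECTED:
                accepted.append(ann)
        if not accepted:
            continue
        accepted.sort(key=lambda a: (
            -a.composite,
            -(a.ms2_score if a.ms2_score is not None else -1.0),
            a.ppm, a.d_rt,
        ))
        best = accepted[0]
        rows.append({
            "bucket_id": bid,
            "name": best.entry.name,
            "lipid_class": best.entry.lipid_class,
            "adduct": best.entry.adduct,
            "ppm": best.ppm,
            "d_rt": best.d_rt,
            "d_ccs": best.d_ccs,
            "ms2_score": best.ms2_score if best.ms2_score is not None else np.nan,
            "composite": best.composite,
            "tier": best.tier,
            "n_candidates": len(accepted),
            "needs_curation": len(accepted) > 1,
            "candidates": ";".join(a.entry.name for a in accepted),
        })
    annotations = pd.DataFrame(
        rows,
        columns=["bucket_id", "name", "lipid_class", "adduct", "ppm", "d_rt",
                 "d_ccs", "ms2_score", "composite", "tier", "n_candidates",
                 "needs_curation", "candidates"],
    ).set_index("bucket_id")
    out = table.copy()
    out.annotations = annotations
    return out, annotations
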