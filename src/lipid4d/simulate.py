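"""Seeded synthetic-data generators with exported ground truth.

Generates every input the pipeline consumes: 4D libraries laid on
per-class CCS-m/z trends, replicate feature runs with background and
dropout, 1:2 dilution ladders with flat artifact features, 7-point
power-law calibration series, and a multi-individual / multi-matrix /
multi-time-point concentration study. All randomness flows from a
single integer seed through numpy's Generator, so outputs are
reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lipid4d.core import (
    Feature4D,
    LibraryEntry,
    Spectrum,
    StudyDesign,
    ValidationError,
)
from lipid4d.quant import CalibrationPoint
from lipid4d.stats import ConcentrationMatrix


@dataclass(frozen=True)
class ClassSim:
    """Per-class coordinate model: an RT window and a linear CCS-m/z
    trend with scatter."""

    mz_range: tuple[float, float]
    rt_window: tuple[float, float]
    ccs_intercept: float      # Å²
    ccs_slope: float          # Å²/Da
    ccs_scatter: float = 1.0  # Å² SD around the trend


_DEFAULT_CLASSES: dict[str, ClassSim] = {
    "PC": ClassSim((700.0, 850.0), (8.0, 13.0), 120.0, 0.22, 1.5),
    "PE": ClassSim((680.0, 800.0), (9.0, 13.5), 110.0, 0.21, 1.5),
    "SM": ClassSim((650.0, 820.0), (7.5, 12.5), 100.0, 0.24, 1.5),
    "Cer": ClassSim((500.0, 700.0), (10.0, 15.0), 90.0, 0.28, 1.5),
    "TG": ClassSim((800.0, 1000.0), (15.0, 19.0), 140.0, 0.17, 1.5),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    classes: dict[str, ClassSim] = field(
        default_factory=lambda: dict(_DEFAULT_CLASSES))
    n_per_class: int = 10
    polarity: str = "negative"
    # measurement noise
    mz_ppm_sd: float = 0.3
    rt_sd: float = 0.01
    ccs_sd: float = 0.03
    area_cv: float = 0.1           # log-normal CV on areas
    dropout: float = 0.0
    # background model
    n_background: int = 50
    background_area_quantile: float = 0.25
    # dilution design
    dilution_volumes: tuple[float, ...] = (2.0, 1.0, 0.5, 0.25, 0.125, 0.0625)
    dilution_replicates: int = 3
    n_artifacts: int = 10
    # calibration truth
    cal_c1: float = 1.2
    cal_c2: float = 1.1
    cal_c_is: float = 50.0
    cal_levels: tuple[float, ...] = (400.0, 200.0, 100.0, 50.0, 25.0, 12.5, 6.25)
    cal_noise_cv: float = 0.0
    # study design
    individuals: tuple[str, ...] = ("P1", "P2", "P3", "P4")
    matrices: tuple[str, ...] = ("plasma", "serum", "blood", "DBS_venous",
                                 "DBS_finger")
    time_points: tuple[str, ...] = ("day0", "week1", "month1")
    matrix_pair_offset: float = 0.03   # plasma~serum, DBS pair (log10)
    matrix_blood_offset: float = 0.5   # blood vs the rest (log10)
    individual_sd: float = 0.05        # per-person baseline shift (log10)
    time_sd: float = 0.02              # within-matrix time scatter (log10)
    high_variance_class: str = "TG"
    high_variance_time_sd: float = 0.15

    def __post_init__(self) -> None:
        if len(self.classes) < 1:
            raise ValidationError("at least one lipid class required")
        vols = self.dilution_volumes
        if any(b >= a for a, b in zip(vols, vols[1:])):
            raise ValidationError("dilution volumes must be strictly decreasing")
        for lab, v in (("mz_ppm_sd", self.mz_ppm_sd), ("rt_sd", self.rt_sd),
                       ("ccs_sd", self.ccs_sd), ("area_cv", self.area_cv)):
            if v < 0:
                raise ValidationError(f"{lab} must be >= 0")


# ---------------------------------------------------------------------------
# library


def gen_library(config: SimulationConfig,
                seed: Optional[int] = None) -> tuple[list[LibraryEntry], pd.DataFrame]:
    """Library entries on per-class CCS-m/z trends, plus a truth table."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    entries: list[LibraryEntry] = []
    truth_rows = []
    for cls, sim in config.classes.items():
        mzs = np.sort(rng.uniform(*sim.mz_range, size=config.n_per_class))
        # enforce distinct coordinates: nudge near-identical m/z apart
        for i in range(1, len(mzs)):
            if mzs[i] - mzs[i - 1] < 0.01:
                mzs[i] = mzs[i - 1] + 0.01 + rng.uniform(0, 0.005)
        rts = rng.uniform(*sim.rt_window, size=config.n_per_class)
        ccs = (sim.ccs_intercept + sim.ccs_slope * mzs
               + rng.normal(0, sim.ccs_scatter, size=config.n_per_class))
        for i in range(config.n_per_class):
            name = f"{cls} {i:02d}"
            entries.append(LibraryEntry(
                name=name, lipid_class=cls, adduct="[M-H]-",
                polarity=config.polarity,
                expected_mz=float(mzs[i]), expected_rt=float(rts[i]),
                expected_ccs=float(ccs[i]),
                neutral_mass=float(mzs[i]) + 1.007276,
                spectrum_id=f"sp|{name}",
            ))
            truth_rows.append({"name": name, "lipid_class": cls,
                               "mz": float(mzs[i]), "rt": float(rts[i]),
                               "ccs": float(ccs[i])})
    return entries, pd.DataFrame(truth_rows)


def gen_spectra(entries: Sequence[LibraryEntry],
                seed: int = 0,
                n_peaks: tuple[int, int] = (5, 10)) -> dict[str, Spectrum]:
    """Reference MS/MS spectra, one per entry, keyed by spectrum_id."""
    rng = np.random.default_rng(seed)
    store: dict[str, Spectrum] = {}
    for e in entries:
        if e.spectrum_id is None:
            continue
        n = int(rng.integers(n_peaks[0], n_peaks[1] + 1))
        mz = np.sort(rng.uniform(100.0, e.expected_mz - 1.0, size=n))
        mz += np.arange(n) * 1e-4  # guarantee strict increase
        inten = rng.uniform(5.0, 100.0, size=n)
        store[e.spectrum_id] = Spectrum(
            np.column_stack([mz, inten]), precursor_mz=e.expected_mz,
            polarity=e.polarity)
    return store


# ---------------------------------------------------------------------------
# replicate runs


def _jitter(rng: np.random.Generator, mz: float, rt: float, ccs: float,
            area: float, config: SimulationConfig) -> tuple[float, float, float, float]:
    mz_j = mz * (1.0 + rng.normal(0, config.mz_ppm_sd) * 1e-6)
    rt_j = max(0.0, rt + rng.normal(0, config.rt_sd))
    ccs_j = ccs + rng.normal(0, config.ccs_sd)
    if config.area_cv > 0:
        sigma = np.sqrt(np.log(1.0 + config.area_cv ** 2))
        area_j = area * rng.lognormal(-sigma ** 2 / 2.0, sigma)
    else:
        area_j = area
    return mz_j, rt_j, ccs_j, area_j


def gen_runs(
    library: Sequence[LibraryEntry],
    concentrations: dict[str, float],
    config: SimulationConfig,
    n_replicates: int = 32,
    seed: Optional[int] = None,
    sample_prefix: str = "rep",
) -> tuple[list[list[Feature4D]], pd.DataFrame]:
    """Replicate feature runs: jittered library features + uniform
    background + Bernoulli dropout. Truth maps every feature to its
    source entry or 'background'."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    true_areas = np.array([concentrations[e.name] for e in library])
    bg_area = (np.quantile(true_areas, config.background_area_quantile)
               if len(true_areas) else 1000.0)
    mz_lo = min(e.expected_mz for e in library) - 5.0
    mz_hi = max(e.expected_mz for e in library) + 5.0
    rt_lo = min(e.expected_rt for e in library)
    rt_hi = max(e.expected_rt for e in library)
    ccs_lo = min(e.expected_ccs for e in library) - 5.0
    ccs_hi = max(e.expected_ccs for e in library) + 5.0

    runs: list[list[Feature4D]] = []
    truth_rows = []
    for r in range(n_replicates):
        sid = f"{sample_prefix}{r:03d}"
        run: list[Feature4D] = []
        for e in library:
            if config.dropout > 0 and rng.random() < config.dropout:
                continue
            mz, rt, ccs, area = _jitter(
                rng, e.expected_mz, e.expected_rt, e.expected_ccs,
                concentrations[e.name], config)
            run.append(Feature4D(mz=mz, rt=rt, ccs=ccs, area=area,
                                 polarity=config.polarity, sample_id=sid))
            truth_rows.append({"sample_id": sid, "source": e.name,
                               "mz": mz, "rt": rt, "ccs": ccs, "area": area})
        for b in range(config.n_background):
            mz = rng.uniform(mz_lo, mz_hi)
            rt = rng.uniform(rt_lo, rt_hi)
            ccs = rng.uniform(ccs_lo, ccs_hi)
            area = bg_area * rng.lognormal(0, 0.3)
            run.append(Feature4D(mz=mz, rt=rt, ccs=ccs, area=area,
                                 polarity=config.polarity, sample_id=sid))
            truth_rows.append({"sample_id": sid, "source": "background",
                               "mz": mz, "rt": rt, "ccs": ccs, "area": area})
        runs.append(run)
    return runs, pd.DataFrame(truth_rows)


def gen_blank_run(
    background_truth: pd.DataFrame,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> list[Feature4D]:
    """A solvent-blank run re-observing the background population.

    Takes the background rows of a gen_runs truth table (first
    replicate) and re-jitters the coordinates, so blank subtraction has
    realistic (not byte-identical) twins to remove.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    first = background_truth[background_truth["source"] == "background"]
    first = first[first["sample_id"] == first["sample_id"].iloc[0]]
    blank = []
    for _, row in first.iterrows():
        mz, rt, ccs, area = _jitter(rng, row["mz"], row["rt"], row["ccs"],
                                    row["area"], config)
        blank.append(Feature4D(mz=mz, rt=rt, ccs=ccs, area=area,
                               polarity=config.polarity, sample_id="blank"))
    return blank


# ---------------------------------------------------------------------------
# dilution experiment


def gen_dilution_experiment(
    library: Sequence[LibraryEntry],
    config: SimulationConfig,
    seed: Optional[int] = None,
    base_area: float = 1.0e5,
) -> tuple[list[list[Feature4D]], StudyDesign, pd.DataFrame]:
    """Dilution ladder runs: true-lipid areas proportional to the
    volume on column, plus flat artifact features. Returns (runs,
    design, truth) where truth labels each coordinate as responsive or
    flat."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    # artifact features occupy their own coordinate space, clear of the library
    art = []
    rt_hi = max(e.expected_rt for e in library)
    for a in range(config.n_artifacts):
        art.append((
            1000.0 + 10.0 * a + rng.uniform(0, 1),
            rt_hi + 2.0 + 0.5 * a,
            300.0 + 5.0 * a,
        ))
    runs: list[list[Feature4D]] = []
    design_rows = []
    truth_rows = [{"name": e.name, "kind": "responsive", "mz": e.expected_mz,
                   "rt": e.expected_rt, "ccs": e.expected_ccs}
                  for e in library]
    truth_rows += [{"name": f"artifact{a:02d}", "kind": "flat", "mz": c[0],
                    "rt": c[1], "ccs": c[2]} for a, c in enumerate(art)]
    for li, vol in enumerate(config.dilution_volumes):
        for rep in range(config.dilution_replicates):
            sid = f"dil_L{li}_r{rep}"
            run: list[Feature4D] = []
            for e in library:
                mz, rt, ccs, area = _jitter(
                    rng, e.expected_mz, e.expected_rt, e.expected_ccs,
                    base_area * vol, config)
                run.append(Feature4D(mz=mz, rt=rt, ccs=ccs, area=area,
                                     polarity=config.polarity, sample_id=sid))
            for a, (amz, art_rt, accs) in enumerate(art):
                mz, rt, ccs, area = _jitter(rng, amz, art_rt, accs,
                                            base_area, config)
                run.append(Feature4D(mz=mz, rt=rt, ccs=ccs, area=area,
                                     polarity=config.polarity, sample_id=sid))
            runs.append(run)
            design_rows.append({"sample_id": sid, "batch_role": "sample",
                                "dilution_volume": vol})
    design = StudyDesign(pd.DataFrame(design_rows))
    return runs, design, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# calibration series


def gen_calibration(
    config: SimulationConfig,
    seed: Optional[int] = None,
    istd_area: float = 1.0e5,
) -> tuple[list[CalibrationPoint], dict]:
    """7-point power-law calibration series with optional log-normal
    noise; truth carries (c1, c2, C_IS)."""
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    points = []
    for c_es in config.cal_levels:
        conc_ratio = c_es / config.cal_c_is
        area_ratio = config.cal_c1 * conc_ratio ** (1.0 / config.cal_c2)
        if config.cal_noise_cv > 0:
            sigma = np.sqrt(np.log(1.0 + config.cal_noise_cv ** 2))
            area_ratio *= rng.lognormal(-sigma ** 2 / 2.0, sigma)
        points.append(CalibrationPoint(
            c_es=c_es, c_is=config.cal_c_is,
            area_es=area_ratio * istd_area, area_is=istd_area))
    truth = {"c1": config.cal_c1, "c2": config.cal_c2,
             "c_is": config.cal_c_is, "levels": list(config.cal_levels)}
    return points, truth


# ---------------------------------------------------------------------------
# study


def gen_study(
    config: SimulationConfig,
    seed: Optional[int] = None,
    base_conc: float = 1.0,
) -> tuple[ConcentrationMatrix, pd.DataFrame]:
    """Multi-matrix concentration study with known effect structure.

    Per-matrix mean profiles put plasma~serum and DBS_venous~
    DBS_finger close together (small log offsets) and blood far from
    everything; time points are stable except one configured
    high-variance class. Returns (ConcentrationMatrix, truth table of
    per-lipid matrix offsets).
    """
    if len(config.individuals) < 2:
        raise ValidationError("gen_study needs >= 2 individuals")
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    lipids = [f"{cls} {i:02d}" for cls in config.classes
              for i in range(config.n_per_class)]
    classes = [cls for cls in config.classes
               for _ in range(config.n_per_class)]
    n_lip = len(lipids)
    base = np.log10(base_conc) + rng.normal(0, 0.4, size=n_lip)

    # matrix offsets: paired matrices share a profile +/- a small shift
    pair_profile_1 = rng.normal(0, config.matrix_pair_offset, size=n_lip)
    pair_profile_2 = rng.normal(0, config.matrix_pair_offset, size=n_lip)
    blood_profile = rng.normal(0, config.matrix_blood_offset, size=n_lip)
    offsets = {}
    for m in config.matrices:
        if m in ("plasma", "serum"):
            delta = rng.normal(0, config.matrix_pair_offset / 2, size=n_lip)
            offsets[m] = pair_profile_1 + delta
        elif m.startswith("DBS"):
            delta = rng.normal(0, config.matrix_pair_offset / 2, size=n_lip)
            offsets[m] = pair_profile_2 + delta
        elif m == "blood":
            offsets[m] = blood_profile
        else:
            offsets[m] = rng.normal(0, config.matrix_blood_offset, size=n_lip)

    rows = []
    design_rows = []
    index = []
    for ind in config.individuals:
        ind_shift = rng.normal(0, config.individual_sd, size=n_lip)
        for m in config.matrices:
            for tp in config.time_points:
                sid = f"{ind}_{m}_{tp}"
                tsd = np.where(
                    np.array(classes) == config.high_variance_class,
                    config.high_variance_time_sd, config.time_sd)
                log_conc = (base + offsets[m] + ind_shift
                            + rng.normal(0, 1, size=n_lip) * tsd)
                rows.append(10.0 ** log_conc)
                index.append(sid)
                design_rows.append({"sample_id": sid, "individual": ind,
                                    "matrix": m, "time_point": tp,
                                    "batch_role": "sample"})
    values = pd.DataFrame(rows, index=pd.Index(index, name="sample_id"),
                          columns=lipids)
    design = StudyDesign(pd.DataFrame(design_rows))
    truth = pd.DataFrame(
        {"lipid": lipids, "lipid_class": classes, "base_log10": base,
         **{f"offset_{m}": offsets[m] for m in config.matrices}})
    return ConcentrationMatrix(values=values, design=design), truth
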