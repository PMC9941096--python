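"""Internal-standard molar quantification.

Multi-point calibration fits areaRatio = c1 * concRatio**(1/c2) by
ordinary least squares in log-log space; concentrations are then
back-calculated as A = ((area_analyte/area_istd)/c1)**c2 * C_IS [ng/mL
on column], B = A * final_volume/sample_volume [ng/mL in sample], and
C = B / adduct_mass [nmol/mL]. Detection limits follow LLOD = 3.3*s/s
and LLOQ = 10*s/s with sigma the residual SD and s the slope of an
auxiliary linear response-vs-concentration regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from lipid4d.core import StudyDesign, ValidationError

ACCURACY_BAND = (80.0, 120.0)  # accepted back-calculation accuracy [%]


@dataclass(frozen=True)
class CalibrationPoint:
    """One external-standard dilution point spiked with ISTD."""

    c_es: float      # nominal external-standard concentration [ng/mL]
    c_is: float      # ISTD concentration [ng/mL]
    area_es: float
    area_is: float

    def __post_init__(self) -> None:
        for lab, v in (("c_es", self.c_es), ("c_is", self.c_is),
                       ("area_es", self.area_es), ("area_is", self.area_is)):
            if not v > 0:
                raise ValidationError(f"{lab} must be > 0, got {v}")

    @property
    def conc_ratio(self) -> float:
        return self.c_es / self.c_is

    @property
    def area_ratio(self) -> float:
        return self.area_es / self.area_is


@dataclass
class CalibrationModel:
    c1: float
    c2: float
    c_is: float
    accuracies: list[float]            # back-calculated/nominal, in %
    r_squared: float
    sigma: float                       # residual SD of the linear response fit
    slope_s: float                     # slope of the linear response fit
    llod: float
    lloq: float
    flagged_points: list[int] = field(default_factory=list)

    def back_calculate(self, area_ratio: float) -> float:
        """Concentration ratio reproducing the observed area ratio."""
        return (area_ratio / self.c1) ** self.c2


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationModel:
    """Fit the power-law calibration and detection-limit statistics."""
    if len(points) < 3:
        raise ValidationError(f"need >= 3 calibration points, got {len(points)}")
    conc = np.array([p.conc_ratio for p in points])
    area = np.array([p.area_ratio for p in points])
    if len(np.unique(conc)) < 3:
        raise ValidationError("calibration points must span >= 3 distinct "
                              "concentrations")
    c_is_vals = {p.c_is for p in points}
    if len(c_is_vals) != 1:
        raise ValidationError("all calibration points must share one ISTD "
                              "concentration")

    # log-log OLS: log(area) = log(c1) + (1/c2) log(conc)
    lx, ly = np.log(conc), np.log(area)
    slope, intercept = np.polyfit(lx, ly, 1)
    c1 = float(np.exp(intercept))
    c2 = float(1.0 / slope)
    resid = ly - (intercept + slope * lx)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

    # auxiliary linear regression of response on concentration (ICH limits)
    s_lin, b_lin = np.polyfit(conc, area, 1)
    lin_resid = area - (b_lin + s_lin * conc)
    dof = max(len(points) - 2, 1)
    sigma = float(np.sqrt(np.sum(lin_resid ** 2) / dof))
    slope_s = float(s_lin)
    llod, lloq = llod_lloq(sigma, slope_s) if slope_s > 0 else (np.nan, np.nan)

    back = (area / c1) ** c2
    accuracies = list(100.0 * back / conc)
    flagged = [i for i, a in enumerate(accuracies)
               if not ACCURACY_BAND[0] <= a <= ACCURACY_BAND[1]]
    return CalibrationModel(
        c1=c1, c2=c2, c_is=points[0].c_is, accuracies=accuracies,
        r_squared=r_squared, sigma=sigma, slope_s=slope_s,
        llod=llod, lloq=lloq, flagged_points=flagged,
    )


@dataclass(frozen=True)
class QuantContext:
    """Volumes and per-analyte constants for concentration conversion."""

    final_volume: float = 360.0   # µL after re-dissolution
    sample_volume: float = 20.0   # µL matrix extracted
    adduct_masses: Mapping[str, float] = field(default_factory=dict)
    istd_assignment: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    exclude_recursive: bool = True

    def __post_init__(self) -> None:
        if not (self.final_volume > 0 and self.sample_volume > 0):
            raise ValidationError("volumes must be > 0")

    @property
    def dilution_factor(self) -> float:
        return self.final_volume / self.sample_volume


def _convert(a: float, adduct_mass: float, ctx: QuantContext) -> tuple[float, float, float]:
    b = a * ctx.dilution_factor
    c = b / adduct_mass
    return a, b, c


def quantify_multipoint(
    area_analyte: float,
    area_istd: float,
    model: CalibrationModel,
    ctx: QuantContext,
    analyte: Optional[str] = None,
    adduct_mass: Optional[float] = None,
) -> tuple[float, float, float]:
    """Return (A ng/mL on column, B ng/mL in sample, C nmol/mL)."""
    if area_istd <= 0:
        raise ValidationError("ISTD area must be > 0")
    if area_analyte < 0:
        raise ValidationError("analyte area must be >= 0")
    mass = _resolve_mass(analyte, adduct_mass, ctx)
    a = model.back_calculate(area_analyte / area_istd) * model.c_is
    return _convert(a, mass, ctx)


def quantify_onepoint(
    area_analyte: float,
    area_istd: float,
    calibrant_point: CalibrationPoint,
    ctx: QuantContext,
    analyte: Optional[str] = None,
    adduct_mass: Optional[float] = None,
) -> tuple[float, float, float]:
    """Single-calibrant quantification via m = areaRatio_ES/concRatio_ES."""
    if area_istd <= 0:
        raise ValidationError("ISTD area must be > 0")
    mass = _resolve_mass(analyte, adduct_mass, ctx)
    m = calibrant_point.area_ratio / calibrant_point.conc_ratio
    a = (area_analyte / area_istd) / m * calibrant_point.c_is
    return _convert(a, mass, ctx)


def _resolve_mass(analyte: Optional[str], adduct_mass: Optional[float],
                  ctx: QuantContext) -> float:
    if adduct_mass is None and analyte is not None:
        adduct_mass = ctx.adduct_masses.get(analyte)
    if adduct_mass is None:
        raise ValidationError(
            f"no adduct mass known for analyte {analyte!r}"
        )
    if adduct_mass <= 0:
        raise ValidationError(f"adduct mass must be > 0, got {adduct_mass}")
    return adduct_mass


def llod_lloq(sigma: float, slope_s: float) -> tuple[float, float]:
    """Detection limits: (3.3 * sigma / s, 10 * sigma / s)."""
    if slope_s <= 0:
        raise ValidationError(f"slope must be > 0, got {slope_s}")
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    return 3.3 * sigma / slope_s, 10.0 * sigma / slope_s


def recovery_matrix_effect(
    groups: Mapping[str, Sequence[float]],
) -> dict[str, float]:
    """Ratio-of-means percentages from spiking-scheme area groups.

    recovery% = 100*mean(pre_spike)/mean(post_spike);
    matrix_effect% = 100*mean(post_spike)/mean(neat); the analogous
    ratios are reported for a ``no_extraction`` group when present.
    """
    means = {}
    for key, vals in groups.items():
        if len(vals) == 0:
            raise ValidationError(f"group {key!r} is empty")
        means[key] = float(np.mean(vals))
    out: dict[str, float] = {}
    if "pre_spike" in means and "post_spike" in means:
        out["recovery_pct"] = 100.0 * means["pre_spike"] / means["post_spike"]
    if "post_spike" in means and "neat" in means:
        out["matrix_effect_pct"] = 100.0 * means["post_spike"] / means["neat"]
    if "no_extraction" in means and "post_spike" in means:
        out["recovery_no_extraction_pct"] = (
            100.0 * means["no_extraction"] / means["post_spike"])
    if "no_extraction" in means and "neat" in means:
        out["matrix_effect_no_extraction_pct"] = (
            100.0 * means["no_extraction"] / means["neat"])
    return out


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation: 100 * sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("cv_percent needs >= 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("cv_percent undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass
class BatchReport:
    n_calibration_sets: int
    n_qc: int
    first_is_qc: bool
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_batch(design: StudyDesign) -> BatchReport:
    """Check the acquisition layout: >=3 calibration sets, >=3 QCs,
    and a QC as the first injection."""
    roles = design.table["batch_role"].astype(str)
    cal_mask = roles.str.startswith("calibration_point")
    # a "set" is one pass through the calibration levels: count level-1
    # occurrences (or contiguous calibration blocks when unlabeled)
    level1 = (roles == "calibration_point_1").sum()
    if level1 > 0:
        n_sets = int(level1)
    else:
        blocks = (cal_mask & ~cal_mask.shift(fill_value=False)).sum()
        n_sets = int(blocks)
    n_qc = int((roles == "QC").sum())
    first_is_qc = bool(len(roles) > 0 and roles.iloc[0] == "QC")
    flags = []
    if n_sets < 3:
        flags.append(f"only {n_sets} calibration sets (need >= 3)")
    if n_qc < 3:
        flags.append(f"only {n_qc} QC samples (need >= 3)")
    if not first_is_qc:
        flags.append("first injection is not a QC")
    return BatchReport(n_calibration_sets=n_sets, n_qc=n_qc,
                       first_is_qc=first_is_qc, flags=flags)


def quantify_bucket_table(
    table,
    annotations: pd.DataFrame,
    models: Mapping[str, CalibrationModel],
    istd_areas: Mapping[str, float] | pd.Series,
    ctx: QuantContext,
) -> pd.DataFrame:
    """Quantify annotated buckets across samples.

    ``models`` maps lipid class -> CalibrationModel; ``istd_areas``
    maps sample_id -> ISTD peak area (per the class's assigned ISTD).
    Cells with recursive provenance are excluded from quantification.
    """
    from lipid4d.core.types import PROV_PRIMARY

    rows = []
    for bid, ann in annotations.iterrows():
        cls = ann["lipid_class"]
        if cls not in models:
            continue
        model = models[cls]
        mass = ctx.adduct_masses.get(ann["name"])
        if mass is None:
            continue
        for sid in table.sample_ids:
            prov = table.provenance.at[bid, sid]
            if prov != PROV_PRIMARY and ctx.exclude_recursive:
                continue
            area = table.values.at[bid, sid]
            if not np.isfinite(area):
                continue
            a, b, c = quantify_multipoint(
                float(area), float(istd_areas[sid]), model, ctx,
                adduct_mass=mass)
            rows.append({"bucket_id": bid, "name": ann["name"],
                         "lipid_class": cls, "sample_id": sid,
                         "A_ng_ml": a, "B_ng_ml": b, "C_nmol_ml": c})
    return pd.DataFrame(rows, columns=["bucket_id", "name", "lipid_class",
                                       "sample_id", "A_ng_ml", "B_ng_ml",
                                       "C_nmol_ml"])
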