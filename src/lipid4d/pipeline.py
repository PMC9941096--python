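"""Cross-sample feature selection chain.

Stages: greedy 4D alignment into buckets, recursive gap-filling at a
lowered detection threshold, presence filtering, blank (background)
subtraction, cross-experiment overlap matching, and the dilution
response filter. Every stage returns a subset of its input buckets,
so chained counts are non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lipid4d.core import (
    BucketTable,
    Feature4D,
    ToleranceSet,
    ValidationError,
)
from lipid4d.core.types import PROV_MISSING, PROV_PRIMARY, PROV_RECURSIVE


@dataclass(frozen=True)
class PresenceRule:
    """Two-threshold presence rule.

    A bucket is kept only if it was initially detected in at least
    ``t_seed`` of ``n_samples`` analyses and present in at least
    ``t_final`` analyses after recursive gap-filling.
    """

    n_samples: int
    t_seed: int
    t_final: int

    def __post_init__(self) -> None:
        if not (1 <= self.t_seed <= self.t_final <= self.n_samples):
            raise ValidationError(
                f"need 1 <= t_seed <= t_final <= n_samples, got "
                f"({self.t_seed}, {self.t_final}, {self.n_samples})"
            )


@dataclass(frozen=True)
class DilutionFilterParams:
    r_min: float = 0.9
    sd_min: float = 0.1
    normalization: str = "max_scale"  # max_scale | none | log10

    def __post_init__(self) -> None:
        if not -1 <= self.r_min <= 1:
            raise ValidationError(f"r_min must be in [-1, 1], got {self.r_min}")
        if self.sd_min < 0:
            raise ValidationError(f"sd_min must be >= 0, got {self.sd_min}")
        if self.normalization not in ("max_scale", "none", "log10"):
            raise ValidationError(
                f"unknown normalization {self.normalization!r}"
            )


def _pooled(runs: Sequence[Sequence[Feature4D]]) -> tuple[list[Feature4D], list[str]]:
    """Attach sample ids, check single polarity, pool features."""
    polarities = {f.polarity for run in runs for f in run}
    if len(polarities) > 1:
        raise ValidationError(f"mixed polarities in runs: {sorted(polarities)}")
    pooled: list[Feature4D] = []
    sample_ids: list[str] = []
    for i, run in enumerate(runs):
        ids = {f.sample_id for f in run if f.sample_id is not None}
        sid = ids.pop() if len(ids) == 1 else f"run{i:03d}"
        sample_ids.append(sid)
        for f in run:
            pooled.append(f if f.sample_id == sid else f.with_sample(sid))
    return pooled, sample_ids


def align_buckets(
    runs: Sequence[Sequence[Feature4D]],
    tolerances: ToleranceSet | None = None,
) -> BucketTable:
    """Greedy centroid clustering of features pooled across runs.

    Features are sorted by descending area (ties: mz, rt, ccs,
    sample_id); the highest unassigned feature seeds a bucket and
    collects, per sample, the nearest unassigned feature inside the
    seed's tolerance box (normalized Chebyshev distance). Consensus
    coordinates are the area-weighted means of the members.
    """
    if len(runs) < 1:
        raise ValidationError("align_buckets needs at least one run")
    tol = tolerances or ToleranceSet()
    pooled, sample_ids = _pooled(runs)
    polarity = pooled[0].polarity if pooled else "negative"

    order = sorted(
        range(len(pooled)),
        key=lambda i: (-pooled[i].area, pooled[i].mz, pooled[i].rt,
                       pooled[i].ccs, pooled[i].sample_id),
    )
    mz = np.array([f.mz for f in pooled])
    rt = np.array([f.rt for f in pooled])
    ccs = np.array([f.ccs for f in pooled])
    assigned = np.zeros(len(pooled), dtype=bool)

    bucket_meta: list[dict] = []
    members: dict[int, dict[str, Feature4D]] = {}
    values = []
    for i in order:
        if assigned[i]:
            continue
        seed = pooled[i]
        w = tol.mz_window(seed.mz)
        in_box = (
            ~assigned
            & (np.abs(mz - seed.mz) < w)
            & (np.abs(rt - seed.rt) <= tol.d_rt)
            & (np.abs(ccs - seed.ccs) <= tol.d_ccs)
        )
        candidates = np.flatnonzero(in_box)
        chosen: dict[str, int] = {}
        for j in candidates:
            f = pooled[j]
            sid = f.sample_id
            if sid not in chosen:
                chosen[sid] = j
                continue
            cur = pooled[chosen[sid]]
            d_new = tol.normalized_distance(seed.mz, seed.rt, seed.ccs,
                                            f.mz, f.rt, f.ccs)
            d_cur = tol.normalized_distance(seed.mz, seed.rt, seed.ccs,
                                            cur.mz, cur.rt, cur.ccs)
            if (d_new, f.mz, f.rt, f.ccs) < (d_cur, cur.mz, cur.rt, cur.ccs):
                chosen[sid] = j
        bid = len(bucket_meta)
        mem = {sid: pooled[j] for sid, j in chosen.items()}
        for j in chosen.values():
            assigned[j] = True
        areas = np.array([f.area for f in mem.values()])
        weights = areas if areas.sum() > 0 else np.ones_like(areas)
        coords = np.array([[f.mz, f.rt, f.ccs] for f in mem.values()])
        cons = np.average(coords, axis=0, weights=weights)
        bucket_meta.append({"mz": cons[0], "rt": cons[1], "ccs": cons[2],
                            "seed_mz": seed.mz, "seed_rt": seed.rt,
                            "seed_ccs": seed.ccs})
        members[bid] = mem
        values.append({sid: f.area for sid, f in mem.items()})

    index = pd.RangeIndex(len(bucket_meta), name="bucket_id")
    buckets = pd.DataFrame(bucket_meta, index=index,
                           columns=["mz", "rt", "ccs", "seed_mz", "seed_rt",
                                    "seed_ccs"])
    vals = pd.DataFrame(values, index=index, columns=sample_ids, dtype=float)
    prov = pd.DataFrame(
        np.where(vals.notna(), PROV_PRIMARY, PROV_MISSING),
        index=index, columns=sample_ids,
    )
    return BucketTable(buckets=buckets, values=vals, provenance=prov,
                       polarity=polarity, members=members)


def recursive_fill(
    table: BucketTable,
    low_threshold_runs: Sequence[Sequence[Feature4D]],
    tolerances: ToleranceSet | None = None,
) -> BucketTable:
    """Fill missing (bucket, sample) cells from low-threshold re-runs.

    The nearest in-box low-threshold feature (normalized Chebyshev
    distance to the bucket consensus; tie broken by lower m/z) is
    inserted with provenance ``recursive``. Primary values are never
    overwritten.
    """
    tol = tolerances or ToleranceSet()
    pooled, sample_ids = _pooled(low_threshold_runs)
    unknown = sorted(set(sample_ids) - set(table.sample_ids))
    if unknown:
        raise ValidationError(
            f"low-threshold samples absent from bucket table: {unknown}"
        )
    by_sample: dict[str, list[Feature4D]] = {}
    for f in pooled:
        by_sample.setdefault(f.sample_id, []).append(f)

    out = table.copy()
    for bid, row in out.buckets.iterrows():
        for sid in out.sample_ids:
            if out.provenance.at[bid, sid] != PROV_MISSING:
                continue
            best, best_key = None, None
            for f in by_sample.get(sid, []):
                if not tol.contains(row["mz"], row["rt"], row["ccs"],
                                    f.mz, f.rt, f.ccs):
                    continue
                d = tol.normalized_distance(row["mz"], row["rt"], row["ccs"],
                                            f.mz, f.rt, f.ccs)
                key = (d, f.mz, f.rt, f.ccs)
                if best_key is None or key < best_key:
                    best, best_key = f, key
            if best is not None:
                out.values.at[bid, sid] = best.area
                out.provenance.at[bid, sid] = PROV_RECURSIVE
                if out.members is not None:
                    out.members.setdefault(bid, {})[sid] = best
    return out


def presence_filter(
    table: BucketTable, rule: PresenceRule
) -> tuple[BucketTable, pd.DataFrame]:
    """Keep buckets meeting both presence thresholds; report counts."""
    counts = table.presence_counts()
    keep = (counts["n_primary"] >= rule.t_seed) & (
        counts["n_filled"] >= rule.t_final
    )
    report = counts.assign(kept=keep)
    return table.subset(table.buckets.index[keep]), report


def background_subtract(
    table: BucketTable,
    blank_run: Sequence[Feature4D],
    tolerances: ToleranceSet | None = None,
) -> tuple[BucketTable, pd.DataFrame]:
    """Remove buckets whose tolerance box contains any blank feature."""
    tol = tolerances or ToleranceSet()
    removed = []
    keep_ids = []
    for bid, row in table.buckets.iterrows():
        hit = next(
            (f for f in blank_run
             if tol.contains(row["mz"], row["rt"], row["ccs"],
                             f.mz, f.rt, f.ccs)),
            None,
        )
        if hit is None:
            keep_ids.append(bid)
        else:
            removed.append({"bucket_id": bid, "blank_mz": hit.mz,
                            "blank_rt": hit.rt, "blank_ccs": hit.ccs})
    log = pd.DataFrame(removed, columns=["bucket_id", "blank_mz", "blank_rt",
                                         "blank_ccs"]).set_index("bucket_id")
    return table.subset(keep_ids), log


@dataclass
class OverlapResult:
    pairs: list[tuple[Feature4D, Feature4D]] = field(default_factory=list)
    unmatched_a: list[Feature4D] = field(default_factory=list)
    unmatched_b: list[Feature4D] = field(default_factory=list)


def overlap_match(
    features_a: Sequence[Feature4D],
    features_b: Sequence[Feature4D],
    tolerances: ToleranceSet | None = None,
    one_to_one: bool = True,
) -> OverlapResult:
    """Match features across two experiments inside the tolerance box.

    Default is one-to-one greedy pairing by ascending normalized
    Chebyshev distance; ``one_to_one=False`` returns every in-box pair.
    """
    tol = tolerances or ToleranceSet()
    pols = {f.polarity for f in features_a} | {f.polarity for f in features_b}
    if len(pols) > 1:
        raise ValidationError(f"mixed polarities in overlap: {sorted(pols)}")
    cand = []
    for ia, fa in enumerate(features_a):
        for ib, fb in enumerate(features_b):
            if tol.contains(fa.mz, fa.rt, fa.ccs, fb.mz, fb.rt, fb.ccs):
                d = tol.normalized_distance(fa.mz, fa.rt, fa.ccs,
                                            fb.mz, fb.rt, fb.ccs)
                cand.append((d, fa.mz, fb.mz, ia, ib))
    result = OverlapResult()
    if not one_to_one:
        result.pairs = [(features_a[ia], features_b[ib])
                        for _, _, _, ia, ib in sorted(cand)]
        matched_a = {ia for _, _, _, ia, _ in cand}
        matched_b = {ib for _, _, _, _, ib in cand}
    else:
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, _, _, ia, ib in sorted(cand):
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            result.pairs.append((features_a[ia], features_b[ib]))
        matched_a, matched_b = used_a, used_b
    result.unmatched_a = [f for i, f in enumerate(features_a)
                          if i not in matched_a]
    result.unmatched_b = [f for i, f in enumerate(features_b)
                          if i not in matched_b]
    return result


def dilution_response_filter(
    table: BucketTable,
    design,
    params: DilutionFilterParams | None = None,
) -> tuple[BucketTable, BucketTable, pd.DataFrame]:
    """Keep buckets whose intensity tracks the amount of matrix loaded.

    Per bucket, sample areas are averaged within each dilution level;
    the bucket is kept iff Pearson r(level means, volumes) >= r_min and
    the SD of the normalized level means exceeds sd_min.
    """
    params = params or DilutionFilterParams()
    dmap = design.dilution_map()
    cols = [s for s in table.sample_ids if s in dmap]
    volumes = sorted({dmap[s] for s in cols})
    if len(volumes) < 3:
        raise ValidationError(
            f"dilution filter needs >= 3 dilution levels, got {len(volumes)}"
        )
    level_cols = {v: [s for s in cols if dmap[s] == v] for v in volumes}

    diag_rows = []
    kept_ids, removed_ids = [], []
    vols = np.asarray(volumes, dtype=float)
    for bid in table.buckets.index:
        means = np.array([
            np.nan_to_num(np.nanmean(
                table.values.loc[bid, level_cols[v]].to_numpy(dtype=float))
                if not table.values.loc[bid, level_cols[v]].isna().all()
                else 0.0)
            for v in volumes
        ])
        reason = ""
        if np.ptp(means) == 0:
            r = np.nan
            sd = 0.0
            keep = False
            reason = "constant"
        else:
            r = float(stats.pearsonr(means, vols).statistic)
            if params.normalization == "max_scale":
                norm = means / means.max()
            elif params.normalization == "log10":
                norm = np.log10(np.maximum(means, np.finfo(float).tiny))
            else:
                norm = means
            sd = float(np.std(norm))  # population SD: scale-free criterion
            keep = (r >= params.r_min) and (sd > params.sd_min)
            if not keep:
                reason = "low_r" if r < params.r_min else "low_sd"
        (kept_ids if keep else removed_ids).append(bid)
        diag_rows.append({"bucket_id": bid, "pearson_r": r, "sd_norm": sd,
                          "kept": keep, "reason": reason})
    diagnostics = pd.DataFrame(diag_rows).set_index("bucket_id")
    return table.subset(kept_ids), table.subset(removed_ids), diagnostics


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int


def funnel_report(stages: list[StageCount]) -> pd.DataFrame:
    """Tabular funnel of per-stage bucket counts."""
    return pd.DataFrame([{"stage": s.stage, "n_in": s.n_in, "n_out": s.n_out}
                         for s in stages])
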