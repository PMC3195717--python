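"""Dynamical-module partitioning and variant comparison.

Responsive residues are binned by response time into fixed-width modules
(default 100 fs = 0.1 ps); module k covers the half-open interval
[(k-1) w, k w).  Cross-tabulating modules against structural regions
yields the module-by-region count table; variant analyses difference two
such tables or two dissipation curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, SpecError
from .response import DissipationCurve, ResponseProfile
from .structures import RegionAnnotation

DEFAULT_MODULE_WIDTH = 100.0  # fs


@dataclass
class ModulePartition:
    """Module id per responsive residue; ids are 1-based, NaN elsewhere."""

    width: float
    module_ids: np.ndarray        # (N,) float; NaN for nonresponsive
    nonresponsive: frozenset[int]  # 1-based indices

    @property
    def n_residues(self) -> int:
        return len(self.module_ids)

    @property
    def n_modules(self) -> int:
        """Highest occupied module id (empty trailing modules not counted)."""
        finite = self.module_ids[np.isfinite(self.module_ids)]
        return int(finite.max()) if finite.size else 0

    def members(self, module_id: int) -> list[int]:
        return [i + 1 for i in np.flatnonzero(self.module_ids == module_id)]


@dataclass
class ModuleRegionTable:
    """Region x module count cross-tab with margins."""

    counts: pd.DataFrame   # index = region labels, columns = module ids
    width: float
    meta: dict = field(default_factory=dict)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    @property
    def region_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def module_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.region_totals
        out.loc["Total"] = out.sum(axis=0)
        return out


def partition_modules(profile: ResponseProfile,
                      width: float = DEFAULT_MODULE_WIDTH) -> ModulePartition:
    """Bin response times into modules: id = floor(dt / width) + 1.

    A dt exactly at a bin boundary falls in the higher module (half-open
    bins); perturbed residues (dt = 0) land in module 1.
    """
    if width <= 0:
        raise SpecError("module width must be > 0")
    dts = profile.response_times
    ids = np.where(np.isfinite(dts), np.floor(dts / width) + 1, np.nan)
    nonresp = frozenset(int(i) + 1 for i in np.flatnonzero(~np.isfinite(dts)))
    return ModulePartition(width=float(width), module_ids=ids,
                           nonresponsive=nonresp)


def module_region_table(partition: ModulePartition,
                        annotation: RegionAnnotation) -> ModuleRegionTable:
    """Cross-tab of responsive-residue counts: regions x modules.

    Empty modules up to the highest occupied id are retained as zero
    columns so that module ids stay comparable across variants.
    """
    if annotation.n_residues != partition.n_residues:
        raise AlignmentError("annotation does not cover the partition's residues")
    n_mod = max(partition.n_modules, 1)
    regions = annotation.region_labels
    counts = pd.DataFrame(0, index=regions,
                          columns=list(range(1, n_mod + 1)), dtype=int)
    for i in range(1, partition.n_residues + 1):
        mid = partition.module_ids[i - 1]
        if np.isfinite(mid):
            counts.loc[annotation.label_of(i), int(mid)] += 1
    return ModuleRegionTable(
        counts=counts, width=partition.width,
        meta={"n_nonresponsive": len(partition.nonresponsive)},
    )


@dataclass
class DifferenceCurve:
    """Variant-minus-wild-type dissipation difference dNR(t)."""

    times: np.ndarray
    delta_nr: np.ndarray
    meta: dict = field(default_factory=dict)


def _step_resample(src_t: np.ndarray, src_y: np.ndarray,
                   grid: np.ndarray) -> np.ndarray:
    """Previous-value (step function) interpolation onto `grid`."""
    idx = np.searchsorted(src_t, grid, side="right") - 1
    if np.any(idx < 0):
        raise AlignmentError("target grid starts before the source curve")
    return src_y[idx]


def variant_difference(curve_wt: DissipationCurve,
                       curve_var: DissipationCurve) -> DifferenceCurve:
    """dNR(t) = NR_variant(t) - NR_wildtype(t).

    Mismatched grids are aligned by step-function resampling of both
    curves onto their overlapping time range (union of grid points);
    disjoint grids raise AlignmentError.
    """
    if np.array_equal(curve_wt.times, curve_var.times):
        grid = np.asarray(curve_wt.times, dtype=float)
        d = np.asarray(curve_var.nr, dtype=float) - np.asarray(curve_wt.nr,
                                                               dtype=float)
    else:
        lo = max(curve_wt.times[0], curve_var.times[0])
        hi = min(curve_wt.times[-1], curve_var.times[-1])
        if lo > hi:
            raise AlignmentError("curve time grids do not overlap")
        grid = np.union1d(curve_wt.times, curve_var.times)
        grid = grid[(grid >= lo) & (grid <= hi)]
        d = (_step_resample(curve_var.times, np.asarray(curve_var.nr, float), grid)
             - _step_resample(curve_wt.times, np.asarray(curve_wt.nr, float), grid))
    return DifferenceCurve(times=grid, delta_nr=d,
                           meta={"sign": "variant-minus-wildtype"})


def compare_partitions(p1: ModuleRegionTable | ModulePartition,
                       p2: ModuleRegionTable | ModulePartition,
                       annotation: RegionAnnotation | None = None) -> pd.DataFrame:
    """Elementwise count difference (second minus first), padded to the
    common module range and region set.

    Accepts either two ModuleRegionTables or two ModulePartitions plus
    the annotation to tabulate them with.
    """
    if isinstance(p1, ModulePartition):
        if annotation is None:
            raise SpecError("annotation required when passing partitions")
        t1 = module_region_table(p1, annotation)
        t2 = module_region_table(p2, annotation)
    else:
        t1, t2 = p1, p2
    if t1.width != t2.width:
        raise SpecError(f"module widths differ: {t1.width} vs {t2.width}")
    cols = sorted(set(t1.counts.columns) | set(t2.counts.columns))
    rows = list(dict.fromkeys(list(t1.counts.index) + list(t2.counts.index)))
    a = t1.counts.reindex(index=rows, columns=cols, fill_value=0)
    b = t2.counts.reindex(index=rows, columns=cols, fill_value=0)
    return b - a
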