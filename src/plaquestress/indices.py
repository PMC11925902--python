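"""Per-component stress parameters and the global plaque stress indexes.

For each plaque component (calcific, lipid, fibrous) four scalar stress
parameters are extracted from the FE solution: the volume-weighted 99th
percentile of the von Mises and maximum principal stress (VM99 / MPS99 —
the stress value at 99% of the component's cumulative element volume,
i.e. excluding the 1% of volume carrying the highest stresses) and the
volume-weighted means (VMmean / MPSmean). The global index of each
parameter is the average of the component values weighted by the relative
component volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elasticity import FEAResult
from .geometry import VolumeReport
from .labels import COMPONENT_NAMES, Label, PLAQUE_LABELS


def volume_weighted_percentile(values, volumes, q: float) -> float:
    """Smallest value whose cumulative element volume reaches ``q`` x total.

    Elements are sorted by value ascending and their volumes accumulated;
    the value at the first crossing of ``q`` x total volume is returned
    (lower-bound convention, no interpolation — tied values share a
    crossing). With equal volumes this reduces to the empirical
    inverted-CDF percentile.
    """
    values = np.asarray(values, float)
    volumes = np.asarray(volumes, float)
    if values.size == 0:
        raise ValueError("empty value list")
    if values.shape != volumes.shape:
        raise ValueError("values and volumes must have equal length")
    if np.any(volumes <= 0):
        raise ValueError("volumes must be positive")
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(volumes[order])
    target = q * cum[-1]
    idx = int(np.searchsorted(cum, target - 1e-12 * cum[-1]))
    return float(values[order[min(idx, len(values) - 1)]])


@dataclass
class ComponentStressSummary:
    """The four stress parameters of one plaque component (kPa)."""

    component: str
    vm99: float
    mps99: float
    vm_mean: float
    mps_mean: float
    volume: float  # mm^3
    missing: bool = False


@dataclass
class GlobalStressIndex:
    """Relative-volume-weighted whole-plaque stress indexes (kPa)."""

    vm99: float
    mps99: float
    vm_mean: float
    mps_mean: float


def component_stress_summary(result: FEAResult, component: Label) -> ComponentStressSummary:
    """Summarise VM/MPS within one component of the FE solution.

    An absent component yields a flagged-missing summary with zero volume,
    which downstream receives zero weight.
    """
    name = COMPONENT_NAMES[component]
    sel = result.element_labels == int(component)
    if not sel.any():
        return ComponentStressSummary(name, np.nan, np.nan, np.nan, np.nan, 0.0, missing=True)
    vols = result.element_volumes[sel]
    vm = result.von_mises[sel]
    mps = result.max_principal[sel]
    w = vols / vols.sum()
    return ComponentStressSummary(
        component=name,
        vm99=volume_weighted_percentile(vm, vols, 0.99),
        mps99=volume_weighted_percentile(mps, vols, 0.99),
        vm_mean=float(vm @ w),
        mps_mean=float(mps @ w),
        volume=float(vols.sum()),
    )


def global_stress_index(
    summaries: list[ComponentStressSummary],
    volumes: VolumeReport | None = None,
) -> GlobalStressIndex:
    """Weighted average of the component stress parameters.

    Weights are the relative plaque-component volumes (from ``volumes`` if
    given, else from the mesh volumes carried by the summaries); missing
    components contribute zero weight and the weights are renormalized.
    """
    present = [s for s in summaries if not s.missing]
    if not present:
        raise ValueError("all plaque components are missing: no index defined")
    if volumes is not None and volumes.plaque_defined:
        w = np.array([volumes.relative.get(s.component, 0.0) for s in present])
    else:
        w = np.array([s.volume for s in present])
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total component volume")
    w = w / total
    agg = lambda attr: float(sum(wi * getattr(s, attr) for wi, s in zip(w, present)))
    return GlobalStressIndex(agg("vm99"), agg("mps99"), agg("vm_mean"), agg("mps_mean"))


def summarise_patient_stress(
    result: FEAResult, volumes: VolumeReport | None = None
) -> tuple[dict[str, ComponentStressSummary], GlobalStressIndex]:
    """All three component summaries plus the global index."""
    summaries = {
        COMPONENT_NAMES[lab]: component_stress_summary(result, lab) for lab in PLAQUE_LABELS
    }
    index = global_stress_index(list(summaries.values()), volumes)
    return summaries, index


def stress_table(
    summaries: dict[str, ComponentStressSummary],
    index: GlobalStressIndex,
    volumes: VolumeReport | None = None,
) -> pd.DataFrame:
    """One row per component plus a global-index row (CSV-ready)."""
    rows = []
    for name, s in summaries.items():
        rows.append(
            {
                "component": name,
                "VM99": s.vm99,
                "MPS99": s.mps99,
                "VMmean": s.vm_mean,
                "MPSmean": s.mps_mean,
                "vol_mm3": s.volume,
                "vol_pct": volumes.relative.get(name, np.nan) if volumes else np.nan,
            }
        )
    rows.append(
        {
            "component": "global_index",
            "VM99": index.vm99,
            "MPS99": index.mps99,
            "VMmean": index.vm_mean,
            "MPSmean": index.mps_mean,
            "vol_mm3": volumes.total_plaque if volumes else np.nan,
            "vol_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
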