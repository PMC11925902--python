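"""Per-patient and cohort orchestration: generation to comparison tables.

``run_patient`` chains every stage for one synthetic patient: label-map
generation, wall reconstruction, component volumes, meshing, the static FE
solve under the differential carotid pressure, stress indexes, the
echo-tracking stiffness report and histology grading.

``run_cohort`` runs a whole two-class cohort, supports injected per-stage
exclusions (emulating the real study's accounting, where patients drop out
of histology, CTA segmentation or the reconstruction independently of the
remaining stages), and builds the five publication-style comparison
tables: clinical, histology, stiffness, volumes and stresses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elasticity import MaterialTable, solve_elasticity
from .geometry import (
    ReconstructionConfig,
    VolumeReport,
    compute_component_volumes,
    reconstruct_atherosclerotic_wall,
)
from .histology import HistologyScorecard, score_histology
from .indices import ComponentStressSummary, GlobalStressIndex, summarise_patient_stress
from .labels import Label
from .meshing import mesh_vessel
from .stats import VariableSpec, build_comparison_table
from .stiffness import QASReport, measure_distension, qas_report, swe_young_modulus
from .synthetic import (
    EffectConfig,
    SyntheticPatient,
    generate_cohort,
    generate_distension_waveform,
    generate_vessel_labelmap,
)


@dataclass
class ExclusionConfig:
    """Number of patients to drop, per stage, mirroring a real cohort's
    attrition: histology exclusions are independent of the imaging chain;
    CTA and reconstruction failures remove patients from volumes and FEA."""

    histology: int = 0
    cta: int = 0
    reconstruction: int = 0


@dataclass
class RunConfig:
    """Everything needed to reproduce a cohort run."""

    n_vulnerable: int = 43
    n_stable: int = 57
    seed: int = 11
    effects: EffectConfig = field(default_factory=EffectConfig)
    reconstruction: ReconstructionConfig = field(
        default_factory=lambda: ReconstructionConfig(wall_thickness=2.0)
    )
    materials: MaterialTable = field(default_factory=MaterialTable)
    target_edge: float | None = None
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    waveform_noise_um: float = 5.0
    outdir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PatientResult:
    """Stage outputs for one patient; failed/excluded stages stay None."""

    record: "object"
    volumes: VolumeReport | None = None
    summaries: dict[str, ComponentStressSummary] | None = None
    index: GlobalStressIndex | None = None
    qas: QASReport | None = None
    ym_plaque: float | None = None
    ym_ica: float | None = None
    ym_cca: float | None = None
    scorecard: HistologyScorecard | None = None
    error: str | None = None


@dataclass
class ExclusionLog:
    """Which patient was dropped at which stage."""

    entries: list[tuple[str, str]] = field(default_factory=list)  # (id, stage)

    def add(self, pid: str, stage: str) -> None:
        self.entries.append((pid, stage))

    def ids(self, *stages: str) -> set[str]:
        return {pid for pid, st in self.entries if not stages or st in stages}

    def count(self, stage: str) -> int:
        return sum(1 for _, st in self.entries if st == stage)


def plan_exclusions(config: RunConfig) -> tuple[list[SyntheticPatient], ExclusionLog]:
    """Draw the cohort and assign the injected per-stage exclusions.

    CTA and reconstruction exclusions are disjoint (a patient already
    dropped at segmentation never reaches reconstruction); histology
    exclusions are drawn independently. The FE cohort is everyone not
    dropped by the imaging chain.
    """
    patients = generate_cohort(config.n_vulnerable, config.n_stable, config.effects, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    ids = [p.record.id for p in patients]
    log = ExclusionLog()
    exc = config.exclusions
    n_img = exc.cta + exc.reconstruction
    if n_img > len(ids) or exc.histology > len(ids):
        raise ValueError("more exclusions requested than patients")
    img_drop = rng.choice(ids, size=n_img, replace=False) if n_img else []
    for i, pid in enumerate(img_drop):
        log.add(str(pid), "cta" if i < exc.cta else "reconstruction")
    hist_drop = rng.choice(ids, size=exc.histology, replace=False) if exc.histology else []
    for pid in hist_drop:
        log.add(str(pid), "histology")
    return patients, log


def fea_cohort_size(config: RunConfig) -> int:
    """Number of patients reaching the FE stage under the exclusion plan."""
    patients, log = plan_exclusions(config)
    return len(patients) - len(log.ids("cta", "reconstruction"))


# ---------------------------------------------------------------------------
# Per-patient run
# ---------------------------------------------------------------------------


def run_patient(
    patient: SyntheticPatient,
    config: RunConfig | None = None,
    skip_imaging: bool = False,
    skip_histology: bool = False,
) -> PatientResult:
    """Run every stage for one patient.

    Stage failures are captured in ``error`` without corrupting the other
    stage outputs.
    """
    config = config or RunConfig()
    rec = patient.record
    out = PatientResult(record=rec)

    # stiffness metrics (ultrasound chain, never excluded)
    wav = generate_distension_waveform(
        rec,
        rec.mean_diameter_mm,
        rec.distension_um,
        noise_sd=config.waveform_noise_um,
        seed=int.from_bytes(
            hashlib.sha256(f"{config.seed}:{rec.id}".encode()).digest()[:4], "little"
        )
        % (2**31),
    )
    dist = measure_distension(wav)
    out.qas = qas_report(
        dist.diastolic_diameter,
        dist.systolic_diameter,
        rec.systolic_pressure,
        rec.diastolic_pressure,
    )
    out.ym_plaque = swe_young_modulus(rec.plaque_shear_speed)
    out.ym_ica = swe_young_modulus(rec.ica_shear_speed)
    out.ym_cca = swe_young_modulus(rec.cca_shear_speed)

    if not skip_histology:
        out.scorecard = score_histology(patient.histology)

    if not skip_imaging:
        try:
            labelmap = generate_vessel_labelmap(patient.geometry)
            model = reconstruct_atherosclerotic_wall(labelmap, config.reconstruction)
            out.volumes = compute_component_volumes(model)
            mesh = mesh_vessel(model, config.target_edge)
            result = solve_elasticity(mesh, config.materials, pressure=rec.pulse_pressure)
            if out.volumes.plaque_defined:
                out.summaries, out.index = summarise_patient_stress(result, out.volumes)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            out.error = f"{type(exc).__name__}: {exc}"
    return out


# ---------------------------------------------------------------------------
# Cohort run
# ---------------------------------------------------------------------------

_CLINICAL_VARS = [
    VariableSpec("female", "binary"),
    VariableSpec("age", "continuous"),
    VariableSpec("bmi", "continuous"),
    VariableSpec("dyslipidemia", "binary"),
    VariableSpec("cad", "binary"),
    VariableSpec("copd", "binary"),
    VariableSpec("diabetes", "binary"),
    VariableSpec("cerebrovascular_event", "binary"),
]

_HISTOLOGY_VARS = [
    VariableSpec(name, "ordinal")
    for name in (
        "atheroma_score",
        "cap_score",
        "inflammation_score",
        "cholesterol_score",
        "cd68_score",
        "cd163_score",
    )
]

_STIFFNESS_VARS = [
    VariableSpec(n, "continuous")
    for n in ("distension", "diameter", "dc", "cc", "alpha", "beta", "pwv", "ym_plaque", "ym_ica", "ym_cca")
]

_VOLUME_VARS = [
    VariableSpec(n, "continuous")
    for n in (
        "calcific_pct",
        "lipid_pct",
        "fibrous_pct",
        "calcific_mm3",
        "lipid_mm3",
        "fibrous_mm3",
        "total_mm3",
    )
]

_STRESS_VARS = [
    VariableSpec(n, "continuous")
    for comp in ("calcific", "lipid", "fibrous", "index")
    for n in (f"{comp}_vm99", f"{comp}_mps99", f"{comp}_vm_mean", f"{comp}_mps_mean")
]


@dataclass
class CohortResult:
    patients: list[SyntheticPatient]
    results: dict[str, PatientResult]
    exclusions: ExclusionLog
    tables: dict[str, pd.DataFrame]
    data: pd.DataFrame  # per-patient flat frame feeding the tables

    def table_n(self, table: str) -> tuple[int, int]:
        t = self.tables[table]
        return int(t["n_vulnerable"].max()), int(t["n_stable"].max())


def _patient_row(pr: PatientResult) -> dict:
    rec = pr.record
    row = {
        "id": rec.id,
        "group": rec.group,
        "female": rec.sex == "F",
        "age": rec.age,
        "bmi": rec.bmi,
        "dyslipidemia": rec.dyslipidemia,
        "cad": rec.cad,
        "copd": rec.copd,
        "diabetes": rec.diabetes,
        "cerebrovascular_event": rec.cerebrovascular_event,
    }
    if pr.qas is not None:
        row.update(
            distension=pr.qas.distension,
            diameter=pr.qas.diameter,
            dc=pr.qas.dc,
            cc=pr.qas.cc,
            alpha=pr.qas.alpha,
            beta=pr.qas.beta,
            pwv=pr.qas.pwv,
            ym_plaque=pr.ym_plaque,
            ym_ica=pr.ym_ica,
            ym_cca=pr.ym_cca,
        )
    if pr.scorecard is not None:
        row.update(dataclasses.asdict(pr.scorecard))
    if pr.volumes is not None and pr.volumes.plaque_defined:
        row.update(
            calcific_pct=pr.volumes.relative["calcific"],
            lipid_pct=pr.volumes.relative["lipid"],
            fibrous_pct=pr.volumes.relative["fibrous"],
            calcific_mm3=pr.volumes.absolute["calcific"],
            lipid_mm3=pr.volumes.absolute["lipid"],
            fibrous_mm3=pr.volumes.absolute["fibrous"],
            total_mm3=pr.volumes.total_plaque,
        )
    if pr.summaries is not None:
        for name, s in pr.summaries.items():
            if not s.missing:
                row.update(
                    {
                        f"{name}_vm99": s.vm99,
                        f"{name}_mps99": s.mps99,
                        f"{name}_vm_mean": s.vm_mean,
                        f"{name}_mps_mean": s.mps_mean,
                    }
                )
    if pr.index is not None:
        row.update(
            index_vm99=pr.index.vm99,
            index_mps99=pr.index.mps99,
            index_vm_mean=pr.index.vm_mean,
            index_mps_mean=pr.index.mps_mean,
        )
    return row


def run_cohort(config: RunConfig | None = None) -> CohortResult:
    """Generate, process and statistically compare a full cohort."""
    config = config or RunConfig()
    if config.n_vulnerable < 1 or config.n_stable < 1:
        raise ValueError("cohort sizes must be >= 1 per group")
    patients, log = plan_exclusions(config)
    img_excluded = log.ids("cta", "reconstruction")
    hist_excluded = log.ids("histology")

    results: dict[str, PatientResult] = {}
    for p in patients:
        pid = p.record.id
        results[pid] = run_patient(
            p,
            config,
            skip_imaging=pid in img_excluded,
            skip_histology=pid in hist_excluded,
        )
        if results[pid].error is not None:
            log.add(pid, "reconstruction_failure")

    data = pd.DataFrame([_patient_row(pr) for pr in results.values()])
    tables = {
        "clinical": build_comparison_table(data, _CLINICAL_VARS),
        "histology": build_comparison_table(data, _HISTOLOGY_VARS),
        "stiffness": build_comparison_table(data, _STIFFNESS_VARS),
        "volumes": build_comparison_table(data, _VOLUME_VARS),
        "stress": build_comparison_table(data, _STRESS_VARS),
    }
    out = CohortResult(patients, results, log, tables, data)
    if config.outdir:
        _write_outputs(out, config)
    return out


def _write_outputs(result: CohortResult, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.data.to_csv(outdir / "patients.csv", index=False)
    for name, table in result.tables.items():
        table.to_csv(outdir / f"table_{name}.csv", index=False)
    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_vulnerable": config.n_vulnerable,
        "n_stable": config.n_stable,
        "exclusions": [{"id": pid, "stage": st} for pid, st in result.exclusions.entries],
    }
    (outdir / "provenance.json").write_text(json.dumps(meta, indent=2) + "\n")
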