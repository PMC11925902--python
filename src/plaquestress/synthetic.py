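"""Synthetic study inputs: vessel segmentations, patient records, waveforms.

Everything the real study acquired from patients is emulated here with the
statistical structure the downstream analysis assumes:

* voxelized CTA-like segmentations of a stenosed common-carotid segment with
  calcific and lipid inclusions (``generate_vessel_labelmap``);
* a two-class cohort (vulnerable vs stable plaque) whose class-conditional
  plaque stiffness and composition follow the published group medians —
  vulnerable plaques are lipid-richer, less calcified and softer
  (``generate_cohort``);
* periodic arterial diameter waveforms with a prescribed systolic-diastolic
  excursion for the echo-tracking stiffness report
  (``generate_distension_waveform``).

All randomness flows through explicit integer seeds; identical seeds yield
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .labels import Label, LabelVolume

MMHG_TO_KPA = 0.133322

# Shear-wave conversion E = 3 rho c^2 assumes this soft-tissue density.
TISSUE_DENSITY = 1000.0  # kg/m^3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeometryParams:
    """Parameters of one synthetic stenosed vessel segment.

    Lengths in mm; fractions are dimensionless in [0, 1].
    ``stenosis_degree`` is the fractional lumen-radius reduction at the
    throat; ``calcific_fraction``/``lipid_fraction`` are fractions of the
    plaque volume occupied by each segmented component (the remainder
    becomes fibrous tissue during reconstruction).
    """

    lumen_radius: float = 4.0
    vessel_length: float = 60.0
    stenosis_degree: float = 0.0
    calcific_fraction: float = 0.0
    lipid_fraction: float = 0.0
    voxel_size: float = 0.3
    stenosis_length: float = 15.0
    bifurcated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not (0 <= self.stenosis_degree < 1):
            raise ValueError("stenosis_degree must lie in [0, 1)")
        for name in ("calcific_fraction", "lipid_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.calcific_fraction + self.lipid_fraction > 1 + 1e-12:
            raise ValueError("calcific_fraction + lipid_fraction must be <= 1")
        if self.lumen_radius <= 0 or self.vessel_length <= 0:
            raise ValueError("lumen_radius and vessel_length must be positive")


@dataclass
class PatientRecord:
    """One synthetic patient. Pressures in kPa, shear speeds in m/s."""

    id: str
    group: str  # "vulnerable" | "stable"
    systolic_pressure: float
    diastolic_pressure: float
    plaque_shear_speed: float
    ica_shear_speed: float
    cca_shear_speed: float
    age: float
    sex: str  # "F" | "M"
    bmi: float
    mean_diameter_mm: float
    distension_um: float
    dyslipidemia: bool = False
    cad: bool = False
    copd: bool = False
    diabetes: bool = False
    cerebrovascular_event: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("vulnerable", "stable"):
            raise ValueError("group must be 'vulnerable' or 'stable'")
        if not (self.systolic_pressure > self.diastolic_pressure > 0):
            raise ValueError("require systolic > diastolic > 0 (kPa)")

    @property
    def pulse_pressure(self) -> float:
        """Differential carotid pressure (kPa): the static FE lumen load."""
        return self.systolic_pressure - self.diastolic_pressure


@dataclass
class HistologyRaw:
    """Raw section measurements feeding the semi-quantitative grading."""

    necrosis_pct: float
    cap_thickness: float  # micrometres
    inflamed: bool
    cholesterol_present: bool
    cd68_pct: float
    cd163_pct: float

    def __post_init__(self) -> None:
        for name in ("necrosis_pct", "cd68_pct", "cd163_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.cap_thickness <= 0:
            raise ValueError("cap_thickness must be positive (um)")


@dataclass
class DiameterWaveform:
    """Uniformly sampled arterial diameter trace (s, mm)."""

    time: np.ndarray
    diameter: np.ndarray
    n_cycles: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.diameter = np.asarray(self.diameter, float)
        if self.time.shape != self.diameter.shape:
            raise ValueError("time and diameter must have the same length")
        if np.any(self.diameter <= 0):
            raise ValueError("diameters must be positive")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "diameter_mm": self.diameter}).to_csv(
            path, index=False
        )


@dataclass
class SyntheticPatient:
    record: PatientRecord
    geometry: GeometryParams
    histology: HistologyRaw


# ---------------------------------------------------------------------------
# Vessel label map
# ---------------------------------------------------------------------------


def _lumen_radius_profile(z: np.ndarray, params: GeometryParams) -> tuple[np.ndarray, np.ndarray]:
    """Lumen radius and stenosis bump profile along the axis."""
    zc = 0.5 * params.vessel_length
    if params.bifurcated:
        zc = 0.35 * params.vessel_length
    bump = np.zeros_like(z)
    half = 0.5 * params.stenosis_length
    inside = np.abs(z - zc) < half
    bump[inside] = 0.5 * (1.0 + np.cos(np.pi * (z[inside] - zc) / half))
    r = params.lumen_radius * (1.0 - params.stenosis_degree * bump)
    return r, bump


def generate_vessel_labelmap(params: GeometryParams) -> LabelVolume:
    """Voxelize a stenosed vessel segmentation (lumen + plaque components).

    The lumen is a tube of radius ``lumen_radius`` narrowing with a raised
    cosine profile at mid-vessel; the plaque occupies the annulus between the
    narrowed lumen and a mildly outward-remodelled outer boundary. Calcific
    voxels are placed as an eccentric blob abutting the outer plaque
    boundary and lipid voxels as a core near the lumen, at the requested
    volume fractions of the plaque; the angular position of each blob is
    random per seed. All remaining plaque voxels stay unlabelled
    (background): they become fibrous tissue only after wall reconstruction,
    mirroring what a CTA segmentation can actually see.
    """
    h = params.voxel_size
    r0 = params.lumen_radius
    deg = params.stenosis_degree
    bulge = 1.5 * deg  # modest outward remodelling at the throat, mm

    # coarseness guard: the plaque annulus must span >= 2 voxels at the throat
    if deg > 0:
        annulus = (r0 * deg) + bulge  # throat: outer (r0+bulge) - lumen r0(1-deg)
        if annulus < 2 * h:
            raise ValueError(
                f"voxel_size {h} mm too coarse: plaque annulus at the throat is "
                f"{annulus:.2f} mm (< 2 voxels); reduce voxel_size"
            )

    half_width = r0 + bulge + 4.0  # leave room for the reconstructed wall
    nxy = int(math.ceil(2 * half_width / h))
    nz = int(math.ceil(params.vessel_length / h))
    # voxel-centre coordinates, origin at the corner voxel centre
    xs = (np.arange(nxy) + 0.5) * h - half_width
    zs = (np.arange(nz) + 0.5) * h
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    RR = np.sqrt(X**2 + Y**2)
    theta = np.arctan2(Y, X)

    r_lum, bump = _lumen_radius_profile(zs, params)
    outer = r0 + bulge * bump

    data = np.zeros((nxy, nxy, nz), dtype=np.uint8)
    lumen = RR[:, :, None] < r_lum[None, None, :]

    if params.bifurcated:
        # planar Y-split: beyond the bifurcation the lumen continues as two
        # diverging branches (ICA/ECA-like radii) in the xz-plane
        zb = 0.7 * params.vessel_length
        ang = math.radians(20.0)
        branches = np.zeros_like(lumen)
        for r_b, sgn in ((3.0, 1.0), (2.5, -1.0)):
            off = sgn * np.maximum(zs - zb, 0.0) * math.tan(ang)
            branch = (X[:, :, None] - off[None, None, :]) ** 2 + Y[:, :, None] ** 2 < r_b**2
            branches |= branch & (zs[None, None, :] >= zb)
        lumen = (lumen & (zs[None, None, :] < zb)) | branches

    data[lumen] = int(Label.LUMEN)

    rng = np.random.default_rng(params.seed)
    plaque = (
        (RR[:, :, None] >= r_lum[None, None, :])
        & (RR[:, :, None] < outer[None, None, :])
        & (bump[None, None, :] > 1e-9)
        & ~lumen
    )
    n_plaque = int(plaque.sum())
    if n_plaque > 0 and (params.calcific_fraction > 0 or params.lipid_fraction > 0):
        idx = np.argwhere(plaque)
        pr = RR[idx[:, 0], idx[:, 1]]
        pth = theta[idx[:, 0], idx[:, 1]]
        lum_r = r_lum[idx[:, 2]]
        out_r = outer[idx[:, 2]]
        radpos = (pr - lum_r) / np.maximum(out_r - lum_r, 1e-9)  # 0 lumen .. 1 outer

        def ang_dist(a: np.ndarray, b: float) -> np.ndarray:
            d = np.abs(a - b) % (2 * np.pi)
            return np.minimum(d, 2 * np.pi - d)

        n_c = int(round(params.calcific_fraction * n_plaque))
        n_l = int(round(params.lipid_fraction * n_plaque))
        theta_c = rng.uniform(0, 2 * np.pi)
        theta_l = rng.uniform(0, 2 * np.pi)

        score_c = radpos - 1.2 * ang_dist(pth, theta_c) / np.pi
        order = np.argsort(-score_c, kind="stable")
        calcific_sel = order[:n_c]
        data[tuple(idx[calcific_sel].T)] = int(Label.CALCIFIC)

        remaining = order[n_c:]
        score_l = (1.0 - radpos[remaining]) - 1.2 * ang_dist(pth[remaining], theta_l) / np.pi
        order_l = remaining[np.argsort(-score_l, kind="stable")]
        lipid_sel = order_l[:n_l]
        data[tuple(idx[lipid_sel].T)] = int(Label.LIPID)

    return LabelVolume(data, h, origin=np.array([xs[0], xs[0], zs[0]]))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class ClassEffects:
    """Class-conditional population parameters for one plaque group.

    Medians follow the published group contrasts: the vulnerable class is
    softer (lower plaque Young's modulus, hence lower shear speed),
    lipid-richer and less calcified than the stable class.
    """

    ym_plaque_median: float  # kPa; lognormal median
    ym_plaque_sigma: float
    calcific_fraction_median: float  # of plaque volume; logit-normal median
    lipid_fraction_median: float
    fraction_sigma: float  # logit-scale SD, shared
    distension_median_um: float
    diameter_mean_mm: float
    female_rate: float
    necrosis_mean_pct: float
    cap_median_um: float
    cap_sigma: float
    inflamed_rate: float
    cholesterol_rate: float
    cd68_zero_rate: float
    cd68_median_pct: float
    cd163_zero_rate: float
    cd163_median_pct: float
    dyslipidemia_rate: float
    cad_rate: float
    copd_rate: float
    diabetes_rate: float
    cerebrovascular_rate: float


@dataclass
class EffectConfig:
    """Full cohort generating model (both classes + shared settings)."""

    vulnerable: ClassEffects = field(
        default_factory=lambda: ClassEffects(
            ym_plaque_median=12.40,
            ym_plaque_sigma=0.8,
            calcific_fraction_median=0.105,
            lipid_fraction_median=0.060,
            fraction_sigma=0.7,
            distension_median_um=302.0,
            diameter_mean_mm=9.17,
            female_rate=0.23,
            necrosis_mean_pct=48.0,
            cap_median_um=350.0,
            cap_sigma=0.8,
            inflamed_rate=0.47,
            cholesterol_rate=0.79,
            cd68_zero_rate=0.0,
            cd68_median_pct=6.0,
            cd163_zero_rate=0.0,
            cd163_median_pct=5.0,
            dyslipidemia_rate=0.84,
            cad_rate=0.23,
            copd_rate=0.02,
            diabetes_rate=0.33,
            cerebrovascular_rate=0.14,
        )
    )
    stable: ClassEffects = field(
        default_factory=lambda: ClassEffects(
            ym_plaque_median=34.70,
            ym_plaque_sigma=0.8,
            calcific_fraction_median=0.260,
            lipid_fraction_median=0.010,
            fraction_sigma=0.7,
            distension_median_um=281.0,
            diameter_mean_mm=8.46,
            female_rate=0.40,
            necrosis_mean_pct=32.0,
            cap_median_um=200.0,
            cap_sigma=1.2,
            inflamed_rate=0.31,
            cholesterol_rate=0.53,
            cd68_zero_rate=0.30,
            cd68_median_pct=4.0,
            cd163_zero_rate=0.29,
            cd163_median_pct=3.0,
            dyslipidemia_rate=0.85,
            cad_rate=0.21,
            copd_rate=0.05,
            diabetes_rate=0.32,
            cerebrovascular_rate=0.12,
        )
    )
    # off-plaque wall stiffness (class-independent, wide spread)
    ym_wall_median: float = 6.0
    ym_wall_sigma: float = 1.1
    # brachial pressures, mmHg (cohort distributions are a modelling choice)
    systolic_mean_mmhg: float = 135.0
    systolic_sd_mmhg: float = 15.0
    diastolic_mean_mmhg: float = 78.0
    diastolic_sd_mmhg: float = 10.0
    # stenosis severity, shared between classes so total plaque volume is
    # class-independent (the published total-volume comparison is null)
    stenosis_low: float = 0.55
    stenosis_high: float = 0.80
    diameter_sd_mm: float = 1.3
    distension_sigma: float = 0.45
    # geometry template for per-patient FE runs (desk-scale profile)
    geometry: GeometryParams = field(
        default_factory=lambda: GeometryParams(
            lumen_radius=4.0,
            vessel_length=18.0,
            stenosis_length=12.0,
            voxel_size=1.0,
        )
    )


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    n_vulnerable: int,
    n_stable: int,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
) -> list[SyntheticPatient]:
    """Draw a reproducible two-class cohort of synthetic patients."""
    if n_vulnerable < 0 or n_stable < 0:
        raise ValueError("group sizes must be non-negative")
    cfg = effect_config or EffectConfig()
    rng = np.random.default_rng(seed)
    patients: list[SyntheticPatient] = []
    groups = ["vulnerable"] * n_vulnerable + ["stable"] * n_stable
    for i, group in enumerate(groups):
        eff = cfg.vulnerable if group == "vulnerable" else cfg.stable

        ym_plaque = eff.ym_plaque_median * math.exp(rng.normal(0, eff.ym_plaque_sigma))
        ym_ica = cfg.ym_wall_median * math.exp(rng.normal(0, cfg.ym_wall_sigma))
        ym_cca = cfg.ym_wall_median * math.exp(rng.normal(0, cfg.ym_wall_sigma))
        # invert E = 3 rho c^2 (E in kPa -> Pa)
        to_speed = lambda e: math.sqrt(e * 1000.0 / (3.0 * TISSUE_DENSITY))

        ps = rng.normal(cfg.systolic_mean_mmhg, cfg.systolic_sd_mmhg)
        pd_ = rng.normal(cfg.diastolic_mean_mmhg, cfg.diastolic_sd_mmhg)
        pd_ = min(pd_, ps - 20.0)
        pd_ = max(pd_, 40.0)
        ps = max(ps, pd_ + 20.0)

        f_c = float(_expit(rng.normal(_logit(eff.calcific_fraction_median), eff.fraction_sigma)))
        f_l = float(_expit(rng.normal(_logit(eff.lipid_fraction_median), eff.fraction_sigma)))
        total = f_c + f_l
        if total > 0.85:  # keep a fibrous matrix of at least 15%
            f_c *= 0.85 / total
            f_l *= 0.85 / total

        geom = replace(
            cfg.geometry,
            stenosis_degree=float(rng.uniform(cfg.stenosis_low, cfg.stenosis_high)),
            calcific_fraction=f_c,
            lipid_fraction=f_l,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

        record = PatientRecord(
            id=f"P{i:04d}",
            group=group,
            systolic_pressure=ps * MMHG_TO_KPA,
            diastolic_pressure=pd_ * MMHG_TO_KPA,
            plaque_shear_speed=to_speed(ym_plaque),
            ica_shear_speed=to_speed(ym_ica),
            cca_shear_speed=to_speed(ym_cca),
            age=float(np.round(rng.normal(74.0, 7.5))),
            sex="F" if rng.random() < eff.female_rate else "M",
            bmi=float(np.round(rng.normal(25.7, 3.8), 2)),
            mean_diameter_mm=float(np.clip(rng.normal(eff.diameter_mean_mm, cfg.diameter_sd_mm), 5.0, 14.0)),
            distension_um=float(eff.distension_median_um * math.exp(rng.normal(0, cfg.distension_sigma))),
            dyslipidemia=bool(rng.random() < eff.dyslipidemia_rate),
            cad=bool(rng.random() < eff.cad_rate),
            copd=bool(rng.random() < eff.copd_rate),
            diabetes=bool(rng.random() < eff.diabetes_rate),
            cerebrovascular_event=bool(rng.random() < eff.cerebrovascular_rate),
        )

        hist = HistologyRaw(
            necrosis_pct=float(np.clip(rng.normal(eff.necrosis_mean_pct, 22.0), 0.0, 100.0)),
            cap_thickness=float(eff.cap_median_um * math.exp(rng.normal(0, eff.cap_sigma))),
            inflamed=bool(rng.random() < eff.inflamed_rate),
            cholesterol_present=bool(rng.random() < eff.cholesterol_rate),
            cd68_pct=0.0
            if rng.random() < eff.cd68_zero_rate
            else float(np.clip(eff.cd68_median_pct * math.exp(rng.normal(0, 0.8)), 0.01, 100.0)),
            cd163_pct=0.0
            if rng.random() < eff.cd163_zero_rate
            else float(np.clip(eff.cd163_median_pct * math.exp(rng.normal(0, 0.9)), 0.01, 100.0)),
        )
        patients.append(SyntheticPatient(record, geom, hist))
    return patients


def cohort_to_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Flatten a cohort into one row per patient (records + histology)."""
    rows = []
    for p in patients:
        row = asdict(p.record)
        row.update({f"hist_{k}": v for k, v in asdict(p.histology).items()})
        row.update(
            stenosis_degree=p.geometry.stenosis_degree,
            calcific_fraction=p.geometry.calcific_fraction,
            lipid_fraction=p.geometry.lipid_fraction,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diameter waveform
# ---------------------------------------------------------------------------


def generate_distension_waveform(
    record: PatientRecord,
    mean_diameter: float,
    distension: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_cycles: int = 8,
    period: float = 0.9,
    sampling_rate: float = 100.0,
) -> DiameterWaveform:
    """Periodic diameter trace with a raised-cosine systolic upstroke.

    ``mean_diameter`` in mm is the mid-excursion diameter; ``distension``
    and ``noise_sd`` are in micrometres. Before noise, every cycle's
    max-min diameter excursion equals ``distension`` exactly (the sampling
    grid hits both extremes). At least 6 cycles are produced so the
    echo-tracking report can average six successive beats.
    """
    if distension < 0:
        raise ValueError("distension must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if mean_diameter <= 0:
        raise ValueError("mean_diameter must be positive")
    n_cycles = max(int(n_cycles), 6)
    dt = 1.0 / sampling_rate
    n = int(round(n_cycles * period * sampling_rate))
    t = np.arange(n) * dt
    phase = (t / period) % 1.0
    ts = 0.3  # systolic fraction of the cycle
    pulse = np.where(
        phase <= ts,
        0.5 * (1.0 - np.cos(np.pi * phase / ts)),
        0.5 * (1.0 + np.cos(np.pi * (phase - ts) / (1.0 - ts))),
    )
    dd_mm = distension / 1000.0
    diam = (mean_diameter - 0.5 * dd_mm) + dd_mm * pulse
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        diam = diam + rng.normal(0.0, noise_sd / 1000.0, size=n)
    return DiameterWaveform(t, diam, n_cycles)
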