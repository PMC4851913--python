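"""Synthetic cross-sectional infant cohort generator.

Emulates a developmental quantitative-MRI study: for each subject (default:
the 18 study ages, 102-2713 days, 13 M / 5 F) the generator produces
pre-aligned 3-D parameter maps of myelin water volume fraction (vfm), NODDI
intracellular volume fraction (nu_ic) and isotropic volume fraction
(nu_iso) over a shared block-shaped region atlas, following region-specific
growth laws:

* vfm rises sigmoidally with age (4-parameter logistic),
* nu_ic rises logarithmically,
* nu_iso stays an approximately constant small fraction,

plus additive Gaussian voxel noise clamped to [0, 1]. The default logistic
parameters are calibrated so that each region's mean g-ratio trajectory
(through the voxel-wise index computation) approximately tracks the
published hemispheric logarithmic fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

from . import reference
from .roi import RegionDefinition

#: Invented midline corpus-callosum trajectories (no published coefficients
#: exist for these regions); slopes/intercepts chosen within the range of
#: the published lateral-region fits.
_MIDLINE_TARGET_CURVES = {
    "Genu CC": (-0.050, 1.2100),
    "Body CC": (-0.048, 1.1900),
    "Splenium CC": (-0.042, 1.1500),
}

DEFAULT_GRID_SHAPE = (32, 32, 32)
DEFAULT_VOXEL_SIZE_MM = 1.8


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    sex: str  # "M" | "F"
    age_days: float  # gestation-corrected

    def __post_init__(self):
        if self.age_days <= 0:
            raise ValueError("age_days must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class SigmoidCurve:
    """4-parameter logistic: lower + (upper-lower)/(1+exp(-rate*(age-midpoint)))."""

    lower: float
    upper: float
    midpoint_days: float
    rate: float  # per day

    def __post_init__(self):
        if not (0 <= self.lower <= 1 and 0 <= self.upper <= 1):
            raise ValueError("sigmoid bounds must lie in [0, 1]")

    def __call__(self, age_days):
        z = np.clip(self.rate * (np.asarray(age_days, dtype=float)
                                 - self.midpoint_days), -700, 700)
        return self.lower + (self.upper - self.lower) / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class LogCurve:
    """slope * ln(age_days) + intercept, clamped to [0, 1]."""

    slope: float  # per ln-day
    intercept: float

    def __call__(self, age_days):
        return np.clip(self.slope * np.log(np.asarray(age_days, dtype=float))
                       + self.intercept, 0.0, 1.0)


@dataclass(frozen=True)
class NoiseSD:
    """Per-parameter voxel noise standard deviations."""

    vfm: float = 0.008
    nu_ic: float = 0.02
    nu_iso: float = 0.01

    def __post_init__(self):
        if min(self.vfm, self.nu_ic, self.nu_iso) < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GrowthLaw:
    """Region-specific expected developmental curves plus voxel noise."""

    region_id: int
    region: str
    hemisphere: str
    vfm_curve: SigmoidCurve
    nuic_curve: LogCurve
    nuiso_level: float = 0.05
    noise_sd: NoiseSD = field(default_factory=NoiseSD)

    def __post_init__(self):
        if not 0 <= self.nuiso_level <= 1:
            raise ValueError("nuiso_level must lie in [0, 1]")


def evaluate_growth(law: GrowthLaw, age_days):
    """Noiseless expected (vfm, nu_ic, nu_iso) for a region at an age.

    Accepts a scalar or array of positive ages (days).
    """
    age = np.asarray(age_days, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age_days must be positive")
    vfm = np.clip(law.vfm_curve(age), 0.0, 1.0)
    nu_ic = law.nuic_curve(age)
    nu_iso = np.broadcast_to(np.float64(law.nuiso_level), age.shape).copy()
    if age.ndim == 0:
        return float(vfm), float(nu_ic), float(nu_iso)
    return vfm, nu_ic, nu_iso


def default_cohort_ages() -> list[SubjectRecord]:
    """The study cohort: 18 infants/toddlers, 102-2713 days, 13 M / 5 F."""
    subjects = reference.load_published_tables()["subjects"]
    return [SubjectRecord(s["subject_id"], s["sex"], float(s["age_days"]))
            for s in subjects]


def sample_log_uniform_ages(n: int, rng: np.random.Generator,
                            low_days: float = 100.0,
                            high_days: float = 2700.0) -> list[SubjectRecord]:
    """Uniform-in-log-age sampler for larger simulated cohorts."""
    ages = np.exp(rng.uniform(math.log(low_days), math.log(high_days), size=n))
    sexes = rng.choice(["M", "F"], size=n)
    return [SubjectRecord(f"sim-{i + 1:03d}", str(sexes[i]), float(ages[i]))
            for i in range(n)]


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

def default_region_definitions() -> list[RegionDefinition]:
    """10 bilateral white-matter regions plus 3 midline callosal regions."""
    regions = []
    next_id = 1
    bilateral_names = list(reference.load_published_tables()["trajectory_fits"])
    for name in bilateral_names:
        for hemi in ("left", "right"):
            regions.append(RegionDefinition(next_id, name, hemi))
            next_id += 1
    for name in _MIDLINE_TARGET_CURVES:
        regions.append(RegionDefinition(next_id, name, "midline"))
        next_id += 1
    return regions


def build_atlas(grid_shape=DEFAULT_GRID_SHAPE,
                regions: list[RegionDefinition] | None = None) -> tuple[np.ndarray, list[RegionDefinition]]:
    """Deterministic block-shaped label atlas on a small grid.

    Bilateral regions get mirrored left/right blocks; midline regions a
    central block. Each base region occupies its own z-slab. Background is
    label 0.
    """
    if regions is None:
        regions = default_region_definitions()
    nx, ny, nz = grid_shape
    base_names = list(dict.fromkeys(r.name for r in regions))
    slab = max(1, (nz - 4) // len(base_names))
    if 2 + slab * len(base_names) > nz:
        raise ValueError(f"grid z-extent {nz} too small for {len(base_names)} regions")
    labels = np.zeros(grid_shape, dtype=np.int16)
    y_sl = slice(2, ny - 2)
    for i, name in enumerate(base_names):
        z_sl = slice(2 + i * slab, 2 + (i + 1) * slab)
        for r in (r for r in regions if r.name == name):
            if r.hemisphere == "left":
                x_sl = slice(2, nx // 2 - 1)
            elif r.hemisphere == "right":
                x_sl = slice(nx // 2 + 1, nx - 2)
            else:
                x_sl = slice(nx // 4, nx - nx // 4)
            labels[x_sl, y_sl, z_sl] = r.region_id
    return labels, regions


# ---------------------------------------------------------------------------
# Growth-law calibration against the published trajectory fits
# ---------------------------------------------------------------------------

def vfm_for_target_g(g, nu_ic, nu_iso):
    """Invert the g-ratio index for the myelin fraction that produces it.

    Given g = sqrt(1 - vfm/vff) with vff = vfm + (1-vfm)(1-nu_iso)nu_ic,
    solve for vfm: with q = 1 - g^2 and A = (1-nu_iso)*nu_ic,
    vfm = q*A / (1 - q + q*A).
    """
    q = 1.0 - np.asarray(g, dtype=float) ** 2
    a = (1.0 - nu_iso) * np.asarray(nu_ic, dtype=float)
    return q * a / (1.0 - q + q * a)


_DEFAULT_NUIC = LogCurve(slope=0.055, intercept=0.25)
_CAL_AGES = np.geomspace(100.0, 3000.0, 40)


def calibrate_vfm_sigmoid(g_alpha: float, g_intercept: float,
                          nuic_curve: LogCurve = _DEFAULT_NUIC,
                          nuiso_level: float = 0.05) -> SigmoidCurve:
    """Fit logistic vfm(age) so the induced regional g tracks a target log curve.

    The target g(age) = g_alpha*ln(age) + g_intercept is clamped to
    [0.05, 0.995] before inversion (the published cerebellar curve exceeds
    1 at the youngest ages).
    """
    g_target = np.clip(g_alpha * np.log(_CAL_AGES) + g_intercept, 0.05, 0.995)
    m_target = vfm_for_target_g(g_target, nuic_curve(_CAL_AGES), nuiso_level)

    def logistic(age, lower, upper, midpoint, rate):
        return lower + (upper - lower) / (1.0 + np.exp(-rate * (age - midpoint)))

    p0 = (max(float(m_target[0]) * 0.8, 1e-4),
          min(float(m_target[-1]) * 1.05, 0.6), 500.0, 0.004)
    popt, _ = curve_fit(logistic, _CAL_AGES, m_target, p0=p0,
                        bounds=([0.0, 0.0, 20.0, 1e-5], [0.3, 0.8, 4000.0, 0.1]),
                        maxfev=20000)
    lower, upper, midpoint, rate = (float(v) for v in popt)
    return SigmoidCurve(lower=lower, upper=upper, midpoint_days=midpoint, rate=rate)


_default_laws_cache: list[GrowthLaw] | None = None


def default_growth_laws(regions: list[RegionDefinition] | None = None) -> list[GrowthLaw]:
    """One calibrated GrowthLaw per default region (bilateral + midline)."""
    global _default_laws_cache
    if regions is None and _default_laws_cache is not None:
        return list(_default_laws_cache)
    if regions is None:
        regions = default_region_definitions()
    fits = {(f.region, f.hemisphere): f for f in reference.published_fits()}
    laws = []
    for r in regions:
        if (r.name, r.hemisphere) in fits:
            f = fits[(r.name, r.hemisphere)]
            target = (f.alpha, f.intercept)
        elif r.name in _MIDLINE_TARGET_CURVES:
            target = _MIDLINE_TARGET_CURVES[r.name]
        else:
            raise KeyError(f"no target trajectory for region {r.name!r} ({r.hemisphere})")
        laws.append(GrowthLaw(
            region_id=r.region_id, region=r.name, hemisphere=r.hemisphere,
            vfm_curve=calibrate_vfm_sigmoid(*target),
            nuic_curve=_DEFAULT_NUIC,
        ))
    if _default_laws_cache is None and all(
            r1.region_id == r2.region_id for r1, r2 in
            zip(laws, default_region_definitions())):
        _default_laws_cache = list(laws)
    return laws


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class ParameterMaps:
    """One subject's aligned volume-fraction maps plus validity mask."""

    vfm: np.ndarray
    nu_ic: np.ndarray
    nu_iso: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        shapes = {self.vfm.shape, self.nu_ic.shape, self.nu_iso.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("all parameter maps and the mask must share one grid")


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    subjects: list[SubjectRecord]
    growth_laws: list[GrowthLaw]
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    rng_seed: int = 0
    #: atlas regions; None derives one region per growth law
    regions: list[RegionDefinition] | None = None

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject_id values must be unique within a cohort")
        law_ids = [l.region_id for l in self.growth_laws]
        if len(law_ids) != len(set(law_ids)):
            raise ValueError("duplicate GrowthLaw region_id")


def default_cohort_spec(rng_seed: int = 0,
                        grid_shape=DEFAULT_GRID_SHAPE) -> CohortSpec:
    return CohortSpec(subjects=default_cohort_ages(),
                      growth_laws=default_growth_laws(),
                      grid_shape=tuple(grid_shape), rng_seed=rng_seed)


@dataclass
class Cohort:
    """Generated cohort: per-subject maps plus the shared atlas."""

    spec: CohortSpec
    subjects: list[SubjectRecord]
    maps: dict[str, ParameterMaps]
    labels: np.ndarray
    regions: list[RegionDefinition]
    clamp_fraction: float  # fraction of in-mask voxel values clipped to [0,1]

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject_id": s.subject_id, "sex": s.sex,
                              "age_days": s.age_days} for s in self.subjects])


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw the full cohort: expectation per region/age plus Gaussian noise.

    The label atlas is identical across subjects (maps are generated
    pre-aligned; registration is outside this model). Identical spec and
    seed give bit-identical volumes.
    """
    regions = spec.regions or [RegionDefinition(l.region_id, l.region, l.hemisphere)
                               for l in spec.growth_laws]
    labels, _ = build_atlas(spec.grid_shape, regions)
    present = set(np.unique(labels)) - {0}
    laws_by_id = {l.region_id: l for l in spec.growth_laws}
    missing = present - set(laws_by_id)
    if missing:
        raise ValueError(f"atlas labels without a GrowthLaw: {sorted(missing)}")

    affine = np.diag([DEFAULT_VOXEL_SIZE_MM] * 3 + [1.0])
    mask = labels > 0
    rng = np.random.default_rng(spec.rng_seed)
    maps: dict[str, ParameterMaps] = {}
    n_clamped = 0
    n_values = 0
    for subj in spec.subjects:
        vols = {p: np.zeros(spec.grid_shape) for p in ("vfm", "nu_ic", "nu_iso")}
        noise = {p: rng.standard_normal(spec.grid_shape)
                 for p in ("vfm", "nu_ic", "nu_iso")}
        for region_id in sorted(present):
            law = laws_by_id[region_id]
            sel = labels == region_id
            mu = dict(zip(("vfm", "nu_ic", "nu_iso"),
                          evaluate_growth(law, subj.age_days)))
            sd = {"vfm": law.noise_sd.vfm, "nu_ic": law.noise_sd.nu_ic,
                  "nu_iso": law.noise_sd.nu_iso}
            for p in vols:
                raw = mu[p] + sd[p] * noise[p][sel]
                n_clamped += int(np.count_nonzero((raw < 0) | (raw > 1)))
                n_values += raw.size
                vols[p][sel] = np.clip(raw, 0.0, 1.0)
        maps[subj.subject_id] = ParameterMaps(
            vfm=vols["vfm"], nu_ic=vols["nu_ic"], nu_iso=vols["nu_iso"],
            mask=mask.copy(), affine=affine)
    clamp_fraction = n_clamped / n_values if n_values else 0.0
    return Cohort(spec=spec, subjects=list(spec.subjects), maps=maps,
                  labels=labels, regions=regions, clamp_fraction=clamp_fraction)


# ---------------------------------------------------------------------------
# On-disk representation (NIfTI volumes + CSV table + YAML ground truth)
# ---------------------------------------------------------------------------

def save_volume(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    dtype = np.int16 if np.issubdtype(data.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))


def write_cohort(cohort: Cohort, outdir: str | Path) -> list[Path]:
    """Write per-subject NIfTI maps, the label atlas, the subject table and
    the ground-truth growth-law record. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for subj in cohort.subjects:
        pm = cohort.maps[subj.subject_id]
        for p in ("vfm", "nu_ic", "nu_iso"):
            path = outdir / f"{subj.subject_id}_{p}.nii"
            save_volume(getattr(pm, p), pm.affine, path)
            written.append(path)
    atlas_path = outdir / "atlas_labels.nii"
    save_volume(cohort.labels, np.diag([DEFAULT_VOXEL_SIZE_MM] * 3 + [1.0]),
                atlas_path)
    written.append(atlas_path)

    table_path = outdir / "subjects.csv"
    cohort.subject_table().to_csv(table_path, index=False)
    written.append(table_path)

    truth = {
        "rng_seed": cohort.spec.rng_seed,
        "grid_shape": list(cohort.spec.grid_shape),
        "growth_laws": [asdict(l) for l in cohort.spec.growth_laws],
    }
    truth_path = outdir / "growth_truth.yaml"
    truth_path.write_text(yaml.safe_dump(truth, sort_keys=True))
    written.append(truth_path)
    return written


def load_subject_maps(directory: str | Path, subject_id: str) -> ParameterMaps:
    """Read one subject's three parameter maps back from NIfTI."""
    directory = Path(directory)
    vols = {}
    affine = np.eye(4)
    for p in ("vfm", "nu_ic", "nu_iso"):
        img = nib.load(str(directory / f"{subject_id}_{p}.nii"))
        vols[p] = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    atlas = np.asarray(nib.load(str(directory / "atlas_labels.nii")).dataobj)
    return ParameterMaps(vfm=vols["vfm"], nu_ic=vols["nu_ic"],
                         nu_iso=vols["nu_iso"], mask=atlas > 0, affine=affine)
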