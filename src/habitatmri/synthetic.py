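"""Synthetic DCE-MRI cohort generator with planted intratumoral habitats.

Every downstream stage of the pipeline (preprocessing, voxel features,
habitat clustering, region radiomics, modelling) is exercised against
phantoms produced here, because no public imaging cohort accompanies the
study design this package implements.

A phantom is an ellipsoidal "tumor" embedded in low-signal background
tissue.  The tumor is partitioned into ``n_habitats`` spatially coherent
subregions (compact Voronoi cells by default, concentric equal-volume
shells as an option).  Each habitat carries

* a spatially correlated Gaussian intensity field (its peak-enhancement
  appearance), parameterised by mean, standard deviation and correlation
  length, and
* a dynamic enhancement curve (baseline signal, time-to-peak phase,
  wash-out slope) that scales the voxel signal across the 1 pre-contrast +
  N post-contrast phases.

Cohort-level generation couples imaging to outcome: a per-patient latent
severity changes the spatial coherence (texture correlation length) of
planted habitat 1, and the binary endpoint (axillary pCR after
neoadjuvant chemotherapy) is drawn from a logistic model on that
habitat-1 texture burden.  Clinical covariates are then drawn
conditionally on the outcome from group-wise marginals matching the
published cohort (pCR prevalence ~0.43; ER-negative enriched among pCR,
Her-2-positive enriched among pCR, and so on).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .image import DynamicSeries, VolumeImage, save_volume

__all__ = [
    "HabitatParams",
    "PhantomSpec",
    "ClinicalModel",
    "SyntheticPatient",
    "generate_phantom",
    "generate_cohort",
    "sample_clinical_cohort",
    "simulate_logistic_cohort",
    "write_cohort",
    "default_phantom_spec",
    "default_clinical_model",
    "null_clinical_model",
]


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HabitatParams:
    """Generative parameters of one planted habitat.

    mean / sd describe the peak-enhancement intensity field; corr_length_mm
    is the Gaussian-smoothing correlation length of its spatial texture;
    (s0, ttp_phase, washout_slope) define the enhancement curve: signal
    ramps linearly from s0 to the peak value over ``ttp_phase`` post-contrast
    phases, then decays by ``washout_slope`` (fraction of peak enhancement
    per phase; negative = wash-out, 0 = plateau).
    """

    mean: float
    sd: float
    corr_length_mm: float = 4.0
    s0: float = 100.0
    ttp_phase: int = 4
    washout_slope: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a single synthetic patient's imaging."""

    grid_shape: tuple[int, int, int] = (24, 22, 19)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tumor_semiaxes_mm: tuple[float, float, float] = (30.0, 26.0, 22.0)
    n_habitats: int = 3
    habitat_params: tuple[HabitatParams, ...] = (
        # habitat 1 (the outcome-linked subregion in cohort generation):
        # intermediate intensity/texture, mid peak with mild wash-out
        HabitatParams(mean=330.0, sd=20.0, corr_length_mm=2.0, s0=100.0,
                      ttp_phase=5, washout_slope=-0.12),
        # habitat 2: dim, homogeneous, persistent late enhancement
        HabitatParams(mean=120.0, sd=5.0, corr_length_mm=2.0, s0=100.0,
                      ttp_phase=8, washout_slope=0.0),
        # habitat 3: bright, heterogeneous, early peak with marked
        # wash-out (fixes the peak-enhancement phase); every habitat pair
        # is distinct in both intensity and kinetics
        HabitatParams(mean=500.0, sd=50.0, corr_length_mm=2.0, s0=100.0,
                      ttp_phase=2, washout_slope=-0.35),
    )
    geometry: Literal["shells", "blobs"] = "blobs"
    #: Gaussian smoothing (mm) of the habitat mean/kinetics maps across
    #: subregion boundaries; soft transitions, not razor-sharp edges.
    boundary_smooth_mm: float = 1.5
    n_post_phases: int = 8
    phase_interval_s: float = 60.0
    noise_sd: float = 3.0
    bias_amplitude: float = 0.08
    background_mean: float = 60.0
    background_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_habitats < 1:
            raise ValueError("n_habitats must be >= 1")
        if len(self.habitat_params) != self.n_habitats:
            raise ValueError(
                f"habitat_params has {len(self.habitat_params)} entries "
                f"for n_habitats={self.n_habitats}"
            )
        if self.noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise/background sds must be >= 0")
        for i, hp in enumerate(self.habitat_params):
            if hp.sd < 0:
                raise ValueError(f"habitat {i + 1}: sd must be >= 0")
            if not (1 <= hp.ttp_phase <= self.n_post_phases):
                raise ValueError(
                    f"habitat {i + 1}: ttp_phase {hp.ttp_phase} outside "
                    f"1..{self.n_post_phases}"
                )
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        for ax in range(3):
            half_extent = (self.grid_shape[ax] - 1) / 2 * self.voxel_spacing_mm[ax]
            if self.tumor_semiaxes_mm[ax] >= half_extent:
                raise ValueError(
                    f"tumor semiaxis {self.tumor_semiaxes_mm[ax]} mm exceeds "
                    f"grid half-extent {half_extent:.1f} mm on axis {ax}"
                )

    @property
    def times_s(self) -> tuple[float, ...]:
        return tuple(self.phase_interval_s * j for j in range(self.n_post_phases + 1))


@dataclass
class SyntheticPatient:
    """One synthetic patient: imaging, ground truth and clinical data."""

    patient_id: str
    series: DynamicSeries
    tumor_mask: VolumeImage
    truth_labels: VolumeImage
    clinical: dict | None = None
    outcome: int | None = None
    latent: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------

def _ellipsoid_radius(spec: PhantomSpec) -> np.ndarray:
    """Normalized ellipsoidal radius at every voxel centre (1 = surface)."""
    coords = [
        (np.arange(n) - (n - 1) / 2) * sp
        for n, sp in zip(spec.grid_shape, spec.voxel_spacing_mm)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    a, b, c = spec.tumor_semiaxes_mm
    return np.sqrt((xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2)


def _partition_habitats(spec: PhantomSpec, mask: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Integer habitat labels 1..n on the tumor mask, 0 elsewhere."""
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    n = spec.n_habitats
    if spec.geometry == "shells":
        r = _ellipsoid_radius(spec)
        # equal-volume concentric shells: r**3 uniform on [0, 1]
        bounds = (np.arange(1, n) / n) ** (1.0 / 3.0)
        lab = np.digitize(r, bounds) + 1  # 1 = innermost shell
        labels[mask] = lab[mask]
    elif spec.geometry == "blobs":
        # Voronoi cells from farthest-point-sampled seeds: compact,
        # near-equal-volume subregions whose layout varies with the seed
        idx = np.argwhere(mask)
        pts_mm = idx * np.asarray(spec.voxel_spacing_mm)
        first = rng.integers(len(idx))
        seed_ids = [int(first)]
        dmin = np.linalg.norm(pts_mm - pts_mm[first], axis=1)
        while len(seed_ids) < n:
            nxt = int(np.argmax(dmin))
            seed_ids.append(nxt)
            dmin = np.minimum(dmin, np.linalg.norm(pts_mm - pts_mm[nxt], axis=1))
        seeds_mm = pts_mm[seed_ids]
        d = np.linalg.norm(pts_mm[:, None, :] - seeds_mm[None, :, :], axis=2)
        labels[tuple(idx.T)] = np.argmin(d, axis=1) + 1
    else:  # pragma: no cover
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    # guarantee every habitat id occurs (tiny regions can vanish on coarse grids)
    present = set(np.unique(labels[mask]))
    missing = [h for h in range(1, n + 1) if h not in present]
    if missing:
        raise ValueError(f"habitats {missing} received no voxels; enlarge the tumor")
    return labels


def _correlated_field(shape: tuple[int, int, int], corr_length_mm: float,
                      spacing: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise: a Gaussian random field with unit-ish scale."""
    g = rng.standard_normal(shape)
    sigma = [max(corr_length_mm / s, 1e-6) for s in spacing]
    return gaussian_filter(g, sigma=sigma, mode="nearest")


def _enhancement_fraction(ttp: int, washout: float, n_post: int) -> np.ndarray:
    """Curve g(j), j = 0..n_post: 0 at baseline, 1 at the peak phase."""
    j = np.arange(n_post + 1, dtype=float)
    g = np.where(j <= ttp, j / ttp, 1.0 + washout * (j - ttp))
    return np.clip(g, 0.0, None)


def generate_phantom(spec: PhantomSpec,
                     rng: np.random.Generator | None = None) -> SyntheticPatient:
    """Generate one phantom patient (imaging only; no clinical record).

    Deterministic for a fixed ``spec`` (the spec's ``seed`` is used when no
    generator is supplied).  Habitat intensity fields are standardized over
    their own voxels, so each habitat's empirical peak-phase mean and sd
    match its parameters exactly before acquisition noise.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    r = _ellipsoid_radius(spec)
    mask = r <= 1.0
    n_tumor = int(mask.sum())
    if n_tumor < spec.n_habitats:
        raise ValueError(
            f"tumor has {n_tumor} voxels < n_habitats={spec.n_habitats}"
        )
    labels = _partition_habitats(spec, mask, rng)

    # peak-phase intensity map = smoothed habitat-mean map + per-habitat
    # texture field; the mean/kinetics maps transition softly across
    # subregion boundaries (masked Gaussian smoothing within the tumor)
    bg_field = _correlated_field(spec.grid_shape, 6.0, spec.voxel_spacing_mm, rng)
    bg_sd = bg_field.std()
    background = spec.background_mean + (
        spec.background_sd * (bg_field - bg_field.mean()) / bg_sd if bg_sd > 0 else 0.0
    )
    mean_map = np.zeros(spec.grid_shape)
    texture = np.zeros(spec.grid_shape)
    s0_map = np.full(spec.grid_shape, 0.95 * spec.background_mean)
    curves = np.empty((spec.n_habitats + 1, spec.n_post_phases + 1))
    curves[0] = _enhancement_fraction(spec.n_post_phases, 0.0, spec.n_post_phases)
    region_of = np.where(mask, labels, 0)

    for h, hp in enumerate(spec.habitat_params, start=1):
        sel = labels == h
        mean_map[sel] = hp.mean
        if hp.sd > 0:
            fld = _correlated_field(spec.grid_shape, hp.corr_length_mm,
                                    spec.voxel_spacing_mm, rng)
            v = fld[sel]
            sd = v.std()
            if sd > 0:
                texture[sel] = hp.sd * (v[...] - v.mean()) / sd
        s0_map[sel] = hp.s0
        curves[h] = _enhancement_fraction(hp.ttp_phase, hp.washout_slope,
                                          spec.n_post_phases)

    g_per_voxel = curves[region_of]          # (nx, ny, nz, n_phases)
    if spec.boundary_smooth_mm > 0:
        sigma = [spec.boundary_smooth_mm / s for s in spec.voxel_spacing_mm]
        m = mask.astype(np.float64)
        norm = gaussian_filter(m, sigma=sigma, mode="nearest")
        norm = np.where(norm > 1e-9, norm, 1.0)

        def masked_smooth(f):
            return np.where(mask, gaussian_filter(f * m, sigma=sigma,
                                                  mode="nearest") / norm, f)

        mean_map = masked_smooth(mean_map)
        s0_map = np.where(mask, masked_smooth(s0_map), s0_map)
        for j in range(spec.n_post_phases + 1):
            g_per_voxel[..., j] = np.where(
                mask, masked_smooth(g_per_voxel[..., j]), g_per_voxel[..., j])

    peak = np.where(mask, mean_map + texture, background)

    # multiplicative bias field: exp(a * normalized random quadratic)
    if spec.bias_amplitude > 0:
        coords = [np.linspace(-1, 1, n) for n in spec.grid_shape]
        xx, yy, zz = np.meshgrid(*coords, indexing="ij")
        c = rng.standard_normal(9)
        q = (c[0] * xx + c[1] * yy + c[2] * zz + c[3] * xx * yy + c[4] * xx * zz
             + c[5] * yy * zz + c[6] * xx ** 2 + c[7] * yy ** 2 + c[8] * zz ** 2)
        q = q - q.mean()
        amax = np.abs(q).max()
        bias = np.exp(spec.bias_amplitude * (q / amax if amax > 0 else q))
    else:
        bias = None

    phases = []
    for j in range(spec.n_post_phases + 1):
        sig = s0_map + (peak - s0_map) * g_per_voxel[..., j]
        if spec.noise_sd > 0:
            sig = sig + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        if bias is not None:
            sig = sig * bias
        phases.append(VolumeImage(np.maximum(sig, 1e-6),
                                  spacing_mm=spec.voxel_spacing_mm))

    series = DynamicSeries(phases=tuple(phases), times_s=spec.times_s)
    return SyntheticPatient(
        patient_id="phantom",
        series=series,
        tumor_mask=VolumeImage(mask.astype(np.uint8), spacing_mm=spec.voxel_spacing_mm),
        truth_labels=VolumeImage(labels, spacing_mm=spec.voxel_spacing_mm),
    )


# --------------------------------------------------------------------------
# clinical model
# --------------------------------------------------------------------------

#: outcome-conditional marginals of the published cohort
#: (non-pCR group n=107, pCR group n=82)
_TABLE1 = {
    "menopause_post": (42 / 107, 42 / 82),
    "er_negative": (29 / 107, 47 / 82),
    "pr_negative": (40 / 107, 54 / 82),
    "her2_positive": (22 / 107, 59 / 82),
    "cT": ((7 / 107, 52 / 107, 40 / 107, 8 / 107),
           (5 / 82, 32 / 82, 33 / 82, 12 / 82)),
    "cN2": (15 / 107, 12 / 82),
    # Ki-67 medians (IQR): 40 (20, 60) vs 50 (30, 60) -> truncated normals
    "ki67": ((40.0, 29.7), (50.0, 22.2)),
    "age": ((48.0, 10.0), (51.0, 10.0)),
}


@dataclass(frozen=True)
class ClinicalModel:
    """Outcome model plus outcome-conditional covariate distributions.

    The endpoint is drawn from ``P(pCR) = sigmoid(intercept + imaging_effect
    * burden)`` where *burden* is the habitat-1 texture burden of the
    patient's phantom: a latent severity u ~ N(0,1) multiplies the
    habitat-1 texture correlation length by ``exp(habitat1_texture_effect
    * u)``, changing the spatial coherence (coarseness) of habitat-1
    texture while leaving its intensity histogram untouched.  Covariates
    are then drawn given the outcome from the group conditionals (Bayes
    inversion of the target marginals at the target prevalence).

    Every other habitat receives outcome-independent per-patient
    variability of the same kind: ``nuisance_texture_effect`` scales its
    correlation length log-normally and ``nuisance_jitter_sd`` jitters its
    mean intensity — biological variability that dilutes whole-tumor
    features while leaving the habitat-1 signal intact.
    """

    prevalence: float = 0.433
    imaging_effect: float = 2.5
    habitat1_texture_effect: float = 0.4
    nuisance_texture_effect: float = 0.6
    nuisance_jitter_sd: float = 10.0
    conditionals: dict = field(default_factory=lambda: dict(_TABLE1))

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        for key in ("menopause_post", "er_negative", "pr_negative",
                    "her2_positive", "cN2"):
            for p in self.conditionals[key]:
                if not (0 <= p <= 1):
                    raise ValueError(f"conditional {key}: probability {p} outside [0,1]")
        for probs in self.conditionals["cT"]:
            if abs(sum(probs) - 1.0) > 1e-6 or any(p < 0 for p in probs):
                raise ValueError("cT conditional probabilities must be a simplex")

    @property
    def intercept(self) -> float:
        """Logit intercept calibrated so the marginal prevalence over a
        standard-normal burden matches the target (logistic-normal
        marginalization correction; exact logit at zero imaging effect)."""
        kappa = np.sqrt(1.0 + (0.5875 * self.imaging_effect) ** 2)
        return float(logit(self.prevalence) * kappa)


def default_clinical_model() -> ClinicalModel:
    return ClinicalModel()


def null_clinical_model() -> ClinicalModel:
    """Covariates independent of outcome; no imaging effect.

    Group conditionals are replaced by their prevalence-weighted mixture, so
    every covariate has the same distribution in both outcome groups.
    """
    base = ClinicalModel()
    w0, w1 = 1 - base.prevalence, base.prevalence
    mixed = {}
    for key, (c0, c1) in base.conditionals.items():
        if key == "cT":
            mixed[key] = (tuple(w0 * a + w1 * b for a, b in zip(c0, c1)),) * 2
        elif key in ("ki67", "age"):
            m = (w0 * c0[0] + w1 * c1[0], w0 * c0[1] + w1 * c1[1])
            mixed[key] = (m, m)
        else:
            mixed[key] = (w0 * c0 + w1 * c1,) * 2
    return replace(base, imaging_effect=0.0, habitat1_texture_effect=0.0,
                   nuisance_texture_effect=0.0, conditionals=mixed)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def sample_clinical_cohort(n: int, model: ClinicalModel,
                           rng: np.random.Generator,
                           burden: np.ndarray | None = None) -> pd.DataFrame:
    """Draw outcomes and clinical covariates for *n* patients.

    ``burden`` is the standardized habitat-1 imaging burden per patient;
    when omitted (covariate-only simulations) it is drawn standard normal.
    Returns a DataFrame with columns age, menopause, er, pr, her2, ki67,
    cT, cN and the binary ``pcr`` outcome.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if burden is None:
        burden = rng.standard_normal(n)
    burden = np.asarray(burden, dtype=float)
    p = expit(model.intercept + model.imaging_effect * burden)
    y = (rng.random(n) < p).astype(int)

    cond = model.conditionals
    out = {"pcr": y}
    for col, key in [("menopause", "menopause_post"), ("er", "er_negative"),
                     ("pr", "pr_negative"), ("her2", "her2_positive"),
                     ("cN", "cN2")]:
        probs = np.where(y == 1, cond[key][1], cond[key][0])
        draw = (rng.random(n) < probs).astype(int)
        if key in ("er_negative", "pr_negative"):
            draw = 1 - draw  # stored as positive-receptor indicator
        if col == "cN":
            draw = draw + 1  # ordinal 1/2
        out[col] = draw
    ct = np.empty(n, dtype=int)
    for grp in (0, 1):
        sel = y == grp
        k = int(sel.sum())
        if k:
            ct[sel] = rng.choice(4, size=k, p=cond["cT"][grp]) + 1
    out["cT"] = ct
    ki = np.empty(n)
    age = np.empty(n)
    for grp in (0, 1):
        sel = y == grp
        k = int(sel.sum())
        if k:
            m, s = cond["ki67"][grp]
            ki[sel] = _trunc_normal(rng, m, s, 0.0, 100.0, k)
            m, s = cond["age"][grp]
            age[sel] = _trunc_normal(rng, m, s, 20.0, 85.0, k)
    out["ki67"] = np.round(ki, 1)
    out["age"] = np.round(age, 1)
    df = pd.DataFrame(out)
    df["burden"] = burden
    return df[["age", "menopause", "er", "pr", "her2", "ki67", "cT", "cN",
               "burden", "pcr"]]


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def generate_cohort(n_patients: int, spec: PhantomSpec | None = None,
                    clinical_model: ClinicalModel | None = None,
                    seed: int = 0) -> list[SyntheticPatient]:
    """Generate a cohort of synthetic patients with imaging + outcomes.

    Per patient, a latent severity u ~ N(0,1) scales the habitat-1 texture
    correlation length by ``exp(habitat1_texture_effect * u)``; other
    habitats receive independent coherence and mean jitter.  The outcome
    is drawn from the clinical model's logistic on the habitat-1 texture
    burden u, and covariates follow the outcome-conditional marginals.
    Ground-truth latents are recorded on each patient for
    parameter-recovery tests.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    spec = spec or default_phantom_spec()
    model = clinical_model or default_clinical_model()
    rng = np.random.default_rng(seed)
    tau = model.habitat1_texture_effect

    patients: list[SyntheticPatient] = []
    burdens = np.empty(n_patients)
    for i in range(n_patients):
        u = rng.standard_normal()
        params = list(spec.habitat_params)
        params[0] = replace(params[0], corr_length_mm=params[0].corr_length_mm
                            * float(np.exp(tau * u)))
        for h in range(1, len(params)):
            params[h] = replace(
                params[h],
                mean=params[h].mean + model.nuisance_jitter_sd * rng.standard_normal(),
                corr_length_mm=params[h].corr_length_mm * float(np.exp(
                    model.nuisance_texture_effect * rng.standard_normal())),
            )
        pspec = replace(spec, habitat_params=tuple(params),
                        seed=int(rng.integers(0, 2**31 - 1)))
        pat = generate_phantom(pspec, rng=np.random.default_rng(pspec.seed))
        pat.patient_id = f"P{i:04d}"

        # the burden is the planted coherence severity itself (a property
        # of the phantom recorded as ground truth)
        burdens[i] = u
        pat.latent = {"u": float(u), "burden": float(u)}
        patients.append(pat)

    clin = sample_clinical_cohort(n_patients, model, rng, burden=burdens)
    for i, pat in enumerate(patients):
        row = clin.iloc[i]
        pat.outcome = int(row["pcr"])
        pat.clinical = {
            "age": float(row["age"]), "menopause": int(row["menopause"]),
            "er": int(row["er"]), "pr": int(row["pr"]), "her2": int(row["her2"]),
            "ki67": float(row["ki67"]), "cT": int(row["cT"]), "cN": int(row["cN"]),
        }
        pat.latent["intercept"] = model.intercept
        pat.latent["imaging_effect"] = model.imaging_effect
    return patients


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The default study-condition phantom (three concentric habitats)."""
    return PhantomSpec(**overrides)


def clinical_table(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    """Cohort-level clinical covariate table with outcome column."""
    rows = []
    for p in patients:
        if p.clinical is None or p.outcome is None:
            raise ValueError(f"patient {p.patient_id} has no clinical record")
        rows.append({"patient_id": p.patient_id, **p.clinical, "pcr": p.outcome})
    return pd.DataFrame(rows).set_index("patient_id")


# --------------------------------------------------------------------------
# auxiliary simulators and I/O
# --------------------------------------------------------------------------

def simulate_logistic_cohort(n: int, coefs: Sequence[float], intercept: float,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian features, binary outcome from a known logistic model.

    Used for parameter-recovery and null-calibration experiments.
    """
    rng = np.random.default_rng(seed)
    coefs = np.asarray(coefs, dtype=float)
    X = rng.standard_normal((n, coefs.size))
    p = expit(intercept + X @ coefs)
    y = (rng.random(n) < p).astype(int)
    return X, y


def write_cohort(patients: Sequence[SyntheticPatient], outdir: str | Path) -> Path:
    """Write per-patient NIfTI volumes, a clinical CSV and a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"patients": []}
    for p in patients:
        pdir = outdir / p.patient_id
        pdir.mkdir(exist_ok=True)
        entry = {"patient_id": p.patient_id, "phases": [], "outcome": p.outcome,
                 "latent": p.latent}
        for j, ph in enumerate(p.series.phases):
            path = save_volume(ph, pdir / f"phase_{j:02d}.nii.gz")
            entry["phases"].append(str(path))
        entry["mask"] = str(save_volume(p.tumor_mask, pdir / "mask.nii.gz"))
        entry["truth"] = str(save_volume(p.truth_labels, pdir / "truth.nii.gz"))
        entry["times_s"] = list(p.series.times_s)
        manifest["patients"].append(entry)
    clin = clinical_table(patients)
    clin_path = outdir / "clinical.csv"
    clin.to_csv(clin_path)
    manifest["clinical_csv"] = str(clin_path)
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    return man_path
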