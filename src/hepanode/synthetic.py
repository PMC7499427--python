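"""Synthetic patch-cohort generator.

Clinical CT cohorts of small hypoattenuating hepatic nodules are not
publicly shareable, so every downstream stage of this package is exercised
on synthetic cohorts that emulate the statistical structure of such data:

* each patient carries 1-6 nodules (zero-truncated Poisson, capped at 6,
  matching a "no more than 6 per patient" selection rule), each nodule
  rendered on ~3 axial slices as one 32x32 attenuation patch per slice;
* malignant nodules are on average larger, of higher attenuation (closer
  to enhanced liver, i.e. smaller hypoattenuation depth), blurrier and
  less solid at the margin than benign nodules;
* a per-patient binary covariate (synchronous >= 1 cm liver metastasis)
  shifts the per-nodule malignancy odds by a configurable multiplier, so
  the downstream logistic fusion model has a known ground truth;
* optional simulated readers produce benign/malignant calls with 5-point
  Likert confidences.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so identical configs yield byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

from .records import (
    BENIGN,
    MALIGNANT,
    PATCH_SIZE,
    Cohort,
    LesionPhenotype,
    LesionRecord,
    PatchRecord,
    PatientRecord,
    SimulatedRating,
)

MAX_NODULES_PER_PATIENT = 6

# Class-conditional phenotype means at class_separation = 1.  The midpoints
# stay fixed while the benign/malignant gap scales with class_separation,
# so widening the gap makes the classes strictly easier to tell apart
# without moving the cohort-level feature averages.
_PHENOTYPE_MIDPOINTS = {"radius": 4.5, "depth": 47.5, "blur": 1.0, "irregularity": 0.35}
_PHENOTYPE_GAPS = {"radius": 2.0, "depth": -25.0, "blur": 0.9, "irregularity": 0.4}
_PHENOTYPE_SDS = {"radius": 0.55, "depth": 7.0, "blur": 0.18, "irregularity": 0.10}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate the training-set demographics
    of a ~150-patient staging cohort (≈2.75 nodules/patient, ≈3 slices per
    nodule, ≈34% malignant nodules, ≈24% liver-metastasis prevalence).

    ``liver_met_odds_multiplier`` is the odds ratio linking the patient's
    liver-metastasis status to each of their nodules being malignant; the
    baseline malignancy logit is solved so that the marginal malignant
    fraction equals ``malignant_nodule_fraction``.
    """

    n_patients: int = 150
    malignant_nodule_fraction: float = 0.342
    mean_nodules_per_patient: float = 2.75
    mean_slices_per_nodule: float = 3.32
    liver_met_prevalence: float = 0.244
    liver_met_odds_multiplier: float = 8.0
    extrahepatic_met_prevalence: float = 0.122
    noise_sd: float = 6.0
    background_level: float = 100.0
    class_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors: list[str] = []
        for name in (
            "malignant_nodule_fraction",
            "liver_met_prevalence",
            "extrahepatic_met_prevalence",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                errors.append(f"{name} must be a probability in [0,1], got {v}")
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 1):
            errors.append(f"n_patients must be a positive integer, got {self.n_patients}")
        if not (
            math.isfinite(self.mean_nodules_per_patient)
            and 1.0 <= self.mean_nodules_per_patient <= MAX_NODULES_PER_PATIENT
        ):
            errors.append(
                "mean_nodules_per_patient must lie in "
                f"[1,{MAX_NODULES_PER_PATIENT}], got {self.mean_nodules_per_patient}"
            )
        if not (math.isfinite(self.mean_slices_per_nodule) and self.mean_slices_per_nodule >= 1):
            errors.append(f"mean_slices_per_nodule must be >= 1, got {self.mean_slices_per_nodule}")
        if not (math.isfinite(self.liver_met_odds_multiplier) and self.liver_met_odds_multiplier > 0):
            errors.append("liver_met_odds_multiplier must be a positive real")
        if not (math.isfinite(self.noise_sd) and self.noise_sd >= 0):
            errors.append(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not math.isfinite(self.background_level):
            errors.append("background_level must be finite")
        if not (math.isfinite(self.class_separation) and self.class_separation >= 0):
            errors.append("class_separation must be >= 0")
        if errors:
            raise ValueError("; ".join(errors))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ReaderProfile:
    """A simulated reader: call accuracy per class + confidence spread.

    ``confidence_spread`` = 0 means the reader always reports Likert 5
    (maximal confidence); large values flatten the confidence distribution
    towards uniform over 1..5.
    """

    reader_id: str
    sensitivity: float
    specificity: float
    confidence_spread: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.confidence_spread < 0:
            raise ValueError("confidence_spread must be >= 0")


# ---------------------------------------------------------------------------
# Patch rendering
# ---------------------------------------------------------------------------

def render_patch(
    phenotype: LesionPhenotype,
    background_level: float,
    noise_sd: float,
    seed: int | np.random.Generator,
    patch_id: str = "patch",
    lesion_id: str = "lesion",
) -> PatchRecord:
    """Render one 32x32 attenuation patch for a nodule phenotype.

    The nodule is a star-shaped region around the patch center whose
    boundary radius varies smoothly with angle (a low-order Fourier
    perturbation scaled by ``boundary_irregularity``).  Its noise-free
    profile drops ``depth`` units below the background, is blurred with a
    Gaussian of ``edge_blur_sigma``, and Gaussian pixel noise of
    ``noise_sd`` is added.  The returned ground-truth mask is the sharp
    (pre-blur) region; it is a single connected component centered in the
    patch and must not touch the patch border.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c = (PATCH_SIZE - 1) / 2.0
    yy, xx = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE]
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # Smooth periodic boundary perturbation; star-shaped => one component.
    amps = rng.normal(0.0, 1.0, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    pert = sum(a * np.cos(k * theta + p) for k, (a, p) in enumerate(zip(amps, phases), start=2))
    pert = pert / math.sqrt(3)
    max_radial = PATCH_SIZE / 2 - 2.0  # keep a margin to the patch border
    if phenotype.radius >= max_radial:
        raise ValueError(
            f"radius {phenotype.radius:.2f} too large: nodule would touch "
            f"the patch border (max {max_radial:.1f})"
        )
    radial = phenotype.radius * np.clip(1.0 + phenotype.boundary_irregularity * pert, 0.25, 2.5)
    radial = np.minimum(radial, max_radial)  # tail perturbations stay inside

    mask = r <= radial
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    assert not np.any(mask & border)

    profile = np.where(mask, 1.0, 0.0)
    if phenotype.edge_blur_sigma > 0:
        profile = ndimage.gaussian_filter(profile, sigma=phenotype.edge_blur_sigma)
    pixels = background_level - phenotype.depth * profile
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    return PatchRecord(patch_id=patch_id, lesion_id=lesion_id, pixels=pixels, mask=mask)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _truncated_poisson_lambda(target_mean: float, cap: int = MAX_NODULES_PER_PATIENT) -> float:
    """Rate of a zero-truncated Poisson capped at ``cap`` whose mean equals
    ``target_mean`` (solved numerically)."""
    if target_mean <= 1.0:
        return 0.0
    if target_mean >= cap:
        return 50.0  # essentially always the cap

    def mean_of(lam: float) -> float:
        k = np.arange(1, cap)
        pmf = stats.poisson.pmf(k, lam) / (1 - stats.poisson.pmf(0, lam))
        tail = 1.0 - pmf.sum()
        return float((k * pmf).sum() + cap * tail)

    return float(optimize.brentq(lambda lam: mean_of(lam) - target_mean, 1e-9, 60.0))


def _sample_capped_ztp(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    """n draws of min(ZTPoisson(lam), cap)."""
    if lam <= 0:
        return np.ones(n, dtype=int)
    out = np.zeros(n, dtype=int)
    todo = np.arange(n)
    while todo.size:
        draws = rng.poisson(lam, size=todo.size)
        ok = draws >= 1
        out[todo[ok]] = draws[ok]
        todo = todo[~ok]
    return np.minimum(out, MAX_NODULES_PER_PATIENT)


def _baseline_logit(config: CohortConfig) -> float:
    """Baseline malignancy logit b such that the marginal malignant-nodule
    fraction equals the configured one under the liver-met odds shift."""
    f = config.malignant_nodule_fraction
    if f <= 0.0:
        return -np.inf
    if f >= 1.0:
        return np.inf
    prev = config.liver_met_prevalence
    shift = math.log(config.liver_met_odds_multiplier)

    def marginal(b: float) -> float:
        return prev * _sigmoid(b + shift) + (1 - prev) * _sigmoid(b)

    return float(optimize.brentq(lambda b: marginal(b) - f, -40.0, 40.0))


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z)) if z > -700 else 0.0


def _sample_phenotype(rng: np.random.Generator, label: str, separation: float) -> LesionPhenotype:
    sign = 1.0 if label == MALIGNANT else -1.0
    vals = {}
    for key in _PHENOTYPE_MIDPOINTS:
        mean = _PHENOTYPE_MIDPOINTS[key] + sign * separation * _PHENOTYPE_GAPS[key] / 2.0
        vals[key] = rng.normal(mean, _PHENOTYPE_SDS[key])
    # Clips keep every nodule hypoattenuating, above water attenuation and
    # clear of the patch border even in the distribution tails.
    radius = float(np.clip(vals["radius"], 1.5, 8.0))
    depth = float(np.clip(vals["depth"], 12.0, 85.0))
    blur = float(np.clip(vals["blur"], 0.2, 3.0))
    irregularity = float(np.clip(vals["irregularity"], 0.0, 0.75))
    return LesionPhenotype(
        radius=radius,
        depth=depth,
        edge_blur_sigma=blur,
        boundary_irregularity=irregularity,
        label=label,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Sample a full patient/lesion/patch cohort from ``config``.

    Each nodule's malignancy is Bernoulli on the logit scale: baseline logit
    (solved to hit the marginal malignant fraction) plus
    ``log(liver_met_odds_multiplier)`` when the patient has a synchronous
    >= 1 cm liver metastasis.  Each slice of a nodule is an independent
    re-render with fresh pixel noise and a small downward radius jitter
    (slices away from the nodule equator cut smaller cross-sections).
    """
    root = np.random.SeedSequence(config.seed)
    rng_struct, rng_render = [np.random.default_rng(s) for s in root.spawn(2)]

    lam_nod = _truncated_poisson_lambda(config.mean_nodules_per_patient)
    base_logit = _baseline_logit(config)
    shift = math.log(config.liver_met_odds_multiplier)

    n_nodules = _sample_capped_ztp(rng_struct, lam_nod, config.n_patients)
    liver_met = rng_struct.random(config.n_patients) < config.liver_met_prevalence
    extra_met = rng_struct.random(config.n_patients) < config.extrahepatic_met_prevalence

    patients: list[PatientRecord] = []
    lesions: list[LesionRecord] = []
    patches: list[PatchRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        patient = PatientRecord(
            patient_id=pid,
            liver_met_status=int(liver_met[i]),
            extrahepatic_met_status=int(extra_met[i]),
        )
        p_mal = _sigmoid(base_logit + (shift if liver_met[i] else 0.0))
        for j in range(n_nodules[i]):
            lid = f"{pid}_L{j}"
            label = MALIGNANT if rng_struct.random() < p_mal else BENIGN
            phen = _sample_phenotype(rng_struct, label, config.class_separation)
            lesion = LesionRecord(lesion_id=lid, patient_id=pid, label=label, phenotype=phen)
            n_slices = 1 + rng_struct.poisson(max(config.mean_slices_per_nodule - 1.0, 0.0))
            for s in range(n_slices):
                # off-equator slices cut a smaller cross-section
                jitter = 1.0 if n_slices == 1 else float(rng_struct.uniform(0.8, 1.0))
                slice_phen = dataclasses.replace(
                    phen, radius=max(phen.radius * jitter, 1.2)
                )
                patch = render_patch(
                    slice_phen,
                    background_level=config.background_level,
                    noise_sd=config.noise_sd,
                    seed=rng_render,
                    patch_id=f"{lid}_S{s}",
                    lesion_id=lid,
                )
                lesion.patch_ids.append(patch.patch_id)
                patches.append(patch)
            patient.lesion_ids.append(lid)
            lesions.append(lesion)
        patients.append(patient)
    return Cohort(patients, lesions, patches)


# ---------------------------------------------------------------------------
# Simulated readers
# ---------------------------------------------------------------------------

def simulate_readers(
    cohort: Cohort,
    reader_profiles: list[ReaderProfile],
    seed: int,
) -> list[SimulatedRating]:
    """Simulate benign/malignant calls with Likert confidences per lesion.

    A reader calls a malignant lesion correctly with probability
    ``sensitivity`` and a benign one with ``specificity``.  Confidence is
    drawn from a geometric-like distribution over 5..1 with decay
    ``exp(-1/confidence_spread)``: spread 0 collapses to always-5, large
    spread approaches uniform over 1..5.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ratings: list[SimulatedRating] = []
    levels = np.arange(5, 0, -1)  # 5 (most confident) first
    for profile in reader_profiles:
        if profile.confidence_spread == 0:
            conf_p = np.array([1.0, 0, 0, 0, 0])
        else:
            w = np.exp(-(5 - levels) / profile.confidence_spread)
            conf_p = w / w.sum()
        for lid in sorted(cohort.lesions):
            lesion = cohort.lesions[lid]
            p_correct = profile.sensitivity if lesion.is_malignant else profile.specificity
            correct = rng.random() < p_correct
            call = lesion.label if correct else (BENIGN if lesion.is_malignant else MALIGNANT)
            confidence = int(levels[rng.choice(5, p=conf_p)])
            ratings.append(
                SimulatedRating(
                    reader_id=profile.reader_id,
                    lesion_id=lid,
                    call=call,
                    confidence=confidence,
                )
            )
    return ratings
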