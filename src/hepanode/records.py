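"""Core record types for patient / lesion / patch cohorts.

The data model mirrors how small hypoattenuating hepatic nodules (SHHN,
< 1 cm, "too small to characterize") present on contrast-enhanced CT in a
staging cohort: each *patient* carries one to six indeterminate nodules
(*lesions*), each lesion spans a few axial slices, and every slice
contributes one 32x32 attenuation *patch* with a ground-truth mask.  The
patient additionally carries two scan-level covariates: presence of a
definitive synchronous >= 1 cm hepatic metastasis (the fusion model's X2)
and synchronous extrahepatic metastatic disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PATCH_SIZE = 32

BENIGN = "benign"
MALIGNANT = "malignant"


@dataclass(frozen=True)
class LesionPhenotype:
    """Physical parameters of one rendered nodule.

    Attributes
    ----------
    radius : float
        Nominal nodule radius in pixels; must leave a margin to the patch
        border (the nodule is < 10 mm, i.e. smaller than the patch).
    depth : float
        Background minus nodule-core attenuation (HU-like units).  Positive
        by definition: the nodule is hypoattenuating relative to enhanced
        liver, but never reaches water attenuation (definite cysts are
        excluded by the selection rule).
    edge_blur_sigma : float
        Gaussian blur applied to the noise-free nodule profile; larger
        values produce less sharp margins.
    boundary_irregularity : float
        Amplitude of the angular perturbation of the nodule boundary;
        0 renders a disk, larger values lower the mask's solidity.
    label : str
        ``"benign"`` or ``"malignant"`` — the reference-standard class.
    """

    radius: float
    depth: float
    edge_blur_sigma: float
    boundary_irregularity: float
    label: str

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not (self.depth >= 0):
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.edge_blur_sigma < 0:
            raise ValueError("edge_blur_sigma must be >= 0")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"label must be benign/malignant, got {self.label!r}")


@dataclass
class PatchRecord:
    """One 32x32 attenuation patch plus its ground-truth nodule mask."""

    patch_id: str
    lesion_id: str
    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"pixels must be {PATCH_SIZE}x{PATCH_SIZE}")
        if self.mask.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"mask must be {PATCH_SIZE}x{PATCH_SIZE}")


@dataclass
class LesionRecord:
    """One nodule: reference-standard label, phenotype and its patch ids."""

    lesion_id: str
    patient_id: str
    label: str
    phenotype: LesionPhenotype
    patch_ids: list[str] = field(default_factory=list)

    @property
    def is_malignant(self) -> bool:
        return self.label == MALIGNANT


@dataclass
class PatientRecord:
    """One patient: scan-level metastasis covariates and lesion ids."""

    patient_id: str
    liver_met_status: int
    extrahepatic_met_status: int
    lesion_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SimulatedRating:
    """A simulated reader's call + 5-point Likert confidence for one lesion."""

    reader_id: str
    lesion_id: str
    call: str
    confidence: int

    def __post_init__(self) -> None:
        if self.call not in (BENIGN, MALIGNANT):
            raise ValueError(f"call must be benign/malignant, got {self.call!r}")
        if self.confidence not in (1, 2, 3, 4, 5):
            raise ValueError(f"confidence must be in 1..5, got {self.confidence}")


class Cohort:
    """A full synthetic cohort: patients, lesions and patches, keyed by id."""

    def __init__(
        self,
        patients: list[PatientRecord],
        lesions: list[LesionRecord],
        patches: list[PatchRecord],
    ) -> None:
        self.patients = {p.patient_id: p for p in patients}
        self.lesions = {l.lesion_id: l for l in lesions}
        self.patches = {p.patch_id: p for p in patches}
        if len(self.patients) != len(patients):
            raise ValueError("duplicate patient ids")
        if len(self.lesions) != len(lesions):
            raise ValueError("duplicate lesion ids")
        if len(self.patches) != len(patches):
            raise ValueError("duplicate patch ids")

    # -- convenience views -------------------------------------------------
    def patient_of_lesion(self, lesion_id: str) -> PatientRecord:
        return self.patients[self.lesions[lesion_id].patient_id]

    def lesions_of_patient(self, patient_id: str) -> list[LesionRecord]:
        return [self.lesions[i] for i in self.patients[patient_id].lesion_ids]

    def patches_of_lesion(self, lesion_id: str) -> list[PatchRecord]:
        return [self.patches[i] for i in self.lesions[lesion_id].patch_ids]

    def patch_label(self, patch_id: str) -> str:
        return self.lesions[self.patches[patch_id].lesion_id].label

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def lesion_labels(self) -> dict[str, int]:
        """Map lesion_id -> 0/1 malignancy indicator."""
        return {l.lesion_id: int(l.is_malignant) for l in self.lesions.values()}

    def patch_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Stack all patches into (pixels, labels, patch_ids) arrays."""
        ids = sorted(self.patches)
        pixels = np.stack([self.patches[i].pixels for i in ids])
        labels = np.array([int(self.patch_label(i) == MALIGNANT) for i in ids])
        return pixels, labels, ids
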