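"""On-disk cohort format: CSV metadata tables + an array archive of patches.

Layout written by :func:`write_cohort` into a directory:

* ``patients.csv`` — patient_id, liver_met_status, extrahepatic_met_status
* ``lesions.csv``  — lesion_id, patient_id, label + phenotype columns
* ``patches.csv``  — patch_id, lesion_id
* ``patches.npz``  — ``pixels_<patch_id>`` / ``mask_<patch_id>`` arrays
* ``ratings.csv``  — optional simulated reader ratings
* ``config.json``  — optional generator config

:func:`export_patch_pngs` additionally writes 16-bit grayscale PNGs for
visual inspection; the npz archive remains the authoritative store.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import Cohort, LesionPhenotype, LesionRecord, PatchRecord, PatientRecord, SimulatedRating


def write_cohort(cohort: Cohort, out_dir: str | Path, config_json: str | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "liver_met_status": p.liver_met_status,
                "extrahepatic_met_status": p.extrahepatic_met_status,
            }
            for p in cohort.patients.values()
        ]
    ).sort_values("patient_id").to_csv(out / "patients.csv", index=False)
    pd.DataFrame(
        [
            {
                "lesion_id": l.lesion_id,
                "patient_id": l.patient_id,
                "label": l.label,
                "radius": l.phenotype.radius,
                "depth": l.phenotype.depth,
                "edge_blur_sigma": l.phenotype.edge_blur_sigma,
                "boundary_irregularity": l.phenotype.boundary_irregularity,
            }
            for l in cohort.lesions.values()
        ]
    ).sort_values("lesion_id").to_csv(out / "lesions.csv", index=False)
    pd.DataFrame(
        [{"patch_id": p.patch_id, "lesion_id": p.lesion_id} for p in cohort.patches.values()]
    ).sort_values("patch_id").to_csv(out / "patches.csv", index=False)
    arrays: dict[str, np.ndarray] = {}
    for pid in sorted(cohort.patches):
        patch = cohort.patches[pid]
        arrays[f"pixels_{pid}"] = patch.pixels
        arrays[f"mask_{pid}"] = patch.mask
    np.savez_compressed(out / "patches.npz", **arrays)
    if config_json is not None:
        (out / "config.json").write_text(config_json)


def read_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    pats = pd.read_csv(src / "patients.csv")
    les = pd.read_csv(src / "lesions.csv")
    pats_df = pd.read_csv(src / "patches.csv")
    archive = np.load(src / "patches.npz")

    patients = [
        PatientRecord(
            patient_id=row.patient_id,
            liver_met_status=int(row.liver_met_status),
            extrahepatic_met_status=int(row.extrahepatic_met_status),
        )
        for row in pats.itertuples()
    ]
    lesions = [
        LesionRecord(
            lesion_id=row.lesion_id,
            patient_id=row.patient_id,
            label=row.label,
            phenotype=LesionPhenotype(
                radius=row.radius,
                depth=row.depth,
                edge_blur_sigma=row.edge_blur_sigma,
                boundary_irregularity=row.boundary_irregularity,
                label=row.label,
            ),
        )
        for row in les.itertuples()
    ]
    patches = [
        PatchRecord(
            patch_id=row.patch_id,
            lesion_id=row.lesion_id,
            pixels=archive[f"pixels_{row.patch_id}"],
            mask=archive[f"mask_{row.patch_id}"],
        )
        for row in pats_df.itertuples()
    ]
    by_patient = {p.patient_id: p for p in patients}
    by_lesion = {l.lesion_id: l for l in lesions}
    for lesion in lesions:
        by_patient[lesion.patient_id].lesion_ids.append(lesion.lesion_id)
    for patch in patches:
        by_lesion[patch.lesion_id].patch_ids.append(patch.patch_id)
    return Cohort(patients, lesions, patches)


def write_ratings(ratings: list[SimulatedRating], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "reader_id": r.reader_id,
                "lesion_id": r.lesion_id,
                "call": r.call,
                "confidence": r.confidence,
            }
            for r in ratings
        ]
    ).to_csv(path, index=False)


def read_ratings(path: str | Path) -> list[SimulatedRating]:
    df = pd.read_csv(path)
    return [
        SimulatedRating(
            reader_id=str(row.reader_id),
            lesion_id=str(row.lesion_id),
            call=row.call,
            confidence=int(row.confidence),
        )
        for row in df.itertuples()
    ]


def export_patch_pngs(cohort: Cohort, out_dir: str | Path, window: tuple[float, float] = (-50.0, 150.0)) -> None:
    """Write each patch as a 16-bit grayscale PNG, linearly windowed."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo, hi = window
    for pid in sorted(cohort.patches):
        px = cohort.patches[pid].pixels
        scaled = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
        iio.imwrite(out / f"{pid}.png", (scaled * 65535).astype(np.uint16))
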