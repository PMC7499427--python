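"""Patient-grouped cross-validated training of the patch CNN.

The cohort's patients are stratified into 5 groups of approximately equal
numbers of patients, lesions and patches; all lesions of a patient stay in
one group, so no patient's data ever appears on both sides of a
train/evaluate split.  Five models are trained, each on 4 of the 5
groups; held-out predictions come from each lesion's own fold model,
while external cohorts are scored by averaging the 5 saved models.

Patch probabilities are aggregated to a lesion probability by the
arithmetic mean (permutation-invariant; ``max`` available), and lesions
are called malignant at a probability threshold of 0.5, ties going to
malignant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .augmentation import EpochSamplingPlan, balanced_epoch, center_crop
from .evaluation import roc_auc
from .nn import Adam, ArchitectureSpec, SmallCNN
from .records import Cohort

THRESHOLD = 0.5


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (batch 80 / 50 epochs by default)."""

    batch_size: int = 80
    epochs: int = 50
    n_folds: int = 5
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class FoldAssignment:
    """Patient-level fold partition."""

    fold_of_patient: dict[str, int]
    n_folds: int

    def patients_in_fold(self, k: int) -> list[str]:
        return sorted(p for p, f in self.fold_of_patient.items() if f == k)

    def fold_of_lesion(self, cohort: Cohort, lesion_id: str) -> int:
        return self.fold_of_patient[cohort.lesions[lesion_id].patient_id]


def assign_group_folds(
    patient_weights: dict[str, int],
    n_folds: int,
    seed: int = 0,
) -> FoldAssignment:
    """Greedy balanced partition of patients into folds.

    ``patient_weights`` maps patient_id to that patient's patch count.
    Patients are taken in decreasing weight order (seeded shuffle breaks
    ties) and each goes to the currently lightest fold — the classic LPT
    heuristic, which keeps patients, lesions and patches near-equal across
    folds while guaranteeing each patient occupies exactly one fold.
    """
    if len(patient_weights) < n_folds:
        raise ValueError(
            f"need at least {n_folds} patients for {n_folds} folds, got {len(patient_weights)}"
        )
    rng = np.random.default_rng(seed)
    ids = sorted(patient_weights)
    rng.shuffle(ids)
    ids.sort(key=lambda p: -patient_weights[p])  # stable: ties stay shuffled
    load = np.zeros(n_folds)
    count = np.zeros(n_folds, dtype=int)
    assignment: dict[str, int] = {}
    for pid in ids:
        # lightest fold; ties -> fewest patients -> lowest index
        k = min(range(n_folds), key=lambda f: (load[f], count[f], f))
        assignment[pid] = k
        load[k] += patient_weights[pid]
        count[k] += 1
    return FoldAssignment(assignment, n_folds)


def aggregate_lesion(patch_probabilities: Sequence[float], method: str = "mean") -> float:
    """Combine a lesion's patch probabilities into one lesion probability."""
    probs = np.asarray(patch_probabilities, dtype=float)
    if probs.size == 0:
        raise ValueError("aggregate_lesion needs at least one patch probability")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("patch probabilities must lie in [0,1]")
    if method == "mean":
        return float(probs.mean())
    if method == "max":
        return float(probs.max())
    raise ValueError(f"unknown aggregation method {method!r}")


def classify(lesion_probability: float, threshold: float = THRESHOLD) -> str:
    """Threshold call; exactly at threshold counts as malignant (the tie
    favors sensitivity in an oncologic setting)."""
    if not (0.0 <= lesion_probability <= 1.0):
        raise ValueError(f"probability must be in [0,1], got {lesion_probability}")
    return "malignant" if lesion_probability >= threshold else "benign"


@dataclass
class FoldMetrics:
    fold: int
    patch_auc: float
    lesion_auc: float
    epoch_losses: list[float] = field(default_factory=list)


@dataclass
class TrainedEnsemble:
    """The 5 fold models + fold assignment + normalization constants."""

    models: list[SmallCNN]
    assignment: FoldAssignment
    norm_mean: float
    norm_sd: float
    fold_metrics: list[FoldMetrics]
    config: TrainingConfig
    aggregation: str = "mean"

    # -- prediction --------------------------------------------------------
    def _standardize(self, patches_24: np.ndarray) -> np.ndarray:
        return (np.asarray(patches_24, dtype=float) - self.norm_mean) / self.norm_sd

    def predict_patch_proba(self, patches_32: np.ndarray, model: SmallCNN | None = None) -> np.ndarray:
        """Ensemble-mean (or single-model) probability for 32x32 patches,
        center-cropped and standardized."""
        patches_32 = np.atleast_3d(np.asarray(patches_32, dtype=float))
        if patches_32.ndim == 2:
            patches_32 = patches_32[None]
        x = self._standardize(np.stack([center_crop(p) for p in patches_32]))
        if model is not None:
            return model.predict_proba(x)
        return np.mean([m.predict_proba(x) for m in self.models], axis=0)

    def lesion_probabilities(
        self, cohort: Cohort, out_of_fold: bool = False
    ) -> dict[str, float]:
        """Lesion probabilities for a cohort.

        With ``out_of_fold=True`` each lesion is scored by its own fold's
        model (valid only for the training cohort, and yields honest
        held-out predictions); otherwise the 5 models are averaged.
        """
        out: dict[str, float] = {}
        for lid in sorted(cohort.lesions):
            patches = np.stack([p.pixels for p in cohort.patches_of_lesion(lid)])
            model = None
            if out_of_fold:
                model = self.models[self.assignment.fold_of_lesion(cohort, lid)]
            probs = self.predict_patch_proba(patches, model=model)
            out[lid] = aggregate_lesion(probs, self.aggregation)
        return out

    @property
    def mean_patch_auc(self) -> float:
        return float(np.mean([m.patch_auc for m in self.fold_metrics]))

    @property
    def mean_lesion_auc(self) -> float:
        return float(np.mean([m.lesion_auc for m in self.fold_metrics]))

    # -- persistence -------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, model in enumerate(self.models):
            np.savez(out / f"fold{k}.npz", **model.state_dict())
        manifest = {
            "n_folds": self.assignment.n_folds,
            "fold_of_patient": self.assignment.fold_of_patient,
            "norm_mean": self.norm_mean,
            "norm_sd": self.norm_sd,
            "aggregation": self.aggregation,
            "architecture": vars(self.models[0].arch) if hasattr(self.models[0].arch, "__dict__") else self.models[0].arch.__dict__,
            "training": self.config.__dict__,
            "fold_metrics": [
                {"fold": m.fold, "patch_auc": m.patch_auc, "lesion_auc": m.lesion_auc,
                 "epoch_losses": m.epoch_losses}
                for m in self.fold_metrics
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "TrainedEnsemble":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        arch = ArchitectureSpec(**manifest["architecture"])
        models = []
        for k in range(manifest["n_folds"]):
            model = SmallCNN(arch)
            with np.load(src / f"fold{k}.npz") as data:
                model.load_state_dict(dict(data))
            models.append(model)
        return cls(
            models=models,
            assignment=FoldAssignment(manifest["fold_of_patient"], manifest["n_folds"]),
            norm_mean=manifest["norm_mean"],
            norm_sd=manifest["norm_sd"],
            fold_metrics=[FoldMetrics(**m) for m in manifest["fold_metrics"]],
            config=TrainingConfig(**manifest["training"]),
            aggregation=manifest["aggregation"],
        )


def train_cross_validated(
    cohort: Cohort,
    arch: ArchitectureSpec | None = None,
    cfg: TrainingConfig | None = None,
    plan: EpochSamplingPlan | None = None,
    aggregation: str = "mean",
) -> TrainedEnsemble:
    """Train ``cfg.n_folds`` CNNs under patient-grouped cross-validation.

    Each fold model sees only patches from patients outside its evaluation
    group; every epoch is a fresh oversampled, augmented draw.  Per-fold
    held-out patch-level and lesion-level AUCs and the per-epoch training
    losses are recorded.  If no sampling plan is given, benign patches are
    oversampled x2 and malignant patches by the exact-balance factor.
    """
    arch = arch or ArchitectureSpec()
    cfg = cfg or TrainingConfig()
    root = np.random.SeedSequence(cfg.seed)
    seeds = root.spawn(cfg.n_folds * 2 + 1)
    fold_seed = int(seeds[-1].generate_state(1)[0] % (2**31))

    weights = {
        pid: sum(len(cohort.lesions[lid].patch_ids) for lid in p.lesion_ids)
        for pid, p in cohort.patients.items()
    }
    assignment = assign_group_folds(weights, cfg.n_folds, seed=fold_seed)

    pixels, labels, patch_ids = cohort.patch_arrays()
    patch_fold = np.array(
        [assignment.fold_of_patient[cohort.patient_of_lesion(cohort.patches[i].lesion_id).patient_id]
         for i in patch_ids]
    )
    lesion_label = cohort.lesion_labels()
    for k in range(cfg.n_folds):
        fold_lesions = {
            lid for lid in cohort.lesions
            if assignment.fold_of_lesion(cohort, lid) == k
        }
        classes = {lesion_label[lid] for lid in fold_lesions}
        if classes != {0, 1}:
            raise ValueError(f"fold {k} does not contain both classes (labels seen: {sorted(classes)})")

    norm_mean = float(pixels.mean())
    norm_sd = float(pixels.std())
    if norm_sd == 0:
        raise ValueError("degenerate cohort: zero pixel variance")

    if plan is None:
        n_b = int((labels == 0).sum())
        n_m = int((labels == 1).sum())
        plan = EpochSamplingPlan.exact_balance(n_b, n_m, seed=cfg.seed)

    models: list[SmallCNN] = []
    metrics: list[FoldMetrics] = []
    for k in range(cfg.n_folds):
        train_mask = patch_fold != k
        train_px = [pixels[i] for i in np.flatnonzero(train_mask)]
        train_y = labels[train_mask]
        model_seed = int(seeds[2 * k].generate_state(1)[0] % (2**31))
        sample_rng = np.random.default_rng(seeds[2 * k + 1])
        model = SmallCNN(arch, seed=model_seed)
        opt = Adam(model.params, lr=cfg.learning_rate)
        drop_rng = np.random.default_rng(seeds[2 * k + 1].spawn(1)[0])
        losses: list[float] = []
        for _ in range(cfg.epochs):
            batch_x: list[np.ndarray] = []
            batch_y: list[int] = []
            epoch_loss = 0.0
            n_batches = 0

            def flush() -> None:
                nonlocal epoch_loss, n_batches
                x = (np.stack(batch_x) - norm_mean) / norm_sd
                loss, grads = model.loss_and_grads(x, np.array(batch_y), drop_rng)
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
                batch_x.clear()
                batch_y.clear()

            for patch24, y in balanced_epoch(train_px, train_y, plan, rng=sample_rng):
                batch_x.append(patch24)
                batch_y.append(y)
                if len(batch_x) == cfg.batch_size:
                    flush()
            if batch_x:
                flush()
            losses.append(epoch_loss / max(n_batches, 1))

        # held-out evaluation on fold k
        eval_idx = np.flatnonzero(~train_mask)
        x_eval = np.stack([center_crop(pixels[i]) for i in eval_idx])
        probs = model.predict_proba((x_eval - norm_mean) / norm_sd)
        patch_auc = roc_auc(probs, labels[eval_idx]).auc
        eval_lesions = sorted(
            lid for lid in cohort.lesions if assignment.fold_of_lesion(cohort, lid) == k
        )
        lesion_probs, lesion_y = [], []
        id_to_pos = {pid: j for j, pid in enumerate(patch_ids)}
        for lid in eval_lesions:
            pos = [id_to_pos[pid] for pid in cohort.lesions[lid].patch_ids]
            idx_in_eval = [np.flatnonzero(eval_idx == p)[0] for p in pos]
            lesion_probs.append(aggregate_lesion(probs[idx_in_eval], aggregation))
            lesion_y.append(lesion_label[lid])
        lesion_auc = roc_auc(np.array(lesion_probs), np.array(lesion_y)).auc
        models.append(model)
        metrics.append(FoldMetrics(fold=k, patch_auc=patch_auc, lesion_auc=lesion_auc,
                                   epoch_losses=losses))

    return TrainedEnsemble(
        models=models,
        assignment=assignment,
        norm_mean=norm_mean,
        norm_sd=norm_sd,
        fold_metrics=metrics,
        config=cfg,
        aggregation=aggregation,
    )
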