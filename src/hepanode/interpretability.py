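"""Physical nodule features, probability clustering and embeddings.

Four region features known to differentiate benign from malignant small
hepatic nodules are quantified per patch from the ground-truth mask:

* **area** — mask pixel count (malignant nodules tend to be larger);
* **mean central attenuation** — mean over the central 3x3 pixel block
  (malignant nodules sit closer to enhanced-liver attenuation);
* **edge sharpness** — mean attenuation just outside the margin minus
  just inside it (1-pixel morphological bands; benign margins are
  sharper);
* **solidity** — mask area over convex-hull area (benign margins are
  more regular).

The module also clusters lesions by CNN malignancy probability (1-d
k-means), tests benign-vs-malignant feature differences (Welch t and
Mann-Whitney), and embeds the CNN's 64-d penultimate features in 2-d
with t-SNE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import label as cc_label, regionprops
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .records import PatchRecord


@dataclass(frozen=True)
class NoduleFeatures:
    area: float
    mean_central_attenuation: float
    edge_sharpness: float
    solidity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area,
            "mean_central_attenuation": self.mean_central_attenuation,
            "edge_sharpness": self.edge_sharpness,
            "solidity": self.solidity,
        }


FEATURE_NAMES = ("area", "mean_central_attenuation", "edge_sharpness", "solidity")


def compute_features(patch: PatchRecord, band_width: int = 1) -> NoduleFeatures:
    """Quantify the four physical features of one patch.

    The inner margin band is the mask minus its ``band_width``-pixel
    erosion; the outer band is the ``band_width``-pixel dilation minus the
    mask (4-connected structuring element, so the bands are invariant
    under rotations and reflections of the patch).
    """
    mask = patch.mask
    if not mask.any():
        raise ValueError("empty mask")
    if cc_label(mask).max() != 1:
        raise ValueError("mask must be a single connected component")
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if np.any(mask & border):
        raise ValueError("mask touches the patch border: margin bands undefined")

    pixels = patch.pixels
    n = mask.shape[0]
    # "central 9 pixels": a 3x3 grid of unit-spaced sample points centered
    # on the exact patch center.  The grid is even-sized, so the points sit
    # at half-integer coordinates and each is read bilinearly (= mean of
    # its 4 neighbors); equivalently a [1,2,2,1]/6-weighted mean over the
    # central 4x4 block.  This keeps the feature exactly symmetric under
    # rotations/reflections of the patch.
    w = np.array([1.0, 2.0, 2.0, 1.0]) / 6.0
    c0 = n // 2 - 2
    block = pixels[c0 : c0 + 4, c0 : c0 + 4]
    central_mean = float(w @ block @ w)

    inner = mask & ~ndimage.binary_erosion(mask, iterations=band_width)
    outer = ndimage.binary_dilation(mask, iterations=band_width) & ~mask
    edge_sharpness = float(pixels[outer].mean() - pixels[inner].mean())

    props = regionprops(mask.astype(np.uint8))[0]
    return NoduleFeatures(
        area=float(mask.sum()),
        mean_central_attenuation=central_mean,
        edge_sharpness=edge_sharpness,
        solidity=float(props.solidity),
    )


def feature_table(patches: list[PatchRecord], band_width: int = 1) -> pd.DataFrame:
    """One row of features per patch, indexed by patch and lesion id."""
    rows = []
    for p in patches:
        feats = compute_features(p, band_width=band_width)
        rows.append({"patch_id": p.patch_id, "lesion_id": p.lesion_id, **feats.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Probability clustering
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityClustering:
    k: int
    cluster_of: dict[str, int]     # lesion_id -> cluster id (0..k-1)
    centroids: np.ndarray          # ascending probability centroids

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lesion_id": list(self.cluster_of), "cluster": list(self.cluster_of.values())}
        )


def cluster_by_probability(
    lesion_probabilities: dict[str, float],
    k: int = 5,
    seed: int = 0,
) -> ProbabilityClustering:
    """1-d k-means over lesion malignancy probabilities.

    Clusters are relabelled so ids increase with the probability centroid
    (cluster 0 = most benign-looking, k-1 = most malignant-looking).
    """
    ids = sorted(lesion_probabilities)
    values = np.array([lesion_probabilities[i] for i in ids], dtype=float)
    if values.size < k:
        raise ValueError(f"need at least k={k} lesions, got {values.size}")
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    raw = km.fit_predict(values.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = {int(old): new for new, old in enumerate(order)}
    assignment = {i: relabel[int(c)] for i, c in zip(ids, raw)}
    centroids = np.sort(km.cluster_centers_.ravel())
    return ProbabilityClustering(k=k, cluster_of=assignment, centroids=centroids)


# ---------------------------------------------------------------------------
# Class tests
# ---------------------------------------------------------------------------

def feature_class_tests(features: pd.DataFrame, labels: dict[str, int]) -> pd.DataFrame:
    """Benign-vs-malignant two-sample tests per feature.

    ``features`` must carry a ``lesion_id`` column plus the four feature
    columns; ``labels`` maps lesion_id to 0/1.  Both a Welch t test and a
    Mann-Whitney U test (two-sided) are reported per feature.
    """
    y = features["lesion_id"].map(labels)
    if y.isna().any():
        raise ValueError("every row needs a label")
    if y.nunique() != 2:
        raise ValueError("both classes must be present")
    rows = []
    for name in FEATURE_NAMES:
        benign = features.loc[y == 0, name].to_numpy()
        malignant = features.loc[y == 1, name].to_numpy()
        if min(benign.size, malignant.size) < 2:
            raise ValueError(f"need >= 2 observations per class for {name}")
        t_stat, t_p = stats.ttest_ind(malignant, benign, equal_var=False)
        u_stat, u_p = stats.mannwhitneyu(malignant, benign, alternative="two-sided")
        rows.append(
            {
                "feature": name,
                "benign_mean": benign.mean(),
                "malignant_mean": malignant.mean(),
                "welch_t": float(t_stat),
                "welch_p": float(t_p),
                "mannwhitney_u": float(u_stat),
                "mannwhitney_p": float(u_p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

@dataclass
class Embedding2D:
    coords: np.ndarray    # (n, 2)
    perplexity: float
    seed: int


def extract_presoftmax(ensemble_or_model, patches_32: np.ndarray) -> np.ndarray:
    """64-d penultimate (dense-layer) activations for 32x32 patches.

    Accepts either a single model with ``penultimate_features`` plus
    explicit standardization, or a :class:`~hepanode.classifier.TrainedEnsemble`
    (features from the first fold model, using the ensemble's
    normalization constants).
    """
    from .augmentation import center_crop  # local import avoids cycle

    patches_32 = np.asarray(patches_32, dtype=float)
    if patches_32.ndim == 2:
        patches_32 = patches_32[None]
    x = np.stack([center_crop(p) for p in patches_32])
    if hasattr(ensemble_or_model, "models"):
        ens = ensemble_or_model
        x = (x - ens.norm_mean) / ens.norm_sd
        return ens.models[0].penultimate_features(x)
    return ensemble_or_model.penultimate_features(x)


def tsne_embed(vectors: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> Embedding2D:
    """2-d t-SNE embedding of feature vectors (requires n > 3*perplexity)."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be a 2-d array (n, d)")
    if vectors.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={vectors.shape[0]} "
            "(need n > 3*perplexity)"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(vectors)
    return Embedding2D(coords=np.asarray(coords), perplexity=perplexity, seed=seed)
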