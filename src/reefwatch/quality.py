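"""Automatic image-quality screening by PCA ordination of calibrated panel colors.

After calibration, frames acquired under good visibility cluster tightly in
RGB space (the panel is a uniform target), while turbid or badly lit frames
drift away.  Each frame is summarized by the mean calibrated RGB of the
panel-center window, the summaries are ordinated by PCA, and frames are kept
when they fall inside the training cloud of manually vetted good-visibility
frames (Mahalanobis rule) or, alternatively, on the positive side of PC1 and
PC3 (the sign rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImageFeature",
    "ScreenResult",
    "build_feature_table",
    "pca_ordinate",
    "select_images",
]


@dataclass(frozen=True)
class ImageFeature:
    """Mean calibrated RGB of the panel-center window for one frame."""

    image_id: str
    timestamp: object
    mean_rgb: tuple[float, float, float]


@dataclass
class ScreenResult:
    """PCA scores plus the per-frame keep/discard decision."""

    features: list[ImageFeature]
    scores: np.ndarray            # (n, k) PC coordinates
    loadings: np.ndarray          # (3, k) loading vectors (columns)
    explained_variance: np.ndarray  # fractions, sum <= 1
    selected: np.ndarray          # (n,) bool
    rule: str

    def to_frame(self) -> pd.DataFrame:
        """Screening report: image_id, timestamp, pc1..pc3, selected, reason."""
        k = self.scores.shape[1]
        data = {
            "image_id": [f.image_id for f in self.features],
            "timestamp": [f.timestamp for f in self.features],
        }
        for j in range(min(k, 3)):
            data[f"pc{j + 1}"] = self.scores[:, j]
        data["selected"] = self.selected
        data["reason"] = np.where(self.selected, "inlier", f"outlier:{self.rule}")
        return pd.DataFrame(data)


def build_feature_table(
    images: dict[str, np.ndarray] | list[tuple[str, object, np.ndarray]],
    center_region: tuple[int, int, int, int],
) -> list[ImageFeature]:
    """One feature row per frame: mean RGB over ``center_region``.

    ``images`` is either a mapping image_id -> array, or a list of
    ``(image_id, timestamp, array)``.  ``center_region`` is a half-open pixel
    rectangle ``(row0, col0, row1, col1)`` that must lie inside every frame.
    """
    if isinstance(images, dict):
        items = [(key, None, arr) for key, arr in images.items()]
    else:
        items = list(images)
    r0, c0, r1, c1 = center_region
    out = []
    for image_id, timestamp, arr in items:
        arr = np.asarray(arr)
        h, w = arr.shape[:2]
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(
                f"{image_id}: center region {center_region} outside image {(h, w)}"
            )
        mean = arr[r0:r1, c0:c1].astype(float).mean(axis=(0, 1))
        out.append(ImageFeature(image_id, timestamp, tuple(mean)))
    return out


def pca_ordinate(features: list[ImageFeature]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-centered SVD PCA of the n x 3 feature matrix.

    Covariance (not correlation) PCA: the three channels share 8-bit units.
    Sign convention: each loading vector's largest-magnitude element is made
    positive, so ordinations are reproducible across runs and platforms.

    Returns ``(scores, loadings, explained_variance_fractions)``.
    """
    if len(features) < 4:
        raise ValueError("PCA screening needs at least 4 images")
    x = np.array([f.mean_rgb for f in features], dtype=float)
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate input: all feature rows identical")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|.| element of each loading positive
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    explained = s ** 2 / np.sum(s ** 2)
    return scores, vt.T, explained


def select_images(
    features: list[ImageFeature],
    training_ids: set[str] | list[str],
    rule: str = "mahalanobis",
    coverage: float = 0.99,
) -> ScreenResult:
    """Keep frames that resemble the manually vetted good-visibility set.

    ``mahalanobis`` (default): a frame is kept iff its squared Mahalanobis
    distance to the training-score cloud over PC1-PC3 is at most the chi-square
    (3 df) quantile at ``coverage``; the threshold is raised to the training
    cloud's own maximum so training frames are always kept.  ``pc_sign``: keep
    iff PC1 > 0 and PC3 > 0.
    """
    training_ids = set(training_ids)
    ids = [f.image_id for f in features]
    unknown = training_ids - set(ids)
    if unknown:
        raise ValueError(f"training ids not among images: {sorted(unknown)[:5]}")
    if len(training_ids) < 3:
        raise ValueError("need at least 3 training images")

    scores, loadings, explained = pca_ordinate(features)
    k = scores.shape[1]
    if rule == "pc_sign":
        if k < 3:
            raise ValueError("pc_sign rule needs 3 components")
        selected = (scores[:, 0] > 0) & (scores[:, 2] > 0)
    elif rule == "mahalanobis":
        train_mask = np.array([i in training_ids for i in ids])
        train = scores[train_mask]
        mean = train.mean(axis=0)
        cov = np.cov(train, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular training covariance; falling back to diagonal")
            inv = np.diag(1.0 / np.maximum(np.diag(cov), 1e-12))
        delta = scores - mean
        d2 = np.einsum("ij,jk,ik->i", delta, inv, delta)
        threshold = stats.chi2.ppf(coverage, df=k)
        threshold = max(threshold, d2[train_mask].max())  # never drop training frames
        selected = d2 <= threshold
    else:
        raise ValueError(f"unknown selection rule {rule!r}")

    return ScreenResult(
        features=features,
        scores=scores,
        loadings=loadings,
        explained_variance=explained,
        selected=selected,
        rule=rule,
    )
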