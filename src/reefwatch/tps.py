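"""3D thin-plate-spline color calibration.

Each frame carries the nine-patch chart; the observed patch means define a
smooth warp of RGB space (biharmonic kernel phi(r) = r plus an affine part)
that pins each observed patch color to its reference sRGB.  Applying the warp
to every pixel normalizes the frame's colors across illumination conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .colorimetry import ChartReference

__all__ = [
    "TPSColorModel",
    "PatchObservation",
    "extract_patch_means",
    "fit_tps3d",
    "apply_tps3d",
]

_SCALE = 255.0  # colors are normalized to [0, 1] for conditioning


@dataclass(frozen=True)
class PatchObservation:
    """Mean RGB of one chart patch's central window in a single frame."""

    patch_id: int
    mean_rgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.mean_rgb):
            raise ValueError(f"patch {self.patch_id}: non-finite mean RGB")


@dataclass
class TPSColorModel:
    """Fitted RGB->RGB thin-plate-spline warp.

    f(x) = a0 + A x + sum_i w_i phi(||x - c_i||) per output channel, with
    phi(r) = r (the 3-D biharmonic kernel).  Control points ``c_i`` are the
    nine observed patch means; side conditions sum w = 0 and sum w * c = 0
    hold per channel.  All quantities live in normalized [0, 1] coordinates.
    """

    control_points: np.ndarray  # (9, 3), normalized source colors
    weights: np.ndarray         # (9, 3), one column per output channel
    affine: np.ndarray          # (4, 3): row 0 = a0, rows 1:4 = A^T columns
    lam: float = 0.0

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        return apply_tps3d(self, rgb)

    def to_json(self, path) -> None:
        payload = {
            "control_points": self.control_points.tolist(),
            "weights": self.weights.tolist(),
            "affine": self.affine.tolist(),
            "lambda": self.lam,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TPSColorModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            control_points=np.array(d["control_points"], dtype=float),
            weights=np.array(d["weights"], dtype=float),
            affine=np.array(d["affine"], dtype=float),
            lam=float(d["lambda"]),
        )


def extract_patch_means(image: np.ndarray, chart: ChartReference) -> list[PatchObservation]:
    """Channelwise means over each patch's central window, ordered by patch id.

    Raises a geometry error if any window falls outside the image.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    out = []
    for patch in sorted(chart.patches, key=lambda p: p.patch_id):
        r0, c0, r1, c1 = patch.central_window
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(
                f"patch {patch.patch_id}: central window {patch.central_window} "
                f"outside image of shape {(h, w)}"
            )
        window = image[r0:r1, c0:c1].astype(float)
        out.append(PatchObservation(patch.patch_id, tuple(window.mean(axis=(0, 1)))))
    return out


def fit_tps3d(source: np.ndarray, target: np.ndarray, lam: float = 0.0) -> TPSColorModel:
    """Fit the thin-plate-spline warp pinning source colors onto target colors.

    Solves, per output channel, the polyharmonic system

        [[K + lam*I, P], [P^T, 0]] [w; a] = [t; 0]

    with K_ij = ||c_i - c_j|| and P rows (1, R, G, B).  With ``lam = 0`` the
    warp interpolates the targets exactly at every control point.

    Parameters
    ----------
    source, target : (9, 3) arrays on the 8-bit [0, 255] scale.
    lam : regularization, >= 0, in normalized coordinates.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must both be (n, 3)")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n = source.shape[0]
    src = source / _SCALE
    tgt = target / _SCALE

    diff = src[:, None, :] - src[None, :, :]
    kernel = np.sqrt((diff ** 2).sum(-1))
    dup = [(i + 1, j + 1) for i in range(n) for j in range(i + 1, n)
           if kernel[i, j] < 1e-12]
    if dup:
        raise np.linalg.LinAlgError(
            f"duplicate control points make the TPS system singular: patches {dup}"
        )

    poly = np.hstack([np.ones((n, 1)), src])  # (n, 4)
    system = np.zeros((n + 4, n + 4))
    system[:n, :n] = kernel + lam * np.eye(n)
    system[:n, n:] = poly
    system[n:, :n] = poly.T
    rhs = np.vstack([tgt, np.zeros((4, 3))])
    try:
        solution = np.linalg.solve(system, rhs)
    except np.linalg.LinAlgError as exc:  # degenerate (coplanar) chart
        raise np.linalg.LinAlgError(f"TPS system singular: {exc}") from exc
    return TPSColorModel(
        control_points=src,
        weights=solution[:n],
        affine=solution[n:],
        lam=float(lam),
    )


def apply_tps3d(model: TPSColorModel, image: np.ndarray) -> np.ndarray:
    """Map every pixel through the fitted warp; output clipped to [0, 255].

    Accepts an (h, w, 3) image or an (n, 3) list of colors on the 8-bit
    scale; returns float64 of the same shape.
    """
    arr = np.asarray(image, dtype=float)
    shape = arr.shape
    if shape[-1] != 3:
        raise ValueError("last axis must be RGB")
    flat = arr.reshape(-1, 3) / _SCALE
    dist = np.sqrt(
        ((flat[:, None, :] - model.control_points[None, :, :]) ** 2).sum(-1)
    )  # (npix, n)
    poly = np.hstack([np.ones((flat.shape[0], 1)), flat])
    mapped = dist @ model.weights + poly @ model.affine
    return np.clip(mapped * _SCALE, 0.0, 255.0).reshape(shape)
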