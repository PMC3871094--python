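"""Spectral reflectance to sRGB conversion for the nine-patch calibration chart.

The chart patches are measured pre-deployment with a D50/2-degree integrating-sphere
spectrocolorimeter over 400-700 nm at a 10 nm step.  Those reflectance spectra are
integrated against the measurement illuminant and the CIE 1931 2-degree observer,
chromatically adapted to D65 (Bradford), and encoded as 8-bit sRGB.  The resulting
nine triplets are the fixed calibration targets every image is warped onto.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralReflectance",
    "ChartPatch",
    "ChartReference",
    "WAVELENGTHS_NM",
    "CMF_1931_2DEG",
    "ILLUMINANT_D50",
    "ILLUMINANT_D65",
    "D65_WHITE_XYZ",
    "reflectance_to_xyz",
    "xyz_to_srgb",
    "srgb_encode",
    "srgb_decode",
    "build_chart_reference",
    "read_reflectance_csv",
]

#: Wavelength grid shared by every spectral quantity in this module (nm).
WAVELENGTHS_NM = np.arange(400, 701, 10)

# CIE 1931 2-degree standard observer colour-matching functions, 400-700 nm,
# 10 nm step (columns: xbar, ybar, zbar).  Standard published values.
CMF_1931_2DEG = np.array([
    [0.01431, 0.000396, 0.06785],
    [0.04351, 0.00121, 0.20740],
    [0.13438, 0.00400, 0.64560],
    [0.28390, 0.01160, 1.38560],
    [0.34828, 0.02300, 1.74706],
    [0.33620, 0.03800, 1.77211],
    [0.29080, 0.06000, 1.66920],
    [0.19536, 0.09098, 1.28764],
    [0.09564, 0.13902, 0.81295],
    [0.03201, 0.20802, 0.46518],
    [0.00490, 0.32300, 0.27200],
    [0.00930, 0.50300, 0.15820],
    [0.06327, 0.71000, 0.07825],
    [0.16550, 0.86200, 0.04216],
    [0.29040, 0.95400, 0.02030],
    [0.43345, 0.99495, 0.00875],
    [0.59450, 0.99500, 0.00390],
    [0.76210, 0.95200, 0.00210],
    [0.91630, 0.87000, 0.00165],
    [1.02630, 0.75700, 0.00110],
    [1.06220, 0.63100, 0.00080],
    [1.00260, 0.50300, 0.00034],
    [0.85445, 0.38100, 0.00019],
    [0.64240, 0.26500, 0.00005],
    [0.44790, 0.17500, 0.00002],
    [0.28350, 0.10700, 0.00000],
    [0.16490, 0.06100, 0.00000],
    [0.08740, 0.03200, 0.00000],
    [0.04677, 0.01700, 0.00000],
    [0.02270, 0.00821, 0.00000],
    [0.01136, 0.00410, 0.00000],
])

#: CIE standard illuminant D50 relative spectral power, 400-700 nm, 10 nm step.
ILLUMINANT_D50 = np.array([
    49.31, 56.51, 60.03, 57.82, 74.82, 87.25, 90.61, 91.37, 95.11, 91.96,
    95.72, 96.61, 97.13, 102.10, 100.75, 102.32, 100.00, 97.74, 98.92, 93.50,
    97.69, 99.27, 99.04, 95.72, 98.86, 95.67, 98.19, 103.00, 99.13, 87.38,
    91.60,
])

#: CIE standard illuminant D65 relative spectral power, 400-700 nm, 10 nm step.
ILLUMINANT_D65 = np.array([
    82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81, 114.86, 115.92,
    108.81, 109.35, 107.80, 104.79, 107.69, 104.41, 104.05, 100.00, 96.33,
    95.79, 88.69, 90.01, 89.60, 87.70, 83.29, 83.70, 80.03, 80.21, 82.28,
    78.28, 69.72, 71.61,
])

#: sRGB reference white (D65, Y = 100), IEC 61966-2-1.
D65_WHITE_XYZ = np.array([95.047, 100.0, 108.883])

# Bradford cone-response matrix and the XYZ(D65) -> linear-sRGB matrix.
_BRADFORD = np.array([
    [0.8951, 0.2664, -0.1614],
    [-0.7502, 1.7135, 0.0367],
    [0.0389, -0.0685, 1.0296],
])
_XYZ_TO_RGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


@dataclass(frozen=True)
class SpectralReflectance:
    """A reflectance spectrum on the 400-700 nm grid, 10 nm step.

    Values are unitless reflectance factors; fluorescent patches may exceed 1.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.size == 0 or vals.size == 0:
            raise ValueError("empty spectrum")
        if wl.shape != vals.shape:
            raise ValueError("wavelength grid and values have different lengths")
        steps = np.diff(wl)
        if wl.size > 1 and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("wavelength grid must be strictly increasing and uniform")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("reflectance values must be finite and non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class ChartPatch:
    """One chart patch: its reference sRGB and where it sits in the frame.

    ``patch_region`` and ``central_window`` are ``(row0, col0, row1, col1)``
    half-open pixel rectangles; the window is the area whose channel means are
    extracted for calibration, and must lie inside the patch region.
    """

    patch_id: int
    srgb: tuple[int, int, int]
    patch_region: tuple[int, int, int, int]
    central_window: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.patch_region
        w0, wc0, w1, wc1 = self.central_window
        if not (r0 <= w0 < w1 <= r1 and c0 <= wc0 < wc1 <= c1):
            raise ValueError(
                f"patch {self.patch_id}: central window not inside patch region"
            )
        if not all(0 <= v <= 255 for v in self.srgb):
            raise ValueError(f"patch {self.patch_id}: sRGB out of [0, 255]")


@dataclass
class ChartReference:
    """The nine reference sRGB triplets plus the pixel layout of the chart."""

    patches: list[ChartPatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.patches) != 9:
            raise ValueError(f"chart must have exactly 9 patches, got {len(self.patches)}")
        ids = [p.patch_id for p in self.patches]
        if sorted(ids) != list(range(1, 10)):
            raise ValueError("patch ids must be 1..9")
        for i, a in enumerate(self.patches):
            for b in self.patches[i + 1:]:
                if _rects_overlap(a.patch_region, b.patch_region):
                    raise ValueError(
                        f"patch regions {a.patch_id} and {b.patch_id} overlap"
                    )

    @property
    def srgb_array(self) -> np.ndarray:
        """9x3 float array of reference sRGB values, ordered by patch id."""
        return np.array([p.srgb for p in sorted(self.patches, key=lambda p: p.patch_id)],
                        dtype=float)

    def to_json(self, path) -> None:
        payload = [
            {
                "patch_id": p.patch_id,
                "srgb": list(p.srgb),
                "patch_region": list(p.patch_region),
                "central_window": list(p.central_window),
            }
            for p in self.patches
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ChartReference":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([
            ChartPatch(
                patch_id=d["patch_id"],
                srgb=tuple(d["srgb"]),
                patch_region=tuple(d["patch_region"]),
                central_window=tuple(d["central_window"]),
            )
            for d in payload
        ])


def _rects_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def reflectance_to_xyz(
    spectrum: SpectralReflectance,
    illuminant: np.ndarray = ILLUMINANT_D50,
    observer: np.ndarray = CMF_1931_2DEG,
) -> np.ndarray:
    """Integrate a reflectance spectrum to CIE XYZ tristimulus values.

    X = k * sum R(l) S(l) xbar(l) dl, similarly Y and Z, with the normalization
    k = 100 / sum S(l) ybar(l) dl, so a perfect reflecting diffuser has Y = 100.
    Rectangular quadrature on the shared 10 nm grid; no interpolation.

    Parameters
    ----------
    spectrum
        Reflectance factors on the module grid.
    illuminant
        Relative spectral power of the measurement illuminant, same grid.
    observer
        (n, 3) colour-matching functions, same grid.

    Returns
    -------
    numpy.ndarray
        ``[X, Y, Z]`` with Y in [0, 100] for reflectances in [0, 1].
    """
    illuminant = np.asarray(illuminant, dtype=float)
    observer = np.asarray(observer, dtype=float)
    n = spectrum.values.size
    if illuminant.shape != (n,) or observer.shape != (n, 3):
        raise ValueError("illuminant/observer not on the spectrum's wavelength grid")
    k = 100.0 / np.sum(illuminant * observer[:, 1])
    return k * (spectrum.values * illuminant) @ observer


def _bradford_adapt(xyz: np.ndarray, source_white: np.ndarray,
                    dest_white: np.ndarray = D65_WHITE_XYZ) -> np.ndarray:
    cone_src = _BRADFORD @ source_white
    cone_dst = _BRADFORD @ dest_white
    scale = np.diag(cone_dst / cone_src)
    m = np.linalg.inv(_BRADFORD) @ scale @ _BRADFORD
    return m @ xyz


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """IEC 61966-2-1 transfer curve, linear [0,1] -> encoded [0,1]."""
    linear = np.asarray(linear, dtype=float)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.maximum(linear, 0.0) ** (1 / 2.4) - 0.055,
    )


def srgb_decode(encoded: np.ndarray) -> np.ndarray:
    """Inverse sRGB transfer curve, encoded [0,1] -> linear [0,1]."""
    encoded = np.asarray(encoded, dtype=float)
    return np.where(
        encoded <= 0.04045,
        encoded / 12.92,
        ((encoded + 0.055) / 1.055) ** 2.4,
    )


def xyz_to_srgb(xyz: np.ndarray, source_white: np.ndarray) -> tuple[int, int, int]:
    """Encode XYZ (Y normalized to 100) as an 8-bit sRGB triplet.

    Chromatically adapts from the measurement white to D65 with the Bradford
    transform, applies the IEC 61966-2-1 primaries matrix and transfer curve,
    scales to [0, 255] with round-half-up, and clips.  Out-of-gamut linear
    values are clipped, not gamut mapped.
    """
    xyz = np.asarray(xyz, dtype=float)
    source_white = np.asarray(source_white, dtype=float)
    if not (np.all(np.isfinite(xyz)) and np.all(np.isfinite(source_white))):
        raise ValueError("non-finite XYZ input")
    if np.any(source_white <= 0):
        raise ValueError("source white must be positive")
    adapted = _bradford_adapt(xyz, source_white)
    linear = _XYZ_TO_RGB @ (adapted / 100.0)
    encoded = srgb_encode(np.clip(linear, 0.0, None))
    eight_bit = np.floor(encoded * 255.0 + 0.5)  # round half up
    eight_bit = np.clip(eight_bit, 0, 255).astype(int)
    return tuple(int(v) for v in eight_bit)


def illuminant_white_xyz(
    illuminant: np.ndarray = ILLUMINANT_D50,
    observer: np.ndarray = CMF_1931_2DEG,
) -> np.ndarray:
    """XYZ of the illuminant itself (a perfect diffuser under it), Y = 100."""
    flat = SpectralReflectance(WAVELENGTHS_NM[: len(illuminant)],
                               np.ones(len(illuminant)))
    return reflectance_to_xyz(flat, illuminant, observer)


def build_chart_reference(
    spectra: list[SpectralReflectance],
    patch_layout: list[dict],
    illuminant: np.ndarray = ILLUMINANT_D50,
    observer: np.ndarray = CMF_1931_2DEG,
) -> ChartReference:
    """Convert the nine measured patch spectra into the calibration reference.

    ``patch_layout`` is a list of nine dicts with keys ``patch_id``,
    ``patch_region`` and ``central_window`` (pixel rectangles, row-major,
    half-open).  Spectra are matched to layout entries by position.
    """
    if len(spectra) != 9 or len(patch_layout) != 9:
        raise ValueError("exactly 9 patch spectra and 9 layout entries required")
    white = illuminant_white_xyz(illuminant, observer)
    patches = []
    for spec, layout in zip(spectra, patch_layout):
        xyz = reflectance_to_xyz(spec, illuminant, observer)
        patches.append(ChartPatch(
            patch_id=int(layout["patch_id"]),
            srgb=xyz_to_srgb(xyz, white),
            patch_region=tuple(layout["patch_region"]),
            central_window=tuple(layout["central_window"]),
        ))
    return ChartReference(patches)


def read_reflectance_csv(path) -> list[SpectralReflectance]:
    """Read the pre-deployment reflectance table.

    Expected header ``wavelength_nm,patch1,...,patch9``; one wavelength per row.
    Returns the nine spectra in patch order.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("first column must be wavelength_nm")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    cols = [c for c in df.columns if c.startswith("patch")]
    if len(cols) != 9:
        raise ValueError(f"expected 9 patch columns, got {len(cols)}")
    cols.sort(key=lambda c: int(c.removeprefix("patch")))
    return [SpectralReflectance(wl, df[c].to_numpy(dtype=float)) for c in cols]
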