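"""Frame-quality metrics, color-cast index, and risk-gated frame routing.

Sharpness and contrast of a grayscale frame are summarized by four standard
focus/contrast measures, each with population (1/N) normalization:

* Laplacian variance — variance of the 4-neighbor Laplacian response;
* edge gradient mean — mean Sobel gradient magnitude;
* Tenengrad — mean *squared* Sobel gradient magnitude (gradient energy);
* RMS contrast — root of the population intensity variance.

Borders are replicated for all convolutions.  Color cast on a nominally
neutral-white region (e.g. a display screen) is quantified as
D = max(R̄, Ḡ, B̄) − min(R̄, Ḡ, B̄) of the 8-bit channel means inside the ROI.

An image-acquisition-quality (IAQ) gate extracts five per-frame features
(DCT high-frequency energy ratio, local-contrast variance, Laplacian
variance, cross-channel deviation, inter-frame consistency), z-scores them
against calibration statistics, fuses them linearly, and routes each frame:
score >= tau -> "BYPASS" (fall back to the baseline path), otherwise
"ROBUST" (use the enhanced path).  The enhancement networks themselves are
external; a pluggable command-template interface attaches any enhancer that
maps an input image file to an output image file.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.fft import dctn

__all__ = [
    "laplacian_variance",
    "edge_gradient_mean",
    "tenengrad",
    "rms_contrast",
    "color_cast_index",
    "IAQFeatures",
    "iaq_features",
    "fit_gate_stats",
    "iaq_gate",
    "gate_sequence",
    "CommandEnhancer",
    "IdentityEnhancer",
]

_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


def _as_gray(img: np.ndarray, min_size: int = 3) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a nonempty 2-D (or HxWx3) image")
    if min_size and (arr.shape[0] < min_size or arr.shape[1] < min_size):
        raise ValueError(f"image must be at least {min_size}x{min_size}")
    return arr


def laplacian_variance(img: np.ndarray) -> float:
    """Population variance of the 4-neighbor Laplacian response."""
    arr = _as_gray(img)
    lap = ndimage.convolve(arr, _LAPLACIAN, mode="nearest")
    return float(lap.var())


def _sobel_mag_sq(arr: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(arr, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(arr, _SOBEL_Y, mode="nearest")
    return gx * gx + gy * gy


def edge_gradient_mean(img: np.ndarray) -> float:
    """Mean Sobel gradient magnitude."""
    arr = _as_gray(img)
    return float(np.sqrt(_sobel_mag_sq(arr)).mean())


def tenengrad(img: np.ndarray) -> float:
    """Mean squared Sobel gradient magnitude (gradient energy)."""
    arr = _as_gray(img)
    return float(_sobel_mag_sq(arr).mean())


def rms_contrast(img: np.ndarray) -> float:
    """Root of the population intensity variance (shift-invariant)."""
    arr = _as_gray(img, min_size=0)
    return float(arr.std())


def color_cast_index(
    img: np.ndarray, roi: tuple[int, int, int, int] | None = None
) -> tuple[float, tuple[float, float, float]]:
    """Channel-mean spread D = max - min inside the ROI, on the 0-255 scale.

    ``roi`` is (x, y, w, h) in pixel coordinates; ``None`` uses the whole
    image.  Returns (D, (R_mean, G_mean, B_mean)).
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if roi is not None:
        x, y, w, h = roi
        if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > arr.shape[1] or y + h > arr.shape[0]:
            raise ValueError("ROI empty or outside the image")
        arr = arr[y : y + h, x : x + w]
    means = tuple(float(m) for m in arr.reshape(-1, 3).mean(axis=0))
    return max(means) - min(means), means


@dataclass(frozen=True)
class IAQFeatures:
    """Five frame-quality features feeding the fused risk score."""

    r_hf: float
    sigma_lc: float
    v_lap: float
    delta_rgb: float
    c_temp: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.r_hf, self.sigma_lc, self.v_lap, self.delta_rgb, self.c_temp]
        )


def _dct_highfreq_ratio(arr: np.ndarray) -> float:
    coeff = dctn(arr, norm="ortho")
    energy = coeff**2
    total = energy.sum()
    if total == 0:
        return 0.0
    h_lo = (arr.shape[0] + 1) // 2
    w_lo = (arr.shape[1] + 1) // 2
    low = energy[:h_lo, :w_lo].sum()
    return float(1.0 - low / total)


def _local_contrast_variance(arr: np.ndarray, window: int, stride: int) -> float:
    values = []
    for y in range(0, max(arr.shape[0] - window, 0) + 1, stride):
        for x in range(0, max(arr.shape[1] - window, 0) + 1, stride):
            values.append(arr[y : y + window, x : x + window].std())
    if not values:
        values = [arr.std()]
    return float(np.var(values))


def _temporal_consistency(arr: np.ndarray, prev: np.ndarray) -> float:
    a = arr.ravel()
    b = prev.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def iaq_features(
    frame: np.ndarray,
    prev: np.ndarray | None = None,
    window: int = 16,
    stride: int = 16,
) -> IAQFeatures:
    """Extract the five IAQ features from an RGB (or grayscale) frame.

    The low-frequency DCT quadrant is the first ceil(n/2) coefficients per
    axis; temporal consistency is the Pearson correlation with the previous
    frame (1.0 when there is none).
    """
    arr = np.asarray(frame, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] == 3:
            means = arr.reshape(-1, 3).mean(axis=0)
            delta_rgb = float(means.max() - means.min())
        else:
            raise ValueError("3-D input must be HxWx3")
        gray = arr.mean(axis=2)
    else:
        gray = _as_gray(arr)
        delta_rgb = 0.0
    if prev is not None:
        prev_arr = np.asarray(prev, dtype=float)
        if prev_arr.shape != arr.shape:
            raise ValueError("frame/prev size mismatch")
        prev_gray = prev_arr.mean(axis=2) if prev_arr.ndim == 3 else prev_arr
        c_temp = _temporal_consistency(gray, prev_gray)
    else:
        c_temp = 1.0
    return IAQFeatures(
        r_hf=_dct_highfreq_ratio(gray),
        sigma_lc=_local_contrast_variance(gray, window, stride),
        v_lap=laplacian_variance(gray),
        delta_rgb=delta_rgb,
        c_temp=c_temp,
    )


def fit_gate_stats(
    features: Sequence[IAQFeatures],
) -> tuple[np.ndarray, np.ndarray]:
    """Calibration means/sds (population) over a reference clip's features."""
    if not features:
        raise ValueError("need at least one calibration frame")
    mat = np.stack([f.as_vector() for f in features])
    return mat.mean(axis=0), mat.std(axis=0)


def iaq_gate(
    feats: IAQFeatures,
    stats: tuple[np.ndarray, np.ndarray],
    w: np.ndarray,
    tau: float,
) -> str:
    """Route a frame: z-score, fuse linearly, BYPASS iff score >= tau."""
    means, sds = np.asarray(stats[0], float), np.asarray(stats[1], float)
    if np.any(sds == 0):
        raise ValueError("calibration sds must be nonzero")
    z = (feats.as_vector() - means) / sds
    score = float(z @ np.asarray(w, float))
    return "BYPASS" if score >= tau else "ROBUST"


def gate_sequence(
    frames: Sequence[np.ndarray],
    stats: tuple[np.ndarray, np.ndarray],
    w: np.ndarray,
    tau: float,
) -> list[str]:
    """Gate every frame of a sequence (temporal feature chains frames)."""
    decisions = []
    prev = None
    for frame in frames:
        decisions.append(iaq_gate(iaq_features(frame, prev), stats, w, tau))
        prev = frame
    return decisions


class CommandEnhancer:
    """External enhancer invoked as a shell command template.

    The template must contain ``{input}`` and ``{output}`` placeholders,
    e.g. ``"deblur-model --in {input} --out {output}"``.
    """

    def __init__(self, template: str):
        if "{input}" not in template or "{output}" not in template:
            raise ValueError("template needs {input} and {output} placeholders")
        self.template = template

    def enhance(self, input_path: str | Path, output_path: str | Path) -> Path:
        cmd = self.template.format(input=str(input_path), output=str(output_path))
        subprocess.run(shlex.split(cmd), check=True)
        return Path(output_path)


class IdentityEnhancer:
    """Pass-through enhancer (copies the input image unchanged)."""

    def enhance(self, input_path: str | Path, output_path: str | Path) -> Path:
        Path(output_path).write_bytes(Path(input_path).read_bytes())
        return Path(output_path)
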