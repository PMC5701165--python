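"""HMAX S1 layer: the Gabor simple-cell filter bank model of V1.

S1 units are Gabor filters at 4 orientations and a pyramid of sizes,
emulating orientation- and scale-tuned simple cells in primary visual
cortex.  Responses are the absolute value of the filter output, divided by
the local image norm over the filter support (contrast normalization).  The
model dissimilarity matrix is the Euclidean distance between the flattened
S1 response vectors of each stimulus pair.

Filter parameterization follows the canonical published S1 table: sizes
7..37 px in steps of 2 with paired effective width sigma and wavelength
lambda, aspect ratio 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .rdm import RDM, CONDITION_LABELS
from .stimuli import StimulusImage

__all__ = ["GaborBankSpec", "S1Response", "gabor_kernel", "s1_filter", "model_rdm"]

# canonical S1 parameter table: (size px, sigma, lambda)
_S1_TABLE = (
    (7, 2.8, 3.5), (9, 3.6, 4.6), (11, 4.5, 5.6), (13, 5.4, 6.8),
    (15, 6.3, 7.9), (17, 7.3, 9.1), (19, 8.2, 10.3), (21, 9.2, 11.5),
    (23, 10.2, 12.7), (25, 11.3, 14.1), (27, 12.3, 15.4), (29, 13.4, 16.8),
    (31, 14.6, 18.2), (33, 15.8, 19.7), (35, 17.0, 21.2), (37, 18.2, 22.8),
)


@dataclass
class GaborBankSpec:
    """S1 Gabor filter bank: orientations x scales, aspect ratio gamma."""

    orientations: tuple = (0.0, 45.0, 90.0, 135.0)
    scales: tuple = _S1_TABLE
    aspect_ratio: float = 0.3

    def __post_init__(self):
        for size, _, _ in self.scales:
            if size % 2 == 0:
                raise ValueError("filter sizes must be odd")

    @property
    def max_size(self) -> int:
        return max(s for s, _, _ in self.scales)


@dataclass
class S1Response:
    """Per-orientation, per-scale response maps of one stimulus.

    ``values[(theta, size)]`` is a 2-D map the size of the input image.
    """

    values: dict
    stimulus_id: int = 0

    def feature_vector(self) -> np.ndarray:
        keys = sorted(self.values.keys())
        return np.concatenate([self.values[k].ravel() for k in keys])


def gabor_kernel(size: int, sigma: float, lam: float, theta_deg: float,
                 gamma: float = 0.3) -> np.ndarray:
    """Zero-mean, unit-norm Gabor restricted to a circular support.

    G(x, y) = exp(-(X^2 + gamma^2 Y^2) / (2 sigma^2)) * cos(2 pi X / lambda)
    with (X, Y) the image coordinates rotated by theta; theta=0 prefers a
    vertical grating (luminance varying along x).
    """
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    th = np.radians(theta_deg)
    X = x * np.cos(th) + y * np.sin(th)
    Y = -x * np.sin(th) + y * np.cos(th)
    g = np.exp(-(X**2 + (gamma * Y) ** 2) / (2 * sigma**2)) * np.cos(
        2 * np.pi * X / lam
    )
    g[x**2 + y**2 > half**2] = 0.0
    mask = x**2 + y**2 <= half**2
    g[mask] -= g[mask].mean()
    norm = np.sqrt(np.sum(g**2))
    if norm > 0:
        g /= norm
    return g


def s1_filter(image: StimulusImage | np.ndarray, bank: GaborBankSpec = None,
              rectify: bool = True) -> S1Response:
    """Apply the S1 Gabor bank to a stimulus image.

    Each response map is |image * G| normalized by the local L2 norm of the
    image over the filter support, so responses are contrast-invariant and a
    uniform (zero-contrast) image yields zero away from the image border
    (the zero-padded boundary looks like a luminance step to the filters).
    """
    if bank is None:
        bank = GaborBankSpec()
    pixels = image.pixels if isinstance(image, StimulusImage) else np.asarray(image)
    pixels = pixels.astype(float)
    if min(pixels.shape) < bank.max_size:
        raise ValueError(
            f"image {pixels.shape} smaller than largest filter "
            f"({bank.max_size} px)"
        )
    sq = pixels**2
    out = {}
    for size, sigma, lam in bank.scales:
        # local image energy over the circular filter support
        half = size // 2
        y, x = np.mgrid[-half:half + 1, -half:half + 1]
        support = (x**2 + y**2 <= half**2).astype(float)
        local_norm = np.sqrt(
            np.clip(fftconvolve(sq, support, mode="same"), 0.0, None)
        )
        for theta in bank.orientations:
            g = gabor_kernel(size, sigma, lam, theta, bank.aspect_ratio)
            resp = fftconvolve(pixels, g[::-1, ::-1], mode="same")
            if rectify:
                resp = np.abs(resp)
            with np.errstate(invalid="ignore", divide="ignore"):
                resp = np.where(local_norm > 1e-9, resp / local_norm, 0.0)
            out[(theta, size)] = resp
    sid = image.spec.condition if isinstance(image, StimulusImage) and image.spec else 0
    return S1Response(values=out, stimulus_id=sid)


def model_rdm(responses: list[S1Response], labels=CONDITION_LABELS) -> RDM:
    """Euclidean-distance RDM over the flattened S1 feature vectors."""
    feats = [r.feature_vector() for r in responses]
    n = len(feats)
    if any(f.shape != feats[0].shape for f in feats):
        raise ValueError("S1 responses have mismatched shapes")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = np.linalg.norm(feats[i] - feats[j])
    return RDM(matrix=m, labels=tuple(labels[:n]), source="model")
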