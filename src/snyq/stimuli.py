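"""Parametric pattern-reversal checkerboard stimuli.

The experiment uses six stimuli: polar (radial x angular) checkerboards of
low, medium or high spatial frequency, confined to a half-disc of 28 degrees
radius in the left or right visual hemifield, counter-phasing at 15 Hz for
1000 ms.  Radial spatial frequencies are 0.036, 0.071 and 0.143 cycles per
degree of eccentricity (1, 2 and 4 black/white wavelengths across the
radius); the paired angular frequencies are 0.011, 0.022 and 0.044 cycles
per angular degree (2, 4 and 8 wavelengths per semicircle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RADIAL_SFS",
    "ANGULAR_SFS",
    "SF_NAMES",
    "HEMIFIELDS",
    "StimulusSpec",
    "StimulusImage",
    "stimulus_set",
    "render_checkerboard",
]

#: Radial spatial frequencies in cycles/degree, low -> high.
RADIAL_SFS = (0.036, 0.071, 0.143)
#: Paired angular spatial frequencies in cycles per angular degree.
ANGULAR_SFS = (0.011, 0.022, 0.044)
SF_NAMES = ("low", "medium", "high")
HEMIFIELDS = ("left", "right")

_GRAY = 0.5
_WHITE = 1.0
_BLACK = 0.0


@dataclass(frozen=True)
class StimulusSpec:
    """One of the six checkerboard stimulus conditions.

    Parameters
    ----------
    radial_sf : float
        Radial spatial frequency in cycles per degree of visual angle.
    angular_sf : float
        Angular spatial frequency in cycles per angular degree.
    hemifield : {"left", "right"}
        Visual hemifield the half-disc occupies.
    radius_deg : float
        Radius of the stimulus disc in degrees of arc.
    flicker_hz : float
        Pattern-reversal rate.
    duration_ms : float
        Stimulus duration.
    """

    radial_sf: float
    angular_sf: float
    hemifield: str
    radius_deg: float = 28.0
    flicker_hz: float = 15.0
    duration_ms: float = 1000.0

    def __post_init__(self):
        if self.hemifield not in HEMIFIELDS:
            raise ValueError(f"hemifield must be one of {HEMIFIELDS}")
        if self.radius_deg <= 0 or self.flicker_hz <= 0:
            raise ValueError("radius_deg and flicker_hz must be positive")

    @property
    def sf_name(self) -> str:
        """'low' / 'medium' / 'high' label of the radial spatial frequency."""
        i = int(np.argmin([abs(self.radial_sf - s) for s in RADIAL_SFS]))
        return SF_NAMES[i]

    @property
    def condition(self) -> int:
        """Condition code 1..6 (left low/med/high, right low/med/high)."""
        sf_i = SF_NAMES.index(self.sf_name)
        return HEMIFIELDS.index(self.hemifield) * 3 + sf_i + 1


@dataclass
class StimulusImage:
    """Rendered checkerboard: luminance values in {black, white, gray}."""

    pixels: np.ndarray
    pixels_per_degree: float
    phase: int
    spec: StimulusSpec = field(repr=False, default=None)

    @property
    def shape(self):
        return self.pixels.shape


def stimulus_set(**kwargs) -> list[StimulusSpec]:
    """The six stimulus conditions in condition-code order.

    Order: left-low, left-medium, left-high, right-low, right-medium,
    right-high (condition codes 1..6).
    """
    specs = []
    for hemi in HEMIFIELDS:
        for rsf, asf in zip(RADIAL_SFS, ANGULAR_SFS):
            specs.append(StimulusSpec(rsf, asf, hemi, **kwargs))
    return specs


def render_checkerboard(
    spec: StimulusSpec, pixels_per_degree: float, phase: int = 0
) -> StimulusImage:
    """Render one reversal phase of a polar checkerboard stimulus.

    The canvas spans the full display (+- radius_deg in both axes) on a
    mid-gray background; the checkerboard fills the half-disc of
    ``spec.radius_deg`` on the stated hemifield.  Checks are half-wavelength
    tiles in eccentricity and polar angle whose colour is the parity of the
    (radial band, angular band) pair; ``phase=1`` exchanges black and white.

    Raises
    ------
    ValueError
        If the resolution leaves the finest radial check under 4 pixels.
    """
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    min_check_deg = 1.0 / (2.0 * spec.radial_sf)
    min_ppd = 4.0 / min_check_deg
    if pixels_per_degree * min_check_deg < 4.0:
        raise ValueError(
            f"pixels_per_degree={pixels_per_degree:g} too low for "
            f"radial_sf={spec.radial_sf:g}: finest check spans "
            f"{pixels_per_degree * min_check_deg:.2f} px; need at least "
            f"{min_ppd:.3f} pixels per degree"
        )

    half = spec.radius_deg
    n = int(round(2 * half * pixels_per_degree))
    # pixel-centre coordinates in degrees; x rightward, y upward
    coords = (np.arange(n) + 0.5) / pixels_per_degree - half
    x, y = np.meshgrid(coords, coords[::-1])
    r = np.hypot(x, y)
    # polar angle from the vertical meridian, 0..180 deg within a hemifield;
    # symmetric in |x|, so left and right stimuli are exact mirror images
    beta = np.degrees(np.arctan2(np.abs(x), y))

    inside = r <= spec.radius_deg
    if spec.hemifield == "right":
        inside &= x >= 0
    else:
        inside &= x <= 0

    radial_band = np.floor(2.0 * spec.radial_sf * r).astype(int)
    angular_band = np.floor(2.0 * spec.angular_sf * beta).astype(int)
    parity = (radial_band + angular_band + phase) % 2

    pixels = np.full((n, n), _GRAY)
    pixels[inside] = np.where(parity[inside] == 0, _WHITE, _BLACK)
    return StimulusImage(pixels=pixels, pixels_per_degree=pixels_per_degree,
                         phase=phase, spec=spec)
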