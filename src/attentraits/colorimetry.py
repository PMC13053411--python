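"""CIE 1976 L*a*b* color distances for distractor-color equivalence checks.

Salient color-singleton distractors are only comparable across conditions if
they are equally far, perceptually, from the uniform array color. The classic
scalar for that is ΔE, the Euclidean distance in CIE 1976 L*a*b* space.

The sRGB → XYZ → L*a*b* conversion here deliberately uses the long-standing
"reference card" constants (the 4-decimal sRGB matrix, D65 white point
X=95.047, Y=100, Z=108.883 for the 2° observer, companding threshold 0.04045,
and the 0.008856 / 7.787 linear knee of the Lab cube root). These rounded
constants are what GIMP-era tools and most online converters implement, and
they are the convention under which the distractor-color distances in this
package's tests were defined. Higher-precision constant sets (e.g., the ones
in scikit-image) shift ΔE in the second decimal place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["LabColor", "srgb_to_lab", "delta_e_76"]

# sRGB (IEC 61966-2-1) to XYZ under D65, rounded to the 4-decimal form.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

# D65 reference white, 2 degree standard observer (XYZ scaled so Y=100).
_WHITE_D65 = np.array([95.047, 100.0, 108.883])

_LAB_EPS = 0.008856  # (6/29)**3, rounded as in the CIE 15 tables
_LAB_KAPPA = 7.787  # (1/3)*(29/6)**2, rounded likewise


@dataclass(frozen=True)
class LabColor:
    """A color in CIE 1976 L*a*b* coordinates.

    ``L`` is lightness (0 black to 100 diffuse white), ``a`` the green–red
    opponent axis, and ``b`` the blue–yellow opponent axis.
    """

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])


def srgb_to_lab(rgb: tuple[float, float, float]) -> LabColor:
    """Convert an 8-bit sRGB triple to CIE 1976 L*a*b* (D65, 2° observer).

    Parameters
    ----------
    rgb:
        Red, green, blue components on the 0–255 integer scale.

    Raises
    ------
    ConfigurationError
        If any component lies outside [0, 255].
    """
    c = np.asarray(rgb, dtype=float)
    if c.shape != (3,):
        raise ConfigurationError(f"expected an RGB triple, got shape {c.shape}")
    if np.any(c < 0) or np.any(c > 255):
        raise ConfigurationError(f"RGB components must be in [0, 255], got {rgb}")

    c = c / 255.0
    # inverse sRGB companding
    linear = np.where(c > 0.04045, ((c + 0.055) / 1.055) ** 2.4, c / 12.92)
    xyz = _SRGB_TO_XYZ @ linear * 100.0

    v = xyz / _WHITE_D65
    f = np.where(v > _LAB_EPS, np.cbrt(v), _LAB_KAPPA * v + 16.0 / 116.0)
    L = 116.0 * f[1] - 16.0
    a = 500.0 * (f[0] - f[1])
    b = 200.0 * (f[1] - f[2])
    return LabColor(float(L), float(a), float(b))


def delta_e_76(c1: LabColor, c2: LabColor) -> float:
    """CIE 1976 color difference: Euclidean distance in L*a*b* space."""
    return float(np.linalg.norm(c1.as_array() - c2.as_array()))
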