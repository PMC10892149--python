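"""Color-space primitives for colorimetric LAMP analysis.

Amplification is read out as a shift in hue (the angular coordinate of the
HSB color space) rescaled to an 8-bit 0-255 range.  Hue is circular: 255
adjoins 0 at red, which matters for phenol red, whose pink-to-yellow
transition crosses the red wrap.  This module provides the RGB-to-8-bit-hue
conversion, signed circular hue arithmetic, series unwrapping, and the
built-in dye profiles that give hue changes a sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DyeProfile",
    "builtin_dye",
    "hue_delta_signed",
    "rgb_to_hue8",
    "unwrap_series",
    "PR_NEGATIVE_RGB",
    "PR_POSITIVE_RGB",
    "HNB_NEGATIVE_RGB",
    "HNB_POSITIVE_RGB",
]

#: Scale factor from hexcone hue in degrees to the 8-bit hue range.
HUE8_PER_DEGREE = 255.0 / 360.0

# Default endpoint colors for the built-in dyes.  Chosen so that
# rgb_to_hue8 reproduces the canonical 8-bit hue endpoints exactly:
# a saturated pink (220), yellow (40), violet (200) and blue (160).
PR_NEGATIVE_RGB = (255, 0, 210)
PR_POSITIVE_RGB = (255, 240, 0)
HNB_NEGATIVE_RGB = (180, 0, 255)
HNB_POSITIVE_RGB = (0, 60, 255)


def rgb_to_hue8(rgb) -> float | np.ndarray:
    """Convert RGB to hue on the 8-bit (0-255) scale.

    Standard hexcone hue H in [0, 360) degrees, rescaled as
    ``round(H * 255 / 360)``.  Achromatic input (r == g == b) maps to 0
    by convention, keeping the function total.

    Parameters
    ----------
    rgb
        A sequence ``(r, g, b)`` with channels in [0, 255], or an array
        of shape ``(..., 3)``.  Channels may be float (e.g. a mean color).

    Returns
    -------
    float or ndarray
        Integer-valued hue(s) in [0, 255]; a scalar input yields a float.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB with a trailing axis of size 3")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("RGB channels must lie in [0, 255]")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = mx - mn
    safe = np.where(delta == 0, 1.0, delta)
    # sector offsets: red 0, green 120, blue 240 degrees
    h_r = (60.0 * ((g - b) / safe)) % 360.0
    h_g = 60.0 * ((b - r) / safe) + 120.0
    h_b = 60.0 * ((r - g) / safe) + 240.0
    hue_deg = np.where(mx == r, h_r, np.where(mx == g, h_g, h_b))
    hue_deg = np.where(delta == 0, 0.0, hue_deg)
    hue8 = np.round(hue_deg * HUE8_PER_DEGREE)
    if hue8.ndim == 0:
        return float(hue8)
    return hue8


def hue_delta_signed(h: float, ref: float) -> float | np.ndarray:
    """Signed minimal circular difference ``h - ref`` modulo 256.

    The result lies in (-128, +128]; a tie at magnitude 128 resolves to
    +128.  This is what gives a dye transition its direction: phenol red's
    220 -> 40 is +76 through the red wrap, hydroxynaphthol blue's
    200 -> 160 is -40.
    """
    d = (np.asarray(h, dtype=float) - np.asarray(ref, dtype=float)) % 256.0
    out = np.where(d > 128.0, d - 256.0, d)
    if out.ndim == 0:
        return float(out)
    return out


def unwrap_series(values: Sequence[float]) -> np.ndarray:
    """Remove 256-wrap discontinuities from a hue series.

    ``out[0] = values[0]`` and each subsequent point advances by the
    signed minimal circular step, so consecutive differences of the
    output equal ``hue_delta_signed`` of consecutive raw values.  The
    unwrapped series lives on an unbounded real scale where ordinary
    means and standard deviations are meaningful.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("unwrap_series requires a non-empty 1-D series")
    steps = hue_delta_signed(arr[1:], arr[:-1])
    return np.concatenate(([arr[0]], arr[0] + np.cumsum(np.atleast_1d(steps))))


@dataclass(frozen=True)
class DyeProfile:
    """A colorimetric indicator's endpoints, hue direction and threshold width.

    Parameters
    ----------
    name
        Dye identifier, e.g. ``"PR"`` (phenol red) or ``"HNB"``
        (hydroxynaphthol blue).
    negative_color, positive_color
        RGB endpoint colors before and after amplification.
    negative_hue, positive_hue
        8-bit hue endpoints.
    direction
        +1 if hue rises on amplification (PR), -1 if it falls (HNB);
        must equal the sign of the minimal circular path from the
        negative to the positive hue.
    k_sd
        Baseline standard-deviation multiplier used for the call
        threshold (3 or 5 for the built-ins).
    """

    name: str
    negative_color: tuple[int, int, int]
    positive_color: tuple[int, int, int]
    negative_hue: float
    positive_hue: float
    direction: int
    k_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        delta = hue_delta_signed(self.positive_hue, self.negative_hue)
        if delta != 0 and int(np.sign(delta)) != self.direction:
            raise ValueError(
                f"dye {self.name!r}: direction {self.direction:+d} contradicts the "
                f"signed circular hue path {delta:+.1f}"
            )

    @property
    def hue_delta(self) -> float:
        """Signed circular hue change from negative to positive endpoint."""
        return hue_delta_signed(self.positive_hue, self.negative_hue)

    def to_config(self) -> dict[str, str]:
        """Serialize to a flat key=value block (all values as strings)."""
        return {
            "name": self.name,
            "negative_color": ",".join(str(c) for c in self.negative_color),
            "positive_color": ",".join(str(c) for c in self.positive_color),
            "negative_hue": repr(float(self.negative_hue)),
            "positive_hue": repr(float(self.positive_hue)),
            "direction": str(self.direction),
            "k_sd": repr(float(self.k_sd)),
        }

    @classmethod
    def from_config(cls, config: Mapping[str, str]) -> "DyeProfile":
        """Rebuild a profile from :meth:`to_config` output (user dyes too)."""
        def _rgb(s: str) -> tuple[int, int, int]:
            parts = tuple(int(x) for x in s.split(","))
            if len(parts) != 3:
                raise ValueError(f"expected r,g,b triple, got {s!r}")
            return parts  # type: ignore[return-value]

        return cls(
            name=config["name"],
            negative_color=_rgb(config["negative_color"]),
            positive_color=_rgb(config["positive_color"]),
            negative_hue=float(config["negative_hue"]),
            positive_hue=float(config["positive_hue"]),
            direction=int(config["direction"]),
            k_sd=float(config.get("k_sd", 3.0)),
        )


_BUILTINS = {
    "PR": DyeProfile(
        name="PR",
        negative_color=PR_NEGATIVE_RGB,
        positive_color=PR_POSITIVE_RGB,
        negative_hue=220.0,
        positive_hue=40.0,
        direction=+1,
        k_sd=3.0,
    ),
    "HNB": DyeProfile(
        name="HNB",
        negative_color=HNB_NEGATIVE_RGB,
        positive_color=HNB_POSITIVE_RGB,
        negative_hue=200.0,
        positive_hue=160.0,
        direction=-1,
        k_sd=3.0,
    ),
}


def builtin_dye(name: str) -> DyeProfile:
    """Return a built-in dye profile by name.

    ``"PR"``: phenol red, pink (hue 220) to yellow (hue 40); LAMP
    acidification drives the change, hue rises through the red wrap.
    ``"HNB"``: hydroxynaphthol blue, violet (hue 200) to blue (hue 160);
    Mg2+ depletion drives the change, hue falls.
    """
    try:
        return _BUILTINS[name]
    except KeyError:
        available = ", ".join(sorted(_BUILTINS))
        raise KeyError(f"unknown dye {name!r}; available: {available}") from None
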