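"""Vegetation-index layers: NDVI and EVI over reflectance bands.

The texture analysis runs on four layers: the RED and IR bands themselves
plus NDVI = (IR - RED) / (IR + RED) and the enhanced vegetation index
EVI = G * (IR - RED) / (IR + C1*RED - C2*BLUE + L) with the standard
coefficients C1 = 6, C2 = 7.5, L = 1 and gain G = 2.5.  Undefined pixels
(zero or non-positive denominators) are masked, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EVI_C1 = 6.0
EVI_C2 = 7.5
EVI_L = 1.0
EVI_GAIN = 2.5

LAYER_NAMES = ("RED", "IR", "NDVI", "EVI")


def _as_masked(a) -> np.ma.MaskedArray:
    return a if isinstance(a, np.ma.MaskedArray) else np.ma.masked_invalid(a)


def ndvi(ir, red) -> np.ma.MaskedArray:
    """Normalized difference vegetation index; masked where IR + RED <= 0."""
    ir, red = _as_masked(ir), _as_masked(red)
    if ir.shape != red.shape:
        raise ValueError(f"shape mismatch: {ir.shape} vs {red.shape}")
    denom = ir + red
    out = np.ma.where(denom > 0, (ir - red) / np.ma.masked_less_equal(denom, 0), 0)
    out.mask = np.ma.getmaskarray(ir) | np.ma.getmaskarray(red) | (denom <= 0)
    return out


def evi(ir, red, blue, gain: float = EVI_GAIN) -> np.ma.MaskedArray:
    """Enhanced vegetation index; masked where the denominator is <= 0."""
    ir, red, blue = _as_masked(ir), _as_masked(red), _as_masked(blue)
    if not (ir.shape == red.shape == blue.shape):
        raise ValueError("shape mismatch among IR/RED/BLUE")
    denom = ir + EVI_C1 * red - EVI_C2 * blue + EVI_L
    out = gain * (ir - red) / np.ma.masked_less_equal(denom, 0)
    out.mask = (np.ma.getmaskarray(ir) | np.ma.getmaskarray(red)
                | np.ma.getmaskarray(blue) | (denom <= 0))
    return out


@dataclass
class LayerStack:
    """The four analysis layers sharing one grid shape."""

    layers: dict[str, np.ma.MaskedArray]

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers disagree in shape: {shapes}")

    def __getitem__(self, name: str) -> np.ma.MaskedArray:
        return self.layers[name]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape


def build_layers(bands: dict[str, np.ndarray]) -> LayerStack:
    """Assemble RED, IR, NDVI, EVI from BLUE/RED/IR reflectance grids."""
    red, ir, blue = (_as_masked(bands[b]) for b in ("RED", "IR", "BLUE"))
    return LayerStack({
        "RED": red,
        "IR": ir,
        "NDVI": ndvi(ir, red),
        "EVI": evi(ir, red, blue),
    })
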