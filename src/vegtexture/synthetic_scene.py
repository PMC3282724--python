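"""Synthetic successional landscapes: imagery, stem communities, ground truth.

The generator emulates a mosaic of differently-aged secondary-forest stands
as seen by a very-high-resolution optical sensor.  Each pixel mixes a soil
and a canopy spectral endmember according to a per-pixel canopy-cover
fraction; mean cover saturates with stand age while the pixel-to-pixel
variability of cover decays with age.  Young stands are therefore bright in
RED and spatially heterogeneous (soil showing through an open canopy), old
stands are dark in RED, bright in IR, and smooth — the construction that
makes image texture informative about succession.

Stem communities are generated with the qualitative successional trends of
field chronosequences: basal area and species richness increase with age,
dominance decreases, height saturates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BANDS = ("BLUE", "RED", "IR")

#: sampled-area bounds (cm DBH) for the nested inventory design
DBH_CLASS_BOUNDS = {"large": (5.0, 60.0), "medium": (2.5, 5.0), "small": (1.0, 2.5)}


class LayoutError(ValueError):
    """A stand rectangle does not fit inside the image."""


@dataclass(frozen=True)
class StandSpec:
    """Axis-aligned rectangular stand: top-left corner, size (pixels), age."""

    row: int
    col: int
    height: int
    width: int
    age: float

    @property
    def center(self) -> tuple[int, int]:
        return self.row + self.height // 2, self.col + self.width // 2


# Endmember reflectances are illustrative, not calibrated to a sensor:
# dry bare soil is bright in RED, green canopy absorbs RED and scatters IR.
_SOIL = {"BLUE": 0.10, "RED": 0.28, "IR": 0.32}
_CANOPY = {"BLUE": 0.03, "RED": 0.04, "IR": 0.45}


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic successional scene.

    Cover follows the saturating curve ``cover(age) = A * (1 - exp(-r*age))``
    with ``A = cover_asymptote`` and ``r = cover_rate`` (per year).  Per-pixel
    cover is Beta-distributed around the stand mean with variance
    ``heterogeneity_var0 * exp(-heterogeneity_decay * age)``, so within-stand
    spectral variance declines monotonically with age.
    """

    image_height: int = 120
    image_width: int = 120
    pixel_size: float = 2.6  # m
    stand_layout: list[StandSpec] = field(default_factory=list)
    cover_asymptote: float = 0.95
    cover_rate: float = 0.08  # 1/yr
    endmembers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"soil": dict(_SOIL), "canopy": dict(_CANOPY)}
    )
    heterogeneity_var0: float = 0.04  # cover variance extrapolated to age 0
    heterogeneity_decay: float = 0.05  # 1/yr
    noise_sd: float = 0.004  # reflectance units, per band
    species_pool_size: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name, em in self.endmembers.items():
            for band in BANDS:
                v = em[band]
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"endmember {name}/{band}={v} outside [0, 1]")
        if not 0.0 < self.cover_asymptote <= 1.0:
            raise ValueError("cover_asymptote must lie in (0, 1]")
        if self.heterogeneity_var0 <= 0:
            raise ValueError("heterogeneity_var0 must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.stand_layout:
            self.stand_layout = grid_layout(
                DEFAULT_AGES, self.image_height, self.image_width
            )
        for s in self.stand_layout:
            if s.row < 0 or s.col < 0 or s.row + s.height > self.image_height or \
                    s.col + s.width > self.image_width:
                raise LayoutError(f"stand {s} exceeds image bounds")

    def mean_cover(self, age: float) -> float:
        """Stand-mean canopy cover fraction at a given age."""
        return self.cover_asymptote * (1.0 - np.exp(-self.cover_rate * age))

    def cover_variance(self, age: float) -> float:
        """Latent per-pixel cover variance at a given age (before the Beta cap)."""
        return self.heterogeneity_var0 * np.exp(-self.heterogeneity_decay * age)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stand_layout"] = [dataclasses.asdict(s) for s in self.stand_layout]
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        d = json.loads(Path(path).read_text())
        d["stand_layout"] = [StandSpec(**s) for s in d["stand_layout"]]
        return cls(**d)


#: ages of the study chronosequence: 14 fallows (2-60 yr) plus a mature stand
#: coded with a large numeric age
DEFAULT_AGES = (2, 3, 5, 7, 9, 12, 13, 18, 20, 25, 32, 38, 42, 60, 90)


def grid_layout(
    ages=DEFAULT_AGES,
    image_height: int = 120,
    image_width: int = 120,
    stand_size: int = 24,
) -> list[StandSpec]:
    """Place square stands on a regular grid, row-major, left to right.

    Stand size defaults to 24 px so the 15x15 analysis window around each
    stand center samples mostly that stand.
    """
    per_row = image_width // stand_size
    layout = []
    for i, age in enumerate(ages):
        r, c = divmod(i, per_row)
        row, col = r * stand_size, c * stand_size
        if row + stand_size > image_height:
            raise LayoutError(f"{len(ages)} stands of {stand_size} px do not fit")
        layout.append(StandSpec(row, col, stand_size, stand_size, float(age)))
    return layout


@dataclass
class ReflectanceScene:
    """Multiband reflectance grids plus the registry of plot centers."""

    bands: dict[str, np.ndarray]  # BLUE, RED, IR in [0, 1]
    plot_registry: pd.DataFrame  # plot_id, row, col, age

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["RED"].shape


def _beta_cover(rng, mean, var, shape):
    """Per-pixel cover ~ Beta(mean, var), degenerate when var vanishes."""
    if mean <= 0.0:
        return np.zeros(shape)
    if mean >= 1.0:
        return np.ones(shape)
    # Beta variance cannot reach mean*(1-mean); cap keeps parameters valid.
    var = min(var, 0.95 * mean * (1.0 - mean))
    if var <= 1e-12:  # degenerate: constant cover
        return np.full(shape, mean)
    nu = mean * (1.0 - mean) / var - 1.0
    return rng.beta(mean * nu, (1.0 - mean) * nu, size=shape)


def generate_scene(config: ScenarioConfig) -> ReflectanceScene:
    """Render the reflectance mosaic described by ``config``.

    Pixel model: ``refl = cover * canopy + (1 - cover) * soil + noise``,
    clipped to [0, 1].  Pixels outside every stand get cover 0 (bare
    matrix).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    cover = np.zeros((h, w))
    for s in config.stand_layout:
        mean = config.mean_cover(s.age)
        var = config.cover_variance(s.age)
        block = _beta_cover(rng, mean, var, (s.height, s.width))
        cover[s.row:s.row + s.height, s.col:s.col + s.width] = block

    soil, canopy = config.endmembers["soil"], config.endmembers["canopy"]
    bands = {}
    for band in BANDS:
        refl = cover * canopy[band] + (1.0 - cover) * soil[band]
        if config.noise_sd > 0:
            refl = refl + rng.normal(0.0, config.noise_sd, size=(h, w))
        bands[band] = np.clip(refl, 0.0, 1.0)

    registry = pd.DataFrame(
        [
            {"plot_id": f"P{i:02d}", "row": s.center[0], "col": s.center[1],
             "age": s.age}
            for i, s in enumerate(config.stand_layout, start=1)
        ]
    )
    return ReflectanceScene(bands=bands, plot_registry=registry)


# ---------------------------------------------------------------------------
# stem communities


def _expected_stems(age: float) -> dict[str, float]:
    """Expected stem counts per sampling class in the sampled transects.

    Saturating recruitment into the large class; small-stem thinning with
    age is left out deliberately — only the qualitative trends matter.
    """
    large = 1 + 40 * (1 - np.exp(-0.05 * age))  # in 400 m^2
    medium = 10 + 20 * (1 - np.exp(-0.10 * age))  # in 200 m^2
    small = 12 + 10 * (1 - np.exp(-0.15 * age))  # in 100 m^2
    return {"large": large, "medium": medium, "small": small}


def _species_probs(age: float, pool: int) -> np.ndarray:
    """Geometric rank-abundance; evenness (1 - k) grows with age.

    Young stands are dominated by a few pioneers (large k, steep series);
    older stands spread abundance over many species.
    """
    k = 0.65 * np.exp(-0.04 * age) + 0.05
    p = k * (1 - k) ** np.arange(pool)
    return p / p.sum()


def generate_stem_table(config: ScenarioConfig, ages=None) -> pd.DataFrame:
    """Simulate the stem-level inventory for each plot.

    Columns: plot_id, quadrat (1-16), species, dbh_cm, crown_d1_m,
    crown_d2_m, height_m, sampling_class.  Deterministic given seed.
    """
    if ages is None:
        ages = [s.age for s in config.stand_layout]
    ages = list(ages)
    if len(ages) == 0:
        raise ValueError("ages must be a non-empty list of positive ages")
    if any(a <= 0 for a in ages):
        raise ValueError("ages must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    rows = []
    for i, age in enumerate(ages, start=1):
        plot = f"P{i:02d}"
        probs = _species_probs(age, config.species_pool_size)
        counts = _expected_stems(age)
        # mean canopy height saturates with age (chronosequence Hgt trend)
        hgt_mean = 1.5 + 6.5 * (1 - np.exp(-0.09 * age))
        for cls, (lo, hi) in DBH_CLASS_BOUNDS.items():
            n = rng.poisson(counts[cls])
            n = max(n, 2) if cls == "large" else n  # keep plots non-degenerate
            if cls == "large":
                # stature builds up over succession: the attainable DBH
                # ceiling itself grows with stand age
                hi = lo + 45.0 * (1 - np.exp(-0.03 * age))
            for _ in range(n):
                # DBH within class bounds, skewed toward the lower bound
                dbh = lo + (hi - lo) * rng.beta(1.2, 3.0)
                species = int(rng.choice(config.species_pool_size, p=probs))
                # crown diameter roughly allometric in DBH, lognormal scatter
                cd = 0.45 * dbh ** 0.8
                d1 = cd * rng.lognormal(0.0, 0.25)
                d2 = cd * rng.lognormal(0.0, 0.25)
                height = max(hgt_mean * rng.lognormal(0.0, 0.20)
                             * (dbh / 5.0) ** 0.25, 0.5)
                rows.append(
                    {"plot_id": plot, "quadrat": int(rng.integers(1, 17)),
                     "species": f"sp{species:03d}", "dbh_cm": dbh,
                     "crown_d1_m": d1, "crown_d2_m": d2,
                     "height_m": height, "sampling_class": cls}
                )
    return pd.DataFrame(rows)


def ground_truth(config: ScenarioConfig) -> dict[str, dict]:
    """Latent per-stand parameters used by the generators.

    Returns, per stand id, the age, mean cover, latent cover variance and
    expected class-wise stem counts — the quantities parameter-recovery
    tests compare against.
    """
    truth = {}
    for i, s in enumerate(config.stand_layout, start=1):
        truth[f"P{i:02d}"] = {
            "age": s.age,
            "mean_cover": float(config.mean_cover(s.age)),
            "cover_variance": float(config.cover_variance(s.age)),
            "expected_stems": {k: float(v) for k, v in _expected_stems(s.age).items()},
        }
    return truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
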