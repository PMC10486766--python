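"""Image-based appearance scoring for cooked rice.

Cooked rice with poor sensory appearance tends to look yellow and dull,
while good-looking rice is white and glossy.  The scorer quantifies this
by converting an RGB photograph to HSV and counting the pixels whose hue
falls below a threshold near the yellow/green boundary (0.167 on the unit
hue circle, i.e. 60°).  The fraction of such "yellow" pixels is the
appearance proxy: larger yellow area, worse appearance.

The classification rule is deliberately literal: a pixel is yellow iff
``hue < hue_threshold``.  Because achromatic pixels carry hue 0 under the
standard hexcone convention, glossy pure-white pixels would also satisfy
the rule; an optional saturation gate (``saturation >= saturation_gate``)
is available to exclude them but is disabled by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv as _skimage_rgb2hsv

from .errors import ConfigError, InputError

DEFAULT_HUE_THRESHOLD = 0.167


@dataclass(frozen=True)
class RGBImage:
    """An H×W×3 raster of 8-bit red/green/blue intensities."""

    pixels: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(
                f"expected an H×W×3 RGB raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("image must contain at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise InputError("channel intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class HSVImage:
    """Hue/saturation/value rasters; hue in [0,1) with red at 0."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


@dataclass(frozen=True)
class YellowMask:
    """Binary yellow/non-yellow classification of every pixel."""

    mask: np.ndarray
    n_yellow: int
    n_total: int


@dataclass(frozen=True)
class AppearanceScore:
    """Yellow-area percentage plus the thresholds that produced it."""

    yellow_area_percent: float
    hue_threshold: float
    saturation_gate: float | None
    n_yellow: int
    n_total: int
    path: str | None = None


@dataclass(frozen=True)
class AppearanceConfig:
    """Scoring configuration.

    Parameters
    ----------
    hue_threshold
        Pixels with hue strictly below this value are classified yellow.
        Unit hue circle, default 0.167 (≈ 60°).
    saturation_gate
        If set, a pixel must additionally have saturation at or above this
        value to count as yellow; ``None`` disables the gate (default),
        which keeps the literal hue-only rule.
    roi
        Optional ``(row0, row1, col0, col1)`` crop applied before scoring,
        for frames that include container edges.  Default: whole frame.
    """

    hue_threshold: float = DEFAULT_HUE_THRESHOLD
    saturation_gate: float | None = None
    roi: tuple[int, int, int, int] | None = None


def load_image(path: str | Path) -> RGBImage:
    """Read a TIFF or PNG file into an :class:`RGBImage`.

    Grayscale and alpha-carrying images are rejected: the scoring rule is
    defined on three-channel RGB only.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        import imageio.v3 as iio

        arr = iio.imread(path)
    except InputError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise InputError(f"could not decode image {path}: {exc}") from exc
    if arr.ndim == 2:
        raise InputError(
            f"{path}: grayscale image; three-channel RGB is required"
        )
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(
            f"{path}: expected 3 channels (RGB), got shape {arr.shape}; "
            "alpha channels are not supported"
        )
    if arr.dtype != np.uint8:
        raise InputError(f"{path}: expected 8-bit channels, got {arr.dtype}")
    return RGBImage(pixels=arr, metadata={"path": str(path)})


def rgb_to_hsv(img: RGBImage) -> HSVImage:
    """Standard hexcone RGB→HSV conversion.

    Hue is scaled to [0,1) with red at 0; achromatic pixels (max = min)
    get hue 0 and saturation 0.
    """
    hsv = _skimage_rgb2hsv(img.pixels)
    return HSVImage(hue=hsv[..., 0], saturation=hsv[..., 1], value=hsv[..., 2])


def yellow_mask(
    hsv: HSVImage,
    hue_threshold: float = DEFAULT_HUE_THRESHOLD,
    saturation_gate: float | None = None,
) -> YellowMask:
    """Classify pixels as yellow by ``hue < hue_threshold``.

    With ``saturation_gate`` set, low-saturation (near-white) pixels are
    excluded from the yellow class regardless of hue.
    """
    if not (0.0 < hue_threshold < 1.0):
        raise ConfigError(
            f"hue_threshold must lie in (0, 1), got {hue_threshold}"
        )
    if saturation_gate is not None and not (0.0 <= saturation_gate <= 1.0):
        raise ConfigError(
            f"saturation_gate must lie in [0, 1], got {saturation_gate}"
        )
    mask = hsv.hue < hue_threshold
    if saturation_gate is not None:
        mask &= hsv.saturation >= saturation_gate
    return YellowMask(
        mask=mask, n_yellow=int(mask.sum()), n_total=int(mask.size)
    )


def yellow_area_percent(mask: YellowMask) -> float:
    """Yellow pixels as a percentage of all pixels."""
    if mask.n_total <= 0:
        raise InputError("empty mask: no pixels to score")
    return 100.0 * mask.n_yellow / mask.n_total


def score_image(
    path: str | Path, config: AppearanceConfig | None = None
) -> AppearanceScore:
    """Load, convert, classify and score one image file."""
    config = config or AppearanceConfig()
    img = load_image(path)
    if config.roi is not None:
        r0, r1, c0, c1 = config.roi
        cropped = img.pixels[r0:r1, c0:c1]
        if cropped.size == 0:
            raise ConfigError(f"roi {config.roi} selects no pixels")
        img = RGBImage(pixels=cropped, metadata=dict(img.metadata))
    hsv = rgb_to_hsv(img)
    mask = yellow_mask(hsv, config.hue_threshold, config.saturation_gate)
    return AppearanceScore(
        yellow_area_percent=yellow_area_percent(mask),
        hue_threshold=config.hue_threshold,
        saturation_gate=config.saturation_gate,
        n_yellow=mask.n_yellow,
        n_total=mask.n_total,
        path=str(path),
    )


def score_images(
    paths: Sequence[str | Path] | Iterable[str | Path],
    config: AppearanceConfig | None = None,
) -> pd.DataFrame:
    """Score several images; one row per image.

    The per-sample averaging of repeat shots is left to the caller (the
    CLI appends a mean row over the batch it was given).
    """
    rows = []
    for p in paths:
        s = score_image(p, config)
        rows.append(
            {
                "path": s.path,
                "n_total": s.n_total,
                "n_yellow": s.n_yellow,
                "yellow_area_percent": s.yellow_area_percent,
                "hue_threshold": s.hue_threshold,
                "saturation_gate": s.saturation_gate,
            }
        )
    if not rows:
        raise InputError("no images to score")
    return pd.DataFrame(rows)
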