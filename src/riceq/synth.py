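"""Seeded generators with known ground truth for every analysis module.

No raw study data (images, force curves, panel tables) were deposited,
so each pipeline stage gets a generator that emulates its input at a
controllable, known truth:

* :func:`make_image` — a grain-textured frame in which an exact, seeded
  subset of pixels is colored with yellow hues and the rest stay
  blue-tinted near-white; the per-class pixel counts are emitted as
  ground truth (defined by the generated labels, never by re-running the
  classifier).
* :func:`make_curve` — a piecewise-linear two-cycle compression profile
  whose areas, durations and peak have closed forms; the sample grid
  includes every breakpoint so trapezoidal integration of the samples is
  exact.
* :func:`make_panel` — a balanced variety × year × replicate score table
  with specified genetic and environmental variance components and an
  overall score (IVOE) generated from a latent linear model of the
  component traits.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import ellipse

from .errors import ConfigError
from .image import RGBImage
from .tpa import ForceCurve, TPAFeatures

# ---------------------------------------------------------------------------
# images


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of a synthetic cooked-rice frame.

    The full frame is treated as rice (the imaging protocol fills the
    field of view with grains), so any ``yellow_fraction`` in [0, 1] is
    achievable.  Non-yellow pixels are near-white with a slight blue
    tint (hue ≈ 0.6, saturation ≈ 0.02–0.04) so that, like real glossy
    white rice under a calibrated lamp, they fall outside the yellow hue
    band even with the saturation gate disabled.  Yellow pixels draw
    hues from ``yellow_hue_range``, a sub-interval of [0, 0.167) kept
    clear of the threshold so channel noise cannot flip a class.
    """

    width: int = 320
    height: int = 240
    n_grains: int = 350
    yellow_fraction: float = 0.2
    yellow_hue_range: tuple[float, float] = (0.09, 0.145)
    white_color: tuple[int, int, int] = (246, 248, 255)
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigError("image dimensions must be positive")
        if not (0.0 <= self.yellow_fraction <= 1.0):
            raise ConfigError(
                f"yellow_fraction must lie in [0, 1], got {self.yellow_fraction}"
            )
        lo, hi = self.yellow_hue_range
        if not (0.0 <= lo < hi < 0.167):
            raise ConfigError(
                "yellow_hue_range must be a sub-interval of [0, 0.167)"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        r, g, b = self.white_color
        if not all(0 <= c <= 255 for c in (r, g, b)):
            raise ConfigError("white_color channels must lie in [0, 255]")


@dataclass(frozen=True)
class ImageTruth:
    """Generated class labels and their counts."""

    yellow_mask: np.ndarray
    n_yellow: int
    n_total: int

    @property
    def yellow_area_percent(self) -> float:
        return 100.0 * self.n_yellow / self.n_total


def _grain_labels(spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Ellipse 'grains' stamped over the frame; later grains overwrite."""
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    # grain size scales with frame so coverage stays dense
    major = max(spec.width, spec.height) / 18.0
    for g in range(1, spec.n_grains + 1):
        cy = rng.uniform(0, spec.height)
        cx = rng.uniform(0, spec.width)
        a = rng.uniform(0.5, 1.0) * major
        b = rng.uniform(0.3, 0.5) * a
        rr, cc = ellipse(
            cy, cx, a, b, shape=labels.shape, rotation=rng.uniform(0, np.pi)
        )
        labels[rr, cc] = g
    return labels


def make_image(spec: ImageSpec) -> tuple[RGBImage, ImageTruth]:
    """Render a synthetic frame with an exact yellow pixel count.

    Whole grains are assigned to the yellow class in seeded order until
    the target count ``round(yellow_fraction · H · W)`` would be
    exceeded; the remainder is filled pixel-by-pixel from the next grain
    (and, for extreme fractions, from inter-grain pixels), so the ground
    truth count always equals the target exactly.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    labels = _grain_labels(spec, rng)
    n_total = h * w
    n_target = int(round(spec.yellow_fraction * n_total))

    yellow = np.zeros((h, w), dtype=bool)
    flat = labels.ravel()
    order = rng.permutation(spec.n_grains) + 1
    remaining = n_target
    pool: list[np.ndarray] = [np.flatnonzero(flat == g) for g in order]
    pool.append(np.flatnonzero(flat == 0))  # inter-grain fallback
    yflat = yellow.ravel()
    for px in pool:
        if remaining <= 0:
            break
        take = px[~yflat[px]]
        if take.size <= remaining:
            yflat[take] = True
            remaining -= take.size
        else:
            yflat[rng.choice(take, size=remaining, replace=False)] = True
            remaining = 0
    assert int(yflat.sum()) == n_target

    # white base: blue-tinted near-white with per-grain brightness texture
    base = np.empty((h, w, 3), dtype=float)
    base[:] = np.asarray(spec.white_color, float)
    gains = rng.uniform(0.90, 1.0, size=spec.n_grains + 1)
    base *= gains[labels][..., None]
    base[labels == 0] *= 0.94  # inter-grain shadow

    # yellow pixels: sample HSV inside the band, convert to RGB
    idx = np.flatnonzero(yflat)
    if idx.size:
        hsv = np.empty((idx.size, 1, 3), dtype=float)
        hsv[:, 0, 0] = rng.uniform(*spec.yellow_hue_range, size=idx.size)
        hsv[:, 0, 1] = rng.uniform(0.30, 0.55, size=idx.size)
        hsv[:, 0, 2] = rng.uniform(0.80, 0.96, size=idx.size)
        rgb = hsv2rgb(hsv)[:, 0, :] * 255.0
        base.reshape(-1, 3)[idx] = rgb

    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
    pixels = np.clip(np.rint(base), 0, 255).astype(np.uint8)
    truth = ImageTruth(yellow_mask=yellow, n_yellow=n_target, n_total=n_total)
    return RGBImage(pixels=pixels, metadata={"synthetic": True, "seed": spec.seed}), truth


# ---------------------------------------------------------------------------
# force curves


@dataclass(frozen=True)
class CurveSpec:
    """Parameters of a synthetic double-compression force curve.

    The profile is piecewise linear: a triangular first compression of
    peak ``hardness`` and base ``t1`` (apex at ``apex_fraction`` of the
    base), a triangular negative adhesion dip of area ``a3_magnitude``
    over ``dip_duration``, and a triangular second compression of base
    ``t2`` whose peak is set so that A2 = ``cohesiveness_target`` · A1.
    """

    hardness: float = 500.0
    a3_magnitude: float = 100.0
    t1: float = 2.0
    t2: float = 1.5
    cohesiveness_target: float = 0.6
    apex_fraction: float = 0.5
    dip_duration: float = 1.0
    lead: float = 0.25
    gap: float = 0.25
    sample_rate: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hardness", "a3_magnitude", "t1", "t2", "dip_duration",
                     "sample_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 < self.apex_fraction < 1.0):
            raise ConfigError("apex_fraction must lie in (0, 1)")
        if not (0.0 < self.cohesiveness_target):
            raise ConfigError("cohesiveness_target must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    def truth(self) -> TPAFeatures:
        """Closed-form feature values implied by the spec."""
        a1 = 0.5 * self.hardness * self.t1
        a2 = self.cohesiveness_target * a1
        a4 = self.apex_fraction * a1
        a5 = (1.0 - self.apex_fraction) * a1
        springiness = self.t2 / self.t1
        gumminess = self.cohesiveness_target * self.hardness
        return TPAFeatures(
            hardness=self.hardness,
            brittleness=None,
            A1=a1,
            A2=a2,
            A3=self.a3_magnitude,
            A4=a4,
            A5=a5,
            T1=self.t1,
            T2=self.t2,
            adhesiveness=self.a3_magnitude,
            springiness=springiness,
            cohesiveness=self.cohesiveness_target,
            gumminess=gumminess,
            chewiness=gumminess * springiness,
            resilience=a5 / a4,
        )


def make_curve(spec: CurveSpec) -> tuple[ForceCurve, TPAFeatures]:
    """Sample the piecewise-linear profile; grid includes every breakpoint."""
    a1 = 0.5 * spec.hardness * spec.t1
    peak2 = 2.0 * spec.cohesiveness_target * a1 / spec.t2
    dip_depth = 2.0 * spec.a3_magnitude / spec.dip_duration

    t0 = spec.lead
    bp_t = [0.0, t0]
    bp_f = [0.0, 0.0]
    # cycle 1
    apex_t = t0 + spec.apex_fraction * spec.t1
    bp_t += [apex_t, t0 + spec.t1]
    bp_f += [spec.hardness, 0.0]
    # adhesion dip (starts immediately at cycle-1 end)
    d0 = t0 + spec.t1
    bp_t += [d0 + spec.dip_duration / 2.0, d0 + spec.dip_duration]
    bp_f += [-dip_depth, 0.0]
    # rest gap
    g0 = d0 + spec.dip_duration
    bp_t += [g0 + spec.gap]
    bp_f += [0.0]
    # cycle 2 (symmetric triangle)
    c2 = g0 + spec.gap
    bp_t += [c2 + spec.t2 / 2.0, c2 + spec.t2, c2 + spec.t2 + spec.lead]
    bp_f += [peak2, 0.0, 0.0]

    bp_t = np.asarray(bp_t)
    bp_f = np.asarray(bp_f)
    grid = np.arange(0.0, bp_t[-1], 1.0 / spec.sample_rate)
    time = np.unique(np.concatenate([grid, bp_t]))
    force = np.interp(time, bp_t, bp_f)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        force = force + rng.normal(0.0, spec.noise_sd, size=force.shape)
    return ForceCurve(time=time, force=force), spec.truth()


# ---------------------------------------------------------------------------
# sensory panels


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic sensory-panel table.

    The default shape mirrors the study design: 322 varieties scored in
    2 years with 3 sensory replicates, each trait carrying a genetic
    variance ``var_g`` (variety effects) and an environmental variance
    ``var_e`` (variety × year deviations).  Component traits share a
    genetic correlation ``trait_corr`` through a common factor.  IVOE is
    generated from the latent linear model
    ``trait_betas · (viscosity, appearance, taste) + intercept + noise``;
    with ``ivoe_noise_sd=None`` the noise is calibrated at run time so
    the latent model's R² equals ``target_r2``.

    Scores are clipped to the −3..+3 panel scale; trait means sit in the
    slightly-negative range typical of panels judging against a premium
    reference, keeping the clipping rate well below 1% at the default
    variances.
    """

    n_varieties: int = 322
    n_years: int = 2
    n_reps: int = 3
    var_g: float = 0.15
    var_e: float = 0.05
    trait_corr: float = 0.5
    trait_betas: tuple[float, float, float] = (0.20, 0.35, 0.59)
    intercept: float = 0.13
    target_r2: float = 0.87
    ivoe_noise_sd: float | None = None
    noise_sd: float = 0.1  # replicate-level measurement noise
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "viscosity": -0.56,
            "appearance": -0.49,
            "taste": -0.66,
            "hardness": 0.06,
            "fragrance": -0.20,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_varieties < 2 or self.n_years < 1 or self.n_reps < 1:
            raise ConfigError("panel shape must have >=2 varieties, >=1 year/rep")
        if self.var_g < 0 or self.var_e < 0 or self.noise_sd < 0:
            raise ConfigError("variances must be non-negative")
        if not (0.0 <= self.trait_corr < 1.0):
            raise ConfigError("trait_corr must lie in [0, 1)")


@dataclass(frozen=True)
class PanelTruth:
    """Generating parameters and derived expectations."""

    var_g: float
    var_e: float
    h2: float
    trait_betas: tuple[float, float, float]
    intercept: float
    ivoe_noise_sd: float
    clip_rate: float


_COMPONENTS = ("viscosity", "appearance", "taste", "hardness", "fragrance")


def make_panel(spec: PanelSpec) -> tuple[pd.DataFrame, PanelTruth]:
    """Draw a balanced long-format panel table with known truth."""
    rng = np.random.default_rng(spec.seed)
    nv, ny, nr = spec.n_varieties, spec.n_years, spec.n_reps
    sg = np.sqrt(spec.var_g)
    se = np.sqrt(spec.var_e)
    rho = spec.trait_corr

    # correlated variety effects for the three model traits via one factor;
    # hardness and fragrance independent
    common_g = rng.normal(size=nv)
    common_e = rng.normal(size=(nv, ny))
    values: dict[str, np.ndarray] = {}
    for trait in _COMPONENTS:
        own_g = rng.normal(size=nv)
        own_e = rng.normal(size=(nv, ny))
        if trait in ("viscosity", "appearance", "taste"):
            g = np.sqrt(rho) * common_g + np.sqrt(1 - rho) * own_g
            e = np.sqrt(rho) * common_e + np.sqrt(1 - rho) * own_e
        else:
            g, e = own_g, own_e
        year_shift = rng.normal(0.0, 0.1, size=ny)  # small year main effect
        values[trait] = (
            spec.trait_means.get(trait, 0.0)
            + sg * g[:, None]
            + se * e
            + year_shift[None, :]
        )

    vat = np.stack(
        [values["viscosity"], values["appearance"], values["taste"]], axis=-1
    )
    signal = vat @ np.asarray(spec.trait_betas) + spec.intercept
    if spec.ivoe_noise_sd is None:
        # calibrate residual sd so the latent model R2 hits target_r2
        var_signal = float(signal.var())
        r2 = spec.target_r2
        noise_sd = np.sqrt(var_signal * (1.0 - r2) / r2) if var_signal > 0 else 0.0
    else:
        noise_sd = spec.ivoe_noise_sd
    values["IVOE"] = signal + rng.normal(0.0, noise_sd, size=signal.shape)

    rows = []
    varieties = [f"V{i + 1:03d}" for i in range(nv)]
    years = [2020 + j for j in range(ny)]
    n_clipped = 0
    n_scores = 0
    for trait in ("IVOE",) + _COMPONENTS:
        cell = values[trait]
        rep_noise = (
            rng.normal(0.0, spec.noise_sd, size=(nv, ny, nr))
            if spec.noise_sd > 0
            else np.zeros((nv, ny, nr))
        )
        scores = cell[..., None] + rep_noise
        n_clipped += int(((scores < -3) | (scores > 3)).sum())
        n_scores += scores.size
        scores = np.clip(scores, -3.0, 3.0)
        for i, v in enumerate(varieties):
            for j, yr in enumerate(years):
                for r in range(nr):
                    rows.append((v, yr, r + 1, trait, scores[i, j, r]))
    table = pd.DataFrame(
        rows, columns=["variety", "year", "replicate", "trait", "score"]
    )
    denom = spec.var_g + spec.var_e
    truth = PanelTruth(
        var_g=spec.var_g,
        var_e=spec.var_e,
        h2=spec.var_g / denom if denom > 0 else 0.0,
        trait_betas=spec.trait_betas,
        intercept=spec.intercept,
        ivoe_noise_sd=float(noise_sd),
        clip_rate=n_clipped / n_scores if n_scores else 0.0,
    )
    return table, truth
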