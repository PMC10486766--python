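"""Texture-profile analysis (TPA) of double-compression force curves.

A texture analyzer presses a cylindrical probe twice into a bed of cooked
rice and records force against time.  The first compression produces a
positive-force pulse; as the probe withdraws, sticky rice pulls it back,
producing a negative-force excursion; the second compression produces a
second positive pulse.  The classic TPA descriptors are defined on the
areas and durations of these phases:

==============  =======================================================
hardness        peak force of the first compression (gf)
brittleness     largest local maximum before the hardness peak, if any
A1, A2          force–time areas of compressions 1 and 2 (gf·s)
A3              negative area between the compressions; its magnitude is
                *adhesiveness*, the objective proxy for sensory viscosity
A4, A5          areas of the first compression before/after its peak
T1, T2          durations of compressions 1 and 2 (s)
springiness     T2 / T1
cohesiveness    A2 / A1
gumminess       cohesiveness × hardness
chewiness       gumminess × springiness
resilience      A5 / A4
==============  =======================================================

Areas integrate force over time (gf·s) with a zero-force baseline and the
trapezoidal rule.  Ratios with a zero denominator are reported as ``None``
rather than raising.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigError, InputError, SegmentationError

logger = logging.getLogger(__name__)

DEFAULT_TRIGGER_GF = 25.0

#: ordered feature columns used by :func:`batch_tpa` and the CLI
FEATURE_COLUMNS = (
    "hardness",
    "brittleness",
    "adhesiveness",
    "springiness",
    "cohesiveness",
    "gumminess",
    "chewiness",
    "resilience",
    "A1",
    "A2",
    "A3",
    "A4",
    "A5",
    "T1",
    "T2",
)


@dataclass(frozen=True)
class ForceCurve:
    """A sampled force trace: time (s), force (gf), optional displacement (mm)."""

    time: np.ndarray
    force: np.ndarray
    displacement: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if t.ndim != 1 or f.ndim != 1 or t.size != f.size:
            raise InputError("time and force must be 1-D arrays of equal length")
        if t.size < 10:
            raise InputError(f"need at least 10 samples, got {t.size}")
        if np.isnan(t).any() or np.isnan(f).any():
            row = int(np.flatnonzero(np.isnan(t) | np.isnan(f))[0])
            raise InputError(f"missing value at row {row}")
        dt = np.diff(t)
        if (dt <= 0).any():
            row = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise InputError(f"time is not strictly increasing at row {row}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)
        if self.displacement is not None:
            d = np.asarray(self.displacement, dtype=float)
            if d.shape != t.shape:
                raise InputError("displacement length must match time")
            object.__setattr__(self, "displacement", d)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class Window:
    """Half-open index window [start, stop) into a curve."""

    start: int
    stop: int

    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass(frozen=True)
class CycleSegmentation:
    """Index windows for the two compressions and the adhesion phase."""

    cycle1: Window
    adhesion_window: Window | None
    cycle2: Window
    down1: Window
    up1: Window


@dataclass(frozen=True)
class TPAFeatures:
    """The TPA descriptor set; undefined ratios are ``None``."""

    hardness: float
    brittleness: float | None
    A1: float
    A2: float
    A3: float  # stored as magnitude
    A4: float
    A5: float
    T1: float
    T2: float
    adhesiveness: float
    springiness: float | None
    cohesiveness: float | None
    gumminess: float | None
    chewiness: float | None
    resilience: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


@dataclass(frozen=True)
class CurveDialect:
    """Column names and separator for delimited force-curve files."""

    time_column: str | None = None
    force_column: str | None = None
    displacement_column: str | None = None
    sep: str | None = None  # None = sniff comma/tab

    _TIME_ALIASES = ("time", "t", "time_s", "time (s)", "seconds")
    _FORCE_ALIASES = ("force", "f", "force_gf", "force (gf)", "load")


def parse_force_curve(
    path: str | Path, dialect: CurveDialect | None = None
) -> ForceCurve:
    """Read a delimited time/force text file into a validated curve.

    Column names are matched case-insensitively against common aliases
    unless the dialect pins them down; comma and tab separators are
    auto-detected.
    """
    dialect = dialect or CurveDialect()
    path = Path(path)
    if not path.exists():
        raise InputError(f"force-curve file not found: {path}")
    sep = dialect.sep
    if sep is None:
        head = path.read_text().splitlines()[:1]
        sep = "\t" if head and "\t" in head[0] else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise InputError(f"could not parse {path}: {exc}") from exc

    def _find(pinned: str | None, aliases: tuple[str, ...], what: str) -> str:
        if pinned is not None:
            if pinned not in df.columns:
                raise InputError(f"{path}: no column named {pinned!r}")
            return pinned
        lower = {c.strip().lower(): c for c in df.columns}
        for a in aliases:
            if a in lower:
                return lower[a]
        raise InputError(
            f"{path}: could not find a {what} column among {list(df.columns)}"
        )

    tcol = _find(dialect.time_column, CurveDialect._TIME_ALIASES, "time")
    fcol = _find(dialect.force_column, CurveDialect._FORCE_ALIASES, "force")
    disp = None
    if dialect.displacement_column is not None:
        if dialect.displacement_column not in df.columns:
            raise InputError(
                f"{path}: no column named {dialect.displacement_column!r}"
            )
        disp = df[dialect.displacement_column].to_numpy(float)
    return ForceCurve(
        time=df[tcol].to_numpy(float),
        force=df[fcol].to_numpy(float),
        displacement=disp,
    )


def _positive_extent(force: np.ndarray, idx: int) -> Window:
    """Grow from a supra-trigger index to the full positive-force phase.

    The window is extended on either side to include the adjacent
    non-positive boundary samples so the trapezoid catches the zero
    crossing.
    """
    n = force.size
    lo = idx
    while lo > 0 and force[lo - 1] > 0:
        lo -= 1
    if lo > 0:
        lo -= 1  # boundary sample (force <= 0)
    hi = idx
    while hi < n - 1 and force[hi + 1] > 0:
        hi += 1
    if hi < n - 1:
        hi += 1
    return Window(lo, hi + 1)


def segment_cycles(
    curve: ForceCurve, trigger: float = DEFAULT_TRIGGER_GF
) -> CycleSegmentation:
    """Locate the two compression cycles and the adhesion phase.

    A cycle is entered when force rises to ``trigger`` (the instrument's
    auto-trigger level) and extends over the surrounding positive-force
    phase; the exit condition is force falling to <= 0 — the hysteresis
    prevents chatter near the trigger level.  The adhesion window is the
    contiguous negative-force run between the cycles.
    """
    if trigger <= 0:
        raise ConfigError(f"trigger must be positive, got {trigger}")
    f = curve.force
    above = f >= trigger
    if not above.any():
        raise SegmentationError("no samples reach the trigger force")
    # excursions = maximal positive-force phases containing a trigger crossing
    windows: list[Window] = []
    i = 0
    n = f.size
    while i < n:
        if above[i]:
            w = _positive_extent(f, i)
            windows.append(w)
            i = w.stop
        else:
            i += 1
    if len(windows) < 2:
        raise SegmentationError(
            f"expected two compression cycles above {trigger} gf, "
            f"found {len(windows)}"
        )
    if len(windows) > 2:
        # keep the two largest-peak excursions, in temporal order
        peaks = [f[w.slice()].max() for w in windows]
        keep = sorted(np.argsort(peaks)[-2:])
        windows = [windows[k] for k in keep]
    cycle1, cycle2 = windows[0], windows[1]

    # adhesion: contiguous negative run between the cycles
    mid = f[cycle1.stop - 1 : cycle2.start + 1]
    neg = np.flatnonzero(mid < 0)
    adhesion: Window | None = None
    if neg.size:
        first = int(neg[0])
        last = first
        while last + 1 < neg.size and neg[last + 1] == neg[last] + 1:
            last += 1
        lo = cycle1.stop - 1 + first
        hi = cycle1.stop - 1 + int(neg[last])
        lo = max(lo - 1, 0)  # include boundary samples
        hi = min(hi + 1, f.size - 1)
        adhesion = Window(lo, hi + 1)

    peak_rel = int(np.argmax(f[cycle1.slice()]))
    peak_idx = cycle1.start + peak_rel
    down1 = Window(cycle1.start, peak_idx + 1)
    up1 = Window(peak_idx, cycle1.stop)
    return CycleSegmentation(
        cycle1=cycle1,
        adhesion_window=adhesion,
        cycle2=cycle2,
        down1=down1,
        up1=up1,
    )


def _area(curve: ForceCurve, w: Window, clip: str = "pos") -> float:
    t = curve.time[w.slice()]
    f = curve.force[w.slice()]
    if clip == "pos":
        f = np.maximum(f, 0.0)
    else:
        f = np.minimum(f, 0.0)
    return float(np.trapezoid(f, t))


def _safe_ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def _brittleness(
    curve: ForceCurve, down1: Window, hardness: float, min_prominence_frac: float
) -> float | None:
    """Largest local maximum strictly before the hardness peak.

    Peaks need a minimum prominence (default 5% of hardness) so noise
    ripples on the rising flank are not reported as fracture events.
    """
    f = curve.force[down1.slice()][:-1]  # exclude the hardness peak itself
    if f.size < 3:
        return None
    idx, _ = find_peaks(f, prominence=min_prominence_frac * hardness)
    if idx.size == 0:
        return None
    cand = f[idx]
    cand = cand[cand < hardness]
    return float(cand.max()) if cand.size else None


def compute_tpa(
    curve: ForceCurve,
    seg: CycleSegmentation | None = None,
    *,
    trigger: float = DEFAULT_TRIGGER_GF,
    brittleness_prominence: float = 0.05,
) -> TPAFeatures:
    """Compute the TPA descriptor set from a segmented curve.

    ``seg`` defaults to :func:`segment_cycles` on the curve.  Undefined
    ratios (zero denominators) come back as ``None``, never as a crash.
    """
    if seg is None:
        seg = segment_cycles(curve, trigger)
    a1 = _area(curve, seg.cycle1)
    a2 = _area(curve, seg.cycle2)
    a3 = (
        abs(_area(curve, seg.adhesion_window, clip="neg"))
        if seg.adhesion_window is not None
        else 0.0
    )
    a4 = _area(curve, seg.down1)
    a5 = _area(curve, seg.up1)
    t1 = float(curve.time[seg.cycle1.stop - 1] - curve.time[seg.cycle1.start])
    t2 = float(curve.time[seg.cycle2.stop - 1] - curve.time[seg.cycle2.start])
    hardness = float(curve.force[seg.cycle1.slice()].max())
    springiness = _safe_ratio(t2, t1)
    cohesiveness = _safe_ratio(a2, a1)
    gumminess = None if cohesiveness is None else cohesiveness * hardness
    chewiness = (
        None
        if gumminess is None or springiness is None
        else gumminess * springiness
    )
    resilience = _safe_ratio(a5, a4)
    return TPAFeatures(
        hardness=hardness,
        brittleness=_brittleness(curve, seg.down1, hardness, brittleness_prominence),
        A1=a1,
        A2=a2,
        A3=a3,
        A4=a4,
        A5=a5,
        T1=t1,
        T2=t2,
        adhesiveness=a3,
        springiness=springiness,
        cohesiveness=cohesiveness,
        gumminess=gumminess,
        chewiness=chewiness,
        resilience=resilience,
    )


_SAMPLE_REP_RE = re.compile(r"^(?P<sample>.+?)[_\-](?:rep)?(?P<replicate>\d+)$")


def _sample_replicate(stem: str) -> tuple[str, int]:
    m = _SAMPLE_REP_RE.match(stem)
    if m:
        return m.group("sample"), int(m.group("replicate"))
    return stem, 1


def batch_tpa(
    paths: Sequence[str | Path] | Iterable[str | Path],
    *,
    dialect: CurveDialect | None = None,
    trigger: float = DEFAULT_TRIGGER_GF,
    control: str | None = None,
    sample_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Extract features from many curve files into a long table.

    Samples and replicate indices are taken from the file stem
    (``<sample>_<replicate>``); per-sample means are appended as rows with
    ``replicate == "mean"``.  With ``control`` set to a sample name, each
    mean row also carries ``<feature>_vs_control`` differences, supporting
    batch-effect correction by comparison with a control sample.  Files
    that fail to parse or segment are logged and skipped; if every file
    fails, an error is raised.
    """
    rows = []
    failures = []
    for p in paths:
        p = Path(p)
        stem = p.stem
        if sample_names and stem in sample_names:
            sample, rep = sample_names[stem], 1
        else:
            sample, rep = _sample_replicate(stem)
        try:
            curve = parse_force_curve(p, dialect)
            feats = compute_tpa(curve, trigger=trigger)
        except InputError as exc:
            logger.warning("skipping %s: %s", p, exc)
            failures.append((str(p), str(exc)))
            continue
        rows.append(
            {"sample": sample, "replicate": rep, "path": str(p), **feats.as_dict()}
        )
    if not rows:
        raise InputError(
            "no force curve could be processed; failures: "
            + "; ".join(f"{p}: {e}" for p, e in failures)
        )
    per_curve = pd.DataFrame(rows)
    means = (
        per_curve.groupby("sample", sort=False)[list(FEATURE_COLUMNS)]
        .mean()
        .reset_index()
    )
    means.insert(1, "replicate", "mean")
    means.insert(2, "path", "")
    if control is not None:
        if control not in means["sample"].values:
            raise InputError(f"control sample {control!r} not in batch")
        ctrl = means.loc[means["sample"] == control, list(FEATURE_COLUMNS)].iloc[0]
        for c in FEATURE_COLUMNS:
            means[f"{c}_vs_control"] = means[c] - ctrl[c]
    out = pd.concat([per_curve, means], ignore_index=True)
    out.attrs["failures"] = failures
    return out
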