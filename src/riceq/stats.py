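"""Variance-component and association statistics for sensory-panel scores.

Panels score each variety in each year on a −3..+3 scale relative to a
reference variety, for six traits: the overall eating-quality score
(IVOE) and its components viscosity, appearance, taste, hardness and
fragrance.  This module decomposes trait variance over a balanced
variety × year layout, estimates broad-sense heritability from the
expected mean squares, and provides the correlation and paired-t
utilities used to relate instrument readouts to panel scores.

The ANOVA is the additive two-way decomposition without interaction:
sensory replicates are averaged into one value per (variety, year) cell,
giving ``df_year = n_years − 1``, ``df_variety = n_varieties − 1`` and
``df_error = (n_years − 1)(n_varieties − 1)``; both F statistics are
tested against the error mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

TRAITS = ("IVOE", "viscosity", "appearance", "taste", "hardness", "fragrance")

SENSORY_COLUMNS = ("variety", "year", "replicate", "trait", "score")


def validate_sensory_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format panel table: columns, score range, uniqueness."""
    missing = [c for c in SENSORY_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"sensory table lacks columns: {missing}")
    s = table["score"].to_numpy(float)
    if np.isnan(s).any():
        raise InputError("sensory table contains missing scores")
    if (s < -3).any() or (s > 3).any():
        bad = table.loc[(table["score"] < -3) | (table["score"] > 3)].index[0]
        raise InputError(f"score outside [-3, 3] at row {bad}")
    keys = ["variety", "year", "replicate", "trait"]
    if table.duplicated(subset=keys).any():
        dup = table[table.duplicated(subset=keys, keep=False)].iloc[0]
        raise InputError(
            "duplicate (variety, year, replicate, trait) entry: "
            f"{tuple(dup[k] for k in keys)}"
        )
    return table


@dataclass(frozen=True)
class HeritabilityResult:
    """Broad-sense heritability h² = var(G) / (var(G) + var(E))."""

    var_g: float
    var_e: float
    r_reps: int
    h2: float
    formula: str = (
        "var_g = max(0, (MS_variety - MS_error) / r); var_e = MS_error; "
        "h2 = var_g / (var_g + var_e)"
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two paired score vectors."""

    r: float | None
    n: int
    p: float | None
    pair: tuple[str, str] = ("x", "y")
    flagged: str | None = None


@dataclass(frozen=True)
class PairedTResult:
    t: float | None
    p: float | None
    ci_low: float
    ci_high: float
    mean_diff: float
    n: int
    flagged: str | None = None


def anova_two_way(
    table: pd.DataFrame, trait: str, replicate_policy: str = "mean"
) -> pd.DataFrame:
    """Balanced two-way ANOVA (Year + Variety, no interaction) for one trait.

    Returns a table indexed by source (Year, Variety, Error, Total) with
    columns df, ss, ms, f, p.  The design must be balanced: every variety
    observed in every year.  ``replicate_policy`` "mean" averages sensory
    replicates into the (variety, year) cell before decomposing; the mode
    is recorded in ``result.attrs``.
    """
    validate_sensory_table(table)
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise InputError(f"no rows for trait {trait!r}")
    if replicate_policy != "mean":
        raise InputError(f"unknown replicate_policy {replicate_policy!r}")
    cells = (
        sub.groupby(["variety", "year"], sort=True)["score"].mean().unstack("year")
    )
    if cells.isna().any().any():
        missing = [
            (v, y)
            for (v, y) in zip(*np.nonzero(cells.isna().to_numpy()))
        ]
        names = [
            f"({cells.index[v]}, {cells.columns[y]})" for v, y in missing[:5]
        ]
        raise InputError(
            f"unbalanced design: missing cells {', '.join(names)}"
            + (" ..." if len(missing) > 5 else "")
        )
    y = cells.to_numpy(float)  # varieties × years
    nv, ny = y.shape
    if nv < 2 or ny < 2:
        raise InputError("need at least two varieties and two years")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_variety = float(ny * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_year = float(nv * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_variety - ss_year
    df_year, df_variety = ny - 1, nv - 1
    df_error = df_year * df_variety
    ms_year = ss_year / df_year
    ms_variety = ss_variety / df_variety
    ms_error = ss_error / df_error
    if ms_error > 0:
        f_year = ms_year / ms_error
        f_variety = ms_variety / ms_error
        p_year = float(sps.f.sf(f_year, df_year, df_error))
        p_variety = float(sps.f.sf(f_variety, df_variety, df_error))
    else:
        f_year = f_variety = p_year = p_variety = np.nan
    out = pd.DataFrame(
        {
            "df": [df_year, df_variety, df_error, df_year + df_variety + df_error],
            "ss": [ss_year, ss_variety, ss_error, ss_total],
            "ms": [ms_year, ms_variety, ms_error, np.nan],
            "f": [f_year, f_variety, np.nan, np.nan],
            "p": [p_year, p_variety, np.nan, np.nan],
        },
        index=pd.Index(["Year", "Variety", "Error", "Total"], name="source"),
    )
    out.attrs["trait"] = trait
    out.attrs["replicate_policy"] = replicate_policy
    out.attrs["zero_error_variance"] = bool(ms_error == 0)
    return out


def broad_sense_h2(anova: pd.DataFrame, r_reps: int = 2) -> HeritabilityResult:
    """Heritability from expected mean squares, with zero truncation.

    Treating variety as a random effect, E[MS_variety] = var_e + r·var_g
    and E[MS_error] = var_e, so ``var_g = max(0, (MS_variety − MS_error)/r)``.
    ``r_reps`` is the number of replications per variety entering the
    variety mean square — the number of years (2) in the default layout.
    """
    if r_reps < 1:
        raise InputError(f"r_reps must be >= 1, got {r_reps}")
    for needed in ("Variety", "Error"):
        if needed not in anova.index:
            raise InputError(f"ANOVA table lacks a {needed!r} row")
    ms_v = float(anova.loc["Variety", "ms"])
    ms_e = float(anova.loc["Error", "ms"])
    var_g = max(0.0, (ms_v - ms_e) / r_reps)
    var_e = ms_e
    denom = var_g + var_e
    h2 = var_g / denom if denom > 0 else 0.0
    return HeritabilityResult(var_g=var_g, var_e=var_e, r_reps=r_reps, h2=h2)


def pearson(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D vectors")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise InputError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            r=None, n=n, p=None, pair=pair, flagged="zero variance"
        )
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), n=n, p=float(res.pvalue), pair=pair
    )


def paired_t(x, y, confidence: float = 0.95) -> PairedTResult:
    """Paired-sample t test on the differences, with a CI of the mean difference."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise InputError(f"need at least 2 pairs, got {n}")
    d = x - y
    md = float(d.mean())
    if np.ptp(d) == 0:
        return PairedTResult(
            t=None,
            p=None,
            ci_low=md,
            ci_high=md,
            mean_diff=md,
            n=n,
            flagged="zero-variance differences (degenerate CI)",
        )
    res = sps.ttest_rel(x, y)
    ci = res.confidence_interval(confidence)
    return PairedTResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        mean_diff=md,
        n=n,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise-complete trait correlation matrix over per-variety means."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flagged: tuple[str, ...] = ()


def trait_correlation_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Correlations among trait means per variety (unit diagonal, symmetric).

    Constant traits have their rows/columns flagged and reported as NaN.
    """
    validate_sensory_table(table)
    wide = (
        table.groupby(["variety", "trait"], sort=True)["score"].mean().unstack("trait")
    )
    traits = list(wide.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    flagged = [t for t in traits if np.ptp(wide[t].dropna().to_numpy()) == 0]
    for i, a in enumerate(traits):
        for j, b in enumerate(traits[: i + 1]):
            pairs = wide[[a, b]].dropna()
            n[i, j] = n[j, i] = len(pairs)
            if a == b:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            if a in flagged or b in flagged or len(pairs) < 3:
                continue
            res = pearson(pairs[a], pairs[b], pair=(a, b))
            if res.r is not None:
                r[i, j] = r[j, i] = res.r
                p[i, j] = p[j, i] = res.p
    idx = pd.Index(traits, name="trait")
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        flagged=tuple(flagged),
    )
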