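"""Published reference statistics from the 322-variety Geng rice study.

The source study evaluated 322 Geng (japonica) rice varieties over the
2020 and 2021 seasons and reported a variety × year ANOVA for each
sensory trait.  The printed sums of squares and degrees of freedom are
reproduced here so the decomposition can be re-checked without the raw
panel data (which were not deposited).

Notes on internal consistency of the printed table:

* the printed variety/error mean squares are rounded to two decimals and
  are not exactly SS/DF; the variety F statistic, however, equals
  SS_variety / SS_error (the two sources share df = 321) to within
  rounding for every trait, and that is the identity asserted here;
* the printed year F values are not recoverable from any combination of
  the printed mean squares, and the printed broad-sense heritabilities
  (``PUBLISHED_H2``) are not derivable from the table under the
  expected-mean-square estimator for any plausible replication count —
  they are recorded for reference only and never asserted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

#: Printed ANOVA decomposition per trait: source -> (df, ss).
PUBLISHED_ANOVA: dict[str, dict[str, tuple[int, float]]] = {
    "IVOE": {"Year": (1, 8.71), "Variety": (321, 50.03), "Error": (321, 16.87)},
    "appearance": {"Year": (1, 2.06), "Variety": (321, 29.33), "Error": (321, 18.28)},
    "viscosity": {"Year": (1, 5.24), "Variety": (321, 29.43), "Error": (321, 11.32)},
    "taste": {"Year": (1, 3.49), "Variety": (321, 33.12), "Error": (321, 15.73)},
    "hardness": {"Year": (1, 7.03), "Variety": (321, 19.75), "Error": (321, 18.36)},
    "fragrance": {"Year": (1, 3.29), "Variety": (321, 15.59), "Error": (321, 9.82)},
}

#: Printed variety F statistics (two decimals) per trait.
PUBLISHED_VARIETY_F: dict[str, float] = {
    "IVOE": 2.96,
    "appearance": 1.60,
    "viscosity": 2.60,
    "taste": 2.11,
    "hardness": 1.08,
    "fragrance": 1.59,
}

#: Printed broad-sense heritabilities (documented, not asserted — see module docstring).
PUBLISHED_H2: dict[str, float] = {
    "IVOE": 0.78,
    "viscosity": 0.76,
    "taste": 0.71,
    "appearance": 0.5,
    "fragrance": 0.38,
}


def anova_from_sums(
    ss_by_source: dict[str, float], df_by_source: dict[str, int]
) -> pd.DataFrame:
    """Rebuild a full ANOVA table (MS, F, P) from sums of squares and df.

    Sources must include Variety and Error; Year is optional.  F for each
    tested source is its mean square against the error mean square.
    """
    for needed in ("Variety", "Error"):
        if needed not in ss_by_source or needed not in df_by_source:
            raise InputError(f"missing {needed!r} sum of squares / df")
    sources = [s for s in ("Year", "Variety", "Error") if s in ss_by_source]
    df = np.array([df_by_source[s] for s in sources], dtype=int)
    ss = np.array([ss_by_source[s] for s in sources], dtype=float)
    ms = ss / df
    ms_error = ms[sources.index("Error")]
    df_error = df[sources.index("Error")]
    f = np.full(len(sources), np.nan)
    p = np.full(len(sources), np.nan)
    for i, s in enumerate(sources):
        if s != "Error" and ms_error > 0:
            f[i] = ms[i] / ms_error
            p[i] = sps.f.sf(f[i], df[i], df_error)
    out = pd.DataFrame(
        {"df": df, "ss": ss, "ms": ms, "f": f, "p": p},
        index=pd.Index(sources, name="source"),
    )
    total = pd.DataFrame(
        {"df": [df.sum()], "ss": [ss.sum()], "ms": [np.nan], "f": [np.nan], "p": [np.nan]},
        index=pd.Index(["Total"], name="source"),
    )
    return pd.concat([out, total])


def published_variety_f(trait: str) -> float:
    """Variety F recomputed from the published sums of squares.

    Variety and Error share df = 321, so the F statistic reduces to the
    ratio of their sums of squares.
    """
    if trait not in PUBLISHED_ANOVA:
        raise InputError(f"no published ANOVA for trait {trait!r}")
    tab = anova_from_sums(
        {s: ss for s, (d, ss) in PUBLISHED_ANOVA[trait].items()},
        {s: d for s, (d, ss) in PUBLISHED_ANOVA[trait].items()},
    )
    return float(tab.loc["Variety", "f"])
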