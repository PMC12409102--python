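"""Canopy stratification, vertical profiles, and nonparametric strata tests.

Heights are partitioned into three strata — S1 (lower canopy, 0–20 m),
S2 (mid canopy, 20–40 m) and S3 (upper canopy, > 40 m) — with half-open
boundaries assigned upward. Vertical profiles summarise any measured variable
in 1-m height bins with Student-t confidence intervals (90% by default).
Strata are compared with a Kruskal–Wallis omnibus test followed by pairwise
Mann–Whitney U tests (raw and Holm-adjusted p-values) summarised as a compact
letter display: strata sharing a letter are not significantly different.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STRATA_BOUNDS",
    "assign_stratum",
    "vertical_profile",
    "strata_compare",
    "strata_deltas",
    "compact_letter_display",
]

#: Half-open stratum intervals [low, high) in metres.
STRATA_BOUNDS = {"S1": (0.0, 20.0), "S2": (20.0, 40.0), "S3": (40.0, np.inf)}


def assign_stratum(height):
    """Map height (m) to its stratum label; total on [0, ∞)."""
    h = np.asarray(height, dtype=float)
    if np.any(h < 0) or np.any(~np.isfinite(h)):
        raise ValueError("height must be finite and >= 0")
    out = np.where(h < 20.0, "S1", np.where(h < 40.0, "S2", "S3"))
    return out if out.ndim else str(out)


def vertical_profile(records: pd.DataFrame, variable: str,
                     height_col: str = "height_m", bin_width: float = 1.0,
                     ci: float = 0.90) -> pd.DataFrame:
    """Per-height-bin mean and t-based CI half-width of one variable.

    Bins are ``[i·w, (i+1)·w)``; empty bins are omitted and the CI half-width
    is NaN for singleton bins.
    """
    if records.empty:
        raise ValueError("need at least one record")
    h = records[height_col].to_numpy(dtype=float)
    v = records[variable].to_numpy(dtype=float)
    ok = np.isfinite(h) & np.isfinite(v)
    h, v = h[ok], v[ok]
    idx = np.floor(h / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        vals = v[idx == b]
        n = len(vals)
        mean = float(np.mean(vals))
        if n >= 2:
            sem = float(np.std(vals, ddof=1)) / np.sqrt(n)
            half = float(stats.t.ppf(0.5 + ci / 2.0, n - 1) * sem)
        else:
            half = np.nan
        rows.append(dict(bin_low=b * bin_width, bin_high=(b + 1) * bin_width,
                         n=n, mean=mean, ci_half_width=half, variable=variable))
    return pd.DataFrame(rows)


def compact_letter_display(groups: list[str], reject: dict[frozenset, bool]) -> dict[str, str]:
    """Assign letters so groups sharing one are not significantly different.

    Insert-and-absorb construction: start from a single letter holding every
    group; for each significantly different pair, split any letter containing
    both into two letters (one without each member); absorb letters fully
    contained in another. The result covers every group and separates exactly
    the rejected pairs.
    """
    letters: list[set[str]] = [set(groups)]
    for pair, rej in reject.items():
        if not rej:
            continue
        a, b = tuple(pair)
        for s in [s for s in letters if a in s and b in s]:
            letters.remove(s)
            letters.extend([s - {a}, s - {b}])
        letters = [s for i, s in enumerate(letters)
                   if s and not any(s < o or (s == o and i > j)
                                    for j, o in enumerate(letters) if i != j)]
    order = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda s: min(order[g] for g in s))
    out = {g: "" for g in groups}
    for label, s in zip("abcdefghij", letters):
        for g in sorted(s):
            out[g] += label
    return out


def strata_compare(records: pd.DataFrame, variable: str,
                   stratum_col: str = "stratum", alpha: float = 0.05) -> dict:
    """Kruskal–Wallis across strata plus pairwise Mann–Whitney U letters.

    Returns a dict with the omnibus statistic/p-value, per-pair raw and
    Holm-adjusted Mann–Whitney p-values, and a compact letter display built
    on the Holm-adjusted values at the given alpha. Strata with fewer than
    two records are excluded with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    if stratum_col not in records.columns:
        records = records.assign(**{stratum_col: assign_stratum(
            records["height_m"].to_numpy())})
    samples: dict[str, np.ndarray] = {}
    for s, grp in records.groupby(stratum_col, observed=True):
        vals = grp[variable].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            warnings.warn(f"stratum {s} has <2 records; excluded", stacklevel=2)
            continue
        samples[str(s)] = vals
    names = sorted(samples)
    if len(names) < 2:
        raise ValueError("need at least two strata with >=2 records")
    kw_stat, kw_p = stats.kruskal(*[samples[s] for s in names])
    pairs = list(itertools.combinations(names, 2))
    raw = [float(stats.mannwhitneyu(samples[a], samples[b],
                                    alternative="two-sided").pvalue)
           for a, b in pairs]
    adj = list(multipletests(raw, method="holm")[1]) if pairs else []
    reject = {frozenset(p): bool(q <= alpha) for p, q in zip(pairs, adj)}
    # order groups by median so letter 'a' goes to the lowest-median stratum
    order = sorted(names, key=lambda s: np.median(samples[s]))
    letters = compact_letter_display(order, reject)
    return dict(
        kw_stat=float(kw_stat), kw_p=float(kw_p),
        pairwise={f"{a}-{b}": dict(p_raw=r, p_holm=h)
                  for (a, b), r, h in zip(pairs, raw, adj)},
        letters=letters,
        n={s: int(len(samples[s])) for s in names},
    )


def strata_deltas(records: pd.DataFrame, variable: str,
                  stratum_col: str = "stratum") -> dict:
    """Per-stratum means and the lower-to-upper (S1→S3) change.

    The delta is reported in percentage points, ``100·(mean_S3 − mean_S1)``,
    the natural unit for quantum-yield fractions.
    """
    if stratum_col not in records.columns:
        records = records.assign(**{stratum_col: assign_stratum(
            records["height_m"].to_numpy())})
    means = records.groupby(stratum_col, observed=True)[variable].mean().to_dict()
    if "S1" not in means or "S3" not in means:
        raise ValueError("both S1 and S3 must be populated")
    return dict(means={k: float(v) for k, v in means.items()},
                delta_s1_to_s3_pp=float(100.0 * (means["S3"] - means["S1"])))
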