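"""Sweep co-signals in elevated windows: permutation tests and D/pi flags.

A hard selective sweep leaves a local excess of rare variants (negative
Tajima's D) and depressed diversity in the swept population.  Outlier
windows are therefore compared with an equal number of randomly chosen
neutral windows using a label-permutation test on the one-way ANOVA
F-statistic (the difference in means is reported alongside), and each
merged elevated region is flagged for a negative mean Tajima's D and for
below-median diversity in the saltmarsh (colonising) deme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PermutationTestResult", "permutation_compare", "cosignal_flags"]


@dataclass
class PermutationTestResult:
    """One permutation comparison of outlier vs neutral window values."""

    observed_f: float
    observed_diff: float  # mean(outliers) - mean(neutral subset)
    n_perm: int
    p_value: float
    null_f: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    outlier_mean: float = float("nan")
    neutral_mean: float = float("nan")
    seed: int = 0
    degenerate: bool = False
    reason: str | None = None


def _f_stat(x: np.ndarray, y: np.ndarray) -> float:
    """One-way ANOVA F for two groups (equals squared two-sample t with pooled var)."""
    nx, ny = len(x), len(y)
    gm = (x.sum() + y.sum()) / (nx + ny)
    ss_between = nx * (x.mean() - gm) ** 2 + ny * (y.mean() - gm) ** 2
    ss_within = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    df_b, df_w = 1, nx + ny - 2
    if ss_within == 0:
        return float("inf") if ss_between > 0 else float("nan")
    return float((ss_between / df_b) / (ss_within / df_w))


def permutation_compare(
    outlier_values,
    neutral_pool,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of outlier windows against matched neutral windows.

    A seeded random neutral subset of the same size as the outlier set is
    drawn from the pool, the observed one-way F-statistic computed, and the
    null built from ``n_perm`` label permutations of the combined groups.
    The p-value uses the add-one rule ``(1 + #{null >= obs}) / (1 + n_perm)``
    so it is never zero.  Identical constant values in both groups make F
    undefined; that case is reported as a no-test with a reason.
    """
    out = np.asarray(outlier_values, dtype=float)
    out = out[np.isfinite(out)]
    pool = np.asarray(neutral_pool, dtype=float)
    pool = pool[np.isfinite(pool)]
    if len(out) < 2:
        raise ValueError("need >= 2 outlier values")
    if len(pool) < 2 * len(out):
        raise ValueError(
            f"neutral pool ({len(pool)}) must be >= twice the outlier count ({len(out)})"
        )
    rng = np.random.default_rng(seed)
    neutral = rng.choice(pool, size=len(out), replace=False)
    f_obs = _f_stat(out, neutral)
    diff = float(out.mean() - neutral.mean())
    if not np.isfinite(f_obs):
        return PermutationTestResult(
            observed_f=float("nan"), observed_diff=diff, n_perm=n_perm,
            p_value=float("nan"), null_f=np.zeros(0),
            outlier_mean=float(out.mean()), neutral_mean=float(neutral.mean()),
            seed=seed, degenerate=True,
            reason="zero variance in both groups; F undefined",
        )
    combined = np.concatenate([out, neutral])
    k = len(out)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(combined)
        null[i] = _f_stat(perm[:k], perm[k:])
    p = (1 + int(np.sum(null >= f_obs))) / (1 + n_perm)
    return PermutationTestResult(
        observed_f=f_obs, observed_diff=diff, n_perm=n_perm, p_value=float(p),
        null_f=null, outlier_mean=float(out.mean()), neutral_mean=float(neutral.mean()),
        seed=seed,
    )


def cosignal_flags(
    regions: pd.DataFrame,
    windows: pd.DataFrame,
    deme: str | None = None,
) -> pd.DataFrame:
    """Flag merged regions for sweep co-signals in the chosen deme.

    ``negative_d``: mean Tajima's D over the region's windows is below zero
    (missing when every window's D is undefined, and such regions are
    excluded from co-signal percentages).  ``reduced_pi``: region mean pi is
    below the genome-wide median window pi.  The deme defaults to the
    second (saltmarsh/derived) deme recorded on the window table.
    """
    demes = windows.attrs.get("demes")
    if deme is None:
        if not demes:
            raise ValueError("deme not given and window table carries no deme labels")
        deme = demes[1]
    d_col, pi_col = f"tajima_d_{deme}", f"pi_{deme}"
    if d_col not in windows.columns:
        raise KeyError(f"window table has no column {d_col!r}")
    genome_median_pi = float(windows.loc[windows["eligible"], pi_col].median())
    out = regions.copy()
    neg_d, red_pi, mean_d, mean_pi = [], [], [], []
    for _, r in out.iterrows():
        in_r = (
            (windows["chrom"] == r["chrom"])
            & (windows["start"] >= r["start"])
            & (windows["end"] <= r["end"])
        )
        d_vals = windows.loc[in_r, d_col].dropna()
        pi_vals = windows.loc[in_r, pi_col].dropna()
        if len(d_vals) == 0:
            neg_d.append(None)
            mean_d.append(float("nan"))
        else:
            m = float(d_vals.mean())
            mean_d.append(m)
            neg_d.append(bool(m < 0))
        if len(pi_vals) == 0:
            red_pi.append(None)
            mean_pi.append(float("nan"))
        else:
            mp = float(pi_vals.mean())
            mean_pi.append(mp)
            red_pi.append(bool(mp < genome_median_pi))
    out["mean_tajima_d"] = mean_d
    out["mean_pi"] = mean_pi
    out["negative_d"] = neg_d
    out["reduced_pi"] = red_pi
    out.attrs["cosignal_deme"] = deme
    out.attrs["genome_median_pi"] = genome_median_pi
    return out
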