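"""Per-SNP Weir–Cockerham FST and windowed diversity statistics.

The per-site FST estimator is the Weir & Cockerham (1984) two-population
analysis-of-variance estimator, partitioning allele-frequency variance into
an among-population component ``a``, an among-individual-within-population
component ``b`` and a within-individual component ``c``; the per-site
estimate is ``a / (a + b + c)``.  This is the estimator VCFtools reports,
including its occasionally negative values, which are deliberately left
unclamped.

Window statistics are computed on fixed, non-overlapping 25 kb tiles laid
from coordinate 0 on each chromosome: the window *mean FST* is the
arithmetic mean of per-site estimates (a ratio-of-sums variant is available
as an option), nucleotide diversity uses the unbiased per-site
heterozygosity ``2*p*(1-p)*n/(n-1)`` summed over sites and divided by window
length, and Tajima's D follows the 1989 normalisation with the sample size
taken as the minimum number of called chromosomes across the window's
segregating sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_filters import MISSING, PopulationMap, VariantTable

__all__ = [
    "fst_components",
    "fst_site",
    "per_site_fst",
    "window_mean_fst",
    "window_pi",
    "window_tajima_d",
    "tajima_constants",
    "individual_heterozygosity",
    "compute_window_stats",
    "WINDOW_LENGTH",
]

WINDOW_LENGTH = 25_000


def _deme_summaries(g: np.ndarray):
    """Per-site (n called diploids, alt frequency, het frequency) for one deme."""
    g = np.atleast_2d(np.asarray(g))
    called = g != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, g, 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, (g == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
    return n, p, h


def fst_components(g1: np.ndarray, g2: np.ndarray):
    """Weir–Cockerham variance components per site for two demes.

    Parameters are ``(n_sites, n_diploids)`` dosage arrays (missing = -1).
    Returns ``(a, b, c)`` arrays; all three are NaN where the estimator is
    undefined (a deme with no called genotypes, or mean sample size <= 1).
    """
    n1, p1, h1 = _deme_summaries(g1)
    n2, p2, h2 = _deme_summaries(g2)
    r = 2.0
    nbar = (n1 + n2) / r
    ok = (n1 > 0) & (n2 > 0) & (nbar > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = ~ok | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def fst_site(g1, g2) -> float:
    """Per-site FST ``a/(a+b+c)`` for one site; NaN when undefined."""
    a, b, c = fst_components(np.atleast_2d(g1), np.atleast_2d(g2))
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, a / denom, np.nan)
    return float(out[0])


def per_site_fst(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Vector of per-site FST estimates; NaN where undefined or monomorphic."""
    a, b, c = fst_components(g1, g2)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, a / denom, np.nan)


def window_mean_fst(site_fst: np.ndarray, min_snps: int = 1, ratio_of_sums=None):
    """Arithmetic mean of defined per-site FST values in one window.

    Returns ``(mean, n_defined)``; mean is NaN when fewer than ``min_snps``
    sites have a defined estimate.  When ``ratio_of_sums`` is given as an
    ``(a, b, c)`` triple the Weir–Cockerham ratio-of-sums window estimate is
    returned instead of the mean of per-site ratios.
    """
    if ratio_of_sums is not None:
        a, b, c = ratio_of_sums
        keep = np.isfinite(a + b + c)
        n = int(keep.sum())
        if n < min_snps or (a + b + c)[keep].sum() == 0:
            return float("nan"), n
        return float(a[keep].sum() / (a + b + c)[keep].sum()), n
    vals = np.asarray(site_fst, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < min_snps:
        return float("nan"), len(vals)
    return float(vals.mean()), len(vals)


def _pairwise_terms(g: np.ndarray):
    """Per-site n_chrom, unbiased heterozygosity 2pq*n/(n-1), and segregating flag."""
    g = np.atleast_2d(np.asarray(g))
    called = g != MISSING
    nc = 2 * called.sum(axis=1).astype(float)
    alt = np.where(called, g, 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nc > 0, alt / np.maximum(nc, 1), 0.0)
        het = np.where(nc > 1, 2 * p * (1 - p) * nc / np.maximum(nc - 1, 1), 0.0)
    seg = (alt > 0) & (alt < nc)
    return nc, het, seg


def window_pi(genotypes: np.ndarray, window_length: int = WINDOW_LENGTH) -> float:
    """Nucleotide diversity per site for one deme over one window.

    Sum over sites of the unbiased expected heterozygosity, divided by the
    window length (monomorphic or absent sites contribute zero).
    """
    if genotypes is None or np.size(genotypes) == 0:
        return 0.0
    _, het, _ = _pairwise_terms(genotypes)
    return float(np.nansum(het) / window_length)


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalisation constants for ``n`` sampled chromosomes."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def window_tajima_d(genotypes: np.ndarray) -> float:
    """Tajima's D for one deme over one window of sites; NaN when S = 0.

    With missing data the constants use a single n: the minimum number of
    called chromosomes across the window's segregating sites.
    """
    if genotypes is None or np.size(genotypes) == 0:
        return float("nan")
    nc, het, seg = _pairwise_terms(genotypes)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    n = int(nc[seg].min())
    if n < 3:
        return float("nan")
    k_hat = float(het[seg].sum())
    const = tajima_constants(n)
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (k_hat - S / const["a1"]) / np.sqrt(var)


def individual_heterozygosity(vt: VariantTable) -> pd.Series:
    """Fraction of called sites that are heterozygous, per sample."""
    called = vt.genotypes != MISSING
    n_called = called.sum(axis=0)
    n_het = (vt.genotypes == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    return pd.Series(frac, index=vt.samples, name="heterozygosity")


@dataclass
class GenomicWindow:
    """One fixed tile with its divergence and diversity summaries."""

    chrom: str
    start: int
    end: int
    n_snps: int
    mean_fst: float
    pi: dict
    tajima_d: dict
    partial: bool
    eligible: bool
    elevated: bool = False


def compute_window_stats(
    vt: VariantTable,
    popmap: PopulationMap,
    window_length: int = WINDOW_LENGTH,
    min_snps: int = 5,
    chrom_lengths: dict | None = None,
    fst_mode: str = "mean_of_ratios",
) -> pd.DataFrame:
    """Windowed FST / pi / Tajima's D table over non-overlapping tiles.

    Windows tile each chromosome from coordinate 0.  A terminal window
    shorter than ``window_length`` is retained but flagged ``partial`` and,
    like windows with fewer than ``min_snps`` defined-FST sites, excluded
    from the genome-wide mean/SD via ``eligible = False``.  Returns a
    DataFrame with one row per window; per-deme columns are named
    ``pi_<deme>`` and ``tajima_d_<deme>``.  ``df.attrs['demes']`` records the
    deme labels.
    """
    d1, d2 = popmap.demes
    idx1 = vt.sample_indices(popmap.samples(d1))
    idx2 = vt.sample_indices(popmap.samples(d2))
    fst = per_site_fst(vt.genotypes[:, idx1], vt.genotypes[:, idx2])
    if fst_mode not in ("mean_of_ratios", "ratio_of_sums"):
        raise ValueError(f"unknown fst_mode {fst_mode!r}")
    comps = fst_components(vt.genotypes[:, idx1], vt.genotypes[:, idx2])

    rows = []
    for chrom in vt.chromosomes():
        on_c = vt.chrom == chrom
        pos = vt.pos[on_c]
        length = (chrom_lengths or {}).get(chrom, int(pos.max()) + 1 if len(pos) else 0)
        n_win = max(1, int(np.ceil(length / window_length)))
        g_c = vt.genotypes[on_c]
        fst_c = fst[on_c]
        comps_c = tuple(x[on_c] for x in comps)
        for w in range(n_win):
            start = w * window_length
            end = min(start + window_length, length)
            partial = (end - start) < window_length
            in_w = (pos >= start) & (pos < end)
            if fst_mode == "ratio_of_sums":
                mean_fst, n_def = window_mean_fst(
                    None, min_snps, ratio_of_sums=tuple(x[in_w] for x in comps_c)
                )
            else:
                mean_fst, n_def = window_mean_fst(fst_c[in_w], min_snps)
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_snps": n_def,
                "mean_fst": mean_fst,
                "partial": partial,
                "eligible": (n_def >= min_snps) and not partial,
            }
            for deme, idx in ((d1, idx1), (d2, idx2)):
                gw = g_c[np.ix_(in_w, idx)]
                row[f"pi_{deme}"] = window_pi(gw, end - start)
                row[f"tajima_d_{deme}"] = window_tajima_d(gw)
            rows.append(row)
    cols = ["chrom", "start", "end", "n_snps", "mean_fst",
            f"pi_{d1}", f"pi_{d2}", f"tajima_d_{d1}", f"tajima_d_{d2}",
            "partial", "eligible"]
    df = pd.DataFrame(rows, columns=cols)
    df["elevated"] = False
    df.attrs["demes"] = (d1, d2)
    df.attrs["window_length"] = window_length
    return df
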