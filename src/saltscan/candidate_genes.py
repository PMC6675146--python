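"""Candidate-gene assignment and shared-vs-lineage-specific classification.

Genes within 50 kb of a merged elevated region are its candidates (distance
is the gap between the intervals, zero on overlap, inclusive at exactly
50 kb).  Across several independent upland–saltmarsh pair comparisons, a
gene found near elevated regions in two or more pairs is a *shared*
(parallel-selection) candidate; a gene found in exactly one pair is
*lineage-specific*.  Matching is by gene identity in one shared annotation
namespace, so all pairs must be scanned against the same reference
annotation (a name-normalisation hook is provided for minor label drift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .io_filters import IntervalSet

__all__ = ["genes_near_regions", "CrossPairSummary", "classify_shared_specific"]


def genes_near_regions(
    regions: pd.DataFrame,
    annotations: IntervalSet,
    max_dist: int = 50_000,
) -> pd.DataFrame:
    """Attach genes within ``max_dist`` bp to each elevated region.

    Returns one row per (region, gene) with the gap distance (0 for
    overlap); regions without any nearby gene keep a single row with a null
    gene so unannotated regions stay reportable.  A region chromosome with
    no annotated feature at all triggers a warning.
    """
    ann_chroms = {r.chrom for r in annotations}
    missing = sorted(set(regions["chrom"]) - ann_chroms)
    if missing:
        warnings.warn(
            f"{len(missing)} region chromosome(s) absent from the annotation: "
            + ", ".join(missing[:5])
        )
    rows = []
    for ridx, r in regions.iterrows():
        chrom, start, end = r["chrom"], int(r["start"]), int(r["end"])
        hits = []
        # query widened by 1 bp so a gene whose gap is exactly max_dist is seen
        for g in annotations.overlapping(chrom, start - max_dist - 1, end + max_dist + 1):
            if g.start >= end:
                dist = g.start - end
            elif g.end <= start:
                dist = start - g.end
            else:
                dist = 0
            if dist <= max_dist:
                hits.append((g.name, dist))
        base = {k: r[k] for k in regions.columns}
        base["region_id"] = f"{chrom}:{start}-{end}"
        if hits:
            for name, dist in sorted(hits, key=lambda h: (h[1], str(h[0]))):
                rows.append({**base, "gene": name, "gene_distance": dist})
        else:
            rows.append({**base, "gene": None, "gene_distance": float("nan")})
    return pd.DataFrame(rows)


@dataclass
class CrossPairSummary:
    """Cross-pair classification of candidate genes.

    ``venn`` maps each non-empty subset of pair ids (as a frozenset) to the
    number of genes found in exactly that subset of pairs; cells sum to the
    total number of distinct candidate genes.
    """

    gene_pairs: dict
    shared_genes: list
    lineage_specific_genes: list
    venn: dict
    duplicates_collapsed: dict = field(default_factory=dict)

    @property
    def n_shared(self) -> int:
        return len(self.shared_genes)

    @property
    def n_lineage_specific(self) -> int:
        return len(self.lineage_specific_genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "pairs": ",".join(sorted(ps)),
                "n_pairs": len(ps),
                "classification": "shared" if len(ps) >= 2 else "lineage_specific",
            }
            for g, ps in sorted(self.gene_pairs.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "pairs", "n_pairs", "classification"])


def classify_shared_specific(
    per_pair_candidates: dict,
    normalize=None,
) -> CrossPairSummary:
    """Classify candidate genes as shared or lineage-specific across pairs.

    ``per_pair_candidates`` maps pair id to an iterable of gene ids (or a
    DataFrame from :func:`genes_near_regions`, whose non-null ``gene``
    column is used).  Duplicate genes within a pair are collapsed (counts
    logged); ``normalize`` optionally maps raw gene labels to a shared
    namespace.  Requires at least two pairs.
    """
    if len(per_pair_candidates) < 2:
        raise ValueError("cross-pair classification needs >= 2 pairs")
    sets, dups = {}, {}
    for pair, genes in per_pair_candidates.items():
        if isinstance(genes, pd.DataFrame):
            genes = genes["gene"].dropna().tolist()
        genes = [normalize(g) if normalize else g for g in genes]
        s = set(genes)
        dups[pair] = len(genes) - len(s)
        sets[pair] = s

    gene_pairs: dict = {}
    for pair, s in sets.items():
        for g in s:
            gene_pairs.setdefault(g, set()).add(pair)
    gene_pairs = {g: frozenset(ps) for g, ps in gene_pairs.items()}
    shared = sorted(g for g, ps in gene_pairs.items() if len(ps) >= 2)
    specific = sorted(g for g, ps in gene_pairs.items() if len(ps) == 1)

    pairs = sorted(sets)
    venn = {}
    for k in range(1, len(pairs) + 1):
        for subset in combinations(pairs, k):
            key = frozenset(subset)
            venn[key] = sum(1 for ps in gene_pairs.values() if ps == key)
    return CrossPairSummary(
        gene_pairs=gene_pairs,
        shared_genes=shared,
        lineage_specific_genes=specific,
        venn=venn,
        duplicates_collapsed=dups,
    )
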