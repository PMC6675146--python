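"""Variant and interval I/O plus the two variant-filter regimes.

Two distinct filter sets are applied to a genotyped SNP table:

* the *scan* set, used for windowed divergence statistics — biallelic sites
  with minor allele frequency >= 5%, mean coverage within [2, 50]X and at
  most 20% missing genotypes;
* the *SFS* set, used for demographic inference — biallelic sites with mean
  coverage strictly between 8X and 50X, genotyped in every individual, off
  the Z chromosome and more than 100 kb from any exon.  No frequency filter
  is applied, since rare variants carry most of the demographic signal.

Internal coordinates are 0-based half-open throughout; VCF (1-based) and
GFF3 (1-based inclusive) are converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

MISSING = -1

__all__ = [
    "MISSING",
    "VariantTable",
    "PopulationMap",
    "IntervalSet",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "read_intervals",
    "filter_variants_scan",
    "filter_variants_sfs",
]


@dataclass
class VariantTable:
    """Filtered biallelic SNP table with diploid alt-allele dosages.

    ``genotypes`` is an ``(n_sites, n_samples)`` int8 array of alt-allele
    dosages in {0, 1, 2} with :data:`MISSING` (-1) for uncalled genotypes.
    ``pos`` is 0-based; ``site_mean_depth`` is mean reads per sample (X).
    Multi-allelic records are retained at load time with
    ``is_biallelic = False`` so that filter stages can report how many they
    removed.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genotypes: np.ndarray
    site_mean_depth: np.ndarray
    samples: list[str]
    is_biallelic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = len(self.pos)
        if self.is_biallelic is None:
            self.is_biallelic = np.ones(n, dtype=bool)
        for name in ("chrom", "ref_allele", "alt_allele", "site_mean_depth", "is_biallelic"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch with pos")
        if self.genotypes.shape != (n, len(self.samples)):
            raise ValueError("genotypes shape does not match (n_sites, n_samples)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missingness(self) -> np.ndarray:
        """Fraction of missing genotypes per site."""
        if self.n_sites == 0:
            return np.zeros(0)
        return (self.genotypes == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per site over non-missing genotypes.

        Sites with zero called genotypes get MAF 0.
        """
        called = self.genotypes != MISSING
        n_chrom = 2 * called.sum(axis=1)
        alt = np.where(called, self.genotypes, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), 0.0)
        return np.minimum(p, 1.0 - p)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref_allele=self.ref_allele[mask],
            alt_allele=self.alt_allele[mask],
            genotypes=self.genotypes[mask],
            site_mean_depth=self.site_mean_depth[mask],
            samples=list(self.samples),
            is_biallelic=self.is_biallelic[mask],
        )

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)


class PopulationMap:
    """Mapping of sample id to deme label for exactly two demes.

    Deme order is first appearance in the mapping; downstream axis and
    column conventions (joint-SFS axes, per-deme window columns, the
    default co-signal deme) follow that order, so a popmap listing upland
    samples before saltmarsh samples yields upland on the first axis.
    """

    def __init__(self, mapping: dict[str, str]):
        demes = list(dict.fromkeys(mapping.values()))
        if len(demes) != 2:
            raise ValueError(f"exactly two demes required, got {demes}")
        for d in demes:
            n = sum(1 for v in mapping.values() if v == d)
            if n < 2:
                raise ValueError(f"deme {d!r} has {n} sample(s); need >= 2")
        self.mapping = dict(mapping)
        self.demes = tuple(demes)

    def samples(self, deme: str | None = None) -> list[str]:
        if deme is None:
            return list(self.mapping)
        return [s for s, d in self.mapping.items() if d == deme]

    def __contains__(self, sample: str) -> bool:
        return sample in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def read_popmap(path) -> PopulationMap:
    """Read a two-column TSV ``sample<TAB>deme``."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"popmap line not two tab-separated fields: {line!r}")
            mapping[parts[0]] = parts[1]
    return PopulationMap(mapping)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None


class IntervalSet:
    """Sorted set of 0-based half-open genomic intervals with distance queries."""

    def __init__(self, records):
        recs = []
        for r in records:
            if not isinstance(r, Interval):
                r = Interval(*r)
            if r.start >= r.end:
                raise ValueError(f"bad interval {r.chrom}:{r.start}-{r.end} (start >= end)")
            recs.append(r)
        self.records = sorted(recs, key=lambda r: (r.chrom, r.start, r.end))
        self._trees: dict[str, IntervalTree] = {}
        for r in self.records:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda r: (r.start, r.end))

    def distance(self, chrom: str, start: int, end: int) -> float:
        """Gap (bp) to the nearest interval on ``chrom``; 0 on overlap, inf if none.

        Distance between half-open [a,b) and [c,d) with b <= c is c - b
        (number of intervening bases).
        """
        tree = self._trees.get(chrom)
        if tree is None or len(tree) == 0:
            return float("inf")
        if tree.overlap(start, end):
            return 0.0
        best = float("inf")
        for iv in tree:
            if iv.end <= start:
                best = min(best, start - iv.end)
            elif iv.begin >= end:
                best = min(best, iv.begin - end)
        return best


def read_intervals(path, fmt: str, feature_type: str = "gene") -> IntervalSet:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) intervals.

    GFF3 records of ``feature_type`` are kept, carrying their ID/Name
    attribute so gene identity survives into candidate tables.
    """
    fmt = fmt.upper()
    if fmt == "BED":
        recs = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"BED line with <3 fields: {line!r}")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else None
                strand = parts[5] if len(parts) > 5 else None
                recs.append(Interval(chrom, start, end, name, strand))
        return IntervalSet(recs)
    if fmt == "GFF3":
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, merge_strategy="create_unique"
        )
        recs = []
        for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
            name = (feat.attributes.get("ID") or feat.attributes.get("Name") or [None])[0]
            recs.append(Interval(feat.seqid, feat.start - 1, feat.end, name, feat.strand))
        return IntervalSet(recs)
    raise ValueError(f"unknown interval format {fmt!r}")


def read_vcf(path, popmap: PopulationMap | None = None) -> VariantTable:
    """Load a VCF 4.x into a :class:`VariantTable`.

    Samples are restricted to the population map (order as in the VCF) when
    one is given; a popmap sample missing from the VCF header is an error
    naming that sample.  Multi-allelic records are kept but flagged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    if popmap is not None:
        missing = [s for s in popmap.samples() if s not in header_samples]
        if missing:
            raise KeyError(f"popmap sample(s) absent from VCF: {', '.join(missing)}")
        keep = [s for s in header_samples if s in popmap]
    else:
        keep = header_samples
    keep_idx = np.array([header_samples.index(s) for s in keep], dtype=int)

    chroms, poss, refs, alts, depth, biall, genos = [], [], [], [], [], [], []
    for i, v in enumerate(vcf):
        try:
            gt = np.asarray(v.genotype.array())[:, :2]
            dos = np.where((gt < 0).any(axis=1), MISSING, (gt > 0).sum(axis=1))
            dos = dos[keep_idx].astype(np.int8)
            dp = v.format("DP")
            if dp is not None:
                dp = np.asarray(dp, dtype=float).reshape(-1)[keep_idx]
                dp = dp[dp >= 0]
                mean_dp = float(dp.mean()) if dp.size else float("nan")
            else:  # pragma: no cover - DP-less VCFs
                info_dp = v.INFO.get("DP")
                mean_dp = float(info_dp) / len(keep) if info_dp is not None else float("nan")
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed VCF record #{i + 1} at {v.CHROM}:{v.POS}: {exc}") from exc
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
        biall.append(len(v.ALT) == 1 and len(v.REF) == 1 and all(len(a) == 1 for a in v.ALT))
        depth.append(mean_dp)
        genos.append(dos)

    vt = VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        genotypes=np.array(genos, dtype=np.int8).reshape(len(poss), len(keep)),
        site_mean_depth=np.array(depth, dtype=float),
        samples=keep,
        is_biallelic=np.array(biall, dtype=bool),
    )
    _check_sorted(vt)
    return vt


def _check_sorted(vt: VariantTable) -> None:
    for c in vt.chromosomes():
        p = vt.pos[vt.chrom == c]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not strictly increasing on {c}")


def write_vcf(vt: VariantTable, path, depth_as_int: bool = True) -> None:
    """Write a minimal VCF 4.2 (GT + per-sample DP) for downstream tools."""
    dose_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in vt.chromosomes():
            length = int(vt.pos[vt.chrom == c].max()) + 2
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            dp = vt.site_mean_depth[i]
            dp_str = str(int(round(dp))) if depth_as_int and np.isfinite(dp) else "."
            cells = [f"{dose_to_gt[int(d)]}:{dp_str}" for d in vt.genotypes[i]]
            fh.write(
                f"{vt.chrom[i]}\t{vt.pos[i] + 1}\t.\t{vt.ref_allele[i]}\t{vt.alt_allele[i]}"
                f"\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


def filter_variants_scan(
    vt: VariantTable,
    maf_min: float = 0.05,
    depth_min: float = 2.0,
    depth_max: float = 50.0,
    max_missing: float = 0.20,
) -> VariantTable:
    """Scan-set filter: biallelic, MAF >= 5%, depth in [2, 50]X, missingness <= 20%.

    Sites with MAF below 5% are removed; a site at exactly 5% is kept.
    Depth bounds are inclusive.  Order is preserved; output may be empty.
    """
    mask = (
        vt.is_biallelic
        & (vt.maf() >= maf_min)
        & (vt.site_mean_depth >= depth_min)
        & (vt.site_mean_depth <= depth_max)
        & (vt.missingness() <= max_missing)
    )
    return vt.subset(mask)


def filter_variants_sfs(
    vt: VariantTable,
    exons: IntervalSet | None = None,
    z_chroms=(),
    depth_min: float = 8.0,
    depth_max: float = 50.0,
    exon_buffer: int = 100_000,
) -> VariantTable:
    """SFS-set filter for demographic inference.

    Keeps biallelic sites with mean depth strictly inside (8, 50)X, called in
    every individual, off the listed Z scaffolds, and strictly more than
    100 kb from the nearest exon (a site exactly 100 kb away is excluded).
    No minor-allele-frequency filter: rare variants are kept.
    """
    z = set(z_chroms)
    mask = (
        vt.is_biallelic
        & (vt.site_mean_depth > depth_min)
        & (vt.site_mean_depth < depth_max)
        & (vt.missingness() == 0.0)
    )
    if z:
        mask &= np.array([c not in z for c in vt.chrom], dtype=bool)
    if exons is not None and len(exons):
        far = np.ones(vt.n_sites, dtype=bool)
        idx = np.nonzero(mask)[0]
        for i in idx:
            d = exons.distance(vt.chrom[i], int(vt.pos[i]), int(vt.pos[i]) + 1)
            far[i] = d > exon_buffer
        mask &= far
    return vt.subset(mask)
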