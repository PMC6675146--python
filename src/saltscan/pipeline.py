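"""End-to-end orchestration of the scan for one upland–saltmarsh pair.

A single structured config drives: variant filtering (scan and SFS sets),
windowed statistics, the mean+5SD cutoff with window classification and
region merging, demographic inference and neutral-null calibration, sweep
co-signal tests, and candidate-gene assignment.  Each stage writes its
output under the run directory, a resolved-config snapshot is saved, and
every stochastic stage takes its stream from the single config seed, so a
rerun with the same config is reproducible.  Cross-pair classification is a
separate step that consumes several pairs' candidate tables, mirroring the
per-pair variant-calling design of the study it implements.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .candidate_genes import classify_shared_specific, genes_near_regions
from .coalescent_sim import DemographicModel
from .io_filters import (
    filter_variants_scan,
    filter_variants_sfs,
    read_intervals,
    read_popmap,
    read_vcf,
)
from .outlier_scan import calibrate_null, classify_windows, empirical_cutoff
from .popgen_stats import compute_window_stats, individual_heterozygosity
from .sweep_cosignal import cosignal_flags, permutation_compare

log = logging.getLogger("saltscan")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "cross_pairs",
    "model_to_yaml",
    "model_from_yaml",
    "write_windows_tsv",
    "read_windows_tsv",
    "write_regions_bed",
]


@dataclass
class PipelineConfig:
    """Resolved settings for one pair's scan; defaults follow the study design."""

    vcf: str
    popmap: str
    outdir: str
    pair_id: str = "pair"
    exons: str | None = None
    genes: str | None = None
    z_chroms: list = field(default_factory=list)
    window_length: int = 25_000
    sd_multiplier: float = 5.0
    max_gene_dist: int = 50_000
    min_snps: int = 5
    seed: int = 0
    n_perm: int = 10_000
    # demographic stages (optional)
    run_demography: bool = False
    sfs_family: str = "split_migration"
    n_starts: int = 10
    n_boot: int = 0
    n_draws: int = 0
    calib_n_regions: int = 1072
    calib_region_length: int = 1_000_000
    calib_block_length: int = 25_000
    sweep_n_regions: int = 100
    sweep_region_length: int = 100_000

    def validate(self) -> None:
        for name in ("vcf", "popmap"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name in ("exons", "genes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.window_length <= 0 or self.min_snps < 1:
            raise ValueError("window_length must be positive and min_snps >= 1")
        if self.run_demography and self.exons is None:
            raise ValueError("demographic stages need an exon interval file")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_windows_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    demes = [c[3:] for c in df.columns if c.startswith("pi_")]
    df.attrs["demes"] = tuple(demes)
    return df


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\n")


def model_to_yaml(model: DemographicModel, path) -> None:
    data = {
        "N_anc": float(model.N_anc),
        "T_split": float(model.T_split),
        "epochs_upland": [[float(t), float(N)] for t, N in model.epochs_upland],
        "epochs_saltmarsh": [[float(t), float(N)] for t, N in model.epochs_saltmarsh],
        "m_up_to_salt": float(model.m_up_to_salt),
        "m_salt_to_up": float(model.m_salt_to_up),
        "mu": float(model.mu),
        "gen_time": float(model.gen_time),
        "recomb": float(model.recomb),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def model_from_yaml(path) -> DemographicModel:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["epochs_upland"] = [tuple(e) for e in data.get("epochs_upland", [])]
    data["epochs_saltmarsh"] = [tuple(e) for e in data.get("epochs_saltmarsh", [])]
    return DemographicModel(**data)


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Run filter → stats → cutoff/classify → co-signal → genes for one pair.

    Returns a summary dict (also written as ``summary.json``); each stage's
    table lands in the output directory.  With ``dry_run`` the config is
    validated and nothing is computed.
    """
    config.validate()
    if dry_run:
        return {"dry_run": True, "pair_id": config.pair_id}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({**dataclasses.asdict(config), "saltscan_version": __version__}, fh)

    popmap = read_popmap(config.popmap)
    vt = read_vcf(config.vcf, popmap)
    log.info("loaded %d sites, %d samples", vt.n_sites, vt.n_samples)
    summary: dict = {"pair_id": config.pair_id, "n_sites_loaded": vt.n_sites}

    vt_scan = filter_variants_scan(vt)
    summary["n_sites_scan"] = vt_scan.n_sites
    het = individual_heterozygosity(vt_scan)
    het.to_csv(outdir / "heterozygosity.tsv", sep="\t")

    windows = compute_window_stats(
        vt_scan, popmap, config.window_length, config.min_snps
    )
    cutoff = empirical_cutoff(windows, config.sd_multiplier)
    windows, regions = classify_windows(windows, cutoff)
    write_windows_tsv(windows, outdir / "windows.tsv")
    write_regions_bed(regions, outdir / "regions.bed")
    summary.update(
        empirical_cutoff=cutoff,
        n_windows=len(windows),
        n_eligible_windows=int(windows["eligible"].sum()),
        n_elevated_windows=int(windows["elevated"].sum()),
        n_regions=len(regions),
    )

    # sweep co-signals
    salt = windows.attrs["demes"][1]
    elev = windows["elevated"]
    neutral = windows["eligible"] & ~elev
    perm_summary = {}
    for stat in (f"tajima_d_{salt}", f"pi_{salt}"):
        out_vals = windows.loc[elev, stat].dropna().to_numpy()
        pool = windows.loc[neutral, stat].dropna().to_numpy()
        if len(out_vals) >= 2 and len(pool) >= 2 * len(out_vals):
            res = permutation_compare(out_vals, pool, config.n_perm, config.seed)
            perm_summary[stat] = {
                "F": res.observed_f, "p": res.p_value,
                "outlier_mean": res.outlier_mean, "neutral_mean": res.neutral_mean,
            }
        else:
            perm_summary[stat] = {"skipped": "too few elevated or neutral windows"}
    summary["permutation_tests"] = perm_summary
    if len(regions):
        regions = cosignal_flags(regions, windows)
        flagged = regions["negative_d"].dropna()
        summary["frac_regions_negative_d"] = (
            float(flagged.mean()) if len(flagged) else float("nan")
        )

    # demographic stages
    if config.run_demography:
        from .outlier_scan import uncertainty_sweep
        from .sfs_inference import (
            bootstrap_parameter_cis, build_joint_sfs, fit_model, save_sfs,
        )

        exons = read_intervals(config.exons, "BED")
        vt_sfs = filter_variants_sfs(vt, exons, config.z_chroms)
        summary["n_sites_sfs"] = vt_sfs.n_sites
        sfs = build_joint_sfs(vt_sfs, popmap)  # folded without an outgroup
        save_sfs(sfs, outdir / "joint_sfs.txt")
        fit = fit_model(sfs, config.sfs_family, n_starts=config.n_starts,
                        seed=config.seed)
        summary["sfs_fit"] = {"family": fit.family, "loglik": fit.loglik,
                              "aic": fit.aic, "theta": fit.theta_hat,
                              "params": fit.params}
        L = _sfs_sequence_length(vt)
        model = fit.to_demographic_model(mu=3.3e-9, L=L)
        model_to_yaml(model, outdir / "fitted_model.yaml")
        n1d = len(popmap.samples(popmap.demes[0]))
        n2d = len(popmap.samples(popmap.demes[1]))
        calib = calibrate_null(
            model, n1d, n2d, config.calib_n_regions, config.calib_region_length,
            config.calib_block_length, config.window_length, config.min_snps,
            config.sd_multiplier, config.seed, empirical_cutoff_value=cutoff,
        )
        summary["calibration"] = {"sim_cutoff": calib.sim_cutoff,
                                  "verdicts": calib.verdicts,
                                  "summaries": calib.summaries}
        if config.n_boot:
            cis, _ = bootstrap_parameter_cis(
                vt_sfs, popmap, config.sfs_family, n_boot=config.n_boot,
                seed=config.seed, point_fit=fit,
            )
            summary["bootstrap_cis"] = {k: list(v) for k, v in cis.items()}
            if config.n_draws:
                bounds = _natural_bounds(fit, cis, L)
                sweep = uncertainty_sweep(
                    model, bounds, config.n_draws, n1d, n2d,
                    config.sweep_n_regions, config.sweep_region_length,
                    config.calib_block_length, config.seed,
                    empirical_cutoff_value=cutoff,
                )
                summary["uncertainty_sweep"] = {
                    "p99_of_p95": sweep.summaries["p99_of_p95"]["value"],
                    "p99_of_p99": sweep.summaries["p99_of_p99"]["value"],
                    "verdicts": sweep.verdicts,
                }

    # candidate genes
    if config.genes is not None and len(regions):
        annotations = read_intervals(config.genes, "GFF3")
        candidates = genes_near_regions(regions, annotations, config.max_gene_dist)
        candidates.insert(0, "pair_id", config.pair_id)
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False, na_rep="NA")
        summary["n_candidate_genes"] = int(candidates["gene"].notna().sum())
        summary["n_unannotated_regions"] = int(
            candidates.loc[candidates["gene"].isna(), "region_id"].nunique()
        )
    elif config.genes is None:
        log.info("no gene annotation given; candidate stages skipped")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _sfs_sequence_length(vt) -> float:
    """Callable length proxy behind the SFS: spanned bp across chromosomes."""
    total = 0
    for c in vt.chromosomes():
        p = vt.pos[vt.chrom == c]
        total += int(p.max()) - int(p.min()) + 1
    return float(max(total, 1))


def _natural_bounds(fit, cis: dict, L: float) -> dict:
    """Translate scaled-parameter CIs into natural-unit bounds for the sweep."""
    from .sfs_inference import convert_units

    lo = convert_units(cis.get("theta", (fit.theta_hat, fit.theta_hat))[0],
                       3.3e-9, L, 1.0, {k: v[0] for k, v in cis.items() if k != "theta"})
    hi = convert_units(cis.get("theta", (fit.theta_hat, fit.theta_hat))[1],
                       3.3e-9, L, 1.0, {k: v[1] for k, v in cis.items() if k != "theta"})
    bounds = {}
    if "N_1" in lo:
        bounds["N_upland_0"] = (min(lo["N_1"], hi["N_1"]), max(lo["N_1"], hi["N_1"]))
    if "N_2" in lo:
        bounds["N_saltmarsh_0"] = (min(lo["N_2"], hi["N_2"]), max(lo["N_2"], hi["N_2"]))
    if "T_generations" in lo:
        bounds["T_split"] = (min(lo["T_generations"], hi["T_generations"]),
                             max(lo["T_generations"], hi["T_generations"]))
    for key, out in (("m", "m_up_to_salt"),):
        if key in lo:
            bounds[out] = (min(lo[key], hi[key]), max(lo[key], hi[key]))
            bounds["m_salt_to_up"] = bounds[out]
    return bounds


def cross_pairs(candidate_tsvs: dict, out_path=None):
    """Combine per-pair candidate tables into the cross-pair classification.

    ``candidate_tsvs`` maps pair id to a candidates TSV path (or DataFrame).
    Writes the gene-by-pair table when ``out_path`` is given and returns the
    :class:`~saltscan.candidate_genes.CrossPairSummary`.
    """
    per_pair = {}
    for pair, src in candidate_tsvs.items():
        df = src if isinstance(src, pd.DataFrame) else pd.read_csv(src, sep="\t")
        per_pair[pair] = df["gene"].dropna().tolist()
    summary = classify_shared_specific(per_pair)
    if out_path is not None:
        summary.to_frame().to_csv(out_path, sep="\t", index=False)
    return summary
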