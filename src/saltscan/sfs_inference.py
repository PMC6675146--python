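"""Joint-SFS construction and demographic inference by composite likelihood.

The observed joint site-frequency spectrum is an ``(n1+1) x (n2+1)`` count
matrix over derived-allele (polarized, via an outgroup) or minor-allele
(folded) frequency classes for the two demes, with the invariant corners
masked.  Model fitting maximises a Poisson composite log-likelihood: the
expected spectrum per unit theta comes from Monte-Carlo branch-length
averaging over simulated genealogies (common random numbers make the
objective deterministic per fit), theta has its analytic Poisson MLE
``sum(obs)/sum(exp)``, and the remaining scaled parameters are optimised by
Nelder–Mead from several multiplicatively perturbed starts.  Composite
likelihoods treat linked sites as independent, so AIC values are reported
for ranking only and parameter uncertainty comes from a nonparametric
chromosome bootstrap (resampling chromosomes with replacement, rebuilding
the spectrum, refitting).

Scaled parameterisation (reference size ``N_ref`` = ancestral size):
``nu*`` are deme sizes relative to ``N_ref``, ``T`` is the split time in
units of ``2*N_ref`` generations, and ``M`` is ``2*N_ref*m`` with ``m`` the
per-generation immigrant proportion.  ``convert_units`` maps a fitted theta
to natural units via ``theta = 4*N_ref*mu*L``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .coalescent_sim import DemographicModel, branch_length_sfs
from .io_filters import PopulationMap, VariantTable

__all__ = [
    "JointSFS",
    "ModelFamily",
    "FAMILIES",
    "build_joint_sfs",
    "fold_matrix",
    "expected_joint_sfs",
    "poisson_composite_loglik",
    "projection_weights",
    "project_matrix",
    "FitResult",
    "fit_model",
    "bootstrap_parameter_cis",
    "convert_units",
    "save_sfs",
    "load_sfs",
]


@dataclass
class JointSFS:
    """Two-population SFS count matrix with corner masking."""

    counts: np.ndarray
    folded: bool
    n_dropped_outgroup: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def mask(self) -> np.ndarray:
        """True for masked cells (invariant corners; above-fold cells when folded)."""
        m = np.zeros_like(self.counts, dtype=bool)
        m[0, 0] = True
        m[self.n1, self.n2] = True
        if self.folded:
            i = np.arange(self.n1 + 1)[:, None]
            j = np.arange(self.n2 + 1)[None, :]
            m |= (i + j) > (self.n1 + self.n2) / 2
        return m

    @property
    def n_sites_retained(self) -> float:
        return float(self.counts[~self.mask].sum())

    def fold(self) -> "JointSFS":
        if self.folded:
            return self
        return JointSFS(fold_matrix(self.counts), folded=True,
                        n_dropped_outgroup=self.n_dropped_outgroup)


def fold_matrix(mat: np.ndarray) -> np.ndarray:
    """Fold a polarized joint spectrum onto minor-allele classes.

    Cells with total count above half the chromosomes are added to their
    complements; cells exactly at half share the pair's mass equally (so a
    self-complementary cell keeps its value).  Above-fold cells are zeroed.
    """
    mat = np.asarray(mat, dtype=float)
    n1, n2 = mat.shape[0] - 1, mat.shape[1] - 1
    half = (n1 + n2) / 2
    out = np.zeros_like(mat)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            tot = i + j
            if tot < half:
                out[i, j] = mat[i, j] + mat[n1 - i, n2 - j]
            elif tot == half:
                out[i, j] = 0.5 * (mat[i, j] + mat[n1 - i, n2 - j])
    return out


def build_joint_sfs(
    vt: VariantTable,
    popmap: PopulationMap,
    outgroup_alleles: dict | None = None,
    alt_is_derived: bool = False,
) -> JointSFS:
    """Tally the joint SFS from a complete-cases variant table.

    Polarization: with ``outgroup_alleles`` (``(chrom, pos0) -> base``) the
    outgroup base is taken as ancestral; sites where it matches neither
    allele, or is absent, are dropped and counted in
    ``n_dropped_outgroup``.  ``alt_is_derived`` polarizes without lookup
    (simulated data).  With neither, the folded spectrum is built.
    """
    if np.any(vt.genotypes < 0):
        raise ValueError("SFS construction requires complete cases (no missing genotypes)")
    d1, d2 = popmap.demes
    idx1 = vt.sample_indices(popmap.samples(d1))
    idx2 = vt.sample_indices(popmap.samples(d2))
    n1, n2 = 2 * len(idx1), 2 * len(idx2)
    alt1 = vt.genotypes[:, idx1].sum(axis=1)
    alt2 = vt.genotypes[:, idx2].sum(axis=1)

    counts = np.zeros((n1 + 1, n2 + 1))
    dropped = 0
    if alt_is_derived:
        np.add.at(counts, (alt1, alt2), 1.0)
        folded = False
    elif outgroup_alleles is not None:
        for k in range(vt.n_sites):
            anc = outgroup_alleles.get((vt.chrom[k], int(vt.pos[k])))
            if anc == vt.ref_allele[k]:
                counts[alt1[k], alt2[k]] += 1
            elif anc == vt.alt_allele[k]:
                counts[n1 - alt1[k], n2 - alt2[k]] += 1
            else:
                dropped += 1
        folded = False
        if dropped:
            warnings.warn(f"{dropped} site(s) dropped: outgroup allele missing or triallelic")
    else:
        half = (n1 + n2) / 2
        for a1, a2 in zip(alt1, alt2):
            tot = a1 + a2
            if tot < half:
                counts[a1, a2] += 1
            elif tot > half:
                counts[n1 - a1, n2 - a2] += 1
            else:
                counts[a1, a2] += 0.5
                counts[n1 - a1, n2 - a2] += 0.5
        folded = True
    sfs = JointSFS(counts, folded=folded, n_dropped_outgroup=dropped)
    sfs.counts[sfs.mask] = 0.0
    return sfs


# ---------------------------------------------------------------------------
# model families (scaled parameters)

@dataclass(frozen=True)
class ModelFamily:
    """A named set of free scaled parameters defining an IM-model variant."""

    name: str
    param_names: tuple
    default_start: dict
    bounds: dict  # param -> (low, high), positive

    def build(self, params: dict, N_ref: float = 10_000.0) -> DemographicModel:
        p = dict(params)
        T_gens = p["T"] * 2 * N_ref
        m12 = p.get("M", p.get("M12", 0.0)) / (2 * N_ref)   # upland -> saltmarsh
        m21 = p.get("M", p.get("M21", 0.0)) / (2 * N_ref)
        eps_salt = [(0.0, p["nu2"] * N_ref)]
        if "nuB" in p:
            # bottleneck occupies the older half of the post-split period
            eps_salt = [(0.0, p["nu2"] * N_ref), (0.5 * T_gens, p["nuB"] * N_ref)]
        return DemographicModel(
            N_anc=N_ref,
            T_split=T_gens,
            epochs_upland=[(0.0, p["nu1"] * N_ref)],
            epochs_saltmarsh=eps_salt,
            m_up_to_salt=m12,
            m_salt_to_up=m21,
        )


FAMILIES = {
    f.name: f
    for f in [
        ModelFamily(
            "split_no_migration", ("nu1", "nu2", "T"),
            {"nu1": 1.0, "nu2": 1.0, "T": 0.2},
            {"nu1": (1e-3, 100), "nu2": (1e-3, 100), "T": (1e-3, 10)},
        ),
        ModelFamily(
            "split_migration", ("nu1", "nu2", "T", "M"),
            {"nu1": 1.0, "nu2": 1.0, "T": 0.2, "M": 1.0},
            {"nu1": (1e-3, 100), "nu2": (1e-3, 100), "T": (1e-3, 10), "M": (1e-3, 50)},
        ),
        ModelFamily(
            "split_asym_migration", ("nu1", "nu2", "T", "M12", "M21"),
            {"nu1": 1.0, "nu2": 1.0, "T": 0.2, "M12": 1.0, "M21": 1.0},
            {"nu1": (1e-3, 100), "nu2": (1e-3, 100), "T": (1e-3, 10),
             "M12": (1e-3, 50), "M21": (1e-3, 50)},
        ),
        ModelFamily(
            "split_bottleneck_migration", ("nu1", "nu2", "nuB", "T", "M"),
            {"nu1": 1.0, "nu2": 1.0, "nuB": 0.1, "T": 0.2, "M": 1.0},
            {"nu1": (1e-3, 100), "nu2": (1e-3, 100), "nuB": (1e-4, 100),
             "T": (1e-3, 10), "M": (1e-3, 50)},
        ),
    ]
}


def expected_joint_sfs(
    family: ModelFamily | str,
    params: dict,
    n1: int,
    n2: int,
    n_genealogies: int = 400,
    seed: int = 0,
    N_ref: float = 10_000.0,
) -> np.ndarray:
    """Monte-Carlo expected joint SFS per unit theta (``theta = 4*N_ref*mu*L``).

    Branch generations per frequency class are averaged over
    ``n_genealogies`` simulated genealogies and divided by ``4*N_ref``, so
    the model prediction for the count matrix is ``theta * expected``.
    """
    if isinstance(family, str):
        family = FAMILIES[family]
    model = family.build(params, N_ref)
    rng = np.random.default_rng(seed)
    T = branch_length_sfs(model, n1, n2, n_genealogies, rng)
    return T / (4.0 * N_ref)


def projection_weights(n: int, m: int) -> np.ndarray:
    """Hypergeometric down-projection matrix from n to m chromosomes."""
    if m > n:
        raise ValueError("cannot project up")
    from scipy.special import comb

    i = np.arange(n + 1)[None, :]
    ip = np.arange(m + 1)[:, None]
    return comb(i, ip) * comb(n - i, m - ip) / comb(n, m)


def project_matrix(mat: np.ndarray, m1: int, m2: int) -> np.ndarray:
    """Project a joint spectrum down to (m1+1) x (m2+1) frequency classes.

    Standard hypergeometric subsampling; besides matching sample sizes it
    smooths sparse spectra, which is what makes the Monte-Carlo composite
    likelihood surface tractable for optimisation.
    """
    mat = np.asarray(mat, dtype=float)
    n1, n2 = mat.shape[0] - 1, mat.shape[1] - 1
    return projection_weights(n1, m1) @ mat @ projection_weights(n2, m2).T


def poisson_composite_loglik(
    observed: JointSFS,
    expected: np.ndarray,
    theta: float | None = None,
    eps_frac: float = 1e-8,
    expected_is_folded: bool = False,
):
    """Poisson composite log-likelihood of an observed spectrum.

    ``expected`` is the per-unit-theta matrix (folded automatically when the
    observed spectrum is folded, unless already folded by the caller).  With
    ``theta=None`` the analytic MLE ``sum(obs)/sum(exp)`` over unmasked
    cells is used.  Zero expected cells facing nonzero observations are
    floored at ``eps_frac`` of total expected mass.  Returns
    ``(loglik, theta_used)``.
    """
    exp = np.asarray(expected, dtype=float)
    if observed.folded and not expected_is_folded:
        exp = fold_matrix(exp)
    if exp.shape != observed.counts.shape:
        raise ValueError("expected matrix shape does not match observed spectrum")
    keep = ~observed.mask
    obs = observed.counts[keep]
    exp = exp[keep].copy()
    floor = eps_frac * exp.sum()
    bad = (exp <= 0) & (obs > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} expected cell(s) floored at {floor:.3g}")
        exp[bad] = floor
    use = (exp > 0) | (obs > 0)
    obs, exp = obs[use], exp[use]
    if theta is None:
        theta = float(obs.sum() / exp.sum())
    lam = theta * exp
    ll = float(np.sum(obs * np.log(lam) - lam - gammaln(obs + 1)))
    return ll, theta


@dataclass
class FitResult:
    """Best fit across optimisation starts, with per-start records."""

    family: str
    params: dict
    theta_hat: float
    loglik: float
    aic: float
    n1: int
    n2: int
    starts: list = field(default_factory=list)
    seed: int = 0
    n_genealogies: int = 400

    def expected(self, seed=None, n_genealogies=None) -> np.ndarray:
        return self.theta_hat * expected_joint_sfs(
            self.family, self.params, self.n1, self.n2,
            n_genealogies or self.n_genealogies,
            self.seed if seed is None else seed,
        )

    def to_demographic_model(self, mu: float, L: float, gen_time: float = 1.0,
                             time_scale: str = "2N") -> DemographicModel:
        nat = convert_units(self.theta_hat, mu, L, gen_time, self.params,
                            time_scale=time_scale)
        fam = FAMILIES[self.family]
        m = fam.build(self.params, N_ref=nat["N_ref"])
        return DemographicModel(
            N_anc=m.N_anc, T_split=m.T_split,
            epochs_upland=m.epochs_upland, epochs_saltmarsh=m.epochs_saltmarsh,
            m_up_to_salt=m.m_up_to_salt, m_salt_to_up=m.m_salt_to_up,
            mu=mu, gen_time=gen_time,
        )


def _fit_transforms(observed: JointSFS, project):
    """Projected observed spectrum and the matching expected-matrix transform."""
    if project is None:
        obs = observed
        def tf(e):
            return fold_matrix(e) if observed.folded else e
    else:
        m1, m2 = project
        if observed.folded:
            obs = JointSFS(fold_matrix(project_matrix(observed.counts, m1, m2)),
                           folded=True)
            def tf(e):
                return fold_matrix(project_matrix(fold_matrix(e), m1, m2))
        else:
            obs = JointSFS(project_matrix(observed.counts, m1, m2), folded=False)
            def tf(e):
                return project_matrix(e, m1, m2)
        obs.counts[obs.mask] = 0.0
    return obs, tf


def fit_model(
    observed: JointSFS,
    family: ModelFamily | str,
    n_starts: int = 10,
    perturb_fold: float = 2.0,
    seed: int = 0,
    start_params: dict | None = None,
    n_genealogies: int = 3000,
    maxiter: int = 150,
    project: tuple | None = None,
    simplex_spreads: tuple = (0.5, 0.2),
    polish: tuple | None = None,
    mc_seed: int | None = None,
) -> FitResult:
    """Maximise the Poisson composite likelihood over a model family.

    Each start perturbs the starting point multiplicatively by
    ``exp(U(-ln f, +ln f))`` per parameter and runs two Nelder–Mead rounds
    in log-parameter space with a wide initial simplex (the restart guards
    against premature contraction on the residually noisy surface); the
    Monte-Carlo expected spectrum uses a fixed seed (common random numbers)
    so the objective is deterministic within a fit.  ``project=(m1, m2)``
    fits on the down-projected spectrum, which smooths sparse cells and is
    recommended whenever the sample exceeds ~8 chromosomes per deme.  The
    best start by log-likelihood wins; every start's result is kept.
    """
    if isinstance(family, str):
        family = FAMILIES[family]
    rng = np.random.default_rng(seed)
    if mc_seed is None:
        mc_seed = int(rng.integers(2**31 - 1))
    base = dict(family.default_start)
    if start_params:
        base.update(start_params)
    names = family.param_names
    lo = np.log([family.bounds[p][0] for p in names])
    hi = np.log([family.bounds[p][1] for p in names])
    obs_t, transform = _fit_transforms(observed, project)

    def make_objective(ng):
        def objective(x):
            if np.any(x < lo) or np.any(x > hi):
                return 1e12
            params = {p: float(np.exp(v)) for p, v in zip(names, x)}
            exp = expected_joint_sfs(family, params, observed.n1, observed.n2,
                                     ng, mc_seed)
            ll, _ = poisson_composite_loglik(obs_t, transform(exp),
                                             expected_is_folded=True)
            return -ll
        return objective

    objective = make_objective(n_genealogies)

    starts = []
    x0_base = np.log([base[p] for p in names])
    k = len(names)
    for s in range(n_starts):
        if s == 0 and start_params is not None:
            x0 = x0_base.copy()
        else:
            x0 = x0_base + rng.uniform(-np.log(perturb_fold), np.log(perturb_fold), k)
        x0 = np.clip(x0, lo, hi)
        for spread in simplex_spreads:
            # simplex centred on x0 so truncated runs are not pushed one-sided
            simplex = np.vstack([x0] + [x0 + spread * np.eye(k)[i] for i in range(k)])
            simplex -= spread / (k + 1)
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 1e-4,
                                    "fatol": 1e-8, "initial_simplex": simplex})
            x0 = np.clip(res.x, lo, hi)
        params = {p: float(np.exp(v)) for p, v in zip(names, x0)}
        exp = expected_joint_sfs(family, params, observed.n1, observed.n2,
                                 n_genealogies, mc_seed)
        ll, theta = poisson_composite_loglik(obs_t, transform(exp),
                                             expected_is_folded=True)
        starts.append({"params": params, "loglik": ll, "theta": theta,
                       "converged": bool(res.success), "n_eval": int(res.nfev)})
    best = max(starts, key=lambda s: s["loglik"])
    if polish is not None:
        # final refinement with a larger Monte-Carlo sample to damp the
        # residual surface noise along flat likelihood ridges
        ng_pol, maxiter_pol = polish
        obj_pol = make_objective(ng_pol)
        x0 = np.log([best["params"][p] for p in names])
        simplex = np.vstack([x0] + [x0 + 0.1 * np.eye(k)[i] for i in range(k)])
        simplex -= 0.1 / (k + 1)
        res = minimize(obj_pol, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter_pol, "xatol": 1e-4,
                                "fatol": 1e-8, "initial_simplex": simplex})
        x1 = np.clip(res.x, lo, hi)
        params = {p: float(np.exp(v)) for p, v in zip(names, x1)}
        exp = expected_joint_sfs(family, params, observed.n1, observed.n2,
                                 ng_pol, mc_seed)
        ll, theta = poisson_composite_loglik(obs_t, transform(exp),
                                             expected_is_folded=True)
        best = {"params": params, "loglik": ll, "theta": theta,
                "converged": bool(res.success), "n_eval": int(res.nfev)}
        starts.append(best)
    k = len(names) + 1  # + theta
    return FitResult(
        family=family.name, params=best["params"], theta_hat=best["theta"],
        loglik=best["loglik"], aic=2 * k - 2 * best["loglik"],
        n1=observed.n1, n2=observed.n2, starts=starts,
        seed=mc_seed, n_genealogies=n_genealogies,
    )


def bootstrap_parameter_cis(
    vt_sfs: VariantTable,
    popmap: PopulationMap,
    family: ModelFamily | str,
    n_boot: int = 100,
    seed: int = 0,
    point_fit: FitResult | None = None,
    outgroup_alleles: dict | None = None,
    alt_is_derived: bool = False,
    fit_kwargs: dict | None = None,
    project: tuple | None = None,
):
    """Chromosome-bootstrap 95% CIs for the scaled parameters and theta.

    Chromosomes (distinct ``chrom`` labels) are resampled with replacement
    to the original count, the spectrum rebuilt and the model refit (one
    start from the point estimate unless overridden).  Replicates whose
    refit fails are dropped with a warning; more than 20% failures is an
    error.  Returns ``(ci_dict, replicate_records)`` with
    ``ci_dict[param] = (2.5th, 97.5th percentile)``.
    """
    chroms = vt_sfs.chromosomes()
    if len(chroms) < 2:
        raise ValueError("chromosome bootstrap needs >= 2 chromosomes")
    if isinstance(family, str):
        family = FAMILIES[family]
    fk = dict(n_starts=1, n_genealogies=1500, maxiter=80, project=project,
              simplex_spreads=(0.15, 0.05))
    if point_fit is not None:
        # common random numbers: sharing the point fit's Monte-Carlo stream
        # cancels surface noise between replicates, so the bootstrap spread
        # reflects data resampling rather than simulation jitter
        fk["mc_seed"] = point_fit.seed
    fk.update(fit_kwargs or {})
    start = point_fit.params if point_fit is not None else None
    rng = np.random.default_rng(seed)
    records, failures = [], 0
    for b in range(n_boot):
        pick = rng.choice(len(chroms), size=len(chroms), replace=True)
        masks = [vt_sfs.chrom == chroms[i] for i in pick]
        parts = [vt_sfs.subset(m) for m in masks]
        vt_b = _concat_tables(parts)
        try:
            sfs = build_joint_sfs(vt_b, popmap, outgroup_alleles=outgroup_alleles,
                                  alt_is_derived=alt_is_derived)
            fit = fit_model(sfs, family, seed=int(rng.integers(2**31 - 1)),
                            start_params=start, **fk)
            rec = dict(fit.params)
            rec["theta"] = fit.theta_hat
            rec["loglik"] = fit.loglik
            records.append(rec)
        except Exception as exc:  # noqa: BLE001
            failures += 1
            warnings.warn(f"bootstrap replicate {b} failed: {exc}")
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap replicates failed")
    cis = {}
    for p in list(family.param_names) + ["theta"]:
        vals = np.array([r[p] for r in records])
        cis[p] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return cis, records


def _concat_tables(parts):
    """Concatenate variant tables that share a sample panel.

    Resampled chromosomes keep their original labels suffixed with the draw
    index so positions stay strictly increasing per label.
    """
    first = parts[0]
    chroms, poss, refs, alts, genos, dps, bia = [], [], [], [], [], [], []
    for k, p in enumerate(parts):
        chroms.append(np.array([f"{c}|b{k}" for c in p.chrom], dtype=object))
        poss.append(p.pos)
        refs.append(p.ref_allele)
        alts.append(p.alt_allele)
        genos.append(p.genotypes)
        dps.append(p.site_mean_depth)
        bia.append(p.is_biallelic)
    return VariantTable(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        ref_allele=np.concatenate(refs),
        alt_allele=np.concatenate(alts),
        genotypes=np.vstack(genos),
        site_mean_depth=np.concatenate(dps),
        samples=list(first.samples),
        is_biallelic=np.concatenate(bia),
    )


def convert_units(
    theta_hat: float,
    mu: float,
    L: float,
    gen_time: float,
    scaled_params: dict,
    time_scale: str = "2N",
) -> dict:
    """Map a fitted theta and scaled parameters into natural units.

    ``theta = 4 * N_ref * mu_per_gen * L`` gives the reference diploid size;
    sizes scale as ``nu * N_ref``; times convert from units of ``2*N_ref``
    generations (the package-wide convention, configurable via
    ``time_scale`` in {'2N', 'N'}) to years; migration proportions are
    ``M / (2 * N_ref)``.
    """
    if L <= 0:
        raise ValueError("sequence length L must be positive")
    mu_gen = mu * gen_time
    N_ref = theta_hat / (4.0 * mu_gen * L)
    scale = 2.0 if time_scale == "2N" else 1.0
    out = {"N_ref": N_ref, "theta": theta_hat, "time_scale": time_scale}
    for k, v in scaled_params.items():
        if k.startswith("nu"):
            out[f"N_{k[2:] or 'ref'}"] = v * N_ref
        elif k == "T" or k.startswith("T"):
            out[f"{k}_generations"] = v * scale * N_ref
            out[f"{k}_years"] = v * scale * N_ref * gen_time
        elif k.startswith("M"):
            out[f"m{k[1:]}"] = v / (2.0 * N_ref)
    return out


def save_sfs(sfs: JointSFS, path) -> None:
    """Serialise a spectrum as plain text: one header line, then matrix rows."""
    with open(path, "w") as fh:
        fh.write(f"# n1={sfs.n1} n2={sfs.n2} folded={int(sfs.folded)} "
                 f"dropped_outgroup={sfs.n_dropped_outgroup} "
                 f"masked=corners{'+above_fold' if sfs.folded else ''}\n")
        for row in sfs.counts:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def load_sfs(path) -> JointSFS:
    with open(path) as fh:
        header = fh.readline()
        fields = dict(kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv)
        counts = np.loadtxt(fh)
    sfs = JointSFS(np.atleast_2d(counts), folded=bool(int(fields.get("folded", 0))),
                   n_dropped_outgroup=int(fields.get("dropped_outgroup", 0)))
    if sfs.n1 != int(fields["n1"]) or sfs.n2 != int(fields["n2"]):
        raise ValueError("SFS header dimensions disagree with matrix shape")
    return sfs
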