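"""Generative models for genotype-dependent covariance.

The core generator draws, per individual with minor-allele count g in
{0, 1, 2}, a bivariate-normal trait pair with

    means      (m1 + b1*g,  m2 + b2*g)
    covariance [[s1^2 + v1*g,  b*g      ],
                [b*g,          s2^2 + v2*g]]

so b is the per-genotype covariance slope (the correlation-QTL effect), b1/b2
are eQTL-like mean effects and v1/v2 varQTL-like variance effects.  Non-genetic
confounders mirror the genotype effects but are driven by an independent
Binomial(2, 1/2) variable, so mean and variance shifts of the same magnitude
can occur without any genotype association.  A negative-binomial variant maps
the latent gaussian pair through a copula for count data, and
:func:`simulate_cohort` assembles full synthetic datasets (traits, genotypes,
covariates, strata, ground-truth manifest) for pipeline recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CilpError,
    CovariateTable,
    GenotypeMatrix,
    StratumLabels,
    TraitMatrix,
)

__all__ = [
    "ScenarioConfig",
    "simulate_genotypes",
    "simulate_pair",
    "simulate_pair_batch",
    "simulate_count_pair",
    "CohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
]

_GENOTYPES = np.array([0.0, 1.0, 2.0])


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulated gene pair scenario.

    Defaults correspond to the baseline study conditions: n = 1000
    individuals, minor-allele frequency 0.5, standard-normal baseline
    expression, and a correlation-QTL covariance slope of 0.3.  Confounder
    effect sizes mirror the genotype effect sizes used throughout the power
    grid (mean effect 1, variance effect 10).
    """

    n: int = 1000
    maf: float = 0.5
    m1: float = 0.0
    m2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    v1: float = 0.0
    v2: float = 0.0
    sigma1_sq: float = 1.0
    sigma2_sq: float = 1.0
    b: float = 0.3
    mean_confound1: float = 0.0
    mean_confound2: float = 0.0
    var_confound1: float = 0.0
    var_confound2: float = 0.0
    transcriptome_confound: float = 0.0
    distribution: Literal["gaussian", "negative_binomial"] = "gaussian"
    nb_mean1: float = 100.0
    nb_mean2: float = 100.0
    nb_dispersion1: float = 5.0
    nb_dispersion2: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise CilpError(f"maf must lie in (0, 0.5], got {self.maf}")
        if self.n < 1:
            raise CilpError(f"n must be >= 1, got {self.n}")
        if self.sigma1_sq <= 0 or self.sigma2_sq <= 0:
            raise CilpError("baseline variances must be positive")
        if self.distribution not in ("gaussian", "negative_binomial"):
            raise CilpError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "negative_binomial":
            if self.nb_mean1 <= 0 or self.nb_mean2 <= 0:
                raise CilpError("negative-binomial means must be positive")
            if self.nb_dispersion1 <= 0 or self.nb_dispersion2 <= 0:
                raise CilpError("negative-binomial dispersions must be positive")
        self.check_psd()

    def check_psd(self) -> None:
        """Every genotype/confounder cell must yield a valid covariance."""
        conf = _GENOTYPES if (self.var_confound1 or self.var_confound2) else np.array([0.0])
        for g in _GENOTYPES:
            for c in conf:
                var1 = self.sigma1_sq + self.v1 * g + self.var_confound1 * c
                var2 = self.sigma2_sq + self.v2 * g + self.var_confound2 * c
                if var1 <= 0 or var2 <= 0:
                    raise CilpError(
                        f"non-positive variance at genotype {g:g}, confounder {c:g}"
                    )
                if abs(self.b * g) > np.sqrt(var1 * var2) + 1e-12:
                    raise CilpError(
                        f"covariance {self.b * g:g} exceeds bound at genotype {g:g} "
                        "(matrix not positive semi-definite)"
                    )

    def with_(self, **kwargs) -> "ScenarioConfig":
        params = asdict(self)
        params.update(kwargs)
        return ScenarioConfig(**params)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(n: int, maf: float, seed) -> np.ndarray:
    """Minor-allele counts for one biallelic locus under Hardy-Weinberg
    equilibrium: Binomial(2, maf) per individual."""
    if not 0.0 < maf <= 0.5:
        raise CilpError(f"maf must lie in (0, 0.5], got {maf}")
    if n < 1:
        raise CilpError(f"n must be >= 1, got {n}")
    return _rng(seed).binomial(2, maf, size=n).astype(float)


def _pair_moments(config: ScenarioConfig, g: np.ndarray, c: np.ndarray):
    var1 = config.sigma1_sq + config.v1 * g + config.var_confound1 * c
    var2 = config.sigma2_sq + config.v2 * g + config.var_confound2 * c
    cov = config.b * g
    mu1 = config.m1 + config.b1 * g + config.mean_confound1 * c
    mu2 = config.m2 + config.b2 * g + config.mean_confound2 * c
    if (var1 <= 0).any() or (var2 <= 0).any():
        raise CilpError("non-positive conditional variance encountered")
    rho = cov / np.sqrt(var1 * var2)
    if (np.abs(rho) > 1 + 1e-12).any():
        raise CilpError("covariance matrix not positive semi-definite for some genotype")
    return mu1, mu2, var1, var2, np.clip(rho, -1.0, 1.0)


def simulate_pair(
    config: ScenarioConfig, genotypes: np.ndarray, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one trait pair given per-individual genotypes.

    Uses the conditional construction y2 | y1: with z1, z2 iid standard
    normal, y1 = mu1 + sd1*z1 and y2 = mu2 + sd2*(rho*z1 + sqrt(1-rho^2)*z2),
    which realizes the target covariance exactly per genotype class.
    """
    rng = _rng(seed)
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    needs_conf = any(
        (config.mean_confound1, config.mean_confound2,
         config.var_confound1, config.var_confound2)
    )
    c = rng.binomial(2, 0.5, size=n).astype(float) if needs_conf else np.zeros(n)
    mu1, mu2, var1, var2, rho = _pair_moments(config, g, c)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    y1 = mu1 + np.sqrt(var1) * z1
    y2 = mu2 + np.sqrt(var2) * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    if config.transcriptome_confound:
        # latent factor loading on both traits for a random half of samples
        half = rng.permutation(n) < n // 2
        f = rng.standard_normal(n)
        y1 = y1 + config.transcriptome_confound * f * half
        y2 = y2 + config.transcriptome_confound * f * half
    return y1, y2


def simulate_pair_batch(
    config: ScenarioConfig, n_pairs: int, seed
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized batch of independent gene pairs, each with fresh genotypes.

    Returns (G, Y1, Y2), all of shape (n, n_pairs).  Statistically identical
    to calling :func:`simulate_genotypes` + :func:`simulate_pair` per pair,
    but orders of magnitude faster for power grids.
    """
    rng = _rng(seed)
    n = config.n
    G = rng.binomial(2, config.maf, size=(n, n_pairs)).astype(float)
    needs_conf = any(
        (config.mean_confound1, config.mean_confound2,
         config.var_confound1, config.var_confound2)
    )
    C = (
        rng.binomial(2, 0.5, size=(n, n_pairs)).astype(float)
        if needs_conf
        else np.zeros((n, n_pairs))
    )
    mu1, mu2, var1, var2, rho = _pair_moments(config, G, C)
    Z1 = rng.standard_normal((n, n_pairs))
    Z2 = rng.standard_normal((n, n_pairs))
    Y1 = mu1 + np.sqrt(var1) * Z1
    Y2 = mu2 + np.sqrt(var2) * (rho * Z1 + np.sqrt(1.0 - rho**2) * Z2)
    if config.transcriptome_confound:
        half = (rng.permutation(n) < n // 2)[:, None]
        f = rng.standard_normal((n, 1))
        Y1 = Y1 + config.transcriptome_confound * f * half
        Y2 = Y2 + config.transcriptome_confound * f * half
    return G, Y1, Y2


def simulate_count_pair(
    config: ScenarioConfig, genotypes: np.ndarray, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated negative-binomial counts via a gaussian copula.

    A latent gaussian pair is drawn under the scenario's covariance model,
    standardized per individual by its conditional moments, mapped through the
    normal CDF to uniforms, and through each margin's negative-binomial
    quantile function.  Rank correlation by genotype class is preserved while
    the count margins stay fixed at (mean, dispersion) per gene.
    """
    if config.distribution != "negative_binomial":
        raise CilpError("config.distribution must be 'negative_binomial'")
    rng = _rng(seed)
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    c = np.zeros(n)
    mu1, mu2, var1, var2, rho = _pair_moments(config, g, c)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    l1 = z1
    l2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    u1 = stats.norm.cdf(l1)
    u2 = stats.norm.cdf(l2)

    def nb_ppf(u, mean, disp):
        p = disp / (disp + mean)
        return stats.nbinom.ppf(u, disp, p)

    y1 = nb_ppf(u1, config.nb_mean1, config.nb_dispersion1)
    y2 = nb_ppf(u2, config.nb_mean2, config.nb_dispersion2)
    return y1, y2


# ---------------------------------------------------------------------------
# Synthetic cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Description of a full synthetic cohort with planted effects.

    Defaults define the package's reference decoherence fixture: 200 traits,
    50 planted loss-of-correlation pairs (correlation 0.6 in the healthy
    group, 0.2 in the disease group), 500 individuals per group, one time
    point.  Set ``n_timepoints > 1`` for repeated measures with an
    individual-level random intercept; set ``n_snps``/``n_planted_qtls`` for
    correlation-QTL cohorts.
    """

    n_per_group: int = 500
    n_traits: int = 200
    n_planted_pairs: int = 50
    rho_healthy: float = 0.6
    rho_disease: float = 0.2
    background_rho: float = 0.0
    # alternative planting mode: a factor-driven block of traits that is
    # mutually correlated (rho_healthy) in health and decoheres (rho_disease)
    # in disease; every within-block pair is a planted pair
    decoherent_block_size: int = 0
    n_timepoints: int = 1
    random_intercept_sd: float = 0.5
    n_categories: int = 5
    planted_category_fraction: float = 0.0
    # genetics
    n_snps: int = 0
    n_planted_qtls: int = 0
    qtl_b: float = 0.3
    qtl_maf: float = 0.5
    n_chromosomes: int = 4
    # prospective design: fraction of healthy-at-baseline individuals who will
    # convert to disease, with baseline shift on planted traits
    future_case_fraction: float = 0.0
    future_case_shift: float = 0.5
    # covariates
    age_effect: float = 0.0
    sex_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.n_traits < 2:
            raise CilpError("need at least 2 traits")
        if self.decoherent_block_size:
            if not 2 <= self.decoherent_block_size <= self.n_traits:
                raise CilpError("decoherent_block_size must be in [2, n_traits]")
            if self.n_planted_pairs or self.n_planted_qtls:
                raise CilpError(
                    "block mode and pair/QTL planting are mutually exclusive"
                )
        if 2 * self.n_planted_pairs > self.n_traits:
            raise CilpError(
                f"cannot plant {self.n_planted_pairs} disjoint pairs among "
                f"{self.n_traits} traits"
            )
        if self.n_planted_qtls > min(self.n_snps, self.n_planted_pairs) and self.n_planted_qtls:
            raise CilpError("n_planted_qtls exceeds available SNPs or pairs")
        for r in (self.rho_healthy, self.rho_disease, self.background_rho):
            if not -1.0 < r < 1.0:
                raise CilpError(f"correlation {r} outside (-1, 1)")


@dataclass
class SyntheticCohort:
    """A simulated dataset plus the ground truth used to generate it."""

    traits: TraitMatrix
    covariates: CovariateTable
    strata: StratumLabels
    status: pd.Series
    genotypes: GenotypeMatrix | None
    annotations: pd.Series
    manifest: dict = field(default_factory=dict)

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2, sort_keys=True)


def _correlated_noise(rng, n, rho):
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, rho * z1 + np.sqrt(1 - rho**2) * z2


def simulate_cohort(spec: CohortSpec, seed) -> SyntheticCohort:
    """Generate a cohort with planted decoherent pairs and/or correlation QTLs.

    Trait pairs are planted on disjoint trait sets so each planted pair's
    correlation structure is independent of the others; remaining traits are
    independent noise (or exchange a weak ``background_rho``).  The manifest
    records every planted effect for recovery tests.
    """
    rng = _rng(seed)
    n_ind = 2 * spec.n_per_group
    individuals = [f"ind{i:05d}" for i in range(n_ind)]
    status = np.array([0] * spec.n_per_group + [1] * spec.n_per_group)
    perm = rng.permutation(n_ind)
    status = status[perm]
    status_s = pd.Series(status, index=individuals, name="status")

    # prospective conversions: healthy at baseline, diseased at follow-up
    future_case = np.zeros(n_ind, dtype=bool)
    if spec.future_case_fraction > 0:
        healthy_idx = np.flatnonzero(status == 0)
        n_conv = int(round(spec.future_case_fraction * healthy_idx.size))
        future_case[rng.choice(healthy_idx, size=n_conv, replace=False)] = True

    age = rng.normal(40.0, 10.0, n_ind)
    sex = rng.binomial(1, 0.5, n_ind)

    trait_ids = [f"trait{j:04d}" for j in range(spec.n_traits)]
    order = rng.permutation(spec.n_traits)
    if spec.decoherent_block_size:
        block_pos = sorted(order[: spec.decoherent_block_size])
        planted_trait_pos = set(block_pos)
        planted_pairs = [
            tuple(sorted((trait_ids[i], trait_ids[j])))
            for a, i in enumerate(block_pos)
            for j in block_pos[a + 1 :]
        ]
    else:
        block_pos = []
        planted_pairs = [
            tuple(sorted((trait_ids[order[2 * k]], trait_ids[order[2 * k + 1]])))
            for k in range(spec.n_planted_pairs)
        ]
        planted_trait_pos = {order[i] for i in range(2 * spec.n_planted_pairs)}

    # genotypes and planted correlation QTLs
    genotypes = None
    planted_qtls: list[dict] = []
    G = None
    if spec.n_snps:
        snp_ids = [f"snp{j:05d}" for j in range(spec.n_snps)]
        mafs = rng.uniform(0.1, 0.5, spec.n_snps)
        qtl_snp_pos = rng.choice(spec.n_snps, size=spec.n_planted_qtls, replace=False)
        mafs[qtl_snp_pos] = spec.qtl_maf
        G = rng.binomial(2, mafs, size=(n_ind, spec.n_snps)).astype(float)
        chrom = rng.integers(1, spec.n_chromosomes + 1, spec.n_snps)
        pos = rng.integers(1, 2_000_000_00, spec.n_snps)
        positions = pd.DataFrame(
            {"chrom": [f"chr{c}" for c in chrom], "pos": pos}, index=snp_ids
        )
        genotypes = GenotypeMatrix(
            pd.DataFrame(G, index=individuals, columns=snp_ids), positions
        )
        for k, sj in enumerate(qtl_snp_pos):
            planted_qtls.append(
                {"snp": snp_ids[sj], "pair": list(planted_pairs[k]), "b": spec.qtl_b}
            )

    n_rows = n_ind * spec.n_timepoints
    if spec.n_timepoints == 1:
        sample_ids = list(individuals)
    else:
        sample_ids = [
            f"{ind}_t{t}" for t in range(spec.n_timepoints) for ind in individuals
        ]
    ind_of_row = np.tile(np.arange(n_ind), spec.n_timepoints)
    time_of_row = np.repeat(np.arange(spec.n_timepoints), n_ind)

    values = np.empty((n_rows, spec.n_traits))
    # individual-level random intercepts induce within-individual dependence
    intercepts = (
        rng.normal(0.0, spec.random_intercept_sd, (n_ind, spec.n_traits))
        if spec.n_timepoints > 1
        else np.zeros((n_ind, spec.n_traits))
    )

    qtl_by_pair = {tuple(q["pair"]): q for q in planted_qtls}

    for t in range(spec.n_timepoints):
        rows = slice(t * n_ind, (t + 1) * n_ind)
        block = np.empty((n_ind, spec.n_traits))
        # independent background traits
        free = [j for j in range(spec.n_traits) if j not in planted_trait_pos]
        block[:, free] = rng.standard_normal((n_ind, len(free)))
        if spec.background_rho:
            shared = rng.standard_normal((n_ind, 1))
            r = spec.background_rho
            block[:, free] = np.sqrt(1 - r) * block[:, free] + np.sqrt(r) * shared
        if spec.decoherent_block_size:
            # shared factor with group-dependent loading: within-block pairwise
            # correlation is rho_healthy in health, rho_disease in disease
            f = rng.standard_normal(n_ind)
            rho = np.where(status == 0, spec.rho_healthy, spec.rho_disease)
            for j in block_pos:
                e = rng.standard_normal(n_ind)
                block[:, j] = np.sqrt(rho) * f + np.sqrt(1 - rho) * e
        else:
            for k, (a, b_id) in enumerate(planted_pairs):
                ja, jb = trait_ids.index(a), trait_ids.index(b_id)
                q = qtl_by_pair.get((a, b_id))
                if q is not None and G is not None:
                    g = G[:, genotypes.snp_ids.index(q["snp"])]
                    rho = np.clip(spec.qtl_b * g, -0.99, 0.99)
                else:
                    rho = np.where(status == 0, spec.rho_healthy, spec.rho_disease)
                z1 = rng.standard_normal(n_ind)
                z2 = rng.standard_normal(n_ind)
                block[:, ja] = z1
                block[:, jb] = rho * z1 + np.sqrt(1 - rho**2) * z2
        block += intercepts
        block += spec.age_effect * ((age[:, None] - 40.0) / 10.0)
        block += spec.sex_effect * sex[:, None]
        if spec.future_case_fraction > 0 and t == 0:
            shift_cols = sorted(planted_trait_pos)
            block[np.ix_(future_case, shift_cols)] += spec.future_case_shift
        values[rows] = block

    traits = TraitMatrix(
        pd.DataFrame(values, index=sample_ids, columns=trait_ids)
    )
    fixed = pd.DataFrame(
        {"age": age[ind_of_row], "sex": sex[ind_of_row].astype(float)},
        index=sample_ids,
    )
    if spec.n_timepoints > 1:
        fixed["year"] = time_of_row.astype(float)
    covariates = CovariateTable(
        fixed,
        categorical=("year",) if spec.n_timepoints > 1 else (),
        random_group=pd.Series(
            [individuals[i] for i in ind_of_row], index=sample_ids, name="individual"
        ),
    )
    status_rows = pd.Series(status[ind_of_row], index=sample_ids, name="status")
    strata = StratumLabels.combine(
        pd.Series(time_of_row, index=sample_ids).map(lambda t: f"year{t}"),
        status_rows.map(lambda s: "healthy" if s == 0 else "disease"),
    )

    categories = [f"class{(j % spec.n_categories) + 1}" for j in range(spec.n_traits)]
    if spec.planted_category_fraction > 0:
        # concentrate planted-pair traits into the first category
        planted_positions = sorted(planted_trait_pos)
        n_focus = int(round(spec.planted_category_fraction * len(planted_positions)))
        for j in planted_positions[:n_focus]:
            categories[j] = "class1"
    annotations = pd.Series(categories, index=trait_ids, name="category")

    manifest = {
        "spec": asdict(spec),
        "planted_pairs": [list(p) for p in planted_pairs],
        "planted_qtls": planted_qtls,
        "planted_traits": sorted(trait_ids[j] for j in planted_trait_pos),
        "direction": "loss_in_disease"
        if spec.rho_healthy > spec.rho_disease
        else "gain_in_disease",
        "n_individuals": n_ind,
        "n_rows": n_rows,
        "future_cases": [individuals[i] for i in np.flatnonzero(future_case)],
    }
    assert len({frozenset(p) for p in planted_pairs}) == len(planted_pairs)

    cohort = SyntheticCohort(
        traits=traits,
        covariates=covariates,
        strata=strata,
        status=status_rows,
        genotypes=genotypes,
        annotations=annotations,
        manifest=manifest,
    )
    return cohort
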