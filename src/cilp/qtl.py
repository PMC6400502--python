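"""Correlation-QTL mapping: genotype QC, fast product~SNP scans, annotation.

The scan uses the scalable product construction (covariates residualized out
of expression once, residuals rescaled, products formed) and a vectorized
ordinary-least-squares path over the SNP x pair grid that matches per-test
naive OLS exactly via Frisch-Waugh partialling.  Companion routines classify
hits as cis/trans, test whether a hit is also a mean (eQTL) or variance
(varQTL) locus, and measure replication concordance across cohorts.
"""

from __future__ import annotations

import warnings as _pywarnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .containers import (
    CilpError,
    CovariateTable,
    DegenerateInputError,
    GenotypeMatrix,
    ProductMatrix,
    TraitMatrix,
)
from .core import bh_fdr

__all__ = [
    "SnpQcReport",
    "CorrelationQtl",
    "hwe_test",
    "snp_qc",
    "ld_prune",
    "select_top_features",
    "scan_correlation_qtl",
    "classify_location",
    "test_eqtl",
    "test_varqtl",
    "replication_concordance",
]


@dataclass
class SnpQcReport:
    snp_id: str
    maf: float
    hom_minor_fraction: float
    hwe_p: float
    pruned_by_ld: bool = False
    ld_partner: str | None = None
    ld_r2: float = np.nan
    passed: bool = False


@dataclass
class CorrelationQtl:
    snp_id: str
    pair: tuple[str, str]
    beta: float
    se: float
    stat: float
    p: float
    q: float = np.nan
    location_class: str = "unclassified"
    eqtl_p: dict = field(default_factory=dict)
    varqtl_p: dict = field(default_factory=dict)


def hwe_test(n0: int, n1: int, n2: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg
    genotype frequencies computed from the observed allele frequency.

    Monomorphic SNPs return p = 1 by convention.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise CilpError("need at least one genotyped individual")
    p_alt = (2 * n2 + n1) / (2 * n)
    if p_alt in (0.0, 1.0):
        return 1.0
    exp = np.array(
        [n * (1 - p_alt) ** 2, n * 2 * p_alt * (1 - p_alt), n * p_alt**2]
    )
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _dosage_stats(g: np.ndarray) -> tuple[float, float, float]:
    obs = g[~np.isnan(g)]
    n = obs.size
    counts = [int((obs == k).sum()) for k in (0, 1, 2)]
    p_alt = (2 * counts[2] + counts[1]) / (2 * n) if n else np.nan
    maf = min(p_alt, 1 - p_alt)
    hom_minor = counts[2] / n if p_alt <= 0.5 else counts[0] / n
    return maf, hom_minor, hwe_test(*counts)


def snp_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    hom_minor_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    ld_window_bp: int = 50_000,
    ld_r2_max: float = 0.5,
    prune_ld: bool = True,
) -> list[SnpQcReport]:
    """Apply the standard marker filters: MAF, homozygous-minor fraction,
    Hardy-Weinberg equilibrium, and positional LD pruning."""
    reports: dict[str, SnpQcReport] = {}
    G = genotypes.data
    for snp in genotypes.snp_ids:
        maf, hom_minor, hwe_p = _dosage_stats(G[snp].to_numpy())
        reports[snp] = SnpQcReport(snp, maf, hom_minor, hwe_p)
    marginal_pass = {
        s: (r.maf > maf_min and r.hom_minor_fraction > hom_minor_min and r.hwe_p > hwe_p_min)
        for s, r in reports.items()
    }
    if prune_ld:
        candidates = [s for s in genotypes.snp_ids if marginal_pass[s]]
        sub = GenotypeMatrix(
            genotypes.data[candidates],
            genotypes.positions.loc[candidates] if genotypes.positions is not None else None,
        )
        kept, prune_info = ld_prune(sub, window_bp=ld_window_bp, r2_max=ld_r2_max)
        for snp, (partner, r2) in prune_info.items():
            reports[snp].pruned_by_ld = True
            reports[snp].ld_partner = partner
            reports[snp].ld_r2 = r2
    for s, r in reports.items():
        r.passed = marginal_pass[s] and not r.pruned_by_ld
    return list(reports.values())


def ld_prune(
    genotypes: GenotypeMatrix, window_bp: int = 50_000, r2_max: float = 0.5
) -> tuple[list[str], dict[str, tuple[str, float]]]:
    """Greedy left-to-right LD pruning per chromosome.

    Walking SNPs in position order, a SNP is dropped when its squared Pearson
    dosage correlation with an already-kept SNP within ``window_bp`` (1-based
    positions, half-open window) reaches ``r2_max``.  Returns the kept SNP ids
    and, for each dropped SNP, the kept partner and r-squared that removed it.
    """
    if genotypes.positions is None:
        raise CilpError("LD pruning requires SNP positions")
    pos = genotypes.positions
    kept: list[str] = []
    pruned: dict[str, tuple[str, float]] = {}
    G = genotypes.data
    for chrom, snps in pos.groupby("chrom", sort=True):
        snps = snps.sort_values("pos")
        kept_chr: list[tuple[str, int, np.ndarray]] = []
        for snp_id, row in snps.iterrows():
            g = G[snp_id].to_numpy()
            dropped = False
            for other_id, other_pos, other_g in reversed(kept_chr):
                if row["pos"] - other_pos >= window_bp:
                    break
                ok = ~(np.isnan(g) | np.isnan(other_g))
                if ok.sum() < 3 or g[ok].std() == 0 or other_g[ok].std() == 0:
                    continue
                r2 = float(np.corrcoef(g[ok], other_g[ok])[0, 1] ** 2)
                if r2 >= r2_max:
                    pruned[str(snp_id)] = (str(other_id), r2)
                    dropped = True
                    break
            if not dropped:
                kept_chr.append((str(snp_id), int(row["pos"]), g))
                kept.append(str(snp_id))
    return kept, pruned


def select_top_features(
    traits: TraitMatrix,
    target,
    covariates: CovariateTable | None = None,
    k: int = 300,
    gene_map: pd.Series | None = None,
) -> list[str]:
    """Rank traits by the p-value of trait ~ target (+ covariates) and return
    the top-k unique features.

    When ``gene_map`` maps probe ids to parent gene ids, the best probe per
    gene is kept and k counts unique genes (the returned list still holds
    probe ids).
    """
    if k < 1:
        raise CilpError("k must be >= 1")
    y = pd.Series(np.asarray(target, dtype=float), index=traits.data.index)
    if covariates is not None:
        X = covariates.design_matrix().reindex(traits.data.index).to_numpy(dtype=float)
    else:
        X = np.ones((traits.n_samples, 1))
    Xfull = np.column_stack([X, y.to_numpy()])
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise DegenerateInputError("degenerate design in feature selection")
    XtX_i = np.linalg.inv(Xfull.T @ Xfull)
    vals = traits.data.to_numpy()
    pvals = np.empty(traits.n_traits)
    complete = ~np.isnan(vals).any(axis=0)
    df = traits.n_samples - Xfull.shape[1]
    if complete.any():
        B = XtX_i @ (Xfull.T @ vals[:, complete])
        resid = vals[:, complete] - Xfull @ B
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(sigma2 * XtX_i[-1, -1])
        pvals[complete] = 2 * stats.t.sf(np.abs(B[-1] / se), df)
    for j in np.flatnonzero(~complete):
        yj = vals[:, j]
        ok = ~np.isnan(yj)
        Xs = Xfull[ok]
        XtX_is = np.linalg.inv(Xs.T @ Xs)
        beta = XtX_is @ (Xs.T @ yj[ok])
        resid = yj[ok] - Xs @ beta
        dfs = ok.sum() - Xs.shape[1]
        se = np.sqrt(resid @ resid / dfs * XtX_is[-1, -1])
        pvals[j] = 2 * stats.t.sf(abs(beta[-1] / se), dfs)
    order = np.argsort(pvals, kind="stable")
    ranked = [traits.trait_ids[j] for j in order]
    if gene_map is None:
        return ranked[:k]
    selected: list[str] = []
    seen_genes: set = set()
    for probe in ranked:
        gene = gene_map.get(probe, probe)
        if gene in seen_genes:
            continue
        seen_genes.add(gene)
        selected.append(probe)
        if len(seen_genes) == k:
            break
    return selected


def scan_correlation_qtl(
    products: ProductMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable | None = None,
) -> list[CorrelationQtl]:
    """Vectorized additive-dosage scan of every SNP against every product.

    Covariates (plus intercept) are projected out of both the products and
    the dosages once; per (SNP, pair) the partialled regression then yields
    the same coefficient, Wald t statistic and p-value as a naive OLS of
    product ~ dosage + covariates (Frisch-Waugh).  Missing dosages are
    mean-imputed per SNP.  BH q-values are computed over the full grid.
    """
    samples = products.data.index
    G = genotypes.data.reindex(samples)
    if G.isna().all(axis=0).any():
        bad = list(G.columns[G.isna().all(axis=0)])
        raise CilpError(f"SNPs with no genotyped samples after alignment: {bad[:5]}")
    Gv = G.to_numpy(dtype=float)
    col_mean = np.nanmean(Gv, axis=0)
    nan_mask = np.isnan(Gv)
    if nan_mask.any():
        Gv[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    P = products.values
    if np.isnan(P).any():
        raise CilpError("products contain missing values; fast scan needs complete data")
    n = P.shape[0]
    if covariates is not None:
        X = covariates.design_matrix().reindex(samples).to_numpy(dtype=float)
    else:
        X = np.ones((n, 1))
    k = X.shape[1]
    Q, _ = np.linalg.qr(X)
    P_r = P - Q @ (Q.T @ P)
    G_r = Gv - Q @ (Q.T @ Gv)
    gss = (G_r**2).sum(axis=0)
    if (gss <= 1e-12).any():
        bad = list(G.columns[gss <= 1e-12])
        raise DegenerateInputError(f"constant dosage after covariate adjustment: {bad[:5]}")
    df = n - k - 1
    # beta[s, p] for every SNP x pair
    cross = G_r.T @ P_r
    beta = cross / gss[:, None]
    pss = (P_r**2).sum(axis=0)
    rss = pss[None, :] - beta * cross
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gss[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    qvals = bh_fdr(pvals.ravel()).reshape(pvals.shape)
    results = []
    snp_ids = list(G.columns)
    for si, snp in enumerate(snp_ids):
        for pi, pair in enumerate(products.pair_index):
            results.append(
                CorrelationQtl(
                    snp_id=snp,
                    pair=pair,
                    beta=float(beta[si, pi]),
                    se=float(se[si, pi]),
                    stat=float(tvals[si, pi]),
                    p=float(pvals[si, pi]),
                    q=float(qvals[si, pi]),
                )
            )
    return results


def classify_location(
    qtl: CorrelationQtl, snp_positions: pd.DataFrame, gene_positions: pd.DataFrame
) -> str:
    """cis_both / cis_one / trans by chromosome sharing; 'unclassified' when
    annotation is missing (the hit is kept, not dropped)."""
    try:
        snp_chrom = snp_positions.loc[qtl.snp_id, "chrom"]
        chrom_a = gene_positions.loc[qtl.pair[0], "chrom"]
        chrom_b = gene_positions.loc[qtl.pair[1], "chrom"]
    except KeyError:
        qtl.location_class = "unclassified"
        return qtl.location_class
    shared = int(snp_chrom == chrom_a) + int(snp_chrom == chrom_b)
    qtl.location_class = {0: "trans", 1: "cis_one", 2: "cis_both"}[shared]
    return qtl.location_class


def test_eqtl(expr, dosage, covariates: CovariateTable | None = None) -> float:
    """Additive-dosage mean-effect (eQTL) p-value from an OLS Wald t test."""
    y = np.asarray(expr, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if covariates is not None:
        C = covariates.design_matrix().to_numpy(dtype=float)
    else:
        C = np.ones((y.size, 1))
    X = np.column_stack([C, g])
    ok = ~(np.isnan(y) | np.isnan(g))
    X, y = X[ok], y[ok]
    XtX_i = np.linalg.inv(X.T @ X)
    beta = XtX_i @ (X.T @ y)
    resid = y - X @ beta
    df = y.size - X.shape[1]
    se = np.sqrt(resid @ resid / df * XtX_i[-1, -1])
    return float(2 * stats.t.sf(abs(beta[-1] / se), df))


def test_varqtl(
    expr,
    dosage,
    covariates: CovariateTable | None = None,
    tol: float = 1e-6,
    max_iter: int = 25,
) -> float:
    """Variance-effect (varQTL) p-value from a double generalized linear model.

    Alternates (i) a weighted least-squares fit for the mean with weights from
    the current dispersion model and (ii) a gamma GLM with log link of the
    squared mean-model residuals on dosage (plus covariates), until the
    dosage coefficient of the dispersion submodel changes by less than ``tol``
    or ``max_iter`` is reached.  The returned p-value is the Wald test of the
    dispersion submodel's dosage term.  On non-convergence or a numerically
    singular fit the routine falls back to a Breusch-Pagan style score test
    of squared residuals on dosage.
    """
    y = np.asarray(expr, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if covariates is not None:
        C = covariates.design_matrix().to_numpy(dtype=float)
    else:
        C = np.ones((y.size, 1))
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g, C = y[ok], g[ok], C[ok]
    X_mean = np.column_stack([C, g])
    X_disp = np.column_stack([C, g])

    def bp_fallback() -> float:
        beta, *_ = np.linalg.lstsq(X_mean, y, rcond=None)
        d = (y - X_mean @ beta) ** 2
        XtX_i = np.linalg.inv(X_disp.T @ X_disp)
        bd = XtX_i @ (X_disp.T @ d)
        resid = d - X_disp @ bd
        df = d.size - X_disp.shape[1]
        se = np.sqrt(resid @ resid / df * XtX_i[-1, -1])
        return float(2 * stats.t.sf(abs(bd[-1] / se), df))

    try:
        weights = np.ones_like(y)
        coef_prev = np.inf
        converged = False
        disp_fit = None
        for _ in range(max_iter):
            wls = sm.WLS(y, X_mean, weights=weights).fit()
            d = (y - X_mean @ wls.params) ** 2
            d = np.maximum(d, 1e-300)
            with _pywarnings.catch_warnings():
                _pywarnings.simplefilter("ignore")
                disp_fit = sm.GLM(
                    d, X_disp, family=sm.families.Gamma(sm.families.links.Log())
                ).fit()
            phi = disp_fit.fittedvalues
            weights = 1.0 / np.maximum(phi, 1e-12)
            coef = disp_fit.params[-1]
            if abs(coef - coef_prev) < tol:
                converged = True
                break
            coef_prev = coef
        if not converged or disp_fit is None:
            return bp_fallback()
        # Wald test with gamma dispersion fixed at 2 (chi^2_1 residual deviance
        # scale for squared-normal responses)
        se = disp_fit.bse[-1] / np.sqrt(disp_fit.scale / 2.0)
        z = disp_fit.params[-1] / se
        return float(2 * stats.norm.sf(abs(z)))
    except (np.linalg.LinAlgError, ValueError):
        return bp_fallback()


def replication_concordance(
    discovery: list[CorrelationQtl],
    replication: list[CorrelationQtl],
    fdr_level: float = 0.10,
) -> dict:
    """Replication of discovery hits: Bonferroni and within-candidate FDR
    counts plus an exact binomial test of effect-sign agreement against 0.5."""
    disc = {(r.snp_id, r.pair): r for r in discovery}
    repl = {(r.snp_id, r.pair): r for r in replication}
    shared = sorted(set(disc) & set(repl), key=str)
    if not shared:
        raise CilpError("discovery and replication share no SNP x pair keys")
    n = len(shared)
    bonf_thr = 0.05 / n
    repl_p = np.array([repl[k].p for k in shared])
    repl_q = bh_fdr(repl_p)
    n_bonf = int((repl_p < bonf_thr).sum())
    n_fdr = int((repl_q < fdr_level).sum())
    agree = np.array(
        [np.sign(disc[k].beta) == np.sign(repl[k].beta) for k in shared]
    )
    n_agree = int(agree.sum())
    binom = stats.binomtest(n_agree, n, 0.5, alternative="two-sided")
    return {
        "n_candidates": n,
        "n_replicated_bonferroni": n_bonf,
        "n_replicated_fdr": n_fdr,
        "sign_agreement_fraction": n_agree / n,
        "binomial_p": float(binom.pvalue),
    }
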