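"""Two-group decoherence analysis for molecular trait panels.

"Decoherence" is the systematic loss of correlation between molecular traits
in a perturbed state (disease, infection) relative to baseline.  The pipeline
prefilters near-collinear trait pairs, z-scores traits within each stratum x
group cell, tests every remaining pair's per-individual products against the
group label (mixed model with an individual random intercept for repeated
measures, plain OLS otherwise), quantifies the directional bias of
significant pairs, tests category enrichment, and builds a PC1-based
composite score from the most decoherent traits for prospective prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CilpError,
    CovariateTable,
    DegenerateInputError,
    Direction,
    NormalizationMode,
    PairTestResult,
    StratumLabels,
    TraitMatrix,
)
from .core import (
    all_pairs,
    pairwise_products,
    scale_within_strata,
    test_products_lm,
    test_products_lmm,
)

__all__ = [
    "BiasTestResult",
    "prefilter_pairs",
    "run_decoherence",
    "direction_bias_test",
    "pair_enrichment",
    "decoherence_score",
    "compare_predictors_aic",
]


@dataclass
class BiasTestResult:
    """Directional bias of significant pairs toward loss vs gain of correlation."""

    n_sig_loss: int
    n_sig_gain: int
    table: tuple[tuple[int, int], tuple[int, int]]
    log2_odds: float
    p: float
    method: str


def prefilter_pairs(
    traits: TraitMatrix,
    strata: StratumLabels,
    rho_max: float = 0.9,
    pairs: list[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Drop near-collinear pairs: a pair is kept only if |Spearman rho| <=
    ``rho_max`` within every stratum (average ranks for ties).

    Near-duplicate measurements (e.g. a total and its dominant component)
    produce products that track the trait variance rather than any
    biologically meaningful coupling, so they are excluded up front.
    """
    if pairs is None:
        pairs = all_pairs(traits.trait_ids)
    labels = strata.labels.reindex(traits.data.index)
    if labels.isna().any():
        raise CilpError("samples without stratum labels in prefilter")
    keep = {pair: True for pair in pairs}
    for stratum, rows in StratumLabels(labels).groups().items():
        block = traits.data.iloc[rows]
        if (block.notna().sum(axis=0) < 3).any():
            small = list(block.columns[block.notna().sum(axis=0) < 3])
            raise DegenerateInputError(
                f"stratum {stratum!r} has < 3 observations for traits {small[:5]}"
            )
        ranked = block.rank(axis=0, method="average")
        if not block.isna().any().any():
            # complete stratum: one vectorized Spearman matrix
            R = np.corrcoef(ranked.to_numpy(), rowvar=False)
            col = {t: i for i, t in enumerate(block.columns)}
            for pair in pairs:
                if keep[pair] and abs(R[col[pair[0]], col[pair[1]]]) > rho_max:
                    keep[pair] = False
        else:
            for pair in pairs:
                if not keep[pair]:
                    continue
                sub = ranked[list(pair)].dropna()
                if len(sub) < 3:
                    raise DegenerateInputError(
                        f"stratum {stratum!r} has < 3 complete observations "
                        f"for pair {pair}"
                    )
                if abs(sub[pair[0]].corr(sub[pair[1]])) > rho_max:
                    keep[pair] = False
    return [pair for pair in pairs if keep[pair]]


def run_decoherence(
    traits: TraitMatrix,
    status,
    covariates: CovariateTable | None = None,
    strata: StratumLabels | None = None,
    pairs: list[tuple[str, str]] | None = None,
    model: str = "auto",
) -> list[PairTestResult]:
    """Test every kept pair's products against health status.

    Traits are z-scored within stratum x status cells (so group mean and
    variance differences cannot masquerade as correlation differences), the
    per-individual products are regressed on status -- mixed model with the
    covariates' ``random_group`` as random intercept when repeated measures
    are present (``model='auto'``/'lmm'), OLS otherwise -- and BH q-values are
    assigned over the tested pairs.  ``status`` may be binary or an ordered
    numeric trend (e.g. healthy < transitional < disease).
    """
    status = pd.Series(np.asarray(status, dtype=float), index=traits.data.index)
    if status.nunique() < 2:
        raise DegenerateInputError("status is constant")
    status_factor = status.map(lambda v: f"s{v:g}")
    if strata is None:
        cells = StratumLabels(status_factor)
    else:
        cells = StratumLabels.combine(strata.labels.reindex(traits.data.index), status_factor)
    scaled = scale_within_strata(traits, cells)
    if pairs is None:
        pairs = all_pairs(traits.trait_ids)
    products = pairwise_products(scaled, pairs, NormalizationMode.stratum_zscore)
    random_group = covariates.random_group if covariates is not None else None
    use_lmm = model == "lmm" or (
        model == "auto" and random_group is not None and random_group.duplicated().any()
    )
    if use_lmm:
        results = test_products_lmm(
            products, status, covariates, random_group=random_group,
            predictor_name="status",
        )
    else:
        fixed_only = None
        if covariates is not None and covariates.fixed.shape[1]:
            fixed_only = CovariateTable(covariates.fixed, covariates.categorical)
        results = test_products_lm(
            products, status, fixed_only, predictor_name="status"
        )
    return results


def direction_bias_test(
    results: list[PairTestResult],
    q_threshold: float = 0.05,
    method: str = "fisher_sig_vs_nonsig",
    haldane: bool = False,
) -> BiasTestResult:
    """Test whether significant pairs are biased toward loss of correlation.

    ``loss`` means the products are lower in the higher-status (exposed /
    diseased) group, i.e. direction ``higher_in_reference``.  Two
    constructions are offered: Fisher's exact test on the 2x2 of
    {significant, not} x {loss, gain} of the effect-sign margins, or an exact
    binomial test of the loss fraction among significant pairs against 0.5.
    """
    tested = [r for r in results if np.isfinite(r.p)]
    loss = np.array([r.direction == Direction.higher_in_reference for r in tested])
    sig = np.array([r.q < q_threshold for r in tested])
    n_sig_loss = int((sig & loss).sum())
    n_sig_gain = int((sig & ~loss).sum())
    n_ns_loss = int((~sig & loss).sum())
    n_ns_gain = int((~sig & ~loss).sum())
    table = ((n_sig_loss, n_sig_gain), (n_ns_loss, n_ns_gain))
    if n_sig_loss + n_sig_gain == 0:
        return BiasTestResult(0, 0, table, 0.0, 1.0, method)
    if method == "fisher_sig_vs_nonsig":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        if haldane or not np.isfinite(odds) or odds == 0:
            a, b, c, d = (x + 0.5 for x in (n_sig_loss, n_sig_gain, n_ns_loss, n_ns_gain))
            odds = (a * d) / (b * c)
        log2_odds = float(np.log2(odds)) if odds > 0 else -np.inf
        return BiasTestResult(n_sig_loss, n_sig_gain, table, log2_odds, float(p), method)
    if method == "binomial_among_sig":
        n = n_sig_loss + n_sig_gain
        res = stats.binomtest(n_sig_loss, n, 0.5, alternative="two-sided")
        frac = n_sig_loss / n
        log2_odds = (
            float(np.log2(frac / (1 - frac))) if 0 < frac < 1
            else np.inf if frac == 1 else -np.inf
        )
        return BiasTestResult(
            n_sig_loss, n_sig_gain, table, log2_odds, float(res.pvalue), method
        )
    raise CilpError(f"unknown method {method!r}")


def pair_enrichment(
    results: list[PairTestResult],
    annotations: pd.Series,
    q_threshold: float = 0.05,
    direction: Direction = Direction.higher_in_reference,
    membership: str = "either",
) -> pd.DataFrame:
    """Per-category hypergeometric enrichment of significant pairs.

    A pair belongs to a category when either member trait does
    (``membership='either'``; 'both' requires both members).  The background
    is the full set of tested pairs; upper-tail hypergeometric p-values get a
    Bonferroni correction across categories.  Enrichment runs separately per
    direction of effect.
    """
    tested = [r for r in results if np.isfinite(r.p)]
    sig = [r for r in tested if r.q < q_threshold and r.direction == direction]
    if not sig:
        raise DegenerateInputError("no significant pairs in the requested direction")

    def in_category(pair: tuple[str, str], cat: str) -> bool:
        mem_a = annotations.get(pair[0]) == cat
        mem_b = annotations.get(pair[1]) == cat
        return (mem_a or mem_b) if membership == "either" else (mem_a and mem_b)

    categories = sorted(annotations.unique())
    rows = []
    n_total = len(tested)
    n_sig = len(sig)
    for cat in categories:
        K = sum(in_category(r.pair, cat) for r in tested)
        if K == 0:
            continue
        k = sum(in_category(r.pair, cat) for r in sig)
        p = float(stats.hypergeom.sf(k - 1, n_total, K, n_sig))
        # sample odds ratio of the 2x2 (sig x in-category)
        a, b = k, n_sig - k
        c, d = K - k, (n_total - n_sig) - (K - k)
        if b * c > 0:
            odds = (a * d) / (b * c)
        elif a * d == 0:
            odds = 1.0  # degenerate margins (e.g. category spans everything)
        else:
            odds = np.inf
        rows.append(
            {
                "category": cat,
                "n_background": K,
                "n_significant": k,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out.sort_values("p").reset_index(drop=True)


def decoherence_score(
    traits_baseline: TraitMatrix,
    results: list[PairTestResult],
    q_threshold: float = 0.05,
    fraction_threshold: float = 0.25,
    direction: Direction = Direction.higher_in_reference,
) -> tuple[pd.Series, list[str]]:
    """Composite biomarker: PC1 of the baseline values of the most decoherent
    traits.

    A trait is selected when more than ``fraction_threshold`` of its tested
    pairs lose correlation significantly (q < ``q_threshold`` in the given
    direction).  PCA runs on the centered, unit-variance baseline values of
    the selected traits; PC1 is oriented so its loading sum is positive.
    Returns the per-sample scores and the selected trait list.
    """
    tested = [r for r in results if np.isfinite(r.p)]
    n_tested: dict[str, int] = {}
    n_loss: dict[str, int] = {}
    for r in tested:
        for t in r.pair:
            n_tested[t] = n_tested.get(t, 0) + 1
            if r.q < q_threshold and r.direction == direction:
                n_loss[t] = n_loss.get(t, 0) + 1
    selected = sorted(
        t for t, nt in n_tested.items() if n_loss.get(t, 0) / nt > fraction_threshold
    )
    if len(selected) < 2:
        raise DegenerateInputError(
            f"only {len(selected)} traits exceed the {fraction_threshold} "
            "loss-pair fraction; lower fraction_threshold"
        )
    block = traits_baseline.data[selected].dropna()
    Z = (block - block.mean()) / block.std(ddof=1)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loading = Vt[0]
    if loading.sum() < 0:
        loading = -loading
    scores = pd.Series(Z.to_numpy() @ loading, index=block.index, name="decoherence_pc1")
    return scores, selected


def compare_predictors_aic(
    predictors: dict[str, pd.Series],
    outcome: pd.Series,
    covariates: CovariateTable | None = None,
) -> pd.DataFrame:
    """Linear-probability comparison of candidate biomarkers.

    For each named predictor fits OLS of the binary outcome on the predictor
    (plus covariates) and reports model R-squared, the predictor's p-value
    and the gaussian-likelihood AIC, so candidates can be ranked on the same
    samples.
    """
    y_all = outcome.dropna()
    if y_all.nunique() < 2:
        raise DegenerateInputError("outcome has a single class")
    rows = []
    for name, x in predictors.items():
        common = y_all.index.intersection(x.dropna().index)
        y = y_all.loc[common].to_numpy(dtype=float)
        xv = x.loc[common].to_numpy(dtype=float)
        if covariates is not None:
            C = covariates.design_matrix().reindex(common).to_numpy(dtype=float)
        else:
            C = np.ones((len(common), 1))
        X = np.column_stack([C, xv])
        XtX_i = np.linalg.inv(X.T @ X)
        beta = XtX_i @ (X.T @ y)
        resid = y - X @ beta
        n, k = X.shape
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        se = np.sqrt(rss / (n - k) * XtX_i[-1, -1])
        t = beta[-1] / se
        p = float(2 * stats.t.sf(abs(t), n - k))
        # gaussian log-likelihood with MLE variance rss/n; k slopes + sigma^2
        ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
        aic = 2 * (k + 1) - 2 * ll
        rows.append(
            {"predictor": name, "n": n, "r_squared": 1 - rss / tss, "p": p, "aic": aic}
        )
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
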