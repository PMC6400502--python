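"""The CILP statistic and regression tests on per-individual products.

The Pearson correlation of two traits equals the average of their element-wise
product after each trait is mean-centered and variance-scaled.  Skipping the
averaging step leaves one product per individual, which can then be modeled
with ordinary linear or mixed models: a predictor that shifts the products
shifts the correlation.  This module provides the normalization steps
(z-scoring, within-stratum scaling, covariate residualization), the product
construction, and the per-pair regression tests.
"""

from __future__ import annotations

import warnings as _pywarnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .containers import (
    CilpError,
    CovariateTable,
    DegenerateInputError,
    Direction,
    NormalizationMode,
    PairTestResult,
    ProductMatrix,
    StratumLabels,
    TraitMatrix,
)

__all__ = [
    "zscore",
    "scale_within_strata",
    "residualize",
    "pairwise_products",
    "test_products_lm",
    "test_products_lmm",
    "bh_fdr",
]

_MIN_STRATUM = 3


def zscore(values: np.ndarray, ddof: int = 1, name: str = "trait") -> np.ndarray:
    """Center to mean 0 and scale to variance 1 (sample variance, ddof=1).

    Missing (NaN) entries are ignored for the moments and propagate to the
    output.  Raises :class:`DegenerateInputError` for constant input, naming
    the offending trait.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < _MIN_STRATUM:
        raise DegenerateInputError(
            f"{name!r}: need >= {_MIN_STRATUM} non-missing values, got {obs.size}"
        )
    sd = obs.std(ddof=ddof)
    # near-zero variance (e.g. residuals of an exactly-collinear trait) is as
    # degenerate as an exactly constant vector
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(obs).max())):
        raise DegenerateInputError(f"{name!r}: zero variance (constant input)")
    return (x - obs.mean()) / sd


def scale_within_strata(traits: TraitMatrix, strata: StratumLabels) -> TraitMatrix:
    """Z-score every trait separately within each stratum.

    This is the exact normalization for group contrasts: scaling within, e.g.,
    each year x health-status cell removes any mean or variance effect of the
    grouping before products are formed, so only correlation differences
    remain.
    """
    labels = strata.labels.reindex(traits.data.index)
    if labels.isna().any():
        missing = list(traits.data.index[labels.isna()])
        raise CilpError(f"samples without a stratum label: {missing[:5]}")
    out = traits.data.copy()
    for stratum, rows in StratumLabels(labels).groups().items():
        if len(rows) < _MIN_STRATUM:
            raise DegenerateInputError(
                f"stratum {stratum!r} has {len(rows)} samples; need >= {_MIN_STRATUM}"
            )
        block = out.iloc[rows]
        for col in out.columns:
            out.iloc[rows, out.columns.get_loc(col)] = zscore(
                block[col].to_numpy(), name=f"{col} in stratum {stratum}"
            )
    return TraitMatrix(out)


def residualize(traits: TraitMatrix, covariates: CovariateTable) -> TraitMatrix:
    """Remove covariate mean effects from every trait, then rescale.

    Fits one OLS per trait on the covariate design (with intercept), keeps the
    residuals and z-scores them.  This is the scalable normalization for QTL
    scans: it is done once per dataset rather than once per tested predictor.
    """
    X = covariates.design_matrix(add_intercept=True)
    X = X.reindex(traits.data.index)
    if X.isna().any().any():
        raise CilpError("covariates missing for some trait samples")
    Xv = X.to_numpy(dtype=float)
    if traits.n_samples <= Xv.shape[1] + 1:
        raise CilpError(
            f"need n_samples > n_covariates + 1 ({traits.n_samples} <= {Xv.shape[1] + 1})"
        )
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify collinear columns by checking rank growth column-by-column
        bad = []
        kept = np.empty((Xv.shape[0], 0))
        for j, col in enumerate(X.columns):
            cand = np.column_stack([kept, Xv[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(col)
        raise CilpError(f"rank-deficient covariate design; collinear columns: {bad}")

    out = traits.data.copy()
    vals = out.to_numpy()
    complete_cols = ~np.isnan(vals).any(axis=0)
    if complete_cols.any():
        Y = vals[:, complete_cols]
        beta, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
        vals[:, complete_cols] = Y - Xv @ beta
    for j in np.flatnonzero(~complete_cols):
        y = vals[:, j]
        ok = ~np.isnan(y)
        beta, *_ = np.linalg.lstsq(Xv[ok], y[ok], rcond=None)
        y[ok] = y[ok] - Xv[ok] @ beta
        vals[:, j] = y
    out.loc[:, :] = vals
    for col in out.columns:
        out[col] = zscore(out[col].to_numpy(), name=col)
    return TraitMatrix(out)


def pairwise_products(
    scaled: TraitMatrix,
    pairs: Sequence[tuple[str, str]],
    mode: NormalizationMode = NormalizationMode.stratum_zscore,
) -> ProductMatrix:
    """Element-wise products of normalized trait columns, one column per pair.

    A sample missing either member trait is missing in the product column.
    """
    known = set(scaled.trait_ids)
    pair_list = [(str(a), str(b)) for a, b in pairs]
    for a, b in pair_list:
        if a not in known or b not in known:
            raise CilpError(f"unknown trait id in pair ({a}, {b})")
        if a == b:
            raise CilpError(f"self-pair ({a}, {a}) not allowed")
    cols_a = scaled.data[[a for a, _ in pair_list]].to_numpy()
    cols_b = scaled.data[[b for _, b in pair_list]].to_numpy()
    products = cols_a * cols_b
    names = [f"{a}*{b}" for a, b in pair_list]
    frame = pd.DataFrame(products, index=scaled.data.index, columns=names)
    return ProductMatrix(frame, pair_list, mode)


def all_pairs(trait_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered trait pairs, in lexicographic column order."""
    ids = list(trait_ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def _align_predictor(
    products: ProductMatrix, predictor, name: str | None
) -> tuple[np.ndarray, str]:
    if isinstance(predictor, pd.Series):
        x = predictor.reindex(products.data.index)
        if x.isna().any():
            raise CilpError("predictor missing for some samples")
        label = name or (str(predictor.name) if predictor.name else "predictor")
        return x.to_numpy(dtype=float), label
    x = np.asarray(predictor, dtype=float)
    if x.shape[0] != products.data.shape[0]:
        raise CilpError(
            f"predictor length {x.shape[0]} != n_samples {products.data.shape[0]}"
        )
    return x, name or "predictor"


def _design_with_predictor(
    products: ProductMatrix, x: np.ndarray, covariates: CovariateTable | None
) -> np.ndarray:
    if covariates is not None:
        C = covariates.design_matrix(add_intercept=True).reindex(products.data.index)
        if C.isna().any().any():
            raise CilpError("covariates missing for some samples")
        Cv = C.to_numpy(dtype=float)
    else:
        Cv = np.ones((len(x), 1))
    return np.column_stack([Cv, x])


def _ols_pair_tests(
    P: np.ndarray,
    X: np.ndarray,
    pair_index: list[tuple[str, str]],
    predictor_name: str,
) -> list[PairTestResult]:
    """Per-column OLS of product ~ [covariates, predictor]; Wald t on the
    last column.  Columns with missing values are fit on complete rows."""
    n, k = X.shape
    results: list[PairTestResult] = []
    XtX_inv = None
    complete = ~np.isnan(P).any(axis=0)

    def fit_one(y: np.ndarray, Xs: np.ndarray) -> tuple[float, float, float, float, int]:
        ns = Xs.shape[0]
        df = ns - k
        if df < 1:
            raise DegenerateInputError("not enough observations for OLS fit")
        XtX = Xs.T @ Xs
        try:
            XtX_i = np.linalg.inv(XtX)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError(f"singular design: {exc}") from exc
        beta = XtX_i @ (Xs.T @ y)
        resid = y - Xs @ beta
        sigma2 = float(resid @ resid) / df
        se = float(np.sqrt(sigma2 * XtX_i[-1, -1]))
        b = float(beta[-1])
        if se == 0:
            return b, se, np.inf if b else 0.0, 0.0 if b else 1.0, ns
        t = b / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        return b, se, float(t), p, ns

    if complete.any():
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError(f"singular design matrix: {exc}") from exc
        B = XtX_inv @ (X.T @ P[:, complete])  # k x m
        resid = P[:, complete] - X @ B
        df = n - k
        sigma2 = (resid * resid).sum(axis=0) / df
        se = np.sqrt(sigma2 * XtX_inv[-1, -1])
        betas = B[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, betas / np.where(se > 0, se, 1.0), 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    out: dict[int, PairTestResult] = {}
    ci = 0
    for j in range(P.shape[1]):
        pair = pair_index[j]
        if complete[j]:
            out[j] = PairTestResult(
                pair=pair,
                predictor=predictor_name,
                beta=float(betas[ci]),
                se=float(se[ci]),
                stat=float(tvals[ci]),
                p=float(pvals[ci]),
                direction=Direction.from_beta(float(betas[ci])),
                n_used=n,
            )
            ci += 1
        else:
            y = P[:, j]
            ok = ~np.isnan(y)
            if ok.sum() < k + 1:
                _pywarnings.warn(
                    f"pair {pair}: only {int(ok.sum())} complete observations; skipped"
                )
                out[j] = PairTestResult(
                    pair=pair,
                    predictor=predictor_name,
                    beta=np.nan,
                    se=np.nan,
                    stat=np.nan,
                    p=np.nan,
                    n_used=int(ok.sum()),
                    warnings=("skipped_all_missing",),
                )
                continue
            b, s, t, p, ns = fit_one(y[ok], X[ok])
            out[j] = PairTestResult(
                pair=pair,
                predictor=predictor_name,
                beta=b,
                se=s,
                stat=t,
                p=p,
                direction=Direction.from_beta(b),
                n_used=ns,
            )
    results = [out[j] for j in range(P.shape[1])]
    return results


def _attach_q(results: list[PairTestResult]) -> list[PairTestResult]:
    tested = [r for r in results if np.isfinite(r.p)]
    if tested:
        q = bh_fdr(np.array([r.p for r in tested]))
        for r, qv in zip(tested, q):
            r.q = float(qv)
    return results


def test_products_lm(
    products: ProductMatrix,
    predictor,
    covariates: CovariateTable | None = None,
    predictor_name: str | None = None,
) -> list[PairTestResult]:
    """OLS of each product column on the predictor, controlling for covariates.

    Returns one :class:`PairTestResult` per pair with a two-sided Wald-t
    p-value for the predictor coefficient and BH q-values over all tested
    pairs.  With a binary predictor and no covariates the fit reduces to a
    pooled two-sample t-test on the products.
    """
    x, label = _align_predictor(products, predictor, predictor_name)
    if np.nanstd(x) == 0:
        raise DegenerateInputError(f"predictor {label!r} is constant")
    X = _design_with_predictor(products, x, covariates)
    results = _ols_pair_tests(products.values, X, products.pair_index, label)
    return _attach_q(results)


def test_products_lmm(
    products: ProductMatrix,
    predictor,
    covariates: CovariateTable | None = None,
    random_group: pd.Series | None = None,
    predictor_name: str | None = None,
) -> list[PairTestResult]:
    """Random-intercept mixed model per product column.

    ``random_group`` (e.g. individual identity across repeated measures)
    defaults to ``covariates.random_group``.  The fixed-effect p-value is a
    Wald z test.  Pairs whose mixed fit is singular or fails fall back to the
    OLS path and carry a ``lmm_fallback_lm`` warning flag.
    """
    x, label = _align_predictor(products, predictor, predictor_name)
    if np.nanstd(x) == 0:
        raise DegenerateInputError(f"predictor {label!r} is constant")
    if random_group is None and covariates is not None:
        random_group = covariates.random_group
    if random_group is None:
        raise CilpError("test_products_lmm requires a random_group")
    groups = random_group.reindex(products.data.index)
    if groups.isna().any():
        raise CilpError("random_group missing for some samples")
    if groups.nunique() < 2:
        raise DegenerateInputError("random_group needs >= 2 levels")
    X = _design_with_predictor(products, x, covariates)
    P = products.values
    results: list[PairTestResult] = []
    lm_results = None
    for j, pair in enumerate(products.pair_index):
        y = P[:, j]
        ok = ~np.isnan(y)
        warn_flags: tuple[str, ...] = ()
        try:
            with _pywarnings.catch_warnings():
                _pywarnings.simplefilter("ignore")
                model = MixedLM(y[ok], X[ok], groups=groups.to_numpy()[ok])
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
                idx = X.shape[1] - 1
                beta = float(fit.fe_params[idx])
                se = float(fit.bse_fe[idx])
            if not np.isfinite(se) or se == 0:
                raise np.linalg.LinAlgError("non-finite fixed-effect SE")
            z = beta / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            results.append(
                PairTestResult(
                    pair=pair,
                    predictor=label,
                    beta=beta,
                    se=se,
                    stat=float(z),
                    p=p,
                    direction=Direction.from_beta(beta),
                    n_used=int(ok.sum()),
                    warnings=warn_flags,
                )
            )
        except (np.linalg.LinAlgError, ValueError):
            if lm_results is None:
                lm_results = _ols_pair_tests(P, X, products.pair_index, label)
            r = lm_results[j]
            r.warnings = r.warnings + ("lmm_fallback_lm",)
            results.append(r)
    return _attach_q(results)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise CilpError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
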