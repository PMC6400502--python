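"""Monte-Carlo power and false-positive-rate evaluation.

Runs batches of simulated gene pairs through the product pipeline (z-score
each gene, per-individual products, OLS on genotype) and tabulates detection
rates at the nominal 0.05 threshold and after Bonferroni correction over the
batch.  The eight-scenario grid crosses the correlation-QTL effect with
genetic and non-genetic mean/variance effects to verify that only genuine
covariance differences are detected.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CilpError, DegenerateInputError
from .simulate import ScenarioConfig, simulate_pair_batch

__all__ = [
    "PowerResult",
    "TABLE_SCENARIOS",
    "scenario_config",
    "batch_pair_pvalues",
    "run_scenario",
    "replicate_scenario_grid",
    "power_curve",
]

#: Scenario grid: which effects are switched on in each of the eight columns.
#: Effect magnitudes follow the study conditions: correlation-QTL slope 0.3,
#: mean effects 1, variance effects 10, n = 1000, MAF 0.5.
TABLE_SCENARIOS: dict[int, dict[str, float]] = {
    1: {},
    2: {"b1": 1.0},
    3: {"b1": 1.0, "b2": 1.0},
    4: {"v1": 10.0},
    5: {"b1": 1.0, "v1": 10.0},
    6: {"mean_confound1": 1.0, "mean_confound2": 1.0},
    7: {"var_confound1": 10.0},
    8: {"var_confound1": 10.0, "var_confound2": 10.0},
}


def scenario_config(
    scenario: int,
    n: int = 1000,
    maf: float = 0.5,
    b: float = 0.3,
    mean_effect: float = 1.0,
    var_effect: float = 10.0,
) -> ScenarioConfig:
    """Build the ScenarioConfig for one column of the scenario grid."""
    if scenario not in TABLE_SCENARIOS:
        raise CilpError(f"unknown scenario {scenario}; valid: 1-8")
    flags = TABLE_SCENARIOS[scenario]
    params: dict[str, float] = {}
    for key, val in flags.items():
        if key.startswith(("b1", "b2", "mean_")):
            params[key] = mean_effect if val else 0.0
        else:
            params[key] = var_effect if val else 0.0
    return ScenarioConfig(n=n, maf=maf, b=b, **params)


@dataclass
class PowerResult:
    """Detection rates for one scenario batch."""

    scenario_id: int
    n_pairs_true: int
    n_pairs_null: int
    power_nominal: float
    power_bonferroni: float
    fpr_nominal: float
    fpr_bonferroni: float
    seed: int | None = None

    def __post_init__(self) -> None:
        rates = (
            self.power_nominal,
            self.power_bonferroni,
            self.fpr_nominal,
            self.fpr_bonferroni,
        )
        for r in rates:
            if np.isfinite(r) and not 0.0 <= r <= 1.0:
                raise CilpError(f"rate {r} outside [0, 1]")
        if (
            np.isfinite(self.power_bonferroni)
            and self.power_bonferroni > self.power_nominal + 1e-12
        ):
            raise CilpError("Bonferroni power cannot exceed nominal power")

    def to_dict(self) -> dict:
        return asdict(self)


def batch_pair_pvalues(
    config: ScenarioConfig,
    n_pairs: int,
    seed,
    include_expression_covariates: bool = False,
    chunk: int = 2000,
) -> np.ndarray:
    """Two-sided p-values for product ~ genotype across a batch of pairs.

    Each pair receives fresh genotypes; each gene is z-scored across the whole
    sample (ddof=1), the per-individual product is regressed on minor-allele
    dosage and the OLS t-test p-value for the dosage term is returned.
    ``include_expression_covariates`` additionally adjusts for both genes'
    expression levels.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = config.n
    out = np.empty(n_pairs)
    done = 0
    while done < n_pairs:
        m = min(chunk, n_pairs - done)
        G, Y1, Y2 = simulate_pair_batch(config, m, rng)

        def colscale(Y):
            sd = Y.std(axis=0, ddof=1)
            if (sd == 0).any():
                raise DegenerateInputError("zero-variance simulated trait")
            return (Y - Y.mean(axis=0)) / sd

        Z1 = colscale(Y1)
        Z2 = colscale(Y2)
        P = Z1 * Z2
        if (G.std(axis=0) == 0).any():
            # monomorphic genotype draws cannot be tested; re-draw those pairs
            bad = G.std(axis=0) == 0
            G2, Y1b, Y2b = simulate_pair_batch(config, int(bad.sum()), rng)
            G[:, bad], Y1[:, bad], Y2[:, bad] = G2, Y1b, Y2b
            Z1 = colscale(Y1)
            Z2 = colscale(Y2)
            P = Z1 * Z2
        if include_expression_covariates:
            pv = np.empty(m)
            for j in range(m):
                X = np.column_stack([np.ones(n), Z1[:, j], Z2[:, j], G[:, j]])
                XtX_i = np.linalg.inv(X.T @ X)
                beta = XtX_i @ (X.T @ P[:, j])
                resid = P[:, j] - X @ beta
                sigma2 = resid @ resid / (n - 4)
                se = np.sqrt(sigma2 * XtX_i[-1, -1])
                pv[j] = 2 * stats.t.sf(abs(beta[-1] / se), n - 4)
            out[done : done + m] = pv
        else:
            Gc = G - G.mean(axis=0)
            Pc = P - P.mean(axis=0)
            sxx = (Gc * Gc).sum(axis=0)
            beta = (Gc * Pc).sum(axis=0) / sxx
            resid = Pc - beta * Gc
            sigma2 = (resid * resid).sum(axis=0) / (n - 2)
            se = np.sqrt(sigma2 / sxx)
            tvals = beta / se
            out[done : done + m] = 2 * stats.t.sf(np.abs(tvals), n - 2)
        done += m
    return out


def run_scenario(
    config: ScenarioConfig,
    n_true: int,
    n_null: int,
    seed,
    scenario_id: int = 0,
    bonferroni_n: int | None = None,
    include_expression_covariates: bool = False,
) -> PowerResult:
    """Simulate ``n_true`` effect pairs and ``n_null`` matched null pairs
    (same nuisance effects, covariance slope set to zero) and tabulate
    detection rates.

    The Bonferroni denominator defaults to the number of tests in each batch.
    """
    if n_true + n_null < 1:
        raise CilpError("need at least one pair")
    rng = np.random.default_rng(seed)
    p_true = (
        batch_pair_pvalues(
            config, n_true, rng,
            include_expression_covariates=include_expression_covariates,
        )
        if n_true
        else np.empty(0)
    )
    p_null = (
        batch_pair_pvalues(
            config.with_(b=0.0), n_null, rng,
            include_expression_covariates=include_expression_covariates,
        )
        if n_null
        else np.empty(0)
    )
    thr_true = 0.05 / (bonferroni_n or max(n_true, 1))
    thr_null = 0.05 / (bonferroni_n or max(n_null, 1))
    return PowerResult(
        scenario_id=scenario_id,
        n_pairs_true=n_true,
        n_pairs_null=n_null,
        power_nominal=float((p_true < 0.05).mean()) if n_true else np.nan,
        power_bonferroni=float((p_true < thr_true).mean()) if n_true else np.nan,
        fpr_nominal=float((p_null < 0.05).mean()) if n_null else np.nan,
        fpr_bonferroni=float((p_null < thr_null).mean()) if n_null else np.nan,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def replicate_scenario_grid(
    n: int = 1000,
    n_pairs: int = 10_000,
    b: float = 0.3,
    mean_effect: float = 1.0,
    var_effect: float = 10.0,
    maf: float = 0.5,
    seed: int = 0,
    scenarios: tuple[int, ...] = tuple(range(1, 9)),
) -> pd.DataFrame:
    """Run the full eight-scenario grid: one row per scenario with power and
    false-positive rates at nominal and Bonferroni thresholds.

    Null pairs are scenario-matched: they carry the same mean/variance
    nuisance effects as the effect pairs, with the covariance slope zeroed.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for scen, child in zip(scenarios, ss.spawn(len(scenarios))):
        config = scenario_config(
            scen, n=n, maf=maf, b=b, mean_effect=mean_effect, var_effect=var_effect
        )
        res = run_scenario(
            config,
            n_true=n_pairs,
            n_null=n_pairs,
            seed=np.random.default_rng(child),
            scenario_id=scen,
        )
        row = res.to_dict()
        row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)


def power_curve(
    effect_grid,
    n_grid,
    n_pairs: int = 1000,
    maf: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Nominal and Bonferroni power over a (covariance slope b, sample size n)
    grid, ``n_pairs`` simulated pairs per cell."""
    effect_grid = list(effect_grid)
    n_grid = list(n_grid)
    if not effect_grid or not n_grid:
        raise CilpError("effect and sample-size grids must be non-empty")
    rows = []
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(effect_grid) * len(n_grid)))
    for b in effect_grid:
        for n in n_grid:
            config = ScenarioConfig(n=int(n), maf=maf, b=float(b))
            pv = batch_pair_pvalues(config, n_pairs, np.random.default_rng(next(children)))
            rows.append(
                {
                    "b": float(b),
                    "n": int(n),
                    "n_pairs": n_pairs,
                    "power_nominal": float((pv < 0.05).mean()),
                    "power_bonferroni": float((pv < 0.05 / n_pairs).mean()),
                }
            )
    return pd.DataFrame(rows)
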