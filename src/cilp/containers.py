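"""Core data containers shared across the package.

All containers are thin wrappers around pandas objects: samples are rows,
molecular features (traits, SNPs) are columns, and missing values are NaN.
Validation happens at construction so downstream numerics can assume clean
shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CilpError",
    "DegenerateInputError",
    "NormalizationMode",
    "Direction",
    "TraitMatrix",
    "StratumLabels",
    "CovariateTable",
    "ProductMatrix",
    "GenotypeMatrix",
    "PairTestResult",
    "results_to_frame",
]


class CilpError(ValueError):
    """Base class for input-validation errors raised by this package."""


class DegenerateInputError(CilpError):
    """Raised for inputs that are formally valid but statistically degenerate
    (zero-variance traits, constant predictors, strata that are too small)."""


class NormalizationMode(str, Enum):
    """How trait columns were normalized before taking products.

    ``stratum_zscore`` z-scores each trait within each stratum (the exact
    two-group construction); ``residualize_then_scale`` removes covariate mean
    effects once and rescales the residuals, which makes genome-wide scans
    tractable because the products need not be recomputed per predictor.
    """

    stratum_zscore = "stratum_zscore"
    residualize_then_scale = "residualize_then_scale"


class Direction(str, Enum):
    """Sign of a predictor's effect on the per-individual products.

    ``higher_in_alternative`` means products (hence correlation) increase with
    the predictor; ``higher_in_reference`` means they decrease.
    """

    higher_in_reference = "higher_in_reference"
    higher_in_alternative = "higher_in_alternative"

    @classmethod
    def from_beta(cls, beta: float) -> "Direction":
        return cls.higher_in_alternative if beta > 0 else cls.higher_in_reference


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise CilpError(f"duplicate {what}: {dups[:5]}")


@dataclass
class TraitMatrix:
    """Samples x traits matrix of continuous measurements (NaN = missing)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.shape[0] < 3:
            raise CilpError(f"need at least 3 samples, got {self.data.shape[0]}")
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "trait ids")
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise CilpError("trait matrix contains non-finite (inf) entries")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_traits(self) -> int:
        return self.data.shape[1]


@dataclass
class StratumLabels:
    """One categorical stratum label per sample (e.g. year x health-status)."""

    labels: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "sample ids")
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise CilpError(f"samples without a stratum: {missing[:5]}")
        self.labels = self.labels.astype(str)

    @classmethod
    def single(cls, sample_ids: Sequence[str]) -> "StratumLabels":
        return cls(pd.Series("all", index=list(sample_ids)))

    @classmethod
    def combine(cls, *parts: pd.Series) -> "StratumLabels":
        """Cross several per-sample factors into one stratum label."""
        combined = parts[0].astype(str)
        for p in parts[1:]:
            combined = combined + ":" + p.reindex(combined.index).astype(str)
        return cls(combined)

    def groups(self) -> dict[str, np.ndarray]:
        """Map stratum name -> integer row positions."""
        codes, uniques = pd.factorize(self.labels)
        return {str(u): np.flatnonzero(codes == i) for i, u in enumerate(uniques)}


@dataclass
class CovariateTable:
    """Fixed-effect covariates plus an optional random-effect grouping.

    ``categorical`` names columns to be dummy-coded when building design
    matrices; ``random_group`` is the grouping factor for mixed models (e.g.
    individual identity across repeated measures).
    """

    fixed: pd.DataFrame
    categorical: tuple[str, ...] = ()
    random_group: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.fixed.index, "sample ids")
        unknown = set(self.categorical) - set(self.fixed.columns)
        if unknown:
            raise CilpError(f"categorical columns not present: {sorted(unknown)}")
        if self.random_group is not None and not self.fixed.index.equals(
            pd.Index(self.random_group.index)
        ):
            self.random_group = self.random_group.reindex(self.fixed.index)
            if self.random_group.isna().any():
                raise CilpError("random_group missing for some samples")

    def design_matrix(self, add_intercept: bool = True) -> pd.DataFrame:
        """Numeric design matrix with categorical columns dummy-coded
        (first level dropped); checks for missing values in used columns."""
        if self.fixed.shape[1]:
            if self.fixed.isna().any().any():
                bad = list(self.fixed.columns[self.fixed.isna().any()])
                raise CilpError(f"missing values in covariate columns: {bad}")
            parts = []
            for col in self.fixed.columns:
                if col in self.categorical:
                    dummies = pd.get_dummies(
                        self.fixed[col].astype(str), prefix=col, drop_first=True
                    ).astype(float)
                    parts.append(dummies)
                else:
                    parts.append(self.fixed[[col]].astype(float))
            X = pd.concat(parts, axis=1)
        else:
            X = pd.DataFrame(index=self.fixed.index)
        if add_intercept:
            X.insert(0, "const", 1.0)
        return X

    @classmethod
    def empty(cls, sample_ids: Sequence[str]) -> "CovariateTable":
        return cls(pd.DataFrame(index=list(sample_ids)))


@dataclass
class ProductMatrix:
    """Samples x trait-pairs matrix of per-individual correlation products.

    Each column holds, for one unordered trait pair (a, b), the element-wise
    product of the two normalized trait columns; its sample mean (times
    n/(n-1) under single-stratum ddof=1 scaling) is the Pearson correlation
    of the pair.
    """

    data: pd.DataFrame
    pair_index: list[tuple[str, str]]
    normalization_mode: NormalizationMode

    def __post_init__(self) -> None:
        if len(self.pair_index) != self.data.shape[1]:
            raise CilpError("pair_index length must match number of columns")
        seen = set()
        for a, b in self.pair_index:
            if a == b:
                raise CilpError(f"self-pair ({a}, {a}) not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise CilpError(f"duplicate unordered pair ({a}, {b})")
            seen.add(key)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_pairs(self) -> int:
        return self.data.shape[1]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of minor-allele dosages in {0, 1, 2} (NaN = missing).

    ``positions``, when present, is indexed by snp_id with columns
    ``chrom`` and ``pos`` (1-based).
    """

    data: pd.DataFrame
    positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "snp ids")
        vals = self.data.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise CilpError(f"genotype values outside {{0,1,2,NaN}}: {bad[:5]}")
        if self.positions is not None:
            missing = set(self.data.columns) - set(self.positions.index)
            if missing:
                raise CilpError(f"positions missing for SNPs: {sorted(missing)[:5]}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class PairTestResult:
    """Association result for one trait pair (optionally one SNP x pair)."""

    pair: tuple[str, str]
    predictor: str
    beta: float
    se: float
    stat: float
    p: float
    q: float = np.nan
    direction: Direction = Direction.higher_in_alternative
    n_used: int = 0
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise CilpError(f"p-value out of [0,1]: {self.p}")


def results_to_frame(results: Sequence[PairTestResult]) -> pd.DataFrame:
    """Tabulate results with the package's standard output columns."""
    return pd.DataFrame(
        {
            "pair_a": [r.pair[0] for r in results],
            "pair_b": [r.pair[1] for r in results],
            "predictor": [r.predictor for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "stat": [r.stat for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "direction": [r.direction.value for r in results],
            "n_used": [r.n_used for r in results],
            "warnings": [";".join(r.warnings) for r in results],
        }
    )
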