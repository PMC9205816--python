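"""Selection-index construction and prediction-performance measures.

Two complementary measures of sparse-testing performance are provided:

* *predictive ability* — the Pearson correlation between predicted genetic
  effects and reference BLUEs for the prediction-set lines of one SE;
* *selection-intersection accuracy* — the proportion of lines shared by
  the top-fraction sets chosen with a Smith-Hazel index ``b = P^-1 G w``
  from the prediction model and from the full data, mirroring a breeder's
  advancement decision across SEs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IndexSpec",
    "SelectionSet",
    "smith_hazel_weights",
    "index_scores",
    "select_top",
    "intersection_accuracy",
    "predictive_ability",
]

DEFAULT_ECONOMIC_WEIGHTS = (0.25, 0.1, 0.3, 0.2, 0.1, 0.05)


@dataclass
class IndexSpec:
    """Economic weights plus genetic and phenotypic covariance matrices.

    The default weight vector is the six-SE economic weighting used for
    advancement decisions, bound positionally to the configured SE order.
    """

    economic_weights: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_ECONOMIC_WEIGHTS)
    )
    genetic_cov: np.ndarray | None = None
    phenotypic_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.economic_weights = np.asarray(self.economic_weights, dtype=float)
        if self.genetic_cov is not None:
            self.genetic_cov = np.asarray(self.genetic_cov, dtype=float)
        if self.phenotypic_cov is not None:
            self.phenotypic_cov = np.asarray(self.phenotypic_cov, dtype=float)

    def validate(self) -> None:
        k = len(self.economic_weights)
        for name, m in (("genetic_cov", self.genetic_cov), ("phenotypic_cov", self.phenotypic_cov)):
            if m is None:
                raise ValueError(f"{name} is required")
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if not np.allclose(m, m.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
        if np.linalg.eigvalsh(self.phenotypic_cov)[0] <= 0:
            raise ValueError("phenotypic_cov must be positive definite")


@dataclass(frozen=True)
class SelectionSet:
    """Top-fraction selection: ceil(fraction * n) lines, tie-broken by id."""

    lines: frozenset[str]
    fraction: float
    source: str = "full_data_gblup"


def smith_hazel_weights(spec: IndexSpec) -> np.ndarray:
    """Classic Smith-Hazel index coefficients ``b = P^-1 G w``."""
    spec.validate()
    try:
        return np.linalg.solve(spec.phenotypic_cov, spec.genetic_cov @ spec.economic_weights)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "phenotypic covariance is singular; consider adding a ridge to its diagonal"
        ) from e


def index_scores(values: pd.DataFrame, b: np.ndarray) -> pd.Series:
    """Linear index score per line: ``score_i = sum_k b_k value_ik``.

    ``values`` is a line x environment table; every cell must be present.
    """
    b = np.asarray(b, dtype=float)
    if values.shape[1] != len(b):
        raise ValueError("index weight length must match the number of environments")
    if values.isna().any().any():
        raise ValueError("missing cells in the line x environment table")
    return pd.Series(values.to_numpy() @ b, index=values.index, name="index_score")


def select_top(scores: pd.Series, fraction: float = 0.20, source: str = "full_data_gblup") -> SelectionSet:
    """Select the ``ceil(fraction * n)`` highest-scoring lines; ties at the
    cutoff are broken by stable line-id order for reproducibility."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(scores) == 0:
        raise ValueError("no scores to select from")
    n_sel = math.ceil(fraction * len(scores))
    order = sorted(scores.index, key=lambda l: (-scores[l], str(l)))
    return SelectionSet(frozenset(order[:n_sel]), fraction, source)


def intersection_accuracy(a: SelectionSet, b: SelectionSet) -> float:
    """Proportion of lines shared by two equal-size selections, |a n b|/|a|."""
    if not a.lines or not b.lines:
        raise ValueError("selection sets must be nonempty")
    if len(a.lines) != len(b.lines):
        raise ValueError(
            f"selection sets have different sizes ({len(a.lines)} vs {len(b.lines)})"
        )
    return len(a.lines & b.lines) / len(a.lines)


def predictive_ability(predicted: pd.Series, reference: pd.Series) -> float:
    """Pearson correlation of predictions with reference BLUEs over the
    lines common to both series; NaN (with a warning) if degenerate."""
    common = predicted.index.intersection(reference.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common lines for a correlation")
    x = predicted.loc[common].to_numpy(float)
    y = reference.loc[common].to_numpy(float)
    if x.std() < 1e-14 or y.std() < 1e-14:
        warnings.warn("zero variance in predictive-ability inputs", UserWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
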