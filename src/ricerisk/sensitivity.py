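"""Sensitivity ranking of Monte Carlo inputs by influence on the THQ output.

Two complementary measures per input:

* **effect on output mean** (the tornado-chart statistic): input draws are
  split into equal-count quantile bins; the swing is the spread
  max - min of the conditional output means across bins.  Depending only
  on input ranks, it is invariant under monotone transforms of the input.
* **Spearman rank correlation**, which signs the relationship.

Ranking uses the swing; for the rice exposure model both measures agree
that the contaminant concentration (coefficient of variation ~1.6)
dominates the intake (~0.17).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InvalidInputError

__all__ = [
    "SensitivityResult",
    "effect_on_output_mean",
    "spearman_rank_contribution",
    "rank_inputs",
    "tornado_table",
]

logger = logging.getLogger(__name__)


@dataclass
class SensitivityResult:
    """Influence summary for one input variable."""

    name: str
    swing: float
    bin_means: np.ndarray
    spearman_rho: float
    rank: int | None = None


def effect_on_output_mean(
    input_draws: Sequence[float],
    output_draws: Sequence[float],
    n_bins: int = 10,
) -> tuple[float, np.ndarray]:
    """Conditional-mean swing of the output across quantile bins of one input.

    Returns ``(swing, bin_means)`` where the input is partitioned into
    ``n_bins`` equal-count bins by rank (ties broken stably by draw index)
    and ``swing = max(bin_means) - min(bin_means)``.
    """
    x = np.asarray(input_draws, dtype=float)
    y = np.asarray(output_draws, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("input and output draws must be equal-length vectors")
    if len(x) < 10 * n_bins:
        raise InvalidInputError(f"need at least {10 * n_bins} draws for {n_bins} bins")
    order = np.argsort(x, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_means = np.array([y[idx].mean() for idx in bins])
    return float(bin_means.max() - bin_means.min()), bin_means


def spearman_rank_contribution(
    input_draws: Sequence[float], output_draws: Sequence[float]
) -> float:
    """Spearman rank correlation between one input and the output."""
    x = np.asarray(input_draws, dtype=float)
    y = np.asarray(output_draws, dtype=float)
    if x.shape != y.shape or len(x) < 10:
        raise InvalidInputError("need equal-length vectors of >= 10 draws")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input vector: rank correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def rank_inputs(
    inputs: Mapping[str, Sequence[float]],
    output_draws: Sequence[float],
    n_bins: int = 10,
) -> list[SensitivityResult]:
    """Compute swing and rho for every input; rank 1 = largest swing."""
    if not inputs:
        raise InvalidInputError("no inputs supplied")
    results = []
    for name, draws in inputs.items():
        swing, bin_means = effect_on_output_mean(draws, output_draws, n_bins)
        rho = spearman_rank_contribution(draws, output_draws)
        results.append(SensitivityResult(name=name, swing=swing, bin_means=bin_means, spearman_rho=rho))
    results.sort(key=lambda r: -r.swing)
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def tornado_table(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    """Tornado-chart table (input, swing, rho, rank, bin means) for export."""
    return pd.DataFrame(
        [
            {
                "input": r.name,
                "rank": r.rank,
                "swing": r.swing,
                "spearman_rho": r.spearman_rho,
                **{f"bin_mean_{i+1}": m for i, m in enumerate(r.bin_means)},
            }
            for r in results
        ]
    )
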