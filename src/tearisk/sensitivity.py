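"""Contribution-to-variance sensitivity analysis.

Apportions the variability of a simulated output (typically the hazard
index) among the uncertain inputs the way spreadsheet risk tools' default
"sensitivity chart" does: compute the Spearman rank correlation r_i
between each input's samples and the output, then report

    contribution_i = sign(r_i) · r_i² / Σ_j r_j² × 100   (percent)

so the absolute contributions sum to 100% and the sign carries the
direction of the monotone association. Being rank-based, the measure is
invariant under strictly monotone transforms of any single input. It is a
screening heuristic, not a variance decomposition (no Sobol indices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = ["SensitivityResult", "rank_correlation", "sensitivity_contributions"]

METHOD_LABEL = "contribution_to_variance(spearman_rank)"


def rank_correlation(x, y) -> float:
    """Spearman rank correlation with average-rank ties, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in a ranked vector: correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class SensitivityResult:
    """Signed percentage contribution per input; |contributions| sum to 100."""

    contributions: Mapping[str, float]
    rank_correlations: Mapping[str, float]
    excluded: tuple[str, ...]
    method: str = METHOD_LABEL

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variable": list(self.contributions),
                "contribution_pct": list(self.contributions.values()),
                "rank_correlation": [
                    self.rank_correlations[v] for v in self.contributions
                ],
            }
        ).sort_values("contribution_pct", key=abs, ascending=False, ignore_index=True)


def sensitivity_contributions(
    input_samples: Mapping[str, np.ndarray], output
) -> SensitivityResult:
    """Contribution-to-variance of each sampled input to an output vector.

    Constant inputs carry no information for a rank statistic; they are
    excluded with a warning and reported with zero contribution. A
    constant output is an error (there is no variance to apportion).
    """
    output = np.asarray(output, dtype=float)
    if output.ndim != 1 or output.size < 3:
        raise ValueError("output must be a 1-D vector of length >= 3")
    if np.all(output == output[0]):
        raise ValueError("constant output: no variance to attribute")

    rhos: dict[str, float] = {}
    excluded: list[str] = []
    for name, samples in input_samples.items():
        samples = np.asarray(samples, dtype=float)
        if samples.shape != output.shape:
            raise ValueError(f"input {name!r} length {samples.size} != output length {output.size}")
        if np.all(samples == samples[0]):
            warnings.warn(
                f"input {name!r} is constant; excluded from sensitivity (0% contribution)",
                stacklevel=2,
            )
            excluded.append(name)
            continue
        rhos[name] = rank_correlation(samples, output)

    if len(rhos) < 1:
        raise ValueError("need at least one non-constant input variable")
    total = sum(r**2 for r in rhos.values())
    if total == 0:
        raise ValueError("all rank correlations are exactly zero; nothing to apportion")
    contributions = {
        name: float(np.sign(r) * r**2 / total * 100.0) for name, r in rhos.items()
    }
    for name in excluded:
        contributions[name] = 0.0
        rhos[name] = float("nan")
    return SensitivityResult(
        contributions=contributions,
        rank_correlations=rhos,
        excluded=tuple(excluded),
    )
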