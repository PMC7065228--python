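"""Joint law of the score statistics across arms and stages.

For arm i with allocation ratio lambda_i, the cumulative score statistic at
stage j is W_ij = deltahat_ij * I_ij with Fisher information
I_ij = n_0j * Lambda_i, Lambda_i = (sigma_0^2 + sigma_i^2 / lambda_i)^{-1}.
The vector process W_j is multivariate Brownian: within an arm,
cov(W_ij, W_ij') = I_{i, min(j, j')}; across arms at a common stage,
cov(W_ij, W_hj) = Lambda_i * Lambda_h * sigma_0^2 * n_0j.  The cross-arm
dependence therefore has one-factor (product) structure with loading
a_i = sigma_0 * sqrt(Lambda_i) -- the shared control arm is the factor --
which the numerical kernels in :mod:`mamskit._quad` exploit throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignSpec

__all__ = [
    "arm_precision",
    "information",
    "increment_information",
    "factor_loadings",
    "score_covariance",
    "ScoreDistribution",
]


def arm_precision(spec: DesignSpec, arm: int) -> float:
    """Lambda_i = (sigma_0^2 + lambda_i^{-1} sigma_i^2)^{-1} for arm i >= 1."""
    if not 1 <= arm <= spec.n_arms:
        raise IndexError("arm index must be in 1..%d" % spec.n_arms)
    lam = spec.allocation[arm - 1]
    return 1.0 / (spec.variances[0] + spec.variances[arm] / lam)


def information(spec: DesignSpec, arm: int, stage: int) -> float:
    """Cumulative Fisher information I_ij = n_0j * Lambda_i.

    ``stage`` is 1-based; strictly increasing in stage."""
    if not 1 <= stage <= spec.n_stages:
        raise IndexError("stage index must be in 1..%d" % spec.n_stages)
    return spec.control_stage_sizes[stage - 1] * arm_precision(spec, arm)


def increment_information(spec: DesignSpec, arm: int, stage: int) -> float:
    """Information carried by the stage-``stage`` incremental data,
    I_i(j) = (n_0j - n_0,j-1) * Lambda_i."""
    if not 1 <= stage <= spec.n_stages:
        raise IndexError("stage index must be in 1..%d" % spec.n_stages)
    n0 = (0,) + spec.control_stage_sizes
    return (n0[stage] - n0[stage - 1]) * arm_precision(spec, arm)


def factor_loadings(spec: DesignSpec, arms=None) -> np.ndarray:
    """One-factor loadings a_i = sigma_0 * sqrt(Lambda_i): the cross-arm
    correlation of the score (or Wald) statistics at a common stage is
    a_i * a_h.  Equal allocation and equal variances give a_i^2 = 1/2."""
    arms = range(1, spec.n_arms + 1) if arms is None else arms
    s0 = np.sqrt(spec.variances[0])
    return np.array([s0 * np.sqrt(arm_precision(spec, i)) for i in arms])


@dataclass(frozen=True)
class ScoreDistribution:
    """Mean vector and covariance of a block of score statistics.

    Entries are ordered stage-major: (stage_1 x arms), (stage_2 x arms), ...
    """

    arms: tuple
    stages: tuple
    mean: np.ndarray        # (len(stages) * len(arms),)
    cov: np.ndarray         # square, same order

    @property
    def corr(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.cov))
        return self.cov / np.outer(sd, sd)


def score_covariance(spec: DesignSpec, arms=None, stages=None,
                     delta=None) -> ScoreDistribution:
    """Joint normal law of {W_ij} for the requested arms and stages.

    ``delta`` holds the true effects (length D, defaults to zero) entering
    the means as E(W_ij) = delta_i * I_ij.  Incremental-stage statistics
    W_(j) are increments of this law and are independent of every earlier
    cumulative statistic.
    """
    arms = tuple(range(1, spec.n_arms + 1)) if arms is None else tuple(arms)
    stages = tuple(range(1, spec.n_stages + 1)) if stages is None \
        else tuple(stages)
    if not arms or not stages:
        raise ValueError("arms and stages must be nonempty")
    delta = np.zeros(spec.n_arms) if delta is None else np.asarray(delta, float)
    lam = np.array([arm_precision(spec, i) for i in arms])
    info = np.array([[information(spec, i, j) for i in arms] for j in stages])
    mean = np.concatenate([delta[[i - 1 for i in arms]] * info[j]
                           for j in range(len(stages))])
    k, J = len(arms), len(stages)
    cov = np.empty((J * k, J * k))
    s0sq = spec.variances[0]
    n0 = spec.control_stage_sizes
    for j1 in range(J):
        for j2 in range(J):
            nmin = n0[min(stages[j1], stages[j2]) - 1]
            block = np.outer(lam, lam) * s0sq * nmin
            np.fill_diagonal(block, lam * nmin)
            cov[j1 * k:(j1 + 1) * k, j2 * k:(j2 + 1) * k] = block
    return ScoreDistribution(arms=arms, stages=stages, mean=mean, cov=cov)
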