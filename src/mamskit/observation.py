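"""Per-arm sufficient statistics at each analysis of a MAMS trial.

The container stores incremental (between-analysis) summaries -- sample
size, mean, sum of squared deviations -- per arm and stage, and derives the
cumulative quantities the two testing procedures need: effect estimates
deltahat_ij, estimated Fisher information

    Ihat_ij = n_0j * (sigmahat_0j^2 + sigmahat_ij^2 / lambda_i)^{-1}
            = (sigmahat_0j^2 / n_0j + sigmahat_ij^2 / n_ij)^{-1},

score statistics W_ij = deltahat_ij * Ihat_ij, and their incremental-stage
counterparts.  Variances use divisor (n - 1); pooling happens only within
each (arm, control) pair through the information formula, never across
treatment arms.  Known-variance evaluation (plugging the true sigmas into
the same formulas) is supported for exact-alpha studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StageObservation"]


@dataclass
class StageObservation:
    """Observed summaries of a trial through ``n_stages_observed`` analyses.

    Arrays have shape (J_obs, D+1); column 0 is the control arm.  ``inc_n``
    may be zero for arms not enrolled during a stage (dropped arms).
    """

    inc_n: np.ndarray      # incremental sample sizes
    inc_mean: np.ndarray   # incremental sample means (nan where inc_n == 0)
    inc_ss: np.ndarray     # incremental sums of squared deviations

    def __post_init__(self):
        self.inc_n = np.atleast_2d(np.asarray(self.inc_n, dtype=float))
        self.inc_mean = np.atleast_2d(np.asarray(self.inc_mean, dtype=float))
        self.inc_ss = np.atleast_2d(np.asarray(self.inc_ss, dtype=float))
        if not (self.inc_n.shape == self.inc_mean.shape == self.inc_ss.shape):
            raise ValueError("incremental summary arrays must share a shape")
        if np.any(self.inc_n[0] < 2):
            raise ValueError("every arm needs >= 2 first-stage observations")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_patient_data(cls, stages) -> "StageObservation":
        """``stages`` is a list over analyses of lists over arms (control
        first) of 1-d response arrays; empty arrays mark unenrolled arms."""
        n, mean, ss = [], [], []
        for stage in stages:
            n.append([len(x) for x in stage])
            mean.append([float(np.mean(x)) if len(x) else np.nan
                         for x in stage])
            ss.append([float(np.sum((np.asarray(x) - np.mean(x)) ** 2))
                       if len(x) else 0.0 for x in stage])
        return cls(np.array(n, float), np.array(mean), np.array(ss))

    @classmethod
    def from_summary(cls, df: pd.DataFrame) -> "StageObservation":
        """Build from a tidy table with columns arm, stage, n, mean, sd
        (incremental per-stage summaries; arm 0 = control, stage 1-based)."""
        required = {"arm", "stage", "n", "mean", "sd"}
        if not required.issubset(df.columns):
            raise ValueError("summary table needs columns %s" % sorted(required))
        J = int(df["stage"].max())
        D = int(df["arm"].max())
        inc_n = np.zeros((J, D + 1))
        inc_mean = np.full((J, D + 1), np.nan)
        inc_ss = np.zeros((J, D + 1))
        for _, row in df.iterrows():
            j, i = int(row["stage"]) - 1, int(row["arm"])
            inc_n[j, i] = row["n"]
            inc_mean[j, i] = row["mean"]
            inc_ss[j, i] = row["sd"] ** 2 * max(row["n"] - 1, 0)
        return cls(inc_n, inc_mean, inc_ss)

    # -- cumulative summaries ----------------------------------------------
    @property
    def n_stages_observed(self) -> int:
        return self.inc_n.shape[0]

    @property
    def n_arms(self) -> int:
        return self.inc_n.shape[1] - 1

    @property
    def cum_n(self) -> np.ndarray:
        return np.cumsum(self.inc_n, axis=0)

    def _pooled(self):
        """Stage-by-stage pairwise pooling of (n, mean, ss)."""
        J, A = self.inc_n.shape
        cn = np.zeros((J, A)); cm = np.zeros((J, A)); css = np.zeros((J, A))
        n = np.zeros(A); m = np.zeros(A); ss = np.zeros(A)
        for j in range(J):
            nj = self.inc_n[j]
            mj = np.where(nj > 0, self.inc_mean[j], 0.0)
            tot = n + nj
            with np.errstate(invalid="ignore", divide="ignore"):
                d = mj - m
                extra = np.where((n > 0) & (nj > 0), n * nj / tot * d * d, 0.0)
                ss = ss + self.inc_ss[j] + extra
                m = np.where(tot > 0, (n * m + nj * mj) / tot, 0.0)
            n = tot
            cn[j], cm[j], css[j] = n, m, ss
        return cn, cm, css

    @property
    def cum_mean(self) -> np.ndarray:
        return self._pooled()[1]

    @property
    def cum_ss(self) -> np.ndarray:
        """Cumulative sums of squared deviations about the cumulative mean."""
        return self._pooled()[2]

    def cum_var(self) -> np.ndarray:
        """Cumulative sample variances, divisor (n - 1)."""
        return self.cum_ss / np.maximum(self.cum_n - 1, 1)

    def inc_var(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.inc_n > 1,
                            self.inc_ss / np.maximum(self.inc_n - 1, 1),
                            np.nan)

    # -- test statistics ----------------------------------------------------
    def delta_hat(self, stage: int) -> np.ndarray:
        """Cumulative effect estimates x̄_ij - x̄_0j, length D."""
        cm = self.cum_mean[stage - 1]
        return cm[1:] - cm[0]

    def est_info(self, stage: int, incremental: bool = False,
                 known_variances=None) -> np.ndarray:
        """Estimated (or known-variance) Fisher information per arm.

        Uses the realized sample sizes: Ihat = (s0^2/n0 + si^2/ni)^{-1},
        with s^2 the cumulative (or incremental) sample variances unless
        ``known_variances`` supplies the true values (control first).
        """
        j = stage - 1
        n = self.inc_n[j] if incremental else self.cum_n[j]
        if known_variances is not None:
            v = np.asarray(known_variances, dtype=float)
        else:
            v = self.inc_var()[j] if incremental else self.cum_var()[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 1.0 / (v[0] / n[0] + v[1:] / n[1:])
        return np.where(n[1:] > 0, out, 0.0)

    def score(self, stage: int, incremental: bool = False,
              known_variances=None) -> np.ndarray:
        """Score statistics W_ij = deltahat * Ihat (incremental uses the
        between-analysis data only)."""
        if incremental:
            m = self.inc_mean[stage - 1]
            d = np.where(self.inc_n[stage - 1, 1:] > 0, m[1:] - m[0], np.nan)
        else:
            d = self.delta_hat(stage)
        return d * self.est_info(stage, incremental, known_variances)

    def wald(self, stage: int, incremental: bool = False,
             known_variances=None) -> np.ndarray:
        """Wald/t-scale statistics deltahat * sqrt(Ihat)."""
        info = self.est_info(stage, incremental, known_variances)
        if incremental:
            m = self.inc_mean[stage - 1]
            d = m[1:] - m[0]
        else:
            d = self.delta_hat(stage)
        return d * np.sqrt(info)

    def truncated(self, stage: int) -> "StageObservation":
        """Observations through ``stage`` only."""
        return StageObservation(self.inc_n[:stage], self.inc_mean[:stage],
                                self.inc_ss[:stage])
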