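"""Declarative description of a multiarm multistage (MAMS) design.

A design compares D treatment arms (indexed 1..D) to a shared control arm
(index 0) over J analyses.  Patients are randomized treatment:control at
ratio ``lambda_i``; responses are normal with per-arm variances.  The spec
object carries everything needed to derive boundaries and to simulate:
sample-size schedule, one-sided alpha, error-spending shape, the interim
treatment-selection rule, the reallocation rule for dropped arms' unspent
sample, and the prespecified inverse-normal weights of the stage-wise test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["DesignSpec", "socrates_design"]

_REALLOCATION_RULES = ("proportional_upscaling", "none")
_SPENDING_FUNCTIONS = ("ldobf",)


@dataclass(frozen=True)
class DesignSpec:
    """Full declarative MAMS design.

    Parameters
    ----------
    n_arms : number of treatment arms D (control excluded).
    n_stages : number of analyses J.
    allocation : per-treatment randomization ratios lambda_i (treatment:control).
    variances : response variances (sigma_0^2, sigma_1^2, ..., sigma_D^2),
        control first.
    control_stage_sizes : cumulative control-arm sample sizes n_0j, strictly
        increasing.  Treatment arms enroll round(lambda_i * n_0j).
    one_sided_alpha : overall one-sided familywise level, in (0, 0.5).
    spending : error-spending function identifier ("ldobf" = Lan-DeMets
        O'Brien-Fleming type).
    selection_threshold : drop arm i at the first interim if the observed
        effect estimate falls below this value (response units); ``-inf``
        disables dropping.
    reallocation_rule : "proportional_upscaling" redistributes dropped arms'
        unspent enrollment over continuing arms in proportion to allocation,
        "none" simply does not enroll it.
    weights : inverse-normal stage weights h_j with sum of squares 1;
        default sqrt of the planned incremental information share.
    """

    n_arms: int
    n_stages: int
    allocation: tuple = None
    variances: tuple = None
    control_stage_sizes: tuple = None
    one_sided_alpha: float = 0.025
    spending: str = "ldobf"
    selection_threshold: float = -math.inf
    reallocation_rule: str = "proportional_upscaling"
    weights: tuple = None

    def __post_init__(self):
        D, J = self.n_arms, self.n_stages
        if D < 1 or J < 1:
            raise ValueError("need at least one treatment arm and one stage")
        alloc = tuple(map(float, self.allocation if self.allocation is not None
                          else (1.0,) * D))
        if len(alloc) != D or any(a <= 0 for a in alloc):
            raise ValueError("allocation must hold %d positive ratios" % D)
        var = tuple(map(float, self.variances if self.variances is not None
                        else (1.0,) * (D + 1)))
        if len(var) != D + 1 or any(v <= 0 for v in var):
            raise ValueError("variances must hold %d positive values "
                             "(control first)" % (D + 1))
        if self.control_stage_sizes is None:
            raise ValueError("control_stage_sizes is required")
        n0 = tuple(int(n) for n in self.control_stage_sizes)
        if len(n0) != J or any(n <= 0 for n in n0) or \
                any(b <= a for a, b in zip(n0, n0[1:])):
            raise ValueError("control_stage_sizes must be %d strictly "
                             "increasing positive integers" % J)
        if not 0.0 < self.one_sided_alpha < 0.5:
            raise ValueError("one_sided_alpha must be in (0, 0.5)")
        if self.spending not in _SPENDING_FUNCTIONS:
            raise ValueError("unknown spending function %r" % (self.spending,))
        if self.reallocation_rule not in _REALLOCATION_RULES:
            raise ValueError("unknown reallocation rule %r"
                             % (self.reallocation_rule,))
        if self.weights is None:
            frac = np.diff(np.r_[0.0, np.asarray(n0) / n0[-1]])
            w = tuple(float(x) for x in np.sqrt(frac / frac.sum()))
        else:
            w = tuple(map(float, self.weights))
        if len(w) != J or any(h <= 0 for h in w):
            raise ValueError("weights must hold %d positive values" % J)
        if abs(sum(h * h for h in w) - 1.0) > 1e-12:
            raise ValueError("stage weights must satisfy sum h_j^2 = 1")
        object.__setattr__(self, "allocation", alloc)
        object.__setattr__(self, "variances", var)
        object.__setattr__(self, "control_stage_sizes", n0)
        object.__setattr__(self, "weights", w)

    # -- derived quantities -------------------------------------------------
    @property
    def arm_stage_sizes(self):
        """Cumulative per-arm sample sizes, shape (J, D+1); column 0 = control.

        Treatment arms follow n_ij = round(lambda_i * n_0j) (nearest integer,
        half away from zero)."""
        n0 = np.asarray(self.control_stage_sizes, dtype=float)
        lam = np.asarray(self.allocation)
        out = np.empty((self.n_stages, self.n_arms + 1), dtype=int)
        out[:, 0] = n0.astype(int)
        out[:, 1:] = np.floor(lam[None, :] * n0[:, None] + 0.5).astype(int)
        return out

    @property
    def info_fractions(self):
        n0 = np.asarray(self.control_stage_sizes, dtype=float)
        return n0 / n0[-1]

    @property
    def total_planned(self) -> int:
        return int(self.arm_stage_sizes[-1].sum())

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("allocation", "variances", "control_stage_sizes", "weights"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "DesignSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError("unknown design keys: %s" % sorted(unknown))
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DesignSpec":
        return cls.from_dict(json.loads(text))


def socrates_design(n_stages: int = 2, sigma: float = 0.52,
                    selection_threshold: float = 0.0,
                    reallocation_rule: str = "proportional_upscaling",
                    n_per_arm: int = 97, n_arms: int = 3,
                    alpha: float = 0.025) -> DesignSpec:
    """Seamless phase 2-3 design modeled on the SOCRATES-REDUCED trial.

    Three vericiguat dose arms versus placebo, 97 patients per arm (the
    single-stage Dunnett sample size for 80% power at delta = 0.187,
    sigma = 0.52), equally spaced analyses, one-sided alpha 0.025, arms with
    interim effect estimates below the threshold dropped at the first look.
    """
    looks = tuple(int(math.floor(n_per_arm * j / n_stages + 0.5))
                  for j in range(1, n_stages + 1))
    return DesignSpec(
        n_arms=n_arms, n_stages=n_stages,
        variances=(sigma ** 2,) * (n_arms + 1),
        control_stage_sizes=looks,
        one_sided_alpha=alpha,
        selection_threshold=selection_threshold,
        reallocation_rule=reallocation_rule,
    )
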