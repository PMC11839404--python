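"""Closed-form companions and summary statistics for the damage model.

Fragment lengths under per-junction nicking at rate ``nu`` are geometric,
so the theoretical median read length is ``floor(-ln 2 / ln(1 - nu))``.
The per-position misincorporation profile follows from mixing the
geometric overhang-length distribution with the 50/50 overhang-side draw,
giving the characteristic "U" shape: elevated C->T near the 5' end and
G->A near the 3' end.  A standardized (z-scored predictors) ordinary
least squares fit of expected node distance against the four damage
parameters quantifies which parameter drives placement error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .damage import DamagedRead, DamageParameters

__all__ = [
    "DamageProfile",
    "FitResult",
    "theoretical_median_fragment_length",
    "expected_damage_profile",
    "per_read_error_rate",
    "crossover_overhang_length",
    "standardized_linear_fit",
    "PREDICTORS",
]

PREDICTORS = ("nu", "lam", "delta_ds", "delta_ss")


@dataclass
class DamageProfile:
    """Expected per-position misincorporation probabilities for a read
    population of fixed length, conditional on the base being eligible
    (C for C->T, G for G->A).  Positions are 0-based from the 5' end."""

    c_to_t: np.ndarray
    g_to_a: np.ndarray

    @property
    def read_length(self) -> int:
        return len(self.c_to_t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(self.read_length),
                "c_to_t": self.c_to_t,
                "g_to_a": self.g_to_a,
            }
        )


@dataclass
class FitResult:
    """Standardized OLS fit of eND against the damage parameters."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    intercept: float
    residual_variance: float


def theoretical_median_fragment_length(nu: float) -> float:
    """Median fragment length implied by per-junction nick rate ``nu``.

    Interior fragment lengths are geometric with success probability
    ``nu``; the median is ``floor(-ln 2 / ln(1 - nu))`` (at least 1), and
    infinite when ``nu`` is 0.
    """
    if not 0.0 <= nu <= 1.0:
        raise ValueError(f"nu must be in [0, 1], got {nu}")
    if nu == 0.0:
        return math.inf
    if nu == 1.0:
        return 1
    return max(1, math.floor(-math.log(2.0) / math.log1p(-nu)))


def expected_damage_profile(params: DamageParameters, read_len: int) -> DamageProfile:
    """Closed-form per-position misincorporation probabilities.

    At 0-based position ``i`` from the 5' end, the chance that the
    position lies inside a 5' overhang of geometric length L is
    ``P(L > i) = (1 - lam)^(i+1)``, and the read carries a 5' overhang
    with probability 1/2, so::

        P(C->T at i) = 0.5 * [ (1-lam)^(i+1) * delta_ss
                               + (1 - (1-lam)^(i+1)) * delta_ds ]

    (on the other half of reads, with a 3' overhang, no C->T occurs at
    all).  G->A mirrors the formula from the 3' end.  Values are
    conditional on the base being eligible.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    i = np.arange(read_len)
    p_overhang = (1.0 - params.lam) ** (i + 1)
    c_to_t = 0.5 * (p_overhang * params.delta_ss + (1.0 - p_overhang) * params.delta_ds)
    return DamageProfile(c_to_t=c_to_t, g_to_a=c_to_t[::-1].copy())


def per_read_error_rate(read: DamagedRead) -> float:
    """Fraction of a read's non-gap sites that were misincorporated."""
    n = read.nongap_length
    if n == 0:
        raise ValueError(f"read {read.read_id!r} has zero non-gap length")
    return len(read.events) / n


def crossover_overhang_length(
    read_len: int, delta_ss: float, delta_ds: float
) -> int:
    """Smallest overhang length whose expected single-stranded deamination
    count exceeds the double-stranded expectation of the whole read:
    the least integer k with ``k * delta_ss > read_len * delta_ds``."""
    if delta_ss <= 0.0:
        raise ValueError("delta_ss must be > 0 for a crossover to exist")
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    k = math.floor(read_len * delta_ds / delta_ss) + 1
    return max(1, k)


def standardized_linear_fit(table: pd.DataFrame) -> FitResult:
    """OLS of ``end`` on z-scored damage parameters.

    ``table`` needs columns ``nu, lam, delta_ds, delta_ss, end``.
    Standardizing the predictors (mean 0, SD 1) makes the coefficient
    magnitudes directly comparable across parameters with different
    scales; a predictor's standardized coefficient is invariant under any
    affine rescaling of that predictor.
    """
    for col in (*PREDICTORS, "end"):
        if col not in table.columns:
            raise ValueError(f"results table lacks column {col!r}")
    if len(table) < 6:
        raise ValueError("need at least 6 rows to fit the model")
    X = table[list(PREDICTORS)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    constant = [PREDICTORS[j] for j in range(len(PREDICTORS)) if sd[j] == 0.0]
    if constant:
        raise ValueError(
            "constant (zero-variance) predictors cannot be standardized: "
            + ", ".join(constant)
        )
    Z = (X - X.mean(axis=0)) / sd
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        corr = np.corrcoef(Z, rowvar=False)
        collinear = sorted(
            {
                name
                for a, b in zip(*np.where(np.abs(np.triu(corr, k=1)) > 1 - 1e-10))
                for name in (PREDICTORS[a], PREDICTORS[b])
            }
        )
        raise ValueError(
            "design is rank deficient; collinear predictors: "
            + (", ".join(collinear) if collinear else "undetermined")
        )
    y = table["end"].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(Z)).fit()
    coefs = dict(zip(PREDICTORS, fit.params[1:]))
    return FitResult(
        coefficients={k: float(v) for k, v in coefs.items()},
        std_errors=dict(zip(PREDICTORS, (float(v) for v in fit.bse[1:]))),
        p_values=dict(zip(PREDICTORS, (float(v) for v in fit.pvalues[1:]))),
        intercept=float(fit.params[0]),
        residual_variance=float(fit.scale),
    )
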