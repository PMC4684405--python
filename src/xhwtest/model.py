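"""Genotype-frequency model for a biallelic X-linked marker with inbreeding.

Males are hemizygous, so their data are allele counts (``n1m`` copies of M1,
``n0m`` of M2).  Female genotype frequencies follow the inbreeding model

.. math::

    P(M_1M_1) = p_f^2 + \\rho p_f q_f,\\quad
    P(M_1M_2) = 2(1-\\rho) p_f q_f,\\quad
    P(M_2M_2) = q_f^2 + \\rho p_f q_f,

where :math:`p_f` is the female M1 allele frequency, :math:`q_f = 1 - p_f`
and :math:`\\rho \\ge 0` is the female inbreeding coefficient.  ``rho = 0``
recovers Hardy-Weinberg proportions; ``rho > 0`` means excess homozygosity.

Two departures are of interest when vetting X-linked markers: unequal male
and female allele frequencies, and excess female homozygosity.  The module
encodes the four hypotheses used throughout the package:

* ``H0``:  p_m = p_f and rho = 0 (both in order),
* ``H01``: p_m = p_f (rho free),
* ``H02``: rho = 0 (p_m, p_f free),
* ``H1``:  unconstrained (p_m, p_f free, rho >= 0).

All likelihood computations are in log space and drop the multinomial
coefficients, which cancel in every likelihood ratio formed here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeCounts",
    "ModelParams",
    "Hypothesis",
    "InvalidParameterError",
    "UndefinedStatisticError",
    "female_genotype_freqs",
    "log_likelihood",
]


class InvalidParameterError(ValueError):
    """Raised when model parameters yield a negative genotype probability."""


class UndefinedStatisticError(ValueError):
    """A statistic or estimator is undefined for these counts.

    Typically raised at monomorphic loci, where variance estimates vanish.
    Batch front ends catch this and report the statistic as missing rather
    than aborting the run.
    """


class Hypothesis(str, enum.Enum):
    """Constraint labels for the testing problems on the X chromosome."""

    H0 = "H0"    # p_m = p_f and rho = 0
    H01 = "H01"  # p_m = p_f, rho free
    H02 = "H02"  # rho = 0, frequencies free
    H1 = "H1"    # unconstrained, rho >= 0


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed per-locus data.

    Parameters
    ----------
    n1m, n0m
        Numbers of males carrying allele M1 and M2 respectively.
    n2f, n1f, n0f
        Numbers of females with genotype M1M1, M1M2 and M2M2 respectively.
    """

    n1m: int
    n0m: int
    n2f: int
    n1f: int
    n0f: int

    def __post_init__(self) -> None:
        for name in ("n1m", "n0m", "n2f", "n1f", "n0f"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def Nm(self) -> int:
        """Number of males."""
        return self.n1m + self.n0m

    @property
    def Nf(self) -> int:
        """Number of females."""
        return self.n2f + self.n1f + self.n0f

    @property
    def N(self) -> int:
        """Total sample size."""
        return self.Nm + self.Nf

    def swap_alleles(self) -> "GenotypeCounts":
        """Counts with the M1/M2 labels interchanged."""
        return GenotypeCounts(self.n0m, self.n1m, self.n0f, self.n1f, self.n2f)

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.n1m, self.n0m, self.n2f, self.n1f, self.n0f)


@dataclass(frozen=True)
class ModelParams:
    """Model parameters (p_m, p_f, rho); rho is restricted to [0, 1]."""

    p_m: float
    p_f: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_m <= 1.0:
            raise InvalidParameterError(f"p_m must be in [0, 1], got {self.p_m}")
        if not 0.0 <= self.p_f <= 1.0:
            raise InvalidParameterError(f"p_f must be in [0, 1], got {self.p_f}")
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidParameterError(f"rho must be in [0, 1], got {self.rho}")

    @property
    def q_m(self) -> float:
        return 1.0 - self.p_m

    @property
    def q_f(self) -> float:
        return 1.0 - self.p_f


def female_genotype_freqs(p_f: float, rho: float) -> tuple[float, float, float]:
    """Female genotype frequencies (P(M1M1), P(M1M2), P(M2M2)).

    ``rho = 0`` gives Hardy-Weinberg proportions ``(p^2, 2pq, q^2)``;
    ``rho = 1`` collapses the heterozygote class.

    Raises
    ------
    InvalidParameterError
        If any of the three probabilities would be negative (cannot happen
        for ``0 <= rho <= 1``; guards the mathematically wider model).
    """
    q_f = 1.0 - p_f
    if not 0.0 <= p_f <= 1.0:
        raise InvalidParameterError(f"p_f must be in [0, 1], got {p_f}")
    pq = p_f * q_f
    probs = (p_f * p_f + rho * pq, 2.0 * (1.0 - rho) * pq, q_f * q_f + rho * pq)
    if min(probs) < 0.0:
        raise InvalidParameterError(
            f"negative genotype probability for p_f={p_f}, rho={rho}: {probs}"
        )
    return probs


def _xlogy(x: float, y: float) -> float:
    # 0 * log(0) = 0 convention; positive count on a zero-probability cell -> -inf
    if x == 0.0:
        return 0.0
    if y <= 0.0:
        return -math.inf
    return x * math.log(y)


def log_likelihood(counts: GenotypeCounts, params: ModelParams) -> float:
    """Observed-data log-likelihood, multinomial coefficients omitted.

    The male contribution is binomial in the allele count; the female
    contribution is multinomial over the three genotype classes with the
    inbreeding-model frequencies.  Cells with zero count contribute zero
    (``0 ln 0 = 0``); a positive count on a zero-probability cell gives
    ``-inf``.
    """
    f2, f1, f0 = female_genotype_freqs(params.p_f, params.rho)
    return (
        _xlogy(counts.n1m, params.p_m)
        + _xlogy(counts.n0m, params.q_m)
        + _xlogy(counts.n2f, f2)
        + _xlogy(counts.n1f, f1)
        + _xlogy(counts.n0f, f0)
    )


# ---------------------------------------------------------------------------
# Vectorized internals shared with the estimators and simulation modules.
# Arrays hold one locus/replicate per element.
# ---------------------------------------------------------------------------

def _female_freqs_arrays(p_f: np.ndarray, rho: np.ndarray):
    q_f = 1.0 - p_f
    pq = p_f * q_f
    return p_f * p_f + rho * pq, 2.0 * (1.0 - rho) * pq, q_f * q_f + rho * pq


def _loglik_arrays(n1m, n0m, n2f, n1f, n0f, p_m, p_f, rho) -> np.ndarray:
    """Vectorized observed-data log-likelihood (constants omitted)."""
    from scipy.special import xlogy

    f2, f1, f0 = _female_freqs_arrays(np.asarray(p_f, float), np.asarray(rho, float))
    q_m = 1.0 - np.asarray(p_m, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            xlogy(n1m, p_m)
            + xlogy(n0m, q_m)
            + xlogy(n2f, f2)
            + xlogy(n1f, f1)
            + xlogy(n0f, f0)
        )
    # xlogy already returns 0 for 0*log(0) and -inf for n>0, p=0
    return ll
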