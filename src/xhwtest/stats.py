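"""Per-locus test statistics and asymptotic p-values.

Moment tests
    * ``Z1`` -- equality of male and female allele frequencies (chi2, 1 df),
    * ``Z2`` -- zero inbreeding coefficient, females only (chi2, 1 df),
    * ``Z0 = Z1 + Z2`` -- both at once (chi2, 2 df; the components are
      asymptotically independent under the joint null).

Likelihood-ratio tests
    * ``LRT0`` -- H0 (equal frequencies and rho = 0) vs unconstrained, 2 df,
    * ``LRT1`` -- H01 (equal frequencies, rho free) vs unconstrained, 1 df,
    * ``LRT2`` -- H02 (rho = 0) vs unconstrained, 1 df.

The rho = 0 null sits on the boundary of the parameter space, so the
chi-square reference distribution makes LRT0 and LRT2 conservative; their
bootstrap-calibrated counterparts live in :mod:`xhwtest.bootstrap`.

``dc_variants`` recomputes LRT0 and LRT1 under the dosage-compensation
allele-counting convention (each male allele counted twice).  Z1, Z2, Z0
and LRT2 are unaffected by that convention by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2

from .model import GenotypeCounts, UndefinedStatisticError
from .estimators import (
    EMConfig,
    _em_h1_arrays,
    _em_h01_arrays,
    _loglik_h01_arrays,
    _female_ll_arrays,
    fit_h0,
    fit_h01,
    fit_h02,
    fit_h1,
)

__all__ = ["TestResult", "z1", "z2", "z0", "lrt0", "lrt1", "lrt2", "dc_variants"]

# negative LRT values larger than this (10x the EM parameter tolerance)
# indicate an internal inconsistency rather than convergence noise
_LRT_NEG_TOL = 1e-6

_DF = {"Z1": 1, "Z2": 1, "Z0": 2, "LRT0": 2, "LRT1": 1, "LRT2": 1}


@dataclass
class TestResult:
    """One statistic at one locus.

    ``df`` is None for bootstrap-calibrated results.  ``converged`` is
    False when an underlying EM fit hit its iteration cap.
    """

    name: str
    statistic: float
    df: Optional[int]
    p_value: float
    calibration: str = "asymptotic"
    converged: bool = True
    n_resamples: Optional[int] = None
    n_resamples_nonconverged: int = 0


def _chi2_result(name: str, statistic: float, converged: bool = True) -> TestResult:
    df = _DF[name]
    return TestResult(name, statistic, df, float(chi2.sf(statistic, df)),
                      "asymptotic", converged)


def _clip_lrt(value: float) -> float:
    if value < -_LRT_NEG_TOL:
        raise RuntimeError(
            f"likelihood-ratio statistic {value} is negative beyond convergence "
            "tolerance; constrained fit beat the unconstrained one"
        )
    return max(value, 0.0)


# ---------------------------------------------------------------------------
# Moment tests
# ---------------------------------------------------------------------------

def z1(counts: GenotypeCounts) -> TestResult:
    """Allele-frequency equality test (1 df).

    ``Z1 = (p_m - p_f)^2 / (Var(p_m) + Var(p_f))`` with
    ``Var(p_m) = p_m q_m / Nm`` and
    ``Var(p_f) = [p_f - 2 p_f^2 + P(M1M1)] / (2 Nf)``.
    """
    if counts.Nm < 1 or counts.Nf < 1:
        raise UndefinedStatisticError("Z1 requires males and females")
    pm = counts.n1m / counts.Nm
    pf = (2 * counts.n2f + counts.n1f) / (2 * counts.Nf)
    p11 = counts.n2f / counts.Nf
    var = pm * (1 - pm) / counts.Nm + (pf - 2 * pf * pf + p11) / (2 * counts.Nf)
    if var <= 0.0:
        raise UndefinedStatisticError("Z1 undefined: zero variance (monomorphic)")
    return _chi2_result("Z1", (pm - pf) ** 2 / var)


def z2(counts: GenotypeCounts) -> TestResult:
    """Excess-homozygosity test (1 df, females only).

    ``Z2 = Nf [Delta_f + p_f q_f / (2 Nf)]^2 / (p_f^2 q_f^2)`` where
    ``Delta_f = P(M1M1) - p_f^2`` is the disequilibrium coefficient;
    the ``p_f q_f / (2 Nf)`` term removes the finite-sample bias of
    ``Delta_f``.
    """
    if counts.Nf < 1:
        raise UndefinedStatisticError("Z2 requires females")
    pf = (2 * counts.n2f + counts.n1f) / (2 * counts.Nf)
    if pf <= 0.0 or pf >= 1.0:
        raise UndefinedStatisticError("Z2 undefined for monomorphic females")
    qf = 1.0 - pf
    delta = counts.n2f / counts.Nf - pf * pf
    stat = counts.Nf * (delta + pf * qf / (2 * counts.Nf)) ** 2 / (pf * pf * qf * qf)
    return _chi2_result("Z2", stat)


def z0(counts: GenotypeCounts) -> TestResult:
    """Joint test ``Z0 = Z1 + Z2`` (2 df)."""
    stat = z1(counts).statistic + z2(counts).statistic
    return _chi2_result("Z0", stat)


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

def lrt0(counts: GenotypeCounts, config: EMConfig = EMConfig()) -> TestResult:
    """LRT of H0 (p_m = p_f, rho = 0) against the unconstrained model, 2 df."""
    f1 = fit_h1(counts, config)
    f0 = fit_h0(counts)
    stat = _clip_lrt(2.0 * (f1.loglik - f0.loglik))
    return _chi2_result("LRT0", stat, f1.converged)


def lrt1(counts: GenotypeCounts, config: EMConfig = EMConfig()) -> TestResult:
    """LRT of H01 (p_m = p_f, rho free) against the unconstrained model, 1 df."""
    f1 = fit_h1(counts, config)
    f01 = fit_h01(counts, config)
    stat = _clip_lrt(2.0 * (f1.loglik - f01.loglik))
    return _chi2_result("LRT1", stat, f1.converged and f01.converged)


def lrt2(counts: GenotypeCounts, config: EMConfig = EMConfig()) -> TestResult:
    """LRT of H02 (rho = 0) against the unconstrained model, 1 df.

    The male likelihood terms are identical in the numerator and
    denominator, so the statistic depends on the female counts only.
    """
    f1 = fit_h1(counts, config)
    f02 = fit_h02(counts)
    stat = _clip_lrt(2.0 * (f1.loglik - f02.loglik))
    return _chi2_result("LRT2", stat, f1.converged)


def dc_variants(counts: GenotypeCounts, config: EMConfig = EMConfig()) -> dict:
    """LRT0 and LRT1 under dosage-compensation allele counting.

    Every male allele is counted twice (equivalently, every female allele
    half), so pooled-frequency estimation becomes
    ``p = (2 n1m + 2 n2f + n1f) / (2 Nm + 2 Nf)`` and the male likelihood
    exponents double.  The sex-separate fits (and hence Z1, Z2, Z0, LRT2)
    are unchanged.  Returns ``{"LRT0": TestResult, "LRT1": TestResult}``.
    """
    arrs = [np.array([float(v)]) for v in counts.as_tuple()]
    stats = _lrt_stats_arrays(*arrs, config=config, male_weight=2.0)
    out = {}
    for name in ("LRT0", "LRT1"):
        stat = _clip_lrt(float(stats[name][0]))
        res = _chi2_result(name, stat, bool(stats["converged"][0]))
        out[name] = res
    return out


# ---------------------------------------------------------------------------
# Vectorized internals (used by the simulation engine and the bootstrap)
# ---------------------------------------------------------------------------

def _z_stats_arrays(n1m, n0m, n2f, n1f, n0f):
    """Z1, Z2, Z0 elementwise; NaN where undefined (monomorphic)."""
    n1m, n0m, n2f, n1f, n0f = (np.asarray(a, float) for a in (n1m, n0m, n2f, n1f, n0f))
    Nm = n1m + n0m
    Nf = n2f + n1f + n0f
    with np.errstate(invalid="ignore", divide="ignore"):
        pm = n1m / Nm
        pf = (2 * n2f + n1f) / (2 * Nf)
        p11 = n2f / Nf
        qf = 1.0 - pf
        var1 = pm * (1 - pm) / Nm + (pf - 2 * pf * pf + p11) / (2 * Nf)
        z1s = np.where(var1 > 0, (pm - pf) ** 2 / var1, np.nan)
        delta = p11 - pf * pf
        den2 = pf * pf * qf * qf
        z2s = np.where(den2 > 0,
                       Nf * (delta + pf * qf / (2 * Nf)) ** 2 / den2, np.nan)
    return z1s, z2s, z1s + z2s


def _lrt_stats_arrays(n1m, n0m, n2f, n1f, n0f, *, config: EMConfig = EMConfig(),
                      which=("LRT0", "LRT1", "LRT2"), male_weight: float = 1.0):
    """LRT statistics (and fitted parameters) elementwise.

    Returns a dict with the requested statistics (floored at 0), the
    unconstrained fits ``pm``, ``pf1``, ``rho1``, the H01 fits ``p01``,
    ``rho01`` (when LRT1 requested), the pooled ``p0`` (when LRT0
    requested), and a ``converged`` flag.
    """
    n1m, n0m, n2f, n1f, n0f = (np.asarray(a, float) for a in (n1m, n0m, n2f, n1f, n0f))
    Nm = n1m + n0m
    Nf = n2f + n1f + n0f
    c = float(male_weight)
    kw = dict(tolerance=config.tolerance, max_iter=config.max_iter,
              rho_init=config.rho_init)

    pf1, rho1, _, conv1, ident1 = _em_h1_arrays(n2f, n1f, n0f, **kw)
    with np.errstate(invalid="ignore", divide="ignore"):
        pm = np.where(Nm > 0, n1m / Nm, np.nan)
        pm_safe = np.where(Nm > 0, n1m / np.maximum(Nm, 1), 0.5)  # no males: term is 0
        ll_m = xlogy(n1m, pm_safe) + xlogy(n0m, 1.0 - pm_safe)
    ll_f1 = _female_ll_arrays(n2f, n1f, n0f, pf1, rho1)
    ll_h1 = c * ll_m + ll_f1

    out = {"pm": pm, "pf1": pf1, "rho1": rho1, "rho1_identifiable": ident1}
    converged = conv1

    if "LRT0" in which:
        m1 = c * n1m + 2 * n2f + n1f
        m0 = c * n0m + n1f + 2 * n0f
        with np.errstate(invalid="ignore", divide="ignore"):
            p0 = m1 / (m1 + m0)
        ll_h0 = _loglik_h01_arrays(n1m, n0m, n2f, n1f, n0f, p0,
                                   np.zeros_like(p0), male_weight=c)
        out["LRT0"] = np.maximum(2.0 * (ll_h1 - ll_h0), 0.0)
        out["p0"] = p0
    if "LRT1" in which:
        p01, rho01, _, conv01, _ = _em_h01_arrays(n1m, n0m, n2f, n1f, n0f,
                                                  male_weight=c, **kw)
        ll_h01 = _loglik_h01_arrays(n1m, n0m, n2f, n1f, n0f, p01, rho01,
                                    male_weight=c)
        out["LRT1"] = np.maximum(2.0 * (ll_h1 - ll_h01), 0.0)
        out["p01"] = p01
        out["rho01"] = rho01
        converged = converged & conv01
    if "LRT2" in which:
        with np.errstate(invalid="ignore", divide="ignore"):
            pf02 = (2 * n2f + n1f) / (2 * Nf)
        ll_h02 = _female_ll_arrays(n2f, n1f, n0f, pf02, np.zeros_like(pf02))
        # male terms cancel: compare female log-likelihoods directly
        out["LRT2"] = np.maximum(2.0 * (ll_f1 - ll_h02), 0.0)
    out["converged"] = converged
    return out
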