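"""Maximum-likelihood estimation of (p_m, p_f, rho) under each hypothesis.

Closed forms exist under H0 (pooled allele frequency), H02 (sex-specific
frequencies, rho = 0) and for the moment estimator of rho.  Under H1 and
H01 the inbreeding coefficient requires an EM algorithm obtained by
splitting each female homozygote class into an "allele-copy" part and an
"identical-by-descent" part: the M1M1 cell of size ``n2f`` splits into
latent counts ``w1`` (probability ``p_f^2``) and ``w2`` (``rho p_f q_f``),
and the M2M2 cell into ``w3``/``w4`` analogously.  The E-step takes the
conditional expectations of the ``w``'s; the M-step is a weighted allele
count.  The male allele frequency decouples and equals ``n1m / Nm`` at
every iteration.

The EM core operates on numpy arrays (one locus or replicate per element),
which is what makes the Monte-Carlo and bootstrap machinery in
:mod:`xhwtest.simulate` affordable; the scalar ``fit_*`` functions wrap it.
After the iteration stops, the fit is compared against the analytic
rho = 0 boundary candidate and the better of the two is kept -- EM
converges sublinearly when the maximizer sits on the boundary, and this
polish removes the resulting tolerance-level likelihood deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    GenotypeCounts,
    Hypothesis,
    ModelParams,
    UndefinedStatisticError,
    _loglik_arrays,
    log_likelihood,
)

__all__ = [
    "EMConfig",
    "FitResult",
    "fit_h0",
    "fit_h01",
    "fit_h02",
    "fit_h1",
    "rho_moment",
]

_PF_EPS = 1e-6  # nudge for initial allele frequencies of exactly 0 or 1


@dataclass(frozen=True)
class EMConfig:
    """EM settings.

    tolerance
        Convergence threshold: iteration stops when every parameter moves
        by less than this between consecutive iterations (default 1e-7).
    max_iter
        Iteration cap (default 1000).
    rho_init
        Initial inbreeding coefficient (default 0.02).  Allele-frequency
        starting values are always the closed-form moment estimates.
    """

    tolerance: float = 1e-7
    max_iter: int = 1000
    rho_init: float = 0.02

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.rho_init < 1.0:
            raise ValueError("rho_init must be in (0, 1)")


@dataclass
class FitResult:
    """An ML fit under one hypothesis.

    ``n_iter`` is 0 for closed-form fits.  ``rho_identifiable`` is False
    when the data carry no information on rho (e.g. monomorphic females),
    in which case ``rho`` is reported as 0 by convention.  ``history``
    holds per-iteration ``(p_m, p_f, rho, loglik)`` tuples when the fit was
    run with ``record_history=True``.
    """

    hypothesis: Hypothesis
    params_hat: ModelParams
    loglik: float
    n_iter: int
    converged: bool
    rho_identifiable: bool = True
    history: Optional[list] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Closed-form fits
# ---------------------------------------------------------------------------

def fit_h0(counts: GenotypeCounts) -> FitResult:
    """MLE under H0 (p_m = p_f = p, rho = 0): pooled allele frequency.

    ``p_hat = (n1m + 2 n2f + n1f) / (Nm + 2 Nf)`` -- each male contributes
    one X allele, each female two.
    """
    denom = counts.Nm + 2 * counts.Nf
    if denom < 1:
        raise ValueError("empty sample")
    p = (counts.n1m + 2 * counts.n2f + counts.n1f) / denom
    params = ModelParams(p, p, 0.0)
    return FitResult(Hypothesis.H0, params, log_likelihood(counts, params), 0, True)


def fit_h02(counts: GenotypeCounts) -> FitResult:
    """MLE under H02 (rho = 0): sex-specific allele frequencies.

    ``p_m = n1m/Nm`` and ``p_f = (2 n2f + n1f)/(2 Nf)``.
    """
    if counts.Nm < 1 or counts.Nf < 1:
        raise ValueError("fit_h02 requires at least one male and one female")
    params = ModelParams(
        counts.n1m / counts.Nm, (2 * counts.n2f + counts.n1f) / (2 * counts.Nf), 0.0
    )
    return FitResult(Hypothesis.H02, params, log_likelihood(counts, params), 0, True)


def rho_moment(counts: GenotypeCounts) -> float:
    """Moment estimator of rho from the female homozygote excess.

    ``rho_z = (P_hat(M1M1) - p_f_hat^2) / (p_f_hat q_f_hat)`` with
    ``P_hat(M1M1) = n2f/Nf``.  Reported as-is; it can be negative
    (heterozygote excess), unlike the EM estimators which live in [0, 1].

    Raises
    ------
    UndefinedStatisticError
        If the females are monomorphic (p_f_hat is 0 or 1).
    """
    if counts.Nf < 1:
        raise UndefinedStatisticError("no females in sample")
    pf = (2 * counts.n2f + counts.n1f) / (2 * counts.Nf)
    if pf <= 0.0 or pf >= 1.0:
        raise UndefinedStatisticError(
            f"rho moment estimator undefined for monomorphic females (p_f={pf})"
        )
    p11 = counts.n2f / counts.Nf
    return (p11 - pf * pf) / (pf * (1.0 - pf))


# ---------------------------------------------------------------------------
# Vectorized EM cores
# ---------------------------------------------------------------------------

def _female_ll_arrays(n2f, n1f, n0f, pf, rho):
    z = np.zeros_like(np.asarray(pf, float))
    return _loglik_arrays(z, z, n2f, n1f, n0f, np.full_like(z, 0.5), pf, rho)


def _em_h1_arrays(n2f, n1f, n0f, *, tolerance=1e-7, max_iter=1000, rho_init=0.02):
    """EM for the female parameters (p_f, rho) under H1, elementwise.

    Returns ``(p_f, rho, n_iter, converged, rho_identifiable)`` arrays.
    Degenerate configurations get their analytic boundary MLEs:
    no heterozygotes with both homozygote classes present -> rho = 1;
    all heterozygotes -> rho = 0, p_f = 1/2; monomorphic females -> rho
    non-identifiable, reported 0.
    """
    n2f = np.asarray(n2f, dtype=float)
    n1f = np.asarray(n1f, dtype=float)
    n0f = np.asarray(n0f, dtype=float)
    shape = np.broadcast_shapes(n2f.shape, n1f.shape, n0f.shape)
    n2f, n1f, n0f = (np.broadcast_to(a, shape).ravel() for a in (n2f, n1f, n0f))
    Nf = n2f + n1f + n0f
    n = Nf.size

    pf = np.full(n, np.nan)
    rho = np.full(n, np.nan)
    n_iter = np.zeros(n, dtype=np.int64)
    converged = np.ones(n, dtype=bool)
    identifiable = np.ones(n, dtype=bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        pf_closed = np.where(Nf > 0, (2.0 * n2f + n1f) / (2.0 * Nf), np.nan)

    empty = Nf == 0
    mono = (~empty) & (n1f == 0) & ((n2f == 0) | (n0f == 0))
    allhet = (n2f == 0) & (n0f == 0) & (n1f > 0)
    nohet = (n1f == 0) & (n2f > 0) & (n0f > 0)
    em = ~(empty | mono | allhet | nohet)

    identifiable[empty | mono] = False
    pf[mono] = pf_closed[mono]
    rho[mono] = 0.0
    pf[allhet] = 0.5
    rho[allhet] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pf[nohet] = (n2f / Nf)[nohet]
    rho[nohet] = 1.0

    idx = np.flatnonzero(em)
    if idx.size:
        a2, a1, a0, aNf = n2f[idx], n1f[idx], n0f[idx], Nf[idx]
        p = np.clip(pf_closed[idx], _PF_EPS, 1.0 - _PF_EPS)
        r = np.full(idx.size, float(rho_init))
        k = 0
        while idx.size and k < max_iter:
            k += 1
            q = 1.0 - p
            pq = p * q
            d2 = p * p + r * pq
            d0 = q * q + r * pq
            w1 = a2 * (p * p) / d2
            w2 = a2 - w1
            w3 = a0 * (q * q) / d0
            w4 = a0 - w3
            p_new = (2.0 * w1 + w2 + a1 + w4) / (2.0 * aNf)
            r_new = (w2 + w4) / (w2 + w4 + a1)
            done = (np.abs(p_new - p) < tolerance) & (np.abs(r_new - r) < tolerance)
            p, r = p_new, r_new
            if done.any():
                sel = idx[done]
                pf[sel] = p[done]
                rho[sel] = r[done]
                n_iter[sel] = k
                keep = ~done
                idx = idx[keep]
                p, r = p[keep], r[keep]
                a2, a1, a0, aNf = a2[keep], a1[keep], a0[keep], aNf[keep]
        if idx.size:  # hit max_iter
            pf[idx] = p
            rho[idx] = r
            n_iter[idx] = max_iter
            converged[idx] = False

    # boundary polish: EM approaches a rho = 0 maximizer only sublinearly,
    # so compare against the exact rho = 0 fit and keep the better one
    em_idx = np.flatnonzero(em)
    if em_idx.size:
        ll_em = _female_ll_arrays(n2f[em_idx], n1f[em_idx], n0f[em_idx],
                                  pf[em_idx], rho[em_idx])
        ll_b = _female_ll_arrays(n2f[em_idx], n1f[em_idx], n0f[em_idx],
                                 pf_closed[em_idx], np.zeros(em_idx.size))
        take = em_idx[ll_b >= ll_em]
        pf[take] = pf_closed[take]
        rho[take] = 0.0
        converged[take] = True

    res = (pf.reshape(shape), rho.reshape(shape), n_iter.reshape(shape),
           converged.reshape(shape), identifiable.reshape(shape))
    return res


def _em_h01_arrays(n1m, n0m, n2f, n1f, n0f, *, tolerance=1e-7, max_iter=1000,
                   rho_init=0.02, male_weight=1.0):
    """EM for (p, rho) under H01 (p_m = p_f = p), elementwise.

    ``male_weight`` = 2 counts every male allele twice, the dosage
    compensation convention; the default 1 is the plain allele count.
    Returns ``(p, rho, n_iter, converged, rho_identifiable)`` arrays.
    """
    arrs = [np.asarray(a, dtype=float) for a in (n1m, n0m, n2f, n1f, n0f)]
    shape = np.broadcast_shapes(*(a.shape for a in arrs))
    n1m, n0m, n2f, n1f, n0f = (np.broadcast_to(a, shape).ravel() for a in arrs)
    Nm = n1m + n0m
    Nf = n2f + n1f + n0f
    c = float(male_weight)
    n = Nf.size

    p_out = np.full(n, np.nan)
    rho = np.full(n, np.nan)
    n_iter = np.zeros(n, dtype=np.int64)
    converged = np.ones(n, dtype=bool)
    identifiable = np.ones(n, dtype=bool)

    m1 = c * n1m + 2.0 * n2f + n1f  # weighted M1 allele count
    m0 = c * n0m + n1f + 2.0 * n0f
    with np.errstate(invalid="ignore", divide="ignore"):
        p_closed = m1 / (m1 + m0)

    mono_all = (m1 == 0) | (m0 == 0)  # sample carries one allele only
    nohet = (~mono_all) & (n1f == 0) & (n2f + n0f > 0)  # rho -> 1
    hwe_closed = (~mono_all) & (~nohet) & (n2f == 0) & (n0f == 0)
    em = ~(mono_all | nohet | hwe_closed)

    p_out[mono_all] = np.where(m1[mono_all] > 0, 1.0, 0.0)
    np.putmask(p_out, mono_all & (m1 + m0 == 0), np.nan)
    rho[mono_all] = 0.0
    identifiable[mono_all] = False
    # with no heterozygous females the female likelihood is increasing in
    # rho; at rho = 1 homozygotes behave like single alleles
    with np.errstate(invalid="ignore", divide="ignore"):
        p_out[nohet] = ((c * n1m + n2f) / (c * Nm + Nf))[nohet]
    rho[nohet] = 1.0
    p_out[hwe_closed] = p_closed[hwe_closed]
    rho[hwe_closed] = 0.0
    identifiable[hwe_closed & (Nf == 0)] = False

    idx = np.flatnonzero(em)
    if idx.size:
        a1m, a2, a1, a0 = n1m[idx], n2f[idx], n1f[idx], n0f[idx]
        aNm, aNf = Nm[idx], Nf[idx]
        p = np.clip(p_closed[idx], _PF_EPS, 1.0 - _PF_EPS)
        r = np.full(idx.size, float(rho_init))
        k = 0
        while idx.size and k < max_iter:
            k += 1
            q = 1.0 - p
            pq = p * q
            d2 = p * p + r * pq
            d0 = q * q + r * pq
            w1 = a2 * (p * p) / d2
            w2 = a2 - w1
            w3 = a0 * (q * q) / d0
            w4 = a0 - w3
            p_new = (2.0 * w1 + w2 + w4 + a1 + c * a1m) / (c * aNm + 2.0 * aNf)
            r_new = (w2 + w4) / (w2 + w4 + a1)
            done = (np.abs(p_new - p) < tolerance) & (np.abs(r_new - r) < tolerance)
            p, r = p_new, r_new
            if done.any():
                sel = idx[done]
                p_out[sel] = p[done]
                rho[sel] = r[done]
                n_iter[sel] = k
                keep = ~done
                idx = idx[keep]
                p, r = p[keep], r[keep]
                a1m, a2, a1, a0 = a1m[keep], a2[keep], a1[keep], a0[keep]
                aNm, aNf = aNm[keep], aNf[keep]
        if idx.size:
            p_out[idx] = p
            rho[idx] = r
            n_iter[idx] = max_iter
            converged[idx] = False

    em_idx = np.flatnonzero(em)
    if em_idx.size:
        ll_em = _loglik_h01_arrays(n1m[em_idx], n0m[em_idx], n2f[em_idx],
                                   n1f[em_idx], n0f[em_idx], p_out[em_idx],
                                   rho[em_idx], male_weight=c)
        ll_b = _loglik_h01_arrays(n1m[em_idx], n0m[em_idx], n2f[em_idx],
                                  n1f[em_idx], n0f[em_idx], p_closed[em_idx],
                                  np.zeros(em_idx.size), male_weight=c)
        take = em_idx[ll_b >= ll_em]
        p_out[take] = p_closed[take]
        rho[take] = 0.0
        converged[take] = True

    return (p_out.reshape(shape), rho.reshape(shape), n_iter.reshape(shape),
            converged.reshape(shape), identifiable.reshape(shape))


def _loglik_h01_arrays(n1m, n0m, n2f, n1f, n0f, p, rho, male_weight=1.0):
    """Log-likelihood at (p, p, rho), male exponents scaled by male_weight."""
    ll_f = _female_ll_arrays(n2f, n1f, n0f, p, rho)
    from scipy.special import xlogy

    with np.errstate(divide="ignore", invalid="ignore"):
        ll_m = xlogy(n1m, p) + xlogy(n0m, 1.0 - np.asarray(p, float))
    return male_weight * ll_m + ll_f


# ---------------------------------------------------------------------------
# Scalar EM fits
# ---------------------------------------------------------------------------

def fit_h1(counts: GenotypeCounts, config: EMConfig = EMConfig(),
           record_history: bool = False) -> FitResult:
    """MLE under H1 (p_m, p_f free, rho in [0, 1]).

    ``p_m_hat = n1m/Nm`` in closed form; ``(p_f, rho)`` by EM.  With
    ``record_history=True`` the per-iteration parameter and log-likelihood
    trajectory is attached to the result (useful for checking the EM
    ascent property).
    """
    if counts.Nm < 1 or counts.Nf < 1:
        raise ValueError("fit_h1 requires at least one male and one female")
    pm = counts.n1m / counts.Nm
    history = _scalar_history_h1(counts, pm, config) if record_history else None
    pf, rho, n_iter, conv, ident = _em_h1_arrays(
        np.array([counts.n2f]), np.array([counts.n1f]), np.array([counts.n0f]),
        tolerance=config.tolerance, max_iter=config.max_iter,
        rho_init=config.rho_init,
    )
    params = ModelParams(pm, float(pf[0]), float(rho[0]))
    return FitResult(Hypothesis.H1, params, log_likelihood(counts, params),
                     int(n_iter[0]), bool(conv[0]), bool(ident[0]), history)


def fit_h01(counts: GenotypeCounts, config: EMConfig = EMConfig(),
            record_history: bool = False, male_weight: float = 1.0) -> FitResult:
    """MLE under H01 (p_m = p_f = p, rho free in [0, 1]) by EM.

    ``male_weight=2`` applies the dosage-compensation allele weighting.
    """
    if counts.N < 1:
        raise ValueError("empty sample")
    history = _scalar_history_h01(counts, config, male_weight) if record_history else None
    p, rho, n_iter, conv, ident = _em_h01_arrays(
        *[np.array([v]) for v in counts.as_tuple()],
        tolerance=config.tolerance, max_iter=config.max_iter,
        rho_init=config.rho_init, male_weight=male_weight,
    )
    params = ModelParams(float(p[0]), float(p[0]), float(rho[0]))
    ll = float(_loglik_h01_arrays(
        *[np.array([float(v)]) for v in counts.as_tuple()],
        np.array([params.p_m]), np.array([params.rho]), male_weight=male_weight)[0])
    return FitResult(Hypothesis.H01, params, ll, int(n_iter[0]), bool(conv[0]),
                     bool(ident[0]), history)


def _scalar_history_h1(counts, pm, config):
    """Plain scalar re-run of the H1 EM, recording each iterate."""
    n2f, n1f, n0f = counts.n2f, counts.n1f, counts.n0f
    Nf = counts.Nf
    if n1f == 0 or (n2f == 0 and n0f == 0):
        return []  # analytic case, no iterations
    p = min(max((2 * n2f + n1f) / (2 * Nf), _PF_EPS), 1 - _PF_EPS)
    r = config.rho_init
    hist = [(pm, p, r, log_likelihood(counts, ModelParams(pm, p, r)))]
    for _ in range(config.max_iter):
        q = 1.0 - p
        pq = p * q
        w1 = n2f * p * p / (p * p + r * pq)
        w2 = n2f - w1
        w3 = n0f * q * q / (q * q + r * pq)
        w4 = n0f - w3
        p_new = (2 * w1 + w2 + n1f + w4) / (2 * Nf)
        r_new = (w2 + w4) / (w2 + w4 + n1f)
        done = abs(p_new - p) < config.tolerance and abs(r_new - r) < config.tolerance
        p, r = p_new, r_new
        hist.append((pm, p, r, log_likelihood(counts, ModelParams(pm, p, r))))
        if done:
            break
    return hist


def _scalar_history_h01(counts, config, male_weight=1.0):
    n1m, n0m, n2f, n1f, n0f = counts.as_tuple()
    Nm, Nf = counts.Nm, counts.Nf
    c = male_weight
    m1 = c * n1m + 2 * n2f + n1f
    m0 = c * n0m + n1f + 2 * n0f
    if m1 == 0 or m0 == 0 or n1f == 0 or (n2f == 0 and n0f == 0):
        return []
    def ll(p, r):
        return float(_loglik_h01_arrays(
            *(np.array([float(v)]) for v in (n1m, n0m, n2f, n1f, n0f)),
            np.array([p]), np.array([r]), male_weight=c)[0])
    p = min(max(m1 / (m1 + m0), _PF_EPS), 1 - _PF_EPS)
    r = config.rho_init
    hist = [(p, p, r, ll(p, r))]
    for _ in range(config.max_iter):
        q = 1.0 - p
        pq = p * q
        w1 = n2f * p * p / (p * p + r * pq)
        w2 = n2f - w1
        w3 = n0f * q * q / (q * q + r * pq)
        w4 = n0f - w3
        p_new = (2 * w1 + w2 + w4 + n1f + c * n1m) / (c * Nm + 2 * Nf)
        r_new = (w2 + w4) / (w2 + w4 + n1f)
        done = abs(p_new - p) < config.tolerance and abs(r_new - r) < config.tolerance
        p, r = p_new, r_new
        hist.append((p, p, r, ll(p, r)))
        if done:
            break
    return hist
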