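"""Parametric-bootstrap calibration of the likelihood-ratio tests.

The rho = 0 boundary makes the chi-square reference for LRT0 and LRT2
conservative, so their null distributions are obtained by resampling from
the model fitted under the respective null:

* ``LRT0b`` -- fit the pooled allele frequency ``p``; redraw the ``Nm``
  male alleles Binomial(Nm, p) and the ``Nf`` female genotypes
  Multinomial(Nf; p^2, 2pq, q^2).
* ``LRT2b`` -- fit the female frequency ``p_f``; the male alleles stay
  fixed at their observed values and only the female genotypes are
  redrawn at the Hardy-Weinberg proportions of ``p_f``.
* ``LRT1b`` -- fit ``(p, rho)`` under H01 and redraw both sexes from that
  fit (used mainly with the dosage-compensation variant of LRT1).

The p-value is the fraction of resampled statistics strictly exceeding
the observed one, ``(1/B) * #{LRT_i* > LRT}``; ties do not count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .model import GenotypeCounts, female_genotype_freqs
from .estimators import EMConfig, fit_h0, fit_h01, fit_h02
from .stats import TestResult, _lrt_stats_arrays, lrt0 as _lrt0, lrt1 as _lrt1, lrt2 as _lrt2

__all__ = ["BootstrapConfig", "bootstrap_pvalue"]

_OBSERVED = {"LRT0": _lrt0, "LRT1": _lrt1, "LRT2": _lrt2}


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: number of replicates, RNG seed, target statistic."""

    B: int = 1000
    seed: Optional[Union[int, np.random.SeedSequence]] = None
    which: str = "LRT0"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.which not in ("LRT0", "LRT1", "LRT2"):
            raise ValueError(f"unknown statistic {self.which!r}")


def _null_params(counts: GenotypeCounts, which: str, em: EMConfig,
                 male_weight: float = 1.0):
    """(p_m, female genotype probabilities) of the fitted null model."""
    if which == "LRT0":
        if male_weight == 1.0:
            p = fit_h0(counts).params_hat.p_m
        else:
            m1 = male_weight * counts.n1m + 2 * counts.n2f + counts.n1f
            m0 = male_weight * counts.n0m + counts.n1f + 2 * counts.n0f
            p = m1 / (m1 + m0)
        return p, female_genotype_freqs(p, 0.0)
    if which == "LRT2":
        pf = fit_h02(counts).params_hat.p_f
        return None, female_genotype_freqs(pf, 0.0)  # males not resampled
    params = fit_h01(counts, em, male_weight=male_weight).params_hat
    return params.p_m, female_genotype_freqs(params.p_f, params.rho)


def _resample_stats(counts: GenotypeCounts, which: str, B: int,
                    rng: np.random.Generator, em: EMConfig,
                    male_weight: float = 1.0):
    """B resampled null statistics for one locus (vectorized EM refits)."""
    p_null, fprobs = _null_params(counts, which, em, male_weight)
    if which == "LRT2":
        n1m = np.full(B, float(counts.n1m))
        n0m = np.full(B, float(counts.n0m))
    else:
        n1m = rng.binomial(counts.Nm, p_null, size=B).astype(float)
        n0m = counts.Nm - n1m
    fem = rng.multinomial(counts.Nf, fprobs, size=B).astype(float)
    res = _lrt_stats_arrays(n1m, n0m, fem[:, 0], fem[:, 1], fem[:, 2],
                            config=em, which=(which,), male_weight=male_weight)
    return res[which], res["converged"]


def bootstrap_pvalue(counts: GenotypeCounts, config: BootstrapConfig,
                     em: EMConfig = EMConfig(), dc: bool = False) -> TestResult:
    """Bootstrap-calibrated p-value for LRT0, LRT1 or LRT2 at one locus.

    Results are reproducible given ``config.seed``; per-resample EM fits
    that fail to converge are counted in the result but still used.
    ``dc=True`` applies the dosage-compensation male-allele weighting to
    LRT0/LRT1 (LRT2 is unaffected by it).
    """
    male_weight = 2.0 if (dc and config.which != "LRT2") else 1.0
    if male_weight == 1.0:
        observed = _OBSERVED[config.which](counts, em)
    else:
        from .stats import dc_variants

        observed = dc_variants(counts, em)[config.which]
    rng = np.random.default_rng(config.seed)
    stats, conv = _resample_stats(counts, config.which, config.B, rng, em,
                                  male_weight)
    p = float(np.mean(stats > observed.statistic))
    return TestResult(
        name=config.which + "b",
        statistic=observed.statistic,
        df=None,
        p_value=p,
        calibration="bootstrap",
        converged=observed.converged,
        n_resamples=config.B,
        n_resamples_nonconverged=int(np.sum(~conv)),
    )
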