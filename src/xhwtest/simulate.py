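"""Synthetic genotype data and the Monte-Carlo size/power harness.

Data generation mirrors the sampling model behind the tests: male M1
allele counts are Binomial(Nm, p_m) and female genotype counts are
Multinomial(Nf; p_f^2 + rho p_f q_f, 2(1-rho) p_f q_f, q_f^2 + rho p_f q_f).
A two-subpopulation mixture (equal mixing by default) generates the
Wahlund-effect experiments: pooling subpopulations with different allele
frequencies produces apparent excess homozygosity even though rho = 0
within each subpopulation.

``run_experiment`` simulates a scenario, applies any of the nine tests to
every replicate and aggregates rejection rates (with Monte-Carlo standard
errors) and estimator accuracy summaries.  Replicates where a statistic is
undefined (monomorphic draws) are excluded per test and counted.  Results
are reproducible and independent of execution order for a given seed: the
outer generator and one bootstrap stream per (test, replicate) are derived
from a single SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .model import GenotypeCounts, female_genotype_freqs
from .estimators import EMConfig
from .stats import _z_stats_arrays, _lrt_stats_arrays
from .bootstrap import BootstrapConfig

__all__ = [
    "Stratification",
    "Scenario",
    "TestSummary",
    "EstimatorSummary",
    "ExperimentResult",
    "ALL_TESTS",
    "simulate_counts",
    "simulate_stratified",
    "run_experiment",
    "run_experiment_grid",
    "sample_size_search",
    "load_experiment_config",
]

ALL_TESTS = ("LRT0", "LRT0b", "LRT1", "LRT1b", "LRT2", "LRT2b", "Z0", "Z1", "Z2")
_BOOT_TESTS = {"LRT0b", "LRT1b", "LRT2b"}
_ASY_DF = {"Z1": 1, "Z2": 1, "Z0": 2, "LRT0": 2, "LRT1": 1, "LRT2": 1}

_BOOT_CHUNK = 200  # replicates refitted per vectorized bootstrap EM call


@dataclass(frozen=True)
class Stratification:
    """Two-subpopulation mixture with per-subpopulation frequencies.

    Subpopulation k has male frequency ``p_m[k]`` and female frequency
    ``p_m[k] + epsilon[k]``; ``rho`` within subpopulations comes from the
    enclosing scenario (0 in the Wahlund experiments).  Each individual is
    independently assigned a subpopulation (probability ``mixing`` for the
    first) and a sex (probability ``female_prob`` of being female);
    ``fixed_sex_split=True`` instead fixes the sex split deterministically.
    """

    p_m: tuple[float, float] = (0.3, 0.5)
    epsilon: tuple[float, float] = (0.0, 0.0)
    mixing: float = 0.5
    female_prob: float = 0.5
    fixed_sex_split: bool = False


@dataclass(frozen=True)
class Scenario:
    """One simulation condition.

    ``p_f = p_m + epsilon``; ``ratio`` is the male:female pair r, with
    ``Nm = round(N * r_m / (r_m + r_f))`` and ``Nf = N - Nm``.
    """

    p_m: float = 0.3
    epsilon: float = 0.0
    rho: float = 0.0
    N: int = 800
    ratio: tuple[float, float] = (1.0, 1.0)
    n_reps: int = 10000
    alpha: float = 0.05
    stratification: Optional[Stratification] = None
    dc: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.stratification is None and not 0.0 <= self.p_f <= 1.0:
            raise ValueError(f"p_f = p_m + epsilon = {self.p_f} outside [0, 1]")
        if self.N < 1 or self.n_reps < 1:
            raise ValueError("N and n_reps must be >= 1")

    @property
    def p_f(self) -> float:
        return self.p_m + self.epsilon

    @property
    def Nm(self) -> int:
        rm, rf = self.ratio
        return int(round(self.N * rm / (rm + rf)))

    @property
    def Nf(self) -> int:
        return self.N - self.Nm


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _simulate_counts_arrays(scenario: Scenario, rng: np.random.Generator, n: int):
    """n replicate draws; returns (n1m, n0m, n2f, n1f, n0f) float arrays."""
    Nm, Nf = scenario.Nm, scenario.Nf
    n1m = rng.binomial(Nm, scenario.p_m, size=n).astype(float)
    fem = rng.multinomial(Nf, female_genotype_freqs(scenario.p_f, scenario.rho),
                          size=n).astype(float)
    return n1m, Nm - n1m, fem[:, 0], fem[:, 1], fem[:, 2]


def _simulate_stratified_arrays(scenario: Scenario, rng: np.random.Generator, n: int):
    s = scenario.stratification
    if s is None:
        raise ValueError("scenario has no stratification block")
    N = scenario.N
    if s.fixed_sex_split:
        Nm = np.full(n, int(round(N * (1.0 - s.female_prob))))
    else:
        Nm = rng.binomial(N, 1.0 - s.female_prob, size=n)
    Nf = N - Nm
    m1 = rng.binomial(Nm, s.mixing)  # males in subpopulation 1
    n1m = (rng.binomial(m1, s.p_m[0]) + rng.binomial(Nm - m1, s.p_m[1])).astype(float)
    f1 = rng.binomial(Nf, s.mixing)
    probs1 = female_genotype_freqs(s.p_m[0] + s.epsilon[0], scenario.rho)
    probs2 = female_genotype_freqs(s.p_m[1] + s.epsilon[1], scenario.rho)
    fem = rng.multinomial(f1, probs1) + rng.multinomial(Nf - f1, probs2)
    fem = fem.astype(float)
    n0m = Nm.astype(float) - n1m
    return n1m, n0m, fem[:, 0], fem[:, 1], fem[:, 2]


def simulate_counts(scenario: Scenario, rng: np.random.Generator) -> GenotypeCounts:
    """One replicate draw under the (unstratified) scenario."""
    n1m, n0m, n2f, n1f, n0f = _simulate_counts_arrays(scenario, rng, 1)
    return GenotypeCounts(int(n1m[0]), int(n0m[0]), int(n2f[0]), int(n1f[0]),
                          int(n0f[0]))


def simulate_stratified(scenario: Scenario, rng: np.random.Generator) -> GenotypeCounts:
    """One replicate draw under the two-subpopulation mixture."""
    n1m, n0m, n2f, n1f, n0f = _simulate_stratified_arrays(scenario, rng, 1)
    return GenotypeCounts(int(n1m[0]), int(n0m[0]), int(n2f[0]), int(n1f[0]),
                          int(n0f[0]))


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class TestSummary:
    name: str
    rate: float            # rejection rate among defined replicates
    se: float              # sqrt(rate (1 - rate) / n_used)
    n_used: int
    n_excluded: int


@dataclass
class EstimatorSummary:
    name: str
    mean: float
    sd: float              # population SD (ddof=0), so rmse^2 = bias^2 + sd^2
    bias: Optional[float]  # None when no single true value exists (mixture)
    rmse: Optional[float]
    n_used: int


@dataclass
class ExperimentResult:
    scenario: Scenario
    tests: dict[str, TestSummary]
    estimators: dict[str, EstimatorSummary]

    def to_frame(self) -> pd.DataFrame:
        """One row per test, scenario columns repeated for flat output."""
        sc = self.scenario
        rows = []
        for t in self.tests.values():
            rows.append({
                "p_m": sc.p_m, "epsilon": sc.epsilon, "rho": sc.rho, "N": sc.N,
                "Nm": sc.Nm, "Nf": sc.Nf, "n_reps": sc.n_reps, "alpha": sc.alpha,
                "stratified": sc.stratification is not None, "dc": sc.dc,
                "test": t.name, "rejection_rate": t.rate, "mc_se": t.se,
                "n_used": t.n_used, "n_excluded": t.n_excluded,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The harness
# ---------------------------------------------------------------------------

def _summ(name, values, true=None):
    v = np.asarray(values, float)
    ok = np.isfinite(v)
    v = v[ok]
    mean = float(np.mean(v)) if v.size else float("nan")
    sd = float(np.std(v)) if v.size else float("nan")
    bias = rmse = None
    if true is not None and v.size:
        bias = mean - true
        rmse = float(np.sqrt(np.mean((v - true) ** 2)))
    return EstimatorSummary(name, mean, sd, bias, rmse, int(v.size))


def run_experiment(scenario: Scenario, tests: Sequence[str] = ALL_TESTS,
                   bootstrap: Optional[BootstrapConfig] = None,
                   em: EMConfig = EMConfig(),
                   seed: Optional[int] = None) -> ExperimentResult:
    """Simulate a scenario and estimate per-test rejection rates.

    ``bootstrap`` supplies B for the bootstrap-calibrated tests (default
    B=1000 when one is requested).  Rejection uses ``p_value <= alpha``.
    Estimator summaries for the EM estimators (rho1, rho01, pf1, p01, pm)
    and the moment estimator rho_z are always aggregated; bias and RMSE
    are reported only when the scenario has a single true parameter value
    (i.e. no stratification).
    """
    tests = list(tests)
    unknown = set(tests) - set(ALL_TESTS)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    if not tests:
        raise ValueError("tests must be nonempty")
    n = scenario.n_reps
    B = (bootstrap.B if bootstrap is not None else 1000)

    root = np.random.SeedSequence(seed)
    gen_ss, boot_ss = root.spawn(2)
    rng = np.random.default_rng(gen_ss)
    if scenario.stratification is not None:
        data = _simulate_stratified_arrays(scenario, rng, n)
    else:
        data = _simulate_counts_arrays(scenario, rng, n)
    n1m, n0m, n2f, n1f, n0f = data

    male_weight = 2.0 if scenario.dc else 1.0
    lrts = _lrt_stats_arrays(n1m, n0m, n2f, n1f, n0f, config=em,
                             which=("LRT0", "LRT1", "LRT2"),
                             male_weight=male_weight)
    z1s, z2s, z0s = _z_stats_arrays(n1m, n0m, n2f, n1f, n0f)
    stats = {"Z1": z1s, "Z2": z2s, "Z0": z0s,
             "LRT0": lrts["LRT0"], "LRT1": lrts["LRT1"], "LRT2": lrts["LRT2"]}

    pvals: dict[str, np.ndarray] = {}
    for name in tests:
        if name in _BOOT_TESTS:
            continue
        pvals[name] = chi2.sf(stats[name], _ASY_DF[name])

    boot_requested = [t for t in tests if t in _BOOT_TESTS]
    if boot_requested:
        streams = boot_ss.spawn(len(_BOOT_TESTS))  # stable per-test streams
        stream_of = dict(zip(sorted(_BOOT_TESTS), streams))
        for name in boot_requested:
            base = name[:-1]
            pvals[name] = _bootstrap_pvalues(
                base, data, lrts, B, em, male_weight, stream_of[name])

    summaries = {}
    for name in tests:
        p = np.asarray(pvals[name], float)
        ok = np.isfinite(p)
        used = int(ok.sum())
        rate = float(np.mean(p[ok] <= scenario.alpha)) if used else float("nan")
        se = float(np.sqrt(rate * (1.0 - rate) / used)) if used else float("nan")
        summaries[name] = TestSummary(name, rate, se, used, n - used)

    strat = scenario.stratification is not None
    with np.errstate(invalid="ignore", divide="ignore"):
        Nf = n2f + n1f + n0f
        pf_hat = (2 * n2f + n1f) / (2 * Nf)
        p11 = n2f / Nf
        rhoz = np.where((pf_hat > 0) & (pf_hat < 1),
                        (p11 - pf_hat * pf_hat) / (pf_hat * (1 - pf_hat)), np.nan)
    if strat:
        true_pm = true_pf = true_p = true_rho = None
    else:
        true_pm, true_pf, true_rho = scenario.p_m, scenario.p_f, scenario.rho
        Nm_, Nf_ = scenario.Nm, scenario.Nf
        true_p = (Nm_ * true_pm + 2 * Nf_ * true_pf) / (Nm_ + 2 * Nf_)
    estimators = {
        "pm": _summ("pm", lrts["pm"], true_pm),
        "pf1": _summ("pf1", lrts["pf1"], true_pf),
        "p01": _summ("p01", lrts["p01"], true_p),
        "rho1": _summ("rho1", lrts["rho1"], true_rho),
        "rho01": _summ("rho01", lrts["rho01"], true_rho),
        "rhoz": _summ("rhoz", rhoz, true_rho),
    }
    return ExperimentResult(scenario, summaries, estimators)


def _bootstrap_pvalues(base, data, lrts, B, em, male_weight, seedseq):
    """Vectorized parametric-bootstrap p-values for all replicates.

    Each replicate gets its own child RNG stream (order-independent); the
    null refits for a chunk of replicates are flattened into one EM call.
    """
    n1m, n0m, n2f, n1f, n0f = data
    n = n1m.size
    Nm = (n1m + n0m).astype(np.int64)
    Nf = (n2f + n1f + n0f).astype(np.int64)
    observed = lrts[base]
    with np.errstate(invalid="ignore", divide="ignore"):
        if base == "LRT0":
            p_null = lrts["p0"]
            f2, fh, f0 = (p_null ** 2, 2 * p_null * (1 - p_null), (1 - p_null) ** 2)
        elif base == "LRT1":
            p_null = lrts["p01"]
            from .model import _female_freqs_arrays
            f2, fh, f0 = _female_freqs_arrays(p_null, lrts["rho01"])
        else:  # LRT2: females refit at HWE of pf_hat; males kept fixed
            p_null = (2 * n2f + n1f) / (2 * Nf)
            f2, fh, f0 = (p_null ** 2, 2 * p_null * (1 - p_null), (1 - p_null) ** 2)
    fprobs = np.clip(np.stack([f2, fh, f0], axis=1), 0.0, 1.0)
    # guard monomorphic refits: probabilities may carry fp dust
    fprobs /= fprobs.sum(axis=1, keepdims=True)

    children = seedseq.spawn(n)
    out = np.empty(n)
    for start in range(0, n, _BOOT_CHUNK):
        stop = min(start + _BOOT_CHUNK, n)
        parts_m1, parts_fem = [], []
        for i in range(start, stop):
            r = np.random.default_rng(children[i])
            if base == "LRT2":
                m1 = np.full(B, n1m[i])
                m0 = np.full(B, n0m[i])
            else:
                m1 = r.binomial(Nm[i], p_null[i], size=B).astype(float)
                m0 = Nm[i] - m1
            fem = r.multinomial(Nf[i], fprobs[i], size=B).astype(float)
            parts_m1.append((m1, m0))
            parts_fem.append(fem)
        m1 = np.concatenate([a for a, _ in parts_m1])
        m0 = np.concatenate([b for _, b in parts_m1])
        fem = np.concatenate(parts_fem)
        res = _lrt_stats_arrays(m1, m0, fem[:, 0], fem[:, 1], fem[:, 2],
                                config=em, which=(base,),
                                male_weight=male_weight)
        star = res[base].reshape(stop - start, B)
        out[start:stop] = np.mean(star > observed[start:stop, None], axis=1)
    out[~np.isfinite(observed)] = np.nan
    return out


def run_experiment_grid(scenarios: Sequence[Scenario],
                        tests: Sequence[str] = ALL_TESTS,
                        bootstrap: Optional[BootstrapConfig] = None,
                        em: EMConfig = EMConfig(),
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Run several scenarios; one output row per scenario x test."""
    frames = []
    root = np.random.SeedSequence(seed)
    for sc, ss in zip(scenarios, root.spawn(len(scenarios))):
        res = run_experiment(sc, tests, bootstrap, em,
                             seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)


def sample_size_search(target_power: float, scenario: Scenario, test: str, *,
                       grid_step: int = 50, nf_min: int = 100,
                       nf_max: int = 100000, n_reps: int = 2000,
                       bootstrap: Optional[BootstrapConfig] = None,
                       em: EMConfig = EMConfig(),
                       seed: Optional[int] = None) -> int:
    """Smallest Nf on the grid giving the test at least ``target_power``.

    The male count stays fixed at the scenario's Nm; Nf is varied by
    coarse doubling followed by bisection on multiples of ``grid_step``
    (power assumed monotone in Nf).  Raises if the target is unreachable
    below ``nf_max``.
    """
    if test not in ALL_TESTS:
        raise ValueError(f"unknown test {test!r}")
    Nm = scenario.Nm

    def power_at(nf: int) -> float:
        sc = replace(scenario, N=Nm + nf, ratio=(Nm, nf), n_reps=n_reps)
        sub = np.random.SeedSequence([0 if seed is None else seed, nf])
        res = run_experiment(sc, [test], bootstrap, em,
                             seed=int(sub.generate_state(1)[0] % (2 ** 31)))
        return res.tests[test].rate

    if power_at(nf_min) >= target_power:
        return nf_min
    lo, hi = nf_min, 2 * nf_min
    while power_at(hi) < target_power:
        lo = hi
        hi *= 2
        if hi > nf_max:
            raise ValueError(f"target power {target_power} not reached by Nf={nf_max}")
    # bisect on the grid between the last failure and the first success
    while hi - lo > grid_step:
        mid = ((lo + hi) // 2 // grid_step) * grid_step
        if mid <= lo:
            break
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return int(np.ceil(hi / grid_step) * grid_step) if hi % grid_step else hi


# ---------------------------------------------------------------------------
# Plain-text experiment configuration
# ---------------------------------------------------------------------------

def load_experiment_config(path):
    """Read a YAML experiment grid.

    Layout::

        tests: [LRT0, LRT0b, Z1]        # optional, default all nine
        bootstrap: {B: 1000}            # optional
        seed: 1                         # optional
        defaults: {n_reps: 10000, alpha: 0.05}
        scenarios:
          - {p_m: 0.3, epsilon: 0.0, rho: 0.0, N: 800, ratio: [2, 1]}
          - {p_m: 0.3, stratification: {p_m: [0.3, 0.5], epsilon: [-0.05, -0.05]}}

    Returns ``(scenarios, tests, bootstrap_config, seed)``.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    defaults = cfg.get("defaults", {})
    scenarios = []
    for raw in cfg.get("scenarios", []):
        spec = {**defaults, **raw}
        strat = spec.pop("stratification", None)
        if strat is not None:
            strat = Stratification(
                p_m=tuple(strat.get("p_m", (0.3, 0.5))),
                epsilon=tuple(strat.get("epsilon", (0.0, 0.0))),
                mixing=float(strat.get("mixing", 0.5)),
                female_prob=float(strat.get("female_prob", 0.5)),
                fixed_sex_split=bool(strat.get("fixed_sex_split", False)),
            )
        if "ratio" in spec:
            spec["ratio"] = tuple(spec["ratio"])
        scenarios.append(Scenario(stratification=strat, **spec))
    tests = tuple(cfg.get("tests", ALL_TESTS))
    boot = cfg.get("bootstrap")
    boot_cfg = BootstrapConfig(B=int(boot["B"])) if boot else None
    return scenarios, tests, boot_cfg, cfg.get("seed")
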