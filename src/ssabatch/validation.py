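"""Ensemble statistics and statistical acceptance tests against oracles.

The simulator's correctness is checked distributionally: waiting times at a
frozen state must be Exp(a_total) (Kolmogorov-Smirnov), channel selection
frequencies must match a_i/a_total (chi-square), and ensemble means must
track the analytic solutions of the linear death process and of the
immigration-death (single-gene production-reduction) process, whose
stationary law is Poisson(c5*G/c6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .direct import (
    RNGStream,
    TimeCourse,
    propensity_vector,
    run_trajectory,
    select_reaction,
    total_propensity,
)
from .factory import decay_dimerization, gene_battery
from .model import ModelSpec, ReactionSpec, crs_from_model

__all__ = [
    "EnsembleSummary",
    "summarize",
    "test_waiting_times",
    "test_selection_frequencies",
    "test_analytic_means",
    "decay_dimer_invariant_check",
]

# Not pytest tests: "test_*" here are the validation-suite operations.
__test__ = False


@dataclass(frozen=True)
class EnsembleSummary:
    """Mean and variance per species on a fixed time grid, across N runs.

    The variance is the unbiased (N-1 denominator) estimator; with N == 1 it
    is reported as 0.
    """

    grid: np.ndarray  # (G,)
    mean: np.ndarray  # (G, m_species)
    variance: np.ndarray  # (G, m_species)
    n_realizations: int
    n_excluded: int = 0


def _sample_at(tc: TimeCourse, grid: np.ndarray) -> np.ndarray:
    """Piecewise-constant state: last recorded state at time <= grid point."""
    idx = np.searchsorted(tc.times, grid, side="right") - 1
    return tc.counts[idx]


def summarize(timecourses, grid) -> EnsembleSummary:
    """Cross-realization mean/variance on a time grid.

    A realization whose simulated horizon ends before the last grid point is
    excluded (with a count in the summary) unless it absorbed, in which case
    its final state extends to all later times.
    """
    grid = np.asarray(grid, dtype=float)
    samples = []
    excluded = 0
    for tc in timecourses:
        if not tc.absorbed and tc.times[-1] < grid[-1]:
            excluded += 1
            continue
        samples.append(_sample_at(tc, grid))
    if not samples:
        raise ValueError("empty ensemble (no realization covers the grid)")
    block = np.stack(samples)  # (N, G, m)
    n = block.shape[0]
    var = block.var(axis=0, ddof=1) if n > 1 else np.zeros(block.shape[1:])
    return EnsembleSummary(
        grid=grid,
        mean=block.mean(axis=0),
        variance=var,
        n_realizations=n,
        n_excluded=excluded,
    )


def test_waiting_times(
    model: ModelSpec,
    counts=None,
    n_draws: int = 100_000,
    alpha: float = 0.01,
    seed: int = 0,
    corrupt: bool = False,
) -> dict:
    """KS test of waiting times at a frozen state against Exp(a_total).

    ``corrupt=True`` deliberately squares r1 (a negative control that must
    fail).
    """
    counts = np.asarray(
        model.initial_counts if counts is None else counts, dtype=np.int64
    )
    a = propensity_vector(model, counts)
    a_total = total_propensity(a)
    if a_total <= 0:
        raise ValueError("absorbed state: a_total == 0")
    rng = RNGStream(seed, 0)
    r1 = np.array([rng.uniform() for _ in range(n_draws)])
    if corrupt:
        r1 = r1**2
    taus = np.log(1.0 / r1) / a_total
    ks = stats.kstest(taus, "expon", args=(0, 1.0 / a_total))
    return {
        "test": "waiting-times-ks",
        "a_total": a_total,
        "n_draws": n_draws,
        "statistic": float(ks.statistic),
        "pvalue": float(ks.pvalue),
        "alpha": alpha,
        "passed": bool(ks.pvalue > alpha),
    }


def test_selection_frequencies(
    model: ModelSpec,
    counts=None,
    n_draws: int = 1_000_000,
    alpha: float = 0.01,
    seed: int = 0,
    biased: bool = False,
) -> dict:
    """Chi-square test of channel-selection frequencies against a_i/a_total.

    Draws go through the real linear-scan selector.  ``biased=True`` replaces
    it with "always channel 0" (negative control).
    """
    counts = np.asarray(
        model.initial_counts if counts is None else counts, dtype=np.int64
    )
    a = propensity_vector(model, counts)
    a_total = total_propensity(a)
    if a_total <= 0:
        raise ValueError("absorbed state: a_total == 0")
    rng = RNGStream(seed, 0)
    observed = np.zeros(model.n, dtype=np.int64)
    a_list = [float(x) for x in a]
    for _ in range(n_draws):
        r2 = rng.uniform()
        m = 0 if biased else select_reaction(a_list, r2, a_total)
        observed[m] += 1
    expected = a / a_total * n_draws
    keep = expected > 0
    chi2 = stats.chisquare(observed[keep], expected[keep])
    if keep.sum() < 2:  # single live channel: nothing to test
        return {
            "test": "selection-chi2",
            "n_draws": n_draws,
            "statistic": 0.0,
            "pvalue": 1.0,
            "alpha": alpha,
            "passed": bool((observed[~keep] == 0).all()),
        }
    return {
        "test": "selection-chi2",
        "n_draws": n_draws,
        "statistic": float(chi2.statistic),
        "pvalue": float(chi2.pvalue),
        "alpha": alpha,
        "passed": bool(chi2.pvalue > alpha and (observed[~keep] == 0).all()),
    }


def _pure_decay_model(c: float, x0: int) -> ModelSpec:
    return ModelSpec(
        species=("X",),
        initial_counts=(x0,),
        reactions=(ReactionSpec("decay", c, reactants=((0, 1),), products=()),),
    )


def test_analytic_means(
    family: str,
    n_realizations: int = 10_000,
    tolerance_se: float = 3.0,
    seed: int = 0,
    **params,
) -> dict:
    """Compare ensemble statistics with closed-form oracles.

    family="pure_decay" (params c, x0, t): mean of X(t) vs x0*exp(-c*t),
    within ``tolerance_se`` standard errors.
    family="gene_battery" (params c5, c6, g0, horizon): stationary mean and
    variance of P vs the Poisson value c5*g0/c6, sampled at the horizon after
    a burn-in of 10/c6 time units (>= 10 relaxation times).
    """
    if n_realizations < 1:
        raise ValueError("empty ensemble: n_realizations must be >= 1")
    if family == "pure_decay":
        c = params.get("c", 1.0)
        x0 = params.get("x0", 1000)
        t = params.get("t", 1.0)
        model = _pure_decay_model(c, x0)
        crs = crs_from_model(model)
        finals = np.empty(n_realizations)
        for r in range(n_realizations):
            tc = run_trajectory(
                model, crs, RNGStream(seed, r), max_time=t, cadence=1
            )
            finals[r] = _sample_at(tc, np.array([t]))[0, 0]
        expected = x0 * np.exp(-c * t)
        # binomial thinning: X(t) ~ Binomial(x0, e^{-ct})
        se = np.sqrt(x0 * np.exp(-c * t) * (1 - np.exp(-c * t)) / n_realizations)
        err = abs(finals.mean() - expected)
        return {
            "test": "pure-decay-mean",
            "expected_mean": float(expected),
            "observed_mean": float(finals.mean()),
            "se": float(se),
            "error_in_se": float(err / se),
            "tolerance_se": tolerance_se,
            "n_realizations": n_realizations,
            "passed": bool(err <= tolerance_se * se),
        }
    if family == "gene_battery":
        c5 = params.get("c5", 10.0)
        c6 = params.get("c6", 1.0)
        g0 = params.get("g0", 1)
        burn_in = 10.0 / c6
        horizon = params.get("horizon", burn_in + 5.0 / c6)
        model = gene_battery(1, c5=c5, c6=c6, g0=g0, p0=0)
        crs = crs_from_model(model)
        p_idx = 1
        finals = np.empty(n_realizations)
        for r in range(n_realizations):
            tc = run_trajectory(
                model, crs, RNGStream(seed, r), max_time=horizon, cadence=1
            )
            finals[r] = _sample_at(tc, np.array([horizon]))[0, p_idx]
        lam = c5 * g0 / c6
        mean_se = np.sqrt(lam / n_realizations)
        # var(s^2) for Poisson: (mu4 - sigma^4) / N with mu4 = lam + 3 lam^2
        var_se = np.sqrt((lam + 3 * lam**2 - lam**2) / n_realizations)
        obs_mean = finals.mean()
        obs_var = finals.var(ddof=1)
        return {
            "test": "gene-battery-stationary-poisson",
            "expected": float(lam),
            "observed_mean": float(obs_mean),
            "observed_variance": float(obs_var),
            "mean_se": float(mean_se),
            "variance_se": float(var_se),
            "burn_in": burn_in,
            "horizon": float(horizon),
            "tolerance_se": tolerance_se,
            "n_realizations": n_realizations,
            "passed": bool(
                abs(obs_mean - lam) <= tolerance_se * mean_se
                and abs(obs_var - lam) <= tolerance_se * var_se
            ),
        }
    raise ValueError(f"unknown family {family!r}")


def decay_dimer_invariant_check(tc: TimeCourse) -> dict:
    """Check the conserved weighting Q = S1 + 2*S2 + 2*S3 along a trajectory.

    Q drops by exactly 1 when the S1-decay channel fires and is unchanged by
    the dimerization, dissociation, and conversion channels, so recorded Q
    must be monotone non-increasing with per-step drops in {0, 1} (cadence
    must be every-step for the per-step statement).
    """
    q = tc.counts @ np.array([1, 2, 2])
    drops = -np.diff(q)
    ok = bool((drops >= 0).all() and (tc.cadence > 1 or (drops <= 1).all()))
    return {
        "test": "decay-dimer-conservation",
        "q_initial": int(q[0]),
        "q_final": int(q[-1]),
        "monotone_nonincreasing": bool((drops >= 0).all()),
        "max_single_drop": int(drops.max()) if len(drops) else 0,
        "passed": ok,
    }


# the validation-suite operations are not pytest tests despite their names
test_waiting_times.__test__ = False
test_selection_frequencies.__test__ = False
test_analytic_means.__test__ = False


def validation_report(seed: int = 0, quick: bool = False) -> dict:
    """Run the full validation suite; ``quick`` shrinks the sample sizes."""
    n_ks = 10_000 if quick else 100_000
    n_chi = 50_000 if quick else 1_000_000
    n_ens = 1_000 if quick else 10_000
    model = decay_dimerization()
    tc = run_trajectory(model, seed=seed, max_steps=2_000)
    checks = [
        test_waiting_times(model, n_draws=n_ks, seed=seed),
        test_selection_frequencies(model, n_draws=n_chi, seed=seed),
        test_analytic_means("pure_decay", n_realizations=n_ens, seed=seed),
        test_analytic_means("gene_battery", n_realizations=max(n_ens // 5, 200), seed=seed),
        decay_dimer_invariant_check(tc),
    ]
    return {"seed": seed, "quick": quick, "checks": checks, "passed": all(c["passed"] for c in checks)}
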