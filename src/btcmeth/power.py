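"""Two-sample power for detecting a mean β difference.

The canonical calculation is the two-sided two-sample normal
approximation: with effect Δ, common per-group SD σ and group sizes
n₁, n₂,

    z = Δ / (σ · √(1/n₁ + 1/n₂))
    power = Φ(z − z₁₋α/₂) + Φ(−z − z₁₋α/₂).

A biologically relevant island-level difference is conventionally
Δβ = 0.2; normal-tissue probe SDs are small (median ≈ 0.02, 90th
percentile ≈ 0.09 in public cholangiocarcinoma array data), so even a
10-normal discovery design is overwhelmingly powered at that effect
size. A Monte-Carlo cross-check simulates Welch t-tests on normal data
truncated to the unit interval (β-values cannot leave [0, 1]); group
means are placed symmetric around 0.5 so truncation stays negligible at
realistic SDs, and the truncation rate is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "PowerEstimate", "power_analytic", "power_simulated"]


@dataclass(frozen=True)
class PowerSpec:
    """Design of a two-group mean-β comparison."""

    delta: float
    sd: float
    n1: int
    n2: int
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least two samples per group")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    n_reps: int
    truncation_rate: float


def power_analytic(spec: PowerSpec) -> float:
    """Two-sided two-sample power under the normal approximation."""
    spec.validate()
    se = spec.sd * np.sqrt(1.0 / spec.n1 + 1.0 / spec.n2)
    z = spec.delta / se
    zcrit = stats.norm.isf(spec.alpha / 2.0)
    return float(stats.norm.cdf(z - zcrit) + stats.norm.cdf(-z - zcrit))


def power_simulated(
    spec: PowerSpec,
    n_reps: int = 10_000,
    seed: int = 0,
    test: str = "welch",
    truncate: bool = True,
) -> PowerEstimate:
    """Monte-Carlo power of a two-sided two-sample test.

    Draws Normal(0.5 ∓ Δ/2, σ) per group, optionally truncated (clipped)
    to [0, 1]; reports the rejection fraction at level α with a normal
    95% binomial CI and the fraction of values that hit the truncation
    bounds.

    ``test='welch'`` (default) simulates the Welch t-test — the test a
    practitioner would run, slightly below the analytic formula at
    small, unbalanced designs. ``test='z'`` simulates the known-variance
    z-test the analytic formula describes exactly, for self-consistency
    checks.
    """
    spec.validate()
    if n_reps < 1000:
        raise ValueError("need at least 1000 replicates")
    if test not in ("welch", "z"):
        raise ValueError(f"unknown test {test!r}")
    rng = np.random.default_rng(seed)
    mu1 = 0.5 - spec.delta / 2.0
    mu2 = 0.5 + spec.delta / 2.0
    x1 = rng.normal(mu1, spec.sd, size=(n_reps, spec.n1))
    x2 = rng.normal(mu2, spec.sd, size=(n_reps, spec.n2))
    trunc_rate = 0.0
    if truncate:
        out_of_range = float(
            ((x1 < 0) | (x1 > 1)).mean() * spec.n1
            + ((x2 < 0) | (x2 > 1)).mean() * spec.n2
        ) / (spec.n1 + spec.n2)
        trunc_rate = out_of_range
        x1 = np.clip(x1, 0.0, 1.0)
        x2 = np.clip(x2, 0.0, 1.0)

    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    if test == "z":
        se = spec.sd * np.sqrt(1.0 / spec.n1 + 1.0 / spec.n2)
        p = 2.0 * stats.norm.sf(np.abs(m2 - m1) / se)
    else:
        v1 = x1.var(axis=1, ddof=1)
        v2 = x2.var(axis=1, ddof=1)
        se2 = v1 / spec.n1 + v2 / spec.n2
        t = (m2 - m1) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / spec.n1) ** 2 / (spec.n1 - 1)
            + (v2 / spec.n2) ** 2 / (spec.n2 - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    power = float((p < spec.alpha).mean())
    half = 1.96 * np.sqrt(max(power * (1 - power), 1e-12) / n_reps)
    return PowerEstimate(
        power=power,
        ci_low=max(0.0, power - half),
        ci_high=min(1.0, power + half),
        n_reps=n_reps,
        truncation_rate=trunc_rate,
    )
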