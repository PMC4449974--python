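"""Independence-null simulation of the threshold search, and a power utility.

Under the null the DE and DC magnitudes of a gene's scatter are independent:
|t| values are drawn from a Student t distribution (the DE statistic's
sampling distribution) and |Z| values from a standard normal (the Fisher-z
difference's approximate distribution). Running the chi-square-maximizing
threshold search on such scatters measures how large the maximum chi-square
gets purely by scanning many candidate splits, and how well the
Bonferroni-then-Benjamini-Hochberg cascade controls the resulting false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chimax import ChimaxConfig, adjust_pvalues, select_optimal_thresholds


@dataclass
class SimulationSummary:
    m: int
    replicates: int
    seed: int
    t_df: int
    max_chi2: np.ndarray  # per-replicate maximum chi-square
    n_no_threshold: int
    mean_max_chi2: float = field(init=False)
    q95_max_chi2: float = field(init=False)
    n_sig_raw: int = field(init=False)
    n_sig_bonferroni: int = field(init=False)
    n_sig_bh: int = field(init=False)

    def __post_init__(self) -> None:
        vals = self.max_chi2[~np.isnan(self.max_chi2)]
        self.mean_max_chi2 = float(vals.mean()) if vals.size else float("nan")
        self.q95_max_chi2 = (
            float(np.quantile(vals, 0.95)) if vals.size else float("nan")
        )
        p_raw = stats.chi2.sf(self.max_chi2, df=1)
        stage1, stage2 = adjust_pvalues(p_raw, self.m)
        self.n_sig_raw = int(np.nansum(p_raw < 0.05))
        self.n_sig_bonferroni = int(np.nansum(stage1 < 0.05))
        self.n_sig_bh = int(np.nansum(stage2 < 0.05))

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "replicates": self.replicates,
            "seed": self.seed,
            "t_df": self.t_df,
            "mean_max_chi2": self.mean_max_chi2,
            "q95_max_chi2": self.q95_max_chi2,
            "n_sig_raw": self.n_sig_raw,
            "n_sig_bonferroni": self.n_sig_bonferroni,
            "n_sig_bh": self.n_sig_bh,
            "n_no_threshold": self.n_no_threshold,
        }


def simulate_null(
    m: int,
    replicates: int,
    seed: int,
    config: ChimaxConfig | None = None,
    t_df: int = 100,
) -> SimulationSummary:
    """Simulate ``replicates`` independent null scatters of ``m`` (|t|, |Z|)
    pairs each and record the maximum chi-square of every threshold search.

    Each replicate plays the role of one focal gene; the Bonferroni stage
    multiplies by ``m`` (one test per candidate) and the BH stage runs
    across replicates. The maximum-chi-square distribution is rank-based, so
    ``t_df`` barely matters; it defaults to 100.
    """
    config = config or ChimaxConfig()
    rng = np.random.default_rng(seed)
    max_chi2 = np.empty(replicates, dtype=np.float64)
    n_no_threshold = 0
    for rep in range(replicates):
        abs_t = np.abs(rng.standard_t(t_df, size=m))
        abs_z = np.abs(rng.standard_normal(size=m))
        res = select_optimal_thresholds(abs_z, abs_t, config=config)
        if res.valid:
            max_chi2[rep] = res.chi2
        else:
            max_chi2[rep] = np.nan
            n_no_threshold += 1
    return SimulationSummary(
        m=m, replicates=replicates, seed=seed, t_df=t_df,
        max_chi2=max_chi2, n_no_threshold=n_no_threshold,
    )


@dataclass
class PowerSpec:
    """Design parameters for a two-sample, two-tailed t-test."""

    alpha: float = 0.05
    power: float = 0.8
    effect_size: float = 0.5  # Cohen's d

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")


def t_test_power(n_per_group: int, spec: PowerSpec) -> float:
    """Exact noncentral-t power of the two-sided two-sample t-test with
    ``n_per_group`` samples per arm."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    nc = spec.effect_size * np.sqrt(n_per_group / 2.0)
    crit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def min_sample_size_t(spec: PowerSpec, max_n_per_group: int = 10**6) -> int:
    """Smallest even total sample size (two equal groups) reaching the
    requested power, from the noncentral t distribution.

    For alpha = 0.05, power = 0.8, d = 0.5 this gives 64 per group,
    a total of 128.
    """
    for n in range(2, max_n_per_group + 1):
        if t_test_power(n, spec) >= spec.power:
            return 2 * n
    raise ValueError(
        f"power {spec.power} unreachable at d={spec.effect_size} "
        f"within {max_n_per_group} samples per group"
    )
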