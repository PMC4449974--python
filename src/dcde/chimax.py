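"""Per-gene optimal (DC, DE) threshold selection by chi-square maximization.

For a focal gene, each other gene contributes one point (|Z|, |t|) and, at
the same time, one candidate threshold pair. A candidate (z_c, t_c) splits
the points into the four quadrants high/low DC x high/low DE ("high" is
inclusive, >=), yielding a 2x2 contingency table; the candidate whose table
maximizes Pearson's chi-square is the gene's optimal threshold pair. The
dependency between DC and DE is then tested on the selected table
(chi-square, df = 1), with a Bonferroni correction for the candidate scan
followed by Benjamini-Hochberg across genes, and the high-DC/high-DE cell's
adjusted residual signs the association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._sweep import dominance_counts

PARTITIONS = ("HDC_HDE", "HDC_LDE", "LDC_HDE", "LDC_LDE")


@dataclass
class ChimaxConfig:
    """Candidate-validity and correction rules for the threshold search.

    ``min_expected`` is the floor on every expected cell count for a
    candidate to be admissible. Without a floor, corner candidates that
    isolate one or two points produce chi-square spikes near n; the
    customary floors for a 2x2 chi-square test are 3 or 5. The default is
    3, which reproduces the null calibration of the maximum statistic
    (see the null-simulation module); 0 disables the floor.
    ``bonferroni_by_valid`` multiplies the Bonferroni stage by the number
    of *valid* candidates instead of the nominal candidate count.
    """

    min_expected: float = 3.0
    bonferroni_by_valid: bool = False


@dataclass
class ContingencyTable:
    """2x2 observed table for the high/low DC x high/low DE split."""

    hdc_hde: int
    hdc_lde: int
    ldc_hde: int
    ldc_lde: int

    @property
    def n(self) -> int:
        return self.hdc_hde + self.hdc_lde + self.ldc_hde + self.ldc_lde

    @property
    def obs_hdc(self) -> int:
        return self.hdc_hde + self.hdc_lde

    @property
    def obs_ldc(self) -> int:
        return self.ldc_hde + self.ldc_lde

    @property
    def obs_hde(self) -> int:
        return self.hdc_hde + self.ldc_hde

    @property
    def obs_lde(self) -> int:
        return self.hdc_lde + self.ldc_lde


@dataclass
class ThresholdResult:
    """Optimal thresholds for one focal gene with the attached statistics.

    ``labels`` holds each point's partition (index into ``PARTITIONS``);
    ``valid`` is False when no admissible candidate existed, in which case
    the numeric fields are NaN and the gene is excluded downstream.
    """

    focal_gene: str | None
    z_star: float
    t_star: float
    chi2: float
    p_raw: float
    table: ContingencyTable | None
    direction: str | None  # "positive" | "negative"
    residual: float
    residual_p: float
    labels: np.ndarray | None
    valid: bool
    n_candidates: int
    n_valid_candidates: int


def quadrant_partition(abs_z: np.ndarray, abs_t: np.ndarray,
                       z_thr: float, t_thr: float):
    """Label every point by its quadrant; "high" is inclusive (>=).

    Returns ``(table, labels)`` where labels index into :data:`PARTITIONS`.
    """
    abs_z = np.asarray(abs_z, dtype=np.float64)
    abs_t = np.asarray(abs_t, dtype=np.float64)
    if abs_z.size == 0:
        raise ValueError("empty point list")
    hdc = abs_z >= z_thr
    hde = abs_t >= t_thr
    labels = np.where(hdc, np.where(hde, 0, 1), np.where(hde, 2, 3))
    table = ContingencyTable(
        hdc_hde=int(np.sum(hdc & hde)),
        hdc_lde=int(np.sum(hdc & ~hde)),
        ldc_hde=int(np.sum(~hdc & hde)),
        ldc_lde=int(np.sum(~hdc & ~hde)),
    )
    return table, labels


def expected_counts(table: ContingencyTable) -> dict[str, float]:
    """Independence-expected cell counts, exp = (row total x col total) / n."""
    n = table.n
    if n <= 0:
        raise ValueError("empty table")
    return {
        "HDC_HDE": table.obs_hdc * table.obs_hde / n,
        "HDC_LDE": table.obs_hdc * table.obs_lde / n,
        "LDC_HDE": table.obs_ldc * table.obs_hde / n,
        "LDC_LDE": table.obs_ldc * table.obs_lde / n,
    }


def pearson_chi2(table: ContingencyTable) -> float:
    """Pearson's chi-square, sum (obs - exp)^2 / exp over the four cells.

    Undefined (raises) when a margin is zero; equal to
    n (ad - bc)^2 / (r1 r2 c1 c2) for a 2x2 table.
    """
    if min(table.obs_hdc, table.obs_ldc, table.obs_hde, table.obs_lde) == 0:
        raise ValueError("zero margin: chi-square undefined")
    exp = expected_counts(table)
    obs = {
        "HDC_HDE": table.hdc_hde,
        "HDC_LDE": table.hdc_lde,
        "LDC_HDE": table.ldc_hde,
        "LDC_LDE": table.ldc_lde,
    }
    return float(sum((obs[k] - exp[k]) ** 2 / exp[k] for k in obs))


def _chi2_from_counts(a, r1, c1, n):
    """Vectorized 2x2 chi-square from the HDC_HDE count and the margins.

    Uses the closed form n (ad - bc)^2 / (r1 r2 c1 c2); evaluated
    identically in the fast sweep and the naive scan so the two are
    bit-comparable.
    """
    a = a.astype(np.float64)
    r1 = r1.astype(np.float64)
    c1 = c1.astype(np.float64)
    n = float(n)
    b = r1 - a
    c = c1 - a
    d = n - r1 - c1 + a
    num = n * (a * d - b * c) ** 2
    den = r1 * (n - r1) * c1 * (n - c1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _candidate_validity(a, r1, c1, n, min_expected):
    """Admissibility mask: non-zero margins and every expected cell at or
    above ``min_expected``."""
    margins_ok = (r1 > 0) & (r1 < n) & (c1 > 0) & (c1 < n)
    min_exp = (
        np.minimum(r1, n - r1).astype(np.float64)
        * np.minimum(c1, n - c1).astype(np.float64)
        / n
    )
    return margins_ok & (min_exp >= min_expected)


def _finalize(abs_z, abs_t, best_idx, chi2_vals, n_valid, focal_gene, config):
    z_star = float(abs_z[best_idx])
    t_star = float(abs_t[best_idx])
    table, labels = quadrant_partition(abs_z, abs_t, z_star, t_star)
    chi2_val = float(chi2_vals[best_idx])
    p_raw = float(stats.chi2.sf(chi2_val, df=1))
    residual, direction, residual_p = adjusted_residual(table)
    return ThresholdResult(
        focal_gene=focal_gene,
        z_star=z_star,
        t_star=t_star,
        chi2=chi2_val,
        p_raw=p_raw,
        table=table,
        direction=direction,
        residual=residual,
        residual_p=residual_p,
        labels=labels,
        valid=True,
        n_candidates=int(abs_z.size),
        n_valid_candidates=int(n_valid),
    )


def _no_threshold(focal_gene, n) -> ThresholdResult:
    return ThresholdResult(
        focal_gene=focal_gene, z_star=np.nan, t_star=np.nan, chi2=np.nan,
        p_raw=np.nan, table=None, direction=None, residual=np.nan,
        residual_p=np.nan, labels=None, valid=False,
        n_candidates=int(n), n_valid_candidates=0,
    )


def _tie_broken_argmax(abs_z, abs_t, chi2_vals, valid):
    """Index of the maximal chi-square among valid candidates; ties resolved
    to the lexicographically smallest (z, t)."""
    masked = np.where(valid, chi2_vals, -np.inf)
    best = masked.max()
    if not np.isfinite(best):
        return None
    tied = np.flatnonzero(masked == best)
    if tied.size == 1:
        return int(tied[0])
    order = np.lexsort((abs_t[tied], abs_z[tied]))
    return int(tied[order[0]])


def select_optimal_thresholds(
    abs_z: np.ndarray,
    abs_t: np.ndarray,
    *,
    focal_gene: str | None = None,
    config: ChimaxConfig | None = None,
    candidate_mask: np.ndarray | None = None,
    method: str = "fast",
) -> ThresholdResult:
    """Scan the observed (|Z|, |t|) pairs as threshold candidates and return
    the chi-square-maximizing pair.

    ``candidate_mask`` excludes points (e.g. degenerate genes) from serving
    as candidates while keeping them as points. ``method="naive"`` runs the
    quadratic reference scan; the default sweep is O(n log n) and returns
    bit-identical results.
    """
    config = config or ChimaxConfig()
    abs_z = np.asarray(abs_z, dtype=np.float64)
    abs_t = np.asarray(abs_t, dtype=np.float64)
    n = abs_z.size
    if n != abs_t.size:
        raise ValueError("abs_z and abs_t must have equal length")
    if n < 2:
        return _no_threshold(focal_gene, n)

    if method == "fast":
        a, r1, c1 = dominance_counts(abs_z, abs_t)
    elif method == "naive":
        a = np.empty(n, dtype=np.int64)
        r1 = np.empty(n, dtype=np.int64)
        c1 = np.empty(n, dtype=np.int64)
        for j in range(n):
            hdc = abs_z >= abs_z[j]
            hde = abs_t >= abs_t[j]
            a[j] = np.sum(hdc & hde)
            r1[j] = np.sum(hdc)
            c1[j] = np.sum(hde)
    else:
        raise ValueError(f"unknown method {method!r}")

    valid = _candidate_validity(a, r1, c1, n, config.min_expected)
    if candidate_mask is not None:
        valid &= np.asarray(candidate_mask, dtype=bool)
    chi2_vals = _chi2_from_counts(a, r1, c1, n)
    best_idx = _tie_broken_argmax(abs_z, abs_t, chi2_vals, valid)
    if best_idx is None:
        return _no_threshold(focal_gene, n)
    return _finalize(abs_z, abs_t, best_idx, chi2_vals, int(valid.sum()),
                     focal_gene, config)


def adjusted_residual(table: ContingencyTable):
    """Standardized residual of the high-DC/high-DE cell.

    d = (obs - exp) / sqrt(exp (1 - row/n)(1 - col/n)); its sign gives the
    association direction and the one-sided upper-tail normal p tests
    whether the cell is over-populated.
    """
    n = table.n
    if min(table.obs_hdc, table.obs_ldc, table.obs_hde, table.obs_lde) == 0:
        raise ValueError("zero margin: adjusted residual undefined")
    exp11 = table.obs_hdc * table.obs_hde / n
    denom = np.sqrt(exp11 * (1 - table.obs_hdc / n) * (1 - table.obs_hde / n))
    d = (table.hdc_hde - exp11) / denom
    direction = "positive" if table.hdc_hde > exp11 else "negative"
    p = float(stats.norm.sf(d))
    return float(d), direction, p


def adjust_pvalues(raw_p: np.ndarray, n_candidates: int | np.ndarray,
                   config: ChimaxConfig | None = None,
                   n_valid: np.ndarray | None = None):
    """Two-stage correction of the per-gene maximum-chi-square p-values.

    Stage 1 is Bonferroni for the candidate scan within each gene
    (p x candidate count, capped at 1); stage 2 is Benjamini-Hochberg
    across the genes' stage-1 values. NaN entries (no-threshold genes)
    pass through as NaN.
    """
    config = config or ChimaxConfig()
    raw_p = np.asarray(raw_p, dtype=np.float64)
    if config.bonferroni_by_valid:
        if n_valid is None:
            raise ValueError("bonferroni_by_valid requires n_valid")
        mult = np.asarray(n_valid, dtype=np.float64)
    else:
        mult = np.broadcast_to(np.asarray(n_candidates, dtype=np.float64),
                               raw_p.shape)
    stage1 = np.minimum(1.0, raw_p * mult)
    stage2 = np.full_like(stage1, np.nan)
    ok = ~np.isnan(stage1)
    if ok.any():
        stage2[ok] = multipletests(stage1[ok], method="fdr_bh")[1]
    return stage1, stage2
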