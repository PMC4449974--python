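"""Per-gene differential expression and differential co-expression statistics.

Differential expression (DE) of gene *i* is the unpooled (Welch-form)
two-sample t statistic between case (D) and control (N) samples,

    t_i = (mean_D - mean_N) / sqrt(s_D^2/n_D + s_N^2/n_N),

whose magnitude |t_i| is the quantity dichotomized downstream. Differential
co-expression (DC) of a gene pair (i, j) compares the class-specific Pearson
correlations through their Fisher z-transforms:

    Z_ij = |z_N - z_D| / sqrt(1/(n_N - 3) + 1/(n_D - 3)),

which is approximately standard normal when the population correlation is
the same in both classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CLAMP = 1.0 - 1e-12


@dataclass
class DEVector:
    """Signed and absolute Welch t per gene, with the component summaries."""

    t: np.ndarray
    abs_t: np.ndarray
    mean_case: np.ndarray
    mean_control: np.ndarray
    sd_case: np.ndarray
    sd_control: np.ndarray
    n_case: int
    n_control: int
    degenerate: np.ndarray  # True where both class SDs are zero


@dataclass
class GenePairStats:
    """DC of every other gene to one focal gene, aligned with |t|.

    ``abs_z[k]`` is Z between the focal gene and ``gene_ids[k]``;
    ``degenerate`` marks partner genes that are constant within a class
    (their correlation is taken as 0 and they are excluded as threshold
    candidates downstream).
    """

    focal_gene: str
    gene_ids: list[str]
    abs_z: np.ndarray
    abs_t: np.ndarray
    r_control: np.ndarray
    r_case: np.ndarray
    degenerate: np.ndarray


def compute_de(dataset) -> DEVector:
    """Welch t statistic (case vs control) for every gene.

    Genes with zero variance in both classes get t = 0 and a degenerate flag
    rather than NaN, so vector lengths stay aligned with the dataset.
    """
    xd = dataset.case_values
    xn = dataset.control_values
    nd, nn = xd.shape[1], xn.shape[1]
    if nd < 2 or nn < 2:
        raise ValueError(f"need >= 2 samples per class for t, got {nd} case / {nn} control")
    md = xd.mean(axis=1)
    mn = xn.mean(axis=1)
    sd = xd.std(axis=1, ddof=1)
    sn = xn.std(axis=1, ddof=1)
    denom = np.sqrt(sd**2 / nd + sn**2 / nn)
    degenerate = denom == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (md - mn) / np.where(degenerate, 1.0, denom))
    return DEVector(
        t=t, abs_t=np.abs(t), mean_case=md, mean_control=mn,
        sd_case=sd, sd_control=sn, n_case=nd, n_control=nn,
        degenerate=degenerate,
    )


def fisher_z(r):
    """Fisher z-transform, z = arctanh(r), with |r| clamped below 1.

    Odd and strictly increasing on (-1, 1); the clamp (1 - 1e-12) keeps
    correlations of exactly +/-1 finite.
    """
    r = np.clip(np.asarray(r, dtype=np.float64), -_CLAMP, _CLAMP)
    return np.arctanh(r)


def _class_correlations(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix of the rows; constant rows get r = 0 to
    every partner and are flagged."""
    sd = values.std(axis=1)
    constant = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(values)
    r = np.atleast_2d(r)
    if constant.any():
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    # float error can push |r| slightly over 1
    np.clip(r, -1.0, 1.0, out=r)
    return r, constant


def dc_matrix(dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Full |Z| matrix plus both class correlation matrices.

    Returns ``(abs_z, r_control, r_case, degenerate)`` where ``degenerate``
    flags genes constant in either class. Requires n - 3 > 0 in both classes
    (the Fisher-z variance is 1/(n - 3)).
    """
    nd, nn = dataset.n_case, dataset.n_control
    if nd <= 3 or nn <= 3:
        raise ValueError(
            f"differential co-expression needs > 3 samples per class "
            f"(got {nd} case / {nn} control)"
        )
    r_case, const_case = _class_correlations(dataset.case_values)
    r_control, const_control = _class_correlations(dataset.control_values)
    denom = np.sqrt(1.0 / (nn - 3) + 1.0 / (nd - 3))
    abs_z = np.abs(fisher_z(r_control) - fisher_z(r_case)) / denom
    np.fill_diagonal(abs_z, 0.0)
    return abs_z, r_control, r_case, const_case | const_control


def compute_dc_row(dataset, focal_gene: str, de: DEVector | None = None) -> GenePairStats:
    """DC of every other gene to ``focal_gene``, paired with each partner's |t|."""
    if de is None:
        de = compute_de(dataset)
    i = dataset.gene_index(focal_gene)
    abs_z, r_control, r_case, degenerate = dc_matrix(dataset)
    keep = np.arange(dataset.n_genes) != i
    return GenePairStats(
        focal_gene=focal_gene,
        gene_ids=[g for k, g in enumerate(dataset.gene_ids) if keep[k]],
        abs_z=abs_z[i, keep],
        abs_t=de.abs_t[keep],
        r_control=r_control[i, keep],
        r_case=r_case[i, keep],
        degenerate=(degenerate | de.degenerate)[keep],
    )
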