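"""Synthetic two-class expression data with planted DC/DE structure.

A single latent factor drives a block of genes in the case class only:
block gene g is sqrt(rho) * f + sqrt(1 - rho) * noise (+ a mean shift
delta), so block pairs have population correlation rho among cases and 0
among controls — simultaneous high differential co-expression and high
differential expression, exactly the joint signal the threshold search is
built to detect.

Two distractor groups make the planted set separable *specifically* by the
combined criterion: DE-only genes carry the same mean shift without the
shared factor (they dilute enrichment of any high-DE partition) and
DC-only genes load on the same case-only factor without a mean shift (they
are highly differentially co-expressed with the block, diluting high-DC
partitions). Background genes are independent noise in both classes.

The defaults (1000 genes, 50-gene block, 100 + 100 distractors, rho = 0.8,
delta = 1.5 noise SDs, 100 + 100 samples) give a clearly separable planted
block at a realistic two-class microarray scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset, GeneSetCollection


@dataclass
class SynthSpec:
    """Parameters of the planted-block generator.

    ``block_size`` genes share a case-only latent factor with pairwise
    correlation ``rho`` and receive a case mean shift ``delta`` (in units
    of the noise SD). ``n_de_only`` genes get the shift without the factor;
    ``n_dc_only`` genes load on the same factor without the shift (both
    default to twice the block size). Everything else is i.i.d. Gaussian
    noise.
    """

    m: int = 1000
    n_case: int = 100
    n_control: int = 100
    block_size: int = 50
    n_de_only: int | None = None
    n_dc_only: int | None = None
    rho: float = 0.8
    delta: float = 1.5
    noise_sd: float = 1.0
    n_decoy_sets: int = 5
    decoy_set_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_only is None:
            self.n_de_only = 2 * self.block_size
        if self.n_dc_only is None:
            self.n_dc_only = 2 * self.block_size
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.block_size <= 0 or (
            self.block_size + self.n_de_only + self.n_dc_only >= self.m
        ):
            raise ValueError("planted groups must leave background genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_case, self.n_control) < 4:
            raise ValueError("need >= 4 samples per class")


PLANTED_SET_ID = "PLANTED_BLOCK"


def generate(spec: SynthSpec) -> tuple[ExpressionDataset, list[str], GeneSetCollection]:
    """Generate a dataset, the planted-block gene ids, and a gene-set
    collection holding the planted set plus random decoy sets.

    Identical specs (including seed) generate identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    m, nd, nn = spec.m, spec.n_case, spec.n_control
    gene_ids = [f"G{i:05d}" for i in range(m)]
    case_ids = [f"D{j:04d}" for j in range(nd)]
    control_ids = [f"N{j:04d}" for j in range(nn)]

    case = rng.standard_normal((m, nd)) * spec.noise_sd
    control = rng.standard_normal((m, nn)) * spec.noise_sd

    block = np.arange(spec.block_size)
    dc_only = np.arange(spec.block_size, spec.block_size + spec.n_dc_only)
    de_only = np.arange(spec.block_size + spec.n_dc_only,
                        spec.block_size + spec.n_dc_only + spec.n_de_only)
    # one latent factor drives both the block and the DC-only genes, so a
    # block focal gene sees high-DC partners both inside and outside the set
    factor = rng.standard_normal(nd)
    loaded = np.concatenate([block, dc_only])
    case[loaded, :] = spec.noise_sd * (
        np.sqrt(spec.rho) * factor[None, :]
        + np.sqrt(1.0 - spec.rho) * case[loaded, :] / spec.noise_sd
    )
    case[block, :] += spec.delta * spec.noise_sd
    if spec.n_de_only:
        case[de_only, :] += spec.delta * spec.noise_sd

    values = np.concatenate([case, control], axis=1)
    sample_ids = case_ids + control_ids
    class_of = {s: "case" for s in case_ids}
    class_of.update({s: "control" for s in control_ids})
    dataset = ExpressionDataset(
        gene_ids=gene_ids, sample_ids=sample_ids,
        values=values, class_of_sample=class_of,
    )

    planted = [gene_ids[i] for i in block]
    sets = {PLANTED_SET_ID: ("planted co-expression block", tuple(planted))}
    background = np.arange(spec.block_size + spec.n_dc_only + spec.n_de_only, m)
    for s in range(spec.n_decoy_sets):
        size = min(spec.decoy_set_size, background.size)
        pick = rng.choice(background, size=size, replace=False)
        sets[f"DECOY_{s:02d}"] = (
            "random background set",
            tuple(gene_ids[i] for i in sorted(pick)),
        )
    return dataset, planted, GeneSetCollection(sets)
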