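"""Gene-set enrichment of threshold partitions and functional-information gains.

A focal gene's optimal thresholds partition the other genes into four
quadrants; the combined high-DC/high-DE partition and the single-criterion
HDC and HDE partitions (unions of two quadrants at the same thresholds) are
each scored against every functional gene set with a two-tailed Fisher exact
test. Per partition only the *best associated* set (smallest Bonferroni-
adjusted p over the k sets) is carried forward. Functional information is
FI = -log2(adjusted p) in bits, and the minimum FI gain

    delta* = min(FI_combined - FI_HDE, FI_combined - FI_HDC)

is positive exactly when combining the DC and DE criteria beats both
single criteria for that set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import GeneSetCollection

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class EnrichmentRecord:
    """Best-associated-set scores for one focal gene's partitions."""

    focal_gene: str
    set_id: str
    overlap: int
    p_raw: float
    p_adjusted: float  # combined partition: Bonferroni x k, then BH
    p_hdc: float  # same set scored on the HDC-only partition (same stages)
    p_hde: float
    fi_combined: float
    fi_hdc: float
    fi_hde: float
    gain_vs_hde: float
    gain_vs_hdc: float
    gain_min: float


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-tailed in the usual sense: the sum of the probabilities of all
    tables with the observed margins whose point hypergeometric probability
    does not exceed the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative count")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def overlap_table(partition: frozenset[str] | set[str], gene_set: frozenset[str],
                  universe: frozenset[str] | set[str]) -> tuple[int, int, int, int]:
    """2x2 overlap counts of a partition against a gene set within a universe."""
    part = set(partition) & set(universe)
    gs = set(gene_set) & set(universe)
    a = len(part & gs)
    b = len(part) - a
    c = len(gs) - a
    d = len(universe) - a - b - c
    return a, b, c, d


def best_associated_set(
    partition_members,
    collection: GeneSetCollection,
    universe,
    k: int | None = None,
) -> tuple[str, float, float, int] | None:
    """Per-set Fisher p with Bonferroni x k; return the winner.

    Returns ``(set_id, p_raw, p_bonferroni, overlap)`` for the smallest
    adjusted p (ties broken by set id), or None for an empty partition or
    empty collection.
    """
    members = set(partition_members)
    if not members or len(collection) == 0:
        return None
    k = k if k is not None else len(collection)
    universe = frozenset(universe)
    best: tuple[float, str, float, int] | None = None
    for sid in sorted(collection.sets):
        a, b, c, d = overlap_table(members, collection.members(sid), universe)
        p = fisher_exact_two_tailed(a, b, c, d)
        if best is None or (p, sid) < (best[0], best[1]):
            best = (p, sid, min(1.0, p * k), a)
    p, sid, p_adj, a = best
    return sid, p, p_adj, a


def functional_information(p_adjusted: float) -> float:
    """FI = -log2(p) in bits, with p floored at 1e-300 to stay finite."""
    p = max(float(p_adjusted), _P_FLOOR)
    if p > 1:
        p = 1.0
    return float(-np.log2(p))


def fi_gains(fi_combined: float, fi_hdc: float, fi_hde: float):
    """(gain over HDE alone, gain over HDC alone, minimum of the two).

    Negative gains are meaningful: the combined criterion carried less
    functional information than a single criterion.
    """
    d1 = fi_combined - fi_hde
    d2 = fi_combined - fi_hdc
    return d1, d2, min(d1, d2)


def combined_partitions(gene_ids, labels: np.ndarray) -> dict[str, list[str]]:
    """Partition member lists at a gene's optimal thresholds.

    The base quadrants (labels 0..3 = HDC_HDE, HDC_LDE, LDC_HDE, LDC_LDE)
    are disjoint; the single-criterion partitions are their pairwise unions
    at the same thresholds (HDC = HDC_HDE + HDC_LDE, etc.).
    """
    gene_ids = list(gene_ids)
    labels = np.asarray(labels)
    base = {name: [] for name in ("HDC_HDE", "HDC_LDE", "LDC_HDE", "LDC_LDE")}
    names = ("HDC_HDE", "HDC_LDE", "LDC_HDE", "LDC_LDE")
    for g, lab in zip(gene_ids, labels):
        base[names[int(lab)]].append(g)
    return {
        **base,
        "HDC": base["HDC_HDE"] + base["HDC_LDE"],
        "HDE": base["HDC_HDE"] + base["LDC_HDE"],
        "LDC": base["LDC_HDE"] + base["LDC_LDE"],
        "LDE": base["HDC_LDE"] + base["LDC_LDE"],
    }


def score_partitions(
    partition_sets: dict[str, frozenset[str]],
    collection: GeneSetCollection,
    universe,
    focal_gene: str,
) -> EnrichmentRecord | None:
    """Score one focal gene: best set of its combined partition, FI of the
    same set in the HDC-only and HDE-only partitions, and the FI gains.

    ``p_adjusted`` carries only the within-gene Bonferroni here; the caller
    applies BH across focal genes and recomputes the combined FI from the
    final adjusted p.
    """
    k = len(collection)
    best = best_associated_set(partition_sets["HDC_HDE"], collection, universe, k)
    if best is None:
        return None
    sid, p_raw, p_adj, overlap = best
    gs = collection.members(sid)
    ps = {}
    for name in ("HDC", "HDE"):
        a, b, c, d = overlap_table(partition_sets[name], gs, universe)
        ps[name] = min(1.0, fisher_exact_two_tailed(a, b, c, d) * k)
    fi_comb = functional_information(p_adj)
    fi_hdc = functional_information(ps["HDC"])
    fi_hde = functional_information(ps["HDE"])
    d1, d2, dmin = fi_gains(fi_comb, fi_hdc, fi_hde)
    return EnrichmentRecord(
        focal_gene=focal_gene, set_id=sid, overlap=overlap,
        p_raw=p_raw, p_adjusted=p_adj, p_hdc=ps["HDC"], p_hde=ps["HDE"],
        fi_combined=fi_comb, fi_hdc=fi_hdc, fi_hde=fi_hde,
        gain_vs_hde=d1, gain_vs_hdc=d2, gain_min=dmin,
    )


def bh_across_partitions(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Second correction stage: BH across the m' selected focal genes.

    Each partition family (combined, HDC-only, HDE-only) contributes m'
    Bonferroni-adjusted p-values and is BH-corrected as its own family, so
    the three FI values stay comparable; FI values and gains are recomputed
    from the final adjusted p-values.
    """
    if not records:
        return records
    adjusted = {}
    for family, attr in (("combined", "p_adjusted"),
                         ("hdc", "p_hdc"), ("hde", "p_hde")):
        p = np.array([getattr(r, attr) for r in records])
        adjusted[family] = multipletests(p, method="fdr_bh")[1]
    out = []
    for i, r in enumerate(records):
        fi_comb = functional_information(adjusted["combined"][i])
        fi_hdc = functional_information(adjusted["hdc"][i])
        fi_hde = functional_information(adjusted["hde"][i])
        d1, d2, dmin = fi_gains(fi_comb, fi_hdc, fi_hde)
        out.append(EnrichmentRecord(
            focal_gene=r.focal_gene, set_id=r.set_id, overlap=r.overlap,
            p_raw=r.p_raw, p_adjusted=float(adjusted["combined"][i]),
            p_hdc=float(adjusted["hdc"][i]), p_hde=float(adjusted["hde"][i]),
            fi_combined=fi_comb, fi_hdc=fi_hdc, fi_hde=fi_hde,
            gain_vs_hde=d1, gain_vs_hdc=d2, gain_min=dmin,
        ))
    return out


def summarize_by_gene_set(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Group records by best-associated set; mean minimum FI gain per set,
    sorted descending (ties broken by set id)."""
    if not records:
        return pd.DataFrame(columns=["set_id", "n_partitions", "mean_min_fi_gain"])
    df = pd.DataFrame(
        {"set_id": [r.set_id for r in records],
         "gain_min": [r.gain_min for r in records]}
    )
    out = (
        df.groupby("set_id")["gain_min"]
        .agg(n_partitions="size", mean_min_fi_gain="mean")
        .reset_index()
        .sort_values(["mean_min_fi_gain", "set_id"],
                     ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    out["n_partitions"] = out["n_partitions"].astype(int)
    return out
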