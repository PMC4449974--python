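"""Domain containers and file I/O for two-class expression data and gene sets.

The canonical on-disk form is a pair of TSV files — an expression matrix
(first column ``gene_id``, remaining columns sample ids) and a two-column
sample-to-class table — plus functional gene sets in standard GMT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

RESULT_COLUMNS = [
    "gene_id",
    "t",
    "abs_t",
    "z_star",
    "t_star",
    "max_chi2",
    "p_raw",
    "p_bonferroni",
    "p_bh",
    "direction",
    "n_hdc_hde",
    "n_hdc_lde",
    "n_ldc_hde",
    "n_ldc_lde",
    "adjusted_residual",
    "residual_p",
    "residual_p_bh",
]

ENRICHMENT_COLUMNS = [
    "gene_id",
    "partition",
    "set_id",
    "overlap",
    "p_raw",
    "p_adjusted",
    "fi",
    "fi_gain_vs_hde",
    "fi_gain_vs_hdc",
    "fi_gain_min",
]


class DataError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with a two-class sample labelling.

    Expression values are assumed to be on a roughly symmetric (e.g. log)
    scale, but no scale is enforced. ``class_of_sample`` maps every sample id
    to ``"case"`` or ``"control"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64, no NaN
    class_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        if np.isnan(self.values).any():
            raise DataError("matrix contains missing values")
        for s in self.sample_ids:
            cls = self.class_of_sample.get(s)
            if cls not in (CASE, CONTROL):
                raise DataError(f"sample {s!r} has no valid class label")
        if self.n_case == 0 or self.n_control == 0:
            raise DataError("both classes must be non-empty")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array(
            [self.class_of_sample[s] == CASE for s in self.sample_ids], dtype=bool
        )

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return len(self.sample_ids) - self.n_case

    @property
    def case_values(self) -> np.ndarray:
        return self.values[:, self.case_mask]

    @property
    def control_values(self) -> np.ndarray:
        return self.values[:, ~self.case_mask]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None


@dataclass
class GeneSetCollection:
    """Named functional gene sets (flat membership lists, as read from GMT)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> frozenset[str]:
        return frozenset(self.sets[set_id][1])

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def restrict_to(self, universe, min_set_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets that fall below
        ``min_set_size`` members (dropped sets are logged)."""
        uni = set(universe)
        kept: dict[str, tuple[str, tuple[str, ...]]] = {}
        dropped = 0
        for sid, (desc, members) in self.sets.items():
            inter = tuple(g for g in members if g in uni)
            if len(inter) >= min_set_size:
                kept[sid] = (desc, inter)
            else:
                dropped += 1
        if dropped:
            log.info(
                "restrict_to: dropped %d gene sets below %d members",
                dropped,
                min_set_size,
            )
        return GeneSetCollection(kept)


def read_expression(
    matrix_path,
    labels_path,
    *,
    case_token: str = "case",
    control_token: str = "control",
    min_class_size: int = 2,
) -> ExpressionDataset:
    """Load the two-file expression input.

    Rows containing any missing value are dropped (and counted in the log);
    nothing is ever imputed. Samples present in the matrix but absent from the
    labels file are dropped with a warning; a label for a sample that is not a
    matrix column is a hard error.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype={0: str})
    if mat.index.name != "gene_id":
        raise DataError(
            f"first matrix column must be named 'gene_id', got {mat.index.name!r}"
        )
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene ids in matrix: {dups[:5]}")

    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if list(labels.columns[:2]) != ["sample_id", "class"]:
        raise DataError("labels file must have columns 'sample_id' and 'class'")
    unknown = set(labels["sample_id"]) - set(mat.columns)
    if unknown:
        raise DataError(f"labels reference samples absent from matrix: {sorted(unknown)[:5]}")
    token_map = {case_token: CASE, control_token: CONTROL}
    bad = set(labels["class"]) - set(token_map)
    if bad:
        raise DataError(
            f"unrecognized class tokens {sorted(bad)}; expected "
            f"{case_token!r} or {control_token!r}"
        )
    class_of = {
        s: token_map[c] for s, c in zip(labels["sample_id"], labels["class"])
    }

    unlabeled = [c for c in mat.columns if c not in class_of]
    if unlabeled:
        log.warning("dropping %d unlabeled matrix samples", len(unlabeled))
        mat = mat.drop(columns=unlabeled)

    mat = mat.apply(pd.to_numeric, errors="coerce")
    keep = mat.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d gene rows with missing values", n_dropped)
        mat = mat.loc[keep]
    if mat.shape[0] < 2:
        raise DataError("fewer than 2 genes after filtering")

    ds = ExpressionDataset(
        gene_ids=list(mat.index),
        sample_ids=list(mat.columns),
        values=mat.to_numpy(dtype=np.float64),
        class_of_sample=class_of,
    )
    for name, n in ((case_token, ds.n_case), (control_token, ds.n_control)):
        if n < min_class_size:
            raise DataError(f"class {name!r} has only {n} samples (minimum {min_class_size})")
    return ds


def read_gmt(path) -> GeneSetCollection:
    """Read standard GMT (set id, description, then member gene ids).

    Duplicate members within a set are de-duplicated preserving order;
    a repeated set id or a line with fewer than 3 fields is an error.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            sid, desc = fields[0], fields[1]
            if sid in sets:
                raise DataError(f"GMT line {lineno}: duplicate set id {sid!r}")
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise DataError(f"GMT line {lineno}: set {sid!r} has no members")
            sets[sid] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


def write_results(table: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    """Write a result table as TSV with a fixed column order and >= 6
    significant digits for floats; round-trips through :func:`read_results`."""
    cols = columns if columns is not None else RESULT_COLUMNS
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise DataError(f"result table missing columns: {missing}")
    table.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_labels(dataset: ExpressionDataset, path,
                 case_token: str = "case", control_token: str = "control") -> None:
    tok = {CASE: case_token, CONTROL: control_token}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tclass\n")
        for s in dataset.sample_ids:
            fh.write(f"{s}\t{tok[dataset.class_of_sample[s]]}\n")


def write_expression(dataset: ExpressionDataset, path) -> None:
    df = pd.DataFrame(dataset.values, index=pd.Index(dataset.gene_ids, name="gene_id"),
                      columns=dataset.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.8g")
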