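import numpy as np
import pytest

from dcde.datasets import ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples (2 case / 2 control), hand-pickable values."""
    return ExpressionDataset(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["d1", "d2", "n1", "n2"],
        values=np.array([
            [2.0, 4.0, 0.0, 2.0],
            [1.0, 1.0, 1.0, 1.0],
            [5.0, 3.0, 2.0, 6.0],
        ]),
        class_of_sample={"d1": "case", "d2": "case", "n1": "control", "n2": "control"},
    )


def make_dataset(rng: np.random.Generator, m: int = 20, n_case: int = 30,
                 n_control: int = 25) -> ExpressionDataset:
    """Random two-class dataset with no planted structure."""
    case = [f"d{j}" for j in range(n_case)]
    control = [f"n{j}" for j in range(n_control)]
    class_of = {s: "case" for s in case}
    class_of.update({s: "control" for s in control})
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(m)],
        sample_ids=case + control,
        values=rng.standard_normal((m, n_case + n_control)),
        class_of_sample=class_of,
    )


def write_matrix_tsv(path, gene_rows: dict[str, list], sample_ids: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(sample_ids) + "\n")
        for gid, vals in gene_rows.items():
            fh.write(gid + "\t" + "\t".join(str(v) for v in vals) + "\n")


def write_labels_tsv(path, labels: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for s, c in labels.items():
            fh.write(f"{s}\t{c}\n")
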