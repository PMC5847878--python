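import numpy as np
import pandas as pd
import pytest

from dietswitch.synthetic import GeneClassSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small four-group dataset with all three gene classes planted."""
    return generate_dataset(
        n_genes=400,
        n_per_group=6,
        class_spec=GeneClassSpec(f_null=0.6, f_plastic=0.2, f_persistent=0.2),
        seed=42,
    )


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, hand-written values."""
    return pd.DataFrame(
        [[5.0, 6.0, 7.0, 8.0], [1.0, 1.1, 0.9, 1.0], [4.0, 4.5, 5.0, 5.5]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def tiny_sheet():
    return pd.Series(
        ["CR", "CR", "MF", "MF"],
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        name="group",
    )


def make_de_table(gene_ids, p, logfc):
    """Minimal DE-result table with the columns the classifier reads."""
    return pd.DataFrame(
        {"p": np.asarray(p, dtype=float), "logFC": np.asarray(logfc, dtype=float)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
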