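import numpy as np
import pandas as pd
import pytest

from mutexsl import (
    AlterationProfile,
    EventMatrix,
    GisticMatrix,
    ExpressionZMatrix,
)


def write_tsv(path, genes, samples, rows):
    """Write a gene-major TSV fixture from row lists."""
    lines = ["gene\t" + "\t".join(samples)]
    for gene, row in zip(genes, rows):
        lines.append(gene + "\t" + "\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def gistic_tsv(tmp_path):
    return write_tsv(
        tmp_path / "gistic.tsv",
        ["TP53", "PTEN", "MYC"],
        ["s1", "s2", "s3", "s4"],
        [[0, 2, -2, 1], [-2, 0, 0, -1], [2, 2, 0, 0]],
    )


@pytest.fixture
def zscore_tsv(tmp_path):
    return write_tsv(
        tmp_path / "z.tsv",
        ["TP53", "PTEN", "MYC"],
        ["e1", "e2", "e3"],
        [[0.5, 2.5, -3.1], [-2.0, 0.0, 1.99], [2.0, "NA", 0.1]],
    )


def make_profile(loss: dict, gain: dict, samples: list[str],
                 cohort: str = "toy") -> AlterationProfile:
    """Build a profile from {gene: [samples with event]} dicts."""
    genes = sorted(set(loss) | set(gain))
    loss_df = pd.DataFrame(False, index=genes, columns=samples)
    gain_df = pd.DataFrame(False, index=genes, columns=samples)
    for gene, hit in loss.items():
        loss_df.loc[gene, hit] = True
    for gene, hit in gain.items():
        gain_df.loc[gene, hit] = True
    avail = pd.DataFrame(True, index=samples,
                         columns=["copy_number", "expression"])
    return AlterationProfile(loss_df, gain_df, avail, cohort)


@pytest.fixture
def toy_profile():
    samples = [f"s{i}" for i in range(1, 7)]
    return make_profile(
        loss={"A": ["s1", "s2", "s3"], "C": ["s1"]},
        gain={"B": ["s4", "s5", "s6"], "D": ["s1", "s2", "s3"]},
        samples=samples,
    )
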