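import numpy as np
import pytest

from utrmotif.io import UtrAlignment, UtrRecord

SPECIES = ("human", "mouse", "rat", "dog")


def make_alignment(utr_id: str, rows: dict[str, str] | list[str]) -> UtrAlignment:
    """Alignment from explicit rows; a bare list is assigned to SPECIES order."""
    if isinstance(rows, list):
        rows = dict(zip(SPECIES, rows))
    return UtrAlignment(utr_id, rows, reference_species="human")


def random_utrs(rng: np.random.Generator, n: int, length: int,
                comp=(0.25, 0.25, 0.25, 0.25)) -> list[UtrRecord]:
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        seq = "".join(rng.choice(bases, size=length, p=list(comp)))
        out.append(UtrRecord(f"u{i:03d}", f"g{i:03d}", seq))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset with alignments, shared across fast tests."""
    from utrmotif.simulate import generate_expression_table, generate_utr_set, profile

    cfg = profile("tiny", seed=5)
    utrs, alignments, truth = generate_utr_set(cfg)
    expression = generate_expression_table(truth, cfg)
    return cfg, utrs, alignments, truth, expression
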