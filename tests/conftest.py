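import numpy as np
import pytest

from cnedfe.elements import AlignedElement, Anchor

SPECIES = ("human", "macaque", "mouse", "chicken", "frog", "zebrafish", "fugu")


def make_element(
    columns: dict[str, str] | list[str],
    element_id: str = "e1",
    chrom: str = "chr1",
    start: int = 1000,
    strand: str = "+",
    focal: str = "human",
) -> AlignedElement:
    """Build a seven-species element from per-species sequences.

    ``columns`` maps species to its aligned sequence; species not named get
    the human sequence (or the first provided one).
    """
    if isinstance(columns, list):
        columns = dict(zip(SPECIES, columns))
    base = columns.get(focal) or next(iter(columns.values()))
    seqs = {sp: columns.get(sp, base) for sp in SPECIES}
    length = len(base.replace("-", ""))
    return AlignedElement(element_id, seqs, Anchor(chrom, start, start + length, strand), focal)


@pytest.fixture(scope="session")
def small_bundle():
    """One modestly sized synthetic bundle shared across tests."""
    from cnedfe.simulate import GeneratorConfig, generate_bundle

    cfg = GeneratorConfig(seed=7, n_elements=10, theta_scale=5.0)
    return generate_bundle(cfg)
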