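import numpy as np
import pytest

from mycoevo.seqio import parse_newick


def balanced_tree(n_taxa: int, branch_length: float = 0.15):
    """Fully balanced rooted tree with equal branch lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{branch_length}"
        m = len(ls) // 2
        return f"({build(ls[:m])},{build(ls[m:])}):{branch_length}"

    half = n_taxa // 2
    return parse_newick(
        "(" + build(labels[:half]) + "," + build(labels[half:]) + ");"
    )


@pytest.fixture
def tree12():
    return balanced_tree(12)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _quiet_small_sample_warning():
    """The REL fit warns below 10 sequences; tests use small data on purpose."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* sequences")
        yield
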