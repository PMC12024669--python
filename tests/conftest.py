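import numpy as np
import pytest

from introscreen.matrix import DiagnosticLocus, DiagnosticPanel, GenotypeMatrix


def make_matrix(calls, pops=None, loci=None, samples=None, depths=None, parent_locus=None):
    """Build a GenotypeMatrix from a plain nested list of dosage codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    samples = samples or [f"s{i + 1:03d}" for i in range(n)]
    loci = loci or [f"L{j + 1:03d}" for j in range(L)]
    if pops is None:
        pop_of = {s: "pop1" for s in samples}
    elif isinstance(pops, dict):
        pop_of = pops
    else:  # sequence of per-sample labels
        pop_of = dict(zip(samples, pops))
    return GenotypeMatrix(
        samples=samples,
        loci=loci,
        calls=calls,
        pops=pop_of,
        depths=depths,
        parent_locus=parent_locus,
    )


@pytest.fixture
def small_panel():
    return DiagnosticPanel(
        (
            DiagnosticLocus("L001", "A", "G", read_position=10),
            DiagnosticLocus("L002", "C", "T", read_position=22),
            DiagnosticLocus("L003", "T", "A"),
        )
    )


@pytest.fixture
def two_pop_matrix():
    """Two populations x two loci with every genotype state present."""
    calls = [
        [0, 0],
        [0, 1],
        [1, 2],
        [2, -1],
    ]
    return make_matrix(calls, pops=["north", "north", "south", "south"])
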