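import numpy as np
import pytest

from imotifkit import bisulfite, repeats, synthetic


@pytest.fixture
def tccc9_region():
    """A 200 bp reference region carrying one (TCCC)9 element."""
    sim = synthetic.gen_genome(200, planted=[(100, "TCCC", 9)],
                               cfg=synthetic.SimConfig(seed=42))
    elements = [el for el in repeats.find_elements(sim.sequence, min_n=9)
                if el.c_rich_strand == "+"]
    assert elements, "fixture genome must contain the planted element"
    return bisulfite.ReferenceRegion(id="tccc9", sequence=sim.sequence,
                                     elements=elements)


@pytest.fixture
def two_element_region():
    """A RACK7-like region with a (TCCC)5 and a (TCCC)9 element."""
    sim = synthetic.gen_genome(
        300, planted=[(60, "TCCC", 5), (180, "TCCC", 9)],
        cfg=synthetic.SimConfig(seed=7))
    elements = [el for el in repeats.find_elements(sim.sequence, min_n=5)
                if el.c_rich_strand == "+"]
    assert len(elements) == 2
    return bisulfite.ReferenceRegion(id="rack7_like", sequence=sim.sequence,
                                     elements=elements)


def brute_force_elements(seq: str, unit: str = "TCCC", min_n: int = 5):
    """Exhaustive enumeration oracle for maximal whole-unit tandem runs.

    Returns sorted (start, end, strand, n) tuples, strand being the C-rich
    strand as in repeats.find_elements.
    """
    seq = seq.upper()
    out = []
    rc = repeats.reverse_complement(unit)
    for motif, strand in ((unit, "+"), (rc, "-")):
        k = len(motif)
        for i in range(len(seq) - k + 1):
            if seq[i:i + k] != motif:
                continue
            if i >= k and seq[i - k:i] == motif:
                continue  # not the start of a maximal run
            j = i
            while seq[j:j + k] == motif:
                j += k
            n = (j - i) // k
            if n >= min_n:
                out.append((i, j, strand, n))
    return sorted(out)
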