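import pytest

from xenopept.digestion import AMBIGUOUS_RESIDUES
from xenopept.io import ProteinRecord
from xenopept.species import build_peptide_index
from xenopept.digestion import DigestionParams


def oracle_digest(sequence, max_missed, min_length, max_length, proline_rule=True):
    """Brute-force digestion oracle: enumerate every substring and keep those
    whose boundaries are termini or allowed cleavage sites and whose internal
    allowed sites number at most max_missed. Independent of the production
    digestion code path."""
    n = len(sequence)
    sites = {
        i
        for i in range(1, n)
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P")
    }
    boundaries = sites | {0, n}
    out = set()
    for start in range(n):
        for end in range(start + 1, n + 1):
            if start not in boundaries or end not in boundaries:
                continue
            internal = sum(1 for s in sites if start < s < end)
            if internal > max_missed:
                continue
            if not (min_length <= end - start <= max_length):
                continue
            pep = sequence[start:end]
            if AMBIGUOUS_RESIDUES & set(pep):
                continue
            out.add((pep, start, end, internal))
    return out


@pytest.fixture
def toy_index():
    """Worked mini-proteomes: one human and one mouse protein sharing AAAK."""
    human = [ProteinRecord("P1", "human", "toy human", "AAAKTTTK")]
    mouse = [ProteinRecord("M1", "mouse", "toy mouse", "AAAKSSSK")]
    params = DigestionParams(max_missed_cleavages=0, min_length=3, max_length=50)
    return build_peptide_index(human, mouse, params)
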