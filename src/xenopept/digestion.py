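"""In-silico tryptic digestion with missed cleavages.

Trypsin cleaves C-terminal to K or R; under the classical specificity the cut
is suppressed when the next residue is proline. Peptides spanning up to
``max_missed_cleavages`` internal sites are emitted, filtered to a length
window. Coordinates are 0-based half-open into the parent sequence.

The digestion is written out explicitly (rather than delegated) because the
downstream uniqueness index needs every occurrence with its position and
missed-cleavage count; tests cross-check it against pyteomics' cleavage rule
and a brute-force substring oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import ProteinRecord

# residues whose identity is ambiguous for exact string matching; peptides
# containing them are dropped from the digest
AMBIGUOUS_RESIDUES = frozenset("XBZU")


@dataclass(frozen=True)
class DigestionParams:
    """Tryptic digestion settings.

    max_missed_cleavages mirrors the usual search-engine allowance (2);
    min/max length bound what LC-MS/MS typically identifies.
    """

    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 50
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0 or self.max_missed_cleavages > 5:
            raise ValueError("max_missed_cleavages must be in [0, 5]")
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValueError("require 1 <= min_length <= max_length")


@dataclass(frozen=True)
class PeptideOccurrence:
    """One digested peptide at one position in one parent protein."""

    peptide: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Internal positions i where trypsin cuts between seq[i-1] and seq[i]."""
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P")
    ]


def digest_protein(
    record: ProteinRecord, params: DigestionParams = DigestionParams()
) -> list[PeptideOccurrence]:
    """Digest one protein into length-filtered tryptic peptides.

    Fragments between consecutive cleavage sites (and the protein termini)
    are joined across 0..max_missed_cleavages internal sites. Peptides that
    contain ambiguous residues (X/B/Z/U) are dropped.
    """
    seq = record.sequence
    boundaries = [0, *cleavage_sites(seq, params.proline_rule), len(seq)]
    out: list[PeptideOccurrence] = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        start = boundaries[i]
        for mc in range(params.max_missed_cleavages + 1):
            j = i + mc + 1
            if j >= len(boundaries):
                break
            end = boundaries[j]
            length = end - start
            if length < params.min_length or length > params.max_length:
                continue
            peptide = seq[start:end]
            if AMBIGUOUS_RESIDUES & set(peptide):
                continue
            out.append(PeptideOccurrence(peptide, record.accession, start, end, mc))
    return out


def digest_proteome(
    records: list[ProteinRecord], params: DigestionParams = DigestionParams()
) -> list[PeptideOccurrence]:
    """Digest every record; order-stable by (input order, start, span)."""
    seen: set[str] = set()
    for r in records:
        if r.accession in seen:
            raise ValueError(f"duplicate accession {r.accession!r}")
        seen.add(r.accession)
    out: list[PeptideOccurrence] = []
    for r in records:
        out.extend(digest_protein(r, params))
    return out
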