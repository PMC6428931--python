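"""Species-of-origin assignment for observed peptides.

The core idea: digest the graft (human) and host (mouse) proteomes in silico
with the same settings the identifications were searched under, index every
tryptic peptide by its parent accessions per species, and call an observed
peptide *unambiguously* human when it occurs in the human digest and nowhere
in the mouse digest (and symmetrically for mouse). Peptides present in both
digests are shared and uninformative about origin; peptides in neither are
unmapped.

Because mass spectrometry cannot distinguish isoleucine from leucine, the
index can optionally collapse I onto L (``equate_il``); this only ever merges
keys, so it can only shrink the species-unique sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .digestion import DigestionParams, digest_proteome
from .io import ProteinRecord

LABELS = ("human_unique", "mouse_unique", "shared", "unmapped")

# strip flanking-residue notation "K.PEPTIDER.A" and bracketed or lowercase
# modification annotations like "M(ox)", "M[+15.995]"
_FLANK_RE = re.compile(r"^(?:[A-Z-]\.)(.+?)(?:\.[A-Z-])$")
_MOD_RE = re.compile(r"\(.*?\)|\[.*?\]")


def strip_modifications(peptide: str) -> str:
    """Reduce an annotated peptide string to its plain uppercase sequence."""
    s = peptide.strip()
    m = _FLANK_RE.match(s)
    if m:
        s = m.group(1)
    s = _MOD_RE.sub("", s)
    return "".join(c for c in s.upper() if c.isalpha())


def canonicalize(peptide: str, equate_il: bool) -> str:
    key = peptide.upper()
    return key.replace("I", "L") if equate_il else key


@dataclass(frozen=True)
class PeptideIndex:
    """Map peptide key → (human parent accessions, mouse parent accessions)."""

    entries: Mapping[str, tuple[frozenset[str], frozenset[str]]]
    params_used: DigestionParams
    equate_il: bool

    def lookup(self, peptide: str) -> tuple[frozenset[str], frozenset[str]]:
        key = canonicalize(peptide, self.equate_il)
        return self.entries.get(key, (frozenset(), frozenset()))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ClassifiedPeptide:
    peptide: str
    label: str
    human_parents: frozenset[str]
    mouse_parents: frozenset[str]


# a ClassificationTable is simply a list of ClassifiedPeptide rows, one per
# distinct observed peptide
ClassificationTable = list[ClassifiedPeptide]


def build_peptide_index(
    human_db: list[ProteinRecord],
    mouse_db: list[ProteinRecord],
    params: DigestionParams = DigestionParams(),
    equate_il: bool = False,
) -> PeptideIndex:
    """Digest both proteomes and index peptides by per-species parent sets."""
    if not human_db and not mouse_db:
        raise ValueError("both proteomes are empty; nothing to index")
    human: dict[str, set[str]] = {}
    mouse: dict[str, set[str]] = {}
    for occ in digest_proteome(human_db, params):
        human.setdefault(canonicalize(occ.peptide, equate_il), set()).add(
            occ.parent_accession
        )
    for occ in digest_proteome(mouse_db, params):
        mouse.setdefault(canonicalize(occ.peptide, equate_il), set()).add(
            occ.parent_accession
        )
    entries = {
        key: (frozenset(human.get(key, ())), frozenset(mouse.get(key, ())))
        for key in human.keys() | mouse.keys()
    }
    return PeptideIndex(entries=entries, params_used=params, equate_il=equate_il)


def _label(human_parents: frozenset[str], mouse_parents: frozenset[str]) -> str:
    if human_parents and not mouse_parents:
        return "human_unique"
    if mouse_parents and not human_parents:
        return "mouse_unique"
    if human_parents and mouse_parents:
        return "shared"
    return "unmapped"


def classify_observed(
    observed_peptides: Iterable[str], index: PeptideIndex
) -> ClassificationTable:
    """Label each distinct observed peptide by species of origin.

    Input peptides must be plain sequences (modification annotations already
    stripped); they are canonicalized with the index's own equate_il setting.
    """
    table: ClassificationTable = []
    seen: set[str] = set()
    for raw in observed_peptides:
        key = canonicalize(raw, index.equate_il)
        if key in seen:
            continue
        seen.add(key)
        human_parents, mouse_parents = index.lookup(key)
        table.append(
            ClassifiedPeptide(key, _label(human_parents, mouse_parents),
                              human_parents, mouse_parents)
        )
    return table


def summarize_classification(table: ClassificationTable) -> dict[str, int]:
    """Count rows per label; counts sum to the distinct-peptide total."""
    counts = {label: 0 for label in LABELS}
    for row in table:
        counts[row.label] += 1
    return counts
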