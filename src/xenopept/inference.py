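"""Peptide → protein rollup.

Classified peptides of one species label are aggregated to their parent
accessions: a protein's *unique peptide count* is the number of distinct
peptides whose within-species parent set is exactly that one accession, its
PSM counts are summed per sample over all of its peptides of that label
(degenerate peptides accrue to every parent), and a sample *detects* the
protein when its summed PSM count is at least 1.

No parsimony grouping is attempted: every accession with at least one
peptide of the target label is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import PsmRow
from .species import ClassificationTable, PeptideIndex, canonicalize


@dataclass
class ProteinQuant:
    """Per-protein rollup: unique peptides, PSM totals, detection per group."""

    accession: str
    species: str
    unique_peptide_count: int = 0
    per_sample_psm: dict[str, int] = field(default_factory=dict)
    detection: dict[str, tuple[int, int]] = field(default_factory=dict)
    peptides: set[str] = field(default_factory=set)

    @property
    def psm_total(self) -> int:
        return sum(self.per_sample_psm.values())


def rollup(
    classification: ClassificationTable,
    psm_rows: list[PsmRow],
    index: PeptideIndex,
    target_label: str,
) -> list[ProteinQuant]:
    """Aggregate peptides of ``target_label`` to per-protein quantities.

    Raises if a PSM-table peptide was never classified (pipeline-order
    violation: classification must cover the observed peptides).
    """
    if target_label not in ("human_unique", "mouse_unique"):
        raise ValueError(f"target_label must be a species label, got {target_label!r}")
    species = "human" if target_label == "human_unique" else "mouse"
    parent_side = 0 if species == "human" else 1

    by_peptide = {row.peptide: row for row in classification}
    targets = {p: row for p, row in by_peptide.items() if row.label == target_label}

    quants: dict[str, ProteinQuant] = {}
    sample_groups: dict[str, str] = {}
    for psm in psm_rows:
        key = canonicalize(psm.peptide, index.equate_il)
        if key not in by_peptide:
            raise ValueError(
                f"peptide {psm.peptide!r} in PSM table was never classified"
            )
        sample_groups[psm.sample_id] = psm.group
        row = targets.get(key)
        if row is None:
            continue
        parents = (row.human_parents, row.mouse_parents)[parent_side]
        for acc in parents:
            q = quants.setdefault(acc, ProteinQuant(accession=acc, species=species))
            q.per_sample_psm[psm.sample_id] = (
                q.per_sample_psm.get(psm.sample_id, 0) + psm.psm_count
            )
            q.peptides.add(key)

    # proteins observed via classification only (no PSMs) still appear
    for row in targets.values():
        parents = (row.human_parents, row.mouse_parents)[parent_side]
        for acc in parents:
            q = quants.setdefault(acc, ProteinQuant(accession=acc, species=species))
            q.peptides.add(row.peptide)

    group_sizes: dict[str, int] = {}
    for group in set(sample_groups.values()):
        group_sizes[group] = sum(1 for g in sample_groups.values() if g == group)

    for q in quants.values():
        q.unique_peptide_count = sum(
            1
            for p in q.peptides
            if (targets[p].human_parents, targets[p].mouse_parents)[parent_side]
            == frozenset({q.accession})
        )
        for group, size in group_sizes.items():
            detected = sum(
                1
                for sample, g in sample_groups.items()
                if g == group and q.per_sample_psm.get(sample, 0) >= 1
            )
            q.detection[group] = (detected, size)

    return sorted(quants.values(), key=lambda q: (-q.psm_total, q.accession))
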