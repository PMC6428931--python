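"""Normal-urine abundance categories and cross-model overlap flags.

Human-origin proteins found in xenograft urine are looked up in a normal
human urine concentration table and binned: high (> 1,000 pg/mL), moderate
(> 100 and <= 1,000), low (<= 100), or not reported. Boundary values fall in
the lower category (the thresholds are strict "greater than"). Overlap
annotation is plain set membership against named accession lists, e.g. the
proteins also seen in the Walker 256 and C6 glioma rat tumor models.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping

from .io import ConcentrationRecord, load_fixture


class AbundanceCategory(str, Enum):
    high = "high"
    moderate = "moderate"
    low = "low"
    not_reported = "not_reported"


def categorize_abundance(record: ConcentrationRecord) -> AbundanceCategory:
    """Bin one concentration; None means the protein is unreported in urine."""
    c = record.concentration
    if c is None:
        return AbundanceCategory.not_reported
    if c < 0:
        raise ValueError(f"{record.accession}: negative concentration {c}")
    if c > 1000:
        return AbundanceCategory.high
    if c > 100:
        return AbundanceCategory.moderate
    return AbundanceCategory.low


def summarize_categories(
    records: Iterable[ConcentrationRecord],
) -> dict[AbundanceCategory, int]:
    counts = {cat: 0 for cat in AbundanceCategory}
    for rec in records:
        counts[categorize_abundance(rec)] += 1
    return counts


def annotate_overlap(
    accessions: Iterable[str], reference_lists: Mapping[str, set[str]]
) -> dict[str, dict[str, bool]]:
    """For each accession, one membership flag per named reference list."""
    refs = {name: set(members) for name, members in reference_lists.items()}
    return {acc: {name: acc in members for name, members in refs.items()}
            for acc in accessions}


def packaged_reference_lists() -> dict[str, set[str]]:
    """Overlap lists from the packaged worked-example table's marks."""
    t1 = load_fixture("table1")
    return {
        "walker256": set(t1.loc[t1["walker256_flag"], "accession"]),
        "c6": set(t1.loc[t1["c6_flag"], "accession"]),
    }
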