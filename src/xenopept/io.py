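"""Readers and writers for the formats the pipeline consumes.

Proteomes arrive as multi-record FASTA (UniProt-style ``sp|ACC|NAME`` headers
preferred), identifications as a long-format PSM table (one row per sample ×
peptide, tab-separated), and the packaged worked-example tables ship as TSV
fixtures inside the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Species = Literal["human", "mouse"]
GROUP_LABELS = ("control", "tumor")

# standard residues plus the ambiguity/selenocysteine codes we pass through
_ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: accession, species tag, description, sequence."""

    accession: str
    species: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be nonempty")
        bad = set(self.sequence) - _ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: sequence contains invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class PsmRow:
    """One observed peptide in one sample, with its spectral count."""

    sample_id: str
    group: str
    peptide: str
    psm_count: int

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}"
            )
        if not self.peptide:
            raise ValueError("peptide must be nonempty")
        if self.psm_count < 1:
            raise ValueError(f"psm_count must be >= 1, got {self.psm_count}")


@dataclass(frozen=True)
class ConcentrationRecord:
    """Normal-urine concentration for one accession; None when not reported."""

    accession: str
    concentration: float | None

    def __post_init__(self) -> None:
        if self.concentration is not None and not self.concentration > 0:
            raise ValueError(
                f"{self.accession}: concentration must be positive, "
                f"got {self.concentration}"
            )


def _accession_from_header(header: str) -> str:
    """UniProt ``sp|ACC|NAME`` / ``tr|ACC|NAME``, else first whitespace token."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def read_fasta(path: str | Path, species_tag: Species) -> list[ProteinRecord]:
    """Read a proteome FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased with whitespace stripped. Raises on an empty
    file and on duplicate accessions.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(rec.description or rec.id)
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        description = rec.description or ""
        records.append(
            ProteinRecord(
                accession=accession,
                species=species_tag,
                description=description,
                sequence=str(rec.seq).upper().replace(" ", ""),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as ``sp|ACC|ACC description`` FASTA."""
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"sp|{r.accession}|{r.accession}",
            description=r.description,
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_psm_table(path: str | Path) -> list[PsmRow]:
    """Read the long-format PSM TSV (sample_id, group, peptide, psm_count)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "group", "peptide", "psm_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} lacks columns {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        raw_count = str(rec.psm_count)
        try:
            count = int(raw_count)
        except ValueError:
            raise ValueError(f"non-integer psm_count {raw_count!r}") from None
        rows.append(
            PsmRow(
                sample_id=str(rec.sample_id),
                group=str(rec.group),
                peptide=str(rec.peptide),
                psm_count=count,
            )
        )
    return rows


def write_psm_table(rows: Iterable[PsmRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.group, r.peptide, r.psm_count) for r in rows],
        columns=["sample_id", "group", "peptide", "psm_count"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_concentration_table(path: str | Path) -> dict[str, ConcentrationRecord]:
    """Read an accession → pg/mL lookup; blank concentration means unreported."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, ConcentrationRecord] = {}
    for rec in df.itertuples(index=False):
        conc = getattr(rec, "concentration_pg_ml")
        value = None if conc is None or (isinstance(conc, float) and math.isnan(conc)) else float(conc)
        out[str(rec.accession)] = ConcentrationRecord(str(rec.accession), value)
    return out


_FIXTURES = {"table1": "table1.tsv", "table2": "table2.tsv"}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged worked-example table (``table1`` or ``table2``).

    ``table1`` carries, per human-origin protein: PSM count, detection ratio
    (n_detected / n_group), unique-peptide count, normal-urine concentration
    in pg/mL (NaN when not reported), and overlap flags against the Walker 256
    and C6 glioma model protein lists. ``table2`` carries the differential
    host proteins with presence category, fold change, p-value and trend.
    """
    try:
        filename = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    ref = resources.files("xenopept.fixtures").joinpath(filename)
    with resources.as_file(ref) as fp:
        df = pd.read_csv(fp, sep="\t")
    if name == "table1":
        df["walker256_flag"] = df["walker256_flag"].astype(bool)
        df["c6_flag"] = df["c6_flag"].astype(bool)
    return df
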