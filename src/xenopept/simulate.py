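"""Synthetic graft/host proteome pairs and PSM tables with planted truth.

The generator emulates the xenograft study design: a human-like ("graft")
proteome, a mouse-like ("host") proteome of orthologs derived from it by
per-residue substitution, urine spectral counts for control and tumor
groups, tumor-only human spike-in proteins (tumor-secreted proteins absent
before transplantation), and up-regulated differential host proteins.

Orthologs keep every K, R and P fixed and never mutate a residue to K, R or
P, so the tryptic frames of a graft protein and its host ortholog coincide;
species-unique peptides arise purely from substitutions inside otherwise
aligned peptides. Ground truth is computed by digesting both proteomes and
comparing, so it is definitionally consistent with the classifier's
contract.

Spectral counts are negative-binomial (overdispersed Poisson), the standard
model for counting data; ``dispersion`` is the NB size parameter theta with
variance mu + mu^2/theta, so larger theta means counts closer to Poisson.
Per protein and sample the NB total is spread over the protein's tryptic
peptides by a uniform multinomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .digestion import DigestionParams, digest_proteome
from .io import ProteinRecord, PsmRow, write_fasta, write_psm_table
from .species import canonicalize

_ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")
_FIXED = set("KRP")  # preserved so tryptic frames align across the pair
_MUTABLE = [a for a in _ALPHABET if a not in _FIXED]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs; defaults mirror the emulated experiment
    (4 control + 4 tumor urine samples, modest proteome, 5% ortholog
    divergence, 8-fold up-regulated host proteins, tumor-only graft spikes).
    """

    n_proteins_per_species: int = 200
    protein_length_range: tuple[int, int] = (80, 300)
    ortholog_mutation_rate: float = 0.05
    n_graft_spike_proteins: int = 10
    n_differential_host_proteins: int = 8
    effect_size: float = 8.0
    baseline_mean: float = 20.0
    dispersion: float = 5.0
    n_control: int = 4
    n_tumor: int = 4
    seed: int = 0
    digestion: DigestionParams = field(default_factory=DigestionParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ortholog_mutation_rate <= 1.0):
            raise ValueError("ortholog_mutation_rate must be in [0, 1]")
        if self.effect_size <= 1:
            raise ValueError("effect_size must be > 1")
        if self.n_control < 2 or self.n_tumor < 2:
            raise ValueError("need >= 2 samples per group")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream checks."""

    graft_unique_peptides: set[str]
    shared_peptides: set[str]
    differential_host_accessions: dict[str, str]  # accession -> "Up"
    spike_accessions: set[str]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _mutate_ortholog(rng: np.random.Generator, sequence: str, rate: float) -> str:
    out = []
    for residue in sequence:
        if residue in _FIXED or rng.random() >= rate:
            out.append(residue)
        else:
            choices = [a for a in _MUTABLE if a != residue]
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def generate_proteome_pair(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], list[ProteinRecord], GroundTruth]:
    """Generate the graft proteome, its host ortholog proteome, and truth.

    The graft proteome carries ``n_proteins_per_species`` ortholog-paired
    proteins plus ``n_graft_spike_proteins`` graft-only spike proteins with
    no host counterpart.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.protein_length_range
    human: list[ProteinRecord] = []
    mouse: list[ProteinRecord] = []
    for i in range(config.n_proteins_per_species):
        seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        human.append(
            ProteinRecord(f"HUM{i:04d}", "human", f"synthetic graft protein {i}", seq)
        )
        mouse.append(
            ProteinRecord(
                f"MUS{i:04d}",
                "mouse",
                f"synthetic host ortholog {i}",
                _mutate_ortholog(rng, seq, config.ortholog_mutation_rate),
            )
        )
    spikes: set[str] = set()
    for i in range(config.n_graft_spike_proteins):
        acc = f"SPK{i:04d}"
        spikes.add(acc)
        human.append(
            ProteinRecord(
                acc,
                "human",
                f"synthetic tumor-secreted spike {i}",
                _random_protein(rng, int(rng.integers(lo, hi + 1))),
            )
        )

    human_keys = {canonicalize(o.peptide, False) for o in digest_proteome(human, config.digestion)}
    mouse_keys = {canonicalize(o.peptide, False) for o in digest_proteome(mouse, config.digestion)}

    n_diff = min(config.n_differential_host_proteins, config.n_proteins_per_species)
    differential = {f"MUS{i:04d}": "Up" for i in range(n_diff)}

    truth = GroundTruth(
        graft_unique_peptides=human_keys - mouse_keys,
        shared_peptides=human_keys & mouse_keys,
        differential_host_accessions=differential,
        spike_accessions=spikes,
    )
    return human, mouse, truth


def _nb(rng: np.random.Generator, mean: float, theta: float) -> int:
    return int(rng.negative_binomial(theta, theta / (theta + mean)))


def generate_psm_tables(
    human: list[ProteinRecord],
    mouse: list[ProteinRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[PsmRow]:
    """Draw group-structured spectral counts for host and spike proteins.

    Host proteins appear in every sample (subject to sampling zeros);
    planted differential hosts have their tumor-group mean multiplied by
    ``effect_size``; graft spikes draw counts in tumor samples only.
    """
    rng = np.random.default_rng([config.seed, 1])
    samples = [(f"C{i + 1}", "control") for i in range(config.n_control)] + [
        (f"T{i + 1}", "tumor") for i in range(config.n_tumor)
    ]

    peptides_by_protein: dict[str, list[str]] = {}
    for rec in mouse + [h for h in human if h.accession in truth.spike_accessions]:
        occs = digest_proteome([rec], config.digestion)
        peps = sorted({o.peptide for o in occs})
        if peps:
            peptides_by_protein[rec.accession] = peps

    counts: dict[tuple[str, str, str], int] = {}  # (sample, group, peptide) -> n
    for acc, peps in peptides_by_protein.items():
        is_spike = acc in truth.spike_accessions
        direction = truth.differential_host_accessions.get(acc)
        for sample_id, group in samples:
            if is_spike and group == "control":
                continue
            mean = config.baseline_mean
            if direction == "Up" and group == "tumor":
                mean *= config.effect_size
            total = _nb(rng, mean, config.dispersion)
            if total == 0:
                continue
            split = rng.multinomial(total, np.full(len(peps), 1.0 / len(peps)))
            for pep, n in zip(peps, split):
                if n:
                    key = (sample_id, group, pep)
                    counts[key] = counts.get(key, 0) + int(n)

    return [
        PsmRow(sample_id=s, group=g, peptide=p, psm_count=n)
        for (s, g, p), n in sorted(counts.items())
    ]


def write_synthetic_dataset(
    outdir: str | Path, config: SimulationConfig
) -> dict[str, Path]:
    """Generate one full dataset and write FASTA + PSM TSV + truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    human, mouse, truth = generate_proteome_pair(config)
    psm = generate_psm_tables(human, mouse, truth, config)

    paths = {
        "human_fasta": outdir / "graft.fasta",
        "mouse_fasta": outdir / "host.fasta",
        "psm_tsv": outdir / "psm.tsv",
        "truth_peptides": outdir / "truth_graft_unique_peptides.tsv",
        "truth_differential": outdir / "truth_differential_hosts.tsv",
        "truth_spikes": outdir / "truth_spike_accessions.tsv",
    }
    write_fasta(human, paths["human_fasta"])
    write_fasta(mouse, paths["mouse_fasta"])
    write_psm_table(psm, paths["psm_tsv"])
    paths["truth_peptides"].write_text(
        "peptide\n" + "".join(f"{p}\n" for p in sorted(truth.graft_unique_peptides))
    )
    paths["truth_differential"].write_text(
        "accession\tdirection\n"
        + "".join(
            f"{a}\t{d}\n" for a, d in sorted(truth.differential_host_accessions.items())
        )
    )
    paths["truth_spikes"].write_text(
        "accession\n" + "".join(f"{a}\n" for a in sorted(truth.spike_accessions))
    )
    return paths
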