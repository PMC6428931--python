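"""End-to-end orchestration: digestion → index → classify → rollup →
screen → annotate, with a reproducibility manifest.

Outputs per run: the peptide classification table, the graft (human-origin)
protein table with abundance categories and overlap flags, the host
differential-protein table, and a JSON manifest recording every parameter,
input checksum and the package version. Any stage failure aborts with a
stage-named error and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import categorize_abundance, annotate_overlap
from .differential import (
    CountMatrix,
    ScreenCriteria,
    normalize_counts,
    results_frame,
    screen_differential,
)
from .digestion import DigestionParams
from .inference import rollup
from .io import (
    ConcentrationRecord,
    read_concentration_table,
    read_fasta,
    read_psm_table,
)
from .species import (
    build_peptide_index,
    classify_observed,
    strip_modifications,
    summarize_classification,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    human_fasta: Path
    mouse_fasta: Path
    psm_tsv: Path
    outdir: Path
    concentration_tsv: Path | None = None
    reference_lists: dict[str, Path] = field(default_factory=dict)
    digestion: DigestionParams = field(default_factory=DigestionParams)
    criteria: ScreenCriteria = field(default_factory=ScreenCriteria)
    equate_il: bool = False
    test: str = "student"
    fdr: bool = False
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _check_inputs(config: RunConfig) -> None:
    paths = [config.human_fasta, config.mouse_fasta, config.psm_tsv]
    if config.concentration_tsv:
        paths.append(config.concentration_tsv)
    paths.extend(config.reference_lists.values())
    for p in paths:
        if not Path(p).exists():
            raise PipelineError("inputs", f"input path does not exist: {p}")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name → path map of the artifacts."""
    _check_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    try:
        try:
            human = read_fasta(config.human_fasta, "human")
            mouse = read_fasta(config.mouse_fasta, "mouse")
            psm_rows = read_psm_table(config.psm_tsv)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("read", str(exc)) from exc

        try:
            index = build_peptide_index(
                human, mouse, config.digestion, config.equate_il
            )
        except Exception as exc:
            raise PipelineError("index", str(exc)) from exc

        try:
            observed = [strip_modifications(r.peptide) for r in psm_rows]
            classification = classify_observed(observed, index)
            counts = summarize_classification(classification)
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc

        try:
            graft = rollup(classification, psm_rows, index, "human_unique")
            host = rollup(classification, psm_rows, index, "mouse_unique")
        except Exception as exc:
            raise PipelineError("rollup", str(exc)) from exc

        try:
            samples = sorted({r.sample_id for r in psm_rows})
            groups = {r.sample_id: r.group for r in psm_rows}
            host_counts = pd.DataFrame(
                [[q.per_sample_psm.get(s, 0) for s in samples] for q in host],
                index=[q.accession for q in host],
                columns=samples,
            )
            matrix = normalize_counts(CountMatrix(host_counts, groups))
            results = screen_differential(
                matrix, host, config.criteria, test=config.test, fdr=config.fdr
            )
        except Exception as exc:
            raise PipelineError("screen", str(exc)) from exc

        try:
            concentrations: dict[str, ConcentrationRecord] = {}
            if config.concentration_tsv:
                concentrations = read_concentration_table(config.concentration_tsv)
            refs = {
                name: set(Path(p).read_text().split())
                for name, p in config.reference_lists.items()
            }
            overlap = annotate_overlap([q.accession for q in graft], refs)
        except Exception as exc:
            raise PipelineError("annotate", str(exc)) from exc

        # --- write artifacts ---------------------------------------------
        descriptions = {r.accession: r.description for r in human + mouse}

        classification_tsv = outdir / "classification.tsv"
        pd.DataFrame(
            [
                {
                    "peptide": r.peptide,
                    "label": r.label,
                    "human_parents": ";".join(sorted(r.human_parents)),
                    "mouse_parents": ";".join(sorted(r.mouse_parents)),
                }
                for r in classification
            ]
        ).to_csv(classification_tsv, sep="\t", index=False)
        written.append(classification_tsv)

        graft_tsv = outdir / "graft_proteins.tsv"
        graft_rows = []
        for q in graft:
            det = q.detection.get("tumor", (0, 0))
            conc = concentrations.get(q.accession)
            row = {
                "accession": q.accession,
                "description": descriptions.get(q.accession, ""),
                "psm_count": q.psm_total,
                "detection_tumor": f"{det[0]}/{det[1]}",
                "unique_peptide_count": q.unique_peptide_count,
                "concentration_pg_ml": conc.concentration if conc else None,
                "abundance_category": categorize_abundance(
                    conc or ConcentrationRecord(q.accession, None)
                ).value,
            }
            for name in refs:
                row[f"{name}_overlap"] = overlap[q.accession][name]
            graft_rows.append(row)
        pd.DataFrame(graft_rows).to_csv(graft_tsv, sep="\t", index=False)
        written.append(graft_tsv)

        host_tsv = outdir / "host_differential.tsv"
        frame = results_frame(results)
        frame.insert(
            1, "description", [descriptions.get(a, "") for a in frame["accession"]]
        )
        frame.to_csv(host_tsv, sep="\t", index=False)
        written.append(host_tsv)

        manifest_path = outdir / "manifest.json"
        manifest = {
            "package": "xenopept",
            "version": __version__,
            "inputs": {
                "human_fasta": _sha256(config.human_fasta),
                "mouse_fasta": _sha256(config.mouse_fasta),
                "psm_tsv": _sha256(config.psm_tsv),
                **(
                    {"concentration_tsv": _sha256(config.concentration_tsv)}
                    if config.concentration_tsv
                    else {}
                ),
            },
            "parameters": {
                "digestion": dataclasses.asdict(config.digestion),
                "criteria": dataclasses.asdict(config.criteria),
                "equate_il": config.equate_il,
                "test": config.test,
                "fdr": config.fdr,
                "seed": config.seed,
            },
            "stage_counts": {
                "observed_distinct_peptides": len(classification),
                **{f"peptides_{k}": v for k, v in counts.items()},
                "graft_proteins": len(graft),
                "host_proteins": len(host),
                "host_differential": len(results),
            },
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    return {
        "classification": written[0],
        "graft_proteins": written[1],
        "host_differential": written[2],
        "manifest": written[3],
    }
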