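"""Spectral-count differential screening of host proteins.

Per-sample PSM totals are depth-normalized (each sample scaled to the mean
library size), then proteins are screened under three criteria: at least two
unique peptides; a two-sided between-group test p-value below alpha together
with a tumor/control fold change above fc_up or below fc_down; and presence
in every sample of the group(s) in which the protein is reported. Proteins
detected in every sample of one group and in no sample of the other are
reported as group-exclusive, without a fold change or p-value.

The between-group test defaults to Student's t on normalized counts: at the
tiny group sizes typical of animal studies (4 vs 4) the pooled test holds its
nominal size on overdispersed counts, whereas Welch's unreliable
degrees-of-freedom estimate makes it noticeably conservative. Welch's t and
an exact permutation test of the difference in group means are available as
alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .inference import ProteinQuant


@dataclass(frozen=True)
class CountMatrix:
    """Proteins × samples PSM counts with per-sample group labels."""

    counts: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.groups.values()) - {"control", "tumor"}
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


@dataclass(frozen=True)
class ScreenCriteria:
    """The three-part screen: unique peptides, significance + fold, presence."""

    min_unique_peptides: int = 2
    alpha: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    require_full_presence: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValueError("require 0 < fc_down < 1 < fc_up")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class DifferentialResult:
    accession: str
    presence: str  # both_groups | tumor_only | control_only
    unique_peptides: int
    raw_fc: float | None = None
    fold_change_reported: float | None = None
    p_value: float | None = None
    trend: str | None = None  # Up | Down


def normalize_counts(matrix: CountMatrix) -> CountMatrix:
    """Scale each sample column so its total equals the mean sample total."""
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    scaled = matrix.counts * (totals.mean() / totals)
    return CountMatrix(counts=scaled, groups=matrix.groups)


def presence_category(
    row: pd.Series, matrix: CountMatrix, require_full_presence: bool = True
) -> str | None:
    """Categorize one protein's detection pattern; None when not reportable."""
    ctrl = row[matrix.samples_of("control")]
    tum = row[matrix.samples_of("tumor")]
    n_ctrl = int((ctrl >= 1).sum())
    n_tum = int((tum >= 1).sum())
    full_ctrl = n_ctrl == len(ctrl)
    full_tum = n_tum == len(tum)
    if require_full_presence:
        if full_ctrl and full_tum:
            return "both_groups"
    elif n_ctrl >= 1 and n_tum >= 1:
        return "both_groups"
    if full_tum and n_ctrl == 0:
        return "tumor_only"
    if full_ctrl and n_tum == 0:
        return "control_only"
    return None


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the difference in group means."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    observed = abs(x.mean() - y.mean())
    total = pooled.sum()
    hits = 0
    count = 0
    for idx in combinations(range(n), len(x)):
        sx = pooled[list(idx)].sum()
        diff = abs(sx / len(x) - (total - sx) / len(y))
        hits += diff >= observed - 1e-12
        count += 1
    return hits / count


def _p_value(x: np.ndarray, y: np.ndarray, test: str) -> float:
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # zero variance in both groups: no evidence beyond the mean shift
        if np.isclose(x.mean(), y.mean()):
            return 1.0
        return _exact_permutation_p(x, y)
    if test == "welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if test == "student":
        return float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    if test == "permutation":
        return _exact_permutation_p(x, y)
    raise ValueError(f"unknown test {test!r}")


def group_pvalues(
    matrix: CountMatrix, test: str = "student", require_full_presence: bool = True
) -> pd.Series:
    """Two-sided between-group p-value per protein detected in both groups.

    This is the screen's significance component alone (no fold-change gate,
    no unique-peptide filter) — useful for calibration studies.
    """
    ctrl_cols = matrix.samples_of("control")
    tum_cols = matrix.samples_of("tumor")
    out = {}
    for acc, row in matrix.counts.iterrows():
        if presence_category(row, matrix, require_full_presence) != "both_groups":
            continue
        out[acc] = _p_value(
            row[tum_cols].to_numpy(dtype=float),
            row[ctrl_cols].to_numpy(dtype=float),
            test,
        )
    return pd.Series(out, dtype=float)


def screen_differential(
    matrix: CountMatrix,
    quants: list[ProteinQuant] | Mapping[str, int],
    criteria: ScreenCriteria = ScreenCriteria(),
    test: str = "student",
    fdr: bool = False,
) -> list[DifferentialResult]:
    """Apply the three screening criteria to a normalized count matrix.

    ``quants`` supplies unique-peptide counts, either as rollup output or as
    a plain accession → count mapping. With ``fdr`` the alpha cut is applied
    to Benjamini-Hochberg adjusted p-values instead of raw ones.
    """
    if isinstance(quants, Mapping):
        unique = dict(quants)
    else:
        unique = {q.accession: q.unique_peptide_count for q in quants}

    ctrl_cols = matrix.samples_of("control")
    tum_cols = matrix.samples_of("tumor")
    if len(ctrl_cols) < 2 or len(tum_cols) < 2:
        raise ValueError("need at least 2 samples per group")

    candidates: list[DifferentialResult] = []
    pvals: list[float] = []
    for acc, row in matrix.counts.iterrows():
        n_unique = unique.get(acc, 0)
        if n_unique < criteria.min_unique_peptides:
            continue
        cat = presence_category(row, matrix, criteria.require_full_presence)
        if cat is None:
            continue
        if cat in ("tumor_only", "control_only"):
            candidates.append(
                DifferentialResult(accession=str(acc), presence=cat,
                                   unique_peptides=n_unique)
            )
            pvals.append(np.nan)
            continue
        x = row[tum_cols].to_numpy(dtype=float)
        y = row[ctrl_cols].to_numpy(dtype=float)
        raw_fc = x.mean() / y.mean()
        p = _p_value(x, y, test)
        candidates.append(
            DifferentialResult(
                accession=str(acc),
                presence=cat,
                unique_peptides=n_unique,
                raw_fc=raw_fc,
                fold_change_reported=max(raw_fc, 1.0 / raw_fc),
                p_value=p,
                trend="Up" if raw_fc > 1 else "Down",
            )
        )
        pvals.append(p)

    effective = np.asarray(pvals, dtype=float)
    tested = ~np.isnan(effective)
    if fdr and tested.any():
        effective[tested] = multipletests(effective[tested], method="fdr_bh")[1]

    kept: list[DifferentialResult] = []
    for res, p_eff in zip(candidates, effective):
        if res.presence != "both_groups":
            kept.append(res)
            continue
        significant = p_eff < criteria.alpha and (
            res.raw_fc > criteria.fc_up or res.raw_fc < criteria.fc_down
        )
        if significant:
            kept.append(res)
    return kept


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Tabulate screen output in the worked-example table's column layout."""
    return pd.DataFrame(
        [
            {
                "accession": r.accession,
                "groups_discovered_in": r.presence,
                "unique_peptides": r.unique_peptides,
                "fold_change": (
                    round(r.fold_change_reported, 4)
                    if r.fold_change_reported is not None
                    else None
                ),
                "p_value": round(r.p_value, 6) if r.p_value is not None else None,
                "trend": r.trend,
            }
            for r in results
        ],
        columns=[
            "accession",
            "groups_discovered_in",
            "unique_peptides",
            "fold_change",
            "p_value",
            "trend",
        ],
    )
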