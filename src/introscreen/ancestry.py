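"""Per-individual native-ancestry scoring and its population summaries.

Each diagnostic locus contributes 1.0 (homozygous native), 0.5
(heterozygous) or 0.0 (homozygous foreign); an individual's score is the
mean over the L panel loci, expressed in percent.  With L loci every
attainable score is a multiple of ``100 / (2 L)`` — 3.125 percentage points
for the standard 16-locus panel.  Reported values are rounded
half-away-from-zero to one decimal (so 56.25 prints as 56.3, 81.25 as
81.3); the raw value is always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import HET, HOM_FOREIGN, HOM_NATIVE, MISSING, GenotypeMatrix


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (1.25 -> 1.3, not banker's 1.2)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class AncestryScore:
    sample_id: str
    score: float  # raw percent in [0, 100]
    n_het: int
    n_hom_foreign: int
    n_loci: int

    @property
    def reported(self) -> float:
        """Score rounded half-away-from-zero to one decimal."""
        return round_half_away(self.score, 1)

    @property
    def is_pure(self) -> bool:
        """True only for a raw score of exactly 100 (all calls hom-native)."""
        return self.score == 100.0


def score_calls(calls: Sequence[int] | np.ndarray, sample_id: str = "") -> AncestryScore:
    """Score one individual's genotype calls.

    Raises if any call is missing: the completeness filter is expected to
    run first (see :func:`introscreen.panel_qc.apply_qc_filters`).
    """
    calls = np.asarray(calls)
    if (calls == MISSING).any():
        raise ValueError(
            f"sample {sample_id!r} has missing calls; apply QC filters before scoring"
        )
    L = calls.size
    if L == 0:
        raise ValueError("cannot score an empty call list")
    n_het = int((calls == HET).sum())
    n_hom_foreign = int((calls == HOM_FOREIGN).sum())
    score = 100.0 * (L - 0.5 * n_het - n_hom_foreign) / L
    return AncestryScore(
        sample_id=sample_id,
        score=score,
        n_het=n_het,
        n_hom_foreign=n_hom_foreign,
        n_loci=L,
    )


def score_matrix(matrix: GenotypeMatrix) -> list[AncestryScore]:
    """Score every individual in a genotype matrix."""
    return [
        score_calls(matrix.calls[i], sample_id=s) for i, s in enumerate(matrix.samples)
    ]


@dataclass(frozen=True)
class PopulationAncestrySummary:
    population: str
    n: int
    mean_score: float
    median_score: float
    min_score: float
    max_score: float
    n_pure: int
    pct_pure: float
    mean_het_loci: float


def summarize_population(
    scores: Sequence[AncestryScore],
    pop_of: Mapping[str, str],
    total_label: str = "Total",
) -> list[PopulationAncestrySummary]:
    """Per-population score summaries plus an overall row.

    Median for an even sample count is the midpoint of the two central
    order statistics.  ``pct_pure`` counts individuals whose raw score is
    exactly 100.
    """
    unmapped = [s.sample_id for s in scores if s.sample_id not in pop_of]
    if unmapped:
        raise ValueError("scores without a population mapping: " + ", ".join(unmapped))
    groups: dict[str, list[AncestryScore]] = {}
    for s in scores:
        groups.setdefault(pop_of[s.sample_id], []).append(s)
    out = []
    labels = list(groups)
    if len(labels) > 1 or total_label not in labels:
        groups[total_label] = list(scores)
        labels.append(total_label)
    for pop in labels:
        rows = groups[pop]
        if not rows:
            raise ValueError(f"population {pop!r} is empty")
        vals = np.array([r.score for r in rows])
        n_pure = sum(r.is_pure for r in rows)
        out.append(
            PopulationAncestrySummary(
                population=pop,
                n=len(rows),
                mean_score=float(vals.mean()),
                median_score=float(np.median(vals)),
                min_score=float(vals.min()),
                max_score=float(vals.max()),
                n_pure=int(n_pure),
                pct_pure=100.0 * n_pure / len(rows),
                mean_het_loci=float(np.mean([r.n_het for r in rows])),
            )
        )
    return out


def summary_frame(summaries: Sequence[PopulationAncestrySummary]) -> pd.DataFrame:
    """Summaries as a DataFrame with both raw and reported (rounded) columns."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "population": s.population,
                "n": s.n,
                "mean_ancestry": round_half_away(s.mean_score, 1),
                "median_ancestry": round_half_away(s.median_score, 1),
                "min_ancestry": round_half_away(s.min_score, 1),
                "max_ancestry": round_half_away(s.max_score, 1),
                "n_pure": s.n_pure,
                "pct_pure": round_half_away(s.pct_pure, 1),
                "mean_het_loci": s.mean_het_loci,
                "mean_ancestry_raw": s.mean_score,
                "median_ancestry_raw": s.median_score,
            }
        )
    return pd.DataFrame(rows)
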