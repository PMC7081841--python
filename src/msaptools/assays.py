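"""Companion assay calculators: 2^-ΔΔCt fold change, TUNEL apoptosis index,
cumulative mortality, and total antioxidant capacity (T-AOC) units.

These are the standard bespoke-scored quantities of a stress-physiology
study: relative gene expression from qPCR quantification cycles normalised
to a reference gene (default EF1-α) and a control group; the apoptosis index
as the pooled proportion of TUNEL-positive nuclei over randomly selected
microscope fields; cumulative mortality as a percentage of the initial
cohort; and the spectrophotometric T-AOC unit (one unit = 0.01 absorbance
increase per minute per mg protein).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UsageError

__all__ = [
    "CqRecord",
    "FoldChange",
    "ApoptosisCount",
    "MortalityRecord",
    "ddct_fold_change",
    "apoptosis_index",
    "group_apoptosis_index",
    "cumulative_mortality",
    "taoc_activity",
]

DEFAULT_REFERENCE_GENE = "EF1a"


@dataclass(frozen=True)
class CqRecord:
    """One qPCR replicate: quantification cycle of one gene in one sample."""

    sample_id: str
    gene: str
    group: str
    cq: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cq) and self.cq > 0):
            raise DataError(f"Cq must be finite and positive, got {self.cq}")


@dataclass(frozen=True)
class FoldChange:
    """Per-group relative expression of one target gene.

    ``ddct`` is the group mean ΔΔCt and ``fold = 2**(-ddct)`` exactly (the
    geometric-mean fold); ``mean``/``sd`` are the arithmetic mean and SD of
    the per-sample folds, as expression data are conventionally reported.
    """

    gene: str
    group: str
    ddct: float
    fold: float
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.fold < 0:
            raise UsageError("fold and sd must be >= 0")


@dataclass(frozen=True)
class ApoptosisCount:
    """TUNEL-positive and total nucleus counts in one microscope field."""

    sample_id: str
    field_id: str
    positive: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise DataError(f"field {self.field_id}: total cell count must be > 0")
        if not 0 <= self.positive <= self.total:
            raise DataError(
                f"field {self.field_id}: positive count outside [0, total]"
            )


@dataclass(frozen=True)
class MortalityRecord:
    """Cumulative dead count at one timepoint of an air-exposure trial."""

    timepoint_h: float
    cumulative_dead: int
    initial_n: int

    def __post_init__(self) -> None:
        if self.timepoint_h < 0:
            raise DataError("timepoint_h must be >= 0")
        if self.initial_n <= 0:
            raise DataError("initial_n must be > 0")
        if not 0 <= self.cumulative_dead <= self.initial_n:
            raise DataError("cumulative_dead outside [0, initial_n]")


def _mean_cq(
    records: Sequence[CqRecord],
) -> dict[tuple[str, str, str], float]:
    """Replicate-averaged Cq keyed by (sample, gene, group)."""
    sums: dict[tuple[str, str, str], list[float]] = {}
    for r in records:
        sums.setdefault((r.sample_id, r.gene, r.group), []).append(r.cq)
    return {k: float(np.mean(v)) for k, v in sums.items()}


def ddct_fold_change(
    records: Sequence[CqRecord],
    target_gene: str,
    control_group: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> list[FoldChange]:
    """Relative expression of ``target_gene`` per group by the 2^-ΔΔCt method.

    Per sample: ΔCt = Cq_target - Cq_reference (replicates averaged first);
    ΔΔCt = ΔCt - mean control ΔCt; fold = 2^-ΔΔCt.  Folds are aggregated per
    group (mean ± SD over samples).  The control group's mean ΔΔCt is zero by
    construction, so its geometric-centre fold is exactly 1.
    """
    cq = _mean_cq(records)
    samples: dict[tuple[str, str], dict[str, float]] = {}
    for (sample, gene, group), value in cq.items():
        if gene == target_gene:
            samples.setdefault((sample, group), {})["target"] = value
        elif gene == reference_gene:
            samples.setdefault((sample, group), {})["reference"] = value
    dct: dict[tuple[str, str], float] = {}
    for (sample, group), values in sorted(samples.items()):
        if "target" not in values:
            continue  # sample not measured for this target
        if "reference" not in values:
            raise DataError(
                f"sample {sample!r}: reference gene {reference_gene!r} not measured"
            )
        dct[(sample, group)] = values["target"] - values["reference"]
    control_dcts = [v for (s, g), v in dct.items() if g == control_group]
    if not control_dcts:
        raise UsageError(f"control group {control_group!r} has no usable samples")
    control_mean = float(np.mean(control_dcts))

    by_group: dict[str, list[float]] = {}
    for (sample, group), value in dct.items():
        by_group.setdefault(group, []).append(value - control_mean)
    out = []
    for group, ddcts in by_group.items():
        folds = np.power(2.0, -np.asarray(ddcts))
        mean_ddct = float(np.mean(ddcts))
        out.append(
            FoldChange(
                gene=target_gene,
                group=group,
                ddct=mean_ddct,
                fold=float(2.0 ** (-mean_ddct)),
                mean=float(folds.mean()),
                sd=float(folds.std(ddof=1)) if folds.size > 1 else 0.0,
                n=int(folds.size),
            )
        )
    return out


def apoptosis_index(counts: Sequence[ApoptosisCount], sample_id: str) -> float:
    """Pooled TUNEL-positive fraction across all fields of one sample.

    AI = sum(positive) / sum(total) over fields, so the index is invariant
    to how a field's counts are split into sub-fields.
    """
    fields = [c for c in counts if c.sample_id == sample_id]
    if not fields:
        raise UsageError(f"no fields for sample {sample_id!r}")
    return sum(c.positive for c in fields) / sum(c.total for c in fields)


def group_apoptosis_index(counts: Sequence[ApoptosisCount]) -> float:
    """Group mean AI: average of per-sample pooled indices."""
    samples = sorted({c.sample_id for c in counts})
    if not samples:
        raise UsageError("no apoptosis counts provided")
    return float(np.mean([apoptosis_index(counts, s) for s in samples]))


def cumulative_mortality(
    records: Sequence[MortalityRecord],
    sampled_per_timepoint: int = 0,
) -> pd.DataFrame:
    """Cumulative mortality percentage per timepoint.

    By default the denominator is the initial cohort size (uncorrected for
    individuals removed at sampling points).  ``sampled_per_timepoint`` > 0
    switches to a corrected denominator that removes the animals sampled at
    each preceding timepoint from the population at risk.
    """
    ordered = sorted(records, key=lambda r: r.timepoint_h)
    last = -1
    rows = []
    for k, r in enumerate(ordered):
        if r.cumulative_dead < last:
            raise DataError(
                f"cumulative_dead decreases at timepoint {r.timepoint_h} h"
            )
        last = r.cumulative_dead
        denom = r.initial_n - k * sampled_per_timepoint
        if denom <= 0:
            raise DataError("corrected denominator fell to zero or below")
        rows.append(
            {
                "timepoint_h": r.timepoint_h,
                "cumulative_dead": r.cumulative_dead,
                "initial_n": r.initial_n,
                "mortality_pct": 100.0 * r.cumulative_dead / denom,
            }
        )
    return pd.DataFrame(rows)


def taoc_activity(delta_absorbance_per_min: float, protein_mg: float) -> float:
    """T-AOC in U/mg protein: one unit = 0.01 ΔA per minute per mg protein."""
    if protein_mg <= 0:
        raise UsageError("protein_mg must be > 0")
    if delta_absorbance_per_min < 0:
        raise UsageError("delta_absorbance_per_min must be >= 0")
    return delta_absorbance_per_min / 0.01 / protein_mg
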