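"""MSAP band-type classification and methylation ratios.

Each locus x sample cell of the presence matrix is classified from its
(EH, EM) band pair:

    type I   EH+/EM+   unmethylated CCGG site
    type II  EH+/EM-   hemi-methylated (external cytosine, one strand)
    type III EH-/EM+   fully methylated (internal cytosine, both strands)
    type IV  EH-/EM-   uninformative (no band in either digest)

Ratios use only the informative types:

    hemi-methylation ratio  = II / (I + II + III)
    full-methylation ratio  = III / (I + II + III)
    total-methylation ratio = (II + III) / (I + II + III)

Group summaries pool band counts over individuals and recompute the ratios
from the pooled counts — the informative-band-weighted mean of individual
ratios — rather than averaging per-individual ratios.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .peaks import PresenceMatrix

__all__ = [
    "BandType",
    "MethylationSummary",
    "classify_band",
    "summarize_individual",
    "pool_group",
    "tabulate_types",
    "summaries_to_frame",
]


class BandType(enum.Enum):
    I = (True, True)
    II = (True, False)
    III = (False, True)
    IV = (False, False)


def classify_band(eh_present: bool, em_present: bool) -> BandType:
    """Band type from the (EH, EM) presence pair; total over all 4 cases."""
    return BandType((bool(eh_present), bool(em_present)))


@dataclass(frozen=True)
class MethylationSummary:
    """Band-type counts and methylation ratios for one sample or group.

    ``n4`` (type IV) is reported for QC but never enters a denominator.
    When no informative band exists the ratios are NaN and ``defined`` is
    False.
    """

    label: str
    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3, self.n4) < 0:
            raise UsageError("band-type counts must be >= 0")

    @property
    def n_informative(self) -> int:
        return self.n1 + self.n2 + self.n3

    @property
    def defined(self) -> bool:
        return self.n_informative > 0

    @property
    def hemi_ratio(self) -> float:
        return self.n2 / self.n_informative if self.defined else math.nan

    @property
    def full_ratio(self) -> float:
        return self.n3 / self.n_informative if self.defined else math.nan

    @property
    def total_ratio(self) -> float:
        # (n2+n3)/(n1+n2+n3): equals hemi + full exactly in this form
        return (self.n2 + self.n3) / self.n_informative if self.defined else math.nan

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n1": self.n1,
            "n2": self.n2,
            "n3": self.n3,
            "n4": self.n4,
            "hemi_ratio": self.hemi_ratio,
            "full_ratio": self.full_ratio,
            "total_ratio": self.total_ratio,
            "hemi_pct": round(100 * self.hemi_ratio, 2) if self.defined else math.nan,
            "full_pct": round(100 * self.full_ratio, 2) if self.defined else math.nan,
            "total_pct": round(100 * self.total_ratio, 2) if self.defined else math.nan,
        }


def _counts_for_sample(presence: PresenceMatrix, sample_index: int) -> tuple[int, int, int, int]:
    eh = presence.presence[:, sample_index, 0]
    em = presence.presence[:, sample_index, 1]
    n1 = int(np.sum(eh & em))
    n2 = int(np.sum(eh & ~em))
    n3 = int(np.sum(~eh & em))
    n4 = int(np.sum(~eh & ~em))
    return n1, n2, n3, n4


def summarize_individual(presence: PresenceMatrix, sample_id: str) -> MethylationSummary:
    """Tally band types over all loci for one sample."""
    idx = presence.sample_index(sample_id)
    n1, n2, n3, n4 = _counts_for_sample(presence, idx)
    return MethylationSummary(label=sample_id, n1=n1, n2=n2, n3=n3, n4=n4)


def summarize_all(presence: PresenceMatrix) -> list[MethylationSummary]:
    return [summarize_individual(presence, s) for s in presence.samples]


def pool_group(
    summaries: Sequence[MethylationSummary], group_label: str
) -> MethylationSummary:
    """Pool band counts over individuals; ratios recomputed from pooled counts."""
    if not summaries:
        raise UsageError("pool_group requires at least one summary")
    return MethylationSummary(
        label=group_label,
        n1=sum(s.n1 for s in summaries),
        n2=sum(s.n2 for s in summaries),
        n3=sum(s.n3 for s in summaries),
        n4=sum(s.n4 for s in summaries),
    )


def tabulate_types(presence: PresenceMatrix) -> pd.DataFrame:
    """Long table with one row per locus x sample: locus_id, sample_id, band_type."""
    n_l, n_s, _ = presence.presence.shape
    eh = presence.presence[:, :, 0]
    em = presence.presence[:, :, 1]
    # map (eh, em) -> label via 2*eh + em
    code = 2 * eh.astype(int) + em.astype(int)
    labels = np.array(["IV", "III", "II", "I"])[code]
    return pd.DataFrame(
        {
            "locus_id": np.repeat([b.locus_id for b in presence.loci], n_s),
            "sample_id": np.tile(presence.samples, n_l),
            "band_type": labels.reshape(-1),
        }
    )


def summaries_to_frame(summaries: Iterable[MethylationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
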