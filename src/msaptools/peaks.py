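"""Peak-table ingestion and fragment-size binning.

Fragment-analysis software exports one table of called peaks per sample per
digest (EcoRI+HpaII = "EH", EcoRI+MspI = "EM"): fragment size in bp, peak
height in relative fluorescence units (RFU), and optionally peak area.  This
module validates those tables and converts sized fragments into a
loci x samples x digest boolean presence matrix by clustering sizes into
locus bins.

Binning is single-linkage in one dimension: sizes are sorted and a new bin
starts whenever the gap to the previous size exceeds ``2 * half_width_bp``.
This tolerates small size-calling drift between runs, unlike fixed integer
bins, and is deterministic and order-independent.  The transform step is
exposed as a scikit-learn style transformer (:class:`FragmentBinner`) so the
bin layout learned on one cohort can be reapplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataError, FormatError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "DIGESTS",
    "PeakRecord",
    "LocusBin",
    "PresenceMatrix",
    "read_peak_table",
    "write_peak_table",
    "filter_peaks",
    "FragmentBinner",
    "bin_fragments",
]

#: Digest labels, in tensor order: EcoRI+HpaII, EcoRI+MspI.
DIGESTS = ("EH", "EM")

REQUIRED_COLUMNS = ("sample_id", "digest", "size_bp", "height")


@dataclass(frozen=True)
class PeakRecord:
    """One called capillary-electrophoresis peak."""

    sample_id: str
    digest: str
    size_bp: float
    height: float
    area: float = 0.0

    def __post_init__(self) -> None:
        if self.digest not in DIGESTS:
            raise FormatError(
                f"unknown digest label {self.digest!r} (expected one of {DIGESTS})"
            )
        if not np.isfinite(self.size_bp) or self.size_bp <= 0:
            raise FormatError(f"size_bp must be finite and positive, got {self.size_bp}")
        if self.height < 0 or self.area < 0:
            raise FormatError("height and area must be >= 0")


@dataclass(frozen=True)
class LocusBin:
    """A size bin standing in for one MSAP locus."""

    locus_id: str
    nominal_size_bp: float
    half_width_bp: float

    def __post_init__(self) -> None:
        if self.half_width_bp <= 0:
            raise UsageError("half_width_bp must be > 0")

    def contains(self, size_bp: float) -> bool:
        return (
            self.nominal_size_bp - self.half_width_bp
            <= size_bp
            < self.nominal_size_bp + self.half_width_bp
        )


@dataclass
class PresenceMatrix:
    """Boolean band-presence tensor, loci x samples x (EH, EM)."""

    loci: list[LocusBin]
    samples: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.loci), len(self.samples), 2)
        if self.presence.shape != expected:
            raise UsageError(
                f"presence tensor shape {self.presence.shape} != {expected}"
            )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise UsageError(f"sample {sample_id!r} not in presence matrix") from None

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: locus_id, sample_id, digest, present."""
        n_l, n_s, _ = self.presence.shape
        return pd.DataFrame(
            {
                "locus_id": np.repeat([b.locus_id for b in self.loci], n_s * 2),
                "sample_id": np.tile(np.repeat(self.samples, 2), n_l),
                "digest": np.tile(DIGESTS, n_l * n_s),
                "present": self.presence.reshape(-1),
            }
        )

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [b.locus_id for b in self.loci],
                "nominal_size_bp": [b.nominal_size_bp for b in self.loci],
                "half_width_bp": [b.half_width_bp for b in self.loci],
            }
        )


def peaks_to_frame(records: Iterable[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "digest": r.digest,
                "size_bp": r.size_bp,
                "height": r.height,
                "area": r.area,
            }
            for r in records
        ],
        columns=["sample_id", "digest", "size_bp", "height", "area"],
    )


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    """Write records as CSV with the canonical header."""
    peaks_to_frame(records).to_csv(path, index=False)


def read_peak_table(
    path: str | Path,
    size_window: tuple[float, float] | None = None,
) -> list[PeakRecord]:
    """Read and validate a peak-table CSV.

    Every row is parsed or the file is rejected with the offending line
    number.  Rows whose size falls outside ``size_window`` are dropped with a
    logged count; rows are otherwise returned in file order.
    """
    path = Path(path)
    try:
        # round_trip float parsing: read(write(x)) == x bit-exactly
        frame = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for column in REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    if "area" not in frame.columns:
        frame["area"] = 0.0
    frame["area"] = frame["area"].fillna(0.0)

    records: list[PeakRecord] = []
    dropped = 0
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            size = float(row.size_bp)
            height = float(row.height)
            area = float(row.area)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{line}: non-numeric size/height/area") from exc
        if not np.isfinite(size) or not np.isfinite(height):
            raise FormatError(f"{path}:{line}: non-finite size or height")
        if size_window is not None and not size_window[0] <= size <= size_window[1]:
            dropped += 1
            continue
        try:
            records.append(
                PeakRecord(
                    sample_id=str(row.sample_id),
                    digest=str(row.digest),
                    size_bp=size,
                    height=height,
                    area=area,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{line}: {exc}") from None
    if dropped:
        logger.info("%s: dropped %d peaks outside size window %s", path, dropped, size_window)
    return records


def filter_peaks(
    records: Sequence[PeakRecord],
    min_height: float = 0.0,
    size_window: tuple[float, float] = (0.0, float("inf")),
) -> list[PeakRecord]:
    """Keep peaks with height >= min_height inside [lo, hi]; order preserved."""
    if min_height < 0:
        raise UsageError("min_height must be >= 0")
    lo, hi = size_window
    if not lo < hi:
        raise UsageError("size_window must satisfy lo < hi")
    return [
        r for r in records if r.height >= min_height and lo <= r.size_bp <= hi
    ]


class FragmentBinner(BaseEstimator, TransformerMixin):
    """Cluster fragment sizes into locus bins and emit a presence matrix.

    Parameters
    ----------
    half_width_bp : float, default 0.5
        Size tolerance; a new bin starts when the sorted-size gap exceeds
        ``2 * half_width_bp``.
    min_samples_per_locus : int, default 1
        Bins observed in fewer distinct samples are discarded.

    Attributes
    ----------
    bins_ : list of LocusBin
        Learned bins, sorted by nominal size (mean of member sizes).
    n_peaks_ : int
        Number of peaks the bins were fitted on.
    """

    def __init__(self, half_width_bp: float = 0.5, min_samples_per_locus: int = 1):
        self.half_width_bp = half_width_bp
        self.min_samples_per_locus = min_samples_per_locus

    def _validate(self) -> None:
        if self.half_width_bp <= 0:
            raise UsageError("half_width_bp must be > 0")
        if self.min_samples_per_locus < 1:
            raise UsageError("min_samples_per_locus must be >= 1")

    def fit(self, X: Sequence[PeakRecord], y=None) -> "FragmentBinner":
        """Learn bin boundaries from all samples' peaks pooled together."""
        self._validate()
        records = list(X)
        if not records:
            logger.warning("no peaks to bin; empty presence matrix")
            self.bins_ = []
            self.n_peaks_ = 0
            return self
        sizes = np.array([r.size_bp for r in records])
        samples = np.array([r.sample_id for r in records])
        order = np.argsort(sizes, kind="stable")
        sizes, samples = sizes[order], samples[order]
        # single-linkage: break where consecutive gap exceeds 2*half_width
        breaks = np.flatnonzero(np.diff(sizes) > 2 * self.half_width_bp) + 1
        bins: list[LocusBin] = []
        lowers: list[float] = []
        uppers: list[float] = []
        for chunk_sizes, chunk_samples in zip(
            np.split(sizes, breaks), np.split(samples, breaks)
        ):
            if len(set(chunk_samples)) < self.min_samples_per_locus:
                continue
            nominal = float(chunk_sizes.mean())
            bins.append(
                LocusBin(
                    locus_id=f"L{len(bins) + 1:04d}",
                    nominal_size_bp=nominal,
                    half_width_bp=self.half_width_bp,
                )
            )
            # Chaining can stretch a chunk past +/- half_width around its
            # mean; keep the fitted extent so member peaks always map back.
            lowers.append(min(nominal - self.half_width_bp, float(chunk_sizes[0])))
            uppers.append(
                max(nominal + self.half_width_bp, float(np.nextafter(chunk_sizes[-1], np.inf)))
            )
        self.bins_ = bins
        self.bin_lower_ = np.array(lowers)
        self.bin_upper_ = np.array(uppers)
        self.n_peaks_ = len(records)
        return self

    def transform(self, X: Sequence[PeakRecord]) -> PresenceMatrix:
        """Map peaks onto the learned bins.

        A sample with records for only one digest is excluded with a warning
        rather than scored as all-absent in the missing digest.  Multiple
        peaks of one sample in one bin collapse to a single presence call.
        """
        if not hasattr(self, "bins_"):
            raise UsageError("FragmentBinner is not fitted")
        records = list(X)
        by_sample_digest: dict[str, set[str]] = {}
        for r in records:
            by_sample_digest.setdefault(r.sample_id, set()).add(r.digest)
        samples = []
        for sample_id in sorted(by_sample_digest):
            if by_sample_digest[sample_id] >= set(DIGESTS):
                samples.append(sample_id)
            else:
                logger.warning(
                    "sample %s lacks digest(s) %s; excluded from presence matrix",
                    sample_id,
                    sorted(set(DIGESTS) - by_sample_digest[sample_id]),
                )
        sample_idx = {s: i for i, s in enumerate(samples)}
        digest_idx = {d: i for i, d in enumerate(DIGESTS)}
        presence = np.zeros((len(self.bins_), len(samples), 2), dtype=bool)
        if self.bins_:
            ties = 0
            for r in records:
                if r.sample_id not in sample_idx:
                    continue
                k = int(np.searchsorted(self.bin_lower_, r.size_bp, side="right")) - 1
                if k < 0 or r.size_bp >= self.bin_upper_[k]:
                    continue  # outside every bin
                cell = (k, sample_idx[r.sample_id], digest_idx[r.digest])
                if presence[cell]:
                    ties += 1
                presence[cell] = True
            if ties:
                logger.info("%d duplicate peaks collapsed to single presence calls", ties)
        return PresenceMatrix(loci=list(self.bins_), samples=samples, presence=presence)


def bin_fragments(
    records: Sequence[PeakRecord],
    half_width_bp: float = 0.5,
    min_samples_per_locus: int = 1,
) -> tuple[list[LocusBin], PresenceMatrix]:
    """Fit bins on the pooled records and score presence in one pass."""
    binner = FragmentBinner(
        half_width_bp=half_width_bp, min_samples_per_locus=min_samples_per_locus
    )
    matrix = binner.fit(records).transform(records)
    return binner.bins_, matrix
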