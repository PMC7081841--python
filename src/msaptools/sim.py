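"""Synthetic MSAP cohort generator.

Methylation-sensitive amplification polymorphism (MSAP) profiles a genome's
CCGG-site methylation by digesting each DNA sample twice with isoschizomer
pairs — EcoRI+HpaII ("EH") and EcoRI+MspI ("EM") — and comparing which
amplified fragments appear in each digest.  HpaII is blocked by full
methylation of the internal cytosine while MspI is blocked by hemi-methylation
of the external cytosine, so the per-locus methylation state determines a
deterministic band-presence pattern:

    unmethylated   -> band in EH and EM   (scored type I)
    hemi-methylated-> band in EH only     (type II)
    fully methylated-> band in EM only    (type III)
    uninformative  -> band in neither     (type IV; site absent or
                      hypermethylated, carries no signal)

This module simulates cohorts at three levels: (1) the true per-individual,
per-locus methylation state, (2) the noise-free band-presence pattern implied
by the states, and (3) noisy capillary-electrophoresis peak tables with
size-calling jitter, band dropout, log-normal peak heights and Poisson
spurious peaks, as a fragment-analysis package would export them.

Every output is a pure function of (config, seed); each stage draws from its
own seed substream so stages are independently reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InfeasiblePanelError
from .peaks import DIGESTS, LocusBin, PeakRecord, PresenceMatrix

__all__ = [
    "LocusState",
    "SimConfig",
    "SimTruth",
    "simulate_states",
    "states_to_presence",
    "render_peaks",
    "simulate_cohort",
]


class LocusState(enum.IntEnum):
    """True methylation state of one CCGG locus in one individual."""

    UNMETHYLATED = 0
    HEMI = 1
    FULL = 2
    UNINFORMATIVE = 3


#: Band presence (EH, EM) implied by each state, indexed by LocusState value.
PRESENCE_BY_STATE = np.array(
    [
        [True, True],  # UNMETHYLATED -> EH+/EM+
        [True, False],  # HEMI         -> EH+/EM-
        [False, True],  # FULL         -> EH-/EM+
        [False, False],  # UNINFORMATIVE -> EH-/EM-
    ],
    dtype=bool,
)

# Seed substream indices, one per simulation stage.
_STAGE_SIZES = 0
_STAGE_STATES = 1
_STAGE_PEAKS = 2


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic MSAP cohort.

    Defaults reflect a small decapod-style panel: ten individuals, 500
    scoreable loci in the 50–500 bp analysis window, state frequencies close
    to the pooled control-group band-type frequencies of a typical
    hepatopancreas MSAP screen (~70% unmethylated, 12% hemi-, 18% fully
    methylated), sub-base-pair size-calling jitter and a small per-band
    dropout probability.  The 50–1000 bp size range matches CE runs with a
    long size standard and leaves room for 500 loci at the default minimum
    spacing.
    """

    n_individuals: int = 10
    n_loci: int = 500
    state_probs: tuple[float, float, float, float] = (0.70, 0.12, 0.18, 0.0)
    locus_size_range: tuple[float, float] = (50.0, 1000.0)
    jitter_sd: float = 0.15
    dropout_p: float = 0.02
    spurious_rate: float = 1.0
    height_params: tuple[float, float] = (7.0, 0.6)
    min_locus_spacing: float | None = None
    individual_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ConfigurationError("n_individuals and n_loci must be positive")
        probs = np.asarray(self.state_probs, dtype=float)
        if probs.shape != (4,):
            raise ConfigurationError("state_probs must have exactly 4 entries")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError("state_probs entries must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"state_probs must sum to 1 (got {probs.sum():.12f})"
            )
        lo, hi = self.locus_size_range
        if not lo < hi:
            raise ConfigurationError("locus_size_range must satisfy min < max")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ConfigurationError("dropout_p must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise ConfigurationError("spurious_rate must be >= 0")
        if self.min_locus_spacing is not None and self.min_locus_spacing <= 0:
            raise ConfigurationError("min_locus_spacing must be > 0")
        if self.individual_effect_sd < 0:
            raise ConfigurationError("individual_effect_sd must be >= 0")

    @property
    def spacing(self) -> float:
        """Minimum inter-locus gap in bp.

        Defaults to ``4 * jitter_sd + 1`` so that, at default binning
        tolerance, neighbouring loci stay separable by construction.
        """
        if self.min_locus_spacing is not None:
            return self.min_locus_spacing
        return 4.0 * self.jitter_sd + 1.0


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort.

    ``states`` holds :class:`LocusState` integer codes, shape
    ``(n_individuals, n_loci)``; ``locus_sizes`` is strictly increasing with
    pairwise gaps >= the configured spacing.
    """

    states: np.ndarray
    locus_sizes: np.ndarray
    config: SimConfig
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n_ind, n_loci = self.states.shape
        if n_ind != self.config.n_individuals or n_loci != self.config.n_loci:
            raise ConfigurationError("states shape does not match config")
        if self.locus_sizes.shape != (n_loci,):
            raise ConfigurationError("locus_sizes length does not match config")
        gaps = np.diff(self.locus_sizes)
        if n_loci > 1 and gaps.min() < self.config.spacing - 1e-9:
            raise ConfigurationError("locus_sizes violate min_locus_spacing")
        if not self.sample_ids:
            object.__setattr__(
                self,
                "sample_ids",
                tuple(f"ind{i + 1:02d}" for i in range(n_ind)),
            )

    def state_frequencies(self) -> np.ndarray:
        """Empirical frequency of each of the four states, cohort-wide."""
        return np.bincount(self.states.ravel(), minlength=4) / self.states.size

    def true_ratios(self) -> tuple[float, float, float]:
        """(hemi, full, total) methylation fractions among informative loci."""
        counts = np.bincount(self.states.ravel(), minlength=4)
        informative = counts[:3].sum()
        if informative == 0:
            return (float("nan"),) * 3
        hemi = counts[LocusState.HEMI] / informative
        full = counts[LocusState.FULL] / informative
        # same arithmetic form as the scorer so equality is exact at zero noise
        total = (counts[LocusState.HEMI] + counts[LocusState.FULL]) / informative
        return float(hemi), float(full), float(total)


def _draw_locus_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform locus positions respecting the minimum spacing.

    Draws n points uniformly in the slack left after reserving ``(n-1)``
    spacing gaps, then adds the gaps back — equivalent to uniform sampling
    conditioned on all pairwise gaps >= spacing.
    """
    lo, hi = config.locus_size_range
    n = config.n_loci
    slack = (hi - lo) - (n - 1) * config.spacing
    if slack < 0:
        raise InfeasiblePanelError(
            f"{n} loci at spacing {config.spacing:g} bp do not fit in "
            f"[{lo:g}, {hi:g}] bp"
        )
    offsets = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + offsets + np.arange(n) * config.spacing


def _per_individual_probs(
    config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """State probabilities per individual, shape (n_individuals, 4).

    With ``individual_effect_sd`` > 0 the total methylation fraction among
    informative states receives a logit-normal individual effect
    (overdispersion between individuals); the hemi/full split and the
    uninformative fraction stay fixed.
    """
    base = np.asarray(config.state_probs, dtype=float)
    probs = np.tile(base, (config.n_individuals, 1))
    sd = config.individual_effect_sd
    informative = base[:3].sum()
    methylated = base[1] + base[2]
    if sd == 0 or informative == 0 or methylated in (0.0, informative):
        return probs
    m = methylated / informative
    logit = np.log(m / (1.0 - m))
    shifted = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0.0, sd, config.n_individuals))))
    hemi_share = base[1] / methylated
    probs[:, 0] = informative * (1.0 - shifted)
    probs[:, 1] = informative * shifted * hemi_share
    probs[:, 2] = informative * shifted * (1.0 - hemi_share)
    return probs


def simulate_states(config: SimConfig) -> SimTruth:
    """Draw the ground-truth state matrix and locus size panel."""
    size_rng = _stage_rng(config.seed, _STAGE_SIZES)
    state_rng = _stage_rng(config.seed, _STAGE_STATES)
    locus_sizes = _draw_locus_sizes(config, size_rng)
    probs = _per_individual_probs(config, state_rng)
    # Inverse-CDF draw per individual keeps vectorisation with per-row probs.
    cum = np.cumsum(probs, axis=1)
    u = state_rng.random((config.n_individuals, config.n_loci))
    states = (u[:, :, None] >= cum[:, None, :]).sum(axis=2).astype(np.int8)
    return SimTruth(states=states, locus_sizes=locus_sizes, config=config)


def states_to_presence(truth: SimTruth) -> PresenceMatrix:
    """Deterministic state -> (EH, EM) band-presence mapping, no noise."""
    half_width = min(0.5, truth.config.spacing / 2.0)
    bins = [
        LocusBin(locus_id=f"L{j + 1:04d}", nominal_size_bp=float(s), half_width_bp=half_width)
        for j, s in enumerate(truth.locus_sizes)
    ]
    # states: (ind, locus) -> presence tensor (locus, sample, digest)
    presence = PRESENCE_BY_STATE[truth.states.T]
    return PresenceMatrix(
        loci=bins, samples=list(truth.sample_ids), presence=presence
    )


def render_peaks(
    truth: SimTruth, presence: PresenceMatrix | None = None
) -> list[PeakRecord]:
    """Render noisy CE peak tables from a presence pattern.

    Each present band yields a peak at ``locus_size + N(0, jitter_sd)``
    (clipped to the analysis window), dropped with probability ``dropout_p``;
    heights are log-normal; ``Poisson(spurious_rate)`` spurious peaks per
    sample x digest land uniformly in the window.  Records come out sorted by
    (sample, digest, size).
    """
    if presence is None:
        presence = states_to_presence(truth)
    cfg = truth.config
    if presence.presence.shape != (cfg.n_loci, cfg.n_individuals, 2):
        raise ConfigurationError("presence dimensions do not match truth")
    rng = _stage_rng(cfg.seed, _STAGE_PEAKS)
    lo, hi = cfg.locus_size_range
    mu, sigma = cfg.height_params

    tensor = presence.presence
    # Draw noise for the full tensor in a fixed order so output is a pure
    # function of (config, seed) regardless of how sparse the pattern is.
    jitter = rng.normal(0.0, cfg.jitter_sd, size=tensor.shape)
    kept = rng.random(tensor.shape) >= cfg.dropout_p
    heights = rng.lognormal(mu, sigma, size=tensor.shape)
    n_spurious = rng.poisson(cfg.spurious_rate, size=(cfg.n_individuals, 2))
    spur_sizes = rng.uniform(lo, hi, size=int(n_spurious.sum()))
    spur_heights = rng.lognormal(mu, sigma, size=int(n_spurious.sum()))

    records: list[PeakRecord] = []
    spur_at = 0
    for i, sample in enumerate(presence.samples):
        for d, digest in enumerate(DIGESTS):
            rows: list[tuple[float, float]] = []
            loci_idx = np.flatnonzero(tensor[:, i, d] & kept[:, i, d])
            sizes = np.clip(
                truth.locus_sizes[loci_idx] + jitter[loci_idx, i, d], lo, hi
            )
            rows.extend(zip(sizes, heights[loci_idx, i, d]))
            k = int(n_spurious[i, d])
            rows.extend(
                zip(spur_sizes[spur_at : spur_at + k], spur_heights[spur_at : spur_at + k])
            )
            spur_at += k
            rows.sort()
            records.extend(
                PeakRecord(
                    sample_id=sample,
                    digest=digest,
                    size_bp=float(s),
                    height=float(h),
                    area=float(h),
                )
                for s, h in rows
            )
    return records


def simulate_cohort(config: SimConfig) -> tuple[SimTruth, list[PeakRecord]]:
    """Convenience wrapper: states -> presence -> noisy peak table."""
    truth = simulate_states(config)
    return truth, render_peaks(truth)


def truth_to_frame(truth: SimTruth):
    """Long-format ground truth (individual, locus_id, size_bp, state)."""
    import pandas as pd

    n_ind, n_loci = truth.states.shape
    return pd.DataFrame(
        {
            "individual": np.repeat(truth.sample_ids, n_loci),
            "locus_id": np.tile([f"L{j + 1:04d}" for j in range(n_loci)], n_ind),
            "size_bp": np.tile(truth.locus_sizes, n_ind),
            "state": [LocusState(v).name for v in truth.states.ravel()],
        }
    )
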