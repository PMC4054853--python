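"""Background distributions, z-scores, empirical P-values and motif calls.

A subgraph class is called a motif when it is over-represented in the real
network relative to the background of randomized networks, with the
simultaneous requirements P < 0.01, z > 2.0 and background SD > 1 (in
counts).  The empirical P-value is the one-sided fraction of background
networks whose count reaches the observed count (r/N); a zero is reported
in text output as a bound "< 1/N".  Classes whose background never varies
(SD = 0) are flagged degenerate and never called — a narrow background is
the signature of insufficient randomization, not of significance.  No
multiple-testing correction is applied: the networks this method is run
on are typically nested by construction and the calls are meant for
hypothesis generation, not confirmatory inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .census import CensusResult

__all__ = [
    "BackgroundDistribution",
    "MotifCall",
    "Thresholds",
    "zscore",
    "empirical_p",
    "build_backgrounds",
    "call_motifs",
    "stability_curve",
]


@dataclass
class Thresholds:
    p_max: float = 0.01
    z_min: float = 2.0
    sd_min: float = 1.0


@dataclass
class BackgroundDistribution:
    """Counts of one subgraph class over N randomized networks."""

    canonical_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n(self) -> int:
        return int(self.counts.size)

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def sd(self) -> float:
        # Sample SD (N-1); degenerate backgrounds yield 0.
        if self.n < 2:
            return 0.0
        return float(self.counts.std(ddof=1))


@dataclass
class MotifCall:
    canonical_id: str
    observed: int
    mean: float
    sd: float
    z: float
    p: float
    is_motif: bool
    degenerate: bool = False

    def p_text(self, n_backgrounds: int) -> str:
        return f"<{1.0 / n_backgrounds:g}" if self.p == 0.0 else f"{self.p:g}"


def zscore(observed: float, mean: float, sd: float) -> float:
    """Standard score of the observed count against its background."""
    if sd <= 0:
        raise ValueError("zscore undefined for sd <= 0 (degenerate background)")
    return (observed - mean) / sd


def empirical_p(observed: float, counts: Sequence[int] | np.ndarray) -> float:
    """One-sided over-representation P: fraction of backgrounds >= observed."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empirical_p needs at least one background count")
    return float(np.count_nonzero(counts >= observed) / counts.size)


def build_backgrounds(
    background_results: Sequence[CensusResult],
    extra_classes: Iterable[str] = (),
) -> dict[str, BackgroundDistribution]:
    """Assemble per-class background count vectors.

    A class absent from a randomized network contributes a count of zero
    for that replicate; ``extra_classes`` forces classes seen only in the
    observed network into the map.
    """
    if len(background_results) < 2:
        raise ValueError("backgrounds need at least 2 randomized networks")
    modes = {r.mode for r in background_results}
    if len(modes) > 1:
        raise ValueError(f"mixed census modes in backgrounds: {modes}")
    classes: set[str] = set(extra_classes)
    for r in background_results:
        classes.update(r.counts)
    return {
        cid: BackgroundDistribution(
            cid, np.array([r.get(cid) for r in background_results])
        )
        for cid in sorted(classes)
    }


def call_motifs(
    observed: CensusResult,
    backgrounds: Mapping[str, BackgroundDistribution],
    thresholds: Thresholds | None = None,
) -> list[MotifCall]:
    """One call per class observed in the real network, sorted by (p, -z).

    Only over-representation gates ``is_motif``; under-represented classes
    appear with their (large) P and negative z but are never called.
    """
    thresholds = thresholds or Thresholds()
    calls = []
    for cid, obs in sorted(observed.counts.items()):
        if obs == 0:
            continue
        bg = backgrounds.get(cid)
        if bg is None:
            raise KeyError(f"class {cid} missing from backgrounds")
        sd = bg.sd
        p = empirical_p(obs, bg.counts)
        if sd == 0.0:
            calls.append(
                MotifCall(cid, obs, bg.mean, 0.0, float("nan"), p, False, True)
            )
            continue
        z = zscore(obs, bg.mean, sd)
        is_motif = (
            p < thresholds.p_max and z > thresholds.z_min and sd > thresholds.sd_min
        )
        calls.append(MotifCall(cid, obs, bg.mean, sd, z, p, is_motif))
    calls.sort(key=lambda c: (c.p, -(c.z if c.z == c.z else float("-inf"))))
    return calls


def stability_curve(
    counts_per_class: Mapping[str, Sequence[int]],
    observed: Mapping[str, int],
    checkpoints: Sequence[int],
) -> dict[int, dict[str, float]]:
    """P-value stability as the number of background networks grows.

    For each checkpoint n, computes |P(n) - P(n_max)| per class, where
    P(n) uses the first n background counts; returns per-checkpoint
    summaries (max and mean absolute difference over classes).  The curve
    flattening out tells you how many randomized networks are enough for
    stable motif calls.
    """
    lengths = {len(c) for c in counts_per_class.values()}
    if len(lengths) != 1:
        raise ValueError("all classes need the same number of replicate counts")
    n_max = lengths.pop()
    if any(not 1 <= n <= n_max for n in checkpoints):
        raise ValueError("checkpoints must lie in [1, n_max]")
    p_full = {
        cid: empirical_p(observed.get(cid, 0), counts)
        for cid, counts in counts_per_class.items()
    }
    out: dict[int, dict[str, float]] = {}
    for n in checkpoints:
        diffs = [
            abs(empirical_p(observed.get(cid, 0), np.asarray(counts)[:n]) - p_full[cid])
            for cid, counts in counts_per_class.items()
        ]
        out[int(n)] = {
            "max_abs_dp": float(np.max(diffs)) if diffs else 0.0,
            "mean_abs_dp": float(np.mean(diffs)) if diffs else 0.0,
        }
    return out
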