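"""Breakpoint overlay — the recombination ratchet — and c-gene statistics.

Recombination breakpoints detected independently in different subclades of a
species tree all fragment the same chromosomal coordinate system.  Overlaying
k independent breakpoint sets therefore yields a composite c-gene map whose
c-genes are never larger, and typically about k-fold smaller, than those of
any single subclade: adding taxa can only add breakpoints.  This module
performs that overlay, summarizes the resulting c-gene length distribution
(with a descriptive geometric fit), and labels each composite c-gene with the
tuple of local genealogies holding over its interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io_align import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "CGeneMap",
    "CGeneStats",
    "ConsistencyError",
    "overlay",
    "stats",
    "label_cgenes",
]


class ConsistencyError(ValueError):
    """A genealogy track changes state inside a c-gene of the map."""


@dataclass(frozen=True)
class CGeneMap:
    """Partition of [0, L) into c-genes by sorted unique breakpoints.

    ``labels``, when present, holds one composite-genealogy tuple per c-gene
    (one entry per trichotomy).  ``provenance`` maps each breakpoint position
    to the names of the subclades that contributed it; positions contributed
    by more than one subclade were collapsed to a single breakpoint.
    ``annotations`` carries positions of genealogy changes that do not alter
    topology (deep-coalescence-only boundaries, invisible to the
    four-gamete test) and are deliberately not breakpoints of the map.
    """

    segment_length: int
    breakpoints: tuple[int, ...]
    labels: tuple[tuple[str, ...], ...] | None = None
    provenance: dict[int, tuple[str, ...]] | None = None
    annotations: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise InputError("segment length must be positive")
        bps = list(self.breakpoints)
        if bps != sorted(set(bps)):
            raise InputError("breakpoints must be sorted and unique")
        if bps and not (0 < bps[0] and bps[-1] < self.segment_length):
            raise InputError("breakpoints must lie strictly inside (0, L)")
        if self.labels is not None and len(self.labels) != self.n_cgenes:
            raise InputError("need one label per c-gene")

    @property
    def cgenes(self) -> tuple[tuple[int, int], ...]:
        """Half-open intervals tiling [0, L)."""
        edges = (0, *self.breakpoints, self.segment_length)
        return tuple(zip(edges[:-1], edges[1:]))

    @property
    def n_cgenes(self) -> int:
        return len(self.breakpoints) + 1

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.cgenes)

    @property
    def collapsed(self) -> tuple[int, ...]:
        """Breakpoint positions contributed by more than one subclade."""
        if not self.provenance:
            return ()
        return tuple(p for p, who in sorted(self.provenance.items()) if len(who) > 1)


@dataclass(frozen=True)
class CGeneStats:
    """Summary of a c-gene length distribution.

    ``geometric_p`` is the moment/ML estimate 1/mean for a geometric length
    model on support {1, 2, ...}; ``fit_pvalue`` is a chi-square
    goodness-of-fit probability (NaN when there are too few c-genes to bin).
    The fit is descriptive only.
    """

    count: int
    mean_length: float
    median_length: float
    min_length: int
    max_length: int
    geometric_p: float
    fit_pvalue: float


def overlay(
    sets: Sequence,
    segment_length: int | None = None,
    names: Sequence[str] | None = None,
) -> CGeneMap:
    """Overlay per-subclade breakpoint sets into one composite c-gene map.

    ``sets`` are BreakpointSet-like objects sharing ``segment_length`` and
    exposing ``points``.  Breakpoints are pooled as the sorted union of
    representative points; coincident points from different subclades
    collapse to a single breakpoint (counted once) and are logged, since a
    recurrent breakpoint at the exact same position cannot be told apart
    from two independent ones.  An empty input yields a single c-gene
    spanning [0, L).
    """
    if not sets and segment_length is None:
        raise InputError("segment_length required when no breakpoint sets given")
    lengths = {bs.segment_length for bs in sets}
    if segment_length is not None:
        lengths.add(segment_length)
    if len(lengths) > 1:
        raise InputError(f"breakpoint sets disagree on segment length: {sorted(lengths)}")
    L = lengths.pop()

    if names is None:
        names = [f"subclade{i + 1}" for i in range(len(sets))]
    provenance: dict[int, list[str]] = {}
    for name, bs in zip(names, sets):
        for p in bs.points:
            provenance.setdefault(int(p), []).append(name)

    collapsed = {p: who for p, who in provenance.items() if len(who) > 1}
    for p, who in sorted(collapsed.items()):
        logger.warning(
            "coincident breakpoint at %d contributed by %s: collapsed to one",
            p,
            ", ".join(who),
        )

    return CGeneMap(
        segment_length=L,
        breakpoints=tuple(sorted(provenance)),
        provenance={p: tuple(w) for p, w in provenance.items()},
    )


def stats(cgene_map: CGeneMap, min_expected: float = 5.0) -> CGeneStats:
    """Summarize c-gene lengths and fit a geometric length distribution.

    The geometric parameter is the moment estimate p = 1/mean (also the MLE
    on support {1, 2, ...}).  Goodness of fit uses a chi-square test on
    quantile bins chosen so every bin has expected count >= ``min_expected``;
    with fewer than ~4 usable bins the p-value is NaN.
    """
    lengths = np.asarray(cgene_map.lengths, dtype=float)
    mean = cgene_map.segment_length / cgene_map.n_cgenes
    p = 1.0 / mean

    fit_pvalue = _geometric_gof(lengths, p, min_expected)
    return CGeneStats(
        count=cgene_map.n_cgenes,
        mean_length=mean,
        median_length=float(np.median(lengths)),
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        geometric_p=p,
        fit_pvalue=fit_pvalue,
    )


def _geometric_gof(lengths: np.ndarray, p: float, min_expected: float) -> float:
    n = len(lengths)
    n_bins = min(20, int(n / min_expected))
    if n_bins < 4:
        return float("nan")
    geom = sps.geom(p)
    # Bin edges at geometric quantiles: equal expected counts per bin.
    qs = np.arange(1, n_bins) / n_bins
    edges = np.unique(geom.ppf(qs))
    cuts = np.concatenate(([0.5], edges + 0.5, [np.inf]))
    observed, _ = np.histogram(lengths, bins=cuts)
    expected = np.diff(geom.cdf(cuts)) * n
    keep = expected > 0
    observed, expected = observed[keep], expected[keep]
    if len(observed) < 4:
        return float("nan")
    expected *= observed.sum() / expected.sum()
    # one fitted parameter (p) -> ddof=1
    stat, pval = sps.chisquare(observed, expected, ddof=1)
    return float(pval) if math.isfinite(stat) else float("nan")


def label_cgenes(cgene_map: CGeneMap, tracks: Sequence[Sequence[tuple[int, int, str]]]) -> CGeneMap:
    """Label each c-gene with the tuple of local genealogies covering it.

    Each track is a sequence of (start, end, label) segments tiling
    [0, L) — one track per trichotomy/subclade.  If any track changes label
    strictly inside a c-gene, the map is missing that breakpoint and a
    :class:`ConsistencyError` is raised.
    """
    L = cgene_map.segment_length
    for ti, track in enumerate(tracks):
        pos = 0
        for start, end, _ in track:
            if start != pos:
                raise InputError(f"track {ti} does not tile [0, L): gap at {start}")
            pos = end
        if pos != L:
            raise InputError(f"track {ti} ends at {pos}, expected {L}")

    labels = []
    for s, e in cgene_map.cgenes:
        tup = []
        for ti, track in enumerate(tracks):
            covering = [lab for (ts, te, lab) in track if ts < e and s < te]
            if len(set(covering)) != 1:
                raise ConsistencyError(
                    f"track {ti} changes state inside c-gene [{s}, {e}): "
                    f"breakpoint missing from map"
                )
            tup.append(covering[0])
        labels.append(tuple(tup))
    return CGeneMap(
        segment_length=L,
        breakpoints=cgene_map.breakpoints,
        labels=tuple(labels),
        provenance=cgene_map.provenance,
        annotations=cgene_map.annotations,
    )
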