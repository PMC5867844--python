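"""Genealogical mosaic simulation with known truth tracks.

Along a chromosome, incomplete lineage sorting partitions each trichotomy's
history into alternating segments of four genealogical states — the
concordant topology with or without deep coalescence, and the two discordant
topologies — with geometrically distributed segment lengths, the pattern a
coalescent hidden Markov model recovers from hominid data.  This module draws
such state tracks per trichotomy, composes them into a ground-truth c-gene
map, and emits synthetic alignments whose parsimony-informative site patterns
reflect each segment's local topology.  Because the truth track is known
exactly, the simulator is the oracle for the four-gamete detector and the
overlay machinery.

Sequence emission is deliberately pattern-based rather than a substitution-
model simulation: the four-gamete test consumes only site patterns, and
direct pattern control keeps the truth exactly verifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fourgamete import SPLITS
from .io_align import Alignment, InputError
from .ratchet import CGeneMap
from .topology import SpeciesTreeSpec, Trichotomy

__all__ = [
    "STATES",
    "TrichotomyModel",
    "TrichotomyMosaic",
    "SiteDensities",
    "default_model",
    "simulate_mosaic",
    "topology_of_state",
    "topology_track",
    "compose_tracks",
    "emit_alignment",
    "expected_occupancy",
    "default_outgroups",
]

# Genealogical states per trichotomy.  The two concordant states share the
# species-tree topology and differ only in whether the pair coalesces in its
# immediate ancestral population (deep0) or deeper (deep1) — a branch-length
# distinction invisible to topology-based detectors.
STATES = ("concordant_deep0", "concordant_deep1", "discordant_a", "discordant_b")


@dataclass(frozen=True)
class TrichotomyModel:
    """Per-state mean segment lengths (bp) and stationary bp occupancies.

    ``stationary_freq[s]`` is the expected fraction of sequence in state s
    (summing to 1); segment lengths in state s are geometric with mean
    ``mean_length[s]`` on support {1, 2, ...}.  ``homoplasy_rate`` is the
    probability that an emitted informative site supports a uniformly random
    wrong split instead of its segment's topology.
    """

    mean_length: Mapping[str, float]
    stationary_freq: Mapping[str, float]
    homoplasy_rate: float = 0.0

    def __post_init__(self) -> None:
        if set(self.mean_length) != set(STATES) or set(self.stationary_freq) != set(STATES):
            raise InputError(f"model must define all states {STATES}")
        if any(m <= 0 for m in self.mean_length.values()):
            raise InputError("mean lengths must be positive")
        if any(f < 0 for f in self.stationary_freq.values()):
            raise InputError("frequencies must be non-negative")
        if abs(sum(self.stationary_freq.values()) - 1.0) > 1e-9:
            raise InputError("stationary frequencies must sum to 1")
        if not (0.0 <= self.homoplasy_rate < 1.0):
            raise InputError("homoplasy_rate must be in [0, 1)")

    @property
    def overall_mean_length(self) -> float:
        """Combined mean c-gene length, 1 / sum(freq_s / mean_s)."""
        return 1.0 / sum(
            self.stationary_freq[s] / self.mean_length[s] for s in STATES
        )

    def segment_weights(self) -> dict[str, float]:
        """Long-run fraction of segments in each state: freq/mean, normalized."""
        w = {s: self.stationary_freq[s] / self.mean_length[s] for s in STATES}
        tot = sum(w.values())
        return {s: v / tot for s, v in w.items()}


def default_model(homoplasy_rate: float = 0.0) -> TrichotomyModel:
    """Hominid-like default: long concordant-shallow segments, short others.

    Concordant-without-deep-coalescence segments average 532 bp and occupy
    half the sequence; the three deep-coalescence states average 60.6 bp.
    The combined mean c-gene length is ~108.8 bp, matching the empirical
    scale of coalescent-HMM segmentations of hominid autosomal targets.
    """
    return TrichotomyModel(
        mean_length={
            "concordant_deep0": 532.0,
            "concordant_deep1": 60.6,
            "discordant_a": 60.6,
            "discordant_b": 60.6,
        },
        stationary_freq={
            "concordant_deep0": 0.50,
            "concordant_deep1": 0.20,
            "discordant_a": 0.15,
            "discordant_b": 0.15,
        },
        homoplasy_rate=homoplasy_rate,
    )


@dataclass(frozen=True)
class TrichotomyMosaic:
    """State track for one trichotomy: (state, start, end) segments tiling [0, L)."""

    segment_length: int
    track: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        pos = 0
        prev_state = None
        for state, start, end in self.track:
            if start != pos or end <= start:
                raise InputError("mosaic segments must tile [0, L)")
            if state == prev_state:
                raise InputError("adjacent mosaic segments must differ in state")
            pos = end
            prev_state = state
        if pos != self.segment_length:
            raise InputError("mosaic does not cover [0, L)")

    @property
    def n_segments(self) -> int:
        return len(self.track)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _sampling_weights(model: TrichotomyModel) -> tuple[list[str], np.ndarray]:
    """Sampling weights calibrated for the no-repeat segment chain.

    Drawing each segment's state with raw weight freq/mean, conditioned on
    differing from the previous state, biases the chain towards rarely-drawn
    states (they are never excluded).  This solves for weights w such that
    the chain with P(i -> j) = w_j / (1 - w_i) has stationary *segment*
    distribution exactly q = freq/mean (normalized), so realized bp occupancy
    matches ``stationary_freq``.  Fixed-point iteration on
    w_j = q_j / (T - q_j/(1 - w_j)), T = sum_i q_i/(1 - w_i).
    """
    seg = model.segment_weights()
    states = [s for s in STATES if seg[s] > 0]
    q = np.array([seg[s] for s in states])
    q = q / q.sum()
    if len(states) == 1:
        return states, np.array([1.0])
    if q.max() > 0.5 + 1e-12:
        raise InputError(
            "no alternating renewal realizes a segment-state frequency above 1/2 "
            f"(got {q.max():.3f} for {states[int(q.argmax())]})"
        )
    w = q.copy()
    for _ in range(500):
        T = (q / (1.0 - w)).sum()
        denom = T - q / (1.0 - w)
        if np.any(denom <= 0):
            raise InputError("segment-frequency calibration failed to converge")
        new = q / denom
        new = new / new.sum()
        if np.max(np.abs(new - w)) < 1e-13:
            w = new
            break
        w = new
    return states, w


def simulate_mosaic(model: TrichotomyModel, segment_length: int, seed) -> TrichotomyMosaic:
    """Draw one alternating-renewal state track.

    Segment states are sampled, conditioned on differing from the previous
    state, with weights calibrated so the long-run segment-state frequencies
    are freq/mean — hence bp occupancy matches ``stationary_freq``.  Lengths
    are geometric with the state's mean, the last segment truncated at L.
    Deterministic for a fixed seed.
    """
    rng = _rng(seed)
    states, probs = _sampling_weights(model)
    if len(states) == 1:  # degenerate model: one segment spans the whole length
        return TrichotomyMosaic(
            segment_length=segment_length,
            track=((states[0], 0, segment_length),),
        )

    track: list[tuple[str, int, int]] = []
    pos = 0
    prev = None
    while pos < segment_length:
        if prev is None:
            state = rng.choice(states, p=probs)
        else:
            mask = np.array([s != prev for s in states])
            p = probs * mask
            p = p / p.sum()
            state = rng.choice(states, p=p)
        length = int(rng.geometric(1.0 / model.mean_length[state]))
        end = min(pos + length, segment_length)
        track.append((str(state), pos, end))
        pos = end
        prev = state
    return TrichotomyMosaic(segment_length=segment_length, track=tuple(track))


def topology_of_state(state: str, trichotomy: Trichotomy) -> str:
    """Map a genealogical state to its topology (a resolution label).

    Both concordant states carry the species-tree resolution; the two
    discordant states take the remaining resolutions in canonical order.
    """
    if state in ("concordant_deep0", "concordant_deep1"):
        return trichotomy.species_pair
    others = [r for r in SPLITS if r != trichotomy.species_pair]
    if state == "discordant_a":
        return others[0]
    if state == "discordant_b":
        return others[1]
    raise InputError(f"unknown state {state!r}")


def topology_track(
    mosaic: TrichotomyMosaic, trichotomy: Trichotomy
) -> tuple[list[tuple[int, int, str]], list[int]]:
    """Collapse a state track to its topology track.

    Returns (segments, silent_changes): segments are (start, end, resolution)
    with adjacent equal topologies merged; silent_changes are state-change
    positions where the topology did not change (deep0<->deep1 boundaries).
    """
    merged: list[tuple[int, int, str]] = []
    silent: list[int] = []
    for state, start, end in mosaic.track:
        topo = topology_of_state(state, trichotomy)
        if merged and merged[-1][2] == topo:
            silent.append(start)
            merged[-1] = (merged[-1][0], end, topo)
        else:
            merged.append((start, end, topo))
    return merged, silent


def compose_tracks(
    mosaics: Sequence[TrichotomyMosaic], spec: SpeciesTreeSpec
) -> CGeneMap:
    """Compose per-trichotomy mosaics into the ground-truth labelled c-gene map.

    Breakpoints are the union of per-track *topology*-change positions;
    state changes that only alter coalescence depth are excluded from the
    breakpoints (the four-gamete test cannot see them) but retained in the
    map's ``annotations``.  Labels are resolution tuples, one entry per
    trichotomy.
    """
    if len(mosaics) != spec.k:
        raise InputError("need one mosaic per trichotomy")
    lengths = {m.segment_length for m in mosaics}
    if len(lengths) != 1:
        raise InputError("mosaics disagree on segment length")
    L = lengths.pop()

    tracks = []
    provenance: dict[int, list[str]] = {}
    annotations: list[int] = []
    for mosaic, tri in zip(mosaics, spec.trichotomies):
        segs, silent = topology_track(mosaic, tri)
        tracks.append(segs)
        annotations.extend(silent)
        for _, end, _ in segs[:-1]:
            provenance.setdefault(end, []).append(tri.name)

    from .ratchet import label_cgenes  # deferred to keep module layering flat

    base = CGeneMap(
        segment_length=L,
        breakpoints=tuple(sorted(provenance)),
        provenance={p: tuple(w) for p, w in provenance.items()},
        annotations=tuple(sorted(annotations)),
    )
    return label_cgenes(base, tracks)


@dataclass(frozen=True)
class SiteDensities:
    """Per-column probabilities of emitting each pattern class.

    ``informative`` is the total probability of a parsimony-informative
    column, split evenly across trichotomies; the remainder is ``singleton``
    plus ``invariant``.  Must sum to 1.
    """

    informative: float
    singleton: float
    invariant: float

    def __post_init__(self) -> None:
        for v in (self.informative, self.singleton, self.invariant):
            if v < 0:
                raise InputError("site densities must be non-negative")
        if abs(self.informative + self.singleton + self.invariant - 1.0) > 1e-9:
            raise InputError("site densities must sum to 1")


_BASES = np.array(list("ACGT"))

_SPLIT_PAIR_INDEX = {"T1T2": (0, 1), "T1T3": (0, 2), "T2T3": (1, 2)}


def default_outgroups(spec: SpeciesTreeSpec, extra_taxa: Sequence[str] = ()) -> dict[str, str]:
    """Pick an outgroup taxon for each trichotomy.

    With >= 2 trichotomies, the first taxon of the next trichotomy (cyclic)
    serves; long backbone branches carry the ancestral allele at sites
    informative for other trichotomies, so any outside taxon works.  With a
    single trichotomy an ``extra_taxa`` entry is required.
    """
    out: dict[str, str] = {}
    tris = spec.trichotomies
    for i, tri in enumerate(tris):
        if len(tris) >= 2:
            out[tri.name] = tris[(i + 1) % len(tris)].taxa[0]
        elif extra_taxa:
            out[tri.name] = extra_taxa[0]
        else:
            raise InputError(
                "a single-trichotomy alignment needs an extra outgroup taxon"
            )
    return out


def emit_alignment(
    truth: CGeneMap,
    spec: SpeciesTreeSpec,
    densities: SiteDensities,
    seed,
    homoplasy_rate: float = 0.0,
    extra_taxa: Sequence[str] = (),
) -> Alignment:
    """Emit a synthetic alignment realizing a labelled truth map.

    Column by column: with probability ``densities.invariant`` all taxa share
    one base; with ``densities.singleton`` one random taxon carries an
    alternative base; with ``densities.informative`` (split evenly across
    trichotomies) the column is 2+2-informative for one trichotomy — the pair
    united by the local topology of the enclosing c-gene carries the derived
    base, every other taxon the ancestral one.  With probability
    ``homoplasy_rate`` an informative column instead supports a uniformly
    random wrong split.  Deterministic per seed.
    """
    if truth.labels is None:
        raise InputError("truth map must be labelled")
    rng = _rng(seed)
    taxa = [t for tri in spec.trichotomies for t in tri.taxa] + list(extra_taxa)
    tri_taxon_idx = [
        tuple(taxa.index(t) for t in tri.taxa) for tri in spec.trichotomies
    ]
    L = truth.segment_length
    n_taxa = len(taxa)
    k = spec.k

    # Per-column category: 0 invariant, 1 singleton, 2..2+k-1 informative for
    # trichotomy (cat - 2).
    probs = [densities.invariant, densities.singleton] + [densities.informative / k] * k
    cats = rng.choice(len(probs), size=L, p=probs)

    anc = rng.integers(0, 4, size=L)
    derived = (anc + rng.integers(1, 4, size=L)) % 4  # distinct from ancestral

    cols = np.repeat(_BASES[anc][None, :], n_taxa, axis=0)  # (taxa, columns)

    single_cols = np.flatnonzero(cats == 1)
    if single_cols.size:
        rows = rng.integers(0, n_taxa, size=single_cols.size)
        cols[rows, single_cols] = _BASES[derived[single_cols]]

    edges = np.array([0, *truth.breakpoints], dtype=int)
    labels = truth.labels
    for ti in range(k):
        info_cols = np.flatnonzero(cats == 2 + ti)
        if not info_cols.size:
            continue
        cg_idx = np.searchsorted(edges, info_cols, side="right") - 1
        local = np.array(
            [SPLITS.index(labels[c][ti]) for c in cg_idx], dtype=int
        )
        if homoplasy_rate > 0.0:
            flip = rng.random(info_cols.size) < homoplasy_rate
            # a uniformly random wrong split: shift by 1 or 2 mod 3
            local[flip] = (local[flip] + rng.integers(1, 3, size=int(flip.sum()))) % 3
        pair_rows = np.array([_SPLIT_PAIR_INDEX[s] for s in SPLITS])  # (3, 2)
        taxon_rows = np.array(tri_taxon_idx[ti])  # (3,)
        united = taxon_rows[pair_rows[local]]  # (n_cols, 2)
        d = _BASES[derived[info_cols]]
        cols[united[:, 0], info_cols] = d
        cols[united[:, 1], info_cols] = d

    seqs = ["".join(cols[i]) for i in range(n_taxa)]
    return Alignment(taxa=tuple(taxa), sequences=tuple(seqs))


def expected_occupancy(model: TrichotomyModel) -> dict[str, float]:
    """Exact long-run bp occupancy under the simulator's segment chain.

    The segment-state chain has transitions P(i -> j) = w_j / (1 - w_i) for
    j != i, with w the calibrated sampling weights; occupancy is the chain's
    stationary distribution length-weighted by the state means.  With the
    calibration this equals ``stationary_freq`` up to numerical tolerance —
    the function exists to verify that independently of the calibration.
    """
    states, w = _sampling_weights(model)
    if len(states) == 1:
        return {states[0]: 1.0}
    n = len(states)
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                P[i, j] = w[j] / (1.0 - w[i])
    vals, vecs = np.linalg.eig(P.T)
    q = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    q = q / q.sum()
    m = np.array([model.mean_length[s] for s in states])
    occ = q * m
    occ = occ / occ.sum()
    return dict(zip(states, occ))
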