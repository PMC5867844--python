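"""Four-gamete recombination breakpoint detection for one subclade.

Given a four-taxon alignment (three ingroup taxa plus one outgroup), the
four-gamete test (FGT) declares a recombination event between two biallelic
sites whenever all four allele combinations occur among the haplotypes —
impossible under the infinite-sites model without recombination.  Only
parsimony-informative 2+2 columns can conflict, so the detector first scans
for those, then applies the Hudson–Kaplan minimal-interval procedure to
localize the minimum number of recombination events (Rmin) implied by the
incompatible pairs.

The test is combinatorial, not statistical: it is conservative (a breakpoint
needs flanking informative sites supporting different splits) and it is blind
to genealogy changes that alter only branch lengths, not topology.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_align import Alignment, InputError, SubcladeSpec, subset

__all__ = [
    "SPLITS",
    "InformativeSite",
    "BreakpointSet",
    "extract_informative_sites",
    "incompatible",
    "hudson_kaplan",
    "delimit_subclade",
    "representative_point",
]

# The three possible 2+2 bipartitions of (ingroup1, ingroup2, ingroup3,
# outgroup), labelled by the ingroup pair they unite.  The same vocabulary
# labels trichotomy resolutions throughout the package.
SPLITS = ("T1T2", "T1T3", "T2T3")

_PAIR_TO_SPLIT = {
    frozenset({0, 1}): "T1T2",
    frozenset({0, 2}): "T1T3",
    frozenset({1, 2}): "T2T3",
}


@dataclass(frozen=True)
class InformativeSite:
    """A parsimony-informative (biallelic 2+2) column of a 4-taxon alignment.

    ``alleles`` stores the column in taxon order (ingroup1, ingroup2,
    ingroup3, outgroup); ``split`` names the ingroup pair sharing an allele.
    """

    position: int
    split: str
    alleles: tuple[str, str, str, str]


@dataclass(frozen=True)
class BreakpointSet:
    """Hudson–Kaplan output for one subclade over a segment of length L.

    Each open interval ``(l, r)`` between informative-site positions is
    guaranteed to contain at least one recombination event; intervals are
    pairwise disjoint, so ``len(intervals)`` is Rmin.  ``points`` carries one
    deterministic representative breakpoint per interval (see
    :func:`representative_point`).  ``flank_splits`` records the split labels
    of the informative sites bounding each interval.
    """

    segment_length: int
    intervals: tuple[tuple[int, int], ...]
    points: tuple[int, ...]
    flank_splits: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.points) != len(self.intervals):
            raise InputError("one representative point per interval required")
        prev_end = -1
        for (l, r), p in zip(self.intervals, self.points):
            if l < prev_end:
                raise InputError("breakpoint intervals must be disjoint and sorted")
            if not (l < p <= r):
                raise InputError(f"point {p} outside breakpoint range ({l}, {r}]")
            prev_end = r
        if list(self.points) != sorted(set(self.points)):
            raise InputError("points must be strictly increasing")

    @property
    def n_breakpoints(self) -> int:
        return len(self.points)

    @property
    def n_cgenes(self) -> int:
        return len(self.points) + 1


def _classify_column(column: str) -> str | None:
    """Return the 2+2 split label of a 4-taxon column, or None.

    Columns containing N or a gap among the four taxa, invariant columns,
    singleton (1+3) columns and columns with >2 alleles are all rejected.
    """
    if any(c not in "ACGT" for c in column):
        return None
    alleles = set(column)
    if len(alleles) != 2:
        return None
    a = column[0]
    group = frozenset(i for i in range(4) if column[i] == a)
    if len(group) != 2:
        return None  # 1+3 singleton
    if 3 in group:
        group = frozenset({0, 1, 2} - group)
    return _PAIR_TO_SPLIT[group]


def extract_informative_sites(alignment: Alignment) -> list[InformativeSite]:
    """Scan a 4-taxon alignment for parsimony-informative 2+2 columns.

    Taxon order must be (ingroup1, ingroup2, ingroup3, outgroup); split
    labels are relative to that order.  Results are ordered by position.
    """
    if alignment.n_taxa != 4:
        raise InputError(
            f"four-gamete scan requires exactly 4 taxa, got {alignment.n_taxa}"
        )
    sites = []
    s0, s1, s2, s3 = alignment.sequences
    for i in range(alignment.length):
        col = s0[i] + s1[i] + s2[i] + s3[i]
        split = _classify_column(col)
        if split is not None:
            sites.append(InformativeSite(position=i, split=split, alleles=tuple(col)))
    return sites


def incompatible(a: InformativeSite, b: InformativeSite) -> bool:
    """Four-gamete test on a pair of sites: True iff all four gametes occur.

    For 2+2 biallelic columns this is equivalent to the split labels
    differing, but the check enumerates gametes explicitly.
    """
    gametes = {(x, y) for x, y in zip(a.alleles, b.alleles)}
    return len(gametes) == 4


def representative_point(l: int, r: int) -> int:
    """Deterministic breakpoint position for the open interval (l, r).

    A breakpoint coordinate b means "between columns b-1 and b", so the
    feasible range for (l, r) is [l+1, r]; the midpoint of that range,
    rounded down, is returned.  Adjacent-column ties (l, l+1) yield l+1.
    """
    return (l + r + 1) // 2


def hudson_kaplan(sites: list[InformativeSite], segment_length: int) -> BreakpointSet:
    """Hudson–Kaplan minimal-interval localization of recombination events.

    Collects the open interval between every incompatible site pair, discards
    any interval that properly contains another, then greedily keeps
    non-overlapping survivors left to right.  The surviving intervals are the
    minimum-cardinality disjoint set such that every incompatible pair spans
    at least one of them; their count is Rmin.  For four taxa (where every
    informative site is 2+2) this reduces to the gaps between consecutive
    informative sites with different split labels.
    """
    positions = [s.position for s in sites]
    if positions != sorted(positions):
        raise InputError("informative sites must be ordered by position")

    # Minimal interval ending at each site: the nearest incompatible site to
    # its left.  Every incompatible pair (i, j) contains this interval for j,
    # so restricting to these candidates loses nothing.
    candidates: list[tuple[int, int]] = []
    for j in range(1, len(sites)):
        for i in range(j - 1, -1, -1):
            if incompatible(sites[i], sites[j]):
                candidates.append((sites[i].position, sites[j].position))
                break

    # Candidates arrive with strictly increasing right endpoints; an interval
    # is non-minimal iff it contains an earlier candidate, i.e. its left
    # endpoint does not advance past all previous lefts.
    minimal: list[tuple[int, int]] = []
    max_left = -1
    for l, r in candidates:
        if l > max_left:
            minimal.append((l, r))
            max_left = l

    # Greedy selection by right endpoint.  Open intervals (a, b) and (b, c)
    # are already disjoint in breakpoint space: feasible positions are
    # [a+1, b] and [b+1, c].
    chosen: list[tuple[int, int]] = []
    last_right = None
    for l, r in minimal:
        if last_right is None or l >= last_right:
            chosen.append((l, r))
            last_right = r

    by_pos = {s.position: s for s in sites}
    flanks = tuple((by_pos[l].split, by_pos[r].split) for l, r in chosen)
    return BreakpointSet(
        segment_length=segment_length,
        intervals=tuple(chosen),
        points=tuple(representative_point(l, r) for l, r in chosen),
        flank_splits=flanks,
    )


def write_breakpoints(bs: BreakpointSet, path, header_lines: tuple[str, ...] = ()) -> None:
    """Write a breakpoint set as TSV.

    Columns: interval_start, interval_end, point, left_split, right_split.
    A ``#L=<int>`` comment records the segment length for read-back.
    """
    from pathlib import Path

    lines = [f"# {h}" for h in header_lines]
    lines.append(f"#L={bs.segment_length}")
    lines.append("interval_start\tinterval_end\tpoint\tleft_split\tright_split")
    flanks = bs.flank_splits or tuple(("?", "?") for _ in bs.intervals)
    for (l, r), p, (ls, rs) in zip(bs.intervals, bs.points, flanks):
        lines.append(f"{l}\t{r}\t{p}\t{ls}\t{rs}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_breakpoints(path) -> BreakpointSet:
    """Read a breakpoint-set TSV written by :func:`write_breakpoints`."""
    from pathlib import Path

    L = None
    intervals, points, flanks = [], [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#L="):
            L = int(line[3:])
            continue
        if not line.strip() or line.startswith("#") or line.startswith("interval_start"):
            continue
        l, r, p, ls, rs = line.split("\t")
        intervals.append((int(l), int(r)))
        points.append(int(p))
        flanks.append((ls, rs))
    if L is None:
        raise InputError(f"breakpoint TSV {path} lacks the #L= segment-length header")
    return BreakpointSet(
        segment_length=L,
        intervals=tuple(intervals),
        points=tuple(points),
        flank_splits=tuple(flanks),
    )


def delimit_subclade(alignment: Alignment, spec: SubcladeSpec) -> BreakpointSet:
    """Full subclade pipeline: subset -> informative-site scan -> Hudson–Kaplan.

    Returns the breakpoint set for one 3-ingroup + outgroup subclade; the
    implied c-gene count is ``result.n_cgenes`` (= breakpoints + 1).
    """
    sub = subset(alignment, spec)
    sites = extract_informative_sites(sub)
    return hudson_kaplan(sites, alignment.length)
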