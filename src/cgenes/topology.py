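"""Composite genealogies and restricted Robinson–Foulds distances.

A species tree with k short internodes (trichotomies) admits 3^k composite
gene-tree topologies: each trichotomy resolves independently to one of three
pairs under incomplete lineage sorting, while the long backbone branches are
fixed.  Restricted RF distance between two such genealogies is the number of
trichotomies at which their resolutions differ — which equals half the
bipartition symmetric difference (RF distance in the halved convention)
between the fully resolved trees, since each differing trichotomy swaps
exactly one cherry bipartition.

Resolutions use the same labels as four-gamete splits: "T1T2" unites the
first two taxa of the trichotomy, etc.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import dendropy
import numpy as np

from .fourgamete import SPLITS
from .io_align import InputError
from .ratchet import CGeneMap

__all__ = [
    "Trichotomy",
    "SpeciesTreeSpec",
    "CompositeGenealogy",
    "AdjacencyProfile",
    "enumerate_genealogies",
    "rf_to_species",
    "rf_pairwise",
    "newick_for",
    "adjacency_profile",
    "random_genealogy",
    "mean_pairwise_rf",
    "expected_pairwise_rf",
    "ladder_spec",
]

_ENUM_GUARD = 12  # 3^12 ~ 5.3e5 genealogies; beyond that enumeration refuses


@dataclass(frozen=True)
class Trichotomy:
    """One short internode: three taxa and the species-tree resolution."""

    name: str
    taxa: tuple[str, str, str]
    species_pair: str  # which pair the species tree unites, in SPLITS

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != 3:
            raise InputError(f"trichotomy {self.name!r} needs 3 distinct taxa")
        if self.species_pair not in SPLITS:
            raise InputError(f"species_pair must be one of {SPLITS}")

    def pair_taxa(self, resolution: str) -> tuple[tuple[str, str], str]:
        """Return ((united pair), odd taxon) for a resolution label."""
        a, b, c = self.taxa
        if resolution == "T1T2":
            return (a, b), c
        if resolution == "T1T3":
            return (a, c), b
        if resolution == "T2T3":
            return (b, c), a
        raise InputError(f"unknown resolution {resolution!r}")


@dataclass(frozen=True)
class SpeciesTreeSpec:
    """Backbone Newick plus the k taxon-disjoint trichotomies embedded in it.

    In the backbone each trichotomy appears as an unresolved trifurcation of
    its three taxa; all other branches are taken as long (no ILS).
    """

    trichotomies: tuple[Trichotomy, ...]
    backbone: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tri in self.trichotomies:
            if seen & set(tri.taxa):
                raise InputError("trichotomies must be taxon-disjoint")
            seen.update(tri.taxa)

    @property
    def k(self) -> int:
        return len(self.trichotomies)

    @property
    def species_resolutions(self) -> tuple[str, ...]:
        return tuple(t.species_pair for t in self.trichotomies)


@dataclass(frozen=True)
class CompositeGenealogy:
    """One composite gene-tree topology: a resolution per trichotomy."""

    resolutions: tuple[str, ...]

    def __post_init__(self) -> None:
        for r in self.resolutions:
            if r not in SPLITS:
                raise InputError(f"unknown resolution {r!r}")

    @property
    def k(self) -> int:
        return len(self.resolutions)


def enumerate_genealogies(spec: SpeciesTreeSpec) -> list[CompositeGenealogy]:
    """All 3^k composite genealogies for a species tree with k trichotomies."""
    if spec.k > _ENUM_GUARD:
        raise InputError(
            f"refusing to enumerate 3^{spec.k} genealogies (guard: k <= {_ENUM_GUARD})"
        )
    return [
        CompositeGenealogy(resolutions=combo)
        for combo in product(SPLITS, repeat=spec.k)
    ]


def rf_to_species(g: CompositeGenealogy, spec: SpeciesTreeSpec) -> int:
    """Restricted RF distance from a composite genealogy to the species tree."""
    if g.k != spec.k:
        raise InputError(f"genealogy has {g.k} resolutions, species tree has {spec.k}")
    return sum(r != s for r, s in zip(g.resolutions, spec.species_resolutions))


def rf_pairwise(g1: CompositeGenealogy, g2: CompositeGenealogy) -> int:
    """Restricted RF distance between two composite genealogies."""
    if g1.k != g2.k:
        raise InputError("genealogies differ in number of trichotomies")
    return sum(a != b for a, b in zip(g1.resolutions, g2.resolutions))


def newick_for(g: CompositeGenealogy, spec: SpeciesTreeSpec) -> str:
    """Fully resolved Newick: backbone with each trichotomy resolved as in g."""
    if g.k != spec.k:
        raise InputError("genealogy/species-tree size mismatch")
    tree = dendropy.Tree.get(data=spec.backbone, schema="newick")
    for tri, resolution in zip(spec.trichotomies, g.resolutions):
        node = _find_trichotomy_node(tree, tri)
        (pa, pb), odd = tri.pair_taxa(resolution)
        children = {ch.taxon.label: ch for ch in node.child_nodes()}
        node.clear_child_nodes()
        cherry = node.new_child()
        cherry.add_child(children[pa])
        cherry.add_child(children[pb])
        node.add_child(children[odd])
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()


def _find_trichotomy_node(tree: dendropy.Tree, tri: Trichotomy):
    want = set(tri.taxa)
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 3 and all(ch.is_leaf() for ch in children):
            if {ch.taxon.label for ch in children} == want:
                return node
    raise InputError(
        f"backbone has no trifurcation of {sorted(want)} for trichotomy {tri.name!r}"
    )


@dataclass(frozen=True)
class AdjacencyProfile:
    """RF-to-species series along a c-gene map plus adjacency diagnostics.

    ``deltas[i]`` is |RF(c-gene i+1) - RF(c-gene i)|.  When every breakpoint
    flips exactly one trichotomy, all deltas are 0 or 1 (gene-tree
    autocorrelation along the chromosome); ``flagged`` lists adjacent pairs
    whose labels differ at >= 2 trichotomies — coincident (collapsed)
    breakpoints, where the delta may exceed 1.
    """

    rf_series: tuple[int, ...]
    deltas: tuple[int, ...]
    flagged: tuple[int, ...]  # indices i where c-genes i, i+1 differ at >= 2 trichotomies


def adjacency_profile(cgene_map: CGeneMap, spec: SpeciesTreeSpec) -> AdjacencyProfile:
    """Per-c-gene RF distances to the species tree and adjacent-pair deltas."""
    if cgene_map.labels is None:
        raise InputError("c-gene map must be labelled for an adjacency profile")
    genealogies = [CompositeGenealogy(resolutions=lab) for lab in cgene_map.labels]
    rf_series = tuple(rf_to_species(g, spec) for g in genealogies)
    deltas = tuple(
        abs(b - a) for a, b in zip(rf_series[:-1], rf_series[1:])
    )
    flagged = tuple(
        i
        for i, (g1, g2) in enumerate(zip(genealogies[:-1], genealogies[1:]))
        if rf_pairwise(g1, g2) >= 2
    )
    return AdjacencyProfile(rf_series=rf_series, deltas=deltas, flagged=flagged)


def random_genealogy(k: int, rng: np.random.Generator) -> CompositeGenealogy:
    """Composite genealogy with each resolution uniform over the 3 options."""
    idx = rng.integers(0, 3, size=k)
    return CompositeGenealogy(resolutions=tuple(SPLITS[i] for i in idx))


def expected_pairwise_rf(k: int) -> float:
    """Analytic mean restricted RF between two uniform-random genealogies: 2k/3."""
    return 2.0 * k / 3.0


def mean_pairwise_rf(
    k: int, n_pairs: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo mean pairwise restricted RF and its standard error.

    Two genealogies drawn independently and uniformly differ at each
    trichotomy with probability 2/3, so the mean is 2k/3 (~6 for k=9).
    """
    a = rng.integers(0, 3, size=(n_pairs, k))
    b = rng.integers(0, 3, size=(n_pairs, k))
    d = (a != b).sum(axis=1)
    return float(d.mean()), float(d.std(ddof=1) / np.sqrt(n_pairs))


def ladder_spec(k: int, species_pair: str = "T1T2") -> SpeciesTreeSpec:
    """Convenience species tree: k taxon-disjoint trichotomies on a ladder.

    Trichotomy i has taxa ``t{i}a, t{i}b, t{i}c`` and species resolution
    ``species_pair``; the backbone nests the trifurcations pectinately.
    """
    if k < 1:
        raise InputError("ladder_spec needs k >= 1")
    tris = tuple(
        Trichotomy(
            name=f"T{i + 1}",
            taxa=(f"t{i + 1}a", f"t{i + 1}b", f"t{i + 1}c"),
            species_pair=species_pair,
        )
        for i in range(k)
    )
    clause = "({0},{1},{2})"
    newick = clause.format(*tris[0].taxa)
    for tri in tris[1:]:
        newick = f"({clause.format(*tri.taxa)},{newick})"
    return SpeciesTreeSpec(trichotomies=tris, backbone=newick + ";")
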