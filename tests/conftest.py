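"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import dendropy
import pytest
from hypothesis import settings

from cgenes import Alignment, SubcladeSpec

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from cgenes.fourgamete import InformativeSite, incompatible


def alignment_from_columns(columns, taxa=("t1", "t2", "t3", "og")):
    """Build an Alignment from a list of column strings (one char per taxon)."""
    n = len(taxa)
    assert all(len(c) == n for c in columns)
    seqs = ["".join(col[i] for col in columns) for i in range(n)]
    return Alignment.from_pairs(zip(taxa, seqs))


_SPLIT_COLUMN = {
    "T1T2": "AACC",
    "T1T3": "ACAC",
    "T2T3": "CAAC",
}


def site_for(position, split):
    """An InformativeSite with a canonical 2+2 column for the given split."""
    return InformativeSite(position, split, tuple(_SPLIT_COLUMN[split]))


def brute_force_rmin(sites):
    """Independent minimum-recombination oracle by exhaustive search.

    Candidate breakpoint slots are the gaps between consecutive informative
    sites; a slot set is feasible if every incompatible site pair has at
    least one chosen slot strictly between its members.  Returns the minimum
    feasible slot count.  Exponential — use only on small instances.
    """
    n = len(sites)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if incompatible(sites[i], sites[j])
    ]
    if not pairs:
        return 0
    slots = list(range(n - 1))  # slot s sits between sites s and s+1
    for size in range(1, len(slots) + 1):
        for combo in combinations(slots, size):
            if all(any(i <= s < j for s in combo) for i, j in pairs):
                return size
    raise AssertionError("unreachable: all slots always feasible")


def clade_rf(newick1, newick2):
    """Independent RF/2 oracle: symmetric difference of rooted clade sets.

    Clades are leaf-label sets of internal nodes, excluding the root (full
    taxon set) and leaves.  Half the symmetric difference is the RF distance
    in the halved (Sul & Williams) convention.
    """

    def clades(newick):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        out = set()
        for node in tree.preorder_internal_node_iter():
            labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(labels) < len(leaves):
                out.add(labels)
        return out

    c1, c2 = clades(newick1), clades(newick2)
    diff = len(c1 ^ c2)
    assert diff % 2 == 0
    return diff // 2


@pytest.fixture
def hominid_like_alignment():
    """8-taxon alignment with two subclades, coordinates 0..11."""
    taxa = ("human", "chimp", "gorilla", "orang", "mac1", "mac2", "mac3", "papio")
    cols = [
        "AAAAAAAA",  # invariant
        "CCAAAAAA",  # informative for hominids (T1T2)
        "AAAAAAAA",
        "AACAAAAA",  # singleton
        "CACAAAAA",  # hominid T1T3
        "AAAACCAA",  # macaque T1T2
        "AAAAAAAA",
        "AAAACACA",  # macaque T1T3
        "AAAAAAAA",
        "GAAAAAAA",  # singleton
        "AAAAAAAA",
        "TTAAAAAA",  # hominid T1T2
    ]
    return alignment_from_columns(cols, taxa)


@pytest.fixture
def hominid_spec():
    return SubcladeSpec(
        name="hominids", ingroup=("human", "chimp", "gorilla"), outgroup="orang"
    )


@pytest.fixture
def macaque_spec():
    return SubcladeSpec(
        name="macaques", ingroup=("mac1", "mac2", "mac3"), outgroup="papio"
    )
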