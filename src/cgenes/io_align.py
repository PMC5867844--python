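"""Alignment and c-gene map I/O.

Reads and writes FASTA alignments, projects alignments onto small taxon
subsets without disturbing column coordinates, and serializes c-gene maps
as BED (0-based, half-open).  All downstream breakpoint arithmetic in this
package relies on the coordinate conventions fixed here: a breakpoint at
integer position ``b`` falls between alignment columns ``b - 1`` and ``b``,
with ``1 <= b <= L - 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "SubcladeSpec",
    "AlignmentError",
    "InputError",
    "read_fasta",
    "write_fasta",
    "subset",
    "write_cgene_map",
    "read_cgene_map",
    "load_subclade_specs",
]


class AlignmentError(ValueError):
    """Raised when sequences do not form a rectangular alignment."""


class InputError(ValueError):
    """Raised for malformed user input (labels, specs, configs)."""


# After normalization sequences contain only these characters.  Ambiguity
# codes (R, Y, S, W, ...) carry no unambiguous biallelic information for the
# four-gamete test and are collapsed to N; gaps are retained so that column
# coordinates stay stable.
_KEEP = set("ACGTN-")

_NORMALIZE = {}
for _c in "ACGTN-":
    _NORMALIZE[_c] = _c
_NORMALIZE["U"] = "T"


def _normalize_seq(raw: str) -> str:
    up = raw.upper()
    return "".join(_NORMALIZE.get(c, "N") for c in up)


@dataclass(frozen=True)
class Alignment:
    """A rectangular nucleotide alignment.

    ``taxa`` is an ordered tuple of unique labels; ``sequences`` holds one
    uppercase string per taxon in the same order.  The alphabet is
    {A, C, G, T, N, -}.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("duplicate taxon labels in alignment")
        if self.sequences:
            L = len(self.sequences[0])
            for t, s in zip(self.taxa, self.sequences):
                if len(s) != L:
                    raise AlignmentError(
                        f"sequence for {t!r} has length {len(s)}, expected {L}"
                    )
                bad = set(s) - _KEEP
                if bad:
                    raise AlignmentError(
                        f"sequence for {t!r} contains unexpected characters {sorted(bad)}"
                    )

    @property
    def length(self) -> int:
        """Number of columns (bp)."""
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence_of(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise InputError(f"taxon {taxon!r} not in alignment") from None

    def column(self, i: int) -> str:
        """Return column ``i`` as a string, one character per taxon."""
        return "".join(s[i] for s in self.sequences)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        taxa, seqs = [], []
        for name, seq in pairs:
            taxa.append(name)
            seqs.append(_normalize_seq(seq))
        return cls(tuple(taxa), tuple(seqs))


@dataclass(frozen=True)
class SubcladeSpec:
    """Three ingroup taxa plus one outgroup, the unit the four-gamete test
    operates on."""

    name: str
    ingroup: tuple[str, str, str]
    outgroup: str

    def __post_init__(self) -> None:
        labels = (*self.ingroup, self.outgroup)
        if len(self.ingroup) != 3:
            raise InputError("subclade ingroup must name exactly 3 taxa")
        if len(set(labels)) != 4:
            raise InputError("subclade taxa must be 4 distinct labels")

    @property
    def taxa(self) -> tuple[str, str, str, str]:
        return (*self.ingroup, self.outgroup)


def read_fasta(path: str | Path) -> Alignment:
    """Read a FASTA alignment, normalizing case, U->T and ambiguity->N."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment.from_pairs((r.id, str(r.seq)) for r in records)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="")
        for t, s in zip(alignment.taxa, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def subset(alignment: Alignment, spec: SubcladeSpec) -> Alignment:
    """Project an alignment onto a subclade's 4 taxa.

    Column coordinates are preserved: no column is dropped, so site ``i``
    in the result refers to site ``i`` in the parent alignment.  The result
    orders taxa (ingroup1, ingroup2, ingroup3, outgroup).
    """
    missing = [t for t in spec.taxa if t not in alignment.taxa]
    if missing:
        raise InputError(f"subclade {spec.name!r} names absent taxa: {missing}")
    return Alignment(
        taxa=spec.taxa,
        sequences=tuple(alignment.sequence_of(t) for t in spec.taxa),
    )


def write_cgene_map(cgene_map, path: str | Path, segment_name: str = "segment") -> None:
    """Write a c-gene map as BED: 0-based, half-open intervals tiling [0, L).

    Columns: segment name, start, end, composite-topology label (``.`` when
    the map is unlabelled).
    """
    lines = []
    labels = cgene_map.labels
    for i, (start, end) in enumerate(cgene_map.cgenes):
        if labels is None:
            label = "."
        else:
            label = "|".join(labels[i])
        lines.append(f"{segment_name}\t{start}\t{end}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cgene_map(path: str | Path):
    """Read back a BED c-gene map written by :func:`write_cgene_map`."""
    from .ratchet import CGeneMap  # local import: io <-> ratchet layering

    breakpoints: list[int] = []
    labels: list[tuple[str, ...]] = []
    end = 0
    expected_start = 0
    any_label = False
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        start, end = int(fields[1]), int(fields[2])
        if start != expected_start:
            raise InputError(f"BED intervals do not tile: gap/overlap at {start}")
        if start > 0:
            breakpoints.append(start)
        lab = fields[3] if len(fields) > 3 else "."
        if lab != ".":
            any_label = True
            labels.append(tuple(lab.split("|")))
        else:
            labels.append(())
        expected_start = end
    return CGeneMap(
        segment_length=end,
        breakpoints=tuple(breakpoints),
        labels=tuple(labels) if any_label else None,
    )


def load_subclade_specs(path: str | Path) -> list[SubcladeSpec]:
    """Load subclade definitions from YAML or JSON.

    Accepts either a single mapping or a list of mappings with keys
    ``name``, ``ingroup`` (3 labels) and ``outgroup``.
    """
    import yaml

    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if isinstance(data, dict) and "subclades" in data:
        data = data["subclades"]
    if isinstance(data, dict):
        data = [data]
    specs = []
    for entry in data:
        specs.append(
            SubcladeSpec(
                name=str(entry["name"]),
                ingroup=tuple(entry["ingroup"]),
                outgroup=str(entry["outgroup"]),
            )
        )
    return specs
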