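"""Reading and validating aligned FASTA matrices, newick trees and species maps.

All sequences are normalised on input: upper-cased, ``U`` → ``T`` (RNA to
DNA), ``?`` → ``N`` and ``.`` → ``-``.  Region coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Region tags recognised for a sub-alignment of the fungal barcode.
REGIONS = ("nrITS", "ITS1", "5.8S", "ITS2", "custom")

_NORMALISE = str.maketrans({"U": "T", "?": "N", ".": "-"})

#: IUPAC nucleotide codes plus gap, after normalisation.
VALID_CHARS = frozenset("ACGTNRYSWKMBDHV-")


class AlignmentError(ValueError):
    """Raised when an input alignment violates the matrix invariants."""


class PartitionError(ValueError):
    """Raised when a species map does not cover the alignment."""


class TreeError(ValueError):
    """Raised for unusable newick input (parse failure, duplicate tips,
    missing branch lengths)."""


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map U→T, ?→N, .→- ."""
    return seq.upper().translate(_NORMALISE)


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An aligned matrix of named nucleotide sequences for one dataset/region.

    Parameters
    ----------
    dataset_name : str
        Free-text dataset label (typically a genus).
    region : str
        One of ``nrITS``, ``ITS1``, ``5.8S``, ``ITS2`` or ``custom``.
    ids : tuple of str
        Unique sequence identifiers, in matrix order.
    rows : tuple of str
        Aligned, normalised nucleotide strings; all the same length.
    """

    dataset_name: str
    region: str
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError(
                f"{len(self.ids)} ids but {len(self.rows)} rows in "
                f"{self.dataset_name!r}"
            )
        if not self.ids:
            raise AlignmentError(f"empty alignment in {self.dataset_name!r}")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise AlignmentError(f"duplicate sequence id {dup!r}")
        width = len(self.rows[0])
        if width < 1:
            raise AlignmentError("alignment must have at least one column")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(row)}, expected {width}"
                )
            bad = set(row) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str]],
        dataset_name: str = "dataset",
        region: str = "custom",
    ) -> "AlignedSequenceSet":
        """Build a set from ``(id, sequence)`` pairs, normalising each row."""
        ids, rows = [], []
        for sid, seq in records:
            ids.append(sid)
            rows.append(normalize_sequence(seq))
        return cls(dataset_name, region, tuple(ids), tuple(rows))


@dataclass(frozen=True)
class SpeciesPartition:
    """A mapping from sequence id to species label.

    Alternative partitions of the same sequences (e.g. "lumping" vs
    "splitting" hypotheses) are simply differently named instances.
    """

    name: str
    assignments: Mapping[str, str]

    @property
    def species(self) -> tuple[str, ...]:
        """Distinct species labels, sorted."""
        return tuple(sorted(set(self.assignments.values())))

    @property
    def n_species(self) -> int:
        return len(set(self.assignments.values()))

    def label(self, seq_id: str) -> str:
        return self.assignments[seq_id]

    def members(self) -> dict[str, list[str]]:
        """Species label → list of member sequence ids."""
        out: dict[str, list[str]] = {}
        for sid, sp in self.assignments.items():
            out.setdefault(sp, []).append(sid)
        return out

    def validate_against(self, alignment: AlignedSequenceSet) -> None:
        missing = [i for i in alignment.ids if i not in self.assignments]
        if missing:
            raise PartitionError(
                f"partition {self.name!r} is missing labels for ids: "
                + ", ".join(missing)
            )


@dataclass(frozen=True)
class RegionCoordinates:
    """0-based half-open column intervals for ITS1, 5.8S and ITS2.

    Intervals must be non-overlapping, in 5'→3' order (ITS1, 5.8S, ITS2)
    and within the alignment width when applied.
    """

    its1: tuple[int, int]
    r58s: tuple[int, int]
    its2: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid interval for {name}: [{lo}, {hi})")
        if not (self.its1[1] <= self.r58s[0] and self.r58s[1] <= self.its2[0]):
            raise ValueError(
                "regions must be ordered and non-overlapping: ITS1 < 5.8S < ITS2"
            )

    def items(self) -> Sequence[tuple[str, tuple[int, int]]]:
        return (("ITS1", self.its1), ("5.8S", self.r58s), ("ITS2", self.its2))

    def interval(self, which: str) -> tuple[int, int]:
        try:
            return dict(self.items())[which]
        except KeyError:
            raise ValueError(f"unknown region {which!r}") from None


def read_alignment(
    path: str | Path, dataset_name: str | None = None, region: str = "nrITS"
) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA file into an :class:`AlignedSequenceSet`.

    Sequences are normalised (upper case, U→T, ?→N, .→-).  Raises
    :class:`AlignmentError` on ragged rows, duplicate ids or an empty file.
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    name = dataset_name if dataset_name is not None else path.stem
    return AlignedSequenceSet.from_records(records, dataset_name=name, region=region)


def write_alignment(alignment: AlignedSequenceSet, path: str | Path) -> None:
    """Write an alignment back out as multi-FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


def read_partition(
    path: str | Path,
    alignment: AlignedSequenceSet,
    name: str = "default",
    delimiter: str = "\t",
) -> SpeciesPartition:
    """Read a two-column ``id<TAB>species`` map covering *alignment*.

    Lines starting with ``#`` and blank lines are ignored.  Map entries for
    ids absent from the alignment are dropped with a warning; alignment ids
    without a label raise :class:`PartitionError`.
    """
    path = Path(path)
    raw: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise PartitionError(
                    f"{path}:{lineno}: expected two {delimiter!r}-separated fields"
                )
            raw[parts[0].strip()] = parts[1].strip()
    id_set = set(alignment.ids)
    extra = sorted(set(raw) - id_set)
    if extra:
        logger.warning(
            "species map %s: ignoring %d entries not in alignment (e.g. %s)",
            path, len(extra), extra[:3],
        )
    assignments = {i: raw[i] for i in alignment.ids if i in raw}
    partition = SpeciesPartition(name=name, assignments=assignments)
    partition.validate_against(alignment)
    return partition


def partition_from_headers(
    alignment: AlignedSequenceSet,
    delimiter: str = "|",
    field_index: int = 0,
    name: str = "header",
) -> SpeciesPartition:
    """Derive species labels from sequence headers.

    Splits each id on *delimiter* and takes field *field_index*, e.g.
    ``Russula_magnarosea|XYZ123`` with ``|``/0 → ``Russula_magnarosea``.
    """
    assignments = {}
    for sid in alignment.ids:
        parts = sid.split(delimiter)
        if field_index >= len(parts):
            raise PartitionError(
                f"id {sid!r} has no field {field_index} when split on {delimiter!r}"
            )
        assignments[sid] = parts[field_index]
    return SpeciesPartition(name=name, assignments=assignments)


def read_tree(
    path_or_string: str | Path, assume_unit_lengths: bool = False
) -> dendropy.Tree:
    """Read a newick tree with branch lengths.

    Branch lengths are required (they are the substance of patristic
    distances); pass ``assume_unit_lengths=True`` to substitute 1.0 on every
    edge for topology-only exploration.  Raises :class:`TreeError` on parse
    failure, duplicate tip labels, negative or missing lengths.
    """
    src = str(path_or_string)
    try:
        # preserve_underscores: unquoted labels keep their underscores so tip
        # labels match FASTA ids verbatim
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(
                data=src, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=src, schema="newick", preserve_underscores=True
            )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse newick input: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dup}")

    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge may legitimately carry no length
        if edge.length is None:
            if assume_unit_lengths:
                edge.length = 1.0
            else:
                raise TreeError(
                    "newick edge without a branch length; lengths are required "
                    "for patristic distances (or pass assume_unit_lengths=True)"
                )
        elif edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    return tree


def slice_region(
    alignment: AlignedSequenceSet, coords: RegionCoordinates, which: str
) -> AlignedSequenceSet:
    """Extract the columns of one region as a new sub-alignment."""
    lo, hi = coords.interval(which)
    if hi > alignment.width:
        raise ValueError(
            f"{which} interval [{lo}, {hi}) exceeds alignment width "
            f"{alignment.width}"
        )
    return AlignedSequenceSet(
        dataset_name=alignment.dataset_name,
        region=which if which in REGIONS else "custom",
        ids=alignment.ids,
        rows=tuple(row[lo:hi] for row in alignment.rows),
    )
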