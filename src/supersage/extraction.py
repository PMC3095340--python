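"""Ditag parsing, filtering and tag extraction.

Raw 454-style reads carry one ditag each: two 26-nt CATG-anchored tags
ligated tail-to-tail, flanked by 8-nt library-identification linkers.
Extraction applies three filters before counting:

1. *incomplete* reads (truncated, or an interior that does not parse into
   two valid tags),
2. *twin ditags* (PCR duplicates: the same ditag, in either orientation,
   seen more than once within a library),
3. reads *without complete library-identification linkers* (a corrupted
   linker fails exact matching and the read cannot be demultiplexed).

Every read ends up either as a retained :class:`Ditag` (contributing
exactly two tags) or as a :class:`RejectionRecord` with one reason, so
``reads == retained + rejections`` holds exactly on every run.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

from Bio import SeqIO

from ._util import ANCHOR, DITAG_LENGTH, TAG_LENGTH, revcomp

#: Library-identification linkers, ``library -> (left, right)``.
#: Fixed 8-nt constants (free of CATG) written into every well-formed
#: simulated read; demultiplexing matches them exactly.
LINKERS: dict[str, tuple[str, str]] = {
    "W": ("TGGCAAGT", "AGGTCTTC"),
    "F": ("CCTAGTAC", "GTCTTGAA"),
}

_READ_ALPHABET = frozenset("ACGTN")
_TAG_ALPHABET = frozenset("ACGT")


class RejectReason(str, enum.Enum):
    INCOMPLETE = "incomplete"
    MISSING_LINKER = "missing_linker"
    TWIN_DITAG = "twin_ditag"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SequencingRead:
    """One raw read; bases restricted to A/C/G/T/N."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r} has no bases")
        bad = set(self.bases) - _READ_ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r} has invalid bases {sorted(bad)}")


@dataclass(frozen=True)
class Tag:
    """A 26-nt SuperSAGE tag starting with the CATG anchor."""

    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != TAG_LENGTH:
            raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(self.sequence)}")
        if not self.sequence.startswith(ANCHOR):
            raise ValueError(f"tag must start with {ANCHOR}: {self.sequence}")
        bad = set(self.sequence) - _TAG_ALPHABET
        if bad:
            raise ValueError(f"tag has invalid bases {sorted(bad)}")


@dataclass(frozen=True)
class Ditag:
    """Two tags from one read, with an orientation-independent key."""

    read_id: str
    library: str
    tag_a: Tag
    tag_b: Tag
    canonical_key: str = field(init=False)

    def __post_init__(self) -> None:
        interior = self.tag_a.sequence + revcomp(self.tag_b.sequence)
        object.__setattr__(
            self, "canonical_key", min(interior, revcomp(interior))
        )


@dataclass(frozen=True)
class RejectionRecord:
    read_id: str
    reason: RejectReason


class SplitError(ValueError):
    """The between-linker interior does not parse into two valid tags."""


_FORMAT_BY_SUFFIX = {
    ".fa": "fasta",
    ".fasta": "fasta",
    ".fna": "fasta",
    ".fq": "fastq",
    ".fastq": "fastq",
}


def parse_reads(
    source: Union[str, Path], fmt: str | None = None
) -> Iterator[SequencingRead]:
    """Parse a FASTA/FASTQ file into :class:`SequencingRead` records.

    The format is inferred from the file suffix unless ``fmt`` is given.
    A malformed record raises :class:`ValueError` naming its index.
    """
    path = Path(source)
    if fmt is None:
        try:
            fmt = _FORMAT_BY_SUFFIX[path.suffix.lower()]
        except KeyError:
            raise ValueError(
                f"cannot infer read format from suffix {path.suffix!r}; pass fmt="
            ) from None
    records = SeqIO.parse(str(path), fmt)
    index = 0
    while True:
        try:
            rec = next(records)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed {fmt} record at index {index}: {exc}") from exc
        yield SequencingRead(rec.id, str(rec.seq).upper())
        index += 1


def split_ditag(interior: str) -> tuple[Tag, Tag]:
    """Split a 52-nt ditag interior into its two tags.

    The interior is ``tag_a + revcomp(tag_b)``; both tags must be valid
    (26 nt, CATG-anchored, no N). Raises :class:`SplitError` otherwise.
    """
    if len(interior) != DITAG_LENGTH:
        raise SplitError(
            f"ditag interior must be {DITAG_LENGTH} nt, got {len(interior)}"
        )
    try:
        tag_a = Tag(interior[:TAG_LENGTH])
        tag_b = Tag(revcomp(interior[TAG_LENGTH:]))
    except ValueError as exc:
        raise SplitError(str(exc)) from exc
    return tag_a, tag_b


def locate_ditag(
    read: SequencingRead,
    linker_catalog: Mapping[str, tuple[str, str]] = LINKERS,
) -> Union[Ditag, RejectionRecord]:
    """Demultiplex one read and parse its ditag.

    Returns a :class:`Ditag` when both library linkers are intact and the
    interior parses into two valid tags; otherwise a rejection with reason
    ``incomplete`` (too short / unparseable interior) or ``missing_linker``
    (either linker absent or corrupt). Linker matching is exact.
    """
    expected_len = {
        lib: len(left) + DITAG_LENGTH + len(right)
        for lib, (left, right) in linker_catalog.items()
    }
    if len(read.bases) < min(expected_len.values()):
        return RejectionRecord(read.id, RejectReason.INCOMPLETE)
    for lib, (left, right) in linker_catalog.items():
        if not read.bases.startswith(left):
            continue
        if len(read.bases) != expected_len[lib] or not read.bases.endswith(right):
            return RejectionRecord(read.id, RejectReason.MISSING_LINKER)
        interior = read.bases[len(left) : len(read.bases) - len(right)]
        try:
            tag_a, tag_b = split_ditag(interior)
        except SplitError:
            return RejectionRecord(read.id, RejectReason.INCOMPLETE)
        return Ditag(read.id, lib, tag_a, tag_b)
    return RejectionRecord(read.id, RejectReason.MISSING_LINKER)


def deduplicate_twin_ditags(
    ditags: Iterable[Ditag],
) -> tuple[list[Ditag], list[RejectionRecord]]:
    """Collapse PCR duplicates within each library.

    Ditags sharing a canonical key (identical interior in either
    orientation) within one library are collapsed to their first
    occurrence; every removed copy yields a ``twin_ditag`` rejection.
    Idempotent: a second application changes nothing.
    """
    seen: set[tuple[str, str]] = set()
    retained: list[Ditag] = []
    rejections: list[RejectionRecord] = []
    for ditag in ditags:
        key = (ditag.library, ditag.canonical_key)
        if key in seen:
            rejections.append(RejectionRecord(ditag.read_id, RejectReason.TWIN_DITAG))
        else:
            seen.add(key)
            retained.append(ditag)
    return retained, rejections


@dataclass
class ExtractionResult:
    """Per-library tags plus full accounting of every input read."""

    tags: dict[str, list[Tag]]
    ditags: dict[str, list[Ditag]]
    rejections: list[RejectionRecord]
    n_reads: int

    @property
    def n_retained(self) -> int:
        return sum(len(d) for d in self.ditags.values())

    def rejection_counts(self) -> dict[str, int]:
        counts = {reason.value: 0 for reason in RejectReason}
        for rec in self.rejections:
            counts[rec.reason.value] += 1
        return counts


def extract_tags(
    reads: Iterable[SequencingRead],
    linker_catalog: Mapping[str, tuple[str, str]] = LINKERS,
) -> ExtractionResult:
    """Run the full extraction pipeline over a mixed read stream.

    Composition of :func:`locate_ditag` (demultiplex + parse) and
    :func:`deduplicate_twin_ditags`; each retained ditag contributes its
    two tags to its library's multiset.
    """
    ditags: list[Ditag] = []
    rejections: list[RejectionRecord] = []
    n_reads = 0
    for read in reads:
        n_reads += 1
        result = locate_ditag(read, linker_catalog)
        if isinstance(result, Ditag):
            ditags.append(result)
        else:
            rejections.append(result)
    retained, twin_rejections = deduplicate_twin_ditags(ditags)
    rejections.extend(twin_rejections)
    by_library: dict[str, list[Ditag]] = {lib: [] for lib in linker_catalog}
    for ditag in retained:
        by_library[ditag.library].append(ditag)
    tags = {
        lib: [t for d in dlist for t in (d.tag_a, d.tag_b)]
        for lib, dlist in by_library.items()
    }
    return ExtractionResult(tags, by_library, rejections, n_reads)


def tags_to_tsv(result: ExtractionResult, path: Union[str, Path]) -> None:
    """Write extracted tags as TSV (library, tag, read_id)."""
    with open(path, "w") as handle:
        handle.write("library\ttag\tread_id\n")
        for lib, dlist in result.ditags.items():
            for ditag in dlist:
                for tag in (ditag.tag_a, ditag.tag_b):
                    handle.write(f"{lib}\t{tag.sequence}\t{ditag.read_id}\n")


def rejections_to_tsv(
    rejections: Sequence[RejectionRecord], path: Union[str, Path]
) -> None:
    """Write the rejection log as TSV (read_id, reason)."""
    with open(path, "w") as handle:
        handle.write("read_id\treason\n")
        for rec in rejections:
            handle.write(f"{rec.read_id}\t{rec.reason.value}\n")
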