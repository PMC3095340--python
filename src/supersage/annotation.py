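"""Mismatch-tolerant annotation of 26-nt tags against a reference set.

Each tag is compared ungapped and full-length against every 26-nt window
of every reference sequence on both strands; the best hit is the one with
the fewest mismatches, and all co-optimal hits are reported. Hits are
tiered by the number of matching positions out of 26: 26/26 (perfect)
down to 23/26 (three mismatches), with four to six mismatches reported
as *extended* matches. Reverse-strand hits carry the prefix ``minus`` on
the reference identifier. A minimum-match rule discards weak hits; two
readings are supported:

* ``"total"`` (default): at least 20 of the 26 aligned positions match,
  i.e. at most 6 mismatches;
* ``"contiguous"``: the longest contiguous run of exactly matching
  positions spans at least 20 nt.

The scan is exact (no heuristics): windows are packed 4 bits per base
into two 64-bit words and mismatches counted via XOR/popcount, so a full
scan of all windows and both strands is a few vector operations per tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import TAG_LENGTH, revcomp
from .extraction import Tag

TIERS = ("26/26", "25/26", "24/26", "23/26")
EXTENDED = "extended"
NO_HIT = "no_hit"

_CODE = np.zeros(256, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = 1 << i  # unknown bases code to 0: mismatch vs everything


def tier_of(mismatches: int) -> str:
    """Tier label for a mismatch count (0-6)."""
    if not 0 <= mismatches <= 6:
        raise ValueError(f"mismatch count {mismatches} outside 0-6")
    if mismatches <= 3:
        return TIERS[mismatches]
    return EXTENDED


@dataclass(frozen=True)
class AnnotationHit:
    """One best match of a tag in the reference set.

    ``ref_id`` carries the prefix ``minus`` for reverse-strand hits;
    ``offset`` is the 0-based start of the matched window on the forward
    strand of the reference; ``matched_length`` counts matching positions
    (26 - mismatches).
    """

    tag: str
    ref_id: str
    offset: int
    mismatches: int
    matched_length: int
    tier: str
    strand: str


@dataclass
class ReferenceSet:
    """Reference sequences plus optional per-reference labels."""

    records: dict[str, str]
    categories: dict[str, str] | None = None
    regulatory: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        for ref_id, seq in self.records.items():
            if not seq:
                raise ValueError(f"reference {ref_id!r} has an empty sequence")

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "ReferenceSet":
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate reference id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
        return cls(records)

    def load_labels(self, path: Union[str, Path]) -> None:
        """Load a label TSV with columns ref_id, category[, regulatory_flag]."""
        df = pd.read_csv(path, sep="\t")
        self.categories = dict(zip(df["ref_id"], df["category"]))
        if "regulatory_flag" in df.columns:
            self.regulatory = {
                r: bool(f) for r, f in zip(df["ref_id"], df["regulatory_flag"])
            }


def _pack_words(codes: np.ndarray) -> np.ndarray:
    """Pack rows of 26 4-bit base codes into two uint64 words per row."""
    codes = codes.astype(np.uint64)
    shifts_a = np.arange(16, dtype=np.uint64) * np.uint64(4)
    shifts_b = np.arange(TAG_LENGTH - 16, dtype=np.uint64) * np.uint64(4)
    word_a = (codes[:, :16] << shifts_a).sum(axis=1, dtype=np.uint64)
    word_b = (codes[:, 16:] << shifts_b).sum(axis=1, dtype=np.uint64)
    return np.stack([word_a, word_b], axis=1)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class _WindowIndex:
    """All 26-nt windows of a reference set, both strands, bit-packed."""

    def __init__(self, refs: ReferenceSet):
        words, ref_ids, offsets, strands = [], [], [], []
        self.ref_order = list(refs.records)
        for ref_id, seq in refs.records.items():
            if len(seq) < TAG_LENGTH:
                continue
            n_win = len(seq) - TAG_LENGTH + 1
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                codes = _encode(s)
                windows = np.lib.stride_tricks.sliding_window_view(codes, TAG_LENGTH)
                words.append(_pack_words(windows))
                ref_ids.extend([ref_id] * n_win)
                if strand == "+":
                    offsets.extend(range(n_win))
                else:
                    # window i on the reverse strand covers forward
                    # positions [n_win - 1 - i, ... + 26)
                    offsets.extend(range(n_win - 1, -1, -1))
                strands.extend([strand] * n_win)
        if words:
            self.words = np.concatenate(words, axis=0)
        else:
            self.words = np.empty((0, 2), dtype=np.uint64)
        self.ref_ids = np.array(ref_ids)
        self.offsets = np.array(offsets, dtype=int)
        self.strands = np.array(strands)

    def mismatches(self, tag: str) -> np.ndarray:
        tag_words = _pack_words(_encode(tag)[None, :])[0]
        diff = self.words ^ tag_words
        return (
            np.bitwise_count(diff[:, 0]) + np.bitwise_count(diff[:, 1])
        ) // 2


def _longest_match_run(tag: str, window: str) -> int:
    best = run = 0
    for a, b in zip(tag, window):
        if a == b:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def _window_sequence(refs: ReferenceSet, ref_id: str, offset: int, strand: str) -> str:
    forward = refs.records[ref_id][offset : offset + TAG_LENGTH]
    return forward if strand == "+" else revcomp(forward)


def match_tag(
    tag: Union[Tag, str],
    refs: ReferenceSet,
    max_mismatch: int = 3,
    min_match_mode: str = "total",
    min_match: int = 20,
    _index: "_WindowIndex | None" = None,
) -> list[AnnotationHit]:
    """Best hits of one tag in the reference set (possibly none).

    All co-optimal windows (minimum mismatches across every window of
    every reference, both strands) are returned, in reference input
    order; an empty list means no hit under ``max_mismatch`` and the
    minimum-match rule.
    """
    tag_seq = tag.sequence if isinstance(tag, Tag) else str(tag)
    if len(tag_seq) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} nt")
    index = _index if _index is not None else _WindowIndex(refs)
    if len(index.words) == 0:
        return []
    mm = index.mismatches(tag_seq)
    best = int(mm.min())
    if best > max_mismatch:
        return []
    candidates = np.flatnonzero(mm == best)
    hits: list[AnnotationHit] = []
    order = {ref_id: k for k, ref_id in enumerate(index.ref_order)}
    candidates = sorted(
        candidates,
        key=lambda i: (order[index.ref_ids[i]], index.strands[i], index.offsets[i]),
    )
    for i in candidates:
        ref_id = str(index.ref_ids[i])
        strand = str(index.strands[i])
        offset = int(index.offsets[i])
        if min_match_mode == "total":
            if TAG_LENGTH - best < min_match:
                continue
        elif min_match_mode == "contiguous":
            window = _window_sequence(refs, ref_id, offset, strand)
            if _longest_match_run(tag_seq, window) < min_match:
                continue
        else:
            raise ValueError(f"unknown min_match_mode {min_match_mode!r}")
        hits.append(
            AnnotationHit(
                tag=tag_seq,
                ref_id=("minus" + ref_id) if strand == "-" else ref_id,
                offset=offset,
                mismatches=best,
                matched_length=TAG_LENGTH - best,
                tier=tier_of(best),
                strand=strand,
            )
        )
    return hits


def annotate_table(
    table: pd.DataFrame,
    refs: ReferenceSet,
    max_mismatch: int = 3,
    min_match_mode: str = "total",
    min_match: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate every UniTag of a count table against the reference set.

    Returns ``(annotation, summary)``. The annotation table has one row
    per UniTag with co-optimal reference ids joined by ``" or "`` (empty
    and tier ``no_hit`` when nothing matched). The summary counts
    annotated tags per tier — split by reference category when labels
    are attached to ``refs`` — mirroring the tier-table layout of
    SAGE annotation reports.
    """
    if "status" in table.columns:
        tags = table.index[table["status"] == "unitag"]
    else:
        tags = table.index
    index = _WindowIndex(refs)
    rows = []
    for tag in tags:
        hits = match_tag(
            tag,
            refs,
            max_mismatch=max_mismatch,
            min_match_mode=min_match_mode,
            min_match=min_match,
            _index=index,
        )
        if hits:
            rows.append(
                {
                    "tag": tag,
                    "ref_ids": " or ".join(h.ref_id for h in hits),
                    "strand": "/".join(dict.fromkeys(h.strand for h in hits)),
                    "mismatches": hits[0].mismatches,
                    "tier": hits[0].tier,
                }
            )
        else:
            rows.append(
                {
                    "tag": tag,
                    "ref_ids": "",
                    "strand": "",
                    "mismatches": -1,
                    "tier": NO_HIT,
                }
            )
    annotation = pd.DataFrame(
        rows, columns=["tag", "ref_ids", "strand", "mismatches", "tier"]
    )
    summary = _tier_summary(annotation, refs)
    return annotation, summary


def _primary_ref(ref_ids: str) -> str:
    first = ref_ids.split(" or ")[0]
    return first[5:] if first.startswith("minus") else first


def _tier_summary(annotation: pd.DataFrame, refs: ReferenceSet) -> pd.DataFrame:
    tier_cols = list(TIERS) + [EXTENDED]
    annotated = annotation[annotation["tier"] != NO_HIT]
    if refs.categories:
        categories = sorted(set(refs.categories.values()))
        summary = pd.DataFrame(
            0, index=pd.Index(categories + ["total"], name="category"),
            columns=tier_cols + ["total"],
        )
        for _, row in annotated.iterrows():
            cat = refs.categories.get(_primary_ref(row["ref_ids"]), "total")
            if cat not in summary.index:
                cat = "total"
            summary.loc[cat, row["tier"]] += 1
        summary.loc["total"] = summary.drop(index="total").sum() + summary.loc["total"]
    else:
        summary = pd.DataFrame(
            0, index=pd.Index(["total"], name="category"),
            columns=tier_cols + ["total"],
        )
        for tier, count in annotated["tier"].value_counts().items():
            summary.loc["total", tier] = int(count)
    summary["total"] = summary[tier_cols].sum(axis=1)
    summary.loc["no_hit_tags"] = 0
    summary.loc["no_hit_tags", "total"] = int((annotation["tier"] == NO_HIT).sum())
    return summary


def regulatory_flags(
    annotation: pd.DataFrame, refs: ReferenceSet
) -> dict[str, bool]:
    """Per-tag regulatory yes/no derived from reference labels."""
    flags: dict[str, bool] = {}
    reg = refs.regulatory or {}
    for _, row in annotation.iterrows():
        if row["tier"] == NO_HIT:
            flags[row["tag"]] = False
        else:
            flags[row["tag"]] = bool(reg.get(_primary_ref(row["ref_ids"]), False))
    return flags


def write_annotation(annotation: pd.DataFrame, path: Union[str, Path]) -> None:
    annotation.to_csv(path, sep="\t", index=False)
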