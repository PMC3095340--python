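"""Ground-truth simulator for SuperSAGE libraries.

Generates a reference transcriptome, per-transcript expected abundances
for two libraries — W (wounded) and F (FAC-elicited) — and linker-flanked
ditag reads, while retaining the truth table needed to score every
downstream stage (extraction conservation, differential-expression
recovery, annotation).

The defaults emulate the study conditions of the original two-library
experiment: library depths of 227,536 (W) and 127,394 (F) tags, a
long-tailed abundance distribution in which ~88% of transcripts are
low-abundant (≤ 100 copies per million) yet the two most abundant classes
carry ~47% of all tag copies, and a differentially expressed subset
(~4% of transcripts, mostly up-regulated) with fold changes spanning
0.09–70.

Read architecture (a documented stand-in — the original read layout is
not public): ``left_linker(8) + tag_a(26) + revcomp(tag_b)(26) +
right_linker(8)``, with linkers from :data:`supersage.extraction.LINKERS`
encoding the library. Artifacts injected at configurable rates: twin
ditags (PCR duplicates), incomplete reads (uniform right-truncation below
full length), and uniform per-base substitution errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import ANCHOR, TAG_LENGTH, revcomp
from .extraction import LINKERS, SequencingRead

#: Abundance classes (copies per million), low → very high.
CLASS_LABELS = ("low", "mid", "high", "very_high")
#: Sampling bounds per class on the copies-per-million scale. The lower
#: bound of each non-low class sits just above the class boundary so that
#: clamped draws stay inside the class; the very-high ceiling (50,000 cpm
#: = 5% of a library) is a generous cap for the most abundant transcript.
CLASS_BOUNDS = (
    (1.0, 100.0),
    (100.0 * (1 + 1e-9), 1000.0),
    (1000.0 * (1 + 1e-9), 5000.0),
    (5000.0 * (1 + 1e-9), 50000.0),
)
#: Default transcript-share mixture across classes (low/mid/high/very-high).
DEFAULT_MIXTURE = (0.884, 0.102, 0.012, 0.002)
#: Default share of total tag copies carried by each class.
DEFAULT_COPY_SHARES = (0.198, 0.332, 0.236, 0.234)
#: Mixture for desk-scale runs (~1,000 transcripts). The full-scale
#: mixture is tied to ~12,000 transcripts: with far fewer transcripts the
#: average transcript must be more abundant for the library to sum to
#: 10^6 copies per million, so the mixture shifts toward the upper
#: classes while keeping the long-tailed shape.
DESK_SCALE_MIXTURE = (0.60, 0.30, 0.08, 0.02)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_READ_LENGTH = 8 + 2 * TAG_LENGTH + 8


@dataclass(frozen=True)
class ReferenceTranscript:
    """A synthetic reference transcript with a well-formed 3'-most tag."""

    id: str
    sequence: str

    @property
    def has_anchor(self) -> bool:
        return ANCHOR in self.sequence

    @property
    def true_tag(self) -> str:
        """26-nt tag at the 3'-most CATG; empty string if anchorless."""
        pos = self.sequence.rfind(ANCHOR)
        if pos < 0 or pos + TAG_LENGTH > len(self.sequence):
            return ""
        return self.sequence[pos : pos + TAG_LENGTH]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the emulated study conditions."""

    n_transcripts: int = 12_774
    depth_W: int = 227_536
    depth_F: int = 127_394
    abundance_mixture: tuple[float, float, float, float] = DEFAULT_MIXTURE
    copy_shares: tuple[float, float, float, float] | None = None
    de_fraction: float = 0.043
    de_up_share: float = 0.786
    fc_range: tuple[float, float] = (0.09, 70.0)
    de_up_min: float = 2.5
    de_down_max: float = 0.4
    error_rate: float = 0.001
    twin_ditag_rate: float = 0.05
    incomplete_read_rate: float = 0.05
    length_range: tuple[int, int] = (200, 1500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if self.depth_W < 0 or self.depth_F < 0:
            raise ValueError("library depths must be >= 0")
        mix = self.abundance_mixture
        if len(mix) != 4 or any(not 0 <= p <= 1 for p in mix):
            raise ValueError("abundance_mixture needs 4 proportions in [0, 1]")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("abundance_mixture must sum to 1")
        for rate in (
            self.de_fraction,
            self.de_up_share,
            self.error_rate,
            self.twin_ditag_rate,
            self.incomplete_read_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates and proportions must lie in [0, 1]")
        if self.de_fraction > 0:
            lo, hi = self.fc_range
            if not (lo <= self.de_down_max < 1 < self.de_up_min <= hi):
                raise ValueError(
                    "fc_range must bracket the up/down thresholds with "
                    "fc_range[0] <= de_down_max < 1 < de_up_min <= fc_range[1]; "
                    "ranges crossing 1 ambiguously are rejected"
                )
        if self.copy_shares is not None:
            cs = self.copy_shares
            if len(cs) != 4 or any(p < 0 for p in cs) or abs(sum(cs) - 1) > 1e-9:
                raise ValueError("copy_shares needs 4 nonnegative values summing to 1")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SimConfig":
        kwargs = dict(data)
        for key in ("abundance_mixture", "copy_shares", "fc_range", "length_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def generate_transcriptome(
    n: int,
    length_range: tuple[int, int] = (200, 1500),
    seed: int = 0,
) -> list[ReferenceTranscript]:
    """Generate ``n`` transcripts with unique, well-formed 3'-most tags.

    Each transcript ends with its tag: the final 26 nt are CATG plus 22
    random bases, and no CATG occurs downstream of that anchor, so the
    3'-most NlaIII site always yields a full 26-nt tag. Tags are unique
    across the transcriptome. Deterministic given ``seed``.
    """
    lo, hi = length_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if lo < 60:
        raise ValueError("minimum transcript length must be >= 60 nt")
    if lo > hi:
        raise ValueError("length_range must satisfy min <= max")
    rng = np.random.default_rng(seed)
    seen_tags: set[str] = set()
    transcripts: list[ReferenceTranscript] = []
    max_attempts = 500
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        prefix = _random_bases(rng, length - TAG_LENGTH)
        for attempt in range(max_attempts):
            tag = ANCHOR + _random_bases(rng, TAG_LENGTH - len(ANCHOR))
            seq = prefix + tag
            # the planted anchor must remain the 3'-most CATG
            if seq.find(ANCHOR, len(seq) - TAG_LENGTH + 1) != -1:
                continue
            if tag in seen_tags:
                continue
            break
        else:
            raise ValueError(
                f"could not generate a unique well-formed tag for transcript {i} "
                f"after {max_attempts} attempts; n={n} may exceed what "
                f"length_range={length_range} supports"
            )
        seen_tags.add(tag)
        transcripts.append(ReferenceTranscript(f"tx{i:05d}", seq))
    return transcripts


def _largest_remainder(proportions: Sequence[float], total: int) -> np.ndarray:
    """Integer allocation of ``total`` by proportions, largest remainder."""
    exact = np.asarray(proportions, dtype=float) * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:short]] += 1
    return counts


def _fill_budget(
    values: np.ndarray, budget: float, lo: float, hi: float
) -> np.ndarray:
    """Rescale ``values`` to sum to ``budget`` while staying in [lo, hi].

    Iterative water-filling: scale the unclamped entries, clamp anything
    out of bounds, and repeat. Feasible whenever
    ``n*lo <= budget <= n*hi``.
    """
    n = len(values)
    if not (n * lo <= budget <= n * hi):
        raise ValueError(
            f"infeasible class budget: {budget:.1f} copies per million for "
            f"{n} transcripts bounded to [{lo:.4g}, {hi:.4g}]"
        )
    out = values.astype(float).copy()
    free = np.ones(n, dtype=bool)
    for _ in range(200):
        fixed_sum = out[~free].sum()
        remaining = budget - fixed_sum
        scale = remaining / out[free].sum()
        out[free] *= scale
        too_low = free & (out < lo)
        too_high = free & (out > hi)
        if not too_low.any() and not too_high.any():
            return out
        out[too_low] = lo
        out[too_high] = hi
        free &= ~(too_low | too_high)
        if not free.any():
            return out
    return out  # pragma: no cover - convergence is monotone


def _default_copy_shares(mixture: Sequence[float]) -> np.ndarray:
    """Copy shares proportional to transcript share x class geometric mid."""
    mids = np.array([math.sqrt(lo * hi) for lo, hi in CLASS_BOUNDS])
    shares = np.asarray(mixture, dtype=float) * mids
    return shares / shares.sum()


def _project_budgets(shares: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Project class copy budgets onto the feasible box.

    Each class budget must lie within ``[n_k * lo_k, n_k * hi_k]`` while
    the budgets sum to 10^6; infeasible budgets are clamped and the
    residual redistributed proportionally among the others. Used for
    derived default shares only — explicitly configured shares fail loudly
    instead.
    """
    lo = np.array([b[0] for b in CLASS_BOUNDS]) * counts
    hi = np.array([b[1] for b in CLASS_BOUNDS]) * counts
    if not lo.sum() <= 1e6 <= hi.sum():
        raise ValueError(
            f"no feasible abundance assignment: {counts.tolist()} transcripts "
            "per class cannot carry 10^6 copies per million within the class "
            "bounds; adjust n_transcripts or abundance_mixture"
        )
    budget = shares * 1e6
    free = counts > 0
    for _ in range(20):
        budget[~free] = np.clip(budget[~free], lo[~free], hi[~free])
        remaining = 1e6 - budget[~free].sum()
        budget[free] *= remaining / budget[free].sum()
        clamped = free & ((budget < lo) | (budget > hi))
        if not clamped.any():
            return budget
        budget[clamped] = np.clip(budget[clamped], lo[clamped], hi[clamped])
        free &= ~clamped
        if not free.any():
            break
    return budget


def assign_expression(
    transcriptome: Sequence[ReferenceTranscript], config: SimConfig
) -> pd.DataFrame:
    """Build the ground-truth table of expected abundances and fold changes.

    Per-class transcript counts follow ``config.abundance_mixture`` by
    largest-remainder allocation; within a class, copies-per-million
    values are drawn log-uniformly and water-filled to the class copy
    budget so each library column sums to exactly 10^6. A ``de_fraction``
    subset (restricted to the low/mid classes, where essentially all
    differential expression was observed) receives fold changes drawn
    log-uniformly above ``de_up_min`` or below ``de_down_max``; the F
    column is then renormalized to 10^6 and ``de_status`` is assigned
    from the final ``true_fc`` so the thresholds hold by construction.

    Returns a DataFrame with columns ``transcript_id, true_tag, mean_W,
    mean_F, true_fc, de_status``.
    """
    if len(transcriptome) == 0:
        raise ValueError("transcriptome is empty")
    n = len(transcriptome)
    rng = np.random.default_rng(config.seed + 1)
    mixture = np.asarray(config.abundance_mixture, dtype=float)
    counts = _largest_remainder(mixture, n)
    if config.copy_shares is not None:
        shares = np.asarray(config.copy_shares, dtype=float)
        if ((counts == 0) & (shares > 0)).any():
            raise ValueError(
                "copy_shares assigns copies to a class with no transcripts"
            )
        budgets = shares * 1e6
    else:
        shares = _default_copy_shares(mixture) * (counts > 0)
        if shares.sum() == 0:
            raise ValueError("no class has both transcripts and a copy share")
        budgets = _project_budgets(shares / shares.sum(), counts)

    class_of = np.repeat(np.arange(4), counts)
    rng.shuffle(class_of)
    mean_w = np.empty(n)
    for k, (lo, hi) in enumerate(CLASS_BOUNDS):
        idx = np.flatnonzero(class_of == k)
        if len(idx) == 0:
            continue
        draws = 10 ** rng.uniform(math.log10(lo), math.log10(hi), len(idx))
        mean_w[idx] = _fill_budget(draws, budgets[k], lo, hi)

    fc = np.ones(n)
    n_de = int(round(config.de_fraction * n))
    if n_de > 0:
        eligible = np.flatnonzero(class_of <= 1)  # low/mid classes
        if len(eligible) < n_de:
            raise ValueError(
                "de_fraction requires more low/mid transcripts than available"
            )
        de_idx = rng.choice(eligible, size=n_de, replace=False)
        n_up = int(round(config.de_up_share * n_de))
        lo_fc, hi_fc = config.fc_range
        up_draws = 10 ** rng.uniform(
            math.log10(config.de_up_min), math.log10(hi_fc), n_up
        )
        down_draws = 10 ** rng.uniform(
            math.log10(lo_fc), math.log10(config.de_down_max), n_de - n_up
        )
        fc[de_idx[:n_up]] = up_draws
        fc[de_idx[n_up:]] = down_draws

    mean_f_raw = mean_w * fc
    mean_f = mean_f_raw * (1e6 / mean_f_raw.sum())
    true_fc = mean_f / mean_w
    de_status = np.where(
        true_fc >= config.de_up_min,
        "up",
        np.where(true_fc <= config.de_down_max, "down", "null"),
    )
    return pd.DataFrame(
        {
            "transcript_id": [t.id for t in transcriptome],
            "true_tag": [t.true_tag for t in transcriptome],
            "mean_W": mean_w,
            "mean_F": mean_f,
            "true_fc": true_fc,
            "de_status": de_status,
        }
    )


@dataclass
class SimulatedReads:
    """Reads per library plus the realized tag draws and retained truth."""

    reads: dict[str, list[SequencingRead]]
    draws: dict[str, pd.Series]
    truth: pd.DataFrame

    def draw_totals(self) -> dict[str, int]:
        return {lib: int(s.sum()) for lib, s in self.draws.items()}


def _apply_substitutions(
    read_arr: np.ndarray, rng: np.random.Generator, error_rate: float
) -> np.ndarray:
    n_err = rng.binomial(len(read_arr), error_rate)
    if n_err == 0:
        return read_arr
    positions = rng.choice(len(read_arr), size=n_err, replace=False)
    for pos in positions:
        current = read_arr[pos]
        choices = _BASES[_BASES != current]
        read_arr[pos] = choices[rng.integers(0, 3)]
    return read_arr


def _pair_without_collisions(
    drawn: np.ndarray, tags: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reorder drawn tag indices so consecutive pairs form distinct ditags.

    Random pairing occasionally repeats an unordered tag pair by chance;
    downstream twin-ditag filtering would then silently discard genuine
    draws and break exact count conservation. Ground truth stays exact by
    swapping the second member of a colliding pair with a later draw
    whenever possible (chance ditag re-occurrence is a real-data feature
    the generator deliberately forgoes).
    """
    out = drawn.copy()
    seen: set[tuple[str, str]] = set()
    n = len(out)
    for i in range(0, n - 1, 2):
        a, b = tags[out[i]], tags[out[i + 1]]
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            continue
        resolved = False
        for j in range(i + 2, min(i + 2 + 2000, n)):
            b2 = tags[out[j]]
            key2 = (a, b2) if a <= b2 else (b2, a)
            if key2 not in seen:
                out[i + 1], out[j] = out[j], out[i + 1]
                seen.add(key2)
                resolved = True
                break
        if not resolved:  # unavoidable duplicate (kept, becomes a twin)
            seen.add(key)
    return out


def simulate_reads(truth: pd.DataFrame, config: SimConfig) -> SimulatedReads:
    """Draw tags multinomially and emit linker-flanked ditag reads.

    Per library, ``depth`` tag draws (rounded up to an even number so
    each read holds exactly two tags) are taken from a multinomial over
    the truth means, paired into ditags, and wrapped in the library's
    linkers. Twin-ditag duplicates are appended as extra reads; incomplete
    reads are truncated uniformly below full length; substitution errors
    hit each base independently. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 2)
    tags = truth["true_tag"].to_numpy()
    reads: dict[str, list[SequencingRead]] = {}
    draws: dict[str, pd.Series] = {}
    for lib, depth, mean_col in (
        ("W", config.depth_W, "mean_W"),
        ("F", config.depth_F, "mean_F"),
    ):
        left, right = LINKERS[lib]
        lib_reads: list[SequencingRead] = []
        if depth == 0:
            reads[lib] = lib_reads
            draws[lib] = pd.Series(dtype=int)
            continue
        depth_eff = depth + (depth % 2)
        probs = truth[mean_col].to_numpy() / truth[mean_col].sum()
        counts = rng.multinomial(depth_eff, probs)
        drawn = np.repeat(np.arange(len(tags)), counts)
        rng.shuffle(drawn)
        drawn = _pair_without_collisions(drawn, tags, rng)
        tag_a = tags[drawn[0::2]]
        tag_b = tags[drawn[1::2]]
        n_ditags = len(tag_a)
        ditag_seqs = [
            left + a + revcomp(b) + right for a, b in zip(tag_a, tag_b)
        ]
        twin_mask = rng.random(n_ditags) < config.twin_ditag_rate
        all_seqs = ditag_seqs + [s for s, m in zip(ditag_seqs, twin_mask) if m]
        incomplete_mask = rng.random(len(all_seqs)) < config.incomplete_read_rate
        for i, seq in enumerate(all_seqs):
            if incomplete_mask[i]:
                cut = int(rng.integers(1, _READ_LENGTH))
                seq = seq[:cut]
            if config.error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                seq = _apply_substitutions(arr, rng, config.error_rate).tobytes().decode()
            lib_reads.append(SequencingRead(f"{lib}_{i:07d}", seq))
        reads[lib] = lib_reads
        drawn_counts = pd.Series(counts, index=tags)
        draws[lib] = drawn_counts[drawn_counts > 0]
    return SimulatedReads(reads, draws, truth)


def truth_eval(
    de_results: pd.DataFrame, truth: pd.DataFrame, ignore_unknown: bool = False
) -> dict[str, float]:
    """Score differential-expression calls against the simulation truth.

    ``de_results`` needs columns ``tag`` and ``direction``; ``truth`` is
    keyed by ``true_tag`` with ``de_status``. Truth tags absent from the
    results count as non-calls. Result tags absent from the truth raise
    an error listing the orphans, unless ``ignore_unknown`` is set (for
    runs with substitution errors, where a corrupted tag can survive
    extraction as a novel sequence); those tags are then dropped.

    Returns sensitivity per true status (fraction called in the correct
    direction), overall sensitivity, and the false-positive proportion
    (null-truth tags called up or down).
    """
    truth_status = truth.set_index("true_tag")["de_status"]
    result_tags = pd.Index(de_results["tag"])
    orphans = result_tags.difference(truth_status.index)
    if len(orphans) > 0:
        if not ignore_unknown:
            raise ValueError(
                f"{len(orphans)} result tags missing from truth: "
                f"{sorted(orphans)[:10]}"
            )
        de_results = de_results[~de_results["tag"].isin(orphans)]
    calls = de_results.set_index("tag")["direction"]
    metrics: dict[str, float] = {}
    n_correct_total = 0
    n_de_total = 0
    for status in ("up", "down"):
        members = truth_status.index[truth_status == status]
        if len(members) == 0:
            metrics[f"sensitivity_{status}"] = float("nan")
            continue
        called = calls.reindex(members).fillna("not_called")
        n_correct = int((called == status).sum())
        metrics[f"sensitivity_{status}"] = n_correct / len(members)
        n_correct_total += n_correct
        n_de_total += len(members)
    metrics["sensitivity"] = (
        n_correct_total / n_de_total if n_de_total else float("nan")
    )
    nulls = truth_status.index[truth_status == "null"]
    if len(nulls):
        null_calls = calls.reindex(nulls).fillna("not_called")
        metrics["fp_rate"] = float(null_calls.isin(["up", "down"]).mean())
    else:
        metrics["fp_rate"] = float("nan")
    return metrics


def write_reads(
    reads: Iterable[SequencingRead],
    path: Union[str, Path],
    fmt: str = "fasta",
) -> int:
    """Write reads as FASTA or FASTQ (constant quality 'I')."""
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.bases), id=read.id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(read.bases)
        records.append(rec)
    return SeqIO.write(records, str(path), fmt)


def write_transcriptome(
    transcripts: Iterable[ReferenceTranscript], path: Union[str, Path]
) -> int:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    return SeqIO.write(records, str(path), "fasta")


def write_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
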