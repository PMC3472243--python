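"""Significance-based merging of overlapping paired-end reads.

Mate 2 is reverse-complemented and slid along mate 1; for each relative
placement the number of matching bases k within the n overlapping columns is
scored with the binomial null

    P(k | n) = C(n, k) (1/4)^k (3/4)^(n-k)

(any of the four bases equally likely at each position).  A pair is merged
only when the placement with the smallest probability satisfies
p < p_threshold (default 1e-10) AND the second-smallest probability is at
least ratio_threshold (default 1000) times larger — the ratio condition
guards against repeat-spanning reads.  When the implied fragment is shorter
than a read, bases read through into the adaptor are trimmed.  Overlap
qualities are recombined additively: agreeing bases sum their phreds (capped),
disagreeing bases keep the higher-quality base with the phred difference.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy.stats import binom

from .seqcore import NucleotideRead, read_fastq, reverse_complement, write_fastq

logger = logging.getLogger("venomxtend")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeConfig:
    p_threshold: float = 1e-10
    ratio_threshold: float = 1000.0
    min_overlap: int = 1
    quality_cap: int = 60

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0,1)")
        if self.ratio_threshold < 1.0:
            raise ValueError("ratio_threshold must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class OverlapCandidate:
    """One relative placement of the reverse-complemented mate 2 on mate 1.

    ``fragment_length`` is the insert size the placement implies; the overlap
    spans ``n`` columns of which ``k`` match exactly (N never matches).
    """

    n: int
    k: int
    p: float
    fragment_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("need 0 < p <= 1")


class MergeRejectReason(str, Enum):
    OK = "ok"
    P_TOO_LARGE = "p_too_large"
    RATIO_TOO_SMALL = "ratio_too_small"
    NO_CANDIDATE = "no_candidate"


@dataclass
class MergeDecision:
    accepted: bool
    best: Optional[OverlapCandidate]
    second_best_p: Optional[float]
    reason: MergeRejectReason


@dataclass
class MergedRead(NucleotideRead):
    overlap_n: int = 0
    trimmed_adaptor_nt: tuple[int, int] = (0, 0)


@dataclass
class MergeStats:
    n_pairs: int = 0
    n_merged: int = 0
    total_merged_length: int = 0
    total_merged_quality: int = 0
    reject_reasons: dict = field(default_factory=dict)

    @property
    def merged_fraction(self) -> float:
        return self.n_merged / self.n_pairs if self.n_pairs else 0.0

    @property
    def mean_merged_length(self) -> float:
        return self.total_merged_length / self.n_merged if self.n_merged else 0.0

    @property
    def mean_merged_quality(self) -> float:
        return self.total_merged_quality / self.total_merged_length if self.total_merged_length else 0.0

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_merged": self.n_merged,
            "merged_fraction": self.merged_fraction,
            "mean_merged_length": self.mean_merged_length,
            "mean_merged_quality": self.mean_merged_quality,
            "reject_reasons": dict(self.reject_reasons),
        }


# ---------------------------------------------------------------------------
# Binomial overlap probability
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1024)
def _log_pmf_row(n: int) -> np.ndarray:
    """log P(k|n) for k = 0..n under the 1/4-match null, via scipy in log space."""
    return binom.logpmf(np.arange(n + 1), n, 0.25)


@functools.lru_cache(maxsize=8)
def _log_pmf_matrix(n_max: int) -> np.ndarray:
    """M[n, k] = log P(k|n) for n = 1..n_max (k > n left at +inf)."""
    M = np.full((n_max + 1, n_max + 1), np.inf)
    ns, ks = np.meshgrid(np.arange(1, n_max + 1), np.arange(n_max + 1), indexing="ij")
    mask = ks <= ns
    M[1:, :][mask] = binom.logpmf(ks[mask], ns[mask], 0.25)
    return M


def binomial_overlap_probability(k: int, n: int) -> float:
    """P(k|n) = C(n,k) (1/4)^k (3/4)^(n-k), evaluated in log space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(np.exp(_log_pmf_row(n)[k]))


# ---------------------------------------------------------------------------
# Overlap enumeration
# ---------------------------------------------------------------------------

# N is encoded differently in the two mates so N never matches anything.
_ENCODE_1 = np.zeros(256, dtype=np.uint8)
_ENCODE_2 = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_1[ord(_b)] = _i + 1
    _ENCODE_2[ord(_b)] = _i + 1
_ENCODE_1[ord("N")] = 250
_ENCODE_2[ord("N")] = 251


def _overlap_match_counts(seq1: str, rc2: str) -> tuple[np.ndarray, np.ndarray]:
    """Match counts for every placement of rc2 along seq1.

    Placements are indexed by implied fragment length f = 1 .. L1+L2-1, where
    rc2 occupies positions [f-L2, f) in mate-1 coordinates.  Returns
    (fragment_lengths, k_counts).
    """
    a = _ENCODE_1[np.frombuffer(seq1.encode(), dtype=np.uint8)]
    b = _ENCODE_2[np.frombuffer(rc2.encode(), dtype=np.uint8)]
    eq = a[:, None] == b[None, :]
    # column pairs with i - j = d align when rc2 starts at offset d; f = d + L2
    i = np.arange(len(a))[:, None]
    j = np.arange(len(b))[None, :]
    diag = (i - j + len(b) - 1).ravel()
    k = np.bincount(diag, weights=eq.ravel(), minlength=len(a) + len(b) - 1)
    fragments = np.arange(1, len(a) + len(b))
    return fragments, k.astype(np.int64)


def _overlap_lengths(fragments: np.ndarray, len1: int, len2: int) -> np.ndarray:
    """Overlap column count n for each implied fragment length."""
    return np.minimum(len1, fragments) - np.maximum(0, fragments - len2)


def enumerate_overlaps(
    read1: NucleotideRead,
    read2: NucleotideRead,
    config: MergeConfig = MergeConfig(),
) -> list[OverlapCandidate]:
    """Score every placement of revcomp(mate 2) along mate 1.

    One candidate per placement (implied fragment length), covering both
    normal overlaps and adaptor read-through placements where the fragment is
    shorter than a read.  Placements with overlap below ``min_overlap`` are
    omitted.
    """
    if not read1.sequence or not read2.sequence:
        raise ValueError("both mates must be non-empty")
    rc2 = reverse_complement(read2.sequence)
    fragments, ks = _overlap_match_counts(read1.sequence, rc2)
    ns = _overlap_lengths(fragments, len(read1), len(read2))
    out = []
    for f, n, k in zip(fragments.tolist(), ns.tolist(), ks.tolist()):
        if n < config.min_overlap:
            continue
        out.append(OverlapCandidate(n=n, k=k, p=binomial_overlap_probability(k, n), fragment_length=f))
    return out


# ---------------------------------------------------------------------------
# Merge decision
# ---------------------------------------------------------------------------

def decide_merge(
    candidates: Iterable[OverlapCandidate],
    config: MergeConfig = MergeConfig(),
) -> MergeDecision:
    """Accept iff min-p candidate has p < p_threshold and the second-smallest
    p is at least ratio_threshold times larger.  A tie for the minimum means
    ratio 1 and is rejected."""
    cands = sorted(candidates, key=lambda c: c.p)
    if not cands:
        return MergeDecision(False, None, None, MergeRejectReason.NO_CANDIDATE)
    best = cands[0]
    second_p = cands[1].p if len(cands) > 1 else None
    if best.p >= config.p_threshold:
        return MergeDecision(False, best, second_p, MergeRejectReason.P_TOO_LARGE)
    if second_p is not None and second_p < config.ratio_threshold * best.p:
        return MergeDecision(False, best, second_p, MergeRejectReason.RATIO_TOO_SMALL)
    return MergeDecision(True, best, second_p, MergeRejectReason.OK)


def combine_base(
    base1: str, q1: int, base2: str, q2: int, config: MergeConfig = MergeConfig()
) -> tuple[str, int]:
    """Recombine one overlap column.

    Agreement sums the phreds (capped); disagreement keeps the higher-quality
    base with the phred difference; an exact quality tie keeps the mate-1 base
    at quality 0.  An N defers entirely to its partner.
    """
    if base1 == "N":
        return (base2, q2 if base2 != "N" else 0)
    if base2 == "N":
        return (base1, q1)
    if base1 == base2:
        return (base1, min(q1 + q2, config.quality_cap))
    if q1 >= q2:
        return (base1, q1 - q2)
    return (base2, q2 - q1)


def _build_merged(
    read1: NucleotideRead,
    read2: NucleotideRead,
    fragment_length: int,
    overlap_n: int,
    config: MergeConfig,
) -> MergedRead:
    """Assemble the composite read for an accepted placement."""
    f = fragment_length
    rc2_seq = reverse_complement(read2.sequence)
    rc2_qual = read2.qualities[::-1]
    trim1 = max(0, len(read1) - f)       # mate-1 3' adaptor read-through
    trim2 = max(0, len(read2) - f)       # mate-2 3' adaptor read-through
    # fragment coordinates: mate 1 covers [0, len1-trim1); rc2 covers [f-len2+trim2, f)
    r1_end = len(read1) - trim1
    r2_start = f - (len(read2) - trim2)
    seq = []
    qual = []
    for x in range(f):
        in1 = x < r1_end
        in2 = x >= r2_start
        if in1 and in2:
            b, q = combine_base(
                read1.sequence[x], read1.qualities[x],
                rc2_seq[x - r2_start + trim2], rc2_qual[x - r2_start + trim2],
                config,
            )
        elif in1:
            b, q = read1.sequence[x], read1.qualities[x]
        else:
            b, q = rc2_seq[x - r2_start + trim2], rc2_qual[x - r2_start + trim2]
        seq.append(b)
        qual.append(q)
    return MergedRead(
        id=read1.id,
        sequence="".join(seq),
        qualities=qual,
        overlap_n=overlap_n,
        trimmed_adaptor_nt=(trim1, trim2),
    )


def merge_pair(
    read1: NucleotideRead,
    read2: NucleotideRead,
    config: MergeConfig = MergeConfig(),
) -> tuple[Optional[MergedRead], MergeDecision]:
    """Merge one pair; returns (merged_or_None, decision)."""
    candidates = enumerate_overlaps(read1, read2, config)
    decision = decide_merge(candidates, config)
    if not decision.accepted:
        return None, decision
    best = decision.best
    return _build_merged(read1, read2, best.fragment_length, best.n, config), decision


def _merge_pair_fast(
    read1: NucleotideRead,
    read2: NucleotideRead,
    config: MergeConfig,
) -> tuple[Optional[MergedRead], MergeRejectReason]:
    """Array fast path used by merge_stream (no per-candidate objects)."""
    rc2 = reverse_complement(read2.sequence)
    fragments, ks = _overlap_match_counts(read1.sequence, rc2)
    ns = _overlap_lengths(fragments, len(read1), len(read2))
    valid = ns >= config.min_overlap
    if not valid.any():
        return None, MergeRejectReason.NO_CANDIDATE
    fragments, ks, ns = fragments[valid], ks[valid], ns[valid]
    logps = _log_pmf_matrix(max(len(read1), len(read2)))[ns, ks]
    order = np.argsort(logps)
    best = order[0]
    best_p = float(np.exp(logps[best]))
    if best_p >= config.p_threshold:
        return None, MergeRejectReason.P_TOO_LARGE
    if len(order) > 1:
        second_p = float(np.exp(logps[order[1]]))
        if second_p < config.ratio_threshold * best_p:
            return None, MergeRejectReason.RATIO_TOO_SMALL
    merged = _build_merged(read1, read2, int(fragments[best]), int(ns[best]), config)
    return merged, MergeRejectReason.OK


def merge_stream(
    fastq1: str | Path | Iterable[NucleotideRead],
    fastq2: str | Path | Iterable[NucleotideRead],
    config: MergeConfig = MergeConfig(),
    out_prefix: Optional[str | Path] = None,
) -> tuple[list[MergedRead], list[tuple[NucleotideRead, NucleotideRead]], MergeStats]:
    """Merge two mate streams in matched order.

    With ``out_prefix`` set, writes ``<prefix>.merged.fastq`` and
    ``<prefix>.unmerged.R1/R2.fastq``.  Raises on unequal stream lengths,
    naming the shorter file.
    """
    it1 = read_fastq(fastq1) if isinstance(fastq1, (str, Path)) else iter(fastq1)
    it2 = read_fastq(fastq2) if isinstance(fastq2, (str, Path)) else iter(fastq2)
    name1 = str(fastq1) if isinstance(fastq1, (str, Path)) else "R1"
    name2 = str(fastq2) if isinstance(fastq2, (str, Path)) else "R2"

    merged: list[MergedRead] = []
    unmerged: list[tuple[NucleotideRead, NucleotideRead]] = []
    stats = MergeStats()
    _SENTINEL = object()
    while True:
        r1 = next(it1, _SENTINEL)
        r2 = next(it2, _SENTINEL)
        if r1 is _SENTINEL and r2 is _SENTINEL:
            break
        if r1 is _SENTINEL or r2 is _SENTINEL:
            short = name1 if r1 is _SENTINEL else name2
            raise ValueError(f"unequal mate file lengths: {short} is shorter")
        stats.n_pairs += 1
        m, reason = _merge_pair_fast(r1, r2, config)
        if m is not None:
            merged.append(m)
            stats.n_merged += 1
            stats.total_merged_length += len(m)
            stats.total_merged_quality += sum(m.qualities)
        else:
            unmerged.append((r1, r2))
            stats.reject_reasons[reason.value] = stats.reject_reasons.get(reason.value, 0) + 1

    if out_prefix is not None:
        prefix = str(out_prefix)
        write_fastq(merged, f"{prefix}.merged.fastq")
        write_fastq((p[0] for p in unmerged), f"{prefix}.unmerged.R1.fastq")
        write_fastq((p[1] for p in unmerged), f"{prefix}.unmerged.R2.fastq")
    return merged, unmerged, stats
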