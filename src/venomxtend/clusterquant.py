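"""Divergence, clustering, naming, indel profiling and abundance estimation.

Nucleotide divergence between two transcripts is the mismatch fraction over
the gap-free columns of their global alignment — gaps are excluded entirely,
so a splice-variant insertion does not inflate divergence and such variants
cluster with their parent.  Transcripts are single-linkage clustered at a
divergence threshold (default < 1%), clusters are named CLASS-number with
lettered members, and abundance is estimated as the percentage of reads
mapping to each transcript/cluster at a minimum identity (default 95%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .seqcore import NucleotideRead, Transcript, reverse_complement

logger = logging.getLogger("venomxtend")


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

@dataclass
class GapRun:
    sequence: str           # "a" or "b": which input carries the gap
    start: int              # 0-based column index in the alignment
    length: int


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    matches: int
    mismatches: int
    gap_runs: list[GapRun]

    @property
    def gap_free_columns(self) -> int:
        return self.matches + self.mismatches


@dataclass(frozen=True)
class AlignConfig:
    """Unit-cost affine scheme: match 0, mismatch 1, gap run of length L
    costs gap_open + L * gap_extend."""
    mismatch: float = 1.0
    gap_open: float = 5.0
    gap_extend: float = 1.0


def _make_aligner(config: AlignConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0.0
    aligner.mismatch_score = -config.mismatch
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def global_align(a: str, b: str, config: AlignConfig = AlignConfig()) -> PairwiseAlignment:
    """Optimal global alignment under the affine unit-cost scheme.

    Deterministic: the first optimal traceback reported by the aligner.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _make_aligner(config).align(a, b)[0]
    ga, gb = aln[0], aln[1]
    matches = mismatches = 0
    gap_runs: list[GapRun] = []
    current: Optional[GapRun] = None
    for col, (ca, cb) in enumerate(zip(ga, gb)):
        if ca == "-" or cb == "-":
            which = "a" if ca == "-" else "b"
            if current is not None and current.sequence == which and \
                    current.start + current.length == col:
                current.length += 1
            else:
                current = GapRun(which, col, 1)
                gap_runs.append(current)
        else:
            if ca == cb and ca != "N":
                matches += 1
            else:
                # N never matches
                mismatches += 1
    return PairwiseAlignment(ga, gb, matches, mismatches, gap_runs)


def pairwise_divergence(a: str, b: str, config: AlignConfig = AlignConfig()) -> float:
    """Mismatch fraction over gap-free aligned columns (gaps excluded)."""
    aln = global_align(a, b, config)
    if aln.gap_free_columns == 0:
        raise ValueError("no gap-free aligned columns; divergence undefined")
    return aln.mismatches / aln.gap_free_columns


def indel_profile(a: str, b: str, config: AlignConfig = AlignConfig()) -> list[GapRun]:
    """Gap runs of the global alignment (adjacent runs in the same sequence
    are already merged)."""
    return global_align(a, b, config).gap_runs


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterConfig:
    divergence_threshold: float = 0.01
    use_cds: bool = True    # compare annotated CDS regions when present

    def __post_init__(self) -> None:
        if not (0.0 < self.divergence_threshold < 1.0):
            raise ValueError("divergence_threshold must be in (0,1)")


@dataclass
class TranscriptCluster:
    name: str
    members: list[Transcript]          # descending length, then id
    letters: list[Optional[str]]       # a, b, c ... ; None for singletons

    @property
    def representative(self) -> Transcript:
        return self.members[0]

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


def _compare_sequence(t: Transcript, config: ClusterConfig) -> str:
    return t.cds_sequence if config.use_cds else t.sequence


def single_linkage_cluster(
    transcripts: Sequence[Transcript],
    config: ClusterConfig = ClusterConfig(),
    align_config: AlignConfig = AlignConfig(),
) -> list[TranscriptCluster]:
    """Connected components of the graph with edges at divergence < threshold.

    Clusters are ordered by representative id; members within a cluster by
    descending length then id, lettered a, b, c, ... (singletons unlettered).
    Names here are provisional ("cluster-1", ...); see :func:`name_clusters`.
    """
    if not transcripts:
        raise ValueError("need at least one transcript")
    n = len(transcripts)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    seqs = [_compare_sequence(t, config) for t in transcripts]
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if pairwise_divergence(seqs[i], seqs[j], align_config) < config.divergence_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[Transcript]] = {}
    for i, t in enumerate(transcripts):
        groups.setdefault(find(i), []).append(t)

    clusters = []
    for members in groups.values():
        members = sorted(members, key=lambda t: (-len(t.sequence), t.id))
        letters: list[Optional[str]]
        if len(members) == 1:
            letters = [None]
        else:
            letters = [chr(ord("a") + i) for i in range(len(members))]
        clusters.append(TranscriptCluster("", members, letters))
    clusters.sort(key=lambda c: c.representative.id)
    for i, c in enumerate(clusters):
        c.name = f"cluster-{i + 1}"
    return clusters


def name_clusters(clusters: Sequence[TranscriptCluster]) -> list[TranscriptCluster]:
    """Assign CLASS-number names (e.g. CTL-3) from member class labels.

    Numbers are assigned within each class in cluster order; members keep
    their a, b, c letters.  A cluster mixing class labels is an error.
    """
    counters: dict[str, int] = {}
    for cluster in clusters:
        labels = {m.class_label for m in cluster.members}
        if len(labels) != 1 or None in labels:
            raise ValueError(
                f"cluster with mixed or missing class labels: "
                f"{[(m.id, m.class_label) for m in cluster.members]}"
            )
        (label,) = labels
        counters[label] = counters.get(label, 0) + 1
        cluster.name = f"{label}-{counters[label]}"
    return list(clusters)


def clusters_table(clusters: Sequence[TranscriptCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for member, letter in zip(c.members, c.letters):
            rows.append(
                {
                    "cluster": c.name,
                    "member_id": member.id,
                    "letter": letter or "",
                    "length": len(member.sequence),
                    "label": f"{c.name}{letter}" if letter else c.name,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read assignment and abundance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantConfig:
    min_identity: float = 0.95
    prefilter_k: int = 31
    sample_size: Optional[int] = None   # subsample reads before counting
    fractional_ties: bool = False       # split cross-cluster ties instead of discarding

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0,1]")


@dataclass
class AssignmentCounts:
    transcript_counts: dict[str, float]
    cluster_counts: dict[str, float]
    n_assigned: int
    n_ambiguous: int
    n_unassigned: int

    @property
    def n_reads(self) -> int:
        return self.n_assigned + self.n_ambiguous + self.n_unassigned


def _kmer_index(transcripts: Sequence[Transcript], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, t in enumerate(transcripts):
        seq = t.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], set()).add(i)
    return index


def _read_identity(read_seq: str, target_seq: str, max_dist: int) -> float:
    """Identity of the best semi-global (infix) placement of the read,
    defined as 1 - edit_distance / read_length."""
    res = edlib.align(read_seq, target_seq, mode="HW", task="distance", k=max_dist)
    if res["editDistance"] < 0:
        return -1.0
    return 1.0 - res["editDistance"] / len(read_seq)


def assign_reads(
    reads: Iterable[NucleotideRead],
    transcripts: Sequence[Transcript],
    config: QuantConfig = QuantConfig(),
    clusters: Optional[Sequence[TranscriptCluster]] = None,
    rng_seed: int = 0,
) -> AssignmentCounts:
    """Count reads per transcript/cluster at >= min_identity.

    Candidate targets come from a shared-k-mer prefilter (either read
    orientation); each candidate is scored by semi-global alignment and the
    read goes to the best target.  Identity ties spanning different clusters
    discard the read as ambiguous (or split it fractionally when
    ``fractional_ties``); ties within one cluster count toward the cluster.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    reads = list(reads)
    if config.sample_size is not None and len(reads) > config.sample_size:
        rng = np.random.default_rng(rng_seed)
        idx = rng.choice(len(reads), size=config.sample_size, replace=False)
        reads = [reads[int(i)] for i in sorted(idx)]

    cluster_of: dict[str, str] = {}
    if clusters is not None:
        for c in clusters:
            for m in c.members:
                cluster_of[m.id] = c.name

    k = config.prefilter_k
    index = _kmer_index(transcripts, k)
    t_counts: dict[str, float] = {}
    c_counts: dict[str, float] = {}
    n_assigned = n_ambiguous = n_unassigned = 0

    for read in reads:
        seq = read.sequence
        candidates: set[int] = set()
        for oriented in (seq, reverse_complement(seq)):
            for pos in range(0, len(oriented) - k + 1):
                hit = index.get(oriented[pos:pos + k])
                if hit:
                    candidates.update(hit)
        if not candidates:
            n_unassigned += 1
            continue
        max_dist = int(np.floor((1.0 - config.min_identity) * len(seq)))
        best_identity = -1.0
        best_targets: list[int] = []
        for ti in candidates:
            ident = max(
                _read_identity(seq, transcripts[ti].sequence, max_dist),
                _read_identity(reverse_complement(seq), transcripts[ti].sequence, max_dist),
            )
            if ident > best_identity:
                best_identity, best_targets = ident, [ti]
            elif ident == best_identity:
                best_targets.append(ti)
        if best_identity < config.min_identity:
            n_unassigned += 1
            continue
        tids = [transcripts[ti].id for ti in best_targets]
        tied_clusters = {cluster_of.get(tid, tid) for tid in tids}
        if len(tied_clusters) > 1:
            if config.fractional_ties:
                n_assigned += 1
                w = 1.0 / len(tids)
                for tid in tids:
                    t_counts[tid] = t_counts.get(tid, 0.0) + w
                    cname = cluster_of.get(tid, tid)
                    c_counts[cname] = c_counts.get(cname, 0.0) + w
            else:
                n_ambiguous += 1
            continue
        n_assigned += 1
        tid = min(tids)
        t_counts[tid] = t_counts.get(tid, 0.0) + 1.0
        (cname,) = tied_clusters
        c_counts[cname] = c_counts.get(cname, 0.0) + 1.0

    return AssignmentCounts(t_counts, c_counts, n_assigned, n_ambiguous, n_unassigned)


def abundance_table(
    counts: Mapping[str, float],
    total_reads: int,
    toxin_flags: Mapping[str, bool],
) -> pd.DataFrame:
    """Per-target abundance records mirroring a toxin-expression table.

    ``pct_total_reads`` = 100 * count / total_reads; ``pct_toxin_reads`` is
    computed over toxin-flagged targets only.  Records are sorted by
    descending pct_total within the toxin and nontoxin partitions (toxins
    first) and ranked within partition.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    toxin_total = sum(c for t, c in counts.items() if toxin_flags.get(t, False))
    rows = []
    for target, count in counts.items():
        is_toxin = bool(toxin_flags.get(target, False))
        rows.append(
            {
                "target": target,
                "toxin": is_toxin,
                "read_count": count,
                "pct_total_reads": 100.0 * count / total_reads,
                "pct_toxin_reads": (100.0 * count / toxin_total) if is_toxin and toxin_total else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["toxin", "pct_total_reads", "target"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = df.groupby("toxin", sort=False).cumcount() + 1
    return df[["rank", "target", "toxin", "read_count", "pct_total_reads", "pct_toxin_reads"]]
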