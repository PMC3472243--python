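"""The Extender: greedy transcript completion from high-quality reads.

A seed sequence grows by concatenation.  The k-mers at the two ends of every
seed are keys in two hash tables (5' and 3'); a read whose end k-mer matches
a key extends the corresponding seed end with its non-overlapping bases, the
consumed key is removed and the seed's new end k-mer inserted.  Reads are
cycled through N times without resetting after an extension.  Robustness
comes from replicate seeds — copies trimmed base-by-base from both ends so
that every replicate starts from different keys and extends independently —
followed by a per-column majority consensus anchored on the seed.

Defaults follow the regime the method was designed for: k = 100 on merged
~170-nt reads, 20 replicates, 10 cycles, and only reads whose every base has
phred quality >= 30.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .seqcore import NucleotideRead, Transcript, reverse_complement

logger = logging.getLogger("venomxtend")

SeedLike = Union[str, tuple, NucleotideRead, Transcript]


@dataclass(frozen=True)
class ExtenderConfig:
    k: int = 100
    replicates: int = 20
    cycles: int = 10
    min_base_quality: int = 30
    n_denovo_seeds: int = 1000

    def __post_init__(self) -> None:
        if self.k < 1 or self.replicates < 1 or self.cycles < 0:
            raise ValueError("need k >= 1, replicates >= 1, cycles >= 0")


@dataclass
class ExtensionEvent:
    seed_index: int
    end: str                # "5p" or "3p"
    n_bases: int
    used_revcomp: bool


@dataclass
class ExtensionResult:
    seed_id: str
    replicate_sequences: list[str]
    consensus: str
    extended_5p: int
    extended_3p: int


def filter_reads_quality(
    reads: Iterable[NucleotideRead], min_base_quality: int
) -> list[NucleotideRead]:
    """Keep exactly the reads whose every base quality is >= the threshold."""
    return [r for r in reads if all(q >= min_base_quality for q in r.qualities)]


def make_replicates(seed: str, r: int, k: int) -> list[str]:
    """Replicate i is the seed with i bases trimmed from each end (i = 0..r-1).

    If the seed is too short for r replicates of length >= k, r is reduced to
    the feasible maximum with a logged warning.
    """
    feasible = max(1, min(r, (len(seed) - k) // 2 + 1))
    if feasible < r:
        logger.warning(
            "seed of length %d supports only %d replicates at k=%d (requested %d)",
            len(seed), feasible, k, r,
        )
    return [seed[i:len(seed) - i] for i in range(feasible)]


@dataclass
class _SeedState:
    """One replicate under extension."""
    sequence: str
    owner: int              # index of the original seed
    trim: int               # replicate index = bases trimmed from each end
    left_ext: int = 0       # bases added 5' of the trimmed seed
    right_ext: int = 0
    frozen_5p: bool = False
    frozen_3p: bool = False


class SeedTable:
    """Replicate seeds plus the 5'- and 3'-end k-mer hash tables.

    Keys are unique within each table; a seed whose end k-mer duplicates an
    existing key is dropped from extension with a warning.  When an extension
    would insert a key that already exists, that seed end is frozen instead
    (``on_collision="freeze"``); with ``on_collision="share"`` the colliding
    key becomes shared and a matching read extends every seed holding it.
    """

    def __init__(self, k: int, on_collision: str = "share") -> None:
        if on_collision not in ("freeze", "share"):
            raise ValueError("on_collision must be 'freeze' or 'share'")
        self.k = k
        self.on_collision = on_collision
        self.seeds: list[_SeedState] = []
        self.five_prime: dict[str, list[int]] = {}
        self.three_prime: dict[str, list[int]] = {}

    def add_seed(self, sequence: str, owner: int, trim: int) -> bool:
        """Register a replicate; returns False (dropped) on a duplicate end key."""
        if len(sequence) < self.k:
            raise ValueError(f"seed shorter than k={self.k}")
        key5, key3 = sequence[: self.k], sequence[-self.k:]
        if key5 in self.five_prime or key3 in self.three_prime:
            logger.warning("seed with duplicate end k-mer dropped (owner %d, trim %d)", owner, trim)
            return False
        idx = len(self.seeds)
        self.seeds.append(_SeedState(sequence=sequence, owner=owner, trim=trim))
        self.five_prime[key5] = [idx]
        self.three_prime[key3] = [idx]
        return True

    @property
    def n_live_keys(self) -> tuple[int, int]:
        return (len(self.five_prime), len(self.three_prime))

    # -- extension ---------------------------------------------------------

    def _extend_5p(self, indices: list[int], added: str) -> None:
        old_key = self.seeds[indices[0]].sequence[: self.k]
        del self.five_prime[old_key]
        for idx in indices:
            st = self.seeds[idx]
            st.sequence = added + st.sequence
            st.left_ext += len(added)
        new_key = self.seeds[indices[0]].sequence[: self.k]
        if new_key in self.five_prime:
            if self.on_collision == "share":
                self.five_prime[new_key].extend(indices)
            else:
                for idx in indices:
                    self.seeds[idx].frozen_5p = True
        else:
            self.five_prime[new_key] = list(indices)

    def _extend_3p(self, indices: list[int], added: str) -> None:
        old_key = self.seeds[indices[0]].sequence[-self.k:]
        del self.three_prime[old_key]
        for idx in indices:
            st = self.seeds[idx]
            st.sequence = st.sequence + added
            st.right_ext += len(added)
        new_key = self.seeds[indices[0]].sequence[-self.k:]
        if new_key in self.three_prime:
            if self.on_collision == "share":
                self.three_prime[new_key].extend(indices)
            else:
                for idx in indices:
                    self.seeds[idx].frozen_3p = True
        else:
            self.three_prime[new_key] = list(indices)

    def try_extend_kmers(
        self, seq: str, rc: str, s5: str, s3: str, rc5: str, rc3: str
    ) -> Optional[ExtensionEvent]:
        """One extension attempt with precomputed end k-mers; first hit wins."""
        k = self.k
        hit = self.five_prime.get(s3)
        if hit is not None:
            self._extend_5p(hit, seq[: len(seq) - k])
            return ExtensionEvent(hit[0], "5p", len(seq) - k, False)
        hit = self.three_prime.get(s5)
        if hit is not None:
            self._extend_3p(hit, seq[k:])
            return ExtensionEvent(hit[0], "3p", len(seq) - k, False)
        hit = self.five_prime.get(rc3)
        if hit is not None:
            self._extend_5p(hit, rc[: len(rc) - k])
            return ExtensionEvent(hit[0], "5p", len(rc) - k, True)
        hit = self.three_prime.get(rc5)
        if hit is not None:
            self._extend_3p(hit, rc[k:])
            return ExtensionEvent(hit[0], "3p", len(rc) - k, True)
        return None


def build_seed_tables(
    seeds: Sequence[str], k: int, on_collision: str = "share"
) -> SeedTable:
    """Hash the end k-mers of plain seed sequences (no replicate expansion)."""
    table = SeedTable(k, on_collision=on_collision)
    for i, seq in enumerate(seeds):
        table.add_seed(seq, owner=i, trim=0)
    return table


def try_extend(table: SeedTable, read: NucleotideRead | str) -> Optional[ExtensionEvent]:
    """Attempt to extend one seed end with one read.

    Lookup order: read 3'-end k-mer against the 5' table, read 5'-end k-mer
    against the 3' table, then the same two lookups with the reverse
    complement; the first hit wins.  A read adding zero bases (length == k)
    triggers no event.
    """
    seq = read.sequence if isinstance(read, NucleotideRead) else read
    if len(seq) <= table.k:
        return None
    rc = reverse_complement(seq)
    k = table.k
    return table.try_extend_kmers(seq, rc, seq[:k], seq[-k:], rc[:k], rc[-k:])


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}
_CODE_BASE = "ACGTN"


def _consensus_from_anchored(
    replicates: list[tuple[str, int]], seed_len: int
) -> tuple[str, int, int]:
    """Majority consensus over replicates placed in seed coordinates.

    Each replicate is (sequence, global_start) where global coordinate 0 is
    the first base of the original untrimmed seed.  Every column covered by
    at least one replicate and contiguous with the seed span is emitted with
    the majority base over the replicates covering it; ties go to the
    lowest-index replicate.  Returns (consensus, extended_5p, extended_3p).

    Sparse read sets can leave some replicates unable to extend at all (no
    read end lands exactly k bases inside their trimmed ends), so distal
    columns are often covered by a minority of replicates; majority filtering
    therefore applies per column over covering replicates rather than
    demanding a quorum of all replicates.
    """
    r = len(replicates)
    starts = [g for _, g in replicates]
    ends = [g + len(s) for s, g in replicates]
    lo, hi = min(starts), max(ends)
    span = hi - lo
    codes = np.full((r, span), 255, dtype=np.uint8)
    for i, (s, g) in enumerate(replicates):
        codes[i, g - lo:g - lo + len(s)] = [_BASE_CODE[b] for b in s]
    coverage = (codes != 255).sum(axis=0)
    counts = np.zeros((5, span), dtype=np.int32)
    for c in range(5):
        counts[c] = (codes == c).sum(axis=0)
    best = counts.max(axis=0)
    majority = counts.argmax(axis=0)
    # tie columns: take the base of the lowest-index covering replicate
    # whose base achieves the maximum count
    tie_cols = np.flatnonzero(((counts == best).sum(axis=0) > 1) & (coverage > 0))
    for col in tie_cols:
        cands = {c for c in range(5) if counts[c, col] == best[col]}
        for i in range(r):
            if codes[i, col] != 255 and codes[i, col] in cands:
                majority[col] = codes[i, col]
                break
    emit = coverage > 0
    # restrict to the contiguous run of emitted columns containing the seed
    # (replicate intervals all contain the seed centre, so coverage is
    # unimodal and this run is well defined)
    anchor = -lo  # column index of global coordinate 0
    run_start = anchor
    while run_start > 0 and emit[run_start - 1]:
        run_start -= 1
    run_end = anchor
    while run_end < span and emit[run_end]:
        run_end += 1
    consensus = "".join(_CODE_BASE[c] for c in majority[run_start:run_end])
    extended_5p = anchor - run_start
    extended_3p = (run_end - anchor) - seed_len
    return consensus, extended_5p, max(0, extended_3p)


def consensus_sequences(
    replicate_sequences: Sequence[str],
    seed: str,
    anchors: Optional[Sequence[int]] = None,
) -> str:
    """Consensus across replicate extensions of one seed.

    Replicate i is assumed trimmed by i bases from each end of ``seed``
    before extension; it is anchored at the position of that trimmed seed
    within it (located by substring search unless explicit ``anchors`` —
    positions of the trimmed seed within each replicate — are given).
    Replicates lacking their trimmed seed are excluded with a warning.
    """
    placed: list[tuple[str, int]] = []
    for i, rep in enumerate(replicate_sequences):
        trimmed = seed[i:len(seed) - i] if len(seed) - 2 * i > 0 else ""
        if anchors is not None:
            pos = anchors[i]
        else:
            pos = rep.find(trimmed) if trimmed else -1
        if pos < 0 or not trimmed:
            logger.warning("replicate %d lacks its trimmed seed; excluded from consensus", i)
            continue
        placed.append((rep, i - pos))
    if not placed:
        raise ValueError("no replicate contains its trimmed seed")
    consensus, _, _ = _consensus_from_anchored(placed, len(seed))
    return consensus


# ---------------------------------------------------------------------------
# Main driver
# ---------------------------------------------------------------------------

def _seed_id_seq(seed: SeedLike, i: int) -> tuple[str, str]:
    if isinstance(seed, (NucleotideRead, Transcript)):
        return seed.id, seed.sequence
    if isinstance(seed, tuple):
        return seed[0], seed[1]
    return f"seed_{i + 1:04d}", seed


def run_extender(
    seeds: Sequence[SeedLike],
    reads: Sequence[NucleotideRead],
    config: ExtenderConfig = ExtenderConfig(),
    on_collision: str = "share",
) -> list[ExtensionResult]:
    """Extend each seed through N cycles over the fixed-order read list.

    Reads are assumed quality-filtered; each seed is expanded into replicate
    seeds that extend independently, and a majority consensus anchored on the
    original seed is reported per seed.  Deterministic given seed and read
    order.
    """
    k = config.k
    named = [_seed_id_seq(s, i) for i, s in enumerate(seeds)]
    for sid, seq in named:
        if len(seq) < k:
            raise ValueError(f"seed {sid!r} shorter than k={k}")

    table = SeedTable(k, on_collision=on_collision)
    for owner, (sid, seq) in enumerate(named):
        for trim, rep in enumerate(make_replicates(seq, config.replicates, k)):
            table.add_seed(rep, owner=owner, trim=trim)

    # precompute read end k-mers once; reads not longer than k can never extend
    records = []
    for r in reads:
        seq = r.sequence
        if len(seq) > k:
            rc = reverse_complement(seq)
            records.append((seq, rc, seq[:k], seq[-k:], rc[:k], rc[-k:]))

    for _cycle in range(config.cycles):
        for rec in records:
            table.try_extend_kmers(*rec)

    results: list[ExtensionResult] = []
    for owner, (sid, seq) in enumerate(named):
        states = [st for st in table.seeds if st.owner == owner]
        if not states:
            logger.warning("seed %r had no surviving replicates", sid)
            continue
        placed = [(st.sequence, st.trim - st.left_ext) for st in states]
        consensus, e5, e3 = _consensus_from_anchored(placed, len(seq))
        results.append(
            ExtensionResult(
                seed_id=sid,
                replicate_sequences=[st.sequence for st in states],
                consensus=consensus,
                extended_5p=e5,
                extended_3p=e3,
            )
        )
    return results


def denovo_extender(
    reads: Sequence[NucleotideRead],
    config: ExtenderConfig = ExtenderConfig(),
    rng_seed: int = 0,
    on_collision: str = "share",
) -> list[ExtensionResult]:
    """De novo assembly: seed the Extender with random reads.

    ``n_denovo_seeds`` reads of length >= k are drawn uniformly without
    replacement using ``rng_seed``; duplicate seed sequences collapse to one.
    Results are deduplicated by exact consensus sequence identity.
    """
    rng = np.random.default_rng(rng_seed)
    eligible = [i for i, r in enumerate(reads) if len(r.sequence) >= config.k]
    n_seeds = config.n_denovo_seeds
    if len(eligible) < n_seeds:
        logger.warning(
            "only %d reads of length >= k available; using all as seeds", len(eligible)
        )
        chosen = eligible
    else:
        chosen = rng.choice(len(eligible), size=n_seeds, replace=False)
        chosen = [eligible[int(i)] for i in chosen]
    seen_seqs = set()
    seeds: list[tuple[str, str]] = []
    for i in chosen:
        seq = reads[i].sequence
        if seq in seen_seqs:
            continue
        seen_seqs.add(seq)
        seeds.append((f"seed_{len(seeds) + 1:04d}:{reads[i].id}", seq))
    results = run_extender(seeds, reads, config, on_collision=on_collision)
    unique: dict[str, ExtensionResult] = {}
    for res in results:
        if res.consensus not in unique:
            unique[res.consensus] = res
    return list(unique.values())
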