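"""Synthetic skewed-abundance transcriptome and paired-end read simulator.

Emulates the study conditions the rest of the package is designed for:
100-nt paired reads from ~170-nt fragments (so most pairs overlap at their
3' ends), a strongly skewed transcript abundance distribution whose top
transcript takes ~6% of reads, near-duplicate transcript clusters below the
1% divergence threshold (including a 48-nt splice-like insertion variant),
and per-base qualities that decline toward the 3' read ends.  Full per-read
provenance (source transcript, fragment interval, error positions) is kept
for recovery tests.

The error model is substitution-only and qualities are derived
deterministically from the positional error rate; see docs/methods.md for
what this does and does not emulate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .clusterquant import pairwise_divergence
from .seqcore import NucleotideRead, Transcript, reverse_complement, write_fasta

logger = logging.getLogger("venomxtend")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed synthetic adaptor (not a vendor sequence); read-through beyond short
# fragments runs into this
SYNTHETIC_ADAPTOR = "AGCTGTCAGGCATTACGGATCGGAGATTCCAGCTTGAAGTCCTTAAGCACGGTGATCCGA"

_TOXIN_CLASSES = ("MYO", "CTL", "SVSP", "SVMP", "PLA2", "LAAO", "CRISP", "VEGF")


@dataclass
class PlantedVariant:
    parent_id: str
    variant_id: str
    n_substitutions: int
    insertion_length: int   # 0 when no block insertion
    insertion_pos: int


@dataclass
class SimulatedTranscriptome:
    transcripts: list[Transcript]
    abundances: dict[str, float]        # fragment (read) shares, sum to 1
    toxin_flags: dict[str, bool]
    planted_clusters: dict[str, list[str]]  # parent id -> member ids
    planted_variants: list[PlantedVariant]

    def abundance_array(self) -> np.ndarray:
        return np.array([self.abundances[t.id] for t in self.transcripts])


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 100
    insert_mean: float = 170.0
    insert_sd: float = 30.0
    error_rate_5p: float = 0.0005
    error_rate_3p: float = 0.01
    n_pairs: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate_5p <= 0.2 and 0 <= self.error_rate_3p <= 0.2):
            raise ValueError("error rates must be in [0, 0.2]")

    @property
    def insert_bounds(self) -> tuple[int, int]:
        return (self.read_length // 2, 2 * self.read_length + 100)


@dataclass
class ReadTruth:
    pair_id: str
    source_id: str
    fragment_start: int
    fragment_end: int
    errors_r1: list[int]
    errors_r2: list[int]
    adaptor_r1: int
    adaptor_r2: int


@dataclass
class SimTruth:
    records: list[ReadTruth]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------

def _geometric_shape_for_top(n: int, top: float = 0.06) -> float:
    """Decay ratio rho such that normalized geometric shares rho^i over n
    transcripts give the top transcript the ``top`` share."""
    if top <= 1.0 / n:
        # fewer transcripts than the share allows: fall back to uniform
        logger.info("top share %.3f infeasible for n=%d; using uniform shares", top, n)
        return 1.0

    def top_share(rho: float) -> float:
        w = rho ** np.arange(n)
        return w[0] / w.sum() - top

    return brentq(top_share, 1e-6, 1 - 1e-9)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_below_threshold(
    rng: np.random.Generator,
    parent: str,
    divergence: float,
    insertion_length: int,
) -> tuple[str, int, int]:
    """A variant of ``parent``: point substitutions at the given divergence
    plus an optional block insertion.  Returns (sequence, n_subs, ins_pos)."""
    seq = np.frombuffer(parent.encode(), dtype=np.uint8).copy()
    n_subs = max(1, int(round(divergence * len(parent))))
    positions = rng.choice(len(parent), size=n_subs, replace=False)
    for pos in positions:
        alternatives = _BASES[_BASES != seq[pos]]
        seq[pos] = rng.choice(alternatives)
    variant = seq.tobytes().decode()
    ins_pos = 0
    if insertion_length:
        ins_pos = int(rng.integers(len(parent) // 4, 3 * len(parent) // 4))
        block = _random_sequence(rng, insertion_length)
        variant = variant[:ins_pos] + block + variant[ins_pos:]
    return variant, n_subs, ins_pos


def simulate_transcriptome(
    n_transcripts: int = 20,
    length_range: tuple[int, int] = (900, 2400),
    abundance_shape: Optional[float] = None,
    n_clusters: int = 4,
    rng_seed: int = 0,
    top_share: float = 0.06,
    intra_divergence: float = 0.004,
    nontoxin_fraction: float = 0.25,
    verify: bool = True,
) -> SimulatedTranscriptome:
    """A transcriptome with planted near-duplicate clusters and skewed shares.

    ``n_clusters`` parent transcripts each receive one variant below the 1%
    divergence threshold (the first also gets a 48-nt block insertion, the
    splice-variant case); the remaining transcripts are unrelated singletons.
    Abundances are geometric with decay ``abundance_shape`` (solved so the
    top transcript takes ``top_share`` of reads when None).  The trailing
    ``nontoxin_fraction`` of singletons are flagged nontoxin.  Deterministic
    given ``rng_seed``; planted divergences are verified at generation time.
    """
    if n_transcripts < 2 * n_clusters + 1:
        raise ValueError(
            f"need n_transcripts >= 2*n_clusters + 1 (each cluster uses a parent "
            f"and a variant); got {n_transcripts} with {n_clusters} clusters"
        )
    if length_range[0] < 200 or length_range[1] < length_range[0]:
        raise ValueError(f"infeasible length_range {length_range}")
    rng = np.random.default_rng(rng_seed)

    n_base = n_transcripts - n_clusters
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_base)
    base_seqs = [_random_sequence(rng, int(L)) for L in lengths]

    transcripts: list[Transcript] = []
    planted_clusters: dict[str, list[str]] = {}
    planted_variants: list[PlantedVariant] = []
    toxin_flags: dict[str, bool] = {}

    n_nontoxin = int(round(nontoxin_fraction * (n_base - n_clusters)))
    for i, seq in enumerate(base_seqs):
        is_parent = i < n_clusters
        is_nontoxin = (not is_parent) and i >= n_base - n_nontoxin
        label = None if is_nontoxin else _TOXIN_CLASSES[i % len(_TOXIN_CLASSES)]
        tid = f"tx_{i + 1:03d}"
        transcripts.append(Transcript(id=tid, sequence=seq, class_label=label))
        toxin_flags[tid] = not is_nontoxin

    for ci in range(n_clusters):
        parent = transcripts[ci]
        ins_len = 48 if ci == 0 else 0
        var_seq, n_subs, ins_pos = _mutate_below_threshold(
            rng, parent.sequence, intra_divergence, ins_len
        )
        vid = f"{parent.id}v"
        transcripts.append(
            Transcript(id=vid, sequence=var_seq, class_label=parent.class_label)
        )
        toxin_flags[vid] = toxin_flags[parent.id]
        planted_clusters[parent.id] = [parent.id, vid]
        planted_variants.append(
            PlantedVariant(parent.id, vid, n_subs, ins_len, ins_pos)
        )

    rho = abundance_shape if abundance_shape is not None else \
        _geometric_shape_for_top(len(transcripts), top_share)
    weights = rho ** np.arange(len(transcripts))
    shares = weights / weights.sum()
    abundances = {t.id: float(s) for t, s in zip(transcripts, shares)}

    sim = SimulatedTranscriptome(
        transcripts, abundances, toxin_flags, planted_clusters, planted_variants
    )
    if verify:
        _verify_planted_structure(sim)
    return sim


def _verify_planted_structure(sim: SimulatedTranscriptome) -> None:
    """Generation-time invariants: shares sum to 1; intra-cluster divergence
    < 1%, inter-cluster divergence > 2%."""
    total = sum(sim.abundances.values())
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"abundances sum to {total}")
    by_id = {t.id: t for t in sim.transcripts}
    member_of = {}
    for parent, members in sim.planted_clusters.items():
        for m in members:
            member_of[m] = parent
    for parent, members in sim.planted_clusters.items():
        for m in members[1:]:
            d = pairwise_divergence(by_id[parent].sequence, by_id[m].sequence)
            if d >= 0.01:
                raise AssertionError(f"planted intra divergence {d:.4f} >= 1% ({parent}/{m})")
    # spot-check inter-cluster pairs via the parents and singletons
    ids = [t.id for t in sim.transcripts]
    reps = [i for i in ids if member_of.get(i, i) == i]
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            d = pairwise_divergence(by_id[a].sequence, by_id[b].sequence)
            if d <= 0.02:
                raise AssertionError(f"inter-cluster divergence {d:.4f} <= 2% ({a}/{b})")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _positional_error_rates(config: ReadSimConfig) -> np.ndarray:
    """Per-position substitution rate, linear from the 5' to the 3' rate."""
    return np.linspace(config.error_rate_5p, config.error_rate_3p, config.read_length)


def quality_from_error_rate(rate: float) -> int:
    """Deterministic phred from the positional error rate (floor 1e-6)."""
    return int(round(-10.0 * np.log10(max(rate, 1e-6))))


def _apply_errors(
    seq: str, rates: np.ndarray, rng: np.random.Generator
) -> tuple[str, list[int]]:
    if rates[-1] == 0.0 and rates[0] == 0.0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rates[: len(arr)])
    for pos in hits:
        alternatives = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(alternatives)
    return arr.tobytes().decode(), hits.tolist()


def simulate_reads(
    transcriptome: SimulatedTranscriptome,
    config: ReadSimConfig = ReadSimConfig(),
) -> tuple[list[NucleotideRead], list[NucleotideRead], SimTruth]:
    """Paired 100-nt reads from ~170-nt fragments with full provenance.

    Fragments are drawn from transcripts proportional to abundance (shares
    are fragment shares); insert length is a rounded Normal(insert_mean,
    insert_sd) truncated to the config bounds and to the transcript length.
    R1 is the fragment prefix, R2 the reverse-complement suffix; when the
    fragment is shorter than a read the mates read through into a fixed
    synthetic adaptor (recorded in the truth).  Substitution errors occur at
    a per-position rate interpolated from the 5' to the 3' rate; qualities
    are the phred transform of that rate.
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.read_length
    lo, hi = config.insert_bounds
    rates = _positional_error_rates(config)
    quals = [quality_from_error_rate(r) for r in rates]

    usable = [t for t in transcriptome.transcripts if len(t.sequence) >= lo]
    if len(usable) < len(transcriptome.transcripts):
        dropped = len(transcriptome.transcripts) - len(usable)
        logger.warning("%d transcripts shorter than the minimum insert excluded", dropped)
    shares = np.array([transcriptome.abundances[t.id] for t in usable])
    shares = shares / shares.sum()

    adaptor = (SYNTHETIC_ADAPTOR * ((L // len(SYNTHETIC_ADAPTOR)) + 2))

    sources = rng.choice(len(usable), size=config.n_pairs, p=shares)
    inserts = np.clip(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, size=config.n_pairs)),
        lo, hi,
    ).astype(int)

    r1_list: list[NucleotideRead] = []
    r2_list: list[NucleotideRead] = []
    truths: list[ReadTruth] = []
    for i in range(config.n_pairs):
        t = usable[int(sources[i])]
        f = min(int(inserts[i]), len(t.sequence))
        # fragmentation of a bounded molecule: each molecule's first and last
        # piece are flush with an end, so ~insert_mean/L of fragments start
        # exactly at 0 and as many end exactly at L
        p_flush = min(0.5, config.insert_mean / len(t.sequence))
        u = rng.random()
        if u < p_flush:
            start = 0
        elif u < 2 * p_flush:
            start = len(t.sequence) - f
        else:
            start = int(rng.integers(0, len(t.sequence) - f + 1))
        fragment = t.sequence[start:start + f]
        ad1 = ad2 = max(0, L - f)
        raw1 = (fragment + adaptor)[:L]
        raw2 = (reverse_complement(fragment) + adaptor)[:L]
        seq1, err1 = _apply_errors(raw1, rates, rng)
        seq2, err2 = _apply_errors(raw2, rates, rng)
        pid = f"pair_{i + 1:07d}"
        r1_list.append(NucleotideRead(f"{pid}/1", seq1, quals[: len(seq1)]))
        r2_list.append(NucleotideRead(f"{pid}/2", seq2, quals[: len(seq2)]))
        truths.append(
            ReadTruth(pid, t.id, start, start + f, err1, err2, ad1, ad2)
        )
    return r1_list, r2_list, SimTruth(truths)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_simulation(
    sim: SimulatedTranscriptome,
    r1: Sequence[NucleotideRead],
    r2: Sequence[NucleotideRead],
    truth: SimTruth,
    config: ReadSimConfig,
    out_prefix: str | Path,
) -> dict[str, str]:
    """Write FASTA truth, R1/R2 FASTQ, truth TSV and a JSON manifest."""
    from .seqcore import write_fastq  # local import to avoid cycle at module load

    prefix = str(out_prefix)
    paths = {
        "transcriptome": f"{prefix}.transcripts.fasta",
        "r1": f"{prefix}.R1.fastq",
        "r2": f"{prefix}.R2.fastq",
        "truth": f"{prefix}.truth.tsv",
        "manifest": f"{prefix}.manifest.json",
    }
    annotated = []
    for t in sim.transcripts:
        label = t.class_label if t.class_label is not None else "NT"
        desc = Transcript(
            id=t.id, sequence=t.sequence, class_label=label, cds=t.cds
        )
        annotated.append(desc)
    toxin_tags = {
        tid: f"toxin={int(flag)}" for tid, flag in sim.toxin_flags.items()
    }
    write_fasta(annotated, paths["transcriptome"], extra_tags=toxin_tags)
    write_fastq(r1, paths["r1"])
    write_fastq(r2, paths["r2"])
    with open(paths["truth"], "w") as fh:
        fh.write("pair_id\tsource\tstart\tend\tn_errors_r1\tn_errors_r2\tadaptor_r1\tadaptor_r2\n")
        for rec in truth:
            fh.write(
                f"{rec.pair_id}\t{rec.source_id}\t{rec.fragment_start}\t{rec.fragment_end}\t"
                f"{len(rec.errors_r1)}\t{len(rec.errors_r2)}\t{rec.adaptor_r1}\t{rec.adaptor_r2}\n"
            )
    manifest = {
        "config": asdict(config),
        "abundances": sim.abundances,
        "toxin_flags": sim.toxin_flags,
        "planted_clusters": sim.planted_clusters,
        "outputs": paths,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
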