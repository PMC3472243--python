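"""Alignment, divergence, clustering, naming, indels and quantification."""

import numpy as np
import pytest

from venomxtend import (
    ClusterConfig,
    NucleotideRead,
    QuantConfig,
    Transcript,
    abundance_table,
    assign_reads,
    global_align,
    indel_profile,
    name_clusters,
    pairwise_divergence,
    single_linkage_cluster,
)
from venomxtend.clusterquant import AlignConfig
from conftest import random_dna


def gotoh_cost(a: str, b: str, mismatch=1.0, gap_open=5.0, gap_extend=1.0) -> float:
    """Quadratic-space affine-gap DP oracle (gap run of length L costs
    gap_open + L*gap_extend); independent of the aligner under test."""
    INF = float("inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), INF)
    X = np.full((n + 1, m + 1), INF)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), INF)  # gap in a (consuming b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = 0.0 if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = min(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = min(M[i - 1][j] + gap_open + gap_extend, X[i - 1][j] + gap_extend)
            Y[i][j] = min(M[i][j - 1] + gap_open + gap_extend, Y[i][j - 1] + gap_extend)
    return min(M[n][m], X[n][m], Y[n][m])


def alignment_cost(aln, mismatch=1.0, gap_open=5.0, gap_extend=1.0) -> float:
    cost = aln.mismatches * mismatch
    for run in aln.gap_runs:
        cost += gap_open + run.length * gap_extend
    return cost


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.matches == 4 and aln.mismatches == 0 and not aln.gap_runs

    def test_single_deletion(self):
        aln = global_align("ACGT", "AGT")
        assert len(aln.gap_runs) == 1
        assert aln.gap_runs[0].sequence == "b" and aln.gap_runs[0].length == 1

    def test_ungapping_recovers_inputs(self, rng):
        a, b = random_dna(rng, 60), random_dna(rng, 55)
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_matches_bruteforce_dp_on_short_pairs(self, rng):
        for _ in range(40):
            a = random_dna(rng, int(rng.integers(1, 31)))
            b = random_dna(rng, int(rng.integers(1, 31)))
            aln = global_align(a, b)
            assert alignment_cost(aln) == pytest.approx(gotoh_cost(a, b))

    def test_matches_oracle_on_mutated_pairs(self, rng):
        # related sequences (the regime divergence runs in), not just random
        for _ in range(10):
            a = list(random_dna(rng, 25))
            b = list(a)
            for pos in rng.choice(len(b), size=3, replace=False):
                b[int(pos)] = "ACGT"[int(rng.integers(4))]
            del b[5:8]
            a, b = "".join(a), "".join(b)
            assert alignment_cost(global_align(a, b)) == pytest.approx(gotoh_cost(a, b))


class TestDivergence:
    def test_identical_is_zero(self, rng):
        s = random_dna(rng, 200)
        assert pairwise_divergence(s, s) == 0.0

    def test_one_mismatch_in_200(self, rng):
        a = random_dna(rng, 200)
        b = a[:100] + ("A" if a[100] != "A" else "C") + a[101:]
        assert pairwise_divergence(a, b) == pytest.approx(0.005)

    def test_insertion_does_not_inflate_divergence(self, rng):
        a = random_dna(rng, 500)
        b = a[:250] + random_dna(rng, 48) + a[250:]
        assert pairwise_divergence(a, b) == 0.0

    def test_symmetry(self, rng):
        a, b = random_dna(rng, 150), random_dna(rng, 140)
        assert pairwise_divergence(a, b) == pytest.approx(pairwise_divergence(b, a))


class TestClustering:
    def _mutate(self, rng, seq, n):
        out = list(seq)
        for pos in rng.choice(len(seq), size=n, replace=False):
            current = out[int(pos)]
            out[int(pos)] = "ACGT"[("ACGT".index(current) + 1) % 4]
        return "".join(out)

    def test_chaining_single_linkage(self, rng):
        a = random_dna(rng, 1000)
        b = self._mutate(rng, a, 5)    # 0.5% from a
        c = self._mutate(rng, b, 5)    # 0.5% from b, ~1% from a
        ts = [Transcript("A", a), Transcript("B", b), Transcript("C", c)]
        clusters = single_linkage_cluster(ts)
        assert len(clusters) == 1
        assert clusters[0].member_ids == sorted(["A", "B", "C"], key=lambda i: (-1000, i))

    def test_distant_sequences_are_singletons(self, rng):
        ts = [Transcript(f"t{i}", random_dna(rng, 500)) for i in range(4)]
        clusters = single_linkage_cluster(ts)
        assert len(clusters) == 4
        assert all(c.letters == [None] for c in clusters)

    def test_order_invariance_up_to_naming(self, rng):
        a = random_dna(rng, 800)
        ts = [
            Transcript("A", a),
            Transcript("B", self._mutate(rng, a, 3)),
            Transcript("C", random_dna(rng, 800)),
        ]
        c1 = single_linkage_cluster(ts)
        c2 = single_linkage_cluster(ts[::-1])
        sets1 = sorted(frozenset(c.member_ids) for c in c1)
        sets2 = sorted(frozenset(c.member_ids) for c in c2)
        assert sets1 == sets2

    def test_cluster_count_monotone_in_threshold(self, rng):
        a = random_dna(rng, 600)
        ts = [Transcript("A", a), Transcript("B", self._mutate(rng, a, 9))]
        n_tight = len(single_linkage_cluster(ts, ClusterConfig(divergence_threshold=0.005)))
        n_loose = len(single_linkage_cluster(ts, ClusterConfig(divergence_threshold=0.05)))
        assert n_loose <= n_tight

    def test_members_ordered_by_length_then_lettered(self, rng):
        a = random_dna(rng, 600)
        b = self._mutate(rng, a, 2) + "ACGTAC"   # longer variant
        clusters = single_linkage_cluster([Transcript("A", a), Transcript("B", b)])
        (c,) = clusters
        assert c.member_ids == ["B", "A"]
        assert c.letters == ["a", "b"]
        assert c.representative.id == "B"


class TestNaming:
    def _cluster_fixture(self, rng, label, n):
        a = random_dna(rng, 400)
        ts = [Transcript(f"{label}{i}", a, class_label=label) for i in range(n)]
        return single_linkage_cluster(ts)

    def test_class_numbering(self, rng):
        a, b = random_dna(rng, 400), random_dna(rng, 400)
        ts = [Transcript("x", a, class_label="CTL"), Transcript("y", b, class_label="CTL")]
        named = name_clusters(single_linkage_cluster(ts))
        assert sorted(c.name for c in named) == ["CTL-1", "CTL-2"]

    def test_three_member_letters(self, rng):
        named = name_clusters(self._cluster_fixture(rng, "SVSP", 3))
        (c,) = named
        assert c.letters == ["a", "b", "c"]

    def test_mixed_class_cluster_is_error(self, rng):
        a = random_dna(rng, 400)
        ts = [Transcript("x", a, class_label="CTL"), Transcript("y", a, class_label="SVSP")]
        with pytest.raises(ValueError, match="mixed"):
            name_clusters(single_linkage_cluster(ts))


class TestIndelProfile:
    def test_identical_sequences_no_gaps(self, rng):
        s = random_dna(rng, 300)
        assert indel_profile(s, s) == []

    @pytest.mark.parametrize("gap_len", [27, 132])
    def test_single_block_deletion_reported_as_one_run(self, rng, gap_len):
        a = random_dna(rng, 700)
        b = a[:300] + a[300 + gap_len:]
        runs = indel_profile(a, b)
        assert len(runs) == 1
        assert runs[0].sequence == "b" and runs[0].length == gap_len


class TestAssignReads:
    def _refs(self, rng):
        return [Transcript(f"t{i}", random_dna(rng, 600)) for i in range(3)]

    def test_exact_read_assigned_to_source(self, rng):
        refs = self._refs(rng)
        read = NucleotideRead("r", refs[1].sequence[100:200], [40] * 100)
        counts = assign_reads([read], refs)
        assert counts.transcript_counts == {"t1": 1.0}

    def test_reverse_complement_read_assigned(self, rng):
        from venomxtend import reverse_complement

        refs = self._refs(rng)
        read = NucleotideRead("r", reverse_complement(refs[0].sequence[50:150]), [40] * 100)
        counts = assign_reads([read], refs)
        assert counts.transcript_counts == {"t0": 1.0}

    def test_high_error_read_unassigned(self, rng):
        refs = self._refs(rng)
        seq = list(refs[0].sequence[100:200])
        for pos in range(0, 100, 10):   # 10% corruption
            seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
        counts = assign_reads([NucleotideRead("r", "".join(seq), [40] * 100)], refs)
        assert counts.n_unassigned == 1

    def test_cross_cluster_tie_discarded(self, rng):
        shared = random_dna(rng, 200)
        refs = [
            Transcript("a", shared + random_dna(rng, 400)),
            Transcript("b", shared + random_dna(rng, 400)),
        ]
        read = NucleotideRead("r", shared[:100], [40] * 100)
        counts = assign_reads([read], refs)
        assert counts.n_ambiguous == 1 and counts.n_assigned == 0

    def test_fractional_tie_mode_splits(self, rng):
        shared = random_dna(rng, 200)
        refs = [
            Transcript("a", shared + random_dna(rng, 400)),
            Transcript("b", shared + random_dna(rng, 400)),
        ]
        read = NucleotideRead("r", shared[:100], [40] * 100)
        counts = assign_reads([read], refs, QuantConfig(fractional_ties=True))
        assert counts.transcript_counts == {"a": 0.5, "b": 0.5}

    def test_within_cluster_tie_counts_to_cluster(self, rng):
        shared = random_dna(rng, 600)
        refs = [Transcript("a", shared), Transcript("b", shared)]
        clusters = single_linkage_cluster(refs)
        read = NucleotideRead("r", shared[100:200], [40] * 100)
        counts = assign_reads([read], refs, clusters=clusters)
        assert counts.n_assigned == 1
        assert sum(counts.cluster_counts.values()) == 1.0

    def test_partition_sums_to_input(self, rng):
        refs = self._refs(rng)
        reads = [
            NucleotideRead(f"r{i}", refs[i % 3].sequence[i:i + 100], [40] * 100)
            for i in range(20)
        ] + [NucleotideRead("junk", random_dna(rng, 100), [40] * 100)]
        counts = assign_reads(reads, refs)
        assert counts.n_assigned + counts.n_ambiguous + counts.n_unassigned == 21

    def test_exact_provenance_at_full_identity(self, rng):
        import venomxtend as vx

        sim = vx.simulate_transcriptome(n_transcripts=7, n_clusters=0, rng_seed=11)
        cfg = vx.ReadSimConfig(n_pairs=300, rng_seed=11, error_rate_5p=0.0, error_rate_3p=0.0)
        r1, _, truth = vx.simulate_reads(sim, cfg)
        # adaptor-free reads only: short fragments pad R1 with adaptor bases,
        # which legitimately fail 100% identity
        keep = [i for i, rec in enumerate(truth) if rec.adaptor_r1 == 0]
        counts = assign_reads([r1[i] for i in keep], sim.transcripts,
                              QuantConfig(min_identity=1.0))
        want = {}
        for i in keep:
            rec = truth.records[i]
            want[rec.source_id] = want.get(rec.source_id, 0) + 1
        assert counts.transcript_counts == pytest.approx(want)


class TestAbundanceTable:
    def test_percentages(self):
        df = abundance_table({"A": 50, "B": 50}, 200, {"A": True, "B": True})
        assert df["pct_total_reads"].tolist() == [25.0, 25.0]
        assert df["pct_toxin_reads"].tolist() == [50.0, 50.0]

    def test_single_toxin_target(self):
        df = abundance_table({"A": 10}, 100, {"A": True})
        assert df["pct_toxin_reads"].iloc[0] == 100.0

    def test_toxin_percentages_normalize(self, rng):
        counts = {f"t{i}": int(rng.integers(1, 500)) for i in range(12)}
        flags = {t: i % 2 == 0 for i, t in enumerate(counts)}
        df = abundance_table(counts, 10000, flags)
        assert df.loc[df["toxin"], "pct_toxin_reads"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_sorted_within_partitions_and_ranked(self):
        df = abundance_table(
            {"A": 5, "B": 20, "C": 10, "D": 1}, 100,
            {"A": True, "B": True, "C": False, "D": False},
        )
        assert df["target"].tolist() == ["B", "A", "C", "D"]
        assert df["rank"].tolist() == [1, 2, 1, 2]

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            abundance_table({"A": 1}, 0, {})
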