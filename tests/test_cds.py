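import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import sialotools as st
from sialotools.cds import (STOP_CODONS, pairwise_identity, revcomp,
                            translate)


# ---------------------------------------------------------------------------
# independent six-frame brute-force oracle

CODON_AA = {}
for a in "ACGT":
    for b in "ACGT":
        for c in "ACGT":
            CODON_AA[a + b + c] = None  # filled from Bio below
from Bio.Seq import Seq  # noqa: E402
for codon in list(CODON_AA):
    CODON_AA[codon] = str(Seq(codon).translate())


def orf_oracle(seq, min_nt):
    """Enumerate stop-delimited segments in all 6 frames by direct scan.

    A segment qualifies if it abuts at least one stop codon and spans
    >= min_nt nucleotides (terminal stop included).
    """
    found = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, L - 2, 3)]
            stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
            bounds = [-1] + stops + [len(codons)]
            for prev, nxt in zip(bounds, bounds[1:]):
                if prev == -1 and nxt == len(codons):
                    continue  # never interrupted by a stop
                first, last = prev + 1, nxt - 1
                if last < first:
                    continue
                has_stop = nxt < len(codons)
                nt_s = frame + 3 * first
                nt_e = frame + 3 * (nxt + 1) if has_stop else frame + 3 * len(codons)
                if nt_e - nt_s < min_nt:
                    continue
                if strand == "-":
                    nt_s, nt_e = L - nt_e, L - nt_s
                found.add((strand, nt_s, nt_e, has_stop))
    return found


def random_nt(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFindOrfs:
    def test_minimal_met_orf(self):
        orfs = st.find_orfs(st.SeqRecord("t", "ATGAAATAA"), min_nt=9)
        assert len(orfs) == 1
        (o,) = orfs
        assert (o.strand, o.aa_seq, o.has_terminal_stop) == ("+", "MK", True)
        assert (o.nt_start, o.nt_end) == (0, 9)
        assert o.met_positions == [0]

    def test_below_length_threshold(self):
        assert st.find_orfs(st.SeqRecord("t", "ATGAAATAA"), min_nt=150) == []

    def test_non_nt_alphabet_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            st.find_orfs(st.SeqRecord("t", "MKFL", kind="aa"), min_nt=9)

    def test_matches_oracle_on_2kb(self):
        rng = np.random.default_rng(42)
        seq = random_nt(rng, 2000)
        got = {(o.strand, o.nt_start, o.nt_end, o.has_terminal_stop)
               for o in st.find_orfs(st.SeqRecord("t", seq), min_nt=150)}
        assert got == orf_oracle(seq, 150)

    @given(hst.text(alphabet="ACGT", min_size=1, max_size=400),
           hst.sampled_from([3, 30, 90, 150]))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_oracle_property(self, seq, min_nt):
        got = {(o.strand, o.nt_start, o.nt_end, o.has_terminal_stop)
               for o in st.find_orfs(st.SeqRecord("t", seq), min_nt=min_nt)}
        assert got == orf_oracle(seq, min_nt)

    @given(hst.text(alphabet="ACGT", min_size=30, max_size=300))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_revcomp_symmetry(self, seq):
        """ORFs of the reverse complement are the mirrored, strand-swapped
        ORFs of the forward sequence."""
        L = len(seq)
        fwd = st.find_orfs(st.SeqRecord("t", seq), min_nt=30)
        rev = st.find_orfs(st.SeqRecord("t", revcomp(seq)), min_nt=30)
        mirrored = {("-" if o.strand == "+" else "+",
                     L - o.nt_end, L - o.nt_start) for o in fwd}
        assert {(o.strand, o.nt_start, o.nt_end) for o in rev} == mirrored

    @given(hst.text(alphabet="ACGT", min_size=9, max_size=300))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariants(self, seq):
        for o in st.find_orfs(st.SeqRecord("t", seq), min_nt=9):
            span = o.nt_end - o.nt_start
            assert span % 3 == 0
            assert len(o.aa_seq) == span // 3 - (1 if o.has_terminal_stop else 0)
            assert o.met_positions == sorted(o.met_positions)
            assert translate(o.coding_nt) == o.aa_seq

    def test_require_met_drops_metless(self):
        # segment AAA...TAA has no Met
        seq = "AAAAAATAA"
        assert st.find_orfs(st.SeqRecord("t", seq), 9, require_met=False)
        kept = st.find_orfs(st.SeqRecord("t", seq), 9, require_met=True)
        assert all(o.met_positions for o in kept)


class TestHomologyRoute:
    def _orf(self):
        rec = st.SeqRecord("t1", "ATG" + "GCT" * 80 + "TAA")
        (o,) = [o for o in st.find_orfs(rec, 150) if o.strand == "+"]
        return o

    def test_coverage_above_threshold_promotes(self, hit_factory):
        hit = hit_factory(query_id="t1", sstart=1, send=160, slen=200)
        out = st.extract_cds_by_homology([self._orf()], [hit], 0.70)
        assert len(out) == 1
        assert out[0].start_anchor == "homology"

    def test_coverage_below_threshold_skipped(self, hit_factory):
        hit = hit_factory(query_id="t1", sstart=1, send=120, slen=200)
        assert st.extract_cds_by_homology([self._orf()], [hit], 0.70) == []

    def test_bitscore_breaks_ties_not_coverage(self, hit_factory):
        """Among qualifying hits the best bitscore is the evidence even
        when another hit has higher coverage."""
        h1 = hit_factory(query_id="t1", subject_id="hi-score",
                         sstart=1, send=150, slen=200, bitscore=90)
        h2 = hit_factory(query_id="t1", subject_id="hi-cov",
                         sstart=1, send=190, slen=200, bitscore=50)
        out = st.extract_cds_by_homology([self._orf()], [h1, h2], 0.70)
        assert out[0].evidence.subject_id == "hi-score"

    def test_unknown_transcript_hit_skipped(self, hit_factory, caplog):
        hit = hit_factory(query_id="ghost", sstart=1, send=160, slen=200)
        out = st.extract_cds_by_homology([self._orf()], [hit], 0.70)
        assert out == []

    def test_orf_not_trimmed_to_hit(self, hit_factory):
        orf = self._orf()
        hit = hit_factory(query_id="t1", qstart=10, qend=60,
                          sstart=1, send=180, slen=200)
        out = st.extract_cds_by_homology([orf], [hit], 0.70)
        assert out[0].aa_seq == orf.aa_seq


class TestSignalAnchor:
    def _orf_with_mets(self):
        aa = "M" + "A" * 9 + "M" + "A" * 49
        rec = st.SeqRecord("t1", "ATG" + "GCT" * 9 + "ATG" + "GCT" * 49 + "TAA")
        (o,) = [o for o in st.find_orfs(rec, 150) if o.strand == "+"]
        assert o.aa_seq == aa and o.met_positions == [0, 10]
        return o

    @staticmethod
    def _pred(has_sp):
        return st.SignalPrediction("q", has_sp, 14 if has_sp else None)

    def test_most_5prime_positive_met_wins(self):
        o = self._orf_with_mets()
        cds = st.anchor_start_by_sp(o, {0: self._pred(True), 10: self._pred(True)})
        assert cds.aa_seq.startswith("MAAAAAAAAAM")
        assert cds.start_anchor == "signal_peptide"

    def test_only_positive_candidate_selected(self):
        o = self._orf_with_mets()
        cds = st.anchor_start_by_sp(o, {0: self._pred(False), 10: self._pred(True)})
        assert cds.aa_seq == o.aa_seq[10:]

    def test_no_positive_returns_none(self):
        o = self._orf_with_mets()
        assert st.anchor_start_by_sp(o, {0: self._pred(False)}) is None

    def test_translation_consistency(self):
        o = self._orf_with_mets()
        cds = st.anchor_start_by_sp(o, {10: self._pred(True)})
        assert translate(cds.nt_seq) == cds.aa_seq


class TestMergeSources:
    @staticmethod
    def _cds(i, source="denovo", seq="ATGGCTGCT"):
        return st.CodingSequence(i, source, seq, translate(seq))

    def test_disjoint_union(self):
        out = st.merge_cds_sources(
            [self._cds(f"d{i}") for i in range(3)],
            [self._cds(f"g{i}") for i in range(2)],
            [self._cds("v0")])
        assert len(out) == 6

    def test_genome_wins_collision(self):
        out = st.merge_cds_sources([self._cds("x", seq="ATGAAAGCT")],
                                   [self._cds("x", seq="ATGGGGGCT")], [])
        assert len(out) == 1
        assert out[0].source == "genome"
        assert out[0].nt_seq == "ATGGGGGCT"

    def test_viral_beats_denovo(self):
        out = st.merge_cds_sources([self._cds("x", seq="ATGAAAGCT")], [],
                                   [self._cds("x", seq="ATGGGGGCT")])
        assert out[0].source == "viral"

    def test_within_source_collision_is_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            st.merge_cds_sources([self._cds("x"), self._cds("x")], [], [])


def greedy_oracle(seqs, threshold):
    """All-pairs identity matrix + direct greedy clustering."""
    ids = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    reps, clusters = [], {}
    for i in ids:
        for r in reps:
            if pairwise_identity(seqs[i], seqs[r]) >= threshold:
                clusters[r].append(i)
                break
        else:
            reps.append(i)
            clusters[i] = [i]
    return {r: sorted(m) for r, m in clusters.items()}


class TestConsolidation:
    @staticmethod
    def _cds(i, seq):
        return st.CodingSequence(i, "denovo", seq, "")

    def test_identical_pair_keeps_first_id(self):
        reps, rep_report = st.consolidate_identity(
            [self._cds("b", "ATGGCTAAA"), self._cds("a", "ATGGCTAAA")], 0.95)
        assert [r.id for r in reps] == ["a"]
        assert dict(rep_report.clusters) == {"a": ["a", "b"]}

    def test_90pct_pair_not_merged_at_95(self):
        rng = np.random.default_rng(1)
        s1 = random_nt(rng, 100)
        s2 = list(s1)
        for pos in rng.choice(100, 10, replace=False):
            s2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[pos]]
        reps, _ = st.consolidate_identity(
            [self._cds("a", s1), self._cds("b", "".join(s2))], 0.95)
        assert len(reps) == 2

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        seqs = {}
        for i in range(10):
            base = random_nt(rng, int(rng.integers(120, 300)))
            seqs[f"s{i}"] = base
            # plant two ~96%-identity variants of each base
            for j in range(2):
                var = list(base)
                n_mut = max(1, int(0.04 * len(base)))
                for pos in rng.choice(len(base), n_mut, replace=False):
                    var[pos] = "ACGT"[rng.integers(0, 4)]
                seqs[f"s{i}v{j}"] = "".join(var)
        cds = [self._cds(i, s) for i, s in seqs.items()]
        reps, report = st.consolidate_identity(cds, 0.95)
        got = {r: sorted(m) for r, m in report.clusters}
        assert got == greedy_oracle(seqs, 0.95)

    def test_partition_and_threshold_invariants(self):
        rng = np.random.default_rng(3)
        seqs = {f"x{i}": random_nt(rng, 150) for i in range(8)}
        seqs["x0dup"] = seqs["x0"]
        cds = [self._cds(i, s) for i, s in seqs.items()]
        reps, report = st.consolidate_identity(cds, 0.95)
        members = [m for _, ms in report.clusters for m in ms]
        assert sorted(members) == sorted(seqs)  # a partition
        rep_ids = [r.id for r in reps]
        for i, a in enumerate(rep_ids):
            for b in rep_ids[i + 1:]:
                assert pairwise_identity(seqs[a], seqs[b]) < 0.95
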