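"""Alignment, identity, clustering and representative-selection behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vtaxa import seqops
from vtaxa.seqops import Alignment, OTU, SequenceRecord


def brute_force_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Exhaustive recursion over all global alignments (tiny inputs only)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = seqops.global_align(SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT"))
        assert aln.score == 4.0
        assert aln.rows == ["ACGT", "ACGT"]

    def test_one_gap_matches_exhaustive_enumeration(self):
        aln = seqops.global_align(SequenceRecord("a", "ACGT"), SequenceRecord("b", "AGT"))
        assert aln.score == brute_force_score("ACGT", "AGT") == 1.0
        assert sum(r.count("-") for r in aln.rows) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_score_matches_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            a = "".join(rng.choice(bases, rng.integers(1, 7)))
            b = "".join(rng.choice(bases, rng.integers(1, 7)))
            got = seqops.global_align(SequenceRecord("a", a), SequenceRecord("b", b)).score
            assert got == brute_force_score(a, b)

    def test_score_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            a = "".join(rng.choice(bases, rng.integers(5, 30)))
            b = "".join(rng.choice(bases, rng.integers(5, 30)))
            ra, rb = SequenceRecord("a", a), SequenceRecord("b", b)
            assert seqops.global_align(ra, rb).score == seqops.global_align(rb, ra).score

    def test_score_matches_biopython(self, rng):
        """Independent check of optimal scores against Bio.Align."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, rng.integers(10, 60)))
            b = "".join(rng.choice(bases, rng.integers(10, 60)))
            got = seqops.global_align(SequenceRecord("a", a), SequenceRecord("b", b)).score
            assert got == aligner.score(a, b)

    def test_alignment_roundtrip_recovers_inputs(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 40))
        b = "".join(rng.choice(bases, 25))
        aln = seqops.global_align(SequenceRecord("a", a), SequenceRecord("b", b))
        assert aln.degapped(0) == a
        assert aln.degapped(1) == b

    def test_invalid_character_names_id_and_position(self):
        from types import SimpleNamespace

        bad = SimpleNamespace(id="bad_seq", seq="ACXT")  # bypass ctor validation
        with pytest.raises(ValueError, match="bad_seq.*position 2"):
            seqops.global_align(bad, SequenceRecord("ok", "ACGT"))

    def test_invalid_character_at_construction(self):
        with pytest.raises(ValueError, match="position 1"):
            SequenceRecord("x", "AXGT")


class TestPairwiseIdentity:
    def test_identical(self):
        aln = Alignment(ids=["a", "b"], rows=["ACGT", "ACGT"])
        assert seqops.pairwise_identity(aln) == 1.0

    def test_internal_gap_counts_as_mismatch(self):
        aln = Alignment(ids=["a", "b"], rows=["AC-GT", "ACCGT"])
        assert seqops.pairwise_identity(aln) == pytest.approx(4 / 5)

    def test_terminal_gaps_excluded(self):
        aln = Alignment(ids=["a", "b"], rows=["--ACGT", "TTACGT"])
        assert seqops.pairwise_identity(aln) == 1.0

    def test_one_gap_per_run_policy(self):
        aln = Alignment(ids=["a", "b"], rows=["A--CGT", "ATTCGT"])
        assert seqops.pairwise_identity(aln, mode="each-gap") == pytest.approx(4 / 6)
        assert seqops.pairwise_identity(aln, mode="one-gap-per-run") == pytest.approx(4 / 5)

    def test_identity_in_unit_interval(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(30):
            a = "".join(rng.choice(bases, rng.integers(5, 25)))
            b = "".join(rng.choice(bases, rng.integers(5, 25)))
            ident = seqops.sequence_identity(SequenceRecord("a", a), SequenceRecord("b", b))
            assert 0.0 <= ident <= 1.0


class TestDistanceMatrix:
    def test_identical_pair_zero_distance(self):
        recs = [SequenceRecord("a", "ACGTACGT"), SequenceRecord("b", "ACGTACGT")]
        dm = seqops.distance_matrix(recs)
        assert dm["a", "b"] == 0.0

    def test_matches_per_pair_recomputation(self, rng):
        bases = np.array(list("ACGT"))
        recs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(bases, 30))) for i in range(5)
        ]
        dm = seqops.distance_matrix(recs)
        for a, b in itertools.combinations(recs, 2):
            expected = 1.0 - seqops.sequence_identity(a, b)
            assert dm[a.id, b.id] == pytest.approx(expected)

    def test_duplicate_ids_rejected(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("a", "AGGT")]
        with pytest.raises(ValueError, match="duplicate"):
            seqops.distance_matrix(recs)


class TestCenterStarMSA:
    def test_identical_inputs_no_gaps(self):
        recs = [SequenceRecord(f"s{i}", "ACGTACGT") for i in range(3)]
        msa = seqops.center_star_msa(recs)
        assert all("-" not in r for r in msa.rows)

    def test_center_is_argmin_of_row_sums(self):
        recs = [
            SequenceRecord("a", "ACGTACGTAA"),
            SequenceRecord("b", "ACGTACGTAT"),
            SequenceRecord("c", "ACGAACCTAT"),
        ]
        dm = seqops.distance_matrix(recs)
        center = dm.ids[int(np.argmin(dm.data.sum(axis=1)))]
        msa = seqops.center_star_msa(recs)
        assert msa.ids[0] == center

    def test_degap_roundtrip_and_width(self, rng):
        bases = np.array(list("ACGT"))
        recs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(bases, int(rng.integers(20, 35)))))
            for i in range(5)
        ]
        msa = seqops.center_star_msa(recs)
        by_id = {r.id: r.seq for r in recs}
        for i, rid in enumerate(msa.ids):
            assert msa.degapped(i) == by_id[rid]
        assert msa.n_cols >= max(len(r.seq) for r in recs)

    def test_msa_fasta_roundtrip(self, rng, tmp_path):
        from Bio import SeqIO

        bases = np.array(list("ACGT"))
        recs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(bases, int(rng.integers(20, 30)))))
            for i in range(4)
        ]
        msa = seqops.center_star_msa(recs)
        seqops.write_msa_fasta(msa, tmp_path / "aln.fa")
        back = list(SeqIO.parse(str(tmp_path / "aln.fa"), "fasta"))
        assert [r.id for r in back] == msa.ids
        assert [str(r.seq) for r in back] == msa.rows

    def test_roundtrip_with_indels(self):
        from vtaxa import synthetic_data as sd

        cfg = sd.SynthConfig(
            n_taxa=3, members_per_taxon=3, seq_length=120,
            intra_mut=0.03, inter_div=0.2, indel_rate=0.02, seed=9,
        )
        recs, _ = sd.generate_taxa(cfg)
        msa = seqops.center_star_msa(recs)
        by_id = {r.id: r.seq for r in recs}
        for i, rid in enumerate(msa.ids):
            assert msa.degapped(i) == by_id[rid]


class TestClusterOtus:
    def _fixture(self):
        # 6 sequences, 2 tight groups + 1 intermediate
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        anc1 = rng.choice(bases, 100)
        anc2 = rng.choice(bases, 100)
        recs = []
        for k, anc in enumerate((anc1, anc2)):
            for j in range(3):
                seq = anc.copy()
                pos = rng.choice(100, size=j, replace=False)
                for p in pos:
                    seq[p] = bases[(np.where(bases == seq[p])[0][0] + 1) % 4]
                recs.append(SequenceRecord(f"g{k}s{j}", "".join(seq)))
        return recs

    def test_threshold_zero_gives_singletons_except_duplicates(self):
        recs = self._fixture() + [SequenceRecord("dup", self._fixture()[0].seq)]
        dm = seqops.distance_matrix(recs)
        otus = seqops.cluster_otus(dm, threshold=0.0)
        sizes = sorted(len(o.members) for o in otus)
        assert sizes == [1, 1, 1, 1, 1, 2]

    def test_threshold_one_gives_single_otu(self):
        dm = seqops.distance_matrix(self._fixture())
        otus = seqops.cluster_otus(dm, threshold=1.0)
        assert len(otus) == 1

    def test_matches_scipy_hierarchical_oracle(self):
        """Average-linkage cut agrees with scipy's independent implementation."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        dm = seqops.distance_matrix(self._fixture())
        threshold = 0.03
        Z = linkage(squareform(dm.data, checks=False), method="average")
        flat = fcluster(Z, t=threshold, criterion="distance")
        oracle = {}
        for lab, cl in zip(dm.ids, flat):
            oracle.setdefault(cl, set()).add(lab)
        got = {frozenset(o.members) for o in seqops.cluster_otus(dm, threshold)}
        assert got == {frozenset(s) for s in oracle.values()}

    def test_partition_and_monotonicity(self):
        recs = self._fixture()
        dm = seqops.distance_matrix(recs)
        prev = None
        for t in (0.0, 0.01, 0.03, 0.1, 0.5, 1.0):
            otus = seqops.cluster_otus(dm, threshold=t)
            members = sorted(m for o in otus for m in o.members)
            assert members == sorted(r.id for r in recs)  # partition
            if prev is not None:
                assert len(otus) <= prev  # monotone in threshold
            prev = len(otus)


class TestPickRepresentative:
    def test_singleton(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.zeros((1, 1)), ["a"])
        assert seqops.pick_representative(OTU("o", ["a"], "a"), dm) == "a"

    def test_argmin_of_row_sums(self):
        from skbio import DistanceMatrix

        d = np.array([[0, 0.1, 0.1], [0.1, 0, 0.3], [0.1, 0.3, 0]])
        dm = DistanceMatrix(d, ["A", "B", "C"])
        assert seqops.pick_representative(OTU("o", ["A", "B", "C"], "A"), dm) == "A"

    def test_tie_breaks_lexicographically(self):
        from skbio import DistanceMatrix

        d = np.array([[0, 0.2], [0.2, 0]])
        dm = DistanceMatrix(d, ["b", "a"])
        assert seqops.pick_representative(OTU("o", ["a", "b"], "a"), dm) == "a"


@settings(max_examples=30, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=8))
def test_self_alignment_is_perfect(seq):
    rec = SequenceRecord("x", seq)
    aln = seqops.global_align(rec, SequenceRecord("y", seq))
    assert aln.score == len(seq)
    assert seqops.pairwise_identity(aln) == 1.0
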