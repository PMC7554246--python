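import numpy as np
import pytest

from ubisite import seq_data
from ubisite.seq_data import (
    NEGATIVE,
    POSITIVE,
    ProteinRecord,
    SiteFragment,
    balance_and_split,
    cluster_reduce,
    extract_fragments,
    pairwise_identity,
    read_dataset_tsv,
    read_fasta,
    read_sites_tsv,
    write_dataset_tsv,
    write_sites_tsv,
)


class TestReadFasta:
    @pytest.mark.parametrize(
        "text, expected",
        [
            (">p1\nMKV\n", [("p1", "MKV")]),
            (">p1\nMK\nVK\n", [("p1", "MKVK")]),  # wrapped lines join
            (">p1\nMKV\n>p2\nACD\n", [("p1", "MKV"), ("p2", "ACD")]),
        ],
    )
    def test_parsing(self, tmp_path, text, expected):
        path = tmp_path / "in.fasta"
        path.write_text(text)
        records = read_fasta(path)
        assert [(r.id, r.sequence) for r in records] == expected

    def test_normalization_maps_nonstandard_to_x(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">p1\nmkuv\n")
        with pytest.warns(UserWarning, match="non-standard"):
            records = read_fasta(path)
        assert records[0].sequence == "MKXV"

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(path)

    def test_roundtrip_through_write_fasta(self, tmp_path):
        records = [ProteinRecord("a", "MKV" * 30), ProteinRecord("b", "ACDK")]
        path = tmp_path / "out.fasta"
        seq_data.write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in records
        ]


class TestExtractFragments:
    def test_lone_lysine_is_fully_padded(self):
        frags = extract_fragments(ProteinRecord("p", "K"), {1}, window=31)
        assert len(frags) == 1
        assert frags[0].sequence == "X" * 15 + "K" + "X" * 15
        assert frags[0].label == POSITIVE

    def test_fully_flanked_lysine_needs_no_padding(self):
        seq = "A" * 15 + "K" + "C" * 15
        frags = extract_fragments(ProteinRecord("p", seq), {16}, window=31)
        assert len(frags) == 1
        assert frags[0].sequence == seq

    def test_padding_of_short_protein(self):
        # K at position 4 of "ACDK": 12 pad + ACD before K, 15 pad after
        frags = extract_fragments(ProteinRecord("p", "ACDK"), set(), window=31)
        assert len(frags) == 1
        frag = frags[0]
        assert frag.sequence == "X" * 12 + "ACD" + "K" + "X" * 15
        assert len(frag.sequence) == 31
        assert frag.sequence[15] == "K"
        assert frag.label == NEGATIVE

    def test_one_fragment_per_lysine_with_correct_labels(self, toy_protein):
        # toy_protein = MKVACDKWKLL: K at 2, 7, 9
        frags = extract_fragments(toy_protein, {7}, window=5)
        assert [f.center_position for f in frags] == [2, 7, 9]
        assert [f.label for f in frags] == [NEGATIVE, POSITIVE, NEGATIVE]
        assert all(f.sequence[2] == "K" and len(f.sequence) == 5 for f in frags)

    def test_non_lysine_annotation_is_skipped_with_warning(self, toy_protein):
        with pytest.warns(UserWarning, match="annotation mismatch"):
            frags = extract_fragments(toy_protein, {3}, window=5)
        assert all(f.label == NEGATIVE for f in frags)

    @pytest.mark.parametrize("window", [2, 1, -3, 4])
    def test_bad_window_rejected(self, toy_protein, window):
        with pytest.raises(ValueError, match="window"):
            extract_fragments(toy_protein, set(), window)


class TestClusterReduce:
    def _frag(self, seq):
        return SiteFragment("p", 16, seq, NEGATIVE)

    def test_identical_fragments_collapse(self):
        f = self._frag("A" * 15 + "K" + "C" * 15)
        assert len(cluster_reduce([f, f], 0.99)) == 1

    def test_one_mismatch_still_clusters_at_30_percent(self):
        a = "A" * 15 + "K" + "C" * 15
        b = "G" + a[1:]
        assert pairwise_identity(a, b) == pytest.approx(30 / 31)
        assert len(cluster_reduce([self._frag(a), self._frag(b)], 0.30)) == 1

    def test_low_identity_founds_new_cluster(self):
        # agree at exactly 5 of 31 positions: identity ~16.1% < 30%
        a = "ACDEF" + "G" * 26
        b = "ACDEF" + "H" * 26
        assert pairwise_identity(a, b) == pytest.approx(5 / 31)
        reps = cluster_reduce([self._frag(a), self._frag(b)], 0.30)
        assert len(reps) == 2

    def test_pad_symbol_never_counts_as_match(self):
        a = "X" * 15 + "K" + "X" * 15
        b = "X" * 15 + "K" + "X" * 15
        # identical strings, but only the K column is a real match: 1/31 < 30%
        assert pairwise_identity(a, b) == pytest.approx(1 / 31)
        assert len(cluster_reduce([self._frag(a), self._frag(b)], 0.30)) == 2

    def test_idempotent(self, rng):
        seqs = [
            "".join(rng.choice(list("ACDK"), size=31)) for _ in range(50)
        ]
        frags = [self._frag(s) for s in seqs]
        once = cluster_reduce(frags, 0.5)
        twice = cluster_reduce(once, 0.5)
        assert [f.sequence for f in once] == [f.sequence for f in twice]

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            cluster_reduce([self._frag("AK" + "C" * 29), self._frag("AKC")], 0.3)


class TestBalanceAndSplit:
    def _frags(self, n, label, tag):
        return [
            SiteFragment(f"{tag}{i}", 16, "A" * 15 + "K" + "C" * 15, label)
            for i in range(n)
        ]

    def test_balancing_and_holdout_sizes(self):
        split = balance_and_split(
            self._frags(3500, POSITIVE, "p"),
            self._frags(10000, NEGATIVE, "n"),
            test_size=1500,
            seed=7,
        )
        assert len(split.train) + len(split.test) == 7000
        assert len(split.test) == 1500
        assert len(split.train) == 5500

    def test_labels_balanced_within_one(self):
        split = balance_and_split(
            self._frags(101, POSITIVE, "p"),
            self._frags(300, NEGATIVE, "n"),
            test_size=41,
            seed=1,
        )
        for part in (split.train, split.test):
            assert abs(part.n_positive - part.n_negative) <= 1

    def test_disjoint_and_exhaustive(self):
        pos = self._frags(50, POSITIVE, "p")
        neg = self._frags(80, NEGATIVE, "n")
        split = balance_and_split(pos, neg, test_size=20, seed=3)
        train_ids = {f.protein_id for f in split.train.fragments}
        test_ids = {f.protein_id for f in split.test.fragments}
        assert not train_ids & test_ids
        assert len(split.train) + len(split.test) == 100

    def test_seed_reproducibility(self):
        pos = self._frags(60, POSITIVE, "p")
        neg = self._frags(90, NEGATIVE, "n")
        a = balance_and_split(pos, neg, 20, seed=42)
        b = balance_and_split(pos, neg, 20, seed=42)
        assert [f.protein_id for f in a.train.fragments] == [
            f.protein_id for f in b.train.fragments
        ]
        assert [f.protein_id for f in a.test.fragments] == [
            f.protein_id for f in b.test.fragments
        ]

    def test_fewer_negatives_than_positives_rejected(self):
        with pytest.raises(ValueError, match="negatives"):
            balance_and_split(
                self._frags(10, POSITIVE, "p"), self._frags(5, NEGATIVE, "n"), 2
            )

    def test_oversized_holdout_rejected(self):
        with pytest.raises(ValueError, match="test_size"):
            balance_and_split(
                self._frags(10, POSITIVE, "p"), self._frags(10, NEGATIVE, "n"), 20
            )


class TestTablesIO:
    def test_sites_roundtrip(self, tmp_path):
        sites = {"p1": {4, 16}, "p2": {7}}
        path = tmp_path / "sites.tsv"
        write_sites_tsv(sites, path)
        assert read_sites_tsv(path) == sites

    def test_dataset_roundtrip(self, tmp_path, toy_protein):
        frags = extract_fragments(toy_protein, {7}, window=31)
        ds = seq_data.FragmentDataset(frags)
        path = tmp_path / "data.tsv"
        write_dataset_tsv(ds, path)
        back = read_dataset_tsv(path)
        assert [
            (f.protein_id, f.center_position, f.sequence, f.label)
            for f in back.fragments
        ] == [
            (f.protein_id, f.center_position, f.sequence, f.label) for f in frags
        ]

    def test_counts_consistent_with_labels(self, toy_protein):
        ds = seq_data.FragmentDataset(extract_fragments(toy_protein, {7}, 31))
        assert ds.n_positive + ds.n_negative == len(ds)
        assert np.sum(ds.labels()) == ds.n_positive
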