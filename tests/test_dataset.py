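"""Dataset construction: loading, window extraction, similarity filtering,
splitting, and under-sampling."""

import numpy as np
import pytest

import metharg as m
from metharg.dataset import NEGATIVE, POSITIVE, UNLABELED


def _write_inputs(tmp_path, fasta_text, sites_text):
    fasta = tmp_path / "in.fasta"
    sites = tmp_path / "sites.tsv"
    fasta.write_text(fasta_text)
    sites.write_text(sites_text)
    return fasta, sites


class TestLoadAnnotatedProteins:
    def test_minimal_valid_input(self, tmp_path):
        fasta, sites = _write_inputs(
            tmp_path,
            ">p1\nAAAR" + "A" * 26 + "\n",
            "protein_id\tposition\n" "p1\t4\n",
        )
        proteins = m.load_annotated_proteins(fasta, sites)
        assert len(proteins) == 1
        assert proteins[0].methylated_positions == {4}

    def test_site_not_arginine_is_hard_error(self, tmp_path):
        fasta, sites = _write_inputs(
            tmp_path,
            ">p1\nAAAR" + "A" * 26 + "\n",
            "protein_id\tposition\np1\t3\n",
        )
        with pytest.raises(ValueError, match="position 3 of p1 is not R"):
            m.load_annotated_proteins(fasta, sites)

    def test_unknown_protein_id_is_hard_error(self, tmp_path):
        fasta, sites = _write_inputs(
            tmp_path,
            ">p1\nAAAR" + "A" * 26 + "\n",
            "protein_id\tposition\nmissing\t4\n",
        )
        with pytest.raises(ValueError, match="unknown protein"):
            m.load_annotated_proteins(fasta, sites)

    def test_out_of_range_site_is_hard_error(self, tmp_path):
        fasta, sites = _write_inputs(
            tmp_path,
            ">p1\nAAAR" + "A" * 26 + "\n",
            "protein_id\tposition\np1\t99\n",
        )
        with pytest.raises(ValueError, match="out of range"):
            m.load_annotated_proteins(fasta, sites)

    def test_short_fragment_dropped_with_warning(self, tmp_path, caplog):
        # 29 aa: below the minimum fragment length, silently excluded
        fasta, sites = _write_inputs(
            tmp_path,
            ">tiny\nAAAR" + "A" * 25 + "\n",
            "protein_id\tposition\n",
        )
        with caplog.at_level("WARNING"):
            proteins = m.load_annotated_proteins(fasta, sites)
        assert proteins == []
        assert "tiny" in caplog.text


class TestExtractWindows:
    def test_one_window_per_arginine_with_labels(self):
        seq = "AAAR" + "A" * 20 + "R" + "A" * 9  # R at 4 (annotated) and 25
        protein = m.AnnotatedProtein("p", seq, frozenset({4}))
        windows = m.extract_windows(protein, 7)
        assert len(windows) == seq.count("R")
        by_pos = {w.center_position: w for w in windows}
        assert by_pos[4].label == POSITIVE
        assert by_pos[4].peptide == "AAARAAA"
        assert by_pos[25].label == UNLABELED

    def test_left_padding_at_n_terminus(self):
        protein = m.AnnotatedProtein("p", "R" + "A" * 29)
        (w,) = m.extract_windows(protein, 7)
        assert w.peptide == "XXXRAAA"
        assert w.label == UNLABELED

    def test_right_padding_at_c_terminus(self):
        protein = m.AnnotatedProtein("p", "A" * 29 + "R")
        windows = m.extract_windows(protein, 7)
        assert windows[-1].peptide == "AAARXXX"

    def test_center_is_always_arginine(self, small_proteins):
        for protein in small_proteins[:10]:
            windows = m.extract_windows(protein, 19)
            assert len(windows) == protein.sequence.count("R")
            for w in windows:
                assert w.peptide[len(w) // 2] == "R"

    def test_even_window_length_rejected(self):
        protein = m.AnnotatedProtein("p", "A" * 15 + "R" + "A" * 15)
        with pytest.raises(ValueError):
            m.extract_windows(protein, 18)

    def test_nonstandard_residue_window_dropped(self, caplog):
        seq = "A" * 10 + "BR" + "A" * 10 + "R" + "A" * 10
        protein = m.AnnotatedProtein("p", seq)
        with caplog.at_level("WARNING"):
            windows = m.extract_windows(protein, 7)
        # the R adjacent to B is dropped; the distant R survives
        assert [w.center_position for w in windows] == [23]
        assert "nonstandard" in caplog.text


class TestWindowIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AAAA", "AAAT", 0.75),
            ("AAAX", "AAAA", 0.75),  # X matches nothing
            ("XXAX", "XXAX", 0.25),  # not even another X
            ("RGRG", "RGRG", 1.0),
        ],
    )
    def test_fractional_identity(self, a, b, expected):
        assert m.window_identity(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            m.window_identity("AAA", "AAAA")


def _windows(peptides, label=UNLABELED):
    L = len(peptides[0])
    return m.WindowDataset(
        L,
        [m.PeptideWindow(p, label, f"w{i}", 50) for i, p in enumerate(peptides)],
    )


class TestReduceRedundancy:
    def test_identical_pair_collapses(self):
        ds = _windows(["AARAA", "AARAA"])
        assert m.reduce_redundancy(ds, 0.4).peptides == ["AARAA"]

    def test_dissimilar_windows_all_retained(self):
        ds = _windows(["CCRCC", "DDRDD", "EEREE"])  # pairwise identity 0.2
        assert len(m.reduce_redundancy(ds, 0.4)) == 3

    def test_greedy_keeps_first_drops_similar(self):
        # id(w1,w2)=0.6 >= 0.4; id(w1,w3)=id(w2,w3)=0.2
        ds = _windows(["AARAA", "TARAT", "CCRCC"])
        assert m.reduce_redundancy(ds, 0.4).peptides == ["AARAA", "CCRCC"]

    def test_no_retained_pair_reaches_threshold(self):
        rng = np.random.default_rng(2)
        alphabet = list("AGRST")
        for _ in range(50):
            peptides = [
                "".join(rng.choice(alphabet, 2)) + "R" + "".join(rng.choice(alphabet, 2))
                for _ in range(rng.integers(1, 12))
            ]
            kept = m.reduce_redundancy(_windows(peptides), 0.4)
            assert set(kept.peptides) <= set(peptides)
            for i, a in enumerate(kept):
                for b in list(kept)[i + 1:]:
                    assert m.window_identity(a, b) < 0.4

    def test_bad_threshold_rejected(self):
        ds = _windows(["AARAA"])
        with pytest.raises(ValueError):
            m.reduce_redundancy(ds, 0.0)


class TestDeriveNegatives:
    def test_window_identical_to_positive_removed(self):
        unl = _windows(["AARAA", "CCRCC"])
        pos = _windows(["AARAA"], label=POSITIVE)
        out = m.derive_negatives(unl, pos, 0.4)
        assert out.peptides == ["CCRCC"]
        assert all(w.label == NEGATIVE for w in out)

    def test_matches_exhaustive_pairwise_filter(self):
        rng = np.random.default_rng(7)
        alphabet = list("AGRST")
        make = lambda: "".join(rng.choice(alphabet, 3)) + "R" + "".join(
            rng.choice(alphabet, 3)
        )
        unl = _windows([make() for _ in range(30)])
        pos = _windows([make() for _ in range(10)], label=POSITIVE)
        out = m.derive_negatives(unl, pos, 0.4)
        expected = [
            w.peptide
            for w in unl
            if max(m.window_identity(w, p) for p in pos) < 0.4
        ]
        assert out.peptides == expected

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            m.derive_negatives(_windows(["AARAA"]), _windows(["AAARAAA"]))


class TestSplitDataset:
    def _sets(self, n_pos=100, n_neg=500):
        rng = np.random.default_rng(1)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        make = lambda: "".join(rng.choice(alphabet, 3)) + "R" + "".join(
            rng.choice(alphabet, 3)
        )
        pos = _windows([make() for _ in range(n_pos)], label=POSITIVE)
        neg = _windows([make() for _ in range(n_neg)], label=NEGATIVE)
        return pos, neg

    def test_four_to_one_split_sizes(self):
        pos, neg = self._sets()
        train_pos, test_pos, train_neg, test_neg = m.split_dataset(pos, neg, seed=1)
        assert len(test_pos) == 20 and len(train_pos) == 80
        assert len(test_neg) == 20 and len(train_neg) == 480
        assert set(w.peptide for w in test_pos).isdisjoint(
            w.peptide for w in train_pos
        ) or len(set(pos.peptides)) < 100  # disjoint up to duplicates

    def test_reproducible_under_seed(self):
        pos, neg = self._sets()
        a = m.split_dataset(pos, neg, seed=42)
        b = m.split_dataset(pos, neg, seed=42)
        for da, db in zip(a, b):
            assert da.peptides == db.peptides

    def test_too_few_negatives_rejected(self):
        pos, neg = self._sets(n_pos=50, n_neg=5)
        with pytest.raises(ValueError):
            m.split_dataset(pos, neg, seed=0)


class TestMakeNegativeSubsets:
    def _pool(self, n):
        rng = np.random.default_rng(3)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        return _windows(
            [
                "".join(rng.choice(alphabet, 3)) + "R" + "".join(rng.choice(alphabet, 3))
                for _ in range(n)
            ],
            label=NEGATIVE,
        )

    def test_k_balanced_subsets(self):
        subsets = m.make_negative_subsets(self._pool(400), 80, k=5, seed=7)
        assert len(subsets) == 5
        assert all(len(s) == 80 for s in subsets)
        for s in subsets:  # without replacement within each subset
            assert len(set((w.peptide, w.protein_id) for w in s)) == 80

    def test_reproducible_under_seed(self):
        a = m.make_negative_subsets(self._pool(200), 50, k=3, seed=9)
        b = m.make_negative_subsets(self._pool(200), 50, k=3, seed=9)
        for sa, sb in zip(a, b):
            assert sa.peptides == sb.peptides

    def test_pool_equals_subset_size_degenerates(self):
        subsets = m.make_negative_subsets(self._pool(80), 80, k=5, seed=1)
        assert all(sorted(s.peptides) == sorted(subsets[0].peptides) for s in subsets)

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ValueError):
            m.make_negative_subsets(self._pool(79), 80, k=5, seed=1)


def test_window_dataset_tsv_round_trip(tmp_path, window_sets):
    positives, _ = window_sets
    path = tmp_path / "pos.tsv"
    positives.to_tsv(path)
    loaded = m.WindowDataset.from_tsv(path)
    assert loaded.window_length == positives.window_length
    assert loaded.peptides == positives.peptides
    assert [w.label for w in loaded] == [w.label for w in positives]
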