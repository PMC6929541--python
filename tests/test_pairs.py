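"""Pair construction: negative sampling, replication, images, folds."""

import numpy as np
import pytest

from dtimage.drugs import draw_masks
from dtimage.pairs import (
    DatasetConstructionError,
    PairSample,
    assemble_image,
    assemble_image_stack,
    choose_replication,
    make_folds,
    read_pair_tsv,
    sample_negatives,
    write_pair_tsv,
)
from dtimage.proteins import MoranDescriptor

from conftest import make_property


def positives(n, n_targets=5):
    return [
        PairSample(f"D{i:03d}", f"T{i % n_targets:03d}", label=1, family="enzyme")
        for i in range(n)
    ]


class TestSampleNegatives:
    def test_ratio_two_gives_exactly_twice_as_many(self):
        pos = positives(10)
        drugs = sorted({p.drug_id for p in pos})
        targets = [f"T{i:03d}" for i in range(5)]
        negs = sample_negatives(pos, drugs, targets, ratio=2.0, seed=1)
        assert len(negs) == 20
        assert not {n.key for n in negs} & {p.key for p in pos}
        assert all(n.label == 0 and n.origin == "sampled_negative" for n in negs)

    @pytest.mark.parametrize("ratio", [1.0, 3.0])
    def test_discussion_ratio_variants(self, ratio):
        pos = positives(10)
        drugs = sorted({p.drug_id for p in pos})
        targets = [f"T{i:03d}" for i in range(5)]
        negs = sample_negatives(pos, drugs, targets, ratio=ratio, seed=1)
        assert len(negs) == round(ratio * 10)

    def test_deterministic_given_seed(self):
        pos = positives(8)
        drugs = sorted({p.drug_id for p in pos})
        targets = [f"T{i:03d}" for i in range(5)]
        a = sample_negatives(pos, drugs, targets, seed=3)
        b = sample_negatives(pos, drugs, targets, seed=3)
        assert [n.key for n in a] == [n.key for n in b]
        c = sample_negatives(pos, drugs, targets, seed=4)
        assert [n.key for n in a] != [n.key for n in c]

    def test_exhausted_universe_reports_max_ratio(self):
        pos = [PairSample("D1", "T1", 1), PairSample("D2", "T1", 1)]
        with pytest.raises(DatasetConstructionError, match="maximum achievable ratio"):
            sample_negatives(pos, ["D1", "D2"], ["T1"], ratio=1.0, seed=0)


class TestChooseReplication:
    @pytest.mark.parametrize(
        "n_pairs,expected",
        [(16140, 3), (45000, 1), (100, 400), (40000, 1), (39999, 2), (1, 40000)],
    )
    def test_smallest_n_reaching_band(self, n_pairs, expected):
        n = choose_replication(n_pairs)
        assert n == expected
        assert n * n_pairs >= 40000
        assert n == 1 or (n - 1) * n_pairs < 40000


@pytest.fixture
def small_geometry(rng):
    """58 masked drug columns + 42 protein features = 100 = 10x10."""
    masks = draw_masks(3, subset_size=58, width=120, seed=5)
    protein = MoranDescriptor("T001", rng.standard_normal(42), d_max=7)
    drug_row = rng.standard_normal(120)
    return masks, protein, drug_row


class TestAssembleImage:
    def test_default_geometry_is_28_by_28(self, rng):
        masks = draw_masks(1, subset_size=342, width=1444, seed=5)
        protein = MoranDescriptor("T001", rng.standard_normal(442), d_max=13)
        img = assemble_image(rng.standard_normal(1444), masks[0], protein, label=1)
        assert img.matrix.shape == (28, 28)
        assert img.matrix.size == 784

    def test_flatten_recovers_concatenation(self, small_geometry):
        masks, protein, drug_row = small_geometry
        img = assemble_image(drug_row, masks[0], protein, side=10)
        flat = img.matrix.reshape(-1)
        np.testing.assert_array_equal(flat[:58], drug_row[masks[0].column_indices])
        np.testing.assert_array_equal(flat[58:], protein.values)

    def test_drug_block_ordered_by_ascending_column_index(self, small_geometry):
        masks, protein, drug_row = small_geometry
        img = assemble_image(drug_row, masks[0], protein)
        cols = masks[0].column_indices
        assert (np.diff(cols) > 0).all()
        np.testing.assert_array_equal(img.matrix.reshape(-1)[:58], drug_row[cols])

    def test_geometry_mismatch_is_an_error(self, small_geometry):
        masks, protein, drug_row = small_geometry
        with pytest.raises(Exception, match="image|geometry|fill"):
            assemble_image(drug_row, masks[0], protein, side=9)


class TestAssembleStack:
    def test_views_share_protein_block_and_differ_in_drug_block(self, rng):
        masks = draw_masks(3, subset_size=58, width=120, seed=5)
        proteins = {
            "T000": MoranDescriptor("T000", rng.standard_normal(42), 7),
            "T001": MoranDescriptor("T001", rng.standard_normal(42), 7),
        }
        pairs = [PairSample("D0", "T000", 1), PairSample("D1", "T001", 0)]
        drug_rows = rng.standard_normal((2, 120))
        images, labels, pair_idx, view_idx = assemble_image_stack(
            pairs, drug_rows, {"D0": 0, "D1": 1}, masks, proteins, side=10
        )
        assert images.shape == (6, 10, 10)
        assert labels.tolist() == [1, 1, 1, 0, 0, 0]
        for i, pair in enumerate(pairs):
            rows = images[pair_idx == i].reshape(3, 100)
            # protein block identical across views
            assert (rows[:, 58:] == rows[0, 58:]).all()
            # drug blocks differ between views (masks differ)
            assert not np.array_equal(rows[0, :58], rows[1, :58])
            # each view equals the single-image assembler
            for j, m in enumerate(masks):
                single = assemble_image(
                    drug_rows[i], m, proteins[pair.target_id], side=10
                )
                np.testing.assert_allclose(
                    rows[j], single.matrix.reshape(-1), atol=1e-6
                )


class TestFolds:
    def _pairs(self, n):
        return [
            PairSample(f"D{i:03d}", f"T{i:03d}", label=int(i % 3 == 0)) for i in range(n)
        ]

    def test_partition_laws(self):
        pairs = self._pairs(100)
        folds = make_folds(pairs, k=10, seed=2)
        all_keys = [p.key for p in pairs]
        assert set(folds.fold_of) == set(all_keys)
        sizes = [len(folds.test_pairs(f)) for f in range(10)]
        assert sum(sizes) == 100
        assert max(sizes) - min(sizes) <= 1

    def test_stratified_within_one_label_count(self):
        pairs = self._pairs(100)  # 34 positives
        folds = make_folds(pairs, k=10, seed=2)
        label_of = {p.key: p.label for p in pairs}
        pos_per_fold = [
            sum(label_of[key] for key in folds.test_pairs(f)) for f in range(10)
        ]
        assert max(pos_per_fold) - min(pos_per_fold) <= 1

    def test_all_views_of_a_pair_share_its_fold(self, rng):
        # fold assignment is by pair key, so view rows inherit it by lookup
        pairs = self._pairs(30)
        folds = make_folds(pairs, k=5, seed=0)
        masks = draw_masks(4, subset_size=3, width=10, seed=1)
        proteins = {p.target_id: MoranDescriptor(p.target_id, rng.standard_normal(6), 3) for p in pairs}
        drug_rows = rng.standard_normal((30, 10))
        index = {p.drug_id: i for i, p in enumerate(pairs)}
        _, _, pair_idx, _ = assemble_image_stack(
            pairs, drug_rows, index, masks, proteins, side=3
        )
        view_folds = np.array([folds.fold_of[pairs[i].key] for i in pair_idx])
        for i in range(len(pairs)):
            assert len(set(view_folds[pair_idx == i])) == 1

    def test_k_below_two_is_an_error(self):
        with pytest.raises(DatasetConstructionError):
            make_folds(self._pairs(10), k=1, seed=0)


def test_pair_tsv_round_trip(tmp_path):
    pairs = [
        PairSample("D1", "T1", 1, "gpcr"),
        PairSample("D1", "T2", 0, "enzyme", origin="sampled_negative"),
    ]
    path = tmp_path / "pairs.tsv"
    write_pair_tsv(pairs, path)
    back = read_pair_tsv(path)
    assert [(p.drug_id, p.target_id, p.label, p.family) for p in back] == [
        ("D1", "T1", 1, "gpcr"),
        ("D1", "T2", 0, "enzyme"),
    ]
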