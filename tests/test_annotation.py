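import collections

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plantpatch.annotation import (
    ColorRule,
    class_counts,
    class_weights,
    color_filter_candidates,
    load_annotations,
    relabel_binary,
    stratified_split,
    weighted_sample,
)
from plantpatch.labels import CLASSES
from plantpatch.patch_grid import PatchRef
from tests.conftest import make_patch


class TestLoad:
    def test_roundtrip_with_counts(self, corpus_table, corpus_counts, tmp_path):
        path = tmp_path / "ann.csv"
        corpus_table.to_csv(path, index=False)
        table = load_annotations(path)
        assert len(table) == 62_303
        assert class_counts(table) == {c: corpus_counts[c] for c in CLASSES}

    def test_empty_file_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("image_id,row,col,label\n")
        table = load_annotations(path)
        assert len(table) == 0
        assert all(v == 0 for v in class_counts(table).values())

    def test_unknown_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("image_id,row,col,label\nimg,0,0,stem\n")
        with pytest.raises(ValueError, match="label not in scheme"):
            load_annotations(path)

    def test_duplicate_patch_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "image_id,row,col,label\nimg,0,0,leaf\nimg,0,0,branch\n"
        )
        with pytest.raises(ValueError, match="duplicate patch annotation"):
            load_annotations(path)


class TestSplit:
    def test_corpus_split_sizes(self, corpus_table):
        split = stratified_split(corpus_table, (0.6, 0.2, 0.2), seed=0)
        assert split.sizes() == (37_381, 12_461, 12_461)

    def test_plant_only_split_sizes(self, corpus_table):
        plants = corpus_table[corpus_table["label"] != "background"]
        assert len(plants) == 17_431
        split = stratified_split(plants, (0.6, 0.2, 0.2), seed=0)
        assert len(split.validation) == 3_486
        assert len(split.test) == 3_486

    def test_exact_division_single_class(self):
        table = pd.DataFrame(
            {"image_id": "i", "row": range(10), "col": 0, "label": "leaf"}
        )
        split = stratified_split(table, (0.6, 0.2, 0.2), seed=1)
        assert split.sizes() == (6, 2, 2)

    def test_per_class_counts_within_one_of_target(self, corpus_table):
        split = stratified_split(corpus_table, (0.6, 0.2, 0.2), seed=2)
        for part, frac in ((split.validation, 0.2), (split.test, 0.2)):
            counts = class_counts(part)
            for c, n in class_counts(corpus_table).items():
                assert abs(counts[c] - frac * n) < 1

    @settings(max_examples=20, deadline=None)
    @given(
        counts=st.lists(st.integers(1, 60), min_size=1, max_size=6),
        seed=st.integers(0, 2**16),
    )
    def test_partition_property(self, counts, seed):
        labels = np.repeat(CLASSES[: len(counts)], counts)
        table = pd.DataFrame(
            {
                "image_id": "i",
                "row": np.arange(len(labels)),
                "col": 0,
                "label": labels,
            }
        )
        split = stratified_split(table, (0.6, 0.2, 0.2), seed=seed)
        key = lambda df: set(zip(df["image_id"], df["row"], df["col"]))
        tr, va, te = key(split.train), key(split.validation), key(split.test)
        assert tr | va | te == key(table)
        assert not (tr & va) and not (tr & te) and not (va & te)

    def test_bad_fractions_rejected(self, corpus_table):
        with pytest.raises(ValueError, match="fractions"):
            stratified_split(corpus_table.head(50), (0.5, 0.2, 0.2))


class TestWeights:
    def test_published_weights_reproduce_at_4dp(self, corpus_counts):
        w = class_weights(corpus_counts).rounded(4)
        assert w == {
            "background": 0.0004,
            "leaf": 0.0021,
            "branch": 0.0031,
            "flower": 0.0067,
            "pod": 0.0199,
            "bud": 0.0226,
        }

    def test_weight_formula_identity(self, corpus_counts):
        w = class_weights(corpus_counts)
        for c, n in corpus_counts.items():
            assert w[c] * (0.6 * n) == pytest.approx(10.0)

    def test_direct_formula_small_count(self):
        w = class_weights({"leaf": 100, "bud": 50})
        assert w["leaf"] == pytest.approx(10 / 60)

    def test_weights_decrease_with_count(self, corpus_counts):
        w = class_weights(corpus_counts)
        by_count = sorted(corpus_counts, key=corpus_counts.get)
        weights = [w[c] for c in by_count]
        assert weights == sorted(weights, reverse=True)

    def test_zero_count_class_errors(self):
        with pytest.raises(ValueError, match="empty class"):
            class_weights({"leaf": 100, "bud": 0})


class TestWeightedSample:
    def test_expected_balance_two_classes(self):
        table = pd.DataFrame(
            {
                "image_id": "i",
                "row": range(10_000),
                "col": 0,
                "label": ["leaf"] * 9_000 + ["bud"] * 1_000,
            }
        )
        w = class_weights({"leaf": 9_000, "bud": 1_000})
        draws = weighted_sample(table, w, epoch_length=10_000, seed=7)
        frac_bud = (draws["label"] == "bud").mean()
        # expected 0.5; binomial SE at n=10,000 is 0.005
        assert abs(frac_bud - 0.5) < 3 * 0.005

    def test_single_class_all_draws(self):
        table = pd.DataFrame(
            {"image_id": "i", "row": range(5), "col": 0, "label": "pod"}
        )
        draws = weighted_sample(table, class_weights({"pod": 5}), 50, seed=0)
        assert (draws["label"] == "pod").all()

    def test_seed_determinism(self):
        table = pd.DataFrame(
            {
                "image_id": "i",
                "row": range(100),
                "col": 0,
                "label": ["leaf"] * 60 + ["bud"] * 40,
            }
        )
        w = class_weights({"leaf": 60, "bud": 40})
        a = weighted_sample(table, w, 200, seed=42)
        b = weighted_sample(table, w, 200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_table_errors(self):
        table = pd.DataFrame(columns=["image_id", "row", "col", "label"])
        with pytest.raises(ValueError, match="empty"):
            weighted_sample(table, class_weights({"leaf": 1}), 10)


class TestRelabelBinary:
    def test_flower_positive_counts(self, corpus_table):
        binary = relabel_binary(corpus_table, "flower")
        assert len(binary) == len(corpus_table)
        assert (binary["label"] == 1).sum() == 2_488
        assert (binary["label"] == 0).sum() == 59_815

    def test_background_positive_counts(self, corpus_table):
        binary = relabel_binary(corpus_table, "background")
        assert (binary["label"] == 1).sum() == 44_872

    def test_positives_over_all_classes_sum_to_table_size(self, corpus_table):
        total = sum(
            (relabel_binary(corpus_table, c)["label"] == 1).sum() for c in CLASSES
        )
        assert total == len(corpus_table)

    def test_empty_table(self):
        table = pd.DataFrame(columns=["image_id", "row", "col", "label"])
        assert len(relabel_binary(table, "pod")) == 0


class TestColorFilter:
    def test_pure_yellow_matches_flower_with_full_score(self):
        patch = make_patch((235, 205, 45))
        ref = PatchRef("i", 0, 0)
        out = color_filter_candidates([(ref, patch)])
        assert out["flower"] == [(ref, 1.0)]

    def test_pure_black_matches_no_rule(self):
        patch = make_patch((0, 0, 0))
        out = color_filter_candidates([(PatchRef("i", 0, 0), patch)])
        assert all(not v for v in out.values())

    def test_ranking_descends_by_match_fraction(self):
        full = make_patch((235, 205, 45))
        half = full.copy()
        half[:, 5:] = 0
        refs = [PatchRef("i", 0, 0), PatchRef("i", 0, 1)]
        out = color_filter_candidates([(refs[0], half), (refs[1], full)])
        assert [r for r, _ in out["flower"]] == [refs[1], refs[0]]
        scores = [s for _, s in out["flower"]]
        assert scores == sorted(scores, reverse=True)

    def test_rendered_flowers_top_candidates_match_ground_truth(self):
        from plantpatch.patch_grid import slice_image
        from plantpatch.synthetic import PlantSpec, generate_plant

        rec, gt = generate_plant(PlantSpec(seed=4, growth_day=10))
        _, patches = slice_image(rec)
        flower_truth = {
            (r.row, r.col)
            for r in gt.patch_labels[gt.patch_labels["label"] == "flower"].itertuples()
        }
        assert flower_truth  # schedule puts flowers on by day 10
        ranked = color_filter_candidates(patches)["flower"]
        top = {(ref.row, ref.col) for ref, _ in ranked[: len(flower_truth)]}
        # the top-ranked flower candidates coincide with ground truth cells
        assert len(top & flower_truth) / len(flower_truth) >= 0.8
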