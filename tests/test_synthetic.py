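import collections

import numpy as np
import pytest

from cdsno import synthetic
from cdsno.boxes import find_cd_pair
from cdsno.core_io import EXPRESSED, PSEUDOGENE, GenomicInterval
from cdsno.expression import passes_expression_filters
from cdsno.scanner import reverse_complement
from cdsno.synthetic import (
    LabeledWindow,
    SnoSpec,
    augment_shift,
    box_grammar_features,
    build_first_model_dataset,
    build_second_model_dataset,
    cap_family,
    generate_genome,
    simulate_coverage,
    split_dataset,
    train_reference_classifier,
)


class TestGenerateGenome:
    def test_empty_genome(self):
        record, truth = generate_genome(n_sno=0, genome_length=5000, seed=1)
        assert len(record.seq) == 5000 and truth == []

    def test_seed_determinism(self):
        a = generate_genome(n_sno=3, genome_length=20_000, seed=7)
        b = generate_genome(n_sno=3, genome_length=20_000, seed=7)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_infeasible_placement_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(n_sno=50, genome_length=5000, seed=1)

    def test_planted_boxes_recovered_with_uniform_profile(self):
        record, truth = generate_genome(n_sno=6, genome_length=20_000, seed=3,
                                        expressed_fraction=1.0)
        for t in truth:
            iv = t.interval
            center = (iv.start + iv.end) // 2
            win_start = center - 97
            seq = record.seq[win_start: win_start + 194]
            if iv.strand == "-":
                seq = reverse_complement(seq)
                rel_start = (win_start + 194) - iv.end
            else:
                rel_start = iv.start - win_start
            c, d = find_cd_pair(seq, peaks=[])
            assert c.start == rel_start + 5
            assert d.end == rel_start + iv.length - 5

    def test_truth_bed_roundtrip(self, tmp_path):
        _, truth = generate_genome(n_sno=4, genome_length=20_000, seed=9)
        p = tmp_path / "truth.bed"
        synthetic.write_truth_bed(truth, p)
        assert synthetic.read_truth_bed(p) == truth


class TestAugmentShift:
    @pytest.mark.parametrize("n,expected", [(5, 10), (15, 30)])
    def test_multiplicities(self, n, expected):
        w = GenomicInterval("chr1", 100, 294, "+")
        shifted = augment_shift(w, 1000, n)
        assert len(shifted) == expected
        assert w not in shifted  # original not duplicated
        assert len({s.start for s in shifted}) == expected

    def test_exhausted_context_rejected(self):
        w = GenomicInterval("chr1", 2, 196, "+")
        with pytest.raises(ValueError):
            augment_shift(w, 1000, 5)


class TestCapFamily:
    def test_large_family_reduced(self):
        rng = np.random.default_rng(0)
        examples = list(range(150))
        kept = cap_family(examples, ["famA"] * 150, 100, rng)
        assert len(kept) == 100
        assert len(set(kept)) == 100

    @pytest.mark.parametrize("size", [100, 1])
    def test_small_families_untouched(self, size):
        examples = list(range(size))
        assert cap_family(examples, ["f"] * size, 100) == examples

    def test_mixed_families(self):
        families = ["big"] * 130 + ["small"] * 10
        kept = cap_family(list(range(140)), families, 100)
        counts = collections.Counter(
            "big" if i < 130 else "small" for i in kept)
        assert counts == {"big": 100, "small": 10}


class TestSplitDataset:
    def test_equal_groups_hit_targets_exactly(self):
        examples = list(range(100))
        groups = [f"g{i // 10}" for i in range(100)]
        tune, train, test = split_dataset(examples, groups, seed=5)
        assert (len(tune), len(train), len(test)) == (10, 70, 20)

    def test_groups_never_split(self):
        rng = np.random.default_rng(1)
        groups = [f"g{rng.integers(0, 30)}" for _ in range(300)]
        parts = split_dataset(list(range(300)), groups, seed=2)
        membership = {}
        for k, part in enumerate(parts):
            for i in part:
                g = groups[i]
                assert membership.setdefault(g, k) == k

    def test_singleton_groups_approximate_fractions(self):
        examples = list(range(1000))
        groups = [f"g{i}" for i in range(1000)]
        tune, train, test = split_dataset(examples, groups, seed=11)
        assert abs(len(train) / 1000 - 0.70) <= 0.05
        assert abs(len(tune) / 1000 - 0.10) <= 0.05


@pytest.fixture(scope="module")
def genome():
    return generate_genome(n_sno=10, genome_length=30_000, seed=21)


class TestDatasets:

    def test_first_model_ratio_and_labels(self, genome):
        record, truth = genome
        rng = np.random.default_rng(0)
        ds = build_first_model_dataset(record, truth, rng)
        n_pos = sum(w.label for w in ds)
        n_neg = len(ds) - n_pos
        assert n_pos == len(truth) * 11  # original + 10 shifts
        assert n_neg == 5 * n_pos

    def test_negative_windows_do_not_overlap_truth(self, genome):
        record, truth = genome
        rng = np.random.default_rng(0)
        ds = build_first_model_dataset(record, truth, rng)
        # background negatives are sampled away from truth loci; verify by
        # construction kind bookkeeping
        kinds = collections.Counter(w.kind for w in ds)
        assert set(kinds) == {"positive", "shuffled", "background"}

    def test_shuffled_negatives_preserve_composition(self, genome):
        record, truth = genome
        rng = np.random.default_rng(0)
        ds = build_first_model_dataset(record, truth, rng)
        pos_comp = collections.Counter()
        shuf_comp = collections.Counter()
        for w in ds:
            if w.kind == "positive":
                pos_comp += collections.Counter(w.seq)
            elif w.kind == "shuffled":
                shuf_comp += collections.Counter(w.seq)
        pos_total = sum(pos_comp.values())
        shuf_total = sum(shuf_comp.values())
        for base in "ACGT":
            assert (pos_comp[base] / pos_total
                    == pytest.approx(shuf_comp[base] / shuf_total, abs=0.02))

    def test_second_model_augmentation_asymmetry(self, genome):
        record, truth = genome
        rng = np.random.default_rng(0)
        ds = build_second_model_dataset(record, truth, rng)
        n_exp = sum(1 for t in truth if t.subclass == EXPRESSED)
        n_psg = len(truth) - n_exp
        assert sum(w.label for w in ds) == n_exp * 11
        assert sum(1 - w.label for w in ds) == n_psg * 31


class TestReferenceClassifier:
    def test_training_accuracy_above_09(self, training_genome):
        record, truth = training_genome
        rng = np.random.default_rng(0)
        ds = build_first_model_dataset(record, truth, rng)
        clf = train_reference_classifier(ds, seed=0)
        probs = clf.predict([w.seq for w in ds])
        acc = np.mean((probs >= 0.5) == np.array([w.label for w in ds]))
        assert acc > 0.9

    def test_probabilities_in_unit_interval(self, reference_models):
        first, _ = reference_models
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 194)) for _ in range(20)]
        probs = first.predict(seqs)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_seed_determinism(self, training_genome):
        record, truth = training_genome
        ds = build_first_model_dataset(record, truth, np.random.default_rng(0))
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), 194)) for _ in range(5)]
        a = train_reference_classifier(ds, seed=7).predict(seqs)
        b = train_reference_classifier(ds, seed=7).predict(seqs)
        assert np.array_equal(a, b)

    def test_too_few_examples_rejected(self):
        ds = [LabeledWindow("A" * 194, 1, "f", "positive")] * 30 + [
            LabeledWindow("C" * 194, 0, "n", "background")] * 5
        with pytest.raises(ValueError):
            train_reference_classifier(ds)

    def test_grammar_features_shape_and_range(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 194)) for _ in range(10)]
        F = box_grammar_features(seqs)
        assert F.shape == (10, 5)
        assert (F[:, 0] <= 7).all() and (F[:, 1] <= 4).all()
        assert (F[:, 4] >= 0).all() and (F[:, 4] <= 20).all()


class TestSimulateCoverage:
    def test_expressed_pass_pseudogenes_fail(self):
        _, truth = generate_genome(n_sno=8, genome_length=30_000, seed=31)
        track = simulate_coverage(truth, depth=10.0, seed=31)
        for t in truth:
            result = passes_expression_filters(t.interval, track)
            assert result.passed == (t.subclass == EXPRESSED)

    def test_seed_determinism_with_noise(self):
        _, truth = generate_genome(n_sno=4, genome_length=20_000, seed=33)
        a = simulate_coverage(truth, noise=0.05, seed=1, genome_length=20_000)
        b = simulate_coverage(truth, noise=0.05, seed=1, genome_length=20_000)
        iv = truth[0].interval
        assert np.array_equal(
            a.depth(iv.chrom, "+", 0, 20_000), b.depth(iv.chrom, "+", 0, 20_000)
        )
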