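import numpy as np
import pytest

from tetrabin.cluster import BinningResult
from tetrabin.evaluate import confusion_metrics, nc_counts
from tetrabin.io import GroundTruth


def _result(assignments: dict[str, int]) -> BinningResult:
    return BinningResult(
        contig_ids=list(assignments), labels=np.array(list(assignments.values()))
    )


def _truth(mapping: dict[str, str], sizes=None, labels=None) -> GroundTruth:
    return GroundTruth(
        contig_to_genome=mapping, genome_sizes=sizes or {}, genome_labels=labels or {}
    )


class TestConfusionMetrics:
    def test_perfect_binning_scores_one_everywhere(self):
        mapping = {f"c{i}": f"g{i % 3}" for i in range(30)}
        result = _result({cid: int(g[1]) for cid, g in mapping.items()})
        report = confusion_metrics(result, _truth(mapping))
        for score in report.per_bin:
            assert score.precision == score.recall == score.f1 == 1.0
        assert report.macro_f1 == report.micro_f1 == 1.0

    def test_worked_counts_give_point_eight(self):
        """A bin of 8 true + 2 foreign contigs, with 2 true contigs missed."""
        mapping = {f"a{i}": "A" for i in range(10)} | {f"b{i}": "B" for i in range(12)}
        assignments = (
            {f"a{i}": 0 for i in range(8)}  # TP = 8
            | {"a8": -1, "a9": -1}  # FN = 2 (noise counts as unassigned)
            | {f"b{i}": 1 for i in range(10)}
            | {"b10": 0, "b11": 0}  # FP = 2 in bin 0
        )
        report = confusion_metrics(_result(assignments), _truth(mapping))
        bin0 = next(s for s in report.per_bin if s.bin_id == 0)
        assert (bin0.tp, bin0.fp, bin0.fn) == (8, 2, 2)
        assert bin0.precision == pytest.approx(0.8)
        assert bin0.recall == pytest.approx(0.8)
        assert bin0.f1 == pytest.approx(0.8)

    def test_all_noise_means_zero_scores(self):
        mapping = {f"c{i}": "g0" for i in range(10)}
        report = confusion_metrics(_result({cid: -1 for cid in mapping}), _truth(mapping))
        assert report.per_bin == []
        assert report.macro_f1 == 0.0 and report.micro_recall == 0.0

    def test_contigs_missing_from_truth_are_listed(self):
        result = _result({"known": 0, "mystery": 0})
        with pytest.raises(ValueError, match="mystery"):
            confusion_metrics(result, _truth({"known": "g0"}))

    def test_micro_scores_invariant_to_bin_relabeling(self):
        rng = np.random.default_rng(0)
        mapping = {f"c{i}": f"g{i % 4}" for i in range(40)}
        labels = rng.integers(0, 4, size=40)
        base = confusion_metrics(_result(dict(zip(mapping, labels))), _truth(mapping))
        permuted = confusion_metrics(
            _result(dict(zip(mapping, (labels + 2) % 4))), _truth(mapping)
        )
        assert base.micro_precision == pytest.approx(permuted.micro_precision)
        assert base.micro_recall == pytest.approx(permuted.micro_recall)


class TestNCCounts:
    GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)

    def test_fully_recovered_genome_counts_at_every_threshold(self):
        mapping = {f"c{i}": "g0" for i in range(10)}
        lengths = {f"c{i}": 10_000 for i in range(10)}
        counts = nc_counts(
            _result({cid: 0 for cid in mapping}), _truth(mapping), lengths,
            recall_grid=self.GRID,
        )
        assert all(counts[r] == 1 for r in self.GRID)

    def test_sixty_forty_split_counts_only_to_point_six(self):
        mapping = {"long": "g0", "short": "g0"}
        lengths = {"long": 60_000, "short": 40_000}
        counts = nc_counts(
            _result({"long": 0, "short": 1}), _truth(mapping), lengths,
            recall_grid=self.GRID,
        )
        assert counts[0.5] == 1 and counts[0.6] == 1
        assert all(counts[r] == 0 for r in self.GRID if r > 0.6)

    def test_impure_bin_fails_the_precision_gate(self):
        """A bin that is 94% genome A by bp cannot recover A at precision 0.95."""
        mapping = {"a": "A", "b": "B"}
        lengths = {"a": 94_000, "b": 6_000}
        counts = nc_counts(
            _result({"a": 0, "b": 0}), _truth(mapping), lengths,
            precision_min=0.95, recall_grid=(0.5, 0.9),
        )
        assert counts[0.5] == 0 and counts[0.9] == 0

    def test_counts_never_increase_along_the_recall_grid(self):
        rng = np.random.default_rng(1)
        mapping = {f"c{i}": f"g{i % 5}" for i in range(60)}
        lengths = {cid: int(rng.integers(2000, 20_000)) for cid in mapping}
        for _ in range(20):
            labels = rng.integers(-1, 6, size=60)
            counts = nc_counts(
                _result(dict(zip(mapping, labels))), _truth(mapping), lengths,
                recall_grid=self.GRID,
            )
            values = [counts[r] for r in self.GRID]
            assert values == sorted(values, reverse=True)

    def test_single_contig_genomes_match_contig_level_recall(self):
        """One contig per genome: bp-recall is 0 or 1, like contig recall."""
        mapping = {f"c{i}": f"g{i}" for i in range(6)}
        lengths = {f"c{i}": 5000 for i in range(6)}
        assignments = {f"c{i}": (0 if i < 4 else -1) for i in range(6)}
        # bins of several whole single-contig genomes fail precision except one
        counts = nc_counts(
            _result(assignments), _truth(mapping), lengths, recall_grid=(0.99,)
        )
        assert counts[0.99] == 0  # the shared bin is at most 25% any genome
        pure = {f"c{i}": i for i in range(6)}
        report = confusion_metrics(_result(pure), _truth(mapping))
        counts_pure = nc_counts(_result(pure), _truth(mapping), lengths, recall_grid=(0.99,))
        assert counts_pure[0.99] == 6
        assert report.micro_recall == 1.0

    def test_taxonomic_merge_pools_genomes(self):
        """Two genomes sharing a species label count as one merged unit."""
        mapping = {"x": "gA", "y": "gB"}
        lengths = {"x": 50_000, "y": 50_000}
        truth = _truth(mapping, labels={"gA": "speciesS", "gB": "speciesS"})
        counts = nc_counts(
            _result({"x": 0, "y": 0}), truth, lengths,
            recall_grid=(0.9,), merge_labels=True,
        )
        assert counts[0.9] == 1

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError):
            nc_counts(_result({"c": 0}), _truth({"c": "g"}), {})
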