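import numpy as np
import pytest

from tetrabin.encoder import EncoderConfig, TransformerEncoder
from tetrabin.mlm import MLMConfig, ModelCheckpoint, apply_plan, plan_masking, pretrain
from tetrabin.tokenizer import build_vocabulary, segmentize, tokenize_contig


@pytest.fixture()
def full_segment(vocab):
    rng = np.random.default_rng(0)
    return segmentize(rng.integers(0, 256, size=510).astype(np.int32), "c", vocab)[0]


class TestPlanMasking:
    def test_spans_stay_inside_content_and_never_overlap(self, vocab):
        """Brute-force position audit over 1000 plans of varying pad amounts."""
        rng = np.random.default_rng(1)
        config = MLMConfig()
        for trial in range(1000):
            n_content = int(rng.integers(1, 120))
            seg = segmentize(rng.integers(0, 256, size=n_content).astype(np.int32),
                             "c", vocab, segment_length=128)[0]
            plan = plan_masking(seg, config, rng, vocab)
            seen = set()
            for positions, _ in plan.spans:
                for p in positions:
                    assert 1 <= p <= n_content  # content region is [1, n_content]
                    assert p not in seen
                    seen.add(p)
            assert plan.n_targets == len(seen)
            assert (np.sort(plan.target_positions) == sorted(seen)).all()

    def test_budget_and_branch_statistics(self, full_segment, vocab):
        rng = np.random.default_rng(2)
        config = MLMConfig()
        fracs = []
        branch_counts = {"mask": 0, "random": 0, "keep": 0}
        for _ in range(2000):
            plan = plan_masking(full_segment, config, rng, vocab)
            fracs.append(plan.n_targets / full_segment.n_content)
            for _, branch in plan.spans:
                branch_counts[branch] += 1
        total = sum(branch_counts.values())
        assert abs(np.mean(fracs) - 0.15) < 0.01
        assert abs(branch_counts["mask"] / total - 0.8) < 0.02
        assert abs(branch_counts["random"] / total - 0.1) < 0.02
        assert abs(branch_counts["keep"] / total - 0.1) < 0.02

    def test_single_scale_degenerates_to_token_masking(self, full_segment, vocab):
        rng = np.random.default_rng(3)
        config = MLMConfig(scales=(1,))
        plan = plan_masking(full_segment, config, rng, vocab)
        assert plan.spans
        assert all(len(positions) == 1 for positions, _ in plan.spans)

    def test_reproducible_under_fixed_seed(self, full_segment, vocab):
        config = MLMConfig()
        plan_a = plan_masking(full_segment, config, np.random.default_rng(42), vocab)
        plan_b = plan_masking(full_segment, config, np.random.default_rng(42), vocab)
        assert (plan_a.target_positions == plan_b.target_positions).all()
        assert [b for _, b in plan_a.spans] == [b for _, b in plan_b.spans]

    def test_unknown_tokens_are_never_span_centers(self, vocab):
        """All-[UNK] content admits no spans at all."""
        rng = np.random.default_rng(4)
        seg = tokenize_contig("N" * 40, "c", vocab, segment_length=64)[0]
        plan = plan_masking(seg, MLMConfig(), rng, vocab)
        assert plan.spans == []

    def test_corruption_follows_branches(self, full_segment, vocab):
        rng = np.random.default_rng(5)
        plan = plan_masking(full_segment, MLMConfig(), rng, vocab)
        ids = apply_plan(full_segment, plan, rng, vocab)
        for positions, branch in plan.spans:
            if branch == "mask":
                assert (ids[positions] == vocab.mask_id).all()
            elif branch == "keep":
                assert (ids[positions] == full_segment.token_ids[positions]).all()
            else:
                assert (ids[positions] < 256).all()
        untouched = np.setdiff1d(np.arange(512), plan.target_positions)
        assert (ids[untouched] == full_segment.token_ids[untouched]).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MLMConfig(mask_rate=0.0)
        with pytest.raises(ValueError):
            MLMConfig(branch_probs=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            MLMConfig(scales=())


class TestEncoderGradients:
    def test_gradients_match_finite_differences(self):
        """Analytic backprop agrees with central differences for every block."""
        cfg = EncoderConfig(vocab_size=13, max_len=10, layers=2, hidden_size=8,
                            attention_heads=2)
        enc = TransformerEncoder(cfg, seed=0)
        enc.params = {k: v.astype(np.float64) for k, v in enc.params.items()}
        rng = np.random.default_rng(1)
        ids = rng.integers(0, 13, size=(3, 10))
        mask = np.ones((3, 10), dtype=np.int64)
        mask[0, 7:] = 0
        positions = (np.array([0, 0, 1, 2, 2]), np.array([1, 3, 2, 1, 4]))
        targets = rng.integers(0, 13, size=5)
        _, grads = enc.loss_and_grads(ids, mask, positions, targets)

        eps = 1e-6
        for name, param in enc.params.items():
            flat = param.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                up, _ = enc.loss_and_grads(ids, mask, positions, targets)
                flat[i] = orig - eps
                down, _ = enc.loss_and_grads(ids, mask, positions, targets)
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].ravel()[i]
                assert (
                    abs(numeric - analytic) < 1e-8
                    or abs(numeric - analytic) / max(abs(numeric), abs(analytic)) < 1e-3
                ), f"gradient mismatch in {name}"


def _pattern_corpus(vocab, n=96):
    segs = tokenize_contig("ACGT" * 200, "p", vocab, segment_length=34)
    return [s for s in segs if s.n_content == 32] * (n // 20)


class TestPretrain:
    def test_loss_decreases_on_learnable_data(self, vocab):
        rng = np.random.default_rng(0)
        contigs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(20)]
        corpus = [s for i, c in enumerate(contigs)
                  for s in tokenize_contig(c, f"c{i}", vocab, segment_length=64)]
        assert len(corpus) >= 60
        config = MLMConfig(layers=1, hidden_size=32, attention_heads=2,
                           batch_size=16, learning_rate=1e-3, epochs=5, seed=0)
        checkpoint = pretrain(corpus, vocab, config)
        assert len(checkpoint.loss_history) == 5
        assert checkpoint.loss_history[-1] < checkpoint.loss_history[0]

    def test_repeating_pattern_is_solved(self, vocab):
        """A deterministic periodic corpus makes masked prediction near-perfect."""
        corpus = _pattern_corpus(vocab)
        config = MLMConfig(layers=1, hidden_size=32, attention_heads=2,
                           batch_size=16, learning_rate=5e-3, epochs=30, seed=0)
        checkpoint = pretrain(corpus, vocab, config)
        rng = np.random.default_rng(99)
        eval_config = MLMConfig(branch_probs=(1.0, 0.0, 0.0), seed=99)
        correct = total = 0
        for seg in corpus[:20]:
            plan = plan_masking(seg, eval_config, rng, vocab)
            ids = apply_plan(seg, plan, rng, vocab)
            hidden = checkpoint.encoder.forward(ids[None, :], seg.attention_flags[None, :])
            logits = hidden[0] @ checkpoint.encoder.params["lm_W"] + checkpoint.encoder.params["lm_b"]
            predicted = logits[plan.target_positions].argmax(axis=1)
            correct += int((predicted == plan.target_ids).sum())
            total += plan.n_targets
        assert correct / total > 0.95

    def test_zero_epochs_returns_initial_model(self, vocab):
        corpus = _pattern_corpus(vocab, n=20)
        config = MLMConfig(layers=1, hidden_size=32, attention_heads=2, epochs=0, seed=7)
        checkpoint = pretrain(corpus, vocab, config)
        assert checkpoint.loss_history == []
        fresh = TransformerEncoder(checkpoint.encoder.config, seed=7)
        for name in fresh.params:
            assert np.array_equal(fresh.params[name], checkpoint.encoder.params[name])

    def test_empty_corpus_rejected(self, vocab):
        with pytest.raises(ValueError):
            pretrain([], vocab, MLMConfig())

    def test_checkpoint_round_trip_reproduces_embeddings(self, vocab, tmp_path):
        corpus = _pattern_corpus(vocab, n=20)
        config = MLMConfig(layers=1, hidden_size=32, attention_heads=2,
                           batch_size=16, learning_rate=1e-3, epochs=2, seed=0)
        checkpoint = pretrain(corpus, vocab, config)
        checkpoint.save(tmp_path / "ckpt")
        loaded = ModelCheckpoint.load(tmp_path / "ckpt")
        seg = corpus[0]
        original = checkpoint.encoder.cls_vectors(seg.token_ids[None, :], seg.attention_flags[None, :])
        reloaded = loaded.encoder.cls_vectors(seg.token_ids[None, :], seg.attention_flags[None, :])
        assert np.array_equal(original, reloaded)
        assert loaded.loss_history == pytest.approx(checkpoint.loss_history, abs=1e-6)
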