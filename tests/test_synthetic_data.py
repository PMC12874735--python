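import numpy as np
import pytest

from raslit import (SimulationConfig, generate_dataset, label_recovery_report,
                    load_corpus, load_gene_dictionary, run_pipeline_benchmark,
                    write_dataset)
from raslit.corpus_io import read_label_matrix
from raslit.models import ScoreMatrix


def small_config(**overrides):
    base = dict(n_genes=30, n_pathways=5, n_documents=150, doc_length=40.0,
                vocab_size=300, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


class TestGenerateDataset:
    def test_shapes_and_validators(self):
        ds = generate_dataset(small_config())
        assert len(ds.corpus.documents) == 150
        assert len(ds.dictionary.entries) == 30
        assert ds.labels.values.shape == (30, 5)
        # the dataclass validators already ran on construction; spot-check:
        assert ds.labels.values.min() >= 0 and ds.labels.values.max() <= 1

    def test_every_gene_labelled_every_pathway_populated(self):
        ds = generate_dataset(small_config())
        Y = ds.labels.values
        assert np.all(Y.sum(axis=1) >= 1)
        assert np.all(Y.sum(axis=0) >= 1)

    def test_marker_genes_single_label_and_hallmarks(self):
        ds = generate_dataset(small_config())
        Y = ds.labels.values
        for j, p in enumerate(ds.registry.pathway_ids):
            gene = ds.labels.gene_ids[j]
            assert ds.top_genes[p] == gene
            assert Y[j].sum() == 1 and Y[j, j] == 1

    def test_doc_topics_cover_corpus(self):
        ds = generate_dataset(small_config())
        assert set(ds.doc_topics) == {d.doc_id for d in ds.corpus.documents}
        assert set(ds.doc_topics.values()) <= set(ds.registry.pathway_ids)

    def test_same_seed_reproduces_exactly(self):
        cfg = small_config(seed=99)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert [d.text for d in a.corpus.documents] == \
            [d.text for d in b.corpus.documents]
        np.testing.assert_array_equal(a.labels.values, b.labels.values)
        assert a.dictionary.entries == b.dictionary.entries

    def test_different_seeds_differ(self):
        a = generate_dataset(small_config(seed=1))
        b = generate_dataset(small_config(seed=2))
        assert [d.text for d in a.corpus.documents] != \
            [d.text for d in b.corpus.documents]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_genes=3)  # fewer genes than pathways
        with pytest.raises(ValueError):
            small_config(signal_strength=0.5)
        with pytest.raises(ValueError):
            small_config(label_cardinality=0.0)
        with pytest.raises(ValueError):
            small_config(synonyms_per_gene=(2, 1))

    def test_unrecoverable_signal_warns(self):
        with pytest.warns(UserWarning, match="unrecoverable"):
            generate_dataset(small_config(n_documents=10,
                                          background_rate=0.01,
                                          signal_strength=2.0))

    def test_mention_rates_match_poisson_design(self):
        # Single-synonym genes so every mention is one countable token.
        cfg = SimulationConfig(n_genes=30, n_pathways=5, n_documents=1000,
                               doc_length=30.0, vocab_size=300,
                               synonyms_per_gene=(1, 1), signal_strength=6.0,
                               background_rate=0.1, seed=4)
        ds = generate_dataset(cfg)
        token_of = {g: syns[0] for g, syns, _ in ds.dictionary.entries}
        member = {g: paths for g, _, paths in ds.dictionary.entries}
        hallmarks = set(ds.top_genes.values())
        in_counts = in_docs = off_counts = off_docs = 0
        for doc in ds.corpus.documents:
            topic = ds.doc_topics[doc.doc_id]
            words = doc.text.split()
            for g in ds.labels.gene_ids:
                if g in hallmarks:
                    continue
                c = words.count(token_of[g])
                if topic in member[g]:
                    in_counts += c
                    in_docs += 1
                else:
                    off_counts += c
                    off_docs += 1
        in_rate = in_counts / in_docs
        off_rate = off_counts / off_docs
        assert in_rate == pytest.approx(
            cfg.background_rate * cfg.signal_strength, rel=0.1)
        assert off_rate == pytest.approx(cfg.background_rate, rel=0.1)

    def test_hallmark_boost_applied(self):
        cfg = SimulationConfig(n_genes=20, n_pathways=4, n_documents=1000,
                               doc_length=30.0, vocab_size=300,
                               synonyms_per_gene=(1, 1), signal_strength=4.0,
                               background_rate=0.1, top_gene_boost=3.0, seed=7)
        ds = generate_dataset(cfg)
        token_of = {g: syns[0] for g, syns, _ in ds.dictionary.entries}
        counts = docs = 0
        for doc in ds.corpus.documents:
            topic = ds.doc_topics[doc.doc_id]
            counts += doc.text.split().count(token_of[ds.top_genes[topic]])
            docs += 1
        rate = counts / docs
        expected = cfg.background_rate * cfg.signal_strength * cfg.top_gene_boost
        assert rate == pytest.approx(expected, rel=0.15)


class TestWriteDataset:
    def test_files_byte_identical_across_runs(self, tmp_path):
        cfg = small_config(seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(cfg), d1)
        write_dataset(generate_dataset(cfg), d2)
        for name in ("corpus.jsonl", "dictionary.tsv", "labels.tsv",
                     "registry.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_round_trip_through_loaders(self, tmp_path):
        ds = generate_dataset(small_config(seed=5))
        write_dataset(ds, tmp_path)
        corpus = load_corpus(tmp_path / "corpus.jsonl")
        assert [d.text for d in corpus.documents] == \
            [d.text for d in ds.corpus.documents]
        from raslit import load_pathway_registry
        registry = load_pathway_registry(tmp_path / "registry.tsv")
        assert registry.pathway_ids == ds.registry.pathway_ids
        dictionary = load_gene_dictionary(tmp_path / "dictionary.tsv", registry)
        assert [e[0] for e in dictionary.entries] == ds.labels.gene_ids
        labels = read_label_matrix(tmp_path / "labels.tsv")
        np.testing.assert_array_equal(labels.values, ds.labels.values)
        assert labels.pathway_ids == ds.labels.pathway_ids


class TestLabelRecoveryReport:
    def test_perfect_scores(self):
        ds = generate_dataset(small_config())
        scores = ScoreMatrix(values=ds.labels.values.astype(float),
                             gene_ids=ds.labels.gene_ids,
                             pathway_ids=ds.labels.pathway_ids)
        rep = label_recovery_report(ds.labels, scores)
        assert rep["mean_auc"] == 1.0
        assert rep["metrics"]["f1_macro"] == 1.0

    def test_random_scores_near_half_auc(self):
        ds = generate_dataset(small_config(n_genes=100, n_documents=5))
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = ScoreMatrix(values=rng.random(ds.labels.values.shape),
                                 gene_ids=ds.labels.gene_ids,
                                 pathway_ids=ds.labels.pathway_ids)
            aucs.append(label_recovery_report(ds.labels, scores)["mean_auc"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_auc_and_recovery_invariant_to_monotone_transform(self, rng):
        ds = generate_dataset(small_config())
        S = rng.random(ds.labels.values.shape)
        ids = dict(gene_ids=ds.labels.gene_ids,
                   pathway_ids=ds.labels.pathway_ids)
        r1 = label_recovery_report(ds.labels, ScoreMatrix(values=S, **ids),
                                   ds.top_genes)
        r2 = label_recovery_report(
            ds.labels, ScoreMatrix(values=1 / (1 + np.exp(-8 * S)), **ids),
            ds.top_genes)
        assert r1["per_pathway_auc"] == pytest.approx(r2["per_pathway_auc"])
        assert r1["top_gene_recovered"] == r2["top_gene_recovered"]

    def test_misaligned_indices_rejected(self):
        ds = generate_dataset(small_config())
        scores = ScoreMatrix(values=np.zeros((30, 5)),
                             gene_ids=list(reversed(ds.labels.gene_ids)),
                             pathway_ids=ds.labels.pathway_ids)
        with pytest.raises(ValueError):
            label_recovery_report(ds.labels, scores)


class TestPipelineBenchmark:
    def test_signal_separates_from_null(self):
        """End-to-end sanity: planted signal beats a signal-free corpus."""
        from raslit import ModelConfig

        def auc_at(signal, seed):
            cfg = SimulationConfig(n_genes=60, n_pathways=5, n_documents=400,
                                   doc_length=60.0, vocab_size=500,
                                   signal_strength=signal, seed=seed)
            res = run_pipeline_benchmark(
                cfg, model_config=ModelConfig(seed=seed, max_epochs=300))
            return res["cv_report"].roc_auc_macro

        assert auc_at(8.0, 0) > auc_at(1.0, 0) + 0.15

    def test_benchmark_outputs_are_consistent(self):
        cfg = small_config(n_genes=40, signal_strength=6.0)
        res = run_pipeline_benchmark(cfg)
        assert res["coords"].shape == (40, cfg.n_pathways)
        assert res["features"].shape[0] == 40
        assert 0 <= res["cv_report"].f1_macro <= 1
        assert set(res["recovery"]["top_gene_recovered"]) == \
            set(res["dataset"].registry.pathway_ids)
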