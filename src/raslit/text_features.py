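"""Tokenization and the gene × document TF-IDF feature matrix.

The term weight follows the classical definitions

    TF(t, d)    = f_{t,d} / Σ_{t'} f_{t',d}
    IDF(t, D)   = log(N / n_t)
    TF-IDF      = TF × IDF

with f_{t,d} the number of (non-overlapping) occurrences of the phrase t in
document d, the TF denominator the document's total single-token count, N the
corpus size and n_t the number of documents containing t. The log base is
configurable (e, 2 or 10); natural log is the default. A gene's feature value
in a document aggregates the TF-IDF of all its synonym phrases (sum by
default, max/mean optional).

Phrase matching is exact, case-insensitive, token-sequence based and
non-overlapping — deterministic and free of any NER or fuzzy-matching layer.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from ._stopwords import ENGLISH_STOPWORDS
from .corpus_io import Corpus, Document, FeatureMatrix, GeneDictionary

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")

_LOG = {"e": math.log, "2": math.log2, "10": math.log10}


def tokenize(text: str, stopwords: frozenset[str] | set[str] = ENGLISH_STOPWORDS
             ) -> list[str]:
    """Lowercase alphanumeric tokens, punctuation stripped, stop words removed.

    Original token order is preserved; empty text yields an empty list.
    """
    return [tok for tok in _TOKEN_RE.findall(text.lower()) if tok not in stopwords]


def normalize_phrase(phrase: str,
                     stopwords: frozenset[str] | set[str] = ENGLISH_STOPWORDS
                     ) -> tuple[str, ...]:
    """Normalize a synonym phrase with the same tokenizer used for documents."""
    return tuple(tokenize(phrase, stopwords))


def count_phrase(tokens: Sequence[str], phrase: Sequence[str]) -> int:
    """Non-overlapping occurrences of a token sequence, greedy left-to-right."""
    m = len(phrase)
    if m == 0:
        return 0
    if m == 1:
        t = phrase[0]
        return sum(1 for tok in tokens if tok == t)
    n = len(tokens)
    count = i = 0
    target = tuple(phrase)
    first = target[0]
    while i <= n - m:
        if tokens[i] == first and tuple(tokens[i:i + m]) == target:
            count += 1
            i += m
        else:
            i += 1
    return count


def _ensure_tokens(doc: Document, stopwords) -> list[str]:
    if doc.tokens is None:
        doc.tokens = tokenize(doc.text, stopwords)
    return doc.tokens


def term_frequency(t: str, d: Document,
                   stopwords: frozenset[str] = ENGLISH_STOPWORDS) -> float:
    """f_{t,d} / (total token count of d); 0 for an empty document."""
    tokens = _ensure_tokens(d, stopwords)
    if not tokens:
        return 0.0
    phrase = normalize_phrase(t, stopwords)
    return count_phrase(tokens, phrase) / len(tokens)


def inverse_document_frequency(t: str, corpus: Corpus, log_base: str = "e",
                               stopwords: frozenset[str] = ENGLISH_STOPWORDS
                               ) -> float:
    """log(N / n_t); defined as 0 when no document contains t."""
    if corpus.N < 1:
        raise ValueError("IDF requires a corpus with at least one document")
    phrase = normalize_phrase(t, stopwords)
    n_t = sum(1 for d in corpus if count_phrase(_ensure_tokens(d, stopwords), phrase) > 0)
    if n_t == 0:
        return 0.0
    return _LOG[log_base](corpus.N / n_t)


def tfidf(t: str, d: Document, corpus: Corpus, log_base: str = "e",
          stopwords: frozenset[str] = ENGLISH_STOPWORDS) -> float:
    """TF(t, d) × IDF(t, corpus)."""
    return (term_frequency(t, d, stopwords)
            * inverse_document_frequency(t, corpus, log_base, stopwords))


class TfidfGeneFeaturizer(BaseEstimator):
    """Build the gene × document TF-IDF matrix with synonym aggregation.

    Each gene row aggregates the per-synonym TF-IDF scores over the gene's
    (deduplicated) synonym phrases. Rows are ordered by gene_id, columns by
    doc_id. Genes never mentioned anywhere keep an all-zero row.

    Parameters
    ----------
    agg : {'sum', 'max', 'mean'}
        How per-synonym scores combine into the gene's value. Sum (default)
        preserves total mention mass across alternative names.
    log_base : {'e', '2', '10'}
        Logarithm base of the IDF term.
    """

    def __init__(self, agg: str = "sum", log_base: str = "e",
                 stopwords: frozenset[str] = ENGLISH_STOPWORDS):
        self.agg = agg
        self.log_base = log_base
        self.stopwords = stopwords

    def fit(self, corpus: Corpus, dictionary: GeneDictionary | None = None):
        if self.agg not in ("sum", "max", "mean"):
            raise ValueError(f"unknown aggregation: {self.agg!r}")
        if self.log_base not in _LOG:
            raise ValueError(f"unknown log base: {self.log_base!r}")
        self.corpus_ = corpus
        self.doc_tokens_ = [_ensure_tokens(d, self.stopwords) for d in corpus]
        self.doc_lens_ = np.array([len(t) for t in self.doc_tokens_])
        # Inverted index: token -> set of document positions, for candidate
        # pruning when counting phrase occurrences.
        index: dict[str, set[int]] = {}
        for j, toks in enumerate(self.doc_tokens_):
            for tok in set(toks):
                index.setdefault(tok, set()).add(j)
        self.token_index_ = index
        return self

    def _phrase_counts(self, phrase: tuple[str, ...]) -> dict[int, int]:
        """doc position -> non-overlapping occurrence count, zero rows omitted."""
        candidates: set[int] | None = None
        for tok in set(phrase):
            docs = self.token_index_.get(tok)
            if not docs:
                return {}
            candidates = docs if candidates is None else candidates & docs
        counts: dict[int, int] = {}
        if len(phrase) == 1:
            t = phrase[0]
            for j in candidates:
                c = self.doc_tokens_[j].count(t)
                if c:
                    counts[j] = c
        else:
            for j in candidates:
                c = count_phrase(self.doc_tokens_[j], phrase)
                if c:
                    counts[j] = c
        return counts

    def transform(self, dictionary: GeneDictionary) -> FeatureMatrix:
        """TF-IDF matrix for the dictionary's genes over the fitted corpus."""
        if not hasattr(self, "doc_tokens_"):
            raise RuntimeError("featurizer must be fit on a corpus first")
        N = self.corpus_.N
        log = _LOG[self.log_base]
        lens = self.doc_lens_
        gene_ids = dictionary.gene_ids
        n_zero_genes = 0
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        for i, (gene_id, synonyms, _) in enumerate(dictionary):
            phrases = list(dict.fromkeys(
                p for p in (normalize_phrase(s, self.stopwords) for s in synonyms) if p
            ))
            per_doc: dict[int, list[float]] = {}
            for phrase in phrases:
                counts = self._phrase_counts(phrase)
                if not counts:
                    continue
                idf = log(N / len(counts))
                for j, c in counts.items():
                    if lens[j] == 0:
                        continue
                    per_doc.setdefault(j, []).append((c / lens[j]) * idf)
            if not per_doc:
                n_zero_genes += 1
            for j, scores in per_doc.items():
                if self.agg == "sum":
                    v = sum(scores)
                elif self.agg == "max":
                    v = max(scores)
                else:  # mean over all of the gene's (deduplicated) synonyms
                    v = sum(scores) / len(phrases)
                if v != 0.0:
                    rows.append(i)
                    cols.append(j)
                    vals.append(v)
        if n_zero_genes:
            logger.info("%d gene(s) have no corpus mentions (all-zero rows)",
                        n_zero_genes)
        values = sp.coo_matrix((vals, (rows, cols)),
                               shape=(len(gene_ids), N)).tocsr()
        return FeatureMatrix(values=values, gene_ids=gene_ids,
                             doc_ids=self.corpus_.doc_ids)

    def fit_transform(self, corpus: Corpus, dictionary: GeneDictionary
                      ) -> FeatureMatrix:
        return self.fit(corpus).transform(dictionary)


def build_feature_matrix(corpus: Corpus, dictionary: GeneDictionary,
                         agg: str = "sum", log_base: str = "e") -> FeatureMatrix:
    """Convenience wrapper over :class:`TfidfGeneFeaturizer`."""
    return TfidfGeneFeaturizer(agg=agg, log_base=log_base).fit_transform(
        corpus, dictionary)
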