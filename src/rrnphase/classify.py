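"""Naive-Bayes bootstrap taxonomic classifier over 8-mer words.

The classifier follows the word-based naive-Bayes scheme standard for
rRNA taxonomy: training sequences are reduced to their sets of
overlapping 8-mers; the corpus-wide word prior is (n + 0.5) / (N + 1)
(n sequences containing the word out of N), and the per-label
conditional is (m + prior) / (M + 1) (m of the label's M sequences).
A query is assigned the label maximising the joint log-probability of
its words, and confidence is the percentage of bootstrap trials — each
resampling one eighth of the query's words with replacement — that
agree with the winning label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def kmer_indices(seq: str, k: int = 8) -> np.ndarray:
    """Indices of all overlapping k-mers; words with non-ACGT skipped."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return (windows[valid] * powers).sum(axis=1)


@dataclass
class ClassificationResult:
    query_id: str
    predicted_label: str
    confidence: float  # percent in [0, 100]
    classified: bool  # confidence >= cutoff


class KmerNaiveBayesClassifier:
    """RDP-style naive-Bayes classifier with bootstrap confidence.

    Parameters
    ----------
    word_size:
        k-mer length (default 8).
    n_bootstrap:
        bootstrap trials per query (default 100); each samples
        ``len(words) // word_size`` words with replacement.
    seed:
        seed for the bootstrap RNG; classification is deterministic
        given the seed.

    Fitted attributes (trailing underscore) follow the estimator
    convention: ``labels_`` (sorted), ``log_prob_`` (labels x 4^k).
    """

    def __init__(self, word_size: int = 8, n_bootstrap: int = 100,
                 seed: int = 0):
        self.word_size = word_size
        self.n_bootstrap = n_bootstrap
        self.seed = seed

    def fit(self, sequences: Sequence[str], labels: Sequence[str]
            ) -> "KmerNaiveBayesClassifier":
        if len(sequences) != len(labels):
            raise ValueError("one label per sequence required")
        if not sequences:
            raise ValueError("empty training set")
        k = self.word_size
        if any(len(s) < k for s in sequences):
            raise ValueError(f"training sequences must be >= {k} bases")
        self.labels_ = sorted(set(map(str, labels)))
        label_index = {l: i for i, l in enumerate(self.labels_)}
        n_words = 4 ** k
        n_seqs = len(sequences)

        seen: dict[str, str] = {}
        self.conflicts_ = []
        for seq, lab in zip(sequences, labels):
            key = seq.upper()
            if key in seen and seen[key] != str(lab):
                self.conflicts_.append((seen[key], str(lab)))
            seen.setdefault(key, str(lab))
        if self.conflicts_:
            warnings.warn(f"{len(self.conflicts_)} identical training "
                          "sequences carry conflicting labels; kept "
                          "(ambiguity will surface as low confidence)")

        corpus = np.zeros(n_words, dtype=np.int64)
        per_label = np.zeros((len(self.labels_), n_words), dtype=np.int64)
        label_sizes = np.zeros(len(self.labels_), dtype=np.int64)
        for seq, lab in zip(sequences, labels):
            words = np.unique(kmer_indices(seq, k))
            li = label_index[str(lab)]
            corpus[words] += 1
            per_label[li, words] += 1
            label_sizes[li] += 1
        prior = (corpus + 0.5) / (n_seqs + 1.0)
        with np.errstate(divide="ignore"):
            self.log_prob_ = np.log(
                (per_label + prior[None, :]) /
                (label_sizes[:, None] + 1.0)).astype(np.float32)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "log_prob_"):
            raise RuntimeError("classifier is not fitted")

    def classify(self, query: str, cutoff: float = 80.0,
                 query_id: str = "query",
                 rng: np.random.Generator | None = None
                 ) -> ClassificationResult:
        """Classify one query; confidence from ``n_bootstrap`` trials.

        The predicted label maximises the joint over all the query's
        words (score ties broken by lexicographically first label);
        confidence is the percent of trials whose resampled joint
        agrees with it.  Exact score ties *within a trial* are broken
        uniformly at random, so a query equally supported by several
        labels (e.g. identical training sequences under different
        labels) surfaces as low confidence rather than a confident
        arbitrary call.
        """
        self._check_fitted()
        if len(query) < self.word_size:
            raise ValueError("query shorter than the word size")
        if rng is None:
            rng = np.random.default_rng(self.seed)
        words = kmer_indices(query, self.word_size)
        if words.size == 0:
            raise ValueError("query contains no valid words")
        scores = self.log_prob_[:, words]  # (labels, w)
        joint = scores.sum(axis=1)
        best = int(np.argmax(joint))  # first max = lexicographically first
        w = words.size
        n_draw = max(1, w // self.word_size)
        draws = rng.integers(0, w, size=(self.n_bootstrap, n_draw))
        trial_scores = scores[:, draws].sum(axis=2)  # (labels, trials)
        winners = np.argmax(trial_scores, axis=0)
        top = trial_scores[winners, np.arange(self.n_bootstrap)]
        tied = trial_scores == top[None, :]
        multi = np.flatnonzero(tied.sum(axis=0) > 1)
        for t in multi:
            winners[t] = rng.choice(np.flatnonzero(tied[:, t]))
        confidence = 100.0 * float(np.mean(winners == best))
        return ClassificationResult(query_id=query_id,
                                    predicted_label=self.labels_[best],
                                    confidence=confidence,
                                    classified=confidence >= cutoff)

    def classify_many(self, queries: Sequence[tuple[str, str]],
                      cutoff: float = 80.0) -> list[ClassificationResult]:
        """Classify ``(query_id, sequence)`` pairs with one seeded RNG."""
        rng = np.random.default_rng(self.seed)
        return [self.classify(seq, cutoff, qid, rng) for qid, seq in queries]
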