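"""Collocation phrase detection over a tokenized corpus.

Frequent adjacent token pairs (a, b) are merged into a single unit
``a_b`` when the discounted pointwise score

    score(a, b) = (count(ab) - delta) * N / (count(a) * count(b))

exceeds a threshold tau, with all counts at least ``min_count``
(``N`` is the total token count).  The discount delta suppresses
phrases made of rare words; pairs with count(ab) <= delta can never
score above zero.  Merging within a document is left-greedy and
non-overlapping.  Multiple passes allow longer phrases (a_b then
a_b_c), one extra word per pass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass
class PhraseVocabulary:
    """Unit inventory after phrase merging: tokens + underscore phrases."""

    unit_to_index: dict[str, int]
    unit_counts: dict[str, int]
    total_tokens: int
    phrase_scores: dict[tuple[str, str], float]
    min_count: int
    discount: float
    threshold: float

    @property
    def size(self) -> int:
        return len(self.unit_to_index)

    @property
    def phrases(self) -> set[str]:
        return {u for u in self.unit_to_index if "_" in u}

    def to_tsv(self, path: str | Path) -> None:
        lines = ["unit\tindex\tcount"]
        for unit, idx in sorted(self.unit_to_index.items(), key=lambda x: x[1]):
            lines.append(f"{unit}\t{idx}\t{self.unit_counts.get(unit, 0)}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def save_corpus(corpus: Iterable[Sequence[str]], path: str | Path) -> None:
    """One document per line, space-separated units."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(" ".join(doc) + "\n")


def load_corpus(path: str | Path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.split() for line in fh]


def pair_score(
    count_ab: int, count_a: int, count_b: int, total: int, discount: float
) -> float:
    """Discounted collocation score of an adjacent pair."""
    if count_a == 0 or count_b == 0:
        return 0.0
    return (count_ab - discount) * total / (count_a * count_b)


def _merge_pass(
    corpus: list[list[str]],
    min_count: int,
    discount: float,
    threshold: float,
) -> tuple[list[list[str]], dict[tuple[str, str], float]]:
    unigram: Counter[str] = Counter()
    bigram: Counter[tuple[str, str]] = Counter()
    total = 0
    for doc in corpus:
        unigram.update(doc)
        total += len(doc)
        bigram.update(zip(doc, doc[1:]))

    accepted: dict[tuple[str, str], float] = {}
    for (a, b), cab in bigram.items():
        if cab < min_count or unigram[a] < min_count or unigram[b] < min_count:
            continue
        s = pair_score(cab, unigram[a], unigram[b], total, discount)
        if s > threshold:
            accepted[(a, b)] = s

    if not accepted:
        return corpus, accepted

    merged_corpus = []
    for doc in corpus:
        merged = []
        i = 0
        while i < len(doc):
            if i + 1 < len(doc) and (doc[i], doc[i + 1]) in accepted:
                merged.append(doc[i] + "_" + doc[i + 1])
                i += 2  # left-greedy, non-overlapping
            else:
                merged.append(doc[i])
                i += 1
        merged_corpus.append(merged)
    return merged_corpus, accepted


def learn_phrases(
    corpus: Sequence[Sequence[str]],
    min_count: int = 5,
    discount: float = 5.0,
    threshold: float = 10.0,
    passes: int = 1,
) -> PhraseVocabulary:
    """Detect phrases and build the unit vocabulary from a corpus."""
    if not corpus or all(not doc for doc in corpus):
        raise ValueError("empty corpus")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")

    docs = [list(doc) for doc in corpus]
    all_scores: dict[tuple[str, str], float] = {}
    for _ in range(passes):
        docs, accepted = _merge_pass(docs, min_count, discount, threshold)
        all_scores.update(accepted)
        if not accepted:
            break

    counts: Counter[str] = Counter()
    total = 0
    for doc in docs:
        counts.update(doc)
        total += len(doc)
    unit_to_index = {u: i for i, (u, _) in enumerate(
        sorted(counts.items(), key=lambda x: (-x[1], x[0]))
    )}
    return PhraseVocabulary(
        unit_to_index=unit_to_index,
        unit_counts=dict(counts),
        total_tokens=total,
        phrase_scores=all_scores,
        min_count=min_count,
        discount=discount,
        threshold=threshold,
    )


def apply_phrases(
    vocab: PhraseVocabulary, tokens: Iterable[str]
) -> list[str]:
    """Re-merge a token stream into the vocabulary's units (left-greedy).

    Used to embed tuning/test/left-out-centre documents with a frozen
    vocabulary; out-of-vocabulary units are kept (the embedding stage
    skips and counts them).
    """
    toks = list(tokens)
    phrases = vocab.phrases
    # iterate until no merge applies, to honour multi-pass phrases
    changed = True
    while changed:
        changed = False
        out: list[str] = []
        i = 0
        while i < len(toks):
            if i + 1 < len(toks) and toks[i] + "_" + toks[i + 1] in phrases:
                out.append(toks[i] + "_" + toks[i + 1])
                i += 2
                changed = True
            else:
                out.append(toks[i])
                i += 1
        toks = out
    return toks
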