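"""Textual feature: binary keyword histogram over a fixed caption vocabulary.

Each image caption is tokenized into lowercase alphanumeric runs; the textual
feature is a V-dimensional binary vector whose v-th entry is 1 iff vocabulary
entry v occurs in the caption (whole-token, case-insensitive; multi-word
entries must appear as consecutive tokens). The vector is intentionally NOT
renormalized to sum 1 — it is a presence indicator, not a frequency histogram;
the kernel-level gamma normalization absorbs its scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize_caption(text: str) -> list[str]:
    """Lowercased maximal alphanumeric runs, in order of appearance."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Vocabulary:
    """Ordered keyword list; order defines the histogram dimension assignment.

    Entries are normalized to lowercase token sequences; duplicates after
    normalization are rejected. Multi-word entries are stored as phrases and
    matched as consecutive token runs.
    """

    keywords: list[str]
    phrases: list[tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("vocabulary must contain at least one keyword")
        phrases = []
        normalized = []
        for entry in self.keywords:
            tokens = tuple(tokenize_caption(entry))
            if not tokens:
                raise ValueError(f"vocabulary entry {entry!r} has no tokens")
            phrases.append(tokens)
            normalized.append(" ".join(tokens))
        if len(set(normalized)) != len(normalized):
            dupes = {t for t in normalized if normalized.count(t) > 1}
            raise ValueError(f"duplicate vocabulary entries after normalization: {sorted(dupes)}")
        self.keywords = normalized
        self.phrases = phrases

    def __len__(self) -> int:
        return len(self.keywords)

    def __contains__(self, term: str) -> bool:
        return " ".join(tokenize_caption(term)) in set(self.keywords)

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        """Load a vocabulary file: one keyword or phrase per line, `#` comments."""
        terms = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                terms.append(line)
        return cls(terms)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.keywords) + "\n")


def default_vocabulary() -> Vocabulary:
    """The bundled 90-term modality vocabulary.

    A reconstruction of a typical modality-indicative caption vocabulary
    (modality names, acronyms and common caption terms); the exact word list
    used in the original experiments was never published. Any user-supplied
    vocabulary file can replace it.
    """
    text = resources.files("modclass.data").joinpath("default_vocabulary.txt").read_text()
    terms = [ln.split("#", 1)[0].strip() for ln in text.splitlines()]
    return Vocabulary([t for t in terms if t])


def binary_keyword_histogram(caption: str, vocab: Vocabulary) -> np.ndarray:
    """Binary presence vector: entry v = 1 iff vocabulary entry v occurs in *caption*.

    Matching is whole-token and case-insensitive; an entry occurring any
    number of times (one or more) maps to 1. Empty captions give the zero
    vector.
    """
    tokens = tokenize_caption(caption)
    out = np.zeros(len(vocab))
    if not tokens:
        return out
    token_set = set(tokens)
    for v, phrase in enumerate(vocab.phrases):
        if len(phrase) == 1:
            if phrase[0] in token_set:
                out[v] = 1.0
        else:
            k = len(phrase)
            if any(tuple(tokens[i : i + k]) == phrase for i in range(len(tokens) - k + 1)):
                out[v] = 1.0
    return out
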