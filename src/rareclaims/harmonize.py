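"""Disease-name normalization and cross-vocabulary matching.

Disease vocabularies (claims code masters, rare-disease knowledge bases)
spell the same disease inconsistently: full- vs half-width characters,
punctuation, stop words and near-synonymous disease words (e.g. the
Japanese variants 遺伝 / 遺伝的 / 遺伝学的, all meaning "genetic").
Correspondences are established by exact matching of *normalized* labels,
then expanded by two recall-oriented heuristics: terms subordinate (in the
vocabulary hierarchy) to an exactly matched term, and unmatched terms
sharing enough normalized tokens with an exactly matched term's name.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

import pandas as pd

PROV_EXACT = "exact"
PROV_SUBORDINATE = "subordinate"
PROV_TOKEN_OVERLAP = "token_overlap"

_DEFAULT_STOP_WORDS = ("the", "of", "a")
_DEFAULT_PUNCTUATION = tuple(r"""!"#$%&'()*+,-./:;<=>?@[\]^_`{|}~·・、。""")
_DEFAULT_SYNONYMS = {
    "disease": "syndrome",
    "disorder": "syndrome",
    "hereditary": "genetic",
    "遺伝的": "遺伝",
    "遺伝学的": "遺伝",
}


@dataclass(frozen=True)
class NormalizationRules:
    """Configuration of the label normalizer.

    ``synonym_map`` maps variant strings to canonical ones; canonical values
    must be fixed points of normalization (checked at construction).
    CJK-script keys are also applied by substring replacement (longest key
    first) since such labels carry no whitespace token boundaries.
    """

    width_fold: bool = True
    stop_words: tuple[str, ...] = _DEFAULT_STOP_WORDS
    punctuation: tuple[str, ...] = _DEFAULT_PUNCTUATION
    synonym_map: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_SYNONYMS))
    ngram: int = 2

    def __post_init__(self) -> None:
        for variant, canonical in self.synonym_map.items():
            normalized = normalize_label(canonical, self)
            if normalized != canonical:
                raise ValueError(
                    f"synonym target {canonical!r} is not a fixed point of normalization "
                    f"(normalizes to {normalized!r})"
                )


def _fold(s: str, rules: NormalizationRules) -> str:
    if rules.width_fold:
        s = unicodedata.normalize("NFKC", s)
    s = s.casefold()
    # applied twice: rare casefold/NFKC interactions converge by the second pass
    if rules.width_fold:
        s = unicodedata.normalize("NFKC", s)
    return s.casefold()


def normalize_label(raw: str, rules: NormalizationRules | None = None) -> str:
    """Canonical form of a disease label; idempotent.

    Pipeline: width folding (NFKC) and case folding, punctuation stripped to
    spaces, CJK synonym substrings replaced, stop words dropped, token-level
    synonym standardization, whitespace collapsed.
    """
    rules = rules if rules is not None else NormalizationRules()
    s = _fold(raw, rules)
    for ch in rules.punctuation:
        if ch in s:
            s = s.replace(ch, " ")
    cjk_keys = sorted(
        (k for k in rules.synonym_map if not k.isascii()), key=len, reverse=True
    )
    for key in cjk_keys:
        folded_key = _fold(key, rules)
        if folded_key in s:
            s = s.replace(folded_key, rules.synonym_map[key])
    stop = {_fold(w, rules) for w in rules.stop_words}
    tokens = [t for t in s.split() if t not in stop]
    tokens = [rules.synonym_map.get(t, t) for t in tokens]
    return " ".join(tokens)


def token_set(label: str, rules: NormalizationRules | None = None) -> frozenset[str]:
    """Normalized tokens of a label for the word-overlap heuristic.

    Whitespace tokens of the normalized label; tokens written in scripts
    without spaces additionally contribute character n-grams (length
    ``rules.ngram``) so overlap is measurable for e.g. Japanese labels.
    """
    rules = rules if rules is not None else NormalizationRules()
    norm = normalize_label(label, rules)
    tokens = set(norm.split())
    for tok in list(tokens):
        if not tok.isascii() and len(tok) > rules.ngram:
            tokens.update(tok[i : i + rules.ngram] for i in range(len(tok) - rules.ngram + 1))
    return frozenset(tokens)


@dataclass
class DiseaseVocabulary:
    """Labeled disease terms with an optional parent hierarchy."""

    terms: dict[str, str]
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parent in self.hierarchy.items():
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"hierarchy refers to unknown term: {child!r} -> {parent!r}")
        # acyclicity: walk each chain, marking visited
        for start in self.hierarchy:
            seen = {start}
            node = self.hierarchy.get(start)
            while node is not None:
                if node in seen:
                    raise ValueError(f"hierarchy cycle involving {node!r}")
                seen.add(node)
                node = self.hierarchy.get(node)

    def children(self, term_id: str) -> set[str]:
        return {c for c, p in self.hierarchy.items() if p == term_id}

    def descendants(self, term_id: str) -> set[str]:
        """Transitive closure of the child relation."""
        out: set[str] = set()
        frontier = [term_id]
        while frontier:
            node = frontier.pop()
            for child in self.children(node):
                if child not in out:
                    out.add(child)
                    frontier.append(child)
        return out

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "term_id": list(self.terms),
                "label": [self.terms[t] for t in self.terms],
                "parent_id": [self.hierarchy.get(t, "") for t in self.terms],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DiseaseVocabulary":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("term_id", "label"):
            if col not in df.columns:
                raise ValueError(f"vocabulary TSV missing column {col!r}")
        if df["term_id"].duplicated().any():
            dup = df.loc[df["term_id"].duplicated(), "term_id"].iloc[0]
            raise ValueError(f"duplicate term_id in vocabulary TSV: {dup!r}")
        terms = dict(zip(df["term_id"], df["label"]))
        hierarchy = {}
        if "parent_id" in df.columns:
            hierarchy = {
                t: p for t, p in zip(df["term_id"], df["parent_id"]) if p
            }
        return cls(terms=terms, hierarchy=hierarchy)


@dataclass
class MatchSet:
    """Cross-vocabulary term pairs with per-pair provenance."""

    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.provenance)

    def add(self, pair: tuple[str, str], provenance: str) -> None:
        self.provenance.setdefault(pair, provenance)

    def by_provenance(self, provenance: str) -> set[tuple[str, str]]:
        return {p for p, prov in self.provenance.items() if prov == provenance}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((a, b, prov) for (a, b), prov in self.provenance.items())
        return pd.DataFrame(rows, columns=["term_id_a", "term_id_b", "provenance"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def exact_match(
    vocab_a: DiseaseVocabulary,
    vocab_b: DiseaseVocabulary,
    rules: NormalizationRules | None = None,
) -> MatchSet:
    """All pairs of terms whose normalized labels are identical (and non-empty)."""
    rules = rules if rules is not None else NormalizationRules()
    by_label_a: dict[str, list[str]] = {}
    for tid, label in vocab_a.terms.items():
        norm = normalize_label(label, rules)
        if norm:
            by_label_a.setdefault(norm, []).append(tid)
    matches = MatchSet()
    for tid_b, label in vocab_b.terms.items():
        norm = normalize_label(label, rules)
        for tid_a in by_label_a.get(norm, ()):
            matches.add((tid_a, tid_b), PROV_EXACT)
    return matches


def expand_matches(
    matches: MatchSet,
    vocab_a: DiseaseVocabulary,
    vocab_b: DiseaseVocabulary,
    min_shared_tokens: int = 2,
    rules: NormalizationRules | None = None,
) -> MatchSet:
    """Recall-oriented expansion of an exact match set.

    Adds (i) all descendants of exactly matched terms, paired with the
    matched counterpart (provenance ``subordinate``), and (ii) unmatched
    terms sharing at least ``min_shared_tokens`` normalized tokens with an
    exactly matched term's label (provenance ``token_overlap``). Existing
    pairs are never removed; monotone in hierarchy size and decreasing
    ``min_shared_tokens``.
    """
    if min_shared_tokens < 1:
        raise ValueError("min_shared_tokens must be a positive integer")
    rules = rules if rules is not None else NormalizationRules()
    for a, b in matches.pairs:
        if a not in vocab_a.terms or b not in vocab_b.terms:
            raise ValueError(f"match pair refers to unknown terms: ({a!r}, {b!r})")

    out = MatchSet(provenance=dict(matches.provenance))
    exact_pairs = sorted(matches.by_provenance(PROV_EXACT))

    for a, b in exact_pairs:
        for d in sorted(vocab_a.descendants(a)):
            out.add((d, b), PROV_SUBORDINATE)
        for d in sorted(vocab_b.descendants(b)):
            out.add((a, d), PROV_SUBORDINATE)

    matched_a = {a for a, _ in out.pairs}
    matched_b = {b for _, b in out.pairs}
    tokens_a = {a: token_set(vocab_a.terms[a], rules) for a, _ in exact_pairs}
    tokens_b = {b: token_set(vocab_b.terms[b], rules) for _, b in exact_pairs}

    for u in sorted(set(vocab_a.terms) - matched_a):
        u_tokens = token_set(vocab_a.terms[u], rules)
        for a, b in exact_pairs:
            if len(u_tokens & tokens_a[a]) >= min_shared_tokens:
                out.add((u, b), PROV_TOKEN_OVERLAP)
    for u in sorted(set(vocab_b.terms) - matched_b):
        u_tokens = token_set(vocab_b.terms[u], rules)
        for a, b in exact_pairs:
            if len(u_tokens & tokens_b[b]) >= min_shared_tokens:
                out.add((a, u), PROV_TOKEN_OVERLAP)
    return out
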