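"""Turn citation records into drug / adverse-event mentions and co-mention pairs.

An indexed article contributes a *drug mention* when a descriptor that maps
to a known ingredient carries a drug-role qualifier (by default ``AE``,
adverse effects — e.g. *ofloxacin/adverse effects*), and an *ADE mention*
when a descriptor in the adverse-event vocabulary either carries a
manifestation-role qualifier (default ``CI``, chemically induced — e.g.
*tendinopathy/chemically induced*) or belongs to the configured set of
descriptors inherently indicative of an adverse event (e.g. *drug-induced
liver injury*, which needs no qualifier).

Pairing is the within-article cross product of drug mentions and ADE
mentions — the standard co-mention convention, and the one the article-level
2x2 contingency counts require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import Corpus
from .vocab import AdeVocabulary, DrugVocabulary

__all__ = ["ExtractionRules", "ArticleMentions", "extract_mentions", "extract_pairs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionRules:
    """Qualifier roles and inherent-ADE descriptors driving extraction."""

    drug_qualifiers: frozenset[str] = frozenset({"AE"})
    ade_qualifiers: frozenset[str] = frozenset({"CI"})
    inherent_ade_descriptors: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.drug_qualifiers or not self.ade_qualifiers:
            raise ValueError("drug_qualifiers and ade_qualifiers must be non-empty")
        object.__setattr__(self, "drug_qualifiers", frozenset(self.drug_qualifiers))
        object.__setattr__(self, "ade_qualifiers", frozenset(self.ade_qualifiers))
        object.__setattr__(
            self, "inherent_ade_descriptors", frozenset(self.inherent_ade_descriptors)
        )


@dataclass
class ArticleMentions:
    """Per-article drug-term and ADE-term mention sets."""

    article_id: str
    drug_terms: set[str] = field(default_factory=set)
    ade_terms: set[str] = field(default_factory=set)

    @property
    def complete(self) -> bool:
        """True when the article mentions at least one drug and one ADE."""
        return bool(self.drug_terms) and bool(self.ade_terms)


def extract_mentions(
    corpus: Corpus,
    rules: ExtractionRules,
    drug_vocab: DrugVocabulary,
    ade_vocab: AdeVocabulary,
) -> list[ArticleMentions]:
    """Extract per-article drug and ADE mention sets.

    A descriptor enters ``drug_terms`` iff it normalizes to an ingredient and
    carries at least one drug-role qualifier; it enters ``ade_terms`` iff it
    is in the ADE vocabulary and either carries a manifestation-role
    qualifier or is inherently indicative of an ADE.  Unknown descriptors are
    ignored (real indexing contains many headings irrelevant to safety);
    articles with an empty side are retained so downstream code can decide
    what the analysis universe is.
    """
    out: list[ArticleMentions] = []
    n_unknown = 0
    for rec in corpus:
        m = ArticleMentions(article_id=rec.article_id)
        for ann in rec.annotations:
            d = ann.descriptor_id
            known = False
            if drug_vocab.normalize_drug(d) is not None:
                known = True
                if ann.qualifier_ids & rules.drug_qualifiers:
                    m.drug_terms.add(d)
            if d in ade_vocab:
                known = True
                if (
                    ann.qualifier_ids & rules.ade_qualifiers
                    or d in rules.inherent_ade_descriptors
                ):
                    m.ade_terms.add(d)
            if not known:
                n_unknown += 1
        out.append(m)
    if n_unknown:
        logger.info("ignored %d annotations with unknown descriptors", n_unknown)
    return out


def extract_pairs(
    mentions: list[ArticleMentions],
) -> list[tuple[str, str, str]]:
    """Within-article cross product of drug terms and ADE terms.

    Returns (article_id, drug_term, ade_term) tuples, deduplicated within
    each article; the same co-mention in two articles yields two rows.
    """
    pairs: list[tuple[str, str, str]] = []
    for m in mentions:
        for d in sorted(m.drug_terms):
            for a in sorted(m.ade_terms):
                pairs.append((m.article_id, d, a))
    return pairs
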