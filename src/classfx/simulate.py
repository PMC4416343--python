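"""Synthetic citation corpora with planted class effects.

The generator emulates the statistical structure of MEDLINE-style
drug-safety indexing: each article mentions one or a few drugs (annotated
with the adverse-effects qualifier) and, independently per manifestation
term, reports that manifestation (chemically-induced qualifier) with a
baseline probability that a drug can multiply through a planted relative
risk.  Risks are planted per (drug class, ADE class) and either cover every
member (a true class effect) or only a subset of members (a drug-level
effect masquerading as a class signal).  Multi-drug articles take the
maximum relative risk across their drugs, keeping per-article probabilities
well defined.

The matching vocabularies exercise the terminology machinery: a sampled
subset of ingredients gets a salt-form alias routed through the
precise-ingredient map, and one drug is cross-filed with a second code in a
separate (single-member, hence ineligible) class.

Everything is driven by one seeded generator: the same seed reproduces the
corpus byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Annotation, CitationRecord, Corpus
from .vocab import AdeVocabulary, DrugVocabulary

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "GroundTruth",
    "generate_vocabularies",
    "generate_corpus",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A relative risk planted for (drug class, ADE class).

    ``affected_member_fraction`` = 1 plants a uniform class effect; a
    fraction below 1 confines the risk to the first members of the class,
    producing a heterogeneous (subset) effect.
    """

    class_id: str
    ade_class_id: str
    relative_risk: float
    affected_member_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.relative_risk <= 0:
            raise ValueError("relative_risk must be positive")
        if not 0 < self.affected_member_fraction <= 1:
            raise ValueError("affected_member_fraction must be in (0, 1]")


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic corpus.

    Defaults describe a desk-scale literature: 50,000 articles over
    5 drug classes of 6 ingredients and 5 ADE classes of 3 manifestation
    terms, each term appearing at a 2% baseline per article, most articles
    discussing a single drug, plus one irrelevant heading per article on
    average.
    """

    n_classes: int = 5
    members_per_class: int = 6
    n_ade_classes: int = 5
    terms_per_ade_class: int = 3
    n_articles: int = 50_000
    baseline_ade_prob: float = 0.02
    drugs_per_article: dict[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.25, 3: 0.05}
    )
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    distractor_annotation_rate: float = 1.0
    n_distractor_descriptors: int = 50
    pin_alias_fraction: float = 0.2
    dual_code_drug: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_ade_prob <= 1:
            raise ValueError("baseline_ade_prob must be a probability")
        total = sum(self.drugs_per_article.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("drugs_per_article probabilities must sum to 1")
        if max(self.drugs_per_article) > self.n_classes * self.members_per_class:
            raise ValueError("more drugs per article than drugs exist")

    # deterministic id layout ------------------------------------------------

    def class_ids(self) -> list[str]:
        return [f"ATC{j:02d}" for j in range(self.n_classes)]

    def class_member_ids(self, j: int) -> list[str]:
        base = j * self.members_per_class
        return [f"ING{base + k:03d}" for k in range(self.members_per_class)]

    def ingredient_ids(self) -> list[str]:
        return [
            ing for j in range(self.n_classes) for ing in self.class_member_ids(j)
        ]

    def ade_class_ids(self) -> list[str]:
        return [f"ADC{j:02d}" for j in range(self.n_ade_classes)]

    def ade_term_ids(self, j: int) -> list[str]:
        return [f"ADE{j:02d}_{k}" for k in range(self.terms_per_ade_class)]


@dataclass
class GroundTruth:
    """Planted truth: expected verdict per (class, ADE class) and true RRs."""

    expected_verdicts: dict[tuple[str, str], str]
    drug_term_rr: dict[tuple[str, str], float]
    seed: int

    def rr(self, ingredient_id: str, term_id: str) -> float:
        return self.drug_term_rr.get((ingredient_id, term_id), 1.0)


def generate_vocabularies(
    config: SyntheticConfig,
) -> tuple[DrugVocabulary, AdeVocabulary]:
    """Build drug and ADE vocabularies matching the configured layout."""
    rng = np.random.default_rng(config.seed)
    term_to_ingredient: dict[str, str] = {}
    pin_to_in: dict[str, str] = {}
    ing_to_codes: dict[str, set[str]] = {}
    code_to_class: dict[str, tuple[str, str]] = {}

    for j, cls in enumerate(config.class_ids()):
        for k, ing in enumerate(config.class_member_ids(j)):
            code = f"{cls}{k + 1:02d}"
            term_to_ingredient[f"D_{ing}"] = ing
            ing_to_codes.setdefault(ing, set()).add(code)
            code_to_class[code] = (cls, f"synthetic class {j}")

    ingredients = config.ingredient_ids()
    n_alias = int(round(config.pin_alias_fraction * len(ingredients)))
    if n_alias:
        aliased = rng.choice(len(ingredients), size=n_alias, replace=False)
        for ix in sorted(aliased):
            ing = ingredients[ix]
            pin = f"{ing}_PIN"
            pin_to_in[pin] = ing
            term_to_ingredient[f"D_{ing}_salt"] = pin

    if config.dual_code_drug and ingredients:
        # cross-file the first drug under an alternate-route class; with a
        # single member it stays below any sensible eligibility threshold
        code_to_class["ATCXX01"] = ("ATCXX", "alternate route class")
        ing_to_codes[ingredients[0]].add("ATCXX01")

    drug_vocab = DrugVocabulary(
        term_to_ingredient=term_to_ingredient,
        pin_to_in=pin_to_in,
        ingredient_to_codes=ing_to_codes,
        code_to_class=code_to_class,
    )

    term_to_trees: dict[str, set[str]] = {}
    tree_to_term: dict[str, str] = {}
    for j, acls in enumerate(config.ade_class_ids()):
        parent = f"C{j:02d}.500"
        term_to_trees[acls] = {parent}
        tree_to_term[parent] = acls
        for k, term in enumerate(config.ade_term_ids(j)):
            tree = f"{parent}.{100 + k}"
            term_to_trees[term] = {tree}
            tree_to_term[tree] = term
    ade_vocab = AdeVocabulary(term_to_trees=term_to_trees, tree_to_term=tree_to_term)
    return drug_vocab, ade_vocab


def _ground_truth(config: SyntheticConfig) -> GroundTruth:
    verdicts: dict[tuple[str, str], str] = {}
    rr: dict[tuple[str, str], float] = {}
    for cls in config.class_ids():
        for acls in config.ade_class_ids():
            verdicts[(cls, acls)] = "null"
    for eff in config.planted_effects:
        j = config.class_ids().index(eff.class_id)
        aj = config.ade_class_ids().index(eff.ade_class_id)
        members = config.class_member_ids(j)
        n_aff = max(1, int(round(eff.affected_member_fraction * len(members))))
        for ing in members[:n_aff]:
            for term in config.ade_term_ids(aj):
                rr[(ing, term)] = eff.relative_risk
        if eff.relative_risk == 1.0:
            verdict = "null"
        elif n_aff == len(members):
            verdict = "class_effect"
        else:
            verdict = "heterogeneous"
        verdicts[(eff.class_id, eff.ade_class_id)] = verdict
    return GroundTruth(expected_verdicts=verdicts, drug_term_rr=rr, seed=config.seed)


def generate_corpus(
    config: SyntheticConfig,
    drug_vocab: DrugVocabulary,
    ade_vocab: AdeVocabulary,
) -> tuple[Corpus, GroundTruth]:
    """Sample a citation corpus under the configured risk model."""
    rng = np.random.default_rng(config.seed)
    ingredients = config.ingredient_ids()
    terms = [t for j in range(config.n_ade_classes) for t in config.ade_term_ids(j)]
    n_ing, n_terms, n = len(ingredients), len(terms), config.n_articles

    truth = _ground_truth(config)
    R = np.ones((n_ing, n_terms))
    ing_ix = {x: i for i, x in enumerate(ingredients)}
    term_ix = {x: i for i, x in enumerate(terms)}
    for (ing, term), v in truth.drug_term_rr.items():
        R[ing_ix[ing], term_ix[term]] = v

    counts_support = np.array(sorted(config.drugs_per_article))
    counts_probs = np.array(
        [config.drugs_per_article[int(k)] for k in counts_support]
    )
    counts = rng.choice(counts_support, size=n, p=counts_probs)

    drug_lists: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    max_rr = np.ones((n, n_terms))
    for k in np.unique(counts):
        rows = np.flatnonzero(counts == k)
        # uniform sampling of k distinct drugs per article
        picks = rng.random((len(rows), n_ing)).argsort(axis=1)[:, :k]
        max_rr[rows] = R[picks].max(axis=1)
        for r, p in zip(rows, picks):
            drug_lists[r] = p

    p_ade = np.clip(config.baseline_ade_prob * max_rr, 0.0, 1.0)
    ade_hits = rng.random((n, n_terms)) < p_ade

    n_distract = rng.poisson(config.distractor_annotation_rate, size=n)
    distract_pool = [f"DX{i:03d}" for i in range(config.n_distractor_descriptors)]
    distract_picks = rng.integers(0, len(distract_pool), size=int(n_distract.sum()))

    # salt-form aliases: articles may index the salt rather than the base form
    salt_terms = {
        ing: f"D_{ing}_salt"
        for ing in ingredients
        if f"D_{ing}_salt" in drug_vocab.term_to_ingredient
    }
    use_salt = rng.random(n * int(counts.max())) < 0.3

    records: list[CitationRecord] = []
    ae_qual = frozenset({"AE"})
    ci_qual = frozenset({"CI"})
    no_qual: frozenset[str] = frozenset()
    d_off = 0
    u_off = 0
    for i in range(n):
        anns: list[Annotation] = []
        for d in drug_lists[i]:
            ing = ingredients[int(d)]
            term = f"D_{ing}"
            if ing in salt_terms and use_salt[u_off]:
                term = salt_terms[ing]
            u_off += 1
            anns.append(Annotation(term, ae_qual))
        for t in np.flatnonzero(ade_hits[i]):
            anns.append(Annotation(terms[int(t)], ci_qual))
        for _ in range(int(n_distract[i])):
            anns.append(Annotation(distract_pool[int(distract_picks[d_off])], no_qual))
            d_off += 1
        records.append(CitationRecord(f"PMID{i:07d}", tuple(anns)))
    return Corpus(records=records), truth
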