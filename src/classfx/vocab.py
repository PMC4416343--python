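"""Table-driven drug and adverse-event terminologies.

The drug side mirrors how MEDLINE drug headings reach ATC-style classes
through RxNorm: a literature *term* maps to an *ingredient*; salt/ester
forms ("precise ingredients", PIN) are normalized to their base ingredient
(IN); an ingredient carries one or more drug *codes* (e.g. J01MA01 and
S01AE01 for ofloxacin, which is filed both as a systemic antibacterial and
as an ophthalmological); each code belongs to a fourth-level *class*.  The
ingredient — not the code — is the unit of class membership.

The adverse-event side mirrors MeSH: a manifestation term owns one or more
dot-separated tree numbers, and terms are aggregated to the second level of
the hierarchy (e.g. Rhabdomyolysis C05.651.807 and Tendinopathy C05.651.869
both roll up to Muscular Diseases C05.651).

All tables are TSV with a header row; see the ``load_*`` functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "DrugVocabulary",
    "AdeVocabulary",
    "load_drug_vocabulary",
    "load_ade_vocabulary",
    "eligible_classes",
]


def _resolve_pin_chains(pin_to_in: dict[str, str]) -> dict[str, str]:
    """Collapse PIN->IN chains so every lookup resolves in one hop."""
    resolved: dict[str, str] = {}
    for pin in pin_to_in:
        cur = pin
        seen = {cur}
        while cur in pin_to_in:
            cur = pin_to_in[cur]
            if cur in seen:
                raise ValueError(f"cycle in precise-ingredient map at {pin!r}")
            seen.add(cur)
        resolved[pin] = cur
    return resolved


@dataclass
class DrugVocabulary:
    """Maps from literature drug terms to ingredients, codes and classes."""

    term_to_ingredient: dict[str, str]
    pin_to_in: dict[str, str] = field(default_factory=dict)
    ingredient_to_codes: dict[str, set[str]] = field(default_factory=dict)
    code_to_class: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pin_to_in = _resolve_pin_chains(dict(self.pin_to_in))
        missing = {
            code
            for codes in self.ingredient_to_codes.values()
            for code in codes
            if code not in self.code_to_class
        }
        if missing:
            raise ValueError(f"codes without a class assignment: {sorted(missing)[:5]}")

    @property
    def ingredients(self) -> set[str]:
        """All base-ingredient identifiers known to the vocabulary."""
        ings = set(self.ingredient_to_codes)
        ings.update(self.pin_to_in.values())
        ings.update(
            self.pin_to_in.get(i, i) for i in self.term_to_ingredient.values()
        )
        return ings

    def normalize_drug(self, term_id: str) -> str | None:
        """Resolve a term to its base ingredient, or None if unmapped.

        Idempotent: passing an ingredient id returns it unchanged.
        """
        ing = self.term_to_ingredient.get(term_id)
        if ing is None:
            if term_id in self.pin_to_in or term_id in self.ingredients:
                ing = term_id
            else:
                return None
        return self.pin_to_in.get(ing, ing)

    def drug_classes(self, ingredient_id: str) -> set[str]:
        """Union of class ids over all of the ingredient's codes."""
        return {
            self.code_to_class[code][0]
            for code in self.ingredient_to_codes.get(ingredient_id, ())
        }

    def class_name(self, class_id: str) -> str:
        for cid, cname in self.code_to_class.values():
            if cid == class_id:
                return cname
        return class_id

    def class_members(self, ingredients: set[str] | None = None) -> dict[str, set[str]]:
        """Class -> member-ingredient map, optionally restricted to a subset."""
        pool = self.ingredients if ingredients is None else ingredients
        members: dict[str, set[str]] = {}
        for ing in pool:
            for cls in self.drug_classes(ing):
                members.setdefault(cls, set()).add(ing)
        return members


def _second_level_prefix(tree_number: str) -> str:
    parts = tree_number.split(".")
    return ".".join(parts[:2])


@dataclass
class AdeVocabulary:
    """Adverse-event terms with hierarchy tree numbers.

    ``tree_to_term`` must name an owning term for every second-level prefix
    reachable from ``term_to_trees`` (a term sitting at or above the second
    level owns its own tree number and aggregates to itself).
    """

    term_to_trees: dict[str, set[str]]
    tree_to_term: dict[str, str]

    def __post_init__(self) -> None:
        orphans = {
            _second_level_prefix(t)
            for trees in self.term_to_trees.values()
            for t in trees
            if _second_level_prefix(t) not in self.tree_to_term
        }
        if orphans:
            raise ValueError(
                f"second-level tree prefixes without an owning term: {sorted(orphans)[:5]}"
            )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.term_to_trees

    def aggregate_ade(self, term_id: str) -> set[str]:
        """Second-level class term(s) a manifestation term rolls up to.

        Each tree number is truncated to its first two dot-separated
        components; a term with several tree numbers contributes to every
        second-level class it sits under.  Unknown terms yield an empty set.
        """
        trees = self.term_to_trees.get(term_id, set())
        return {self.tree_to_term[_second_level_prefix(t)] for t in trees}

    @property
    def ade_classes(self) -> set[str]:
        """All second-level class term ids reachable from the vocabulary."""
        return {
            cls for term in self.term_to_trees for cls in self.aggregate_ade(term)
        }

    def class_terms(self) -> dict[str, set[str]]:
        """ADE class -> set of member terms (a class term is its own member)."""
        out: dict[str, set[str]] = {}
        for term in self.term_to_trees:
            for cls in self.aggregate_ade(term):
                out.setdefault(cls, set()).add(term)
        return out


def load_drug_vocabulary(
    drug_terms: str | Path,
    pin_to_in: str | Path,
    ingredient_codes: str | Path,
    code_classes: str | Path,
) -> DrugVocabulary:
    """Load the four drug-terminology TSV tables.

    Expected columns: drug_terms (term_id, ingredient_id);
    pin_to_in (pin_ingredient_id, ingredient_id);
    ingredient_codes (ingredient_id, code_id);
    code_classes (code_id, class_id, class_name).
    """
    terms = pd.read_csv(drug_terms, sep="\t", dtype=str)
    pins = pd.read_csv(pin_to_in, sep="\t", dtype=str)
    codes = pd.read_csv(ingredient_codes, sep="\t", dtype=str)
    classes = pd.read_csv(code_classes, sep="\t", dtype=str)
    ing_to_codes: dict[str, set[str]] = {}
    for ing, code in zip(codes["ingredient_id"], codes["code_id"]):
        ing_to_codes.setdefault(ing, set()).add(code)
    return DrugVocabulary(
        term_to_ingredient=dict(zip(terms["term_id"], terms["ingredient_id"])),
        pin_to_in=dict(zip(pins["pin_ingredient_id"], pins["ingredient_id"])),
        ingredient_to_codes=ing_to_codes,
        code_to_class={
            row.code_id: (row.class_id, row.class_name)
            for row in classes.itertuples()
        },
    )


def load_ade_vocabulary(ade_trees: str | Path) -> AdeVocabulary:
    """Load the ADE terminology TSV (columns: term_id, tree_number)."""
    df = pd.read_csv(ade_trees, sep="\t", dtype=str)
    term_to_trees: dict[str, set[str]] = {}
    tree_to_term: dict[str, str] = {}
    for term, tree in zip(df["term_id"], df["tree_number"]):
        term_to_trees.setdefault(term, set()).add(tree)
        tree_to_term[tree] = term
    return AdeVocabulary(term_to_trees=term_to_trees, tree_to_term=tree_to_term)


def eligible_classes(
    observed_ingredients: set[str],
    vocab: DrugVocabulary,
    min_members: int = 4,
) -> dict[str, set[str]]:
    """Drug classes with at least ``min_members`` observed member ingredients.

    Membership is restricted to the observed ingredients; classes below the
    threshold are dropped entirely.  The default of 4 trades class coverage
    against having enough members to characterize the class.
    """
    members = vocab.class_members(observed_ingredients)
    return {
        cls: mem for cls, mem in members.items() if len(mem) >= min_members
    }
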