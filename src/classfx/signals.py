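"""Article-level contingency tables and PRR disproportionality signals.

The proportional reporting ratio for a (drug, adverse event) pair is built
from an article-level 2x2 table over the analysis universe::

                        with this ADE   without this ADE
    mentioning drug            a               b
    not mentioning drug        c               d

    PRR = (a / (a + b)) / (c / (c + d))

A PRR well above 1 means the event is reported disproportionately often
with that drug.  Signals are computed for every pair that co-occurs in at
least one article (a >= 1); when b or c is zero the usual zero-cell
correction adds 0.5 to all four cells to keep the ratio finite.  Pairs that
never co-occur get a neutral PRR of 1 (log-PRR 0) when a dense matrix is
requested.  The same machinery serves four resolutions: drug x ADE term,
drug x ADE class, drug class x ADE term, and drug class x ADE class, with
class rows counting an article once however many member drugs it mentions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .extraction import ArticleMentions
from .vocab import AdeVocabulary, DrugVocabulary

__all__ = [
    "ContingencyTable",
    "SignalRecord",
    "SignalMatrix",
    "AnalysisUniverse",
    "build_universe",
    "contingency",
    "prr",
    "signal_scan",
    "to_matrix",
]

Level = Literal["drug_x_ade", "drug_x_ade_class", "class_x_ade", "class_x_ade_class"]

LEVELS: tuple[str, ...] = (
    "drug_x_ade",
    "drug_x_ade_class",
    "class_x_ade",
    "class_x_ade_class",
)


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cells of one article-level 2x2 table.

    Cells are floats so the +0.5-corrected table can be represented; raw
    tables always hold integers that sum to the universe size.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "ContingencyTable":
        """The table with 0.5 added to every cell."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


def prr(table: ContingencyTable) -> tuple[float, bool]:
    """PRR of a 2x2 table, applying the zero-cell correction when needed.

    If b or c is zero, 0.5 is first added to all four cells.  Returns the
    ratio and a flag saying whether the correction fired.  Raises if either
    row margin is empty (the proportion is undefined).
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("PRR undefined: empty row margin in contingency table")
    corrected = table.b == 0 or table.c == 0
    t = table.corrected() if corrected else table
    value = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    return value, corrected


@dataclass(frozen=True)
class SignalRecord:
    """One (row entity, column event) disproportionality signal."""

    row_id: str
    col_id: str
    level: str
    table: ContingencyTable | None
    prr: float
    log_prr: float
    corrected: bool = False

    @classmethod
    def from_table(
        cls, row_id: str, col_id: str, level: str, table: ContingencyTable
    ) -> "SignalRecord":
        value, corrected = prr(table)
        return cls(row_id, col_id, level, table, value, math.log(value), corrected)

    @classmethod
    def neutral(cls, row_id: str, col_id: str, level: str) -> "SignalRecord":
        """The neutral record (PRR = 1) for a pair that never co-occurs."""
        return cls(row_id, col_id, level, None, 1.0, 0.0, False)


@dataclass
class SignalMatrix:
    """Dense log-PRR grid; cells for non-co-occurring pairs hold ln(1) = 0."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match axis labels")


class AnalysisUniverse:
    """The set of articles entering every contingency table, plus indicators.

    The universe is restricted to articles with at least one drug mention
    and at least one ADE mention, so the four cells of every table form a
    true partition of a coherent denominator population.  Drug mentions are
    normalized to base ingredients on entry; ADE terms additionally project
    onto their second-level classes.
    """

    def __init__(
        self,
        mentions: Sequence[ArticleMentions],
        drug_vocab: DrugVocabulary,
        ade_vocab: AdeVocabulary,
    ) -> None:
        complete: list[ArticleMentions] = []
        norm_drugs: list[set[str]] = []
        for m in mentions:
            ings = {
                ing
                for t in m.drug_terms
                if (ing := drug_vocab.normalize_drug(t)) is not None
            }
            if ings and m.ade_terms:
                complete.append(m)
                norm_drugs.append(ings)
        if not complete:
            raise ValueError("empty analysis universe: no article mentions both a drug and an ADE")

        self.drug_vocab = drug_vocab
        self.ade_vocab = ade_vocab
        self.mentions = complete
        self.article_ids = [m.article_id for m in complete]
        self.ingredient_ids = sorted(set().union(*norm_drugs))
        self.ade_term_ids = sorted(set().union(*(m.ade_terms for m in complete)))
        ade_classes: set[str] = set()
        for t in self.ade_term_ids:
            ade_classes |= ade_vocab.aggregate_ade(t)
        self.ade_class_ids = sorted(ade_classes)

        ing_ix = {x: i for i, x in enumerate(self.ingredient_ids)}
        term_ix = {x: i for i, x in enumerate(self.ade_term_ids)}
        cls_ix = {x: i for i, x in enumerate(self.ade_class_ids)}
        n = len(complete)
        self.D = np.zeros((n, len(ing_ix)), dtype=bool)
        self.E = np.zeros((n, len(term_ix)), dtype=bool)
        for i, (m, ings) in enumerate(zip(complete, norm_drugs)):
            for ing in ings:
                self.D[i, ing_ix[ing]] = True
            for t in m.ade_terms:
                self.E[i, term_ix[t]] = True
        self.Ec = np.zeros((n, len(cls_ix)), dtype=bool)
        for t, j in term_ix.items():
            for cls in ade_vocab.aggregate_ade(t):
                self.Ec[:, cls_ix[cls]] |= self.E[:, j]
        self._ing_ix = ing_ix
        self._term_ix = term_ix
        self._cls_ix = cls_ix

    def __len__(self) -> int:
        return len(self.article_ids)

    # ---- indicator vectors -------------------------------------------------

    def drug_indicator(self, ingredient_id: str) -> np.ndarray:
        if ingredient_id not in self._ing_ix:
            return np.zeros(len(self), dtype=bool)
        return self.D[:, self._ing_ix[ingredient_id]]

    def drug_class_indicator(self, members: set[str]) -> np.ndarray:
        """Articles mentioning any member ingredient of a class."""
        cols = [self._ing_ix[m] for m in members if m in self._ing_ix]
        if not cols:
            return np.zeros(len(self), dtype=bool)
        return self.D[:, cols].any(axis=1)

    def ade_indicator(self, term_id: str) -> np.ndarray:
        if term_id not in self._term_ix:
            return np.zeros(len(self), dtype=bool)
        return self.E[:, self._term_ix[term_id]]

    def ade_class_indicator(self, class_id: str) -> np.ndarray:
        if class_id not in self._cls_ix:
            return np.zeros(len(self), dtype=bool)
        return self.Ec[:, self._cls_ix[class_id]]

    def table_from_indicators(
        self, rows: np.ndarray, cols: np.ndarray
    ) -> ContingencyTable:
        a = int(np.sum(rows & cols))
        b = int(np.sum(rows & ~cols))
        c = int(np.sum(~rows & cols))
        d = int(np.sum(~rows & ~cols))
        return ContingencyTable(a, b, c, d)


def build_universe(
    mentions: Sequence[ArticleMentions],
    drug_vocab: DrugVocabulary,
    ade_vocab: AdeVocabulary,
) -> AnalysisUniverse:
    """Build the analysis universe (articles with >=1 drug and >=1 ADE)."""
    return AnalysisUniverse(mentions, drug_vocab, ade_vocab)


def contingency(
    universe: AnalysisUniverse,
    row_predicate: Callable[[ArticleMentions], bool],
    col_predicate: Callable[[ArticleMentions], bool],
) -> ContingencyTable:
    """Count the 2x2 table for arbitrary article predicates.

    Predicate-based and O(universe); the vectorized paths in
    :func:`signal_scan` are the production route, this is the general one.
    """
    a = b = c = d = 0
    for m in universe.mentions:
        r, col = row_predicate(m), col_predicate(m)
        if r and col:
            a += 1
        elif r:
            b += 1
        elif col:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _row_matrix(
    universe: AnalysisUniverse,
    level: str,
    class_members: dict[str, set[str]] | None,
    row_ids: Sequence[str] | None,
) -> tuple[list[str], np.ndarray]:
    if level.startswith("class"):
        if class_members is None:
            raise ValueError("class-level scan requires class_members")
        ids = sorted(class_members) if row_ids is None else list(row_ids)
        R = np.column_stack(
            [universe.drug_class_indicator(class_members[c]) for c in ids]
        ) if ids else np.zeros((len(universe), 0), dtype=bool)
    else:
        ids = universe.ingredient_ids if row_ids is None else list(row_ids)
        R = np.column_stack([universe.drug_indicator(i) for i in ids]) if ids else (
            np.zeros((len(universe), 0), dtype=bool)
        )
    return ids, R


def _col_matrix(
    universe: AnalysisUniverse, level: str, col_ids: Sequence[str] | None
) -> tuple[list[str], np.ndarray]:
    if level.endswith("ade_class"):
        ids = universe.ade_class_ids if col_ids is None else list(col_ids)
        C = np.column_stack([universe.ade_class_indicator(c) for c in ids]) if ids else (
            np.zeros((len(universe), 0), dtype=bool)
        )
    else:
        ids = universe.ade_term_ids if col_ids is None else list(col_ids)
        C = np.column_stack([universe.ade_indicator(c) for c in ids]) if ids else (
            np.zeros((len(universe), 0), dtype=bool)
        )
    return ids, C


def signal_scan(
    universe: AnalysisUniverse,
    level: Level,
    class_members: dict[str, set[str]] | None = None,
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
    include_neutral: bool = False,
) -> list[SignalRecord]:
    """Compute PRR signals for all (row, column) pairs at one resolution.

    Only pairs co-occurring in at least one article (a >= 1) yield a real
    record; with ``include_neutral`` the remaining pairs are materialized
    with the neutral PRR of 1 (useful for dense matrices).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    rids, R = _row_matrix(universe, level, class_members, row_ids)
    cids, C = _col_matrix(universe, level, col_ids)
    n = len(universe)
    Ri = R.astype(np.int64)
    Ci = C.astype(np.int64)
    A = Ri.T @ Ci
    row_tot = Ri.sum(axis=0)
    col_tot = Ci.sum(axis=0)
    records: list[SignalRecord] = []
    for i, rid in enumerate(rids):
        for j, cid in enumerate(cids):
            a = int(A[i, j])
            if a < 1:
                if include_neutral:
                    records.append(SignalRecord.neutral(rid, cid, level))
                continue
            b = int(row_tot[i]) - a
            c = int(col_tot[j]) - a
            d = n - a - b - c
            records.append(
                SignalRecord.from_table(rid, cid, level, ContingencyTable(a, b, c, d))
            )
    return records


def to_matrix(
    records: Sequence[SignalRecord],
    row_ids: Sequence[str],
    col_ids: Sequence[str],
) -> SignalMatrix:
    """Assemble a dense log-PRR matrix; absent pairs are neutral (0)."""
    rix = {r: i for i, r in enumerate(row_ids)}
    cix = {c: i for i, c in enumerate(col_ids)}
    values = np.zeros((len(row_ids), len(col_ids)))
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.row_id, rec.col_id)
        if key in seen:
            raise ValueError(f"duplicate signal record for {key}")
        seen.add(key)
        if rec.row_id in rix and rec.col_id in cix:
            values[rix[rec.row_id], cix[rec.col_id]] = rec.log_prr
    return SignalMatrix(list(row_ids), list(col_ids), values)
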