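"""Model/Results interface tying the pipeline together.

:class:`ClassEffectModel` is constructed from a citation corpus plus
terminologies and, on :meth:`~ClassEffectModel.fit`, runs the whole
analysis: mention extraction, universe construction, drug- and class-level
PRR scans, eligibility filtering, and the cluster-then-test class-effect
determination for every eligible (drug class, adverse event) pair.  The
returned :class:`ClassEffectResults` carries per-pair verdicts with their
test statistics, exposes them as a DataFrame, prints a summary table, and
hangs signal matrices and heat maps off the fitted state.

    >>> model = ClassEffectModel.from_corpus(corpus, drug_vocab, ade_vocab)
    >>> res = model.fit(alpha=0.05)
    >>> print(res.summary())
    >>> res.frame.head()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .class_effect import (
    VERDICT_HETEROGENEOUS,
    VERDICT_HOMOGENEOUS,
    VERDICT_SINGLE,
    ClassEffectResult,
    class_effect_scan,
    eligible_pairs,
)
from .extraction import ArticleMentions, ExtractionRules, extract_mentions
from .heatmap import ClusteredMatrix, build_heatmap
from .io import Corpus
from .signals import (
    AnalysisUniverse,
    SignalMatrix,
    SignalRecord,
    build_universe,
    signal_scan,
    to_matrix,
)
from .vocab import AdeVocabulary, DrugVocabulary, eligible_classes

__all__ = ["ClassEffectModel", "ClassEffectResults"]


class ClassEffectModel:
    """Class-effect analysis of a drug-safety co-mention corpus.

    Parameters
    ----------
    universe
        The analysis universe (articles with at least one drug and one ADE
        mention), typically built via :meth:`from_corpus`.
    class_members
        Drug class -> member ingredients, already filtered to classes with
        enough members to characterize (default threshold 4).
    ade_level
        Column unit for the determination: ``"class"`` tests each
        second-level ADE class (the default, matching how broad events such
        as *sexual dysfunctions* are assessed), ``"term"`` tests individual
        manifestation terms.
    """

    def __init__(
        self,
        universe: AnalysisUniverse,
        class_members: dict[str, set[str]],
        ade_level: Literal["class", "term"] = "class",
    ) -> None:
        if ade_level not in ("class", "term"):
            raise ValueError("ade_level must be 'class' or 'term'")
        self.universe = universe
        self.class_members = class_members
        self.ade_level = ade_level

    @classmethod
    def from_corpus(
        cls,
        corpus: Corpus,
        drug_vocab: DrugVocabulary,
        ade_vocab: AdeVocabulary,
        rules: ExtractionRules | None = None,
        min_members: int = 4,
        ade_level: Literal["class", "term"] = "class",
    ) -> "ClassEffectModel":
        """Extract mentions, build the universe and apply the class filter."""
        rules = rules or ExtractionRules()
        mentions = extract_mentions(corpus, rules, drug_vocab, ade_vocab)
        return cls.from_mentions(
            mentions, drug_vocab, ade_vocab, min_members=min_members,
            ade_level=ade_level,
        )

    @classmethod
    def from_mentions(
        cls,
        mentions: Sequence[ArticleMentions],
        drug_vocab: DrugVocabulary,
        ade_vocab: AdeVocabulary,
        min_members: int = 4,
        ade_level: Literal["class", "term"] = "class",
    ) -> "ClassEffectModel":
        universe = build_universe(mentions, drug_vocab, ade_vocab)
        members = eligible_classes(
            set(universe.ingredient_ids), drug_vocab, min_members=min_members
        )
        return cls(universe, members, ade_level=ade_level)

    def fit(self, alpha: float = 0.05) -> "ClassEffectResults":
        """Run the PRR scans and classify every eligible pair."""
        drug_lv = "drug_x_ade_class" if self.ade_level == "class" else "drug_x_ade"
        cls_lv = "class_x_ade_class" if self.ade_level == "class" else "class_x_ade"
        drug_records = signal_scan(self.universe, drug_lv)
        class_records = signal_scan(
            self.universe, cls_lv, class_members=self.class_members
        )
        eligible = eligible_pairs(self.class_members, drug_records)
        results = class_effect_scan(
            eligible, drug_records, self.class_members, class_records, alpha=alpha
        )
        return ClassEffectResults(
            model=self,
            results=results,
            drug_records=drug_records,
            class_records=class_records,
            alpha=alpha,
        )


@dataclass
class ClassEffectResults:
    """Fitted class-effect scan: verdicts, statistics and signal state."""

    model: ClassEffectModel
    results: list[ClassEffectResult]
    drug_records: list[SignalRecord]
    class_records: list[SignalRecord]
    alpha: float
    _class_prr: dict[tuple[str, str], float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._class_prr = {
            (r.row_id, r.col_id): r.prr for r in self.class_records
        }

    @property
    def frame(self) -> pd.DataFrame:
        """One row per eligible (class, ADE) pair with verdict and stats."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "class_id": r.class_id,
                    "ade_id": r.ade_id,
                    "n_members": len(r.member_log_prrs),
                    "class_prr": self._class_prr.get((r.class_id, r.ade_id)),
                    "n_clusters": r.n_clusters,
                    "mean_low": r.cluster_means[0],
                    "mean_high": r.cluster_means[1] if r.n_clusters == 2 else None,
                    "t_stat": r.t_stat,
                    "dof": r.dof,
                    "p_value": r.p_value,
                    "verdict": r.verdict,
                    "class_effect": r.is_class_effect,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "class_id", "ade_id", "n_members", "class_prr", "n_clusters",
                "mean_low", "mean_high", "t_stat", "dof", "p_value",
                "verdict", "class_effect",
            ],
        )

    def summary(self) -> str:
        """Human-readable account of the scan, statsmodels-style."""
        n = len(self.results)
        n_single = sum(1 for r in self.results if r.verdict == VERDICT_SINGLE)
        n_homog = sum(1 for r in self.results if r.verdict == VERDICT_HOMOGENEOUS)
        n_heter = sum(1 for r in self.results if r.verdict == VERDICT_HETEROGENEOUS)
        lines = [
            "Class-effect determination".center(72),
            "=" * 72,
            f"Articles in universe:     {len(self.model.universe)}",
            f"Drug classes (eligible):  {len(self.model.class_members)}",
            f"ADE column unit:          {self.model.ade_level}",
            f"Eligible (class, ADE):    {n}",
            f"Significance level alpha: {self.alpha}",
            "-" * 72,
            f"Single cluster (class effect by design):    {n_single}",
            f"Two clusters, no significant difference:    {n_homog}",
            f"Two clusters, significant difference:       {n_heter}",
            f"Class-effect verdicts in total:             {n_single + n_homog}",
            "=" * 72,
        ]
        if n:
            df = self.frame
            with pd.option_context("display.width", 120, "display.max_rows", 40):
                lines.append(df.to_string(index=False, float_format="%.4g"))
        lines.append(
            "Note: p-values are not corrected for multiple comparisons across"
        )
        lines.append("the scan; significant heterogeneity with high means in both")
        lines.append("clusters may still reflect a class effect (expert judgment).")
        return "\n".join(lines)

    # ---- signal matrices and heat maps ------------------------------------

    def signal_matrix(self, level: str) -> SignalMatrix:
        """Dense log-PRR matrix at one of the four scan resolutions."""
        u = self.model.universe
        recs = signal_scan(
            u, level, class_members=self.class_members_for(level),
            include_neutral=True,
        )
        if level.startswith("class"):
            rows = sorted(self.model.class_members)
        else:
            rows = u.ingredient_ids
        cols = u.ade_class_ids if level.endswith("ade_class") else u.ade_term_ids
        return to_matrix(recs, rows, cols)

    def class_members_for(self, level: str) -> dict[str, set[str]] | None:
        return self.model.class_members if level.startswith("class") else None

    def heatmap(
        self,
        level: int,
        focal_class: str | None = None,
        focal_ade_classes: Sequence[str] | None = None,
        min_class_prr: float | None = None,
    ) -> ClusteredMatrix:
        """Clustered drill-down heat map (see :mod:`classfx.heatmap`)."""
        return build_heatmap(
            self.model.universe,
            self.model.class_members,
            level,
            focal_class=focal_class,
            focal_ade_classes=focal_ade_classes,
            min_class_prr=min_class_prr,
        )
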