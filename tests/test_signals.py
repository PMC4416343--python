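import math

import numpy as np
import pytest

from classfx import (
    Annotation,
    CitationRecord,
    ContingencyTable,
    Corpus,
    ExtractionRules,
    SignalRecord,
    build_universe,
    contingency,
    extract_mentions,
    prr,
    signal_scan,
    to_matrix,
)
from classfx.extraction import ArticleMentions

# ---------------------------------------------------------------------------
# helpers: a tiny world with two drugs and two ADE terms, plus a brute-force
# per-article counting oracle that knows nothing of the vectorized paths
# ---------------------------------------------------------------------------


def _mentions(*specs):
    """specs: (article_id, drug_terms, ade_terms)."""
    return [
        ArticleMentions(a, set(d), set(e)) for a, d, e in specs
    ]


def _universe(specs, drug_vocab, ade_vocab):
    return build_universe(_mentions(*specs), drug_vocab, ade_vocab)


def brute_force_table(mentions, row_pred, col_pred):
    a = b = c = d = 0
    for m in mentions:
        r, co = row_pred(m), col_pred(m)
        a += r and co
        b += r and not co
        c += co and not r
        d += not r and not co
    return ContingencyTable(a, b, c, d)


def _random_mentions(rng, n_articles, drugs, ades):
    out = []
    for i in range(n_articles):
        d = {t for t in drugs if rng.random() < 0.4}
        e = {t for t in ades if rng.random() < 0.4}
        out.append((f"A{i}", d, e))
    return out


# ---------------------------------------------------------------------------
# universe
# ---------------------------------------------------------------------------


def test_universe_drops_articles_lacking_either_side(drug_vocab, ade_vocab):
    u = _universe(
        [
            ("A1", {"D_ofloxacin"}, {"Tendinopathy"}),
            ("A2", {"D_ofloxacin"}, set()),
            ("A3", set(), {"Tendinopathy"}),
        ],
        drug_vocab,
        ade_vocab,
    )
    assert len(u) == 1 and u.article_ids == ["A1"]


def test_universe_equals_corpus_when_all_articles_complete(drug_vocab, ade_vocab):
    specs = [
        (f"A{i}", {"D_ofloxacin"}, {"Tendinopathy"}) for i in range(5)
    ]
    assert len(_universe(specs, drug_vocab, ade_vocab)) == 5


def test_universe_size_matches_brute_force_filter(drug_vocab, ade_vocab):
    rng = np.random.default_rng(7)
    specs = _random_mentions(
        rng, 10, ["D_ofloxacin", "D_cipro"], ["Tendinopathy", "Rhabdomyolysis"]
    )
    expected = sum(1 for _, d, e in specs if d and e)
    if expected == 0:
        pytest.skip("degenerate draw")
    assert len(_universe(specs, drug_vocab, ade_vocab)) == expected


def test_empty_universe_is_an_error(drug_vocab, ade_vocab):
    with pytest.raises(ValueError, match="empty analysis universe"):
        _universe([("A1", {"D_ofloxacin"}, set())], drug_vocab, ade_vocab)


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


def test_contingency_enumeration_of_four_cells(drug_vocab, ade_vocab):
    # articles {drug+ade}, {drug}, {ade}, {} -> a=1,b=1,c=1,d=1; the last
    # article needs other mentions to stay in the universe
    u = _universe(
        [
            ("A1", {"D_ofloxacin"}, {"Tendinopathy"}),
            ("A2", {"D_ofloxacin"}, {"Rhabdomyolysis"}),
            ("A3", {"D_cipro"}, {"Tendinopathy"}),
            ("A4", {"D_cipro"}, {"Rhabdomyolysis"}),
        ],
        drug_vocab,
        ade_vocab,
    )
    t = contingency(
        u,
        lambda m: "D_ofloxacin" in m.drug_terms,
        lambda m: "Tendinopathy" in m.ade_terms,
    )
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_tables_partition_the_universe(drug_vocab, ade_vocab):
    rng = np.random.default_rng(11)
    specs = _random_mentions(
        rng, 40, ["D_ofloxacin", "D_cipro", "D_norflox"],
        ["Tendinopathy", "Rhabdomyolysis", "Muscular Diseases"],
    )
    u = _universe(specs, drug_vocab, ade_vocab)
    for level in ["drug_x_ade", "drug_x_ade_class", "class_x_ade", "class_x_ade_class"]:
        # a proper subset of the observed drugs, so comparator articles exist
        members = {"J01MA": {"ofloxacin", "ciprofloxacin"}}
        for rec in signal_scan(
            u, level, class_members=members if level.startswith("class") else None
        ):
            assert rec.table.n == len(u)


def test_scan_matches_brute_force_oracle_on_small_corpora(drug_vocab, ade_vocab):
    for seed in range(5):
        rng = np.random.default_rng(seed)
        specs = _random_mentions(
            rng, 30, ["D_ofloxacin", "D_cipro"], ["Tendinopathy", "Rhabdomyolysis"]
        )
        try:
            u = _universe(specs, drug_vocab, ade_vocab)
        except ValueError:
            continue
        recs = {
            (r.row_id, r.col_id): r for r in signal_scan(u, "drug_x_ade")
        }
        norm = {"D_ofloxacin": "ofloxacin", "D_cipro": "ciprofloxacin"}
        for dterm, ing in norm.items():
            for ade in ["Tendinopathy", "Rhabdomyolysis"]:
                expected = brute_force_table(
                    u.mentions,
                    lambda m, dt=dterm: dt in m.drug_terms,
                    lambda m, at=ade: at in m.ade_terms,
                )
                if expected.a >= 1:
                    assert recs[(ing, ade)].table == expected
                else:
                    assert (ing, ade) not in recs


def test_single_member_class_table_equals_drug_table(drug_vocab, ade_vocab):
    rng = np.random.default_rng(3)
    specs = _random_mentions(
        rng, 25, ["D_ofloxacin", "D_cipro"], ["Tendinopathy"]
    )
    u = _universe(specs, drug_vocab, ade_vocab)
    drug = {(r.row_id, r.col_id): r.table for r in signal_scan(u, "drug_x_ade")}
    cls = {
        (r.row_id, r.col_id): r.table
        for r in signal_scan(
            u, "class_x_ade", class_members={"solo": {"ofloxacin"}}
        )
    }
    assert cls[("solo", "Tendinopathy")] == drug[("ofloxacin", "Tendinopathy")]


def test_class_row_counts_articles_once_regardless_of_member_count(
    drug_vocab, ade_vocab
):
    u = _universe(
        [
            ("A1", {"D_ofloxacin", "D_cipro"}, {"Tendinopathy"}),
            ("A2", {"D_norflox"}, {"Rhabdomyolysis"}),
        ],
        drug_vocab,
        ade_vocab,
    )
    (rec,) = [
        r
        for r in signal_scan(
            u,
            "class_x_ade",
            class_members={"J01MA": {"ofloxacin", "ciprofloxacin"}},
        )
        if r.col_id == "Tendinopathy"
    ]
    assert rec.table.a == 1  # not 2


# ---------------------------------------------------------------------------
# PRR
# ---------------------------------------------------------------------------


class TestPrr:
    def test_equal_proportions_give_neutral_ratio(self):
        value, corrected = prr(ContingencyTable(10, 90, 100, 900))
        assert value == pytest.approx(1.0)
        assert not corrected

    def test_zero_cell_correction_arithmetic(self):
        value, corrected = prr(ContingencyTable(5, 0, 20, 975))
        assert corrected
        assert value == pytest.approx((5.5 / 6.0) / (20.5 / 996.0))

    def test_correction_also_fires_on_zero_c(self):
        value, corrected = prr(ContingencyTable(5, 10, 0, 985))
        assert corrected
        assert value == pytest.approx((5.5 / 16) / (0.5 / 986))

    def test_empty_row_margin_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            prr(ContingencyTable(0, 0, 5, 5))

    def test_never_co_occurring_pair_gets_neutral_record(self):
        rec = SignalRecord.neutral("x", "y", "drug_x_ade")
        assert rec.prr == 1.0 and rec.log_prr == 0.0 and rec.table is None


def test_scan_emits_only_co_occurring_pairs_and_matches_count(drug_vocab, ade_vocab):
    rng = np.random.default_rng(5)
    specs = _random_mentions(
        rng, 30, ["D_ofloxacin", "D_cipro"], ["Tendinopathy", "Rhabdomyolysis"]
    )
    u = _universe(specs, drug_vocab, ade_vocab)
    recs = signal_scan(u, "drug_x_ade")
    assert all(r.table.a >= 1 for r in recs)
    expected = 0
    for ing, dterm in [("ofloxacin", "D_ofloxacin"), ("ciprofloxacin", "D_cipro")]:
        for ade in ["Tendinopathy", "Rhabdomyolysis"]:
            expected += any(
                dterm in m.drug_terms and ade in m.ade_terms for m in u.mentions
            )
    assert len(recs) == expected


def test_prr_invariant_under_article_reordering(drug_vocab, ade_vocab):
    rng = np.random.default_rng(13)
    specs = _random_mentions(
        rng, 20, ["D_ofloxacin", "D_cipro"], ["Tendinopathy", "Rhabdomyolysis"]
    )
    u1 = _universe(specs, drug_vocab, ade_vocab)
    u2 = _universe(list(reversed(specs)), drug_vocab, ade_vocab)
    r1 = {(r.row_id, r.col_id): r.prr for r in signal_scan(u1, "drug_x_ade")}
    r2 = {(r.row_id, r.col_id): r.prr for r in signal_scan(u2, "drug_x_ade")}
    assert r1 == r2


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


class TestToMatrix:
    def test_no_records_gives_all_zero_matrix(self):
        m = to_matrix([], ["r1", "r2"], ["c1"])
        assert m.values.shape == (2, 1) and not m.values.any()

    def test_single_cell_holds_log_prr(self):
        rec = SignalRecord("r1", "c1", "drug_x_ade", None, math.e, 1.0)
        m = to_matrix([rec], ["r1"], ["c1"])
        assert m.values[0, 0] == pytest.approx(1.0)

    def test_cells_match_records_exactly(self, drug_vocab, ade_vocab):
        rng = np.random.default_rng(2)
        specs = _random_mentions(
            rng, 30, ["D_ofloxacin", "D_cipro"], ["Tendinopathy", "Rhabdomyolysis"]
        )
        u = _universe(specs, drug_vocab, ade_vocab)
        recs = signal_scan(u, "drug_x_ade")
        m = to_matrix(recs, u.ingredient_ids, u.ade_term_ids)
        for r in recs:
            i = u.ingredient_ids.index(r.row_id)
            j = u.ade_term_ids.index(r.col_id)
            assert abs(m.values[i, j] - r.log_prr) < 1e-12

    def test_duplicate_records_rejected(self):
        rec = SignalRecord("r1", "c1", "drug_x_ade", None, 1.0, 0.0)
        with pytest.raises(ValueError, match="duplicate"):
            to_matrix([rec, rec], ["r1"], ["c1"])
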