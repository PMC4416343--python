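"""End-to-end orchestration: extract -> signal -> class effect -> heat maps.

A run is described by a :class:`RunConfig` (usually loaded from TOML),
validated up front so missing inputs fail before any computation, and
produces plain-text TSV tables plus a JSON manifest recording input
digests, configuration, stage counts and the package version — enough to
reproduce or audit the run.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .class_effect import class_effect_scan, eligible_pairs
from .extraction import ExtractionRules, extract_mentions, extract_pairs
from .heatmap import build_heatmap, export
from .io import read_corpus, write_table
from .signals import LEVELS, build_universe, signal_scan
from .vocab import eligible_classes, load_ade_vocabulary, load_drug_vocabulary

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs, rule sets and knobs for one pipeline run."""

    corpus: Path
    drug_terms: Path
    pin_to_in: Path
    ingredient_codes: Path
    code_classes: Path
    ade_trees: Path
    out_dir: Path
    drug_qualifiers: frozenset[str] = frozenset({"AE"})
    ade_qualifiers: frozenset[str] = frozenset({"CI"})
    inherent_ade_descriptors: frozenset[str] = frozenset()
    min_members: int = 4
    alpha: float = 0.05
    ade_level: str = "class"
    heatmap_levels: tuple[int, ...] = (1,)
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = Path(path).parent
        def p(key: str) -> Path:
            q = Path(raw[key])
            return q if q.is_absolute() else base / q
        return cls(
            corpus=p("corpus"),
            drug_terms=p("drug_terms"),
            pin_to_in=p("pin_to_in"),
            ingredient_codes=p("ingredient_codes"),
            code_classes=p("code_classes"),
            ade_trees=p("ade_trees"),
            out_dir=p("out_dir"),
            drug_qualifiers=frozenset(raw.get("drug_qualifiers", ["AE"])),
            ade_qualifiers=frozenset(raw.get("ade_qualifiers", ["CI"])),
            inherent_ade_descriptors=frozenset(
                raw.get("inherent_ade_descriptors", [])
            ),
            min_members=int(raw.get("min_members", 4)),
            alpha=float(raw.get("alpha", 0.05)),
            ade_level=str(raw.get("ade_level", "class")),
            heatmap_levels=tuple(raw.get("heatmap_levels", [1])),
            seed=int(raw.get("seed", 0)),
        )

    def input_paths(self) -> dict[str, Path]:
        return {
            "corpus": self.corpus,
            "drug_terms": self.drug_terms,
            "pin_to_in": self.pin_to_in,
            "ingredient_codes": self.ingredient_codes,
            "code_classes": self.code_classes,
            "ade_trees": self.ade_trees,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    missing = [str(p) for p in config.input_paths().values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    drug_vocab = load_drug_vocabulary(
        config.drug_terms, config.pin_to_in, config.ingredient_codes,
        config.code_classes,
    )
    ade_vocab = load_ade_vocabulary(config.ade_trees)
    corpus = read_corpus(config.corpus)
    rules = ExtractionRules(
        drug_qualifiers=config.drug_qualifiers,
        ade_qualifiers=config.ade_qualifiers,
        inherent_ade_descriptors=config.inherent_ade_descriptors,
    )
    mentions = extract_mentions(corpus, rules, drug_vocab, ade_vocab)
    pairs = extract_pairs(mentions)
    write_table(
        [{"article_id": a, "drug_term": d, "ade_term": t} for a, d, t in pairs],
        out / "pairs.tsv",
    )

    universe = build_universe(mentions, drug_vocab, ade_vocab)
    members = eligible_classes(
        set(universe.ingredient_ids), drug_vocab, min_members=config.min_members
    )

    records_by_level = {}
    for level in LEVELS:
        recs = signal_scan(
            universe,
            level,
            class_members=members if level.startswith("class") else None,
        )
        records_by_level[level] = recs
        write_table(
            [
                {
                    "row_id": r.row_id,
                    "col_id": r.col_id,
                    "a": r.table.a, "b": r.table.b,
                    "c": r.table.c, "d": r.table.d,
                    "prr": r.prr, "log_prr": r.log_prr,
                    "corrected": r.corrected,
                }
                for r in recs
            ],
            out / f"signals_{level}.tsv",
        )

    drug_lv = "drug_x_ade_class" if config.ade_level == "class" else "drug_x_ade"
    cls_lv = "class_x_ade_class" if config.ade_level == "class" else "class_x_ade"
    drug_records = records_by_level[drug_lv]
    class_prr = {
        (r.row_id, r.col_id): r.prr for r in records_by_level[cls_lv]
    }
    eligible = eligible_pairs(members, drug_records)
    verdicts = class_effect_scan(
        eligible, drug_records, members, records_by_level[cls_lv],
        alpha=config.alpha,
    )
    write_table(
        [
            {
                "class_id": r.class_id,
                "ade_id": r.ade_id,
                "n_members": len(r.member_log_prrs),
                "class_prr": class_prr.get((r.class_id, r.ade_id)),
                "n_clusters": r.n_clusters,
                "t_stat": r.t_stat,
                "dof": r.dof,
                "p_value": r.p_value,
                "verdict": r.verdict,
            }
            for r in verdicts
        ],
        out / "verdicts.tsv",
    )

    for level in config.heatmap_levels:
        if level == 1:
            cm = build_heatmap(universe, members, 1)
            export(cm, out / "heatmap_level1.tsv")
        else:
            for cls in sorted(members):
                cm = build_heatmap(universe, members, 2, focal_class=cls)
                export(cm, out / f"heatmap_level2_{cls}.tsv")

    manifest = {
        "tool": "classfx",
        "version": __version__,
        "inputs": {k: _sha256(v) for k, v in config.input_paths().items()},
        "config": {
            "min_members": config.min_members,
            "alpha": config.alpha,
            "ade_level": config.ade_level,
            "drug_qualifiers": sorted(config.drug_qualifiers),
            "ade_qualifiers": sorted(config.ade_qualifiers),
            "seed": config.seed,
        },
        "counts": {
            "articles": len(corpus),
            "universe_articles": len(universe),
            "pairs": len(pairs),
            "ingredients": len(universe.ingredient_ids),
            "ade_terms": len(universe.ade_term_ids),
            "ade_classes": len(universe.ade_class_ids),
            "eligible_classes": len(members),
            "eligible_pairs": len(eligible),
            "verdicts": {
                v: sum(1 for r in verdicts if r.verdict == v)
                for v in sorted({r.verdict for r in verdicts})
            },
        },
        "multiple_testing_correction": "none",
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
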