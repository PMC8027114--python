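"""End-to-end orchestration: input -> store -> analysis -> ranked outputs.

Synthetic mode deliberately goes the long way around — the generated corpus
is written to dialect files and re-ingested through the same parser,
deduplicator and store builder used for real extracts — so every run
exercises the full pipeline.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .config import RunConfig, load_config
from .contingency import ExposureDef
from .ingest import (
    DateWindow,
    DrugDictionary,
    EventTermSet,
    ReportStore,
    build_store,
    deduplicate,
    parse_tables,
    write_store,
)
from .report import forest_export, rank_results, ranked_to_csv
from .ror import AnalysisResult, AnalysisSettings, analyze, results_to_csv, results_to_json
from .simulate import sample_reports, study_config, write_faers_dialect


def _exposures(cfg: RunConfig) -> list[ExposureDef]:
    exps = [ExposureDef.single(d) for d in cfg.drugs]
    exps += [
        ExposureDef(label=name, member_compounds=frozenset(members))
        for name, members in cfg.classes.items()
    ]
    return exps


def ingest_store(cfg: RunConfig, input_dir: Path) -> ReportStore:
    """Parse -> deduplicate -> build the report store from dialect files."""
    paths = {}
    for table in ("demo", "drug", "reac", "indi"):
        p = input_dir / f"{table}.txt"
        if p.exists():
            paths[table] = p
    records = deduplicate(parse_tables(paths))
    return build_store(
        records,
        dictionary=DrugDictionary(),
        terms=EventTermSet(frozenset(cfg.terms)),
        window=DateWindow(cfg.window_start, cfg.window_end),
        suspect_only=cfg.suspect_only,
    )


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Run all stages and write artifacts; returns the run manifest.

    Outputs under ``cfg.out_dir``: the JSON-lines store, results CSV/JSON,
    ranked table, forest CSV + figure, manifest.yaml, and (synthetic mode)
    the dialect corpus plus a ground-truth sidecar. Deterministic for a
    fixed config and seed.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if cfg.mode == "synthetic":
        syn = cfg.synthetic or study_config(seed=cfg.seed)
        if cfg.synthetic is None:
            syn = syn.model_copy(update={"seed": cfg.seed})
        reports, truth = sample_reports(syn)
        corpus_dir = out / "corpus"
        write_faers_dialect(reports, corpus_dir, dup_rate=syn.dup_rate, seed=syn.seed)
        truth.to_json(out / "ground_truth.json")
        store = ingest_store(cfg, corpus_dir)
    else:
        store = ingest_store(cfg, Path(cfg.input_dir))

    write_store(store, out / "store.jsonl")

    settings = AnalysisSettings(
        estimator=cfg.estimator,
        level=cfg.level,
        min_cases=cfg.min_cases,
        correct_zero_cells=cfg.correct_zero_cells,
    )
    result: AnalysisResult = analyze(list(store), _exposures(cfg), settings)
    results_to_csv(result, out / "results.csv")
    results_to_json(result, out / "results.json")

    class_labels = set(cfg.classes)
    drug_rows = [r for r in result.results if r.label not in class_labels]
    class_rows = [r for r in result.results if r.label in class_labels]
    if drug_rows:
        ranked = rank_results(drug_rows, rounding=1)
        ranked_to_csv(ranked, out / "ranked.csv")
        forest_export(ranked, out / "forest")
    if class_rows:
        ranked_to_csv(rank_results(class_rows, rounding=2), out / "ranked_classes.csv")

    manifest = {
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "n": result.n,
        "e": result.e,
        "settings": asdict(settings),
        "fingerprint": result.fingerprint,
        "skipped": result.skipped,
        "tallies": store.tallies,
        "window": [cfg.window_start.isoformat(), cfg.window_end.isoformat()],
        "terms": sorted(cfg.terms),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
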