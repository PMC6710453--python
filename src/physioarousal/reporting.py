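"""Manipulation-check word counting, pipeline orchestration, report assembly.

The manipulation check mirrors standard text-mining preprocessing: strip
punctuation and digits, case-fold, drop stopwords, and rank the k most
frequent words per condition.  ``run_study_pipeline`` wires the full chain —
simulate (or load) -> derive -> segment -> impute -> infer -> summarize —
reproducibly from a (config, seed) pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from collections import Counter
from pathlib import Path

import pandas as pd
import yaml

from . import inference, protocol, synth
from .impute import pmm_impute

__all__ = ["word_frequency", "DEFAULT_STOPWORDS", "run_study_pipeline",
           "DEFAULT_CONFIG"]

log = logging.getLogger("physioarousal")

#: Minimal English stopword list for fixtures; real analyses should pass the
#: corpus language's own list.
DEFAULT_STOPWORDS = frozenset("""
a an and are as at be but by for from has have i if in is it its of on or
that the their them they this to was were what when which will with you
""".split())

_TOKEN_RE = re.compile(r"[^\W\d_]+", flags=re.UNICODE)


def word_frequency(texts, stopwords=DEFAULT_STOPWORDS, k: int = 30) -> pd.DataFrame:
    """Top-``k`` word counts after punctuation/digit stripping and case folding.

    Ties are broken lexicographically.  An empty corpus yields an empty table.
    """
    counts = Counter()
    for text in texts:
        counts.update(tok for tok in _TOKEN_RE.findall(text.lower())
                      if tok not in stopwords)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(ranked, columns=["word", "count"])


DEFAULT_CONFIG = {
    "n_ms": 53,
    "n_dps": 55,
    "miss_rate": synth.DEFAULT_MISS_RATE,
    "effects": {},            # {"PARAM:SEG": shift}, applied to the MS group
    "mode": "segments",       # "segments" (fast) or "recordings" (full chain)
    "m_imputations": 5,
    "imputation_iterations": 5,
    "seed": 0,
    "jzs_scale": 1.0,
    "fdr_method": "bh",
}


def _parse_effects(effects: dict) -> dict:
    return {tuple(key.split(":")): float(v) for key, v in (effects or {}).items()}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return {**DEFAULT_CONFIG, **user}


def run_study_pipeline(config: dict | str | Path | None = None,
                       out_dir: str | Path | None = None) -> dict:
    """Simulate -> derive -> segment -> impute -> infer -> report.

    Returns a bundle with the segment table, change scores, imputed stack,
    per-comparison results and the evidence summary; every stage is seeded
    from ``config['seed']`` and the bundle records the config hash for
    provenance.  With ``out_dir`` set, tidy CSV/JSON artifacts are written.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    seed = int(cfg["seed"])
    effects = _parse_effects(cfg["effects"])
    log.info("pipeline start: seed=%d hash=%s mode=%s", seed, _config_hash(cfg), cfg["mode"])

    if cfg["mode"] == "recordings":
        sim = synth.synth_study(cfg["n_ms"], cfg["n_dps"], effects=effects,
                                miss_rate=cfg["miss_rate"], seed=seed)
        derived = [protocol.process_recording(r) for r in sim.recordings]
        table = protocol.build_segment_table(
            derived, sim.conditions, participants=sim.conditions.index, mask=sim.mask)
    elif cfg["mode"] == "segments":
        table = synth.synth_segment_study(cfg["n_ms"], cfg["n_dps"], effects=effects,
                                          miss_rate=cfg["miss_rate"], seed=seed)
    else:
        raise ValueError("mode must be 'segments' or 'recordings'")

    scores = protocol.change_scores(table)
    if scores.isna().any().any():
        stack = pmm_impute(scores, table.condition, m=cfg["m_imputations"],
                           iterations=cfg["imputation_iterations"], seed=seed)
    else:
        stack = None
    results = inference.analyze_study(stack if stack is not None else scores,
                                      table.condition, scale=cfg["jzs_scale"],
                                      fdr_method=cfg["fdr_method"])
    summary = inference.evidence_summary(results)
    bundle = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "segment_table": table,
        "change_scores": scores,
        "stack": stack,
        "results": results,
        "summary": summary,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_tidy().to_csv(out_dir / "segment_table.csv", index=False)
        results.to_csv(out_dir / "results.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(
            {**summary, "seed": seed, "config_hash": bundle["config_hash"]}, indent=1))
        log.info("artifacts written to %s", out_dir)
    return bundle


def format_report(results: pd.DataFrame, summary: dict) -> str:
    """Human-readable report: per-family evidence table plus percentages."""
    lines = []
    for family, label in (("within", "Segments vs baseline"),
                          ("between", "MS vs DPS")):
        sub = results[results["family"] == family]
        lines.append(label)
        lines.append("-" * len(label))
        pivot = sub.pivot_table(index="parameter", columns="segment",
                                values="bf", aggfunc="first")
        lines.append(pivot.round(2).to_string())
        lines.append("")
    lines.append(f"comparisons: {summary['n_comparisons']}")
    for key in ("pct_significant_uncorrected", "pct_significant_fdr",
                "pct_alternative", "pct_null"):
        val = summary.get(key)
        if val is not None and pd.notna(val):
            lines.append(f"{key}: {val:.2f}%")
    if "n_disagreements" in summary:
        lines.append(f"frequentist/Bayesian disagreements: {summary['n_disagreements']}")
    return "\n".join(lines)
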