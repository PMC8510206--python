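"""End-to-end orchestration of the virtual-screening workflow.

digest → properties → screen → summarize (→ optionally redesign), with a
JSON-serialisable run report echoing the stage-level summary statistics
(peptide totals, length-bin distribution, per-predictor and consensus
counts, mode-of-action tallies, top candidates per category).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import digestion, screening, synthetic
from .redesign import additive_scorer, redesign as greedy_redesign
from .screening import ConsensusThresholds

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    rule: str = "pepsin_pH1.3"
    min_len: int = 5
    max_len: int = 50
    missed_cleavages: int = 0
    thresholds: ConsensusThresholds = field(default_factory=ConsensusThresholds)
    top_n: int = 5
    redesign_top: bool = False
    redesign_max_rounds: int = 2
    seed: int = 0
    fasta: str | None = None       # if None, a synthetic proteome is generated
    scores: str | None = None      # if None, synthetic scores are generated
    n_proteins: int = 120
    out_dir: str | None = None

    def validate(self) -> None:
        digestion.get_rule(self.rule)
        if self.min_len > self.max_len:
            raise digestion.ConfigError("min_len > max_len")
        if not (0 <= self.missed_cleavages <= 5):
            raise digestion.ConfigError("missed_cleavages must be in 0..5")
        if self.top_n < 1:
            raise digestion.ConfigError("top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = ConsensusThresholds(**th)
        cfg.validate()
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow and return the run report (dict).

    The report is deterministic for a fixed config and inputs except for
    the single ``timestamp`` field.
    """
    config.validate()
    rule = digestion.get_rule(config.rule)

    if config.fasta:
        proteins = _load_stage(config.fasta)
        proteome_source = str(config.fasta)
    else:
        proteins = synthetic.gen_proteome(
            n_proteins=config.n_proteins,
            seed=synthetic.stage_seed(config.seed, "proteome"),
        )
        proteome_source = f"synthetic(n={config.n_proteins}, seed={config.seed})"

    peptides = _digest_stage(proteins, rule, config)
    bins = digestion.length_distribution(peptides)

    sequences = [p.sequence for p in peptides]
    if config.scores:
        score_rows = screening.read_scores_tsv(config.scores)
        scores_source = str(config.scores)
    else:
        scores_df, _truth = synthetic.gen_scores(
            sequences, seed=synthetic.stage_seed(config.seed, "scores")
        )
        score_rows = [
            screening.PredictorScores(
                r.peptide, r.anticp_svm, r.iacp_prob, r.mlacp_rf, r.mlacp_svm,
                bool(r.toxic), bool(r.cpp),
            )
            for r in scores_df.itertuples(index=False)
        ]
        scores_source = f"synthetic(seed={config.seed})"

    verdicts = _screen_stage(score_rows, config)
    venn = screening.venn_counts(verdicts)
    moa = screening.classify_moa(verdicts)

    consensus_seqs = [v.peptide for v in verdicts if v.consensus_acp]
    summary = screening.property_summary(consensus_seqs)

    by_cat: dict[str, list] = {}
    score_by_pep = {s.peptide: s for s in score_rows}
    for v in verdicts:
        if v.consensus_acp:
            by_cat.setdefault(v.moa_category, []).append(score_by_pep[v.peptide])
    top_candidates = {
        cat: [s.peptide for s in screening.rank_candidates(rows)[: config.top_n]]
        for cat, rows in sorted(by_cat.items())
    }

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "thresholds"
            },
            "thresholds": dataclasses.asdict(config.thresholds),
        },
        "inputs": {"proteome": proteome_source, "scores": scores_source},
        "digestion": {
            "n_proteins": len(proteins),
            "n_unique_peptides": len(peptides),
            "length_bins": {
                f"{lo}-{hi}": {"count": c, "percent": p}
                for (lo, hi), c, p in zip(bins.edges, bins.counts, bins.proportions)
            },
        },
        "screening": {
            "per_predictor": {
                "anticp": venn["anticp_total"],
                "iacp": venn["iacp_total"],
                "mlacp": venn["mlacp_total"],
            },
            "consensus_acps": venn["consensus"],
            "venn_regions": {k: venn[k] for k in venn if set(k) <= {"0", "1"}},
            "moa": moa,
            "property_summary": None
            if summary.empty
            else {
                "length_pct": summary.length_pct,
                "hydro_pct": summary.hydro_pct,
                "charge_pct": summary.charge_pct,
            },
        },
        "top_candidates": top_candidates,
    }
    if not consensus_seqs:
        report["screening"]["note"] = "zero consensus candidates"

    if config.redesign_top and consensus_seqs:
        report["redesign"] = _redesign_stage(top_candidates, config)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        digestion.write_peptides_tsv(peptides, out / "peptides.tsv")
        screening.write_verdicts_tsv(verdicts, out / "verdicts.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


@_stage("load_proteome")
def _load_stage(fasta_path):
    return digestion.read_fasta(fasta_path)


@_stage("digest")
def _digest_stage(proteins, rule, config: RunConfig):
    return digestion.digest_proteome(
        proteins, rule, config.missed_cleavages, config.min_len, config.max_len
    )


@_stage("screen")
def _screen_stage(score_rows, config: RunConfig):
    return screening.screen_table(score_rows, config.thresholds)


@_stage("redesign")
def _redesign_stage(top_candidates: dict, config: RunConfig) -> dict:
    # demo scorer: additive Eisenberg hydrophobicity weights — transparent
    # and deterministic; real use supplies a trained scorer
    from .properties import EISENBERG

    scorer = additive_scorer(EISENBERG)
    out = {}
    for cat, peps in top_candidates.items():
        if not peps:
            continue
        res = greedy_redesign(peps[0], scorer, max_rounds=config.redesign_max_rounds)
        out[cat] = {
            "original": res.original,
            "variant": res.variant,
            "substitutions": [str(s) for s in res.substitutions],
            "original_score": res.original_score,
            "variant_score": res.variant_score,
            "highlighted": res.highlighted(),
            "scorer": "additive_eisenberg_demo",
        }
    return out
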