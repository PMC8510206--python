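"""Consensus anticancer-peptide screening.

Each peptide carries four predictor outputs — an AntiCP-style SVM score,
an iACP-style probability, and MLACP-style RF and SVM probabilities — plus
binary toxicity and cell-penetration flags.  A peptide is called a
consensus ACP when all three predictors are positive under strict
thresholds (SVM score > 1.00; each probability > 0.5).  Consensus ACPs are
then stratified by mode of action (toxic-only / cell-penetrating-only /
both / none) and ranked within category.

Score tables are external TSV inputs; the pipeline never calls prediction
servers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import properties as props

SCORE_COLUMNS = ["peptide", "anticp_svm", "iacp_prob", "mlacp_rf", "mlacp_svm", "toxic", "cpp"]

MOA_CATEGORIES = ("toxic_only", "cpp_only", "both", "none")


@dataclass(frozen=True)
class PredictorScores:
    peptide: str
    anticp_svm: float
    iacp_prob: float
    mlacp_rf: float
    mlacp_svm: float
    toxic: bool
    cpp: bool

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide sequence in score row")
        for name in ("iacp_prob", "mlacp_rf", "mlacp_svm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.peptide}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ConsensusThresholds:
    """Strict ('over') cut-offs for the three predictors."""

    anticp_min: float = 1.00
    iacp_min: float = 0.5
    mlacp_rf_min: float = 0.5
    mlacp_svm_min: float = 0.5


@dataclass(frozen=True)
class ScreenVerdict:
    peptide: str
    anticp_pos: bool
    iacp_pos: bool
    mlacp_pos: bool
    consensus_acp: bool
    moa_category: str | None = None  # set only for consensus ACPs with flags


def call_predictors(
    scores: PredictorScores, th: ConsensusThresholds = ConsensusThresholds()
) -> ScreenVerdict:
    """Apply strict thresholds per predictor; consensus = all three positive.

    MLACP is positive only when *both* its RF and SVM probabilities exceed
    their cut-offs.
    """
    anticp = scores.anticp_svm > th.anticp_min
    iacp = scores.iacp_prob > th.iacp_min
    mlacp = scores.mlacp_rf > th.mlacp_rf_min and scores.mlacp_svm > th.mlacp_svm_min
    consensus = anticp and iacp and mlacp
    moa = None
    if consensus:
        moa = _moa_category(scores.toxic, scores.cpp)
    return ScreenVerdict(scores.peptide, anticp, iacp, mlacp, consensus, moa)


def _moa_category(toxic: bool, cpp: bool) -> str:
    if toxic and cpp:
        return "both"
    if toxic:
        return "toxic_only"
    if cpp:
        return "cpp_only"
    return "none"


def venn_counts(verdicts: Sequence[ScreenVerdict]) -> dict[str, int]:
    """Counts of the 7 Venn regions over (AntiCP, iACP, MLACP) positives,
    plus per-predictor totals and the union.

    Region keys are binary membership strings, e.g. ``"110"`` = positive in
    AntiCP and iACP only.  Duplicate peptides are rejected: the screen is
    defined over unique peptides.
    """
    seen: set[str] = set()
    regions = {f"{a}{b}{c}": 0 for a in "01" for b in "01" for c in "01" if a + b + c != "000"}
    for v in verdicts:
        if v.peptide in seen:
            raise ValueError(f"duplicate peptide in verdict table: {v.peptide!r}")
        seen.add(v.peptide)
        key = f"{int(v.anticp_pos)}{int(v.iacp_pos)}{int(v.mlacp_pos)}"
        if key != "000":
            regions[key] += 1
    totals = {
        "anticp_total": sum(n for k, n in regions.items() if k[0] == "1"),
        "iacp_total": sum(n for k, n in regions.items() if k[1] == "1"),
        "mlacp_total": sum(n for k, n in regions.items() if k[2] == "1"),
        "consensus": regions["111"],
        "union": sum(regions.values()),
    }
    return {**regions, **totals}


def classify_moa(verdicts: Sequence[ScreenVerdict]) -> dict[str, int]:
    """Mode-of-action tallies over the consensus ACPs.

    Returns the four exclusive category counts (a partition of the
    consensus set) together with the overlapping totals
    ``toxic_total = toxic_only + both`` and ``cpp_total = cpp_only + both``.
    """
    counts = {cat: 0 for cat in MOA_CATEGORIES}
    for v in verdicts:
        if not v.consensus_acp:
            continue
        if v.moa_category is None:
            raise ValueError(f"consensus ACP {v.peptide!r} lacks toxicity/CPP flags")
        counts[v.moa_category] += 1
    counts["toxic_total"] = counts["toxic_only"] + counts["both"]
    counts["cpp_total"] = counts["cpp_only"] + counts["both"]
    counts["consensus"] = sum(counts[c] for c in MOA_CATEGORIES)
    return counts


def rank_candidates(scores: Sequence[PredictorScores]) -> list[PredictorScores]:
    """Sort candidates by descending AntiCP SVM score; break ties by the
    mean of the other three scores (descending), then by sequence."""
    def key(s: PredictorScores):
        other_mean = (s.iacp_prob + s.mlacp_rf + s.mlacp_svm) / 3.0
        return (-s.anticp_svm, -other_mean, s.peptide)

    return sorted(scores, key=key)


@dataclass
class PropertySummary:
    """Percentage breakdowns of a peptide set by length class, hydropathy
    class and charge class (each panel sums to 100, 1-decimal rounding)."""

    length_pct: dict[str, float]
    hydro_pct: dict[str, float]
    charge_pct: dict[str, float]
    n: int
    empty: bool = field(default=False)


def property_summary(
    peptides: Iterable[str],
    length_bins: tuple[tuple[int, int], ...] = ((5, 20), (21, 35), (36, 50)),
) -> PropertySummary:
    peps = list(peptides)
    if not peps:
        return PropertySummary({}, {}, {}, 0, empty=True)
    length_counts = {f"{lo}-{hi}": 0 for lo, hi in length_bins}
    hydro_counts = {"hydrophobic": 0, "hydrophilic": 0}
    charge_counts = {"cationic": 0, "anionic": 0, "neutral": 0}
    for seq in peps:
        p = props.compute_properties(seq)
        for lo, hi in length_bins:
            if lo <= p.length <= hi:
                length_counts[f"{lo}-{hi}"] += 1
                break
        hydro_counts[p.hydro_class] += 1
        charge_counts[p.charge_class] += 1
    n = len(peps)
    pct = lambda d: {k: round(100.0 * v / n, 1) for k, v in d.items()}
    return PropertySummary(pct(length_counts), pct(hydro_counts), pct(charge_counts), n)


# ---------------------------------------------------------------------------
# TSV I/O

def read_scores_tsv(path: str | Path) -> list[PredictorScores]:
    """Read a predictor score table (TSV with header; booleans as 0/1)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        PredictorScores(
            str(r.peptide),
            float(r.anticp_svm),
            float(r.iacp_prob),
            float(r.mlacp_rf),
            float(r.mlacp_svm),
            bool(int(r.toxic)),
            bool(int(r.cpp)),
        )
        for r in df.itertuples(index=False)
    ]


def write_verdicts_tsv(verdicts: Sequence[ScreenVerdict], path: str | Path) -> None:
    rows = [
        {
            "peptide": v.peptide,
            "anticp_pos": int(v.anticp_pos),
            "iacp_pos": int(v.iacp_pos),
            "mlacp_pos": int(v.mlacp_pos),
            "consensus_acp": int(v.consensus_acp),
            "moa_category": v.moa_category or "",
        }
        for v in verdicts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def screen_table(
    scores: Sequence[PredictorScores], th: ConsensusThresholds = ConsensusThresholds()
) -> list[ScreenVerdict]:
    return [call_predictors(s, th) for s in scores]
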