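"""Synthetic inputs for every pipeline stage.

The screening study consumed three things the package cannot ship: a
fungal proteome build, score tables from third-party prediction servers,
and MTT plate absorbances.  This module generates statistical stand-ins
for each, with declared distributions and integer-seeded NumPy generators,
so all downstream stages are testable end-to-end and byte-reproducible.

Seeding: one master seed expands to per-stage streams via
``numpy.random.SeedSequence(master).spawn`` with a fixed stage order
(proteome = 0, scores = 1, mtt = 2, combo = 3); every generator also
accepts a direct seed.

All simulation constants that the study does not state (score-model
separations, Hill slope, noise SD, optical-density levels) are collected
in :data:`DEFAULTS` as this package's own design choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .digestion import ProteinRecord
from .dose_response import PLATE_COLUMNS, four_pl

_STAGE_INDEX = {"proteome": 0, "scores": 1, "mtt": 2, "combo": 3}


def stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed stream from one master seed."""
    return np.random.SeedSequence(master).spawn(max(_STAGE_INDEX.values()) + 1)[
        _STAGE_INDEX[stage]
    ]


# ---------------------------------------------------------------------------
# proteome

#: Residue frequencies loosely modelled on fungal proteome composition but
#: with F+L mass set so a pepsin digest yields fragments averaging ~12
#: residues, populating all three 5–50 aa length bins (majority 5–20).
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.090, "C": 0.015, "D": 0.060, "E": 0.067, "F": 0.045,
    "G": 0.075, "H": 0.022, "I": 0.055, "K": 0.060, "L": 0.045,
    "M": 0.020, "N": 0.047, "P": 0.050, "Q": 0.043, "R": 0.052,
    "S": 0.082, "T": 0.058, "V": 0.073, "W": 0.011, "Y": 0.030,
}
assert abs(sum(DEFAULT_AA_FREQUENCIES.values()) - 1.0) < 1e-9


def gen_proteome(
    n_proteins: int = 120,
    length_mean: int = 450,
    aa_frequencies: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[ProteinRecord]:
    """Random protein records with i.i.d. residues and geometric-ish
    lengths (normal around ``length_mean``, floored at 60)."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    freqs = dict(aa_frequencies or DEFAULT_AA_FREQUENCIES)
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"amino-acid frequencies sum to {total}, not 1")
    letters = sorted(freqs)
    p = np.array([freqs[a] for a in letters])
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_proteins):
        length = max(60, int(round(rng.normal(length_mean, length_mean / 4))))
        seq = "".join(np.array(letters)[rng.choice(len(letters), size=length, p=p)])
        records.append(ProteinRecord(f"synthetic_{i + 1:04d}", seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# predictor score tables

@dataclass(frozen=True)
class ScoreModel:
    """Latent-label generative model for predictor score tables.

    A fraction ``prevalence`` of peptides is a true ACP; each predictor
    column is drawn from a Gaussian whose location depends on the label
    (probability-type columns are clipped to [0, 1]).  Mode-of-action
    flags are Bernoulli given the label.  Defaults put the consensus
    positive rate near the low single-digit percentage a three-way strict
    consensus produces.
    """

    prevalence: float = 0.05
    anticp_pos: tuple[float, float] = (1.45, 0.30)
    anticp_neg: tuple[float, float] = (0.20, 0.45)
    iacp_pos: tuple[float, float] = (0.78, 0.14)
    iacp_neg: tuple[float, float] = (0.32, 0.16)
    mlacp_rf_pos: tuple[float, float] = (0.66, 0.12)
    mlacp_rf_neg: tuple[float, float] = (0.30, 0.13)
    mlacp_svm_pos: tuple[float, float] = (0.66, 0.12)
    mlacp_svm_neg: tuple[float, float] = (0.30, 0.13)
    # MoA rates conditioned on the latent label (ACP rates follow the
    # exclusive 14/242/5/55-of-316 stratification arithmetic)
    p_toxic_acp: float = 19 / 316
    p_cpp_acp: float = 247 / 316
    p_toxic_null: float = 0.02
    p_cpp_null: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")

    def _exceed(self, dist: tuple[float, float], threshold: float) -> float:
        loc, scale = dist
        return float(sps.norm.sf(threshold, loc=loc, scale=scale))

    def predictor_positive_rates(self, label: bool, thresholds=None) -> dict[str, float]:
        """P(predictor positive | label) under the default strict
        thresholds (clipping to [0,1] does not move mass across an
        interior threshold, so the normal tail is exact)."""
        from .screening import ConsensusThresholds

        th = thresholds or ConsensusThresholds()
        pick = (lambda p, n: p) if label else (lambda p, n: n)
        mlacp = self._exceed(pick(self.mlacp_rf_pos, self.mlacp_rf_neg), th.mlacp_rf_min) * \
            self._exceed(pick(self.mlacp_svm_pos, self.mlacp_svm_neg), th.mlacp_svm_min)
        return {
            "anticp": self._exceed(pick(self.anticp_pos, self.anticp_neg), th.anticp_min),
            "iacp": self._exceed(pick(self.iacp_pos, self.iacp_neg), th.iacp_min),
            "mlacp": mlacp,
        }

    def consensus_rate(self, label: bool, thresholds=None) -> float:
        rates = self.predictor_positive_rates(label, thresholds)
        return rates["anticp"] * rates["iacp"] * rates["mlacp"]

    def expected_consensus_fraction(self, thresholds=None) -> float:
        return (
            self.prevalence * self.consensus_rate(True, thresholds)
            + (1 - self.prevalence) * self.consensus_rate(False, thresholds)
        )

    def expected_recall(self, thresholds=None) -> float:
        return self.consensus_rate(True, thresholds)

    def expected_precision(self, thresholds=None) -> float:
        tp = self.prevalence * self.consensus_rate(True, thresholds)
        fp = (1 - self.prevalence) * self.consensus_rate(False, thresholds)
        return tp / (tp + fp)


DEFAULT_SCORE_MODEL = ScoreModel()


def gen_scores(
    peptides: Sequence[str],
    model: ScoreModel = DEFAULT_SCORE_MODEL,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peptide predictor scores plus a separate latent-truth table.

    Returns ``(scores, truth)``: ``scores`` has the screening TSV schema;
    ``truth`` holds the hidden ACP label and is never read by the
    pipeline itself (it exists so tests can measure recall/precision).
    """
    rng = np.random.default_rng(seed)
    n = len(peptides)
    label = rng.random(n) < model.prevalence

    def draw(pos, neg, clip):
        loc = np.where(label, pos[0], neg[0])
        scale = np.where(label, pos[1], neg[1])
        x = rng.normal(loc, scale)
        return np.clip(x, 0.0, 1.0) if clip else x

    scores = pd.DataFrame(
        {
            "peptide": list(peptides),
            "anticp_svm": draw(model.anticp_pos, model.anticp_neg, clip=False),
            "iacp_prob": draw(model.iacp_pos, model.iacp_neg, clip=True),
            "mlacp_rf": draw(model.mlacp_rf_pos, model.mlacp_rf_neg, clip=True),
            "mlacp_svm": draw(model.mlacp_svm_pos, model.mlacp_svm_neg, clip=True),
            "toxic": np.where(
                label,
                rng.random(n) < model.p_toxic_acp,
                rng.random(n) < model.p_toxic_null,
            ).astype(int),
            "cpp": np.where(
                label,
                rng.random(n) < model.p_cpp_acp,
                rng.random(n) < model.p_cpp_null,
            ).astype(int),
        }
    )
    truth = pd.DataFrame({"peptide": list(peptides), "is_acp": label.astype(int)})
    return scores, truth


# ---------------------------------------------------------------------------
# MTT plates

@dataclass(frozen=True)
class MttScenario:
    """Ground truth and design for one simulated MTT experiment."""

    name: str
    top: float = 100.0
    bottom: float = 0.0
    ic50_uM: float = 114.9
    hill: float = 1.5
    doses_uM: tuple[float, ...] = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0)
    replicates: int = 4
    timepoints_h: tuple[float, ...] = (72.0,)
    noise_sd: float = 5.0            # viability percentage points
    control_od: float = 1.0          # corrected control absorbance
    blank_od: float = 0.05
    n_blank_wells: int = 4

    def __post_init__(self) -> None:
        if 0.0 not in self.doses_uM:
            raise ValueError("dose list must include 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


#: Emulates the active peptide: full inhibition curve with the study's
#: reported IC50 as ground truth.  Hill slope and noise are design choices.
C_ORI = MttScenario(name="C-ori")

#: Emulates the inactive redesigned peptide: flat ~100% viability.
C_RDS_FLAT = MttScenario(name="C-rds", top=100.0, bottom=100.0, ic50_uM=50.0)

#: Emulates the doxorubicin arm: two-fold dilutions from 0.25 µM down,
#: with a mid-range true IC50 (design choice inside the reported bracket).
DOX = MttScenario(
    name="doxorubicin",
    ic50_uM=0.12,
    hill=1.2,
    doses_uM=(0.0, 0.015625, 0.03125, 0.0625, 0.125, 0.25),
)

SCENARIOS = {"C_ORI": C_ORI, "C_RDS_FLAT": C_RDS_FLAT, "DOX": DOX}

DEFAULTS = {
    "hill": 1.5,
    "noise_sd_viability_points": 5.0,
    "control_od": 1.0,
    "blank_od": 0.05,
    "score_model": DEFAULT_SCORE_MODEL,
}


def gen_mtt(
    scenario: MttScenario, seed: int | np.random.SeedSequence = 0
) -> pd.DataFrame:
    """Long-format plate table for one scenario.

    Treated/control absorbance = blank + control_od · V(d)/100 + ε with
    ε ~ N(0, control_od · noise_sd / 100); blank wells get the same ε
    around the blank level.  Control wells sit at the scenario's top
    response (dose 0).
    """
    rng = np.random.default_rng(seed)
    od_noise = scenario.control_od * scenario.noise_sd / 100.0
    rows = []
    for t in scenario.timepoints_h:
        for b in range(scenario.n_blank_wells):
            rows.append(
                {
                    "condition": "blank",
                    "compound": "",
                    "dose_uM": 0.0,
                    "timepoint_h": t,
                    "replicate": b + 1,
                    "absorbance": scenario.blank_od + rng.normal(0, od_noise / 5),
                    "role": "blank",
                }
            )
        for r in range(scenario.replicates):
            rows.append(
                {
                    "condition": "control",
                    "compound": "",
                    "dose_uM": 0.0,
                    "timepoint_h": t,
                    "replicate": r + 1,
                    "absorbance": scenario.blank_od
                    + scenario.control_od
                    + rng.normal(0, od_noise),
                    "role": "control",
                }
            )
        for d in scenario.doses_uM:
            if d == 0.0:
                continue
            v = four_pl(d, scenario.top, scenario.bottom, scenario.ic50_uM, scenario.hill)
            for r in range(scenario.replicates):
                rows.append(
                    {
                        "condition": f"{scenario.name} {d:g} uM",
                        "compound": scenario.name,
                        "dose_uM": d,
                        "timepoint_h": t,
                        "replicate": r + 1,
                        "absorbance": scenario.blank_od
                        + scenario.control_od * float(v) / 100.0
                        + rng.normal(0, od_noise),
                        "role": "treated",
                    }
                )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def gen_flat_scenario(seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Plate with ~100% viability at every dose (inactive compound)."""
    return gen_mtt(C_RDS_FLAT, seed)


def gen_combo_mtt(
    peptide: MttScenario = C_ORI,
    dox: MttScenario = DOX,
    seed: int | np.random.SeedSequence = 0,
    interaction: float = 1.0,
) -> pd.DataFrame:
    """Factorial peptide × doxorubicin viability grid under Bliss
    independence, V(p, d) = V_pep(p) · V_dox(d) / 100, optionally scaled
    by an ``interaction`` factor (< 1 = more-than-independent killing).
    Returns tidy replicate-level viabilities with monotherapy margins."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in peptide.doses_uM:
        vp = float(four_pl(p, peptide.top, peptide.bottom, peptide.ic50_uM, peptide.hill))
        for d in dox.doses_uM:
            vd = float(four_pl(d, dox.top, dox.bottom, dox.ic50_uM, dox.hill))
            v = vp * vd / 100.0
            if p > 0 and d > 0:
                v *= interaction
            for r in range(peptide.replicates):
                rows.append(
                    {
                        "peptide_dose_uM": p,
                        "dox_dose_uM": d,
                        "replicate": r + 1,
                        "viability": v + rng.normal(0, peptide.noise_sd),
                    }
                )
    return pd.DataFrame(rows)
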