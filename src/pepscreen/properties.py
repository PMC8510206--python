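"""Physicochemical descriptors of peptides.

Anticancer peptides are typically short, cationic and amphipathic; these
descriptors are the ones used to characterise screening candidates:

* **net charge** — integer side-chain model at neutral pH (K, R = +1;
  D, E = −1; His and the termini contribute 0),
* **GRAVY** — grand average of hydropathy, Kyte–Doolittle by default
  (positive = hydrophobic),
* **hydrophobic moment** μH — Eisenberg's mean-vector magnitude at the
  α-helical periodicity of 100°/residue; μH above a threshold (default
  0.2) marks a peptide amphipathic,
* **composition** — exact per-residue counts.

An optional Henderson–Hasselbalch pH-dependent charge is provided for
users who need fractional charges; classification uses the integer model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from typing import Mapping

from Bio.SeqUtils import ProtParamData

from .digestion import AMINO_ACIDS

__all__ = [
    "net_charge",
    "charge_ph",
    "gravy",
    "hydrophobic_moment",
    "composition",
    "PeptideProperties",
    "compute_properties",
    "HYDROPATHY_SCALES",
]


class SequenceError(ValueError):
    pass


def _check(sequence: str) -> str:
    if not sequence:
        raise SequenceError("empty sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise SequenceError(f"illegal character(s) {sorted(bad)} in {sequence!r}")
    return sequence


_SIDE_CHAIN_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

# Eisenberg consensus hydrophobicity (normalized); used for the moment.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

HYDROPATHY_SCALES: dict[str, Mapping[str, float]] = {
    "kyte_doolittle": ProtParamData.kd,
    "hopp_woods": ProtParamData.hw,
    "eisenberg": EISENBERG,
}

# side-chain / terminal pKa values (EMBOSS set) for the optional pH model
_PKA_POS = {"K": 10.53, "R": 12.50, "H": 6.50}
_PKA_NEG = {"D": 3.90, "E": 4.07, "C": 8.50, "Y": 10.07}
_PKA_NTERM, _PKA_CTERM = 8.6, 3.6


def net_charge(sequence: str) -> int:
    """Integer side-chain charge at neutral pH: K/R +1, D/E −1, H 0,
    termini ignored."""
    _check(sequence)
    return sum(_SIDE_CHAIN_CHARGE.get(aa, 0) for aa in sequence)


def charge_ph(sequence: str, ph: float = 7.0, termini: bool = True) -> float:
    """Henderson–Hasselbalch fractional charge at a given pH (optional
    alternative to the integer model)."""
    _check(sequence)
    q = 0.0
    for aa in sequence:
        if aa in _PKA_POS:
            q += 1.0 / (1.0 + 10 ** (ph - _PKA_POS[aa]))
        elif aa in _PKA_NEG:
            q -= 1.0 / (1.0 + 10 ** (_PKA_NEG[aa] - ph))
    if termini:
        q += 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
        q -= 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    return q


def charge_class(q: float) -> str:
    return "cationic" if q > 0 else ("anionic" if q < 0 else "neutral")


def gravy(sequence: str, scale: str = "kyte_doolittle") -> float:
    """Mean per-residue hydropathy.  Under the default Kyte–Doolittle scale
    a positive GRAVY is read as hydrophobic."""
    _check(sequence)
    try:
        table = HYDROPATHY_SCALES[scale]
    except KeyError:
        raise SequenceError(
            f"unknown hydropathy scale {scale!r}; known: {sorted(HYDROPATHY_SCALES)}"
        )
    return sum(table[aa] for aa in sequence) / len(sequence)


def hydrophobic_moment(
    sequence: str, angle_deg: float = 100.0, scale: str = "eisenberg"
) -> float:
    """Eisenberg hydrophobic moment μH = (1/N)·|Σ_i h_i·e^(i·δ·i)| with the
    helical twist δ (degrees per residue, default 100°)."""
    _check(sequence)
    if len(sequence) < 2:
        raise SequenceError("hydrophobic moment needs length >= 2")
    table = HYDROPATHY_SCALES[scale] if isinstance(scale, str) else scale
    delta = math.radians(angle_deg)
    sx = sum(table[aa] * math.cos(i * delta) for i, aa in enumerate(sequence, start=1))
    sy = sum(table[aa] * math.sin(i * delta) for i, aa in enumerate(sequence, start=1))
    return math.hypot(sx, sy) / len(sequence)


def composition(sequence: str) -> dict[str, int]:
    """Exact per-letter residue counts."""
    _check(sequence)
    return dict(Counter(sequence))


@dataclass(frozen=True)
class PeptideProperties:
    sequence: str
    length: int
    net_charge: int
    gravy: float
    hydrophobic_moment: float
    charge_class: str
    hydro_class: str
    amphipathic: bool
    composition: dict[str, int]


AMPHIPATHIC_THRESHOLD = 0.2


def compute_properties(
    sequence: str,
    gravy_scale: str = "kyte_doolittle",
    moment_angle: float = 100.0,
    amphipathic_threshold: float = AMPHIPATHIC_THRESHOLD,
) -> PeptideProperties:
    """All descriptors for one peptide, with class labels.

    hydro_class is hydrophobic iff GRAVY > 0 (sign convention of the
    default scale); amphipathic iff μH ≥ the threshold.
    """
    _check(sequence)
    q = net_charge(sequence)
    g = gravy(sequence, gravy_scale)
    mu = hydrophobic_moment(sequence, moment_angle) if len(sequence) >= 2 else 0.0
    return PeptideProperties(
        sequence=sequence,
        length=len(sequence),
        net_charge=q,
        gravy=g,
        hydrophobic_moment=mu,
        charge_class=charge_class(q),
        hydro_class="hydrophobic" if g > 0 else "hydrophilic",
        amphipathic=mu >= amphipathic_threshold,
        composition=composition(sequence),
    )
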