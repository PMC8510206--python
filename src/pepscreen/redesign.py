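"""Substitution-based peptide redesign.

Given a candidate peptide and a scorer (any callable mapping a sequence to
a real score), the redesign search enumerates single-residue substitutions
and greedily accepts the best one per round, up to ``max_rounds`` rounds —
the same move structure as server-side "peptide design" options that
suggest a small number of point substitutions to raise a prediction score.
An exhaustive ≤k-substitution search is provided as an oracle for small k.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .digestion import AMINO_ACIDS

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical


@dataclass(frozen=True)
class Substitution:
    """One point substitution at a 1-based position."""

    position: int
    from_residue: str
    to_residue: str

    def __post_init__(self) -> None:
        if self.from_residue == self.to_residue:
            raise ValueError(f"null substitution at position {self.position}")

    def __str__(self) -> str:  # e.g. "M3G"
        return f"{self.from_residue}{self.position}{self.to_residue}"


@dataclass(frozen=True)
class RedesignResult:
    original: str
    variant: str
    substitutions: tuple[Substitution, ...]
    original_score: float
    variant_score: float

    def highlighted(self) -> str:
        """Variant with substituted positions bracketed, mirroring the
        red-letter presentation of redesign tables."""
        marked = set(s.position for s in self.substitutions)
        return "".join(
            f"[{aa}]" if i in marked else aa
            for i, aa in enumerate(self.variant, start=1)
        )


def diff(original: str, variant: str) -> list[Substitution]:
    """Positional differences between two equal-length sequences, N→C."""
    if len(original) != len(variant):
        raise ValueError(
            f"length mismatch: {len(original)} vs {len(variant)}"
        )
    return [
        Substitution(i, a, b)
        for i, (a, b) in enumerate(zip(original, variant), start=1)
        if a != b
    ]


def apply(original: str, substitutions: Sequence[Substitution]) -> str:
    """Apply substitutions; each must match the current residue at its
    position."""
    seq = list(original)
    for sub in substitutions:
        if not (1 <= sub.position <= len(seq)):
            raise ValueError(f"position {sub.position} outside peptide of length {len(seq)}")
        if seq[sub.position - 1] != sub.from_residue:
            raise ValueError(
                f"substitution {sub}: residue at position {sub.position} is "
                f"{seq[sub.position - 1]!r}, not {sub.from_residue!r}"
            )
        seq[sub.position - 1] = sub.to_residue
    return "".join(seq)


def enumerate_single_mutants(
    peptide: str,
    alphabet: str = ALPHABET,
    positions: Sequence[int] | None = None,
) -> list[tuple[str, Substitution]]:
    """All single mutants in deterministic order (position-major, residue
    alphabetical): length × 19 variants for the full alphabet."""
    if not peptide:
        raise ValueError("empty peptide")
    pos_list = positions if positions is not None else range(1, len(peptide) + 1)
    out = []
    for pos in pos_list:
        orig = peptide[pos - 1]
        for aa in sorted(alphabet):
            if aa == orig:
                continue
            sub = Substitution(pos, orig, aa)
            out.append((apply(peptide, [sub]), sub))
    return out


def redesign(
    peptide: str,
    scorer: Callable[[str], float],
    max_rounds: int = 2,
    min_gain: float = 0.0,
) -> RedesignResult:
    """Greedy hill-climb: each round takes the single mutant with the
    highest score (ties broken by lowest position, then alphabetical
    residue), stopping when the best gain is ≤ ``min_gain`` or after
    ``max_rounds`` rounds.  The result never scores below the original.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    original_score = _score(scorer, peptide)
    current, current_score = peptide, original_score
    for _ in range(max_rounds):
        best_seq, best_score = None, float("-inf")
        # enumeration order encodes the tie-break: the first maximum wins
        for variant, _sub in enumerate_single_mutants(current):
            s = _score(scorer, variant)
            if s > best_score:
                best_seq, best_score = variant, s
        if best_seq is None or best_score - current_score <= min_gain:
            break
        current, current_score = best_seq, best_score
    return RedesignResult(
        original=peptide,
        variant=current,
        substitutions=tuple(diff(peptide, current)),
        original_score=original_score,
        variant_score=current_score,
    )


def exhaustive_redesign(
    peptide: str, scorer: Callable[[str], float], max_substitutions: int = 1
) -> RedesignResult:
    """Oracle search over every variant with ≤ ``max_substitutions``
    substitutions (exponential; intended for small peptides / small k).
    Tie-break matches the greedy search: the enumeration runs over fewer
    substitutions first, then lowest positions, then alphabetical residues,
    and only a strictly better score displaces the incumbent."""
    original_score = _score(scorer, peptide)
    best_seq, best_score = peptide, original_score
    n = len(peptide)
    for k in range(1, max_substitutions + 1):
        for pos_combo in itertools.combinations(range(n), k):
            for residues in itertools.product(ALPHABET, repeat=k):
                if any(peptide[p] == r for p, r in zip(pos_combo, residues)):
                    continue
                seq = list(peptide)
                for p, r in zip(pos_combo, residues):
                    seq[p] = r
                cand = "".join(seq)
                s = _score(scorer, cand)
                if s > best_score:
                    best_seq, best_score = cand, s
    return RedesignResult(
        original=peptide,
        variant=best_seq,
        substitutions=tuple(diff(peptide, best_seq)),
        original_score=original_score,
        variant_score=best_score,
    )


def _score(scorer: Callable[[str], float], peptide: str) -> float:
    try:
        return float(scorer(peptide))
    except Exception as exc:  # surface which peptide broke the scorer
        raise RuntimeError(f"scorer failed on {peptide!r}: {exc}") from exc


def additive_scorer(weights: Mapping[str, float]) -> Callable[[str], float]:
    """Transparent per-residue additive scorer (score = Σ weights[aa]);
    used for tests and demos — real use expects a user-supplied model."""
    missing = AMINO_ACIDS - set(weights)
    if missing:
        raise ValueError(f"weight table missing residues: {sorted(missing)}")
    return lambda seq: sum(weights[aa] for aa in seq)
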