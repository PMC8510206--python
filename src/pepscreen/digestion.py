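"""In silico protease digestion of a proteome.

The screening pipeline starts from a protein FASTA, applies a protease
cleavage rule (pepsin by default), and keeps unique peptides in a length
window.  Cleavage rules are of the simplified PeptideCutter style: the bond
C-terminal to a P1 residue is cut unless the P1' residue (the one
immediately after the bond) vetoes it.  Pepsin at pH 1.3 cuts after F/L,
at pH 2 also after W/Y; proline in P1' blocks the cut in both variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: ``X`` (unknown residue) is tolerated in proteins but never a cut site.
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}


class FastaError(ValueError):
    """Raised when a FASTA record fails validation."""


class ConfigError(ValueError):
    """Raised for invalid rule or filter configuration."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"record {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in PROTEIN_ALPHABET:
                raise FastaError(
                    f"record {self.id!r}: illegal character {aa!r} at position {pos}"
                )


@dataclass(frozen=True)
class CleavageRule:
    """Cut C-terminal to any residue in ``p1_residues`` unless the next
    residue is in ``p1prime_blockers``."""

    name: str
    p1_residues: frozenset[str]
    p1prime_blockers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise ConfigError(f"rule {self.name!r}: p1_residues must be non-empty")
        bad = (set(self.p1_residues) | set(self.p1prime_blockers)) - AMINO_ACIDS
        if bad:
            raise ConfigError(f"rule {self.name!r}: not amino acids: {sorted(bad)}")

    def cut_sites(self, sequence: str) -> list[int]:
        """0-based indices i such that the bond between i and i+1 is cut."""
        return [
            i
            for i in range(len(sequence) - 1)
            if sequence[i] in self.p1_residues
            and sequence[i + 1] not in self.p1prime_blockers
        ]


PEPSIN_PH13 = CleavageRule("pepsin_pH1.3", frozenset("FL"), frozenset("P"))
PEPSIN_PH2 = CleavageRule("pepsin_pH2", frozenset("FLWY"), frozenset("P"))

BUILTIN_RULES: dict[str, CleavageRule] = {
    PEPSIN_PH13.name: PEPSIN_PH13,
    PEPSIN_PH2.name: PEPSIN_PH2,
}


def load_rules(path: str | Path) -> dict[str, CleavageRule]:
    """Load cleavage rules from a YAML mapping
    ``name -> {p1_residues: "FL", p1prime_blockers: "P"}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping of rule names")
    rules = {}
    for name, spec in raw.items():
        rules[name] = CleavageRule(
            name,
            frozenset(spec.get("p1_residues", "")),
            frozenset(spec.get("p1prime_blockers", "")),
        )
    return rules


def get_rule(name: str, extra: Mapping[str, CleavageRule] | None = None) -> CleavageRule:
    table = dict(BUILTIN_RULES)
    if extra:
        table.update(extra)
    try:
        return table[name]
    except KeyError:
        raise ConfigError(f"unknown cleavage rule {name!r}; known: {sorted(table)}")


@dataclass(frozen=True)
class PeptideRecord:
    """A digested fragment with 1-based inclusive parent coordinates."""

    sequence: str
    parent_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.sequence!r}: coordinates [{self.start},{self.end}] "
                f"inconsistent with length {len(self.sequence)}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a (possibly line-wrapped) multi-record FASTA into protein records.

    Sequences are upper-cased; record order is preserved.  An illegal
    character raises :class:`FastaError` naming the record and position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    return records


def digest(
    protein: ProteinRecord,
    rule: CleavageRule = PEPSIN_PH13,
    missed_cleavages: int = 0,
) -> list[PeptideRecord]:
    """Digest one protein, optionally allowing missed cleavages.

    With ``k`` missed cleavages the output contains every concatenation of
    up to ``k + 1`` adjacent fully-cleaved fragments.  Fragments are emitted
    N→C (by start position, shorter spans first at equal start).
    """
    if missed_cleavages < 0 or missed_cleavages > 5:
        raise ValueError("missed_cleavages must be in 0..5")
    seq = protein.sequence
    cuts = rule.cut_sites(seq)
    # 0-based half-open fragment bounds internally; 1-based inclusive emitted
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    n_frag = len(bounds) - 1
    out = []
    for i in range(n_frag):
        for j in range(i, min(i + missed_cleavages + 1, n_frag)):
            lo, hi = bounds[i], bounds[j + 1]
            out.append(PeptideRecord(seq[lo:hi], protein.id, lo + 1, hi))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def filter_and_deduplicate(
    peptides: Iterable[PeptideRecord], min_len: int = 5, max_len: int = 50
) -> list[PeptideRecord]:
    """Keep peptides with ``min_len <= length <= max_len``; deduplicate by
    sequence, keeping the first occurrence in input order.

    Deduplication is global across parents (the pipeline counts *unique*
    peptides).  Peptides containing ``X`` are dropped: the downstream
    property math is undefined for unknown residues.
    """
    if min_len > max_len:
        raise ConfigError(f"min_len {min_len} > max_len {max_len}")
    seen: set[str] = set()
    out = []
    n_unknown = 0
    for pep in peptides:
        if not (min_len <= len(pep.sequence) <= max_len):
            continue
        if "X" in pep.sequence:
            n_unknown += 1
            continue
        if pep.sequence in seen:
            continue
        seen.add(pep.sequence)
        out.append(pep)
    if n_unknown:
        logger.info("dropped %d peptide(s) containing unknown residue X", n_unknown)
    return out


DEFAULT_BINS: tuple[tuple[int, int], ...] = ((5, 20), (21, 35), (36, 50))


@dataclass
class LengthBins:
    """Per-bin peptide counts and 1-decimal percentage shares."""

    edges: tuple[tuple[int, int], ...]
    counts: tuple[int, ...]
    total: int
    empty: bool = field(default=False)

    @property
    def proportions(self) -> tuple[float, ...]:
        """Percentages rounded to 1 decimal; undefined (all-zero) when empty."""
        if self.empty:
            return tuple(0.0 for _ in self.counts)
        return tuple(round(100.0 * c / self.total, 1) for c in self.counts)


def length_distribution(
    peptides: Sequence[PeptideRecord],
    bins: tuple[tuple[int, int], ...] = DEFAULT_BINS,
) -> LengthBins:
    """Histogram peptide lengths into inclusive bins (default 5–20 / 21–35 /
    36–50 residues).  A peptide outside every bin indicates a missing length
    filter and raises ``ValueError``."""
    counts = [0] * len(bins)
    for pep in peptides:
        n = len(pep.sequence)
        for i, (lo, hi) in enumerate(bins):
            if lo <= n <= hi:
                counts[i] += 1
                break
        else:
            raise ValueError(
                f"peptide {pep.sequence!r} (length {n}) outside all bins {bins}"
            )
    total = sum(counts)
    return LengthBins(tuple(bins), tuple(counts), total, empty=total == 0)


def digest_proteome(
    proteins: Iterable[ProteinRecord],
    rule: CleavageRule = PEPSIN_PH13,
    missed_cleavages: int = 0,
    min_len: int = 5,
    max_len: int = 50,
) -> list[PeptideRecord]:
    """Digest every protein, then length-filter and deduplicate globally."""
    all_peps: list[PeptideRecord] = []
    for prot in proteins:
        all_peps.extend(digest(prot, rule, missed_cleavages))
    return filter_and_deduplicate(all_peps, min_len, max_len)


def write_peptides_tsv(peptides: Sequence[PeptideRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tparent_id\tstart\tend\tlength\n")
        for p in peptides:
            fh.write(f"{p.sequence}\t{p.parent_id}\t{p.start}\t{p.end}\t{len(p.sequence)}\n")


def write_peptides_fasta(peptides: Sequence[PeptideRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.parent_id}|{p.start}-{p.end}\n{p.sequence}\n")
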