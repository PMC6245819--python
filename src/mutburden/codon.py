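"""Genetic-code computations on coding sequences.

Every single-nucleotide substitution (SNS) in a coding region has a
deterministic outcome under the standard nuclear genetic code: it leaves
the encoded amino acid unchanged (silent), changes it (missense), creates
a stop codon (nonsense), or destroys one (stop loss).  A coding region of
N nucleotides admits exactly 3N possible SNSs, and the per-class tallies
of those 3N outcomes — the *potential sites* for each mutation type — are
gene characteristics that strongly shape how many somatic mutations of
each type a gene can accumulate.

This module classifies substitutions, enumerates potential sites, and
computes sequence-composition statistics (base fractions, CpG fraction,
nucleotide diversity) plus the ortholog-based conservation index.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: codon -> amino acid (one-letter), stop codons map to "*"
CODON_TABLE: Mapping[str, str] = {
    **standard_dna_table.forward_table,
    **{c: "*" for c in STOP_CODONS},
}

ALL_CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))


class SubstitutionClass(enum.Enum):
    """Outcome class of a single-nucleotide substitution in a codon."""

    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class SubstitutionOutcome:
    """One classified single-nucleotide substitution."""

    klass: SubstitutionClass
    ref_codon: str
    alt_codon: str
    codon_index: int = 0
    within_codon_pos: int = 0


@dataclass(frozen=True)
class CodingSequence:
    """A gene's coding region: identifier plus in-frame nucleotide string."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise ValueError(f"{self.gene_id}: coding sequence shorter than one codon")
        if len(seq) % 3:
            raise ValueError(
                f"{self.gene_id}: length {len(seq)} not divisible by 3"
            )
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(
                f"{self.gene_id}: non-ACGT characters {sorted(bad)!r}; "
                "ambiguity codes are not accepted"
            )

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass(frozen=True)
class PotentialSiteCounts:
    """Per-class tallies of all 3N possible substitutions of a CDS."""

    n_total_sns: int
    n_missense: int
    n_nonsense: int
    n_silent: int
    n_stop_loss: int


@dataclass(frozen=True)
class CompositionStats:
    """Base fractions, CpG dinucleotide fraction and nucleotide diversity.

    Nucleotide diversity (ND) is the probability that two bases drawn at
    random from the sequence differ: ``1 - (pA^2 + pC^2 + pG^2 + pT^2)``.
    It is 0 for a homopolymer and at most 0.75 (equal base composition).
    """

    p_a: float
    p_c: float
    p_g: float
    p_t: float
    cpg_fraction: float
    nd: float


@dataclass(frozen=True)
class ConservationIndex:
    """Binned ortholog count across the 20 reference species.

    Genes with 0–1 orthologs get index 1, genes with 2–3 get index 2,
    and so on: ``index = floor(n_orthologs / 2) + 1``.
    """

    n_orthologs: int
    index: int


def _classify_codon_pair(ref_codon: str, alt_codon: str) -> SubstitutionClass:
    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
    if ref_aa == alt_aa:
        return SubstitutionClass.SILENT  # includes stop -> stop
    if alt_aa == "*":
        return SubstitutionClass.NONSENSE
    if ref_aa == "*":
        return SubstitutionClass.STOP_LOSS
    return SubstitutionClass.MISSENSE


def classify_substitution(
    ref_codon: str, within_codon_pos: int, alt_base: str, codon_index: int = 0
) -> SubstitutionOutcome:
    """Classify the substitution of ``alt_base`` at ``within_codon_pos``.

    Case-insensitive; strand-naive (the codon is taken as the coding
    strand).  Raises ``ValueError`` for invalid bases, positions, or an
    ``alt_base`` equal to the reference base.
    """
    ref_codon = ref_codon.upper()
    alt_base = alt_base.upper()
    if len(ref_codon) != 3 or any(b not in _BASE_INDEX for b in ref_codon):
        raise ValueError(f"invalid codon {ref_codon!r}")
    if within_codon_pos not in (0, 1, 2):
        raise ValueError(f"within_codon_pos must be 0, 1 or 2, got {within_codon_pos}")
    if alt_base not in _BASE_INDEX:
        raise ValueError(f"invalid nucleotide {alt_base!r}")
    if alt_base == ref_codon[within_codon_pos]:
        raise ValueError(
            f"alt base {alt_base!r} equals the reference base at position "
            f"{within_codon_pos} of {ref_codon}"
        )
    alt_codon = (
        ref_codon[:within_codon_pos] + alt_base + ref_codon[within_codon_pos + 1 :]
    )
    return SubstitutionOutcome(
        klass=_classify_codon_pair(ref_codon, alt_codon),
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        codon_index=codon_index,
        within_codon_pos=within_codon_pos,
    )


def _build_outcome_table() -> np.ndarray:
    """(64, 3, 4) array of class codes; -1 marks alt == ref (no substitution).

    Codon index is base4 of the three base indices (A=0, C=1, G=2, T=3).
    Class codes follow _CLASS_ORDER.
    """
    table = np.full((64, 3, 4), -1, dtype=np.int8)
    for ci, codon in enumerate(ALL_CODONS):
        for pos in range(3):
            for bi, alt in enumerate(BASES):
                if alt == codon[pos]:
                    continue
                out = classify_substitution(codon, pos, alt)
                table[ci, pos, bi] = _CLASS_ORDER.index(out.klass)
    return table


_CLASS_ORDER = (
    SubstitutionClass.SILENT,
    SubstitutionClass.MISSENSE,
    SubstitutionClass.NONSENSE,
    SubstitutionClass.STOP_LOSS,
)
_OUTCOME_TABLE = _build_outcome_table()


def _codon_indices(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    digits = code[arr]
    if (digits < 0).any():
        raise ValueError("non-ACGT character in sequence")
    return (
        digits[0::3].astype(np.int32) * 16
        + digits[1::3].astype(np.int32) * 4
        + digits[2::3].astype(np.int32)
    )


def count_potential_sites(cds: CodingSequence) -> PotentialSiteCounts:
    """Enumerate all 3N substitutions of a CDS and tally them per class."""
    counts = _class_count_matrix(cds.sequence)
    return PotentialSiteCounts(
        n_total_sns=3 * cds.length_nt,
        n_silent=int(counts[0]),
        n_missense=int(counts[1]),
        n_nonsense=int(counts[2]),
        n_stop_loss=int(counts[3]),
    )


# per-codon class counts, precomputed once: (64, 4)
_CODON_CLASS_COUNTS = np.stack(
    [
        np.bincount(_OUTCOME_TABLE[ci][_OUTCOME_TABLE[ci] >= 0], minlength=4)
        for ci in range(64)
    ]
).astype(np.int64)


def _class_count_matrix(sequence: str) -> np.ndarray:
    idx = _codon_indices(sequence)
    return _CODON_CLASS_COUNTS[idx].sum(axis=0)


def nonsense_capable_codons() -> frozenset[str]:
    """Codons from which at least one SNS yields a stop codon.

    The criterion is "the resulting codon is a stop codon", so stop codons
    that can mutate into other stop codons are themselves members.  Exactly
    21 of the 64 codons qualify.
    """
    capable = set()
    for codon in ALL_CODONS:
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                alt_codon = codon[:pos] + alt + codon[pos + 1 :]
                if alt_codon in STOP_CODONS:
                    capable.add(codon)
    return frozenset(capable)


def composition_stats(cds: CodingSequence) -> CompositionStats:
    """Base fractions, CpG fraction (CG dinucleotides / N) and ND."""
    seq = cds.sequence
    n = len(seq)
    p = {b: seq.count(b) / n for b in BASES}
    # "CG" occurrences cannot overlap, so str.count sees them all
    cpg = seq.count("CG") / n
    nd = 1.0 - sum(v * v for v in p.values())
    return CompositionStats(
        p_a=p["A"], p_c=p["C"], p_g=p["G"], p_t=p["T"], cpg_fraction=cpg, nd=nd
    )


def conservation_index(n_orthologs: int) -> ConservationIndex:
    """Bin an ortholog count (0..20) into the conservation index."""
    if n_orthologs < 0:
        raise ValueError("ortholog count cannot be negative")
    return ConservationIndex(n_orthologs=n_orthologs, index=n_orthologs // 2 + 1)


# ---------------------------------------------------------------------------
# FASTA ingestion and per-gene feature table


def read_cds_fasta(
    path: str | Path, id_delimiter: str | None = "|"
) -> dict[str, CodingSequence]:
    """Read coding sequences from FASTA, keeping one record per gene.

    Record ids of the form ``geneId<delim>transcriptId`` are split on the
    delimiter; plain ids are used as gene ids.  When a gene has several
    records the longest sequence wins; exact length ties are broken by the
    lexicographically smallest record id.
    """
    from Bio import SeqIO

    best: dict[str, tuple[int, str, CodingSequence]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        gene = rid.split(id_delimiter, 1)[0] if id_delimiter else rid
        cds = CodingSequence(gene_id=gene, sequence=str(rec.seq))
        key = (-cds.length_nt, rid)
        if gene not in best or key < best[gene][:2]:
            best[gene] = (-cds.length_nt, rid, cds)
    return {g: t[2] for g, t in best.items()}


SEQUENCE_FEATURE_COLUMNS = [
    "cds_length",
    "n_potential_missense",
    "n_potential_nonsense",
    "n_potential_silent",
    "pct_a",
    "pct_c",
    "pct_g",
    "pct_t",
    "pct_cpg",
    "nd",
]


def sequence_features(genes: Iterable[CodingSequence]) -> pd.DataFrame:
    """Per-gene table of all sequence-derived characteristics.

    Indexed by gene_id with columns ``SEQUENCE_FEATURE_COLUMNS``.
    """
    rows = {}
    for cds in genes:
        sites = count_potential_sites(cds)
        comp = composition_stats(cds)
        rows[cds.gene_id] = (
            cds.length_nt,
            sites.n_missense,
            sites.n_nonsense,
            sites.n_silent,
            comp.p_a,
            comp.p_c,
            comp.p_g,
            comp.p_t,
            comp.cpg_fraction,
            comp.nd,
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=SEQUENCE_FEATURE_COLUMNS)
    df.index.name = "gene_id"
    return df
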