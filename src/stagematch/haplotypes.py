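"""Haplotype collapsing and alignment summary statistics.

Haplotype-based chronograms require that identical sequences be removed from
the alignment first; :func:`collapse_haplotypes` performs that reduction and
emits the membership table needed to expand delimited clusters of haplotypes
back to specimens. :func:`alignment_stats` reports the usual alignment
summary (variable sites, parsimony-informative sites, missing data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .core import DataError

#: IUPAC nucleotide codes -> set of unambiguous bases.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"), "?": frozenset("ACGT"),
}
GAP = "-"
MISSING_CHARS = frozenset("-N?")
UNAMBIGUOUS = frozenset("ACGT")
VALID_CHARS = frozenset(IUPAC) | {GAP}


@dataclass
class Alignment:
    """A multiple sequence alignment over the IUPAC DNA alphabet."""

    gene: str
    sequences: dict[str, str]

    def __post_init__(self):
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise DataError(f"sequences of unequal length in {self.gene} alignment: {sorted(lengths)}")
        for sid, seq in self.sequences.items():
            bad = set(seq) - VALID_CHARS
            if bad:
                raise DataError(f"invalid character(s) {sorted(bad)} in sequence {sid!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n_seqs(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_fasta(cls, path, gene: str) -> "Alignment":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise DataError(f"no sequences in {path}")
        return cls(gene=gene, sequences=seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid}\n{seq}\n")


@dataclass
class HaplotypeSet:
    """Unique haplotypes plus the specimen membership of each."""

    gene: str
    representatives: dict[str, str]
    membership: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.representatives)

    def tip_map(self) -> dict[str, frozenset[str]]:
        return dict(self.membership)

    def to_alignment(self) -> Alignment:
        return Alignment(gene=self.gene, sequences=dict(self.representatives))

    def expand(self) -> list[str]:
        """Sequence multiset obtained by replicating each representative per member."""
        return sorted(
            self.representatives[h] for h, members in self.membership.items() for _ in members
        )

    def membership_frame(self) -> pd.DataFrame:
        rows = [
            {"haplotype": h, "specimen": sid}
            for h in sorted(self.membership)
            for sid in sorted(self.membership[h])
        ]
        return pd.DataFrame(rows, columns=["haplotype", "specimen"])


def _compatible(a: str, b: str) -> bool:
    """Column-wise mergeability under the ``compatible`` policy.

    Identical characters always match (including gap/gap); otherwise the two
    IUPAC sets must intersect and at least one must be unambiguous. A gap
    never matches a different character.
    """
    if a == b:
        return True
    if a == GAP or b == GAP:
        return False
    sa, sb = IUPAC[a], IUPAC[b]
    if not (sa & sb):
        return False
    return len(sa) == 1 or len(sb) == 1


def collapse_haplotypes(aln: Alignment, ambiguity_mode: str = "strict") -> HaplotypeSet:
    """Merge identical (or IUPAC-compatible) sequences into unique haplotypes.

    ``strict`` merges sequences equal character-by-character; ``compatible``
    additionally merges a sequence into the first earlier haplotype whose
    representative is column-wise compatible (greedy, in input order). The
    representative of a haplotype is its first member's sequence.
    """
    if aln.n_seqs == 0:
        raise DataError("empty alignment")
    if ambiguity_mode not in ("strict", "compatible"):
        raise ValueError(f"unknown ambiguity mode {ambiguity_mode!r}")

    reps: list[tuple[str, str]] = []  # (haplotype id, representative sequence)
    members: dict[str, set[str]] = {}
    by_seq: dict[str, str] = {}
    for sid, seq in aln.sequences.items():
        target = by_seq.get(seq)
        if target is None and ambiguity_mode == "compatible":
            for hid, rep in reps:
                if all(_compatible(x, y) for x, y in zip(seq, rep)):
                    target = hid
                    break
        if target is None:
            hid = f"{aln.gene}_h{len(reps) + 1:04d}"
            reps.append((hid, seq))
            by_seq[seq] = hid
            members[hid] = {sid}
        else:
            members[target].add(sid)
    return HaplotypeSet(
        gene=aln.gene,
        representatives=dict(reps),
        membership={h: frozenset(m) for h, m in members.items()},
    )


def alignment_stats(aln: Alignment) -> dict:
    """Alignment summary: counts plus percentages of variable sites,
    parsimony-informative sites, and missing cells.

    A column is *variable* if it shows at least two distinct unambiguous
    nucleotides, and *parsimony-informative* if at least two unambiguous
    states each occur in at least two sequences. Missing cells are ``-``,
    ``N`` and ``?``; other ambiguity codes count as neither unambiguous nor
    missing.
    """
    if aln.n_seqs == 0:
        raise DataError("empty alignment")
    seqs = list(aln.sequences.values())
    n, L = len(seqs), aln.length
    variable = informative = missing = 0
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for ch in col:
            if ch in UNAMBIGUOUS:
                counts[ch] = counts.get(ch, 0) + 1
            elif ch in MISSING_CHARS:
                missing += 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
    return {
        "n_seqs": n,
        "length": L,
        "n_variable": variable,
        "n_parsimony_informative": informative,
        "pct_variable": 100.0 * variable / L,
        "pct_parsimony_informative": 100.0 * informative / L,
        "pct_missing": 100.0 * missing / (n * L),
    }


class StopCodonWarning(UserWarning):
    pass


def check_stop_codons(
    aln: Alignment, frame_offset: int = 0, genetic_code: str = "Invertebrate Mitochondrial"
) -> list[str]:
    """Screen a protein-coding alignment for internal stop codons.

    This is a warning pass only — sequences are reported, never filtered.
    ``frame_offset`` is the number of leading columns before the first full
    codon. Returns the offending specimen ids (also emitted as warnings).
    """
    table = CodonTable.ambiguous_dna_by_name[genetic_code]
    offenders = []
    for sid, seq in aln.sequences.items():
        coding = seq[frame_offset:].replace("-", "").replace("?", "N")
        coding = coding[: 3 * (len(coding) // 3)]
        if not coding:
            continue
        protein = str(Seq(coding).translate(table=table))
        if "*" in protein[:-1]:
            offenders.append(sid)
            warnings.warn(
                f"internal stop codon in {sid!r} ({aln.gene}, {genetic_code} code)",
                StopCodonWarning,
                stacklevel=2,
            )
    return offenders


def stats_frame(alignments: list[Alignment]) -> pd.DataFrame:
    """Alignment-statistics table (one row per alignment)."""
    rows = []
    for aln in alignments:
        st = alignment_stats(aln)
        rows.append({"alignment": aln.gene, **st})
    return pd.DataFrame(rows)
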