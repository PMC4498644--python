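"""Alignment trimming and uncorrected p-distances.

Distances are computed with pairwise deletion: a site enters a pair's
comparison only when both sequences carry an unambiguous base there.  Group
distances report min/mean/max over all cross-group pairs, since a statement
like "the difference reaches X%" pins down only the maximum.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = set("ACGT")
_GAPLIKE = set("-.")


class AlignmentError(ValueError):
    pass


class SequenceAlignment:
    """Ordered (name, aligned sequence) pairs of equal length.

    Accepts A/C/G/T, gaps (`-`/`.`) and IUPAC ambiguity codes (incl. N);
    ambiguity codes are treated like gaps for distance purposes.
    """

    _ALPHABET = _BASES | _GAPLIKE | set("RYSWKMBDHVNU")

    def __init__(self, records: Iterable[tuple[str, str]]):
        self.records = [(name, seq.upper()) for name, seq in records]
        if not self.records:
            raise AlignmentError("empty alignment")
        names = [n for n, _ in self.records]
        if len(set(names)) != len(names):
            raise AlignmentError("duplicate sequence names")
        L = len(self.records[0][1])
        for name, seq in self.records:
            if len(seq) != L:
                raise AlignmentError(
                    f"aligned lengths differ: {name} has {len(seq)}, expected {L}")
            bad = set(seq) - self._ALPHABET
            if bad:
                raise AlignmentError(f"invalid characters in {name}: {sorted(bad)}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise AlignmentError(f"no sequence named {name!r}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, text_or_path) -> "SequenceAlignment":
        handle = (StringIO(text_or_path) if "\n" in str(text_or_path)
                  or str(text_or_path).startswith(">") else open(text_or_path))
        with handle:
            recs = [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
        return cls(recs)

    def to_fasta(self) -> str:
        out = StringIO()
        SeqIO.write([SeqRecord(Seq(s), id=n, description="")
                     for n, s in self.records], out, "fasta")
        return out.getvalue()


@dataclass(frozen=True)
class GroupDistance:
    """Cross-group p-distance summary; fractions in [0, 1]."""

    group_a: frozenset[str]
    group_b: frozenset[str]
    min: float
    mean: float
    max: float

    def __post_init__(self):
        if not self.min <= self.mean <= self.max:
            raise ValueError("inconsistent distance summary")


def _span(seq: str) -> tuple[int, int]:
    """[first, last] indices of non-terminal-gap positions."""
    first = next((i for i, ch in enumerate(seq) if ch not in _GAPLIKE), None)
    if first is None:
        raise AlignmentError("sequence is all gaps")
    last = next(i for i in range(len(seq) - 1, -1, -1) if seq[i] not in _GAPLIKE)
    return first, last


def trim_to_shortest(alignment: SequenceAlignment) -> SequenceAlignment:
    """Trim alignment columns to the span covered by the shortest
    sequence(s) (fewest non-gap positions); idempotent."""
    ungapped = [sum(1 for ch in s if ch not in _GAPLIKE)
                for _, s in alignment.records]
    shortest = min(ungapped)
    lo, hi = 0, alignment.length - 1
    for (name, seq), L in zip(alignment.records, ungapped):
        if L == shortest:
            a, b = _span(seq)
            lo, hi = max(lo, a), min(hi, b)
    if lo > hi:
        raise AlignmentError("shortest-sequence spans do not overlap")
    return SequenceAlignment(
        (name, seq[lo:hi + 1]) for name, seq in alignment.records)


def p_distance(a: str, b: str) -> float:
    """Mismatches / compared sites, excluding sites with a gap or ambiguity
    code in either sequence (pairwise deletion)."""
    if len(a) != len(b):
        raise AlignmentError("sequences must be of equal aligned length")
    compared = 0
    mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _BASES and y in _BASES:
            compared += 1
            if x != y:
                mism += 1
    if compared == 0:
        raise AlignmentError("no comparable sites between the two sequences")
    return mism / compared


def group_p_distance(alignment: SequenceAlignment, group_a: Sequence[str],
                     group_b: Sequence[str]) -> GroupDistance:
    """min/mean/max p-distance over all cross-group sequence pairs."""
    ga, gb = frozenset(group_a), frozenset(group_b)
    if not ga or not gb:
        raise AlignmentError("groups must be non-empty")
    if ga & gb:
        raise AlignmentError("groups must be disjoint")
    have = set(alignment.names)
    missing = (ga | gb) - have
    if missing:
        raise AlignmentError(f"unknown sequence names: {sorted(missing)}")
    dists = [p_distance(alignment.sequence(x), alignment.sequence(y))
             for x in sorted(ga) for y in sorted(gb)]
    return GroupDistance(ga, gb, min(dists), statistics.fmean(dists),
                         max(dists))


def distance_matrix_tsv(alignment: SequenceAlignment) -> str:
    """All pairwise p-distances as a TSV matrix."""
    names = alignment.names
    lines = ["\t" + "\t".join(names)]
    for x in names:
        row = [x]
        for y in names:
            row.append("0" if x == y else
                       f"{p_distance(alignment.sequence(x), alignment.sequence(y)):.6f}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def load_accession_manifest(path) -> list[str]:
    """Read a plain-text manifest of GenBank accession IDs, one per line;
    blank lines and `#` comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def fetch_accessions(accessions: Sequence[str], email: str) -> str:
    """OPTIONAL network helper: download GenBank nucleotide records as FASTA
    text via Entrez.  Everything else in this package works offline."""
    from Bio import Entrez
    Entrez.email = email
    with Entrez.efetch(db="nucleotide", id=",".join(accessions),
                       rettype="fasta", retmode="text") as handle:
        return handle.read()
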