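"""Aligned mitochondrial sequence handling.

This module covers the sequence side of a haplotype survey: reading and
writing aligned FASTA, concatenating per-locus alignments (cytochrome b +
control region) into single per-sample haplotype sequences, locating
variable sites in reference-genome coordinates, and collapsing an alignment
into a table of distinct haplotypes with counts and membership.

Sequences live in the alphabet ``{A, C, G, T, -, N}``: ``-`` is an
alignment gap (a real indel state in these data) and ``N`` is missing data.
Two gap conventions are supported throughout:

* ``GAP_AS_STATE`` - a gap is a fifth character state (ARLEQUIN-style,
  "including sites with gaps");
* ``EXCLUDE_GAP_SITES`` - any column containing a gap is removed before
  sequences are compared (DnaSP-style).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT-N")

__all__ = [
    "ALPHABET",
    "Locus",
    "GapMode",
    "MissingPolicy",
    "AlignedSequence",
    "AlignmentError",
    "VariableSiteSet",
    "HaplotypeEntry",
    "HaplotypeTable",
    "ConcatenationResult",
    "read_fasta",
    "write_fasta",
    "concatenate_loci",
    "find_variable_sites",
    "collapse_haplotypes",
    "haplotype_relative_frequencies",
]


class Locus(str, Enum):
    CYTB = "CYTB"
    CR = "CR"
    CONCAT = "CONCAT"


class GapMode(str, Enum):
    GAP_AS_STATE = "GAP_AS_STATE"
    EXCLUDE_GAP_SITES = "EXCLUDE_GAP_SITES"


class MissingPolicy(str, Enum):
    """How ``N`` is treated when collapsing haplotypes.

    ``WILDCARD`` (default): ``N`` matches any state; an ambiguous sequence
    joins the most frequent compatible haplotype. ``AS_STATE``: ``N`` is a
    literal sixth state (no wildcard matching).
    """

    WILDCARD = "WILDCARD"
    AS_STATE = "AS_STATE"


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged lengths, bad characters...)."""


@dataclass(frozen=True)
class AlignedSequence:
    """One aligned sequence.

    ``offset`` is the 1-based reference-genome position of the first base,
    so alignment column ``i`` (0-based) sits at reference position
    ``offset + i``.
    """

    sample_id: str
    locus: Locus
    bases: str
    offset: int = 1

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.bases)


def _validate_alignment(seqs: Sequence[AlignedSequence]) -> None:
    if not seqs:
        raise AlignmentError("alignment is empty")
    length = len(seqs[0].bases)
    offset = seqs[0].offset
    for s in seqs:
        if len(s.bases) != length:
            raise AlignmentError(
                f"ragged alignment: record '{s.sample_id}' has length "
                f"{len(s.bases)}, expected {length}"
            )
        if s.offset != offset:
            raise AlignmentError(
                f"record '{s.sample_id}' has offset {s.offset}, expected {offset}"
            )


def read_fasta(
    path: str | Path,
    locus: Locus = Locus.CONCAT,
    offset: int = 1,
) -> list[AlignedSequence]:
    """Read an aligned FASTA file into a list of :class:`AlignedSequence`.

    Records are returned in file order; lowercase is normalised to
    uppercase; the description after the first whitespace is ignored.
    Characters outside ``{A,C,G,T,-,N}`` raise :class:`AlignmentError`
    naming the offending record, as do ragged lengths and empty files.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    out: list[AlignedSequence] = []
    for rec in records:
        bases = str(rec.seq).upper()
        bad = set(bases) - ALPHABET
        if bad:
            raise AlignmentError(
                f"record '{rec.id}' contains characters outside "
                f"{{A,C,G,T,-,N}}: {sorted(bad)}"
            )
        out.append(AlignedSequence(rec.id, locus, bases, offset))
    _validate_alignment(out)
    return out


def write_fasta(seqs: Iterable[AlignedSequence], path: str | Path) -> None:
    """Write sequences as wrapped FASTA (id only, no description)."""
    records = [
        SeqRecord(Seq(s.bases), id=s.sample_id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class ConcatenationResult:
    """Concatenated alignment plus bookkeeping.

    ``position_map`` records each locus' reference offset and length in
    concatenation order. ``dropped`` lists sample ids present in only one
    locus (excluded from the concatenated alignment).
    """

    alignment: list[AlignedSequence]
    dropped: list[str]
    position_map: dict[str, tuple[int, int]]


def concatenate_loci(
    cytb: Sequence[AlignedSequence],
    cr: Sequence[AlignedSequence],
) -> ConcatenationResult:
    """Concatenate two per-locus alignments keyed by ``sample_id``.

    Only samples present in both alignments are kept (cytb order);
    samples missing one locus are reported in ``dropped``. Duplicate
    sample ids within a locus are an error.
    """
    _validate_alignment(cytb)
    _validate_alignment(cr)
    for name, aln in (("cytb", cytb), ("cr", cr)):
        ids = [s.sample_id for s in aln]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise AlignmentError(f"duplicate sample ids in {name}: {dupes}")
    cr_by_id = {s.sample_id: s for s in cr}
    cytb_ids = {s.sample_id for s in cytb}
    concat: list[AlignedSequence] = []
    for s in cytb:
        partner = cr_by_id.get(s.sample_id)
        if partner is None:
            continue
        concat.append(
            AlignedSequence(
                s.sample_id, Locus.CONCAT, s.bases + partner.bases, s.offset
            )
        )
    dropped = sorted(
        (cytb_ids - set(cr_by_id)) | (set(cr_by_id) - cytb_ids)
    )
    pos_map = {
        Locus.CYTB.value: (cytb[0].offset, len(cytb[0].bases)),
        Locus.CR.value: (cr[0].offset, len(cr[0].bases)),
    }
    if not concat:
        raise AlignmentError("no sample ids shared between the two loci")
    return ConcatenationResult(concat, dropped, pos_map)


@dataclass(frozen=True)
class VariableSiteSet:
    """Variable alignment columns in reference coordinates.

    A position is variable iff at least two distinct non-``N`` states occur
    there (a gap counts as a state). ``indel_runs`` are maximal contiguous
    runs of variable columns at which both a gap and a base are observed,
    reported as inclusive ``(start, end)`` reference positions.
    """

    positions: tuple[int, ...]
    states: dict[int, frozenset[str]]
    indel_runs: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.positions)

    def in_window(self, start: int, end: int) -> tuple[int, ...]:
        """Positions within the inclusive reference window [start, end]."""
        return tuple(p for p in self.positions if start <= p <= end)


def find_variable_sites(alignment: Sequence[AlignedSequence]) -> VariableSiteSet:
    """Locate variable columns; ``N`` never counts as a state."""
    _validate_alignment(alignment)
    offset = alignment[0].offset
    length = len(alignment[0].bases)
    positions: list[int] = []
    states: dict[int, frozenset[str]] = {}
    gapvar: list[bool] = []
    for col in range(length):
        observed = frozenset(s.bases[col] for s in alignment) - {"N"}
        if len(observed) >= 2:
            pos = offset + col
            positions.append(pos)
            states[pos] = observed
            gapvar.append("-" in observed)
        else:
            gapvar.append(False)
    runs: list[tuple[int, int]] = []
    col = 0
    while col < length:
        if gapvar[col]:
            start = col
            while col + 1 < length and gapvar[col + 1]:
                col += 1
            runs.append((offset + start, offset + col))
        col += 1
    return VariableSiteSet(tuple(positions), states, tuple(runs))


@dataclass(frozen=True)
class HaplotypeEntry:
    haplotype_id: str
    sequence: str
    count: int
    members: tuple[str, ...]


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with counts and member sample ids.

    Entries are ordered by descending count, ties by first occurrence in
    the input. ``dropped`` lists sample ids whose sequences could not be
    resolved to any haplotype under the missing-data policy.
    """

    entries: tuple[HaplotypeEntry, ...]
    n_total: int
    gap_mode: GapMode
    offset: int
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if sum(e.count for e in self.entries) != self.n_total:
            raise ValueError("haplotype counts do not sum to n_total")

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(e.count for e in self.entries)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e.haplotype_id for e in self.entries)

    def by_id(self, haplotype_id: str) -> HaplotypeEntry:
        for e in self.entries:
            if e.haplotype_id == haplotype_id:
                return e
        raise KeyError(haplotype_id)

    def sample_to_haplotype(self) -> dict[str, str]:
        return {m: e.haplotype_id for e in self.entries for m in e.members}

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "haplotype_id": [e.haplotype_id for e in self.entries],
                "count": [e.count for e in self.entries],
                "rel_freq": [e.count / self.n_total for e in self.entries],
                "sequence": [e.sequence for e in self.entries],
                "members": [",".join(e.members) for e in self.entries],
            }
        )


def _compatible(pattern: str, canonical: str) -> bool:
    """True if `pattern` (may contain N) matches `canonical` at non-N sites."""
    return all(
        p == c or p == "N" or c == "N" for p, c in zip(pattern, canonical)
    )


def collapse_haplotypes(
    alignment: Sequence[AlignedSequence],
    gap_mode: GapMode = GapMode.GAP_AS_STATE,
    missing_policy: MissingPolicy = MissingPolicy.WILDCARD,
    label_map: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes.

    Under ``EXCLUDE_GAP_SITES`` every column containing a gap anywhere in
    the alignment is removed before comparison. Under the ``WILDCARD``
    missing policy, a sequence containing ``N`` joins the haplotype it is
    compatible with; if several are compatible it joins the most frequent
    (ties: first occurrence), and if none is, it is flagged and dropped
    with a warning. ``label_map``, keyed by full-length canonical sequence,
    overrides the default ``H1, H2, ...`` descending-count naming (used for
    parity with externally published haplotype labels).
    """
    _validate_alignment(alignment)
    offset = alignment[0].offset
    if gap_mode is GapMode.EXCLUDE_GAP_SITES:
        keep = [
            col
            for col in range(len(alignment[0].bases))
            if not any(s.bases[col] == "-" for s in alignment)
        ]
        keyseqs = ["".join(s.bases[c] for c in keep) for s in alignment]
    else:
        keyseqs = [s.bases for s in alignment]

    # Pass 1: exact classes from unambiguous (N-free) sequences.
    classes: dict[str, list[int]] = {}
    ambiguous: list[int] = []
    for i, key in enumerate(keyseqs):
        if missing_policy is MissingPolicy.WILDCARD and "N" in key:
            ambiguous.append(i)
        else:
            classes.setdefault(key, []).append(i)

    # Pass 2: wildcard assignment of ambiguous sequences.
    dropped: list[str] = []
    order = list(classes)  # first-occurrence order
    for i in ambiguous:
        key = keyseqs[i]
        compat = [k for k in order if _compatible(key, k)]
        if not compat:
            dropped.append(alignment[i].sample_id)
            continue
        best = max(compat, key=lambda k: (len(classes[k]), -order.index(k)))
        classes[best].append(i)
    if dropped:
        warnings.warn(
            f"{len(dropped)} sequence(s) with unresolvable missing data "
            f"dropped from the haplotype table: {dropped}",
            stacklevel=2,
        )

    ranked = sorted(
        classes.items(), key=lambda kv: (-len(kv[1]), min(kv[1]))
    )
    entries = []
    for rank, (key, idxs) in enumerate(ranked, start=1):
        # Canonical sequence: full-length bases of the first N-free member,
        # falling back to the first member.
        rep = next(
            (alignment[i] for i in sorted(idxs) if "N" not in alignment[i].bases),
            alignment[min(idxs)],
        )
        label = f"H{rank}"
        if label_map and rep.bases in label_map:
            label = label_map[rep.bases]
        entries.append(
            HaplotypeEntry(
                haplotype_id=label,
                sequence=rep.bases,
                count=len(idxs),
                members=tuple(alignment[i].sample_id for i in sorted(idxs)),
            )
        )
    return HaplotypeTable(
        entries=tuple(entries),
        n_total=len(alignment) - len(dropped),
        gap_mode=gap_mode,
        offset=offset,
        dropped=tuple(dropped),
    )


def haplotype_relative_frequencies(
    table: HaplotypeTable,
) -> list[tuple[str, float]]:
    """Full-precision relative frequencies; rounding is a report concern."""
    if table.n_total <= 0:
        raise ValueError("n_total must be positive")
    return [(e.haplotype_id, e.count / table.n_total) for e in table.entries]
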