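"""Alignment containers and plumbing for AEP sequence analysis.

The pipeline's substrate is a protein multiple sequence alignment (MSA) of
mature C13-domain asparaginyl endopeptidase (AEP) sequences, optionally
labelled as ligase-type, protease-type or unknown.  This module reads and
writes aligned FASTA, attaches class labels, maps alignment columns onto a
reference sequence's residue numbering (so positions can be reported in,
e.g., "OaAEP1_b numbering"), trims the alignment to a domain, removes
redundant sequences and computes pairwise identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO, Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
VALID_CHARS = frozenset(AMINO_ACIDS + "X" + GAP)

CLASSES = ("ligase", "protease", "unknown")


class MsaError(ValueError):
    """Base error for alignment handling."""


class AlignmentShapeError(MsaError):
    """Rows of an alignment differ in length."""


class AlphabetError(MsaError):
    """A sequence contains a character outside the amino-acid alphabet."""


class MissingIdError(MsaError, KeyError):
    """A referenced sequence id is not present."""


@dataclass(frozen=True)
class Msa:
    """An aligned set of protein sequences with optional class labels.

    Parameters
    ----------
    records : list of (id, aligned_sequence)
        Aligned sequences over the 20 canonical amino acids, ``X`` and the
        gap character ``-``.  Input order is preserved.
    labels : dict, optional
        Map from sequence id to one of ``ligase``/``protease``/``unknown``.
        Ids absent from the map are treated as ``unknown``.
    """

    records: tuple[tuple[str, str], ...]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.records:
            raise MsaError("no records")
        object.__setattr__(self, "records", tuple((i, s) for i, s in self.records))
        width = len(self.records[0][1])
        ids = set()
        for rid, seq in self.records:
            if len(seq) != width:
                raise AlignmentShapeError(
                    f"record {rid!r} has length {len(seq)}, expected {width}"
                )
            if rid in ids:
                raise MsaError(f"duplicate sequence id {rid!r}")
            ids.add(rid)
            for col, ch in enumerate(seq):
                if ch not in VALID_CHARS:
                    raise AlphabetError(
                        f"illegal character {ch!r} in record {rid!r} at column {col}"
                    )
            if set(seq) == {GAP}:
                raise MsaError(f"record {rid!r} is all-gap")
        for rid, cls in self.labels.items():
            if cls not in CLASSES:
                raise MsaError(f"unknown class {cls!r} for id {rid!r}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise MissingIdError(rid)

    def __contains__(self, rid: str) -> bool:
        return any(r == rid for r, _ in self.records)

    def label_of(self, rid: str) -> str:
        return self.labels.get(rid, "unknown")

    def class_ids(self, cls: str) -> list[str]:
        return [rid for rid in self.ids if self.label_of(rid) == cls]


@dataclass(frozen=True)
class ColumnMap:
    """Bidirectional map between alignment columns and reference numbering.

    Columns are 0-based; reference residue numbers are 1-based counts of
    non-gap characters in the reference row (shifted by ``offset`` for
    sequences trimmed mid-protein).  Gap columns of the reference have no
    mapping.
    """

    ref_id: str
    col_to_ref: dict[int, int]
    ref_to_col: dict[int, int]

    def column_for(self, ref_number: int) -> int:
        try:
            return self.ref_to_col[ref_number]
        except KeyError:
            raise MsaError(
                f"reference position {ref_number} not mapped on {self.ref_id!r}"
            ) from None


def read_msa(path, fmt: str = "fasta") -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Residues are uppercased and ``.`` gaps normalised to ``-``.  The id of
    each record is the first whitespace-delimited token of its header.
    """
    if fmt != "fasta":
        raise MsaError(f"unsupported format {fmt!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(".", GAP)
        records.append((rec.id, seq))
    if not records:
        raise MsaError("no records")
    return Msa(tuple(records))


def write_msa(msa: Msa, path, width: int = 60) -> None:
    """Write an :class:`Msa` as aligned FASTA, preserving record order."""
    with open(path, "w") as fh:
        for rid, seq in msa.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_labels(path) -> dict[str, str]:
    """Read a headered TSV with columns ``id`` and ``class``."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            id_i, cls_i = header.index("id"), header.index("class")
        except ValueError:
            raise MsaError("label table must have 'id' and 'class' columns") from None
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rid, cls = parts[id_i], parts[cls_i]
            if rid in labels:
                raise MsaError(f"duplicate label for id {rid!r}")
            labels[rid] = cls
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclass\n")
        for rid, cls in labels.items():
            fh.write(f"{rid}\t{cls}\n")


def attach_labels(msa: Msa, labels: dict[str, str]) -> Msa:
    """Return a copy of ``msa`` carrying class labels.

    Every labelled id must exist in the alignment; unlabelled ids default
    to ``unknown``.
    """
    seen: dict[str, str] = {}
    for rid, cls in labels.items():
        if rid not in msa:
            raise MissingIdError(f"label refers to unknown id {rid!r}")
        if cls not in CLASSES:
            raise MsaError(f"unknown class {cls!r} for id {rid!r}")
        seen[rid] = cls
    return replace(msa, labels=seen)


def reference_numbering(msa: Msa, ref_id: str, offset: int = 1) -> ColumnMap:
    """Number the non-gap columns of a reference row.

    ``offset`` is the residue number assigned to the reference's first
    residue (1 for a full-length mature sequence; higher when the alignment
    was trimmed mid-protein).
    """
    seq = msa[ref_id]  # raises MissingIdError when absent
    col_to_ref: dict[int, int] = {}
    n = offset
    for col, ch in enumerate(seq):
        if ch != GAP:
            col_to_ref[col] = n
            n += 1
    return ColumnMap(ref_id, col_to_ref, {v: k for k, v in col_to_ref.items()})


def trim_to_domain(msa: Msa, start_col: int, end_col: int) -> Msa:
    """Restrict the alignment to columns ``[start_col, end_col]`` inclusive.

    Rows that become all-gap are dropped with a logged warning.
    """
    if not (0 <= start_col <= end_col < msa.n_columns):
        raise MsaError(
            f"bounds [{start_col}, {end_col}] invalid for width {msa.n_columns}"
        )
    kept = []
    for rid, seq in msa.records:
        sub = seq[start_col : end_col + 1]
        if set(sub) == {GAP}:
            logger.warning("dropping %r: all-gap after trimming", rid)
            continue
        kept.append((rid, sub))
    if not kept:
        raise MsaError("trimming removed every sequence")
    ids = {r for r, _ in kept}
    return Msa(tuple(kept), {k: v for k, v in msa.labels.items() if k in ids})


def pairwise_identity(
    a: str, b: str, mode: str = "aligned_columns"
) -> tuple[float, int, int]:
    """Fractional identity between two sequences.

    In ``aligned_columns`` mode the inputs must be equal-length aligned
    rows; in ``global_align`` mode they are first aligned globally
    (Needleman-Wunsch, BLOSUM62, gap open 11 / extend 1).  Only columns
    with a residue in both sequences are compared, so pair-gap columns do
    not dilute the identity and ``identity(a, a) == 1`` for gap-free
    sequences.

    Returns ``(identity, n_identical, n_compared)``.
    """
    if not a or not b:
        raise MsaError("empty sequence")
    if mode == "aligned_columns":
        if len(a) != len(b):
            raise AlignmentShapeError("aligned_columns mode requires equal lengths")
        pairs = zip(a, b)
    elif mode == "global_align":
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        aln = aligner.align(a.replace(GAP, ""), b.replace(GAP, ""))[0]
        pairs = zip(str(aln[0]), str(aln[1]))
    else:
        raise MsaError(f"unknown mode {mode!r}")
    n_identical = n_compared = 0
    for x, y in pairs:
        if x == GAP or y == GAP:
            continue
        n_compared += 1
        if x == y:
            n_identical += 1
    if n_compared == 0:
        raise MsaError("no comparable columns: identity undefined")
    return n_identical / n_compared, n_identical, n_compared


def dedupe_by_identity(msa: Msa, threshold: float = 0.90) -> Msa:
    """Greedy redundancy removal at a pairwise-identity threshold.

    Sequences are considered in input order, labelled (ligase/protease)
    sequences first so that an annotated sequence is always retained in
    preference to a redundant unknown.  A sequence is dropped when its
    identity to any already-retained sequence exceeds ``threshold``.
    """
    if not (0 < threshold <= 1):
        raise MsaError(f"threshold {threshold} outside (0, 1]")
    labelled = [r for r in msa.records if msa.label_of(r[0]) != "unknown"]
    unknown = [r for r in msa.records if msa.label_of(r[0]) == "unknown"]
    retained: list[tuple[str, str]] = []
    for rid, seq in labelled + unknown:
        redundant = False
        for _, kept_seq in retained:
            try:
                ident, _, _ = pairwise_identity(seq, kept_seq)
            except MsaError:  # no shared residue columns: not redundant
                continue
            if ident > threshold:
                redundant = True
                logger.info("dropping %r: >%.0f%% identity", rid, threshold * 100)
                break
        if not redundant:
            retained.append((rid, seq))
    keep_ids = {r for r, _ in retained}
    ordered = tuple(r for r in msa.records if r[0] in keep_ids)
    return Msa(ordered, {k: v for k, v in msa.labels.items() if k in keep_ids})
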