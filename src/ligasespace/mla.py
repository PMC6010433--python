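"""The MLA (marker of ligase activity) diagnostic screen.

Ligase-type plant AEPs carry a distinctive loop — the MLA, His294–His301 in
OaAEP1_b numbering — that is either truncated relative to protease-type
enzymes or unusually hydrophobic; protease-type MLAs are extended,
hydrophilic, and sometimes carry an N-glycosylation sequon that enlarges
the loop.  The screen tags a sequence as a candidate ligase when

  rule 1: its MLA is minimal (truncated) OR has GRAVY > 0.0, and
  rule 2: the MLA contains no N-X-S/T (X != P) glycosylation sequon.

Candidates are additionally annotated with the residue at the "Gatekeeper"
position (homologous to Cys247 of OaAEP1_b) and, when a ligase profile is
supplied, with the ideal-residue match score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .msa import AMINO_ACIDS, GAP, ColumnMap, Msa, MsaError
from .properties import default_property_table
from .sequence_space import LigaseProfile, match_score

logger = logging.getLogger(__name__)

KD = None  # Kyte-Doolittle table, loaded lazily


class MlaError(ValueError):
    pass


def _kd() -> dict[str, float]:
    global KD
    if KD is None:
        KD = dict(default_property_table()["hydropathy"])
    return KD


def gravy(segment: str, skip_unknown: bool = False) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.

    Positive GRAVY indicates net hydrophobicity.  Undefined (error) for an
    empty segment; ``X`` raises unless ``skip_unknown`` is set, in which
    case unknown residues are excluded from the mean.
    """
    table = _kd()
    values = []
    for ch in segment:
        if ch in table:
            values.append(table[ch])
        elif ch == "X" and skip_unknown:
            continue
        else:
            raise MlaError(f"GRAVY undefined for residue {ch!r}")
    if not values:
        raise MlaError("GRAVY undefined for empty segment")
    return sum(values) / len(values)


def find_sequons(segment: str, context_downstream: str = "") -> list[int]:
    """1-based start positions of N-glycosylation sequons in a segment.

    The canonical sequon is N-X-S/T with X != P.  Motifs starting within
    the segment but completing in ``context_downstream`` (up to two
    residues past the segment end) are reported too.
    """
    extended = segment + context_downstream[:2]
    hits = []
    for i in range(len(segment)):
        if extended[i] != "N" or i + 2 >= len(extended):
            continue
        if extended[i + 1] != "P" and extended[i + 2] in ("S", "T"):
            hits.append(i + 1)
    return hits


def is_minimal(segment: str, reference_protease_length: int, delta: int = 3) -> bool:
    """Whether a segment is a truncated ("minimal") MLA.

    True when the segment is at least ``delta`` residues shorter than the
    protease-type reference MLA (known ligase truncations are 4–5 aa, so
    the default deficit of 3 is conservative; closed bound).
    """
    if reference_protease_length < 1:
        raise MlaError("reference protease MLA length must be >= 1")
    return len(segment) <= reference_protease_length - delta


@dataclass(frozen=True)
class MlaRegion:
    """The MLA span expressed in reference numbering.

    ``query_window`` is the 40-residue stretch of the reference sequence
    centered on the MLA, used to map the region onto unaligned sequences;
    ``window_mla_range`` is the (start, end) index range (0-based,
    end-exclusive) of the MLA inside that window.
    """

    ref_id: str
    ref_start: int = 294
    ref_end: int = 301
    query_window: str = ""
    window_mla_range: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.ref_start > self.ref_end:
            raise MlaError("ref_start > ref_end")

    @classmethod
    def from_reference(
        cls,
        msa: Msa,
        colmap: ColumnMap,
        ref_start: int = 294,
        ref_end: int = 301,
        window: int = 40,
    ) -> "MlaRegion":
        """Build the region (and its 40-aa query window) from the aligned
        reference row."""
        ref_seq = msa[colmap.ref_id].replace(GAP, "")
        offset = min(colmap.ref_to_col)  # numbering of the first residue
        start_i = ref_start - offset  # 0-based index into ungapped reference
        end_i = ref_end - offset
        if start_i < 0 or end_i >= len(ref_seq):
            raise MlaError(
                f"MLA span {ref_start}-{ref_end} outside reference "
                f"{colmap.ref_id!r}"
            )
        mla_len = end_i - start_i + 1
        pad = max(0, (window - mla_len) // 2)
        w_start = max(0, start_i - pad)
        w_end = min(len(ref_seq), w_start + window)
        w_start = max(0, w_end - window)  # clip at ends, keep length 40
        if w_end - w_start < window:
            logger.warning("query window clipped to %d residues", w_end - w_start)
        return cls(
            ref_id=colmap.ref_id,
            ref_start=ref_start,
            ref_end=ref_end,
            query_window=ref_seq[w_start:w_end],
            window_mla_range=(start_i - w_start, end_i - w_start + 1),
        )


def mla_columns(colmap: ColumnMap, region: MlaRegion) -> tuple[int, int]:
    """Inclusive alignment-column span of the MLA (insertions included)."""
    return colmap.column_for(region.ref_start), colmap.column_for(region.ref_end)


def locate_mla(msa: Msa, colmap: ColumnMap, region: MlaRegion) -> dict[str, str]:
    """Per-sequence ungapped MLA segment from the aligned columns.

    The span runs from the column of ``ref_start`` to the column of
    ``ref_end`` inclusive, including any insertion columns in between, so
    insertions lengthen a segment and deletions shorten it (possibly to an
    empty string).
    """
    c0, c1 = mla_columns(colmap, region)
    return {rid: seq[c0 : c1 + 1].replace(GAP, "") for rid, seq in msa.records}


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


#: minimum Smith-Waterman score (BLOSUM62, 11/1) for a confident mapping of
#: the 40-aa window; ~45 corresponds to ~15 identities, far above chance
#: for a 40-mer query.
MIN_MAPPING_SCORE = 45.0


def map_mla_unaligned(
    seq: str, region: MlaRegion, min_score: float = MIN_MAPPING_SCORE
) -> str | None:
    """Map the MLA onto an unaligned protein via the 40-aa query window.

    Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1) of
    the reference window against ``seq``; the residues aligned to the
    window's MLA positions form the segment.  Returns ``None`` when no
    alignment reaches ``min_score`` (no confident mapping).
    """
    seq = seq.replace(GAP, "").upper()
    if len(seq) < 20:
        raise MlaError("sequence too short to map (<20 residues)")
    if not region.query_window:
        raise MlaError("region has no query window; build with from_reference")
    aligner = _local_aligner()
    alignments = aligner.align(region.query_window, seq)
    if len(alignments) == 0 or alignments[0].score < min_score:
        return None
    aln = alignments[0]
    m0, m1 = region.window_mla_range
    segment = []
    for (q0, q1), (t0, t1) in zip(*aln.aligned):
        for qi, ti in zip(range(q0, q1), range(t0, t1)):
            if m0 <= qi < m1:
                segment.append(seq[ti])
    return "".join(segment)


def gatekeeper(aligned_seq: str, colmap: ColumnMap, ref_number: int = 247) -> str:
    """Residue homologous to the reference Gatekeeper position (Cys247 of
    OaAEP1_b); ``-`` when deleted."""
    return aligned_seq[colmap.column_for(ref_number)]


@dataclass(frozen=True)
class MlaReport:
    """Per-sequence outcome of the MLA screen."""

    id: str
    mla_segment: str
    length: int
    gravy: float | None  # None for an empty segment
    sequons: tuple[int, ...]  # 1-based within the segment
    is_minimal: bool
    rule1: bool  # minimal MLA or GRAVY > 0.0
    rule2: bool  # no glycosylation sequon
    candidate: bool  # rule1 AND rule2
    gatekeeper: str | None = None
    match_score: float | None = None
    sw_params: str = "BLOSUM62 open=11 extend=1"

    TSV_HEADER = (
        "id\tsegment\tlength\tgravy\tsequons\tis_minimal\trule1\trule2\t"
        "candidate\tgatekeeper\tmatch_score"
    )

    def as_tsv_row(self) -> str:
        fmt = lambda v: "" if v is None else (f"{v:.4f}" if isinstance(v, float) else str(v))
        return "\t".join([
            self.id, self.mla_segment, str(self.length), fmt(self.gravy),
            ",".join(map(str, self.sequons)), str(self.is_minimal),
            str(self.rule1), str(self.rule2), str(self.candidate),
            fmt(self.gatekeeper), fmt(self.match_score),
        ])

    def as_dict(self) -> dict:
        return {
            "id": self.id, "segment": self.mla_segment, "length": self.length,
            "gravy": self.gravy, "sequons": list(self.sequons),
            "is_minimal": self.is_minimal, "rule1": self.rule1,
            "rule2": self.rule2, "candidate": self.candidate,
            "gatekeeper": self.gatekeeper, "match_score": self.match_score,
            "sw_params": self.sw_params,
        }


def _report_for_segment(
    rid: str,
    segment: str,
    context: str,
    reference_protease_length: int,
    delta: int,
    gk: str | None,
    score: float | None,
) -> MlaReport:
    minimal = is_minimal(segment, reference_protease_length, delta)
    g = gravy(segment, skip_unknown=True) if any(c in AMINO_ACIDS for c in segment) else None
    sequons = tuple(find_sequons(segment, context))
    rule1 = minimal or (g is not None and g > 0.0)
    rule2 = len(sequons) == 0
    return MlaReport(
        id=rid, mla_segment=segment, length=len(segment), gravy=g,
        sequons=sequons, is_minimal=minimal, rule1=rule1, rule2=rule2,
        candidate=rule1 and rule2, gatekeeper=gk, match_score=score,
    )


def screen(
    msa: Msa,
    colmap: ColumnMap,
    region: MlaRegion,
    profile: LigaseProfile | None = None,
    reference_protease_length: int | None = None,
    delta: int = 3,
    gatekeeper_ref: int | None = 247,
) -> list[MlaReport]:
    """Run the two-rule MLA screen over every sequence of an alignment.

    ``reference_protease_length`` anchors the minimality test; when not
    given it defaults to the longest MLA segment among protease-labelled
    sequences, falling back to the longest segment overall (the extended,
    protease-type form of the loop).
    """
    segments = locate_mla(msa, colmap, region)
    _, c1 = mla_columns(colmap, region)
    if reference_protease_length is None:
        pro = [segments[r] for r in msa.class_ids("protease")]
        pool = pro if pro else list(segments.values())
        reference_protease_length = max(len(s) for s in pool)
        if reference_protease_length < 1:
            raise MlaError("cannot infer reference protease MLA length")
    reports = []
    for rid, seq in msa.records:
        context = seq[c1 + 1 :].replace(GAP, "")[:2]
        gk = gatekeeper(seq, colmap, gatekeeper_ref) if gatekeeper_ref else None
        score = match_score(seq, profile, rid).score if profile is not None else None
        reports.append(
            _report_for_segment(
                rid, segments[rid], context, reference_protease_length, delta, gk, score
            )
        )
    return reports


def screen_unaligned(
    sequences: list[tuple[str, str]],
    region: MlaRegion,
    reference_protease_length: int,
    delta: int = 3,
    min_score: float = MIN_MAPPING_SCORE,
) -> list[MlaReport | None]:
    """MLA screen for unaligned proteins via window mapping.

    Entries that cannot be confidently mapped yield ``None`` (reported,
    not raised).  Gatekeeper and match score require an alignment and are
    not annotated here.
    """
    out: list[MlaReport | None] = []
    for rid, seq in sequences:
        segment = map_mla_unaligned(seq, region, min_score=min_score)
        if segment is None:
            logger.warning("no confident MLA mapping for %r", rid)
            out.append(None)
            continue
        out.append(
            _report_for_segment(rid, segment, "", reference_protease_length, delta, None, None)
        )
    return out


def write_report_tsv(reports: list[MlaReport], path) -> None:
    with open(path, "w") as fh:
        fh.write(MlaReport.TSV_HEADER + "\n")
        for rep in reports:
            fh.write(rep.as_tsv_row() + "\n")
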