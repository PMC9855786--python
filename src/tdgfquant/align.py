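"""Six-frame translated local alignment of marker proteins against contigs.

The search core: each nucleotide contig is translated in all six reading
frames (bacterial code, table 11), frames are split at stop codons, and the
marker protein is locally aligned (Smith-Waterman, affine gaps) against every
stop-free segment.  The best score over frames and segments is the contig's
score for that marker, and hits below a raw-score threshold (default 250)
are discarded before any abundance is summed.

Scoring convention: raw Smith-Waterman score, BLOSUM62, gap open 11 /
gap extend 1, where a gap of length L costs ``open + (L-1)*extend``.
A stop codon terminates every alignment: frames are segmented at ``*`` and
no alignment, match or gap, may span a segment boundary.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "HitSet",
    "read_fasta",
    "reverse_complement",
    "six_frame_translate",
    "local_align",
    "search_tdgfs",
    "filter_hits",
    "DEFAULT_SCORE_THRESHOLD",
]

#: Raw-score cutoff below which a contig is not considered to carry a marker.
DEFAULT_SCORE_THRESHOLD = 250.0

#: Frame precedence for tie-breaking: forward frames before reverse,
#: lower offset first.
FRAME_ORDER = (1, 2, 3, -1, -2, -3)

_NT_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Bacterial/archaeal genetic code; differs from the standard table only in
# start codons, which are irrelevant to frame translation.
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
_CODON_TO_AA = dict(_CODON_TABLE.forward_table)
for _stop in _CODON_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"


@functools.lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` is the cost of the first gapped position and ``gap_extend``
    the cost of each further position, so a gap of length L costs
    ``gap_open + (L-1)*gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError(
                f"require gap_open >= gap_extend >= 1, "
                f"got open={self.gap_open} extend={self.gap_extend}"
            )
        self.substitution_matrix  # fail early on unknown matrix name

    @property
    def substitution_matrix(self):
        return _load_matrix(self.matrix_name)

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.substitution_matrix
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of one marker against one contig.

    Spans are 1-based inclusive in protein space; the subject span refers to
    the coordinates of the translated frame (not the nucleotide contig).
    """

    tdgf_id: str
    contig_id: str
    frame: int
    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.frame not in FRAME_ORDER:
            raise ValueError(f"frame must be one of {FRAME_ORDER}, got {self.frame}")
        if self.score < 0:
            raise ValueError("alignment score must be non-negative")


@dataclass
class HitSet:
    """Best hit per (marker, contig) pair, sorted by descending score."""

    hits: list[AlignmentHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(h.tdgf_id, h.contig_id) for h in self.hits]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (tdgf_id, contig_id) pair in HitSet")
        self.hits.sort(key=lambda h: (-h.score, h.tdgf_id, h.contig_id))

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def best_scores(self) -> dict[tuple[str, str], float]:
        return {(h.tdgf_id, h.contig_id): h.score for h in self.hits}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    The record id is the first whitespace-delimited token of the header.
    Raises on duplicate ids and on empty files.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def reverse_complement(nt_seq: str) -> str:
    return nt_seq.upper().translate(_COMPLEMENT)[::-1]


def _check_nucleotide(nt_seq: str, name: str = "sequence") -> str:
    seq = nt_seq.upper()
    bad = [(i, c) for i, c in enumerate(seq) if c not in _NT_ALPHABET]
    if bad:
        shown = ", ".join(f"{c!r}@{i}" for i, c in bad[:10])
        raise ValueError(
            f"{name} contains non-nucleotide characters (position, char): {shown}"
        )
    return seq


def _translate_frame(nt_seq: str) -> str:
    """Translate one frame; codons containing N become X, stops become ``*``."""
    aa = []
    for i in range(0, len(nt_seq) - 2, 3):
        codon = nt_seq[i : i + 3]
        aa.append("X" if "N" in codon else _CODON_TO_AA[codon])
    return "".join(aa)


def six_frame_translate(nt_seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1..+3 read the forward strand from offsets 0..2; frames -1..-3
    read the reverse complement from offsets 0..2.  Trailing partial codons
    are dropped.
    """
    seq = _check_nucleotide(nt_seq)
    rc = reverse_complement(seq)
    return {
        1: _translate_frame(seq),
        2: _translate_frame(seq[1:]),
        3: _translate_frame(seq[2:]),
        -1: _translate_frame(rc),
        -2: _translate_frame(rc[1:]),
        -3: _translate_frame(rc[2:]),
    }


def _check_protein(aa_seq: str, name: str = "protein") -> str:
    seq = aa_seq.upper()
    bad = sorted(set(seq) - _AA_ALPHABET)
    if bad:
        raise ValueError(f"{name} contains non-amino-acid characters: {bad}")
    return seq


def local_align(
    query: str, target: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[float, tuple[int, int] | None, tuple[int, int] | None]:
    """Optimal local alignment of two protein sequences.

    Returns ``(score, query_span, subject_span)`` with 1-based inclusive
    spans, or ``(0.0, None, None)`` when no positive-scoring alignment
    exists.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    aligner = scheme.make_aligner()
    score = float(aligner.score(query, target))
    if score <= 0:
        return 0.0, None, None
    aln = aligner.align(query, target)[0]
    q_blocks, t_blocks = aln.aligned
    q_span = (int(q_blocks[0][0]) + 1, int(q_blocks[-1][1]))
    t_span = (int(t_blocks[0][0]) + 1, int(t_blocks[-1][1]))
    return score, q_span, t_span


def _segments(frame_aa: str) -> Iterable[tuple[int, str]]:
    """Stop-free segments of a translated frame with their 0-based offsets."""
    offset = 0
    for seg in frame_aa.split("*"):
        if seg:
            yield offset, seg
        offset += len(seg) + 1


def best_frame_hit(
    query: str, nt_seq: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[float, int | None, tuple[int, int] | None, tuple[int, int] | None]:
    """Best translated local alignment of a protein query against a contig.

    Scans the six frames in :data:`FRAME_ORDER`, aligning against each
    stop-free segment; ties keep the earliest frame and segment.  Returns
    ``(score, frame, query_span, subject_span)``; frame and spans are None
    when the best score is 0.
    """
    aligner = scheme.make_aligner()
    frames = six_frame_translate(nt_seq)
    best_score = 0.0
    best_loc: tuple[int, int, str] | None = None  # (frame, offset, segment)
    for frame in FRAME_ORDER:
        for offset, seg in _segments(frames[frame]):
            s = float(aligner.score(query, seg))
            if s > best_score:
                best_score = s
                best_loc = (frame, offset, seg)
    if best_loc is None:
        return 0.0, None, None, None
    frame, offset, seg = best_loc
    aln = aligner.align(query, seg)[0]
    q_blocks, t_blocks = aln.aligned
    q_span = (int(q_blocks[0][0]) + 1, int(q_blocks[-1][1]))
    s_span = (offset + int(t_blocks[0][0]) + 1, offset + int(t_blocks[-1][1]))
    return best_score, frame, q_span, s_span


def search_tdgfs(
    catalog,
    contigs: Mapping[str, str] | str | Path,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    tdgf_ids: Iterable[str] | None = None,
) -> HitSet:
    """Align every marker protein against every contig; keep best hits.

    ``contigs`` is an ``{id: nucleotide sequence}`` mapping or a FASTA path.
    Hits with score 0 are omitted.  Deterministic given identical inputs.
    """
    if isinstance(contigs, (str, Path)):
        contigs = read_fasta(contigs)
    if not contigs:
        raise ValueError("contig set is empty")
    ids = list(contigs)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate contig ids")
    if tdgf_ids is None:
        tdgf_ids = list(catalog.tdgfs)
    hits: list[AlignmentHit] = []
    for tdgf_id in tdgf_ids:
        query = catalog.tdgfs[tdgf_id].protein_seq
        for contig_id in sorted(contigs):
            score, frame, q_span, s_span = best_frame_hit(
                query, contigs[contig_id], scheme
            )
            if score > 0:
                hits.append(
                    AlignmentHit(
                        tdgf_id=tdgf_id,
                        contig_id=contig_id,
                        frame=frame,
                        score=score,
                        query_span=q_span,
                        subject_span=s_span,
                    )
                )
    return HitSet(hits)


def filter_hits(
    hits: HitSet, threshold: float = DEFAULT_SCORE_THRESHOLD
) -> dict[str, set[str]]:
    """Contigs retained per marker: best score >= threshold.

    The boundary is inclusive — contigs scoring exactly the threshold are
    kept; only strictly lower scores are excluded.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    retained: dict[str, set[str]] = {}
    for hit in hits:
        if hit.score >= threshold:
            retained.setdefault(hit.tdgf_id, set()).add(hit.contig_id)
    return retained
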