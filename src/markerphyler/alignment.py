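"""Translated local alignment and BLAST-style hits.

Queries are DNA reads; references are marker-gene proteins.  Reads are
translated in all six frames, frames are split into stop-free peptide
segments, and each segment is aligned locally (Smith-Waterman with affine
gaps, BLOSUM62 by default) against every reference protein.  Scores are
reported as bit scores

    S' = (lambda * S - ln K) / ln 2

with S the raw (matrix-sum) score and lambda, K the Karlin-Altschul
parameters of the scoring system, so scores are comparable across genes and
lengths.  Externally computed BLAST tabular (12-column outfmt 6) files can be
parsed instead of running the built-in aligner; their bit scores are used
as-is.

Bulk scoring runs through a numba kernel (score only); full alignments with
coordinates are computed only for hits that pass the reporting threshold,
via Biopython's PairwiseAligner under the identical scoring scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .refdb import MarkerDB, SimulatedRead

_LN2 = math.log(2.0)

#: Segments shorter than this (aa) cannot form a meaningful HSP and are skipped.
MIN_SEGMENT_AA = 8

# large negative sentinel, safely inside int32 under repeated gap extension
NEG_INF = -(10**6)


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scoring parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix, affine gap costs and Karlin-Altschul lambda/K.

    A gap of length k costs ``gap_open + k * gap_extend`` (both negative).
    Defaults correspond to BLASTX conventions: BLOSUM62 with gap open -11 /
    extend -1 and the matching gapped constants lambda = 0.267, K = 0.041.
    """

    matrix: dict = field(repr=False)
    alphabet: str
    gap_open: int = -11
    gap_extend: int = -1
    lambda_: float = 0.267
    K: float = 0.041
    matrix_name: str = "BLOSUM62"

    def __post_init__(self):
        if self.lambda_ <= 0 or self.K <= 0:
            raise AlignmentError("lambda and K must be positive")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise AlignmentError("gap penalties must be negative")
        for (a, b), s in self.matrix.items():
            if self.matrix.get((b, a)) != s:
                raise AlignmentError(f"matrix not symmetric at ({a},{b})")
        std = [c for c in "ARNDCQEGHILKMFPSTWYV"]
        exp = sum(self.matrix[(a, b)] for a in std for b in std) / (len(std) ** 2)
        if exp >= 0:
            raise AlignmentError("expected matrix score under background must be < 0")

    @property
    def as_array(self) -> np.ndarray:
        arr = np.full((len(self.alphabet), len(self.alphabet)), -4, dtype=np.int64)
        idx = {c: i for i, c in enumerate(self.alphabet)}
        for (a, b), s in self.matrix.items():
            arr[idx[a], idx[b]] = s
        return arr

    def encode(self, peptide: str) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.alphabet)}
        x = idx.get("X", 0)
        return np.array([idx.get(c, x) for c in peptide], dtype=np.uint8)

    def to_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        m = substitution_matrices.Array(alphabet=self.alphabet, dims=2)
        for (a, b), s in self.matrix.items():
            m[a, b] = s
        aligner.substitution_matrix = m
        # PairwiseAligner charges open on the first gap residue
        aligner.open_gap_score = self.gap_open + self.gap_extend
        aligner.extend_gap_score = self.gap_extend
        return aligner


def default_params() -> ScoringParams:
    m = substitution_matrices.load("BLOSUM62")
    alphabet = str(m.alphabet)
    matrix = {
        (a, b): int(m[a, b]) for a in alphabet for b in alphabet
    }
    return ScoringParams(matrix=matrix, alphabet=alphabet)


def write_params(params: ScoringParams, path) -> None:
    """Key-value text file with the matrix inline."""
    with open(path, "wt") as fh:
        fh.write(f"lambda\t{params.lambda_!r}\n")
        fh.write(f"K\t{params.K!r}\n")
        fh.write(f"gap_open\t{params.gap_open}\n")
        fh.write(f"gap_extend\t{params.gap_extend}\n")
        fh.write(f"matrix_name\t{params.matrix_name}\n")
        fh.write(f"alphabet\t{params.alphabet}\n")
        fh.write("matrix\n")
        for a in params.alphabet:
            row = " ".join(str(params.matrix[(a, b)]) for b in params.alphabet)
            fh.write(f"{a} {row}\n")


def read_params(path) -> ScoringParams:
    kv: dict[str, str] = {}
    matrix: dict[tuple[str, str], int] = {}
    with open(path, "rt") as fh:
        in_matrix = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.strip() == "matrix":
                in_matrix = True
                continue
            if in_matrix:
                parts = line.split()
                a, scores = parts[0], parts[1:]
                for b, s in zip(kv["alphabet"], scores):
                    matrix[(a, b)] = int(s)
            else:
                key, value = line.split("\t", 1)
                kv[key] = value
    return ScoringParams(
        matrix=matrix,
        alphabet=kv["alphabet"],
        gap_open=int(kv["gap_open"]),
        gap_extend=int(kv["gap_extend"]),
        lambda_=float(kv["lambda"]),
        K=float(kv["K"]),
        matrix_name=kv.get("matrix_name", "custom"),
    )


def bit_score(raw_score: float, params: ScoringParams) -> float:
    """Karlin-Altschul normalisation: (lambda*S - ln K) / ln 2."""
    return (params.lambda_ * raw_score - math.log(params.K)) / _LN2


# ---------------------------------------------------------------------------
# Smith-Waterman kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_batch(qcat, qoff, ST, mat_ext, go, ge, out):  # pragma: no cover - numba
    """Local affine-gap DP of every query against all subjects in lockstep.

    ``ST`` is the (max_len, n_subjects) transposed, padded subject code
    matrix; the pad code rows of ``mat_ext`` are strongly negative so padding
    can never extend an alignment.  The subject axis is contiguous and the
    inner loops are branch-free, so they vectorise.
    """
    M, G = ST.shape
    goe = go + ge
    H = np.empty((M + 1, G), dtype=np.int32)
    F = np.empty((M + 1, G), dtype=np.int32)
    E = np.empty(G, dtype=np.int32)
    diag = np.empty(G, dtype=np.int32)
    prof = np.empty((M, G), dtype=np.int32)
    for qi in range(len(qoff) - 1):
        q = qcat[qoff[qi] : qoff[qi + 1]]
        for j in range(M + 1):
            for g in range(G):
                H[j, g] = 0
                F[j, g] = NEG_INF
        for g in range(G):
            out[qi, g] = 0
        for i in range(len(q)):
            row = mat_ext[q[i]]
            for j in range(M):
                for g in range(G):
                    prof[j, g] = row[ST[j, g]]
            for g in range(G):
                diag[g] = 0
                E[g] = NEG_INF
            for j in range(1, M + 1):
                for g in range(G):
                    e = max(H[j - 1, g] + goe, E[g] + ge)
                    E[g] = e
                    hj = H[j, g]
                    f = max(hj + goe, F[j, g] + ge)
                    F[j, g] = f
                    h = max(max(diag[g] + prof[j - 1, g], e), max(f, 0))
                    diag[g] = hj
                    H[j, g] = h
                    out[qi, g] = max(out[qi, g], h)


def local_align_protein(
    query_pep: str, subject_pep: str, params: ScoringParams | None = None
) -> tuple[int, tuple[int, int]]:
    """Optimal gapped local alignment score and matched subject interval.

    Returns ``(raw_score, (s_start, s_end))`` with a half-open, 0-based
    subject interval; a non-positive optimum yields score 0 and an empty span.
    """
    if not query_pep or not subject_pep:
        raise AlignmentError("peptides must be non-empty")
    params = params or default_params()
    for pep in (query_pep, subject_pep):
        bad = set(pep) - set(params.alphabet)
        if bad:
            raise AlignmentError(f"invalid residue characters {sorted(bad)}")
    aligner = params.to_aligner()
    score = int(aligner.score(query_pep, subject_pep))
    if score <= 0:
        return 0, (0, 0)
    aln = aligner.align(query_pep, subject_pep)[0]
    s_blocks = aln.aligned[1]
    return score, (int(s_blocks[0][0]), int(s_blocks[-1][1]))


# ---------------------------------------------------------------------------
# hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    gene_id: str
    bit_score: float
    hsp_length: int
    identity_pct: float = 100.0
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    frame: int = 1
    raw_score: int | None = None
    evalue: float | None = None

    def __post_init__(self):
        if self.hsp_length < 1:
            raise AlignmentError(f"{self.query_id}: hsp_length must be >= 1")


def best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """Maximal bit score; ties to longer HSP, then smallest gene_id.

    Independent of input order.
    """
    if not hits:
        raise AlignmentError("best_hit of an empty hit list")
    return min(
        hits,
        key=lambda h: (-h.bit_score, -h.hsp_length, h.gene_id, h.frame, h.q_start),
    )


_BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def parse_blast_tabular(path_or_handle) -> list[AlignmentHit]:
    """Parse 12-column BLAST outfmt-6; bit score is used as-is."""
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle, "rt") as fh:
            lines = fh.read().splitlines()
    hits = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise AlignmentError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    gene_id=fields[1],
                    identity_pct=float(fields[2]),
                    hsp_length=int(fields[3]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise AlignmentError(f"line {lineno}: {exc}") from None
    return hits


def write_blast_tabular(hits: Iterable[AlignmentHit], path_or_handle) -> None:
    if hasattr(path_or_handle, "write"):
        fh = path_or_handle
        close = False
    else:
        fh = open(path_or_handle, "wt")
        close = True
    try:
        for h in hits:
            mismatches = int(round(h.hsp_length * (1 - h.identity_pct / 100.0)))
            fh.write(
                f"{h.query_id}\t{h.gene_id}\t{h.identity_pct:g}\t{h.hsp_length}\t"
                f"{mismatches}\t0\t{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.evalue if h.evalue is not None else 0:g}\t{h.bit_score:g}\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# six-frame translated search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    read_idx: int
    frame: int  # 1..3, -1..-3
    aa_offset: int  # segment start within the frame's peptide, aa
    peptide: str
    read_len: int


def _normalize_reads(reads) -> list[tuple[str, str]]:
    out = []
    for r in reads:
        if isinstance(r, SimulatedRead):
            out.append((r.read_id, r.sequence))
        elif isinstance(r, tuple):
            out.append((r[0], str(r[1])))
        else:  # SeqRecord
            out.append((r.id, str(r.seq)))
    return out


def six_frame_segments(
    read_idx: int, sequence: str, min_segment_aa: int = MIN_SEGMENT_AA
) -> list[_Segment]:
    """Stop-free peptide segments of all six reading frames."""
    segs: list[_Segment] = []
    seq = Seq(sequence)
    rc = seq.reverse_complement()
    n = len(sequence)
    for strand, s in ((1, seq), (-1, rc)):
        for off in range(3):
            sub = s[off : off + 3 * ((n - off) // 3)]
            if len(sub) < 3:
                continue
            pep = str(sub.translate())
            frame = strand * (off + 1)
            start = 0
            for part in pep.split("*"):
                if len(part) >= min_segment_aa:
                    segs.append(_Segment(read_idx, frame, start, part, n))
                start += len(part) + 1
    return segs


def _segment_query_span(seg: _Segment, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map an aa interval of the segment to 1-based nt read coordinates.

    Minus-frame spans are reported with q_start > q_end (BLAST convention).
    """
    off = abs(seg.frame) - 1
    a = off + 3 * (seg.aa_offset + aa_start)  # 0-based nt in the read frame
    b = off + 3 * (seg.aa_offset + aa_end) - 1
    if seg.frame > 0:
        return a + 1, b + 1
    return seg.read_len - a, seg.read_len - b


class TranslatedSearch:
    """Scores translated reads against a MarkerDB's protein set.

    Builds the six-frame segment table once, then fills a (segments x genes)
    raw-score matrix with the numba kernel.  Full alignments are only traced
    back for hits at or above the reporting threshold.
    """

    def __init__(self, reads, db: MarkerDB, params: ScoringParams | None = None,
                 min_segment_aa: int = MIN_SEGMENT_AA):
        self.params = params or default_params()
        self.db = db
        self.read_ids = [rid for rid, _ in _normalize_reads(reads)]
        pairs = _normalize_reads(reads)
        if not pairs:
            raise AlignmentError("empty read set")
        self.segments: list[_Segment] = []
        for i, (_, seq) in enumerate(pairs):
            self.segments.extend(six_frame_segments(i, seq, min_segment_aa))
        self.gene_ids = [r.gene_id for r in db.records]
        self._raw = self._fill_scores()

    def _fill_scores(self) -> np.ndarray:
        p = self.params
        genes = [p.encode(r.protein) for r in self.db.records]
        out = np.zeros((len(self.segments), len(genes)), dtype=np.int32)
        if not self.segments or not genes:
            return out
        # substitution matrix with an extra pad column that never matches
        A = len(p.alphabet)
        mat_ext = np.full((A, A + 1), NEG_INF, dtype=np.int32)
        mat_ext[:, :A] = p.as_array
        max_len = max(len(g) for g in genes)
        ST = np.full((max_len, len(genes)), A, dtype=np.uint8)
        for gi, g in enumerate(genes):
            ST[: len(g), gi] = g
        qenc = [p.encode(s.peptide) for s in self.segments]
        qcat = np.concatenate(qenc)
        qoff = np.zeros(len(qenc) + 1, dtype=np.int64)
        np.cumsum([len(q) for q in qenc], out=qoff[1:])
        _sw_batch(qcat, qoff, ST, mat_ext, p.gap_open, p.gap_extend, out)
        return out

    @property
    def bits(self) -> np.ndarray:
        """Bit scores, (segments x genes); raw score 0 maps to -inf (no hit)."""
        b = (self.params.lambda_ * self._raw - math.log(self.params.K)) / _LN2
        b[self._raw <= 0] = -np.inf
        return b

    @property
    def segment_read_idx(self) -> np.ndarray:
        return np.array([s.read_idx for s in self.segments], dtype=np.int64)

    def traceback(self, seg_idx: int, gene_idx: int) -> AlignmentHit:
        """Full alignment of one (segment, gene) pair."""
        seg = self.segments[seg_idx]
        gene = self.db.records[gene_idx]
        aligner = self.params.to_aligner()
        aln = aligner.align(seg.peptide, gene.protein)[0]
        raw = int(self._raw[seg_idx, gene_idx])
        counts = aln.counts()
        length = int(aln.length)
        q_blocks, s_blocks = aln.aligned
        qs, qe = _segment_query_span(seg, int(q_blocks[0][0]), int(q_blocks[-1][1]))
        return AlignmentHit(
            query_id=self.read_ids[seg.read_idx],
            gene_id=gene.gene_id,
            bit_score=bit_score(raw, self.params),
            hsp_length=length,
            identity_pct=100.0 * counts.identities / length,
            q_start=qs,
            q_end=qe,
            s_start=int(s_blocks[0][0]) + 1,
            s_end=int(s_blocks[-1][1]),
            frame=seg.frame,
            raw_score=raw,
        )

    def hits(self, min_bits: float = 0.0) -> list[AlignmentHit]:
        """All (segment, gene) hits with bit score >= min_bits and raw > 0."""
        bits = self.bits
        out = []
        for seg_idx, gene_idx in zip(*np.nonzero(bits >= max(min_bits, -np.inf))):
            if self._raw[seg_idx, gene_idx] > 0:
                out.append(self.traceback(int(seg_idx), int(gene_idx)))
        return out

    def best_hits(self, min_bits: float = 0.0) -> dict[str, AlignmentHit | None]:
        """Best hit per read (bit, then HSP length, then gene id), or None.

        Only the winning pairs are traced back, so this is the fast path for
        classification.
        """
        bits = self.bits
        result: dict[str, AlignmentHit | None] = {rid: None for rid in self.read_ids}
        if bits.size == 0:
            return result
        rows_by_read: dict[int, list[int]] = {}
        for seg_idx, seg in enumerate(self.segments):
            rows_by_read.setdefault(seg.read_idx, []).append(seg_idx)
        for read_idx, read_id in enumerate(self.read_ids):
            rows = np.array(rows_by_read.get(read_idx, []), dtype=np.int64)
            if rows.size == 0:
                continue
            sub = bits[rows]
            top = sub.max()
            if not np.isfinite(top) or top < min_bits:
                continue
            cand = [
                self.traceback(int(rows[i]), int(g))
                for i, g in zip(*np.nonzero(sub == top))
            ]
            result[read_id] = best_hit(cand)
        return result


def search_translated(
    reads, db: MarkerDB, params: ScoringParams | None = None, min_bits: float = 0.0
) -> list[AlignmentHit]:
    """Six-frame translated search of DNA reads against reference proteins."""
    return TranslatedSearch(reads, db, params).hits(min_bits)
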