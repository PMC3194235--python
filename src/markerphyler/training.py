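"""Learning per-gene, per-rank, per-length bit-score cutoffs.

For each reference gene G, each classification rank r and each simulated read
length L, the bit scores of simulated reads aligned against G are split into
two vectors: B_level (reads whose source organism is in the same rank-r clade
as G, excluding reads simulated from G itself) and B_else (every other read,
including the negative set of non-marker reads).  The cutoff b_cut is the
threshold minimising the misclassification count

    err(b) = |{s in B_level : s < b}| + |{s in B_else : s >= b}|

with ties broken towards the largest minimiser — the stringent choice that
refuses a specific label when the evidence is ambiguous.  Because bit scores
of gene fragments grow linearly with HSP length, the per-length cutoffs are
summarised by an ordinary least-squares regression of b_cut on length, which
supplies cutoffs for arbitrary matching lengths at classification time.

Lengths are handled in amino acids for the regression (read length in nt / 3)
so that training and classification use a single unit, matching the
amino-acid HSP lengths a translated search reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import ScoringParams, TranslatedSearch, default_params
from .refdb import (
    MarkerDB,
    MarkerGeneRecord,
    simulate_negative_reads,
    simulate_reads,
)
from .taxonomy import RANKS, TaxonomyTree, same_clade


class TrainingError(ValueError):
    pass


class GeneRankUnresolved(TrainingError):
    """The gene's lineage lacks the requested rank; it cannot be trained there."""


@dataclass
class ScorePartition:
    gene_id: str
    rank: str
    length_nt: int
    b_level: list[float]
    b_else: list[float]


@dataclass(frozen=True)
class LengthCutoff:
    gene_id: str
    rank: str
    length_nt: int
    b_cut: float
    error_count: int


@dataclass(frozen=True)
class CutoffRegression:
    """b_cut as a linear function of HSP length (amino acids), clamped at 0."""

    gene_id: str
    rank: str
    slope: float
    intercept: float
    n_points: int
    min_length_nt: int
    max_length_nt: int

    def predict(self, hsp_length_aa: float) -> float:
        return max(0.0, self.slope * hsp_length_aa + self.intercept)

    def in_support(self, hsp_length_aa: float) -> bool:
        return self.min_length_nt / 3 <= hsp_length_aa <= self.max_length_nt / 3


def partition_scores(
    gene: MarkerGeneRecord,
    hits: Iterable,
    truth: Mapping[str, tuple[str | None, str | None]] | None,
    rank: str,
    taxonomy: TaxonomyTree,
    length_nt: int = 0,
) -> ScorePartition:
    """Split bit scores of reads-vs-gene hits into B_level and B_else.

    ``truth`` maps read id -> (true taxid or None, source gene id or None);
    negative reads map to (None, None).  Reads simulated from the gene itself
    are excluded from both vectors (leave-self-out).  Raises
    :class:`GeneRankUnresolved` when the gene's lineage lacks ``rank``.
    """
    gene_lineage = taxonomy.lineage_of(gene.taxid)
    if gene_lineage.get(rank) is None:
        raise GeneRankUnresolved(f"{gene.gene_id}: no {rank} in lineage")
    b_level: list[float] = []
    b_else: list[float] = []
    for hit in hits:
        read_id, score = hit.query_id, hit.bit_score
        true_taxid, true_gene = (None, None) if truth is None else truth.get(
            read_id, (None, None)
        )
        if true_gene == gene.gene_id:
            continue
        if true_taxid is not None and same_clade(
            taxonomy.lineage_of(true_taxid), gene_lineage, rank
        ):
            b_level.append(score)
        else:
            b_else.append(score)
    return ScorePartition(gene.gene_id, rank, length_nt, b_level, b_else)


def find_cutoff(partition: ScorePartition) -> LengthCutoff:
    """Error-minimising threshold over candidate cutoffs.

    Candidates are the observed scores plus a sentinel one unit above the
    maximum (err is a step function that only changes at observed scores).
    Among minimisers the largest candidate wins: the most stringent cutoff.
    """
    level = np.asarray(partition.b_level, dtype=float)
    other = np.asarray(partition.b_else, dtype=float)
    if level.size == 0 and other.size == 0:
        raise TrainingError(
            f"{partition.gene_id}/{partition.rank}: both score vectors empty"
        )
    scores = np.concatenate([level, other])
    candidates = np.unique(scores)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    # err(b) = #(level < b) + #(else >= b), vectorised over candidates
    level_sorted = np.sort(level)
    other_sorted = np.sort(other)
    below = np.searchsorted(level_sorted, candidates, side="left")
    at_or_above = other.size - np.searchsorted(other_sorted, candidates, side="left")
    err = below + at_or_above
    best = err.min()
    b_cut = float(candidates[np.nonzero(err == best)[0][-1]])
    return LengthCutoff(
        partition.gene_id, partition.rank, partition.length_nt, b_cut, int(best)
    )


def fit_cutoff_regression(points: Sequence[LengthCutoff]) -> CutoffRegression:
    """OLS of b_cut on HSP length in amino acids (length_nt / 3).

    A single point falls back to a proportional fit through the origin.
    """
    if not points:
        raise TrainingError("no cutoff points to fit")
    gene_id, rank = points[0].gene_id, points[0].rank
    lengths_nt = np.array([p.length_nt for p in points], dtype=float)
    lengths_aa = lengths_nt / 3.0
    cuts = np.array([p.b_cut for p in points], dtype=float)
    if len(points) == 1:
        slope = float(cuts[0] / lengths_aa[0])
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(lengths_aa, cuts, 1))
    return CutoffRegression(
        gene_id=gene_id,
        rank=rank,
        slope=slope,
        intercept=intercept,
        n_points=len(points),
        min_length_nt=int(lengths_nt.min()),
        max_length_nt=int(lengths_nt.max()),
    )


@dataclass
class ClassifierSet:
    regressions: dict[tuple[str, str], CutoffRegression]
    metadata: dict = field(default_factory=dict)

    def get(self, gene_id: str, rank: str) -> CutoffRegression | None:
        return self.regressions.get((gene_id, rank))

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.regressions})

    def __len__(self) -> int:
        return len(self.regressions)

    def __contains__(self, gene_id: str) -> bool:
        return any(g == gene_id for g, _ in self.regressions)


def save_classifiers(cs: ClassifierSet, path) -> None:
    with open(path, "wt") as fh:
        fh.write("# markerphyler classifiers\n")
        fh.write(f"# metadata: {json.dumps(cs.metadata, sort_keys=True)}\n")
        fh.write("gene_id\trank\tslope\tintercept\tn_points\tmin_len\tmax_len\n")
        for (gene_id, rank) in sorted(cs.regressions):
            r = cs.regressions[(gene_id, rank)]
            fh.write(
                f"{gene_id}\t{rank}\t{r.slope!r}\t{r.intercept!r}\t{r.n_points}"
                f"\t{r.min_length_nt}\t{r.max_length_nt}\n"
            )


def load_classifiers(path) -> ClassifierSet:
    regressions: dict[tuple[str, str], CutoffRegression] = {}
    metadata: dict = {}
    with open(path, "rt") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# metadata: "):
                metadata = json.loads(line[len("# metadata: "):])
                continue
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            gene_id, rank, slope, intercept, n_points, lo, hi = line.split("\t")
            regressions[(gene_id, rank)] = CutoffRegression(
                gene_id, rank, float(slope), float(intercept),
                int(n_points), int(lo), int(hi),
            )
    return ClassifierSet(regressions, metadata)


def default_read_lengths(max_nt: int, step: int = 60) -> list[int]:
    """60, 120, 180, ... up to ``max_nt`` in ``step`` increments."""
    return list(range(step, max_nt + 1, step))


def train_all(
    db: MarkerDB,
    read_lengths: Sequence[int] | None = None,
    params: ScoringParams | None = None,
    stride_nt: int = 30,
    error_rate: float = 0.01,
    negative_ratio: float = 1.0,
    min_bits: float = 0.0,
    seed: int = 0,
) -> ClassifierSet:
    """Build the full classifier set over a reference database.

    For each read length, reads are tiled from every reference gene (plus a
    negative set of random reads, ``negative_ratio`` per positive read) and
    aligned against every gene; per (gene, rank) the cutoff is found, and the
    per-length cutoffs are summarised by the length regression.  Genes whose
    lineage lacks a rank are skipped at that rank (counted in metadata).
    """
    if len(db) == 0:
        raise TrainingError("empty reference database")
    params = params or default_params()
    max_gene_nt = max(r.nt_length for r in db.records)
    if read_lengths is None:
        read_lengths = default_read_lengths(max_gene_nt)
    read_lengths = sorted({int(x) for x in read_lengths})
    taxonomy = db.taxonomy

    points: dict[tuple[str, str], list[LengthCutoff]] = {}
    skipped: dict[str, int] = {}
    gene_nt = {r.gene_id: r.nt_length for r in db.records}

    for li, length in enumerate(read_lengths):
        if length > max_gene_nt:
            continue
        pos = simulate_reads(db, length, stride_nt, error_rate, seed=seed * 1000 + li)
        neg = simulate_negative_reads(
            int(round(negative_ratio * len(pos))), length,
            seed=seed * 1000 + 500 + li,
        )
        reads = pos + neg
        truth = {r.read_id: (r.true_taxid, r.true_gene) for r in reads}
        search = TranslatedSearch(reads, db, params)
        bits = search.bits
        seg_read = search.segment_read_idx
        # per-segment truth labels at every rank, vectorised once per length
        seg_gene = np.array(
            [reads[i].true_gene or "" for i in seg_read], dtype=object
        )
        seg_rank_label: dict[str, np.ndarray] = {}
        for rank in RANKS:
            per_read = [
                (taxonomy.lineage_of(r.true_taxid).get(rank) or "")
                if r.true_taxid is not None
                else ""
                for r in reads
            ]
            seg_rank_label[rank] = np.array(per_read, dtype=object)[seg_read]
        for gi, gene in enumerate(db.records):
            gene_lineage = taxonomy.lineage_of(gene.taxid)
            col = bits[:, gi]
            valid = np.isfinite(col) & (col >= min_bits)
            not_self = seg_gene != gene.gene_id
            usable = valid & not_self
            for rank in RANKS:
                gene_label = gene_lineage.get(rank)
                if gene_label is None:
                    skipped[rank] = skipped.get(rank, 0) + 1
                    continue
                level_mask = seg_rank_label[rank] == gene_label
                b_level = col[usable & level_mask]
                b_else = col[usable & ~level_mask]
                if b_level.size == 0 and b_else.size == 0:
                    continue
                part = ScorePartition(
                    gene.gene_id, rank, length, b_level.tolist(), b_else.tolist()
                )
                if length <= gene_nt[gene.gene_id]:
                    points.setdefault((gene.gene_id, rank), []).append(
                        find_cutoff(part)
                    )

    regressions = {
        key: fit_cutoff_regression(pts) for key, pts in sorted(points.items())
    }
    metadata = {
        "read_lengths": list(read_lengths),
        "stride_nt": stride_nt,
        "error_rate": error_rate,
        "negative_ratio": negative_ratio,
        "min_bits": min_bits,
        "seed": seed,
        "n_genes": len(db),
        "n_classifiers": len(regressions),
        # gene -> taxid so the classifier file is self-contained at
        # classification time (label transfer needs the hit gene's lineage)
        "gene_taxids": {r.gene_id: r.taxid for r in db.records},
        "skipped_gene_ranks": {k: skipped[k] for k in sorted(skipped)},
    }
    return ClassifierSet(regressions, metadata)
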