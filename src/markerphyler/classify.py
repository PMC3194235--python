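"""Hierarchical read classification with novel-clade fall-back.

Each read is classified individually from its single best reference hit.
Ranks are tried most specific first (genus, family, order, class, phylum):
the first rank whose length-dependent cutoff is met (b >= b_cut(L), with L
the HSP length in amino acids) transfers the reference gene's clade label at
that rank to the read; if no rank passes, the read is unclassified.

Because cutoffs are stringent, reads from organisms with no close relative
in the reference stop at a higher rank.  Such reads are reported with a
novelty suffix — a read that stops at family Enterobacteriaceae appears as
``Enterobacteriaceae{family}`` at the genus level — and an excess of reads
assigned exactly at a taxon versus below it flags that taxon as a candidate
novel clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .alignment import AlignmentHit, ScoringParams, TranslatedSearch, best_hit
from .refdb import MarkerDB
from .taxonomy import RANKS, TaxonomyTree, rank_index
from .training import ClassifierSet


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class Classification:
    read_id: str
    gene_id: str | None
    bit_score: float | None
    hsp_length: int | None
    assigned_rank: str | None  # None = unclassified
    assigned_taxid: str | None
    display_label: str
    extrapolated: bool = False

    @property
    def is_classified(self) -> bool:
        return self.assigned_rank is not None


def novel_label(name: str, assigned_rank: str) -> str:
    """Display name with the novelty suffix used below the assigned rank.

    A read assigned at a rank above genus is reported at every lower rank as
    ``<name>{<assigned_rank>}``; genus-level assignments carry no suffix.
    """
    if assigned_rank == "genus":
        return name
    return f"{name}{{{assigned_rank}}}"


def _unclassified(read_id: str, hit: AlignmentHit | None = None) -> Classification:
    return Classification(
        read_id=read_id,
        gene_id=hit.gene_id if hit else None,
        bit_score=hit.bit_score if hit else None,
        hsp_length=hit.hsp_length if hit else None,
        assigned_rank=None,
        assigned_taxid=None,
        display_label="unclassified",
    )


def _gene_taxid(classifiers: ClassifierSet, gene_id: str) -> str:
    taxids = classifiers.metadata.get("gene_taxids", {})
    try:
        return taxids[gene_id]
    except KeyError:
        raise ClassifyError(
            f"gene {gene_id!r} has no taxon in the classifier metadata"
        ) from None


def classify_read(
    hit: AlignmentHit, classifiers: ClassifierSet, taxonomy: TaxonomyTree
) -> Classification:
    """Classify one read from its best hit, genus first, phylum last.

    The comparison is ``b >= b_cut`` (exact ties pass).  HSP lengths outside
    a regression's trained support still classify via the clamped prediction
    but are flagged as extrapolated.
    """
    if hit.gene_id not in classifiers:
        raise ClassifyError(f"gene {hit.gene_id!r} unknown to the classifier set")
    lineage = taxonomy.lineage_of(_gene_taxid(classifiers, hit.gene_id))
    L = float(hit.hsp_length)
    for rank in RANKS:
        reg = classifiers.get(hit.gene_id, rank)
        if reg is None:
            continue
        taxid = lineage.get(rank)
        if taxid is None:
            continue
        if hit.bit_score >= reg.predict(L):
            return Classification(
                read_id=hit.query_id,
                gene_id=hit.gene_id,
                bit_score=hit.bit_score,
                hsp_length=hit.hsp_length,
                assigned_rank=rank,
                assigned_taxid=taxid,
                display_label=novel_label(taxonomy.name(taxid), rank),
                extrapolated=not reg.in_support(L),
            )
    return _unclassified(hit.query_id, hit)


def classify_all(
    hits_by_read: Iterable[tuple[str, Sequence[AlignmentHit]]],
    classifiers: ClassifierSet,
    taxonomy: TaxonomyTree,
) -> list[Classification]:
    """One Classification per read, in input order; hitless reads are
    unclassified.  Reads are independent of each other."""
    out = []
    for read_id, hits in hits_by_read:
        hits = [h for h in hits if h.gene_id in classifiers]
        if not hits:
            out.append(_unclassified(read_id))
        else:
            out.append(classify_read(best_hit(hits), classifiers, taxonomy))
    return out


def classify_reads(
    reads,
    db: MarkerDB,
    classifiers: ClassifierSet,
    params: ScoringParams | None = None,
    min_bits: float = 0.0,
) -> tuple[list[Classification], dict[str, AlignmentHit]]:
    """End-to-end: translated search, best hit per read, classification.

    Returns the classifications (input read order) and the best-hit table
    used, keyed by read id (reads without a qualifying hit are absent).
    """
    search = TranslatedSearch(reads, db, params)
    best = search.best_hits(min_bits=min_bits)
    out = []
    best_hits: dict[str, AlignmentHit] = {}
    for read_id in search.read_ids:
        hit = best.get(read_id)
        if hit is None or hit.gene_id not in classifiers:
            out.append(_unclassified(read_id, hit))
        else:
            best_hits[read_id] = hit
            out.append(classify_read(hit, classifiers, db.taxonomy))
    return out, best_hits


# ---------------------------------------------------------------------------
# novel-clade discrepancy report
# ---------------------------------------------------------------------------

def detect_novel_clades(
    classifications: Sequence[Classification],
    taxonomy: TaxonomyTree,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Assigned-at vs assigned-below discrepancy per taxon.

    For every taxon that received assignments, reports ``n_at`` (reads whose
    classification stopped exactly at that taxon) and ``n_below`` (reads
    assigned at more specific ranks within the taxon).  A taxon above genus
    with ``n_at >= min_reads`` is flagged: those reads were classifiable at
    its rank but at no rank below, the signature of a novel clade.  Member
    read ids are listed for downstream assembly.
    """
    n_at: dict[str, int] = {}
    n_below: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for c in classifications:
        if not c.is_classified:
            continue
        n_at[c.assigned_taxid] = n_at.get(c.assigned_taxid, 0) + 1
        members.setdefault(c.assigned_taxid, []).append(c.read_id)
        lineage = taxonomy.lineage_of(c.assigned_taxid)
        for rank in RANKS[rank_index(c.assigned_rank) + 1 :]:
            anc = lineage.get(rank)
            if anc is not None:
                n_below[anc] = n_below.get(anc, 0) + 1
    rows = []
    for taxid in sorted(set(n_at) | set(n_below)):
        rank = taxonomy.node(taxid).rank
        at = n_at.get(taxid, 0)
        flagged = rank in RANKS and rank != "genus" and at >= min_reads
        rows.append(
            (
                taxid,
                rank,
                at,
                n_below.get(taxid, 0),
                flagged,
                ",".join(sorted(members.get(taxid, []))),
            )
        )
    return pd.DataFrame(
        rows, columns=["taxid", "rank", "n_at", "n_below", "flagged", "read_ids"]
    )


# ---------------------------------------------------------------------------
# classification table I/O
# ---------------------------------------------------------------------------

_CLS_COLUMNS = [
    "read_id", "gene", "bit_score", "hsp_len_aa", "rank", "taxid", "label",
    "extrapolated",
]


def classifications_to_frame(classifications: Sequence[Classification]) -> pd.DataFrame:
    rows = [
        (
            c.read_id,
            c.gene_id or "",
            "" if c.bit_score is None else round(c.bit_score, 4),
            "" if c.hsp_length is None else c.hsp_length,
            c.assigned_rank or "unclassified",
            c.assigned_taxid or "",
            c.display_label,
            int(c.extrapolated),
        )
        for c in classifications
    ]
    return pd.DataFrame(rows, columns=_CLS_COLUMNS)


def write_classifications(classifications: Sequence[Classification], path) -> None:
    classifications_to_frame(classifications).to_csv(path, sep="\t", index=False)


def read_classifications(path) -> list[Classification]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        unclassified = row.rank == "unclassified"
        out.append(
            Classification(
                read_id=row.read_id,
                gene_id=row.gene or None,
                bit_score=float(row.bit_score) if row.bit_score else None,
                hsp_length=int(row.hsp_len_aa) if row.hsp_len_aa else None,
                assigned_rank=None if unclassified else row.rank,
                assigned_taxid=row.taxid or None,
                display_label=row.label,
                extrapolated=bool(int(row.extrapolated)),
            )
        )
    return out
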