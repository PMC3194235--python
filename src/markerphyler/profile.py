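"""Clade abundance estimation from marker-gene depth of coverage.

Counting classified reads over-represents large genomes; depth of coverage
of the single-copy marker genes does not.  For each taxonomic unit at the
profiled rank, the aligned bases of its reads are accumulated per marker
family and divided by the family's reference gene length, giving one
coverage value per family; the unit's depth of coverage is the median over
the configured marker set (absent families count as zero by default), and
relative abundances are the coverages normalised to sum to one.

Reads assigned below the profiled rank are aggregated upward (a genus-level
assignment contributes to its family at the family profile); reads that
stopped above the profiled rank form novel bins labelled ``Name{rank}`` and
participate in the profile alongside named taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentHit
from .classify import Classification, novel_label
from .refdb import MarkerDB
from .taxonomy import RANKS, TaxonomyTree, rank_index


@dataclass(frozen=True)
class ProfileRow:
    label: str
    taxid: str | None  # None for novel bins
    median_coverage: float
    abundance: float  # fraction of total coverage
    n_reads: int


@dataclass(frozen=True)
class TaxonProfile:
    rank: str
    rows: tuple[ProfileRow, ...]
    all_zero: bool = False  # warning flag: no coverage anywhere

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.label, r.taxid or "", r.median_coverage, 100.0 * r.abundance,
                 r.n_reads)
                for r in self.rows
            ],
            columns=["label", "taxid", "median_cov", "abundance_pct", "n_reads"],
        )

    def abundance_by_label(self) -> dict[str, float]:
        return {r.label: r.abundance for r in self.rows}


def _profile_bin(
    c: Classification, rank: str, taxonomy: TaxonomyTree
) -> tuple[str, str | None] | None:
    """(label, taxid-or-None) of the bin a classification falls in at ``rank``.

    Assignments at or below the rank aggregate up the lineage; assignments
    above it become novel bins.  Returns None for unclassified reads.
    """
    if not c.is_classified:
        return None
    if rank_index(c.assigned_rank) <= rank_index(rank):
        taxid = taxonomy.lineage_of(c.assigned_taxid).get(rank)
        if taxid is not None:
            return taxonomy.name(taxid), taxid
        # lineage gap at the profiled rank: keep the read in a novel-style bin
        return novel_label(taxonomy.name(c.assigned_taxid), c.assigned_rank), None
    return novel_label(taxonomy.name(c.assigned_taxid), c.assigned_rank), None


def marker_coverage(
    classifications: Sequence[Classification],
    best_hits: Mapping[str, AlignmentHit],
    db: MarkerDB,
    rank: str,
    taxonomy: TaxonomyTree | None = None,
) -> tuple[dict[tuple[str, str | None], dict[str, float]], dict[tuple[str, str | None], int]]:
    """Per-(bin, marker family) depth of coverage at the profiled rank.

    Coverage of family f in a bin is the summed aligned nucleotide bases
    (3 x HSP aa length) of the bin's reads whose best hit belongs to f,
    divided by the mean nucleotide length of the f genes inside the bin's
    clade (falling back to the family-wide mean when the clade has no
    reference gene, as for novel bins).  Also returns per-bin read counts.
    """
    taxonomy = taxonomy or db.taxonomy
    bases: dict[tuple[str, str | None], dict[str, float]] = {}
    n_reads: dict[tuple[str, str | None], int] = {}
    for c in classifications:
        bin_key = _profile_bin(c, rank, taxonomy)
        if bin_key is None:
            continue
        hit = best_hits.get(c.read_id)
        if hit is None:
            continue
        family = db.gene(hit.gene_id).family
        bases.setdefault(bin_key, {})
        bases[bin_key][family] = bases[bin_key].get(family, 0.0) + 3.0 * hit.hsp_length
        n_reads[bin_key] = n_reads.get(bin_key, 0) + 1

    family_mean_len = {
        f: float(np.mean([r.nt_length for r in db.by_family(f)]))
        for f in db.families()
    }
    coverage: dict[tuple[str, str | None], dict[str, float]] = {}
    for bin_key, fam_bases in bases.items():
        _, taxid = bin_key
        coverage[bin_key] = {}
        for family, b in fam_bases.items():
            if taxid is not None:
                clade_lens = [
                    r.nt_length
                    for r in db.by_family(family)
                    if taxid in taxonomy.ancestors(r.taxid)
                ]
            else:
                clade_lens = []
            denom = float(np.mean(clade_lens)) if clade_lens else family_mean_len[family]
            coverage[bin_key][family] = b / denom
    return coverage, n_reads


def taxon_coverage(
    per_family: Mapping[str, float],
    families: Sequence[str],
    exclude_zeros: bool = False,
) -> float:
    """Median coverage over the configured marker set.

    Families without reads count as zero unless ``exclude_zeros``; with an
    even count the median is the mean of the middle two values.
    """
    values = [float(per_family.get(f, 0.0)) for f in families]
    if exclude_zeros:
        values = [v for v in values if v > 0]
    if not values:
        return 0.0
    return float(np.median(values))


def relative_abundance(
    median_coverages: Mapping[str, float],
    rank: str = "genus",
    taxids: Mapping[str, str | None] | None = None,
    n_reads: Mapping[str, int] | None = None,
) -> TaxonProfile:
    """Normalise per-bin median coverages into relative abundances.

    ``abundance_i = coverage_i / sum_j coverage_j``; an all-zero input is
    reported as zeros with the profile's warning flag set.
    """
    if not median_coverages:
        raise ValueError("at least one taxon required")
    labels = sorted(
        median_coverages, key=lambda k: (-median_coverages[k], k)
    )
    total = float(sum(median_coverages.values()))
    all_zero = total <= 0
    rows = tuple(
        ProfileRow(
            label=label,
            taxid=(taxids or {}).get(label),
            median_coverage=float(median_coverages[label]),
            abundance=0.0 if all_zero else float(median_coverages[label]) / total,
            n_reads=int((n_reads or {}).get(label, 0)),
        )
        for label in labels
    )
    return TaxonProfile(rank=rank, rows=rows, all_zero=all_zero)


def compute_profile(
    classifications: Sequence[Classification],
    best_hits: Mapping[str, AlignmentHit],
    db: MarkerDB,
    rank: str,
    families: Sequence[str] | None = None,
    exclude_zeros: bool = False,
) -> TaxonProfile:
    """Full profile at one rank: coverage per family, median, normalise."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    families = list(families) if families is not None else db.families()
    coverage, reads = marker_coverage(classifications, best_hits, db, rank)
    medians = {
        label: taxon_coverage(per_family, families, exclude_zeros)
        for (label, _taxid), per_family in coverage.items()
    }
    if not medians:
        return TaxonProfile(rank=rank, rows=(), all_zero=True)
    taxids = {label: taxid for (label, taxid) in coverage}
    n_reads = {label: n for (label, _), n in reads.items()}
    return relative_abundance(medians, rank, taxids, n_reads)


def write_profile(profile: TaxonProfile, path) -> None:
    profile.as_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
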