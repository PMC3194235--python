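"""Marker-gene reference database and synthetic data generation.

The reference set consists of protein-coding phylogenetic marker genes: gene
families that are universal across bacteria, (mostly) single-copy, and rarely
horizontally transferred, which makes them a nearly unbiased proxy for
organism abundance.  This module holds the in-memory database (records plus
the taxonomy they resolve against) and generates everything the rest of the
pipeline consumes when no real database is available:

* an "evolved" marker-gene database over a balanced, known taxonomy, in which
  sequence divergence grows with taxonomic distance (the property the
  threshold-learning step relies on in real marker sets);
* tiled training reads with optional per-base substitution errors, and i.i.d.
  random-DNA negative reads;
* simulated metagenomic communities with a per-read truth table and exact
  ground-truth abundances.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import RANKS, Lineage, TaxonNode, TaxonomyTree, same_clade

#: The 31 universal single-copy marker-gene families used as default names.
MARKER_FAMILIES: tuple[str, ...] = (
    "dnaG", "frr", "infC", "nusA", "pgk", "pyrG", "rplA", "rplB", "rplC",
    "rplD", "rplE", "rplF", "rplK", "rplL", "rplM", "rplN", "rplP", "rplS",
    "rplT", "rpmA", "rpoB", "rpsB", "rpsC", "rpsE", "rpsI", "rpsJ", "rpsK",
    "rpsM", "rpsS", "smpB", "tsf",
)

_AA20 = "ARNDCQEGHILKMFPSTWYV"
_DNA = "ACGT"

# genus-ward branches accumulate less divergence than phylum-ward branches
DEFAULT_SUBSTITUTION: dict[str, float] = {
    "phylum": 0.30,
    "class": 0.20,
    "order": 0.15,
    "family": 0.10,
    "genus": 0.06,
    "species": 0.02,
    "strain": 0.005,
}

# deterministic codon per amino acid (lexicographically first of the standard
# table); wobble mutation later replaces some codons with synonymous ones
_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon in ("".join(c) for c in itertools.product(_DNA, repeat=3)):
    _aa = str(Seq(_codon).translate())
    if _aa not in "*":
        _CODONS_BY_AA.setdefault(_aa, ())
        _CODONS_BY_AA[_aa] = _CODONS_BY_AA[_aa] + (_codon,)


class ReferenceError(ValueError):
    """Inconsistent reference input (id mismatch, translation mismatch, ...)."""


@dataclass(frozen=True)
class MarkerGeneRecord:
    gene_id: str
    family: str
    taxid: str
    protein: str
    nucleotide: str | None = None

    def __post_init__(self):
        if not self.family:
            raise ReferenceError(f"{self.gene_id}: empty family")
        if len(self.protein) < 60:
            raise ReferenceError(
                f"{self.gene_id}: protein shorter than 60 aa ({len(self.protein)})"
            )
        if self.nucleotide is not None:
            _check_translation(self.gene_id, self.nucleotide, self.protein)

    @property
    def nt_length(self) -> int:
        return 3 * len(self.protein)


def _check_translation(gene_id: str, nucleotide: str, protein: str) -> None:
    n_nt, n_aa = len(nucleotide), len(protein)
    if n_nt not in (3 * n_aa, 3 * n_aa + 3):
        raise ReferenceError(
            f"{gene_id}: nucleotide length {n_nt} does not match {n_aa} aa"
        )
    translated = str(Seq(nucleotide[: 3 * n_aa]).translate())
    if translated != protein:
        raise ReferenceError(f"{gene_id}: translation does not match protein")


class MarkerDB:
    """Marker-gene records plus the taxonomy they resolve against."""

    def __init__(self, records: Iterable[MarkerGeneRecord], taxonomy: TaxonomyTree):
        self.records: list[MarkerGeneRecord] = sorted(records, key=lambda r: r.gene_id)
        self.taxonomy = taxonomy
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ReferenceError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            if rec.taxid not in taxonomy:
                raise ReferenceError(f"{rec.gene_id}: unknown taxid {rec.taxid!r}")
        self._by_id = {r.gene_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerDB):
            return NotImplemented
        return self.records == other.records and (
            {t: self.taxonomy.node(t) for t in self.taxonomy.taxids()}
            == {t: other.taxonomy.node(t) for t in other.taxonomy.taxids()}
        )

    def gene(self, gene_id: str) -> MarkerGeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def families(self) -> list[str]:
        return sorted({r.family for r in self.records})

    def by_family(self, family: str) -> list[MarkerGeneRecord]:
        return [r for r in self.records if r.family == family]

    def by_taxid(self, taxid: str) -> list[MarkerGeneRecord]:
        return [r for r in self.records if r.taxid == taxid]

    def lineage_of_gene(self, gene_id: str) -> Lineage:
        return self.taxonomy.lineage_of(self.gene(gene_id).taxid)

    def subset(self, keep) -> "MarkerDB":
        """New MarkerDB keeping records for which ``keep(record)`` is true."""
        return MarkerDB([r for r in self.records if keep(r)], self.taxonomy)

    def drop_taxa(self, taxids: Iterable[str]) -> "MarkerDB":
        """Remove every gene whose lineage passes through any of ``taxids``."""
        drop = set(taxids)
        return self.subset(
            lambda r: not drop.intersection(self.taxonomy.ancestors(r.taxid))
        )


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    true_gene: str | None
    true_taxid: str | None
    origin_offset: int
    strand: str = "+"


# ---------------------------------------------------------------------------
# synthetic marker database
# ---------------------------------------------------------------------------

_RANK_ORDER_TOPDOWN = (
    "phylum", "class", "order", "family", "genus", "species", "strain"
)
_RANK_PREFIX = {"phylum": "p", "class": "c", "order": "o", "family": "f",
                "genus": "g", "species": "s", "strain": "t"}


def balanced_taxonomy(tree_shape: Sequence[int]) -> TaxonomyTree:
    """Balanced taxonomy with ``tree_shape[i]`` children at each rank level.

    ``tree_shape`` has five entries (phylum..genus; leaves are genera), six
    (a trailing species count per genus) or seven (strains per species).
    """
    if len(tree_shape) not in (5, 6, 7):
        raise ValueError(
            "tree_shape must have 5 (phylum..genus), 6 (..species) or "
            "7 (..strain) entries"
        )
    if any(int(b) < 1 for b in tree_shape):
        raise ValueError("branching factors must be >= 1")
    nodes = [TaxonNode("root", "root", "root", "root")]
    level = ["root"]
    for rank, branching in zip(_RANK_ORDER_TOPDOWN, tree_shape):
        nxt = []
        for parent in level:
            for i in range(1, int(branching) + 1):
                prefix = "" if parent == "root" else parent + "."
                taxid = f"{prefix}{_RANK_PREFIX[rank]}{i}"
                nodes.append(TaxonNode(taxid, parent, rank, taxid))
                nxt.append(taxid)
        level = nxt
    return TaxonomyTree(nodes)


def _leaf_taxa(tree: TaxonomyTree) -> list[str]:
    return sorted(t for t in tree.taxids() if not tree.children(t) and t != tree.root)


def _mutate_protein(protein: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = protein.copy()
    hits = np.nonzero(rng.random(len(out)) < p)[0]
    if len(hits):
        # substitute to a uniformly chosen *different* residue
        shift = rng.integers(1, 20, size=len(hits))
        out[hits] = (out[hits] + shift) % 20
    return out


def _back_code(protein: str, wobble_rate: float, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_BY_AA[aa]
        codon = options[0]
        if len(options) > 1 and rng.random() < wobble_rate:
            codon = options[int(rng.integers(0, len(options)))]
        codons.append(codon)
    return "".join(codons)


def simulate_marker_db(
    tree_shape: Sequence[int] = (2, 2, 2, 2, 2),
    n_families: int = 3,
    root_length_aa: int = 200,
    per_rank_substitution: Mapping[str, float] | None = None,
    seed: int = 0,
    wobble_rate: float = 0.5,
    family_names: Sequence[str] | None = None,
) -> MarkerDB:
    """Evolve one gene per family down a balanced taxonomy.

    Each branch at rank *r* substitutes residues with probability
    ``per_rank_substitution[r]``; probabilities must be non-increasing from
    phylum to genus so that expected sequence identity is strictly ordered
    same-genus > same-family > same-order, the signal the cutoff learner
    exploits.  Nucleotide sequences are back-coded with a fixed codon per
    amino acid plus synonymous wobble at ``wobble_rate``, so nucleotide
    identity drifts below protein identity.
    """
    sub = dict(DEFAULT_SUBSTITUTION if per_rank_substitution is None else per_rank_substitution)
    used = _RANK_ORDER_TOPDOWN[: len(tree_shape)]
    probs = [sub[r] for r in used]
    if any(probs[i] < probs[i + 1] for i in range(len(probs) - 1)):
        raise ValueError(
            "per-rank substitution probabilities must be non-increasing "
            f"from phylum to {used[-1]}: {dict(zip(used, probs))}"
        )
    tree = balanced_taxonomy(tree_shape)
    if family_names is None:
        family_names = MARKER_FAMILIES
    if n_families > len(family_names):
        raise ValueError(f"at most {len(family_names)} family names available")
    families = list(family_names[:n_families])

    rng = np.random.default_rng(seed)
    records: list[MarkerGeneRecord] = []
    for family in families:
        root_protein = rng.integers(0, 20, size=root_length_aa).astype(np.int64)
        # depth-first, sorted children: deterministic traversal
        stack: list[tuple[str, np.ndarray]] = [(tree.root, root_protein)]
        while stack:
            taxid, protein = stack.pop()
            children = tree.children(taxid)
            if not children:
                if taxid != tree.root:
                    pep = "".join(_AA20[i] for i in protein)
                    nt = _back_code(pep, wobble_rate, rng)
                    records.append(
                        MarkerGeneRecord(
                            gene_id=f"{family}_{taxid}",
                            family=family,
                            taxid=taxid,
                            protein=pep,
                            nucleotide=nt,
                        )
                    )
                continue
            for child in reversed(children):
                p = sub[tree.node(child).rank]
                stack.append((child, _mutate_protein(protein, p, rng)))
    return MarkerDB(records, tree)


def mean_pairwise_identity(db: MarkerDB) -> dict[str, float]:
    """Mean protein identity of same-family gene pairs, by taxonomic relation.

    Categories: same_genus, same_family (different genus), same_order
    (different family-rank clade), same_class, same_phylum, diff_phylum.
    Only categories with at least one pair appear in the result.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for family in db.families():
        recs = db.by_family(family)
        for a, b in itertools.combinations(recs, 2):
            la, lb = db.taxonomy.lineage_of(a.taxid), db.taxonomy.lineage_of(b.taxid)
            cat = "diff_phylum"
            for rank in RANKS:
                if same_clade(la, lb, rank):
                    cat = f"same_{rank}"
                    break
            ia = np.frombuffer(a.protein.encode(), dtype=np.uint8)
            ib = np.frombuffer(b.protein.encode(), dtype=np.uint8)
            ident = float(np.mean(ia == ib))
            sums[cat] = sums.get(cat, 0.0) + ident
            counts[cat] = counts.get(cat, 0) + 1
    return {cat: sums[cat] / counts[cat] for cat in sums}


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits):
        lut = {ord(b): [ord(c) for c in _DNA if c != b] for b in _DNA}
        choices = rng.integers(0, 3, size=len(hits))
        for k, pos in enumerate(hits):
            arr[pos] = lut[arr[pos]][choices[k]]
    return arr.tobytes().decode()


def simulate_reads(
    db: MarkerDB,
    length_nt: int,
    stride_nt: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Tile every gene's nucleotide sequence with fixed-stride reads.

    Offsets run 0, stride, 2*stride, ... while ``offset + length <= gene
    length``; genes shorter than ``length_nt`` contribute nothing.  Per-base
    substitution errors are applied at ``error_rate``.  Raises if no gene is
    long enough.
    """
    if length_nt < 30:
        raise ValueError("read length must be >= 30 nt")
    if stride_nt < 1:
        raise ValueError("stride must be >= 1")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for rec in db.records:
        if rec.nucleotide is None:
            continue
        n = len(rec.nucleotide)
        for offset in range(0, n - length_nt + 1, stride_nt):
            frag = rec.nucleotide[offset : offset + length_nt]
            reads.append(
                SimulatedRead(
                    read_id=f"{rec.gene_id}:{offset}",
                    sequence=_add_errors(frag, error_rate, rng),
                    true_gene=rec.gene_id,
                    true_taxid=rec.taxid,
                    origin_offset=offset,
                )
            )
    if not reads:
        raise ValueError(f"read length {length_nt} nt exceeds every reference gene")
    return reads


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_DNA))[rng.choice(4, size=n, p=p)])


def simulate_negative_reads(
    n: int, length_nt: int, gc: float = 0.5, seed: int = 0
) -> list[SimulatedRead]:
    """``n`` i.i.d. random-DNA reads (no marker homology by construction)."""
    rng = np.random.default_rng(seed)
    return [
        SimulatedRead(
            read_id=f"neg{i}",
            sequence=random_dna(length_nt, gc, rng),
            true_gene=None,
            true_taxid=None,
            origin_offset=0,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------

def simulate_community(
    db: MarkerDB,
    genome_plan: Sequence[tuple[str, int, float]],
    read_length_nt: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
    gc: float = 0.5,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Shotgun-sequence synthetic genomes built around each taxon's markers.

    Each planned taxon's genome is its marker genes embedded, evenly spaced,
    in random non-marker background DNA of the planned total length.  The
    number of reads per genome is ``round(coverage * genome_length /
    read_length)``; read starts are uniform and strands equiprobable.  Returns
    the reads and a truth table (read_id, taxid, gene_id, offset, strand);
    ``gene_id`` is the marker covering the read midpoint, if any.  Ground
    truth abundance of taxon *i* is ``coverage_i / sum(coverage)``.
    """
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    rows = []
    for taxid, genome_length, coverage in genome_plan:
        if coverage <= 0:
            raise ValueError(f"{taxid}: coverage must be positive")
        markers = db.by_taxid(taxid)
        if not markers:
            raise ValueError(f"{taxid}: no marker genes in reference database")
        total_marker = sum(len(m.nucleotide or "") for m in markers)
        if genome_length < total_marker + len(markers) + 1:
            raise ValueError(f"{taxid}: genome_length {genome_length} too short")
        gap = (genome_length - total_marker) // (len(markers) + 1)
        pieces, intervals, pos = [], [], 0
        for m in markers:
            bg = random_dna(gap, gc, rng)
            pieces.append(bg)
            pos += gap
            pieces.append(m.nucleotide)
            intervals.append((pos, pos + len(m.nucleotide), m.gene_id))
            pos += len(m.nucleotide)
        pieces.append(random_dna(genome_length - pos, gc, rng))
        genome = "".join(pieces)
        if len(genome) < read_length_nt:
            raise ValueError(f"{taxid}: genome shorter than read length")
        n_reads = int(round(coverage * len(genome) / read_length_nt))
        starts = rng.integers(0, len(genome) - read_length_nt + 1, size=n_reads)
        rc = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            start = int(starts[i])
            frag = genome[start : start + read_length_nt]
            strand = "-" if rc[i] else "+"
            if strand == "-":
                frag = str(Seq(frag).reverse_complement())
            frag = _add_errors(frag, error_rate, rng)
            mid = start + read_length_nt // 2
            gene = next((g for a, b, g in intervals if a <= mid < b), None)
            read_id = f"{taxid}:r{i}"
            reads.append(
                SimulatedRead(read_id, frag, gene, taxid, start, strand)
            )
            rows.append((read_id, taxid, gene or "", start, strand))
    truth = pd.DataFrame(rows, columns=["read_id", "taxid", "gene_id", "offset", "strand"])
    return reads, truth


def true_abundances(genome_plan: Sequence[tuple[str, int, float]]) -> dict[str, float]:
    total = sum(cov for _, _, cov in genome_plan)
    return {taxid: cov / total for taxid, _, cov in genome_plan}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_reference(db: MarkerDB, outdir) -> dict[str, Path]:
    """Write protein/nucleotide FASTA, mapping TSV and taxonomy TSV."""
    from .taxonomy import write_taxonomy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein": outdir / "markers.faa",
        "nucleotide": outdir / "markers.fna",
        "mapping": outdir / "markers.map.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
    }
    SeqIO.write(
        (SeqRecord(Seq(r.protein), id=r.gene_id, description="") for r in db.records),
        str(paths["protein"]), "fasta",
    )
    SeqIO.write(
        (
            SeqRecord(Seq(r.nucleotide), id=r.gene_id, description="")
            for r in db.records
            if r.nucleotide is not None
        ),
        str(paths["nucleotide"]), "fasta",
    )
    with open(paths["mapping"], "wt") as fh:
        fh.write("gene_id\tfamily\ttaxid\n")
        for r in db.records:
            fh.write(f"{r.gene_id}\t{r.family}\t{r.taxid}\n")
    write_taxonomy(db.taxonomy, paths["taxonomy"])
    return paths


def load_reference(
    protein_fasta,
    nucleotide_fasta,
    mapping_table,
    taxonomy: TaxonomyTree,
    allow_protein_only: bool = False,
) -> MarkerDB:
    """Assemble a MarkerDB from FASTA pair + mapping TSV, with validation.

    Errors on id mismatches between the three files, on nucleotide/protein
    translation mismatches, and on unknown taxids.  Records without a
    nucleotide sequence are only allowed with ``allow_protein_only``.
    """
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta), "fasta")}
    nts: dict[str, str] = {}
    if nucleotide_fasta is not None:
        nts = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(nucleotide_fasta), "fasta")}
    mapping = pd.read_csv(mapping_table, sep="\t", dtype=str)
    required = {"gene_id", "family", "taxid"}
    if not required.issubset(mapping.columns):
        raise ReferenceError(f"mapping table must have columns {sorted(required)}")
    records = []
    for row in mapping.itertuples(index=False):
        if row.gene_id not in proteins:
            raise ReferenceError(f"{row.gene_id}: in mapping but not in protein FASTA")
        nt = nts.pop(row.gene_id, None)
        if nt is None and not allow_protein_only:
            raise ReferenceError(
                f"{row.gene_id}: no nucleotide sequence (use allow_protein_only "
                "for protein-query mode)"
            )
        if row.taxid not in taxonomy:
            raise ReferenceError(f"{row.gene_id}: unknown taxid {row.taxid!r}")
        records.append(
            MarkerGeneRecord(row.gene_id, row.family, row.taxid,
                             proteins.pop(row.gene_id), nt)
        )
    if proteins:
        raise ReferenceError(f"protein FASTA ids not in mapping: {sorted(proteins)[:5]}")
    if nts:
        raise ReferenceError(f"nucleotide FASTA ids not in mapping: {sorted(nts)[:5]}")
    return MarkerDB(records, taxonomy)


def write_reads_fasta(reads: Iterable[SimulatedRead], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads),
        str(path), "fasta",
    )


def write_truth(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "wt") as fh:
        fh.write("read_id\ttaxid\tgene_id\toffset\tstrand\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.true_taxid or ''}\t{r.true_gene or ''}"
                f"\t{r.origin_offset}\t{r.strand}\n"
            )
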