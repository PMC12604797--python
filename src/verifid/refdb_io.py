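"""Shared data model and file I/O.

Readers and writers for basecalled reads (FASTQ), the local reference
database (FASTA with structured headers plus a taxonomy TSV), the barcode
primer panel, and nanopore-index sample sheets.

Conventions
-----------
* Sequences are uppercased on read and ``U`` is mapped to ``T``;
  characters outside the IUPAC nucleotide alphabet are rejected.
* Internal coordinates are 0-based half-open.  Positions in
  human-readable reports are 1-based inclusive and labelled as such.
* Reference FASTA id lines are pipe-delimited
  ``accession|taxid|molecule|record_class|gene_label``; free text after
  the first whitespace becomes the record title (the ``stitle`` field of
  the hit table).
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: canonical panel order; used for deterministic tie-breaking throughout
BARCODES = ("CYTB", "COI", "16S", "12S")

RANKS = ("species", "genus", "tribe", "family", "order", "class", "higher")


class RefDbError(ValueError):
    """Malformed reference database, taxonomy, panel or sample sheet."""


class FastqParseError(ValueError):
    """Malformed FASTQ record."""


def clean_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(IUPAC_CODES)
    if bad:
        raise RefDbError(f"{context}: non-IUPAC characters {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class NanoporeRead:
    """A basecalled read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if any(q < 0 or q > 93 for q in self.qualities):
            raise FastqParseError(f"read {self.read_id!r}: Phred quality outside [0, 93]")

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[NanoporeRead]:
    """Stream reads from a (plain or gzipped) 4-line-per-record FASTQ file.

    Sanger Phred+33 qualities.  Record order is preserved.  A record whose
    sequence and quality lines differ in length raises
    :class:`FastqParseError` naming the record.
    """
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split()[0]
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"read {read_id!r}: sequence/quality length mismatch"
                    )
                yield NanoporeRead(
                    read_id=read_id,
                    sequence=clean_sequence(seq, context=f"read {read_id!r}"),
                    qualities=tuple(ord(c) - 33 for c in qual),
                )
        except ValueError as exc:  # biopython flags structural problems
            if isinstance(exc, (FastqParseError, RefDbError)):
                raise
            raise FastqParseError(str(exc)) from exc


def write_fastq(reads: Iterable[NanoporeRead], path: str | Path) -> int:
    """Write reads as Sanger FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# reference database + taxonomy


@dataclass(frozen=True)
class ReferenceRecord:
    accession: str
    taxid: int
    molecule: str  # "mitochondrial" | "nuclear"
    record_class: str  # "barcode_locus" | "ncRNA_other" | "other"
    gene_label: str
    sequence: str
    title: str = ""


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str


class Taxonomy:
    """A rank-labelled tree of taxa with O(depth) lineage queries.

    Exactly one root (``parent_taxid == taxid``) is required and every
    lineage must terminate there; cycles are rejected on construction.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode], ranks: tuple[str, ...] = RANKS):
        self.ranks = ranks
        self._nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.rank not in ranks:
                raise RefDbError(f"taxid {node.taxid}: unknown rank {node.rank!r}")
            if node.taxid in self._nodes:
                raise RefDbError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        roots = [n for n in self._nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise RefDbError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self._nodes.values():
            self.lineage(node.taxid)  # raises on cycles / dangling parents

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def node(self, taxid: int) -> TaxonomyNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise RefDbError(f"unknown taxid {taxid}") from None

    def lineage(self, taxid: int) -> list[TaxonomyNode]:
        """Path from the taxon (inclusive) to the root (inclusive)."""
        path = [self.node(taxid)]
        seen = {taxid}
        while path[-1].parent_taxid != path[-1].taxid:
            parent = self.node(path[-1].parent_taxid)
            if parent.taxid in seen:
                raise RefDbError(f"taxonomy cycle at taxid {parent.taxid}")
            seen.add(parent.taxid)
            path.append(parent)
        return path

    def lineage_at_rank(self, taxid: int, rank: str) -> Optional[TaxonomyNode]:
        """The ancestor (or self) at ``rank``, or None if the lineage skips it."""
        if rank not in self.ranks:
            raise RefDbError(f"unknown rank {rank!r}")
        for node in self.lineage(taxid):
            if node.rank == rank:
                return node
        return None

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def lca(self, taxids: Iterable[int]) -> TaxonomyNode:
        """Lowest common ancestor of a non-empty taxid collection."""
        taxids = list(taxids)
        if not taxids:
            raise RefDbError("LCA of an empty taxid set")
        common: Optional[list[int]] = None
        for t in taxids:
            ids = [n.taxid for n in self.lineage(t)][::-1]  # root first
            if common is None:
                common = ids
            else:
                k = 0
                while k < min(len(common), len(ids)) and common[k] == ids[k]:
                    k += 1
                common = common[:k]
        assert common  # root is always shared
        return self.node(common[-1])


def read_taxonomy(path: str | Path, ranks: tuple[str, ...] = RANKS) -> Taxonomy:
    """Load a taxonomy TSV with header columns taxid, parent_taxid, rank, name."""
    nodes = []
    with _open_text(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"taxid", "parent_taxid", "rank", "name"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise RefDbError(f"taxonomy file {path}: header must contain {sorted(required)}")
        for row in reader:
            nodes.append(
                TaxonomyNode(
                    taxid=int(row["taxid"]),
                    parent_taxid=int(row["parent_taxid"]),
                    rank=row["rank"],
                    name=row["name"],
                )
            )
    return Taxonomy(nodes, ranks=ranks)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("taxid\tparent_taxid\trank\tname\n")
        for taxid in sorted(taxonomy._nodes):
            n = taxonomy._nodes[taxid]
            handle.write(f"{n.taxid}\t{n.parent_taxid}\t{n.rank}\t{n.name}\n")


@dataclass
class ReferenceDB:
    """Reference records keyed by accession, plus their taxonomy."""

    records: dict[str, ReferenceRecord]
    taxonomy: Taxonomy

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(r.sequence) for r in self)


_MOLECULES = {"mitochondrial", "nuclear"}
_RECORD_CLASSES = {"barcode_locus", "ncRNA_other", "other"}


def parse_reference_header(header: str) -> tuple[str, int, str, str, str, str]:
    """Split ``accession|taxid|molecule|record_class|gene_label [title]``."""
    ident, _, title = header.partition(" ")
    parts = ident.split("|")
    if len(parts) != 5:
        raise RefDbError(
            f"reference header {ident!r}: expected "
            "accession|taxid|molecule|record_class|gene_label"
        )
    accession, taxid_s, molecule, record_class, gene_label = parts
    if molecule not in _MOLECULES:
        raise RefDbError(f"record {accession!r}: unknown molecule {molecule!r}")
    if record_class not in _RECORD_CLASSES:
        raise RefDbError(f"record {accession!r}: unknown record_class {record_class!r}")
    try:
        taxid = int(taxid_s)
    except ValueError:
        raise RefDbError(f"record {accession!r}: non-integer taxid {taxid_s!r}") from None
    return accession, taxid, molecule, record_class, gene_label, title.strip()


def load_reference_db(fasta_path: str | Path, taxonomy_path: str | Path) -> ReferenceDB:
    """Load the local reference database.

    Every record taxid must resolve in the taxonomy; duplicate accessions
    are an error.
    """
    taxonomy = read_taxonomy(taxonomy_path)
    records: dict[str, ReferenceRecord] = {}
    from Bio import SeqIO

    with _open_text(fasta_path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            accession, taxid, molecule, record_class, gene_label, title = (
                parse_reference_header(rec.description)
            )
            if accession in records:
                raise RefDbError(f"duplicate accession {accession!r}")
            if taxid not in taxonomy:
                raise RefDbError(
                    f"record {accession!r}: taxid {taxid} absent from taxonomy"
                )
            records[accession] = ReferenceRecord(
                accession=accession,
                taxid=taxid,
                molecule=molecule,
                record_class=record_class,
                gene_label=gene_label,
                sequence=clean_sequence(str(rec.seq), context=f"record {accession!r}"),
                title=title or f"{taxonomy.name(taxid)} {gene_label}",
            )
    return ReferenceDB(records=records, taxonomy=taxonomy)


def write_reference_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in records:
            ident = f"{r.accession}|{r.taxid}|{r.molecule}|{r.record_class}|{r.gene_label}"
            title = f" {r.title}" if r.title else ""
            handle.write(f">{ident}{title}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# primer panel


@dataclass(frozen=True)
class BarcodePrimers:
    barcode: str
    forward_primer: str
    reverse_primer: str
    tail_unit: str
    tail_repeats: int
    expected_insert_length: int

    def __post_init__(self) -> None:
        if len(self.tail_unit) != 13:
            raise RefDbError(
                f"{self.barcode}: tail unit must be exactly 13 bp, "
                f"got {len(self.tail_unit)}"
            )

    @property
    def tail(self) -> str:
        return self.tail_unit * self.tail_repeats


@dataclass(frozen=True)
class PrimerPanel:
    """The four mitochondrial mini-barcode primer pairs with their 5' tails.

    Each primer carries a tandemly repeated 13-bp tail at its 5' end
    (default two repeats, a 26-nt extension) that serves as the landing
    zone for transposase index insertion during rapid library prep.
    """

    barcodes: dict[str, BarcodePrimers]

    def __getitem__(self, barcode: str) -> BarcodePrimers:
        try:
            return self.barcodes[barcode]
        except KeyError:
            raise RefDbError(f"unknown barcode {barcode!r}") from None

    def __iter__(self) -> Iterator[BarcodePrimers]:
        # fixed panel order for deterministic tie-breaking
        for b in BARCODES:
            if b in self.barcodes:
                yield self.barcodes[b]
        for b in self.barcodes:
            if b not in BARCODES:
                yield self.barcodes[b]


#: Published 13-bp tail units, one per barcode.
TAIL_UNITS = {
    "CYTB": "AGTGTCCTGCTAG",
    "COI": "CTGAGGTGATCAG",
    "16S": "AACATGTGGTAAG",
    "12S": "TTATTCGCACACT",
}

#: Barcode insert lengths (bp) between the primer annealing sites.
INSERT_LENGTHS = {"CYTB": 307, "COI": 214, "12S": 111, "16S": 103}

# Synthetic 22-bp primer pairs (with a few degenerate positions, as real
# vertebrate-universal primers have).  These are stand-ins: the published
# panel's primer sequences are supplied at run time via a panel TSV.
_SYNTHETIC_PRIMERS = {
    "CYTB": ("CCATCCAACATYTCAGCATGAT", "GCRAATAGGAAGTATCATTCGG"),
    "COI": ("GGTCAACAAATCATAAAGAYAT", "TAAACTTCAGGGTGACCAAARA"),
    "16S": ("CGCCTGTTTATCAAAAACATGG", "CCGGTCTGAACTCAGATCACGT"),
    "12S": ("AAACTGGGATTAGATACCCCAC", "GAGGGTGACGGGCGGTGTGTRC"),
}


def default_panel(tail_repeats: int = 2) -> PrimerPanel:
    """The default panel: published tails and insert sizes, synthetic primers."""
    return PrimerPanel(
        barcodes={
            b: BarcodePrimers(
                barcode=b,
                forward_primer=clean_sequence(_SYNTHETIC_PRIMERS[b][0]),
                reverse_primer=clean_sequence(_SYNTHETIC_PRIMERS[b][1]),
                tail_unit=TAIL_UNITS[b],
                tail_repeats=tail_repeats,
                expected_insert_length=INSERT_LENGTHS[b],
            )
            for b in BARCODES
        }
    )


def read_panel(path: str | Path) -> PrimerPanel:
    """Load a panel TSV with columns barcode, forward_primer, reverse_primer,
    tail_unit, tail_repeats, expected_insert_length."""
    barcodes = {}
    with _open_text(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            b = row["barcode"]
            barcodes[b] = BarcodePrimers(
                barcode=b,
                forward_primer=clean_sequence(row["forward_primer"]),
                reverse_primer=clean_sequence(row["reverse_primer"]),
                tail_unit=clean_sequence(row["tail_unit"]),
                tail_repeats=int(row.get("tail_repeats", 2) or 2),
                expected_insert_length=int(row["expected_insert_length"]),
            )
    if not barcodes:
        raise RefDbError(f"panel file {path}: no barcodes")
    return PrimerPanel(barcodes=barcodes)


def write_panel(panel: PrimerPanel, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write(
            "barcode\tforward_primer\treverse_primer\ttail_unit\t"
            "tail_repeats\texpected_insert_length\n"
        )
        for bp in panel:
            handle.write(
                f"{bp.barcode}\t{bp.forward_primer}\t{bp.reverse_primer}\t"
                f"{bp.tail_unit}\t{bp.tail_repeats}\t{bp.expected_insert_length}\n"
            )


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleSheetEntry:
    index_id: str
    index_sequence: str
    sample_name: str
    mode: str  # "single_source" | "mixture"


def read_sample_sheet(path: str | Path) -> list[SampleSheetEntry]:
    """Load a sample sheet CSV (index_id, index_sequence, sample_name, mode)."""
    entries = []
    seen_seqs: dict[str, str] = {}
    with _open_text(path) as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            seq = clean_sequence(row["index_sequence"], context=row["index_id"])
            if seq in seen_seqs:
                raise RefDbError(
                    f"index sequence shared by {seen_seqs[seq]!r} and {row['index_id']!r}"
                )
            seen_seqs[seq] = row["index_id"]
            mode = row.get("mode", "single_source") or "single_source"
            if mode not in ("single_source", "mixture"):
                raise RefDbError(f"{row['index_id']}: unknown mode {mode!r}")
            entries.append(
                SampleSheetEntry(
                    index_id=row["index_id"],
                    index_sequence=seq,
                    sample_name=row["sample_name"],
                    mode=mode,
                )
            )
    return entries


def write_sample_sheet(entries: Iterable[SampleSheetEntry], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("index_id,index_sequence,sample_name,mode\n")
        for e in entries:
            handle.write(f"{e.index_id},{e.index_sequence},{e.sample_name},{e.mode}\n")
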