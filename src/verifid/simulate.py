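"""Synthetic data generation for the whole pipeline.

Emulates the laboratory process end to end: a reference database of
mitochondrial barcode loci (optionally with nuclear pseudogene copies,
numts), tetraplex amplicons built as
``[tail][F-primer][insert][rc(R-primer)][rc(tail)]``, transposase
tagmentation that breaks each amplicon once at a uniform random internal
position and prepends a sample index to both internal 5' ends, and a
nanopore noise model (i.i.d. substitutions/insertions/deletions with
Normal per-base qualities).

Every read is paired with a ground-truth record so downstream stages can
be scored without external data.  All randomness flows from a single
integer seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .refdb_io import (
    BARCODES,
    NanoporeRead,
    PrimerPanel,
    ReferenceDB,
    ReferenceRecord,
    SampleSheetEntry,
    Taxonomy,
    TaxonomyNode,
    default_panel,
    reverse_complement,
    write_fastq,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic sequencing run.

    Divergences are expected pairwise substitutions/site: within a
    species ~0.5% (typical intraspecific mitochondrial variation),
    between species 15% (mid-range for vertebrate mitochondrial
    barcodes).  Error rates default to a ~5% combined nanopore error
    (3% substitution, 1% insertion, 1% deletion); qualities are drawn
    per base from a Normal(18, 4) clipped to [2, 40], so default reads
    clear the Q>=11 filter.
    """

    n_species: int = 5
    sequences_per_species: int = 3
    within_species_divergence: float = 0.005
    between_species_divergence: float = 0.15
    numt_rate: float = 0.0
    numt_divergence: float = 0.08
    numt_amplification_bias: float = 0.5
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01
    mean_quality: float = 18.0
    quality_sd: float = 4.0
    reads_per_sample: int = 2000
    index_length: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not self.within_species_divergence < max(self.between_species_divergence, 1e-12) \
                and self.between_species_divergence > 0:
            raise ValueError("within-species divergence must be below between-species")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("error rates must lie in [0, 1)")
        if not 0 <= self.numt_rate <= 1:
            raise ValueError("numt_rate must lie in [0, 1]")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    sample_name: str
    taxid: int
    barcode: str
    strand: str  # "forward" | "reverse"
    breakpoint: int
    source: str  # "mito" | "numt"


@dataclass
class GroundTruth:
    """One truth record per emitted read, plus per-sample expectations."""

    reads: dict[str, ReadTruth] = field(default_factory=dict)
    sample_species: dict[str, set[int]] = field(default_factory=dict)

    def add(self, truth: ReadTruth) -> None:
        if truth.read_id in self.reads:
            raise ValueError(f"duplicate truth record for read {truth.read_id!r}")
        self.reads[truth.read_id] = truth
        self.sample_species.setdefault(truth.sample_name, set()).add(truth.taxid)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsample_name\ttaxid\tbarcode\tstrand\tbreakpoint\tsource\n")
            for t in self.reads.values():
                fh.write(
                    f"{t.read_id}\t{t.sample_name}\t{t.taxid}\t{t.barcode}\t"
                    f"{t.strand}\t{t.breakpoint}\t{t.source}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        gt = cls()
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                gt.add(
                    ReadTruth(
                        read_id=row["read_id"],
                        sample_name=row["sample_name"],
                        taxid=int(row["taxid"]),
                        barcode=row["barcode"],
                        strand=row["strand"],
                        breakpoint=int(row["breakpoint"]),
                        source=row["source"],
                    )
                )
        return gt


# ---------------------------------------------------------------------------
# sequence evolution


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def mutate(sequence: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``divergence`` (Jukes-Cantor
    style: replacement drawn uniformly from the three other bases)."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < divergence
    if hit.any():
        idx = _BASE_INDEX[arr[hit]]
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(idx + shift) % 4]
    return bytes(arr).decode()


# ---------------------------------------------------------------------------
# reference set


@dataclass
class SyntheticSpecies:
    taxid: int
    name: str
    inserts: dict[str, str]          # barcode -> mitochondrial insert
    numt_barcode: Optional[str] = None
    numt_insert: Optional[str] = None


@dataclass
class ReferenceSet:
    db: ReferenceDB
    species: list[SyntheticSpecies]
    panel: PrimerPanel


def _synthetic_taxonomy(n_species: int) -> tuple[Taxonomy, list[TaxonomyNode]]:
    """Species nested 2-per-genus, 2-genera-per-tribe, 2-tribes-per-family."""
    nodes = [TaxonomyNode(1, 1, "higher", "Root")]
    species_nodes = []
    for i in range(n_species):
        fam, tri, gen = i // 8, i // 4, i // 2
        sp_id, gen_id, tri_id, fam_id = 10000 + i, 1000 + gen, 500 + tri, 100 + fam
        if not any(n.taxid == fam_id for n in nodes):
            nodes.append(TaxonomyNode(fam_id, 1, "family", f"Family_{fam:02d}"))
        if not any(n.taxid == tri_id for n in nodes):
            nodes.append(TaxonomyNode(tri_id, fam_id, "tribe", f"Tribe_{tri:02d}"))
        if not any(n.taxid == gen_id for n in nodes):
            nodes.append(TaxonomyNode(gen_id, tri_id, "genus", f"Genus_{gen:02d}"))
        sp = TaxonomyNode(sp_id, gen_id, "species", f"Species_{i:02d}")
        nodes.append(sp)
        species_nodes.append(sp)
    return Taxonomy(nodes), species_nodes


def generate_reference_set(
    config: SimulationConfig, panel: Optional[PrimerPanel] = None
) -> ReferenceSet:
    """Build a synthetic reference database.

    Each species gets one mitochondrial ``barcode_locus`` record per
    barcode.  Species inserts descend from a common random ancestor, each
    mutated at half the between-species divergence so that pairwise
    species divergence matches the configured value in expectation.  With
    probability ``numt_rate`` a species additionally carries a
    nuclear-flagged copy of one barcode at ``numt_divergence`` from its
    mitochondrial counterpart.  Deterministic given ``config.seed``.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(config.seed)
    taxonomy, species_nodes = _synthetic_taxonomy(config.n_species)

    ancestors = {
        bp.barcode: random_sequence(bp.expected_insert_length, rng) for bp in panel
    }
    species: list[SyntheticSpecies] = []
    records: list[ReferenceRecord] = []
    half = config.between_species_divergence / 2.0
    for node in species_nodes:
        inserts = {b: mutate(ancestors[b], half, rng) for b in ancestors}
        sp = SyntheticSpecies(taxid=node.taxid, name=node.name, inserts=inserts)
        for b, seq in inserts.items():
            records.append(
                ReferenceRecord(
                    accession=f"SYN{node.taxid}_{b}",
                    taxid=node.taxid,
                    molecule="mitochondrial",
                    record_class="barcode_locus",
                    gene_label=b,
                    sequence=seq,
                    title=f"{node.name} mitochondrial {b} barcode segment",
                )
            )
        if rng.random() < config.numt_rate:
            b = BARCODES[int(rng.integers(0, len(BARCODES)))]
            numt = mutate(inserts[b], config.numt_divergence, rng)
            sp.numt_barcode, sp.numt_insert = b, numt
            records.append(
                ReferenceRecord(
                    accession=f"SYN{node.taxid}_{b}_NUMT",
                    taxid=node.taxid,
                    molecule="nuclear",
                    record_class="other",
                    gene_label=f"{b}_numt",
                    sequence=numt,
                    title=f"{node.name} nuclear pseudogene of {b}",
                )
            )
        species.append(sp)
    db = ReferenceDB(records={r.accession: r for r in records}, taxonomy=taxonomy)
    return ReferenceSet(db=db, species=species, panel=panel)


# ---------------------------------------------------------------------------
# amplicons, tagmentation, noise


def make_amplicon(insert: str, barcode: str, panel: PrimerPanel) -> str:
    """Top strand of the double-stranded tetraplex PCR product:
    ``tail + F + insert + rc(R) + rc(tail)``."""
    if len(insert) == 0:
        raise ValueError("insert must be non-empty")
    bp = panel[barcode]
    return bp.tail + bp.forward_primer + insert + reverse_complement(
        bp.reverse_primer
    ) + reverse_complement(bp.tail)


@dataclass(frozen=True)
class TagmentedPair:
    """The two read templates from one tagmented amplicon molecule.

    ``right`` reads the top strand from the breakpoint to the amplicon
    3' end (distal end carries rc(R-primer)+rc(tail)); ``left`` reads
    the bottom strand from the breakpoint to the amplicon 5' end
    (distal end carries rc(F-primer)+rc(tail)).  Both begin with the
    sample index added at the internal free 5' ends.
    """

    left: str
    right: str
    breakpoint: int


def tagment_and_read(
    amplicon: str, index_sequence: str, rng: np.random.Generator
) -> TagmentedPair:
    """One double-strand break at a uniform internal position; the sample
    index is prepended to both resulting templates."""
    if len(amplicon) < 2:
        raise ValueError("amplicon must be at least 2 bases for an internal break")
    k = int(rng.integers(1, len(amplicon)))
    right = index_sequence + amplicon[k:]
    left = index_sequence + reverse_complement(amplicon[:k])
    return TagmentedPair(left=left, right=right, breakpoint=k)


def corrupt(
    template: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    read_id: str = "read",
) -> NanoporeRead:
    """Apply i.i.d. per-base deletions, substitutions and (post-base)
    insertions, then draw clipped-Normal qualities."""
    arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    n = len(arr)
    if config.del_rate > 0:
        arr = arr[rng.random(n) >= config.del_rate]
    m = len(arr)
    if config.sub_rate > 0 and m:
        sub = rng.random(m) < config.sub_rate
        if sub.any():
            idx = _BASE_INDEX[arr[sub]]
            shift = rng.integers(1, 4, size=int(sub.sum()))
            arr[sub] = _BASES[(idx + shift) % 4]
    if config.ins_rate > 0 and m:
        ins = rng.random(m) < config.ins_rate
        if ins.any():
            reps = np.ones(m, dtype=np.int64) + ins
            out = np.repeat(arr, reps)
            ins_pos = (np.cumsum(reps) - 1)[ins]
            out[ins_pos] = _BASES[rng.integers(0, 4, size=len(ins_pos))]
            arr = out
    quals = np.clip(
        np.rint(rng.normal(config.mean_quality, config.quality_sd, size=len(arr))),
        2, 40,
    ).astype(int)
    return NanoporeRead(
        read_id=read_id, sequence=bytes(arr).decode(), qualities=tuple(quals)
    )


# ---------------------------------------------------------------------------
# whole runs


def make_indices(
    n: int, rng: np.random.Generator, length: int = 24, min_distance: int = 7
) -> list[str]:
    """Random sample indices, mutually separated by >= min_distance edits."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = random_sequence(length, rng)
        if all(
            edlib.align(cand, x, mode="NW")["editDistance"] >= min_distance for x in out
        ):
            out.append(cand)
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("could not generate well-separated indices")
    return out


def make_sample_sheet(
    sample_names: Sequence[str],
    modes: Sequence[str],
    rng: np.random.Generator,
    index_length: int = 24,
) -> list[SampleSheetEntry]:
    indices = make_indices(len(sample_names), rng, length=index_length)
    return [
        SampleSheetEntry(
            index_id=f"index{i + 1:02d}",
            index_sequence=indices[i],
            sample_name=sample_names[i],
            mode=modes[i],
        )
        for i in range(len(sample_names))
    ]


def simulate_run(
    sample_sheet: Sequence[SampleSheetEntry],
    proportions: dict[str, list[tuple[int, float]]],
    refset: ReferenceSet,
    config: SimulationConfig,
    fastq_path: str | Path,
    truth_path: Optional[str | Path] = None,
) -> GroundTruth:
    """Simulate a full flow-cell run.

    ``proportions`` maps sample_name to a list of (species taxid,
    fraction); fractions must sum to 1 per sample (singletons for
    single-source samples).  Exactly ``config.reads_per_sample`` reads are
    emitted per sample, interleaved across samples in round-robin order.
    Amplicon molecules yield two fragment reads each; barcodes are drawn
    uniformly; when a species carries a numt on a barcode, the nuclear
    copy replaces the mitochondrial template for that (sample, barcode)
    with probability ``numt_amplification_bias`` (preferential
    amplification), drawn once per sample.
    """
    rng = np.random.default_rng(config.seed + 1)
    species_by_taxid = {sp.taxid: sp for sp in refset.species}
    truth = GroundTruth()
    per_sample_reads: dict[str, list[NanoporeRead]] = {}

    for entry in sample_sheet:
        props = proportions[entry.sample_name]
        total = sum(f for _, f in props)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"sample {entry.sample_name!r}: proportions sum to {total}, not 1"
            )
        # preferential-amplification draw, once per (sample, species-with-numt)
        numt_wins: dict[int, bool] = {}
        for taxid, _ in props:
            sp = species_by_taxid[taxid]
            if sp.numt_barcode is not None:
                numt_wins[taxid] = bool(rng.random() < config.numt_amplification_bias)

        reads: list[NanoporeRead] = []
        truths: list[ReadTruth] = []
        taxids = [t for t, _ in props]
        fracs = np.array([f for _, f in props])
        serial = 0
        while len(reads) < config.reads_per_sample:
            taxid = taxids[int(rng.choice(len(taxids), p=fracs))]
            sp = species_by_taxid[taxid]
            barcode = BARCODES[int(rng.integers(0, len(BARCODES)))]
            source = "mito"
            insert = sp.inserts[barcode]
            if sp.numt_barcode == barcode and numt_wins.get(taxid, False):
                source, insert = "numt", sp.numt_insert  # type: ignore[assignment]
            amplicon = make_amplicon(insert, barcode, refset.panel)
            pair = tagment_and_read(amplicon, entry.index_sequence, rng)
            for template, strand in ((pair.right, "forward"), (pair.left, "reverse")):
                if len(reads) >= config.reads_per_sample:
                    break
                rid = f"{entry.sample_name}:{serial:06d}"
                serial += 1
                reads.append(corrupt(template, config, rng, read_id=rid))
                truths.append(
                    ReadTruth(
                        read_id=rid, sample_name=entry.sample_name, taxid=taxid,
                        barcode=barcode, strand=strand,
                        breakpoint=pair.breakpoint, source=source,
                    )
                )
        per_sample_reads[entry.sample_name] = reads
        for t in truths:
            truth.add(t)

    # round-robin interleave so the FASTQ mimics a pooled flow cell
    interleaved: list[NanoporeRead] = []
    iters = [iter(per_sample_reads[e.sample_name]) for e in sample_sheet]
    while iters:
        alive = []
        for it in iters:
            nxt = next(it, None)
            if nxt is not None:
                interleaved.append(nxt)
                alive.append(it)
        iters = alive
    write_fastq(interleaved, fastq_path)
    if truth_path is not None:
        truth.write(truth_path)
    return truth


def write_run_files(
    refset: ReferenceSet,
    sample_sheet: Sequence[SampleSheetEntry],
    proportions: dict[str, list[tuple[int, float]]],
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Materialise a complete simulated run on disk.

    Writes reference.fasta, taxonomy.tsv, panel.tsv, sample_sheet.csv,
    reads.fastq and truth.tsv under ``out_dir`` and returns their paths.
    """
    from .refdb_io import (
        write_panel,
        write_reference_fasta,
        write_sample_sheet,
        write_taxonomy,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "panel": out / "panel.tsv",
        "sheet": out / "sample_sheet.csv",
        "reads": out / "reads.fastq",
        "truth": out / "truth.tsv",
    }
    write_reference_fasta(refset.db, paths["reference"])
    write_taxonomy(refset.db.taxonomy, paths["taxonomy"])
    write_panel(refset.panel, paths["panel"])
    write_sample_sheet(sample_sheet, paths["sheet"])
    simulate_run(sample_sheet, proportions, refset, config, paths["reads"], paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# purpose-built fixtures


def generate_filter_fixture(
    n: int, seed: int
) -> tuple[list[NanoporeRead], int]:
    """Reads with planted length/quality composition for filter testing.

    Each read falls in exactly one category: pass (length in [100, 500],
    constant quality in [11, 30]), too-short, too-long, or low-quality
    (constant quality <= 10, for which the mean read quality equals the
    per-base value exactly).  Returns the reads and the exact number that
    a Q>=11 / 100-500 bp filter must retain.
    """
    rng = np.random.default_rng(seed)
    reads: list[NanoporeRead] = []
    n_pass = 0
    for i in range(n):
        cat = int(rng.integers(0, 4))
        if cat == 0:
            length, q = int(rng.integers(100, 501)), int(rng.integers(11, 31))
            n_pass += 1
        elif cat == 1:
            length, q = int(rng.integers(30, 100)), int(rng.integers(11, 31))
        elif cat == 2:
            length, q = int(rng.integers(501, 800)), int(rng.integers(11, 31))
        else:
            length, q = int(rng.integers(100, 501)), int(rng.integers(2, 11))
        reads.append(
            NanoporeRead(
                read_id=f"fixture:{i:05d}",
                sequence=random_sequence(length, rng),
                qualities=(q,) * length,
            )
        )
    return reads, n_pass


def generate_barcode_alignments(
    config: SimulationConfig,
    refset: Optional[ReferenceSet] = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Aligned barcode segments for the discrimination workflow.

    Returns, per barcode, a list of (sequence_id, species_name, sequence)
    with ``config.sequences_per_species`` intraspecific copies per
    species, each at the within-species divergence from the species
    insert.  Species sequences carry no indels, so segments are natively
    aligned.
    """
    refset = refset or generate_reference_set(config)
    rng = np.random.default_rng(config.seed + 2)
    out: dict[str, list[tuple[str, str, str]]] = {}
    for bp in refset.panel:
        rows = []
        for sp in refset.species:
            for j in range(config.sequences_per_species):
                seq = mutate(sp.inserts[bp.barcode], config.within_species_divergence, rng)
                rows.append((f"{sp.name}.{j + 1}", sp.name, seq))
        out[bp.barcode] = rows
    return out
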