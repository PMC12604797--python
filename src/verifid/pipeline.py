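"""End-to-end orchestration: reads -> filter/demux -> consensus ->
classification -> species call, with reproducible, seedable outputs.

Default thresholds are the published workflow's: Q >= 11 and 100-500 bp
read filtering, >= 100 supporting reads with both-strand consensuses for
single-source samples, > 20 supporting reads plus at least two
both-strand barcodes for mixtures, a 0.1% cluster abundance ratio, and a
90% top-match identity floor.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import callspecies, classify, consensus, readprep
from .callspecies import (
    BarcodeCall,
    ConsensusEvidence,
    MixtureReport,
    SpeciesCall,
    call_mixture,
    call_single_source,
    flag_numts,
    merge_strands,
)
from .classify import AlignmentHit, HitFilterParams, ScoringParams
from .consensus import ConsensusSequence, consensus_for_bin
from .readprep import FilterParams, prepare_reads
from .refdb_io import (
    BARCODES,
    PrimerPanel,
    ReferenceDB,
    SampleSheetEntry,
    default_panel,
    load_reference_db,
    read_fastq,
    read_panel,
    read_sample_sheet,
)


@dataclass
class RunConfig:
    reads_path: str
    reference_fasta: str
    taxonomy_tsv: str
    sample_sheet_path: str
    out_dir: str
    panel_path: Optional[str] = None
    min_quality: float = 11.0
    min_length: int = 100
    max_length: int = 500
    min_pident: float = 90.0
    single_source_min_reads: int = 100
    mixture_min_reads: int = 21  # "> 20 supporting reads"
    abundance_ratio: float = 0.001
    identity_threshold: float = 0.80
    index_max_edit: int = 3
    primer_max_edit: Optional[int] = None
    require_all_barcodes: bool = True
    mode_override: Optional[str] = None  # force single_source/mixture for all samples
    seed: int = 0


@dataclass
class RunResult:
    calls: dict[str, Union[SpeciesCall, MixtureReport]]
    counts: Counter
    consensuses: list[ConsensusSequence]
    hits: list[AlignmentHit]
    filtered_hits: dict[str, list[AlignmentHit]] = field(default_factory=dict)


def _call_to_dict(call: Union[SpeciesCall, MixtureReport]) -> dict:
    if isinstance(call, SpeciesCall):
        return {
            "type": "single_source",
            "final_taxid": call.final_taxid,
            "level": call.level,
            "name": call.name,
            "supporting_barcodes": list(call.supporting_barcodes),
            "numt_flagged_barcodes": list(call.numt_flagged_barcodes),
            "barcodes": {
                bc.barcode: {
                    "status": bc.status,
                    "numt_reason": bc.numt_reason,
                    "strands": sorted(bc.strands_present),
                    "supporting_reads": dict(sorted(bc.supporting_reads.items())),
                    "candidates": {
                        str(t): round(p, 2) for t, p in sorted(bc.candidates.items())
                    },
                    "discordant_strands": bc.discordant_strands,
                }
                for bc in call.barcode_calls
            },
        }
    return {
        "type": "mixture",
        "species": [
            {
                "taxid": sp.taxid,
                "name": sp.name,
                "supporting_barcodes": list(sp.supporting_barcodes),
                "total_supporting_reads": sp.total_supporting_reads,
            }
            for sp in call.species
        ],
    }


def run_pipeline(
    config: RunConfig,
    db: Optional[ReferenceDB] = None,
    panel: Optional[PrimerPanel] = None,
    sample_sheet: Optional[list[SampleSheetEntry]] = None,
) -> RunResult:
    """Run the full identification workflow and write report files.

    Writes to ``config.out_dir``: ``consensus.fasta`` (headers
    index_id|barcode|strand|supporting_reads), ``hits.tsv`` (outfmt-7
    dialect), ``report.json``/``report.tsv`` (final calls), and
    ``summary.tsv`` (per-stage read accounting).  Deterministic given the
    inputs; an empty read file yields a report with zero calls.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if db is None:
        db = load_reference_db(config.reference_fasta, config.taxonomy_tsv)
    if panel is None:
        panel = read_panel(config.panel_path) if config.panel_path else default_panel()
    if sample_sheet is None:
        sample_sheet = read_sample_sheet(config.sample_sheet_path)
    taxonomy = db.taxonomy
    scoring = ScoringParams()

    reads = read_fastq(config.reads_path)
    prep = prepare_reads(
        reads,
        sample_sheet,
        panel,
        filter_params=FilterParams(
            min_quality=config.min_quality,
            min_length=config.min_length,
            max_length=config.max_length,
        ),
        index_max_edit=config.index_max_edit,
        primer_max_edit=config.primer_max_edit,
    )
    counts = Counter(prep.counts)

    mode_of = {
        e.index_id: (config.mode_override or e.mode) for e in sample_sheet
    }
    sample_of = {e.index_id: e.sample_name for e in sample_sheet}

    consensuses: list[ConsensusSequence] = []
    by_bin: dict[tuple[str, str, str], list[ConsensusSequence]] = {}
    for bin_key in sorted(prep.bins):
        index_id = bin_key[0]
        min_reads = (
            config.mixture_min_reads
            if mode_of[index_id] == "mixture"
            else config.single_source_min_reads
        )
        cons = consensus_for_bin(
            prep.bins[bin_key],
            bin_key,
            identity_threshold=config.identity_threshold,
            abundance_ratio=config.abundance_ratio,
            min_supporting_reads=min_reads,
        )
        by_bin[bin_key] = cons
        consensuses.extend(cons)
    counts["consensuses_retained"] = len(consensuses)

    all_hits: list[AlignmentHit] = []
    filtered: dict[str, list[AlignmentHit]] = {}
    for cons in consensuses:
        index_id = cons.bin_key[0]
        params = HitFilterParams(
            min_pident=config.min_pident, mode=mode_of[index_id]
        )
        qid = f"{cons.qseqid}|rank{cons.cluster_rank}"
        rows = classify.search_db(cons.sequence, db, scoring, qseqid=qid)
        all_hits.extend(rows)
        filtered[qid] = classify.filter_hits(rows, taxonomy, params)
    counts["consensuses_classified"] = sum(1 for v in filtered.values() if v)

    calls: dict[str, Union[SpeciesCall, MixtureReport]] = {}
    for entry in sample_sheet:
        index_id = entry.index_id
        mode = mode_of[index_id]
        if mode == "single_source":
            barcode_calls: list[BarcodeCall] = []
            for barcode in BARCODES:
                per_strand: dict[str, tuple[list[AlignmentHit], int]] = {}
                for strand in ("forward", "reverse"):
                    cons_list = by_bin.get((index_id, barcode, strand), [])
                    top = next((c for c in cons_list if c.cluster_rank == 1), None)
                    if top is None:
                        per_strand[strand] = ([], 0)
                        continue
                    qid = f"{top.qseqid}|rank1"
                    per_strand[strand] = (filtered.get(qid, []), top.supporting_reads)
                barcode_calls.append(
                    merge_strands(
                        barcode,
                        per_strand["forward"][0],
                        per_strand["reverse"][0],
                        forward_support=per_strand["forward"][1],
                        reverse_support=per_strand["reverse"][1],
                    )
                )
            barcode_calls = flag_numts(barcode_calls, taxonomy)
            calls[entry.sample_name] = call_single_source(
                barcode_calls, taxonomy,
                require_all_barcodes=config.require_all_barcodes,
            )
        else:
            evidence = []
            for (idx, barcode, strand), cons_list in by_bin.items():
                if idx != index_id:
                    continue
                for cons in cons_list:
                    qid = f"{cons.qseqid}|rank{cons.cluster_rank}"
                    taxids = frozenset(h.staxids for h in filtered.get(qid, []))
                    if taxids:
                        evidence.append(
                            ConsensusEvidence(
                                barcode=barcode, strand=strand,
                                supporting_reads=cons.supporting_reads,
                                taxids=taxids,
                            )
                        )
            calls[entry.sample_name] = call_mixture(evidence, taxonomy)

    _write_outputs(out_dir, config, calls, counts, consensuses, all_hits)
    return RunResult(
        calls=calls, counts=counts, consensuses=consensuses,
        hits=all_hits, filtered_hits=filtered,
    )


def _write_outputs(out_dir, config, calls, counts, consensuses, all_hits) -> None:
    with open(out_dir / "consensus.fasta", "w") as fh:
        for cons in consensuses:
            fh.write(f">{cons.qseqid}|rank{cons.cluster_rank}\n{cons.sequence}\n")
    classify.write_hit_table(all_hits, out_dir / "hits.tsv")
    report = {sample: _call_to_dict(call) for sample, call in sorted(calls.items())}
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "report.tsv", "w") as fh:
        fh.write("sample\ttype\ttaxid\tname\tlevel\tbarcodes\tsupporting_reads\n")
        for sample, call in sorted(calls.items()):
            if isinstance(call, SpeciesCall):
                fh.write(
                    f"{sample}\tsingle_source\t{call.final_taxid or ''}\t"
                    f"{call.name or ''}\t{call.level}\t"
                    f"{','.join(call.supporting_barcodes)}\t\n"
                )
            else:
                if not call.species:
                    fh.write(f"{sample}\tmixture\t\t\tnone\t\t\n")
                for sp in call.species:
                    fh.write(
                        f"{sample}\tmixture\t{sp.taxid}\t{sp.name}\tspecies\t"
                        f"{','.join(sp.supporting_barcodes)}\t"
                        f"{sp.total_supporting_reads}\n"
                    )
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write("stage\tcount\n")
        for key in sorted(counts):
            fh.write(f"{key}\t{counts[key]}\n")
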