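"""Consensus classification against the local reference database.

Each consensus is aligned locally (affine gaps) against every database
record, yielding a tabular hit list in the BLAST outfmt-7 column dialect
(qseqid qlen evalue qcovs pident staxids stitle scomnames).  The E-value
column is a Karlin-Altschul surrogate, E = K*m*n*exp(-lambda*S), with
BLASTN-like constants for the +2/-3 scoring pair; the database here is
desk-scale and E is used only for ranking, so the constants are a
documented surrogate rather than a calibration.  Hit filtering follows
the sort / taxid-dedupe / top-hit rules of the identification workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align

from .refdb_io import ReferenceDB, Taxonomy, reverse_complement


@dataclass(frozen=True)
class ScoringParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 0.625
    K: float = 0.41

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of the outfmt-7-compatible hit table."""

    qseqid: str
    qlen: int
    evalue: float
    qcovs: float  # percent of the query covered by the aligned span
    pident: float  # percent identity over alignment columns
    staxids: int
    stitle: str
    scomnames: str
    score: float = 0.0
    accession: str = ""
    subject_molecule: Optional[str] = None
    subject_record_class: Optional[str] = None


@dataclass(frozen=True)
class HitFilterParams:
    min_pident: float = 90.0
    require_species_level: bool = True
    exclude_ncrna: bool = True
    mode: str = "single_source"  # or "mixture"


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def local_align(
    query: str, subject: str, scoring: ScoringParams = ScoringParams()
) -> tuple[float, float, float, tuple[int, int]]:
    """Optimal local alignment under affine gap scoring.

    Returns (raw score S, pident, qcovs, query span).  pident is
    100 x identities / alignment columns (gap columns included); qcovs is
    100 x (query span covered by the alignment) / query length.  A pair
    with no positive-scoring local alignment returns S = 0.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _aligner(scoring)
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, 0.0, 0.0, (0, 0)
    aln = aligner.align(query, subject)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / columns if columns else 0.0
    qranges = aln.aligned[0]
    qstart, qend = int(qranges[0][0]), int(qranges[-1][-1])
    qcovs = 100.0 * (qend - qstart) / len(query)
    return float(score), pident, qcovs, (qstart, qend)


def evalue(
    score: float,
    query_length: int,
    database_length: int,
    scoring: ScoringParams = ScoringParams(),
) -> float:
    """Karlin-Altschul expected hit count, E = K*m*n*exp(-lambda*S)."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return scoring.K * query_length * database_length * math.exp(-scoring.lam * score)


def search_db(
    query: str,
    db: ReferenceDB,
    scoring: ScoringParams = ScoringParams(),
    qseqid: str = "query",
) -> list[AlignmentHit]:
    """Align a consensus against every database record.

    One row per subject with a positive local score; rows sorted by
    ascending E-value, then descending pident, descending qcovs, and
    ascending accession (a total order, so repeated calls agree).
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    n = db.total_length
    taxonomy = db.taxonomy
    rc_query = reverse_complement(query)
    rows: list[AlignmentHit] = []
    for record in db:
        # both query orientations, as a nucleotide BLAST search would
        score, pident, qcovs, _span = local_align(query, record.sequence, scoring)
        rc_res = local_align(rc_query, record.sequence, scoring)
        if rc_res[0] > score:
            score, pident, qcovs, _span = rc_res
        if score <= 0:
            continue
        rows.append(
            AlignmentHit(
                qseqid=qseqid,
                qlen=len(query),
                evalue=evalue(score, len(query), n, scoring),
                qcovs=qcovs,
                pident=pident,
                staxids=record.taxid,
                stitle=record.title,
                scomnames=taxonomy.name(record.taxid),
                score=score,
                accession=record.accession,
                subject_molecule=record.molecule,
                subject_record_class=record.record_class,
            )
        )
    rows.sort(key=lambda h: (h.evalue, -h.pident, -h.qcovs, h.accession))
    return rows


def filter_hits(
    rows: Sequence[AlignmentHit],
    taxonomy: Taxonomy,
    params: HitFilterParams = HitFilterParams(),
) -> list[AlignmentHit]:
    """Dedupe/top-hit filtering for one query's sorted hit rows.

    The best row per taxid is kept; rows not labelled at species rank
    (when required) and non-coding-RNA subjects (when excluded) are
    dropped, letting the next row become top.  If the surviving top row's
    identity is below ``min_pident`` the query yields no retained hits —
    a weak best match discards the consensus rather than promoting a
    worse one.  All rows tied with the top (equal E-value and pident) are
    retained.
    """
    deduped: list[AlignmentHit] = []
    seen: set[int] = set()
    for row in rows:
        if row.staxids in seen:
            continue
        seen.add(row.staxids)
        deduped.append(row)

    surviving = []
    for row in deduped:
        if params.require_species_level and taxonomy.rank(row.staxids) != "species":
            continue
        if params.exclude_ncrna and row.subject_record_class == "ncRNA_other":
            continue
        surviving.append(row)
    if not surviving:
        return []
    top = surviving[0]
    if top.pident < params.min_pident:
        return []
    return [
        r for r in surviving if r.evalue == top.evalue and r.pident == top.pident
    ]


# ---------------------------------------------------------------------------
# hit table I/O (outfmt-7 dialect)

_COLUMNS = ("qseqid", "qlen", "evalue", "qcovs", "pident", "staxids", "stitle", "scomnames")


def write_hit_table(rows: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write rows as a TSV with an outfmt-7-style comment header."""
    with open(path, "w") as fh:
        fh.write("# verifid hit table\n")
        fh.write("# Fields: " + ", ".join(_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.qseqid}\t{r.qlen}\t{r.evalue:.3g}\t{r.qcovs:.1f}\t"
                f"{r.pident:.2f}\t{r.staxids}\t{r.stitle}\t{r.scomnames}\n"
            )


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Ingest an externally produced hit table in the same column dialect
    (e.g. a real BLAST run with
    -outfmt "7 qseqid qlen evalue qcovs pident staxids stitle scomnames").

    Subject molecule/record-class metadata is unavailable in this dialect
    and is left unset.
    """
    rows: list[AlignmentHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise ValueError(
                    f"hit table {path}: expected {len(_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            rows.append(
                AlignmentHit(
                    qseqid=parts[0],
                    qlen=int(parts[1]),
                    evalue=float(parts[2]),
                    qcovs=float(parts[3]),
                    pident=float(parts[4]),
                    staxids=int(parts[5].split(";")[0]),
                    stitle=parts[6],
                    scomnames=parts[7],
                )
            )
    return rows
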