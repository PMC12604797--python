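"""Read filtering, index demultiplexing, and distal primer assignment.

The tagmentation read model dictates the geometry here: every retained
read begins with a sample index (internal 5' end of a fragment) and ends,
at its distal 3' end, with the reverse complement of one of the eight
panel primers followed by the reverse-complemented tail.  A read is
assigned to a (barcode, strand) only when such a primer is found near the
distal end; the primer and everything distal of it are trimmed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .refdb_io import (
    IUPAC_CODES,
    NanoporeRead,
    PrimerPanel,
    SampleSheetEntry,
    reverse_complement,
)

#: edlib equality pairs letting IUPAC degeneracy codes match their base set
#: at zero cost (applied on whichever side carries the code).
IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (code, base)
    for code, members in IUPAC_CODES.items()
    if code not in "ACGT"
    for base in members
]


@dataclass(frozen=True)
class FilterParams:
    min_quality: float = 11.0
    min_length: int = 100
    max_length: int = 500

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.min_quality < 0:
            raise ValueError("min_quality must be >= 0")


@dataclass(frozen=True)
class DemuxedRead:
    read_id: str
    index_id: str
    barcode: str
    strand: str  # "forward" | "reverse"
    trimmed_sequence: str
    trimmed_qualities: tuple[int, ...]
    primer_edit_distance: int


def read_quality(read: NanoporeRead) -> float:
    """Mean read quality on the Phred scale.

    Q = -10 log10(mean per-base error probability), the convention used
    by common long-read filters: a read's quality is driven by its worst
    bases, not the arithmetic mean of its Phred scores.
    """
    if len(read) == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    errors = np.power(10.0, -np.asarray(read.qualities, dtype=float) / 10.0)
    # round away float representation error so a read of constant Phred q
    # scores exactly q and inclusive thresholds behave as stated
    return round(float(-10.0 * np.log10(errors.mean())), 9)


def filter_reads(
    reads: Iterable[NanoporeRead], params: FilterParams = FilterParams()
) -> tuple[list[NanoporeRead], Counter]:
    """Keep reads with mean quality >= min_quality and length within
    [min_length, max_length] (both bounds inclusive).

    Returns the survivors and a Counter partitioning the input over
    {passed, too_short, too_long, low_quality}; length is checked first.
    """
    passed: list[NanoporeRead] = []
    counts: Counter = Counter(passed=0, too_short=0, too_long=0, low_quality=0)
    for read in reads:
        if len(read) < params.min_length:
            counts["too_short"] += 1
        elif len(read) > params.max_length:
            counts["too_long"] += 1
        elif read_quality(read) < params.min_quality:
            counts["low_quality"] += 1
        else:
            counts["passed"] += 1
            passed.append(read)
    return passed, counts


def demux_index(
    read: NanoporeRead,
    sample_sheet: Sequence[SampleSheetEntry],
    max_edit: int = 3,
    window: int = 60,
) -> tuple[Optional[str], NanoporeRead]:
    """Assign a read to its sample index and trim through the index match.

    The best index by edit distance within the leading ``window`` bases
    wins; a tie at the best distance, or a best distance above
    ``max_edit``, leaves the read unassigned (returned untrimmed).
    """
    prefix = read.sequence[:window]
    best: Optional[tuple[int, int, str]] = None  # (distance, trim_end, index_id)
    tied = False
    for entry in sample_sheet:
        res = edlib.align(entry.index_sequence, prefix, mode="HW", task="locations")
        dist = res["editDistance"]
        if dist < 0:
            continue
        if best is None or dist < best[0]:
            best = (dist, res["locations"][0][1] + 1, entry.index_id)
            tied = False
        elif dist == best[0]:
            tied = True
    if best is None or tied or best[0] > max_edit:
        return None, read
    _, end, index_id = best
    trimmed = NanoporeRead(
        read_id=read.read_id,
        sequence=read.sequence[end:],
        qualities=read.qualities[end:],
    )
    return index_id, trimmed


def default_primer_max_edit(primer: str) -> int:
    return math.ceil(0.25 * len(primer))


def assign_barcode_strand(
    read: NanoporeRead,
    panel: PrimerPanel,
    max_edit: Optional[int] = None,
    window_factor: float = 1.5,
) -> Optional[DemuxedRead]:
    """Assign an index-trimmed read to its (barcode, strand) by distal
    primer search, trimming the primer and tail.

    The distal (3') window of each read is scanned for the reverse
    complement of each of the eight panel primers (IUPAC degeneracy at
    zero cost, edit distance otherwise).  A hit to rc(reverse primer) of
    barcode b means the read is the top-strand (forward) fragment; a hit
    to rc(forward primer) the bottom-strand (reverse) fragment.  Ties
    break by lowest distance, then longest primer, then fixed panel
    order, then forward before reverse.  Returns None when no primer
    qualifies within the window.
    """
    seq = read.sequence
    best: Optional[tuple[int, int, int, int, str, str, int]] = None
    for order, bp in enumerate(panel):
        limit = max_edit if max_edit is not None else None
        for strand_order, (primer, strand) in enumerate(
            ((bp.reverse_primer, "forward"), (bp.forward_primer, "reverse"))
        ):
            query = reverse_complement(primer)
            k = limit if limit is not None else default_primer_max_edit(primer)
            wlen = math.ceil(window_factor * (len(primer) + len(bp.tail)))
            offset = max(0, len(seq) - wlen)
            res = edlib.align(
                query,
                seq[offset:],
                mode="HW",
                task="locations",
                k=k,
                additionalEqualities=IUPAC_EQUALITIES,
            )
            if res["editDistance"] < 0:
                continue
            start = offset + res["locations"][0][0]
            cand = (
                res["editDistance"], -len(primer), order, strand_order,
                bp.barcode, strand, start,
            )
            if best is None or cand[:4] < best[:4]:
                best = cand
    if best is None:
        return None
    dist, _, _, _, barcode, strand, start = best
    trimmed_seq = seq[:start]
    trimmed_qual = read.qualities[:start]
    # Read-through removal: a fragment spanning the whole amplicon also
    # carries the *other* primer of its barcode (preceded by a partial
    # tail) at its proximal start; left in place it would inflate
    # between-read identity during clustering.  Trim through it.
    bp = panel[barcode]
    proximal_primer = bp.forward_primer if strand == "forward" else bp.reverse_primer
    k = max_edit if max_edit is not None else default_primer_max_edit(proximal_primer)
    wlen = math.ceil(window_factor * (len(proximal_primer) + len(bp.tail)))
    res = edlib.align(
        proximal_primer,
        trimmed_seq[:wlen],
        mode="HW",
        task="locations",
        k=k,
        additionalEqualities=IUPAC_EQUALITIES,
    )
    if res["editDistance"] >= 0:
        end = res["locations"][0][1] + 1
        trimmed_seq = trimmed_seq[end:]
        trimmed_qual = trimmed_qual[end:]
    return DemuxedRead(
        read_id=read.read_id,
        index_id="",
        barcode=barcode,
        strand=strand,
        trimmed_sequence=trimmed_seq,
        trimmed_qualities=trimmed_qual,
        primer_edit_distance=dist,
    )


@dataclass
class PrepResult:
    """Per-bin assigned reads plus a partition of every input read."""

    bins: dict[tuple[str, str, str], list[DemuxedRead]]
    counts: Counter  # filtered_*, unassigned_index, unassigned_barcode, assigned


def prepare_reads(
    reads: Iterable[NanoporeRead],
    sample_sheet: Sequence[SampleSheetEntry],
    panel: PrimerPanel,
    filter_params: FilterParams = FilterParams(),
    index_max_edit: int = 3,
    primer_max_edit: Optional[int] = None,
) -> PrepResult:
    """Filter -> index demux -> barcode/strand assignment, with bookkeeping.

    Every input read lands in exactly one category: a rejection reason
    from the quality/length filter, unassigned_index, unassigned_barcode,
    or assigned (into its (index_id, barcode, strand) bin).
    """
    passed, counts = filter_reads(reads, filter_params)
    counts = Counter(
        {f"filtered_{k}": v for k, v in counts.items() if k != "passed"}
    )
    counts["unassigned_index"] = 0
    counts["unassigned_barcode"] = 0
    counts["assigned"] = 0
    bins: dict[tuple[str, str, str], list[DemuxedRead]] = {}
    for read in passed:
        index_id, trimmed = demux_index(read, sample_sheet, max_edit=index_max_edit)
        if index_id is None:
            counts["unassigned_index"] += 1
            continue
        demuxed = assign_barcode_strand(trimmed, panel, max_edit=primer_max_edit)
        if demuxed is None or len(demuxed.trimmed_sequence) == 0:
            counts["unassigned_barcode"] += 1
            continue
        demuxed = DemuxedRead(
            read_id=demuxed.read_id,
            index_id=index_id,
            barcode=demuxed.barcode,
            strand=demuxed.strand,
            trimmed_sequence=demuxed.trimmed_sequence,
            trimmed_qualities=demuxed.trimmed_qualities,
            primer_edit_distance=demuxed.primer_edit_distance,
        )
        counts["assigned"] += 1
        bins.setdefault((index_id, demuxed.barcode, demuxed.strand), []).append(demuxed)
    return PrepResult(bins=bins, counts=counts)
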