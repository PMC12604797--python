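"""Within-bin read clustering and consensus building.

Reads in a (sample index, barcode, strand) bin share their distal end —
the amplicon terminus — while their proximal starts are ragged because
tagmentation breaks each molecule at a random internal point.  Both the
greedy clustering and the consensus therefore anchor alignments at the
distal end; proximal columns with thin coverage are trimmed, mirroring
the reduced confidence at the proximal end of each strand consensus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .readprep import DemuxedRead

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

#: cap on members used to compute a consensus (longest first); bounds runtime
MAX_CONSENSUS_MEMBERS = 500


@dataclass
class ReadCluster:
    bin_key: tuple[str, str, str]  # (index_id, barcode, strand)
    members: list[DemuxedRead]
    representative: DemuxedRead

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusSequence:
    sequence: str
    bin_key: tuple[str, str, str]
    supporting_reads: int
    cluster_rank: int  # 1 = most supported cluster in the bin

    @property
    def qseqid(self) -> str:
        index_id, barcode, strand = self.bin_key
        return f"{index_id}|{barcode}|{strand}|{self.supporting_reads}"


def _canonical_sort(reads: Sequence[DemuxedRead]) -> list[DemuxedRead]:
    # length descending, then read id: makes clustering order-invariant
    return sorted(reads, key=lambda r: (-len(r.trimmed_sequence), r.read_id))


def distal_identity(a: str, b: str) -> float:
    """Alignment identity of two reads over their shared distal span.

    The 3' ends are anchored: the longer suffix is clipped to the shorter
    read's length and the pair globally aligned; identity is
    1 - edits/span.
    """
    k = min(len(a), len(b))
    if k == 0:
        return 0.0
    dist = edlib.align(a[-k:], b[-k:], mode="NW")["editDistance"]
    return 1.0 - dist / k


def cluster_reads(
    bin_reads: Sequence[DemuxedRead],
    bin_key: tuple[str, str, str],
    identity_threshold: float = 0.80,
) -> list[ReadCluster]:
    """Greedy star clustering within one bin.

    Reads are visited longest-first (ties by read id); each joins the
    first existing cluster whose representative it matches at or above
    ``identity_threshold`` (distal-anchored identity), otherwise it
    founds a new cluster with itself as representative.  Deterministic.
    """
    clusters: list[ReadCluster] = []
    for read in _canonical_sort(bin_reads):
        placed = False
        for cluster in clusters:
            if (
                distal_identity(
                    read.trimmed_sequence, cluster.representative.trimmed_sequence
                )
                >= identity_threshold
            ):
                cluster.members.append(read)
                placed = True
                break
        if not placed:
            clusters.append(
                ReadCluster(bin_key=bin_key, members=[read], representative=read)
            )
    return clusters


def apply_abundance_filter(
    clusters: Sequence[ReadCluster],
    abundance_ratio: float = 0.001,
    min_supporting_reads: int = 100,
) -> list[ReadCluster]:
    """Retain clusters with size >= abundance_ratio x (bin total) and
    size >= min_supporting_reads.

    The denominator is the number of reads in the bin after filtering,
    i.e. the sum of all cluster sizes.  The single-source floor is 100
    supporting reads; mixture mode uses 21 (a ``> 20`` rule).
    """
    total = sum(c.size for c in clusters)
    cutoff = abundance_ratio * total
    return [
        c for c in clusters if c.size >= cutoff and c.size >= min_supporting_reads
    ]


def build_consensus(
    cluster: ReadCluster,
    min_coverage_fraction: float = 0.30,
    min_coverage_floor: int = 3,
) -> ConsensusSequence:
    """Distal-anchored star-alignment majority consensus.

    The (up to) :data:`MAX_CONSENSUS_MEMBERS` longest members are each
    aligned into the representative; every representative column takes
    the majority vote over {A, C, G, T, gap} with ties resolved to the
    representative's base.  Majority-gap columns are removed.  Proximal
    (left) columns with coverage below ``max(floor, fraction x members)``
    are trimmed, reflecting the thinning read support away from the
    distal anchor.
    """
    if not cluster.members:
        raise ValueError("cannot build a consensus from an empty cluster")
    members = _canonical_sort(cluster.members)[:MAX_CONSENSUS_MEMBERS]
    # work in distal-first coordinates: reverse everything so the shared
    # amplicon terminus is column 0 and alignments are anchored there
    rep_r = cluster.representative.trimmed_sequence[::-1]
    ncol = len(rep_r)
    counts = [dict.fromkeys("ACGT-", 0) for _ in range(ncol)]
    coverage = [0] * ncol
    inserts: list[dict[str, int]] = [dict() for _ in range(ncol + 1)]

    for member in members:
        seq_r = member.trimmed_sequence[::-1]
        if seq_r == rep_r:
            for i, base in enumerate(rep_r):
                counts[i][base] = counts[i].get(base, 0) + 1
                coverage[i] += 1
            continue
        # SHW pins the query (member) start to the target (representative)
        # start, i.e. the distal ends coincide; the proximal tail is free
        res = edlib.align(seq_r, rep_r, mode="SHW", task="path")
        pos = 0
        qi = 0
        for n_s, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(n_s)
            if op in "=X":
                for k in range(n):
                    base = seq_r[qi + k]
                    if base in counts[pos + k]:
                        counts[pos + k][base] += 1
                    coverage[pos + k] += 1
                qi += n
                pos += n
            elif op == "I":
                # member bases absent from the representative: voted on as
                # a junction insert, so a base the representative lost (or
                # hid behind adjacent errors) can be restored by majority
                frag = seq_r[qi:qi + n]
                inserts[pos][frag] = inserts[pos].get(frag, 0) + 1
                qi += n
            else:  # "D": member lacks these representative columns
                for k in range(n):
                    counts[pos + k]["-"] += 1
                    coverage[pos + k] += 1
                pos += n

    min_cov = max(min_coverage_floor, int(min_coverage_fraction * len(members)))
    end = ncol
    while end > 0 and coverage[end - 1] < min_cov:
        end -= 1  # trim thin proximal columns (far from the distal anchor)

    def _junction_insert(j: int, cov: int) -> str:
        if not inserts[j] or cov == 0:
            return ""
        frag, votes = min(inserts[j].items(), key=lambda kv: (-kv[1], kv[0]))
        return frag if votes > cov / 2 else ""

    out = []
    for i in range(end):
        out.append(_junction_insert(i, coverage[i]))
        col = counts[i]
        best = max(col.values())
        winners = [b for b, v in col.items() if v == best]
        base = rep_r[i] if rep_r[i] in winners else sorted(winners)[0]
        if base != "-":
            out.append(base)
    return ConsensusSequence(
        sequence="".join(out)[::-1],
        bin_key=cluster.bin_key,
        supporting_reads=cluster.size,
        cluster_rank=0,
    )


def consensus_for_bin(
    bin_reads: Sequence[DemuxedRead],
    bin_key: tuple[str, str, str],
    identity_threshold: float = 0.80,
    abundance_ratio: float = 0.001,
    min_supporting_reads: int = 100,
) -> list[ConsensusSequence]:
    """Cluster one bin, filter by abundance/support, and build consensuses
    ranked by supporting reads (rank 1 = largest cluster)."""
    clusters = cluster_reads(bin_reads, bin_key, identity_threshold)
    retained = apply_abundance_filter(clusters, abundance_ratio, min_supporting_reads)
    retained.sort(key=lambda c: (-c.size, c.representative.read_id))
    out = []
    for rank, cluster in enumerate(retained, start=1):
        cons = build_consensus(cluster)
        out.append(
            ConsensusSequence(
                sequence=cons.sequence,
                bin_key=cons.bin_key,
                supporting_reads=cons.supporting_reads,
                cluster_rank=rank,
            )
        )
    return out
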