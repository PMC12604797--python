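"""Final taxonomic decisions from per-barcode, per-strand evidence.

Single-source calls demand both-strand consensuses per barcode, flag
nuclear pseudogene (numt) amplifications by top-match molecule and by
cross-barcode discordance, and escalate to a coarser taxonomic level
(genus, tribe, ...) via the lowest common ancestor when the identifying
barcodes do not agree on a single species.  Mixture calls are
qualitative: a species is present only when at least two barcodes show
both-strand consensus evidence for it.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .classify import AlignmentHit
from .refdb_io import BARCODES, Taxonomy

#: barcode-call statuses
IDENTIFYING = "identifying"
NUMT = "numt"
NO_CONSENSUS = "no_consensus"
FILTERED_OUT = "filtered_out"
ONE_STRAND_ONLY = "one_strand_only"


@dataclass
class BarcodeCall:
    barcode: str
    status: str
    candidates: dict[int, float] = field(default_factory=dict)  # taxid -> best pident
    strands_present: frozenset[str] = frozenset()
    supporting_reads: dict[str, int] = field(default_factory=dict)
    top_hits: dict[str, Optional[AlignmentHit]] = field(default_factory=dict)
    discordant_strands: bool = False
    numt_reason: Optional[str] = None  # "nuclear_top_hit" | "cross_barcode_disagreement"


@dataclass(frozen=True)
class SpeciesCall:
    final_taxid: Optional[int]
    level: str  # species | genus | tribe | family | order | class | higher | none
    name: Optional[str]
    supporting_barcodes: tuple[str, ...]
    numt_flagged_barcodes: tuple[str, ...]
    barcode_calls: tuple[BarcodeCall, ...] = ()


@dataclass(frozen=True)
class MixtureSpecies:
    taxid: int
    name: str
    supporting_barcodes: tuple[str, ...]  # barcodes with both-strand evidence
    total_supporting_reads: int


@dataclass(frozen=True)
class MixtureReport:
    species: tuple[MixtureSpecies, ...]


def merge_strands(
    barcode: str,
    forward_hits: Sequence[AlignmentHit],
    reverse_hits: Sequence[AlignmentHit],
    forward_support: int = 0,
    reverse_support: int = 0,
) -> BarcodeCall:
    """Combine the two strand consensuses' retained top hits for a barcode.

    A barcode identifies only when both strands produced retained hits;
    the candidate taxa are the intersection of the strands' top-tied
    taxid sets.  If the strands' sets are disjoint the union is kept and
    the call is marked strand-discordant (the cross-barcode majority
    adjudicates later).  One strand only -> one_strand_only; neither
    strand -> no_consensus (covering filtered-out consensuses as well).
    """
    fwd = {h.staxids: h.pident for h in forward_hits}
    rev = {h.staxids: h.pident for h in reverse_hits}
    strands = frozenset(
        s for s, hits in (("forward", fwd), ("reverse", rev)) if hits
    )
    support = {"forward": forward_support, "reverse": reverse_support}
    tops = {
        "forward": forward_hits[0] if forward_hits else None,
        "reverse": reverse_hits[0] if reverse_hits else None,
    }
    if len(strands) == 2:
        common = set(fwd) & set(rev)
        if common:
            candidates = {t: max(fwd[t], rev[t]) for t in common}
            discordant = False
        else:
            candidates = {t: max(fwd.get(t, 0.0), rev.get(t, 0.0)) for t in set(fwd) | set(rev)}
            discordant = True
        return BarcodeCall(
            barcode=barcode, status=IDENTIFYING, candidates=candidates,
            strands_present=strands, supporting_reads=support, top_hits=tops,
            discordant_strands=discordant,
        )
    if len(strands) == 1:
        return BarcodeCall(
            barcode=barcode, status=ONE_STRAND_ONLY,
            candidates={}, strands_present=strands,
            supporting_reads=support, top_hits=tops,
        )
    return BarcodeCall(
        barcode=barcode, status=NO_CONSENSUS, strands_present=strands,
        supporting_reads=support, top_hits=tops,
    )


def _majority_species(calls: Iterable[BarcodeCall]) -> Optional[int]:
    """The single most frequent candidate species across identifying
    barcodes, or None on a tie (conservative: no flagging)."""
    votes: Counter = Counter()
    for call in calls:
        for taxid in call.candidates:
            votes[taxid] += 1
    if not votes:
        return None
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def flag_numts(
    barcode_calls: Sequence[BarcodeCall], taxonomy: Taxonomy
) -> list[BarcodeCall]:
    """Flag barcodes whose evidence traces to a nuclear pseudogene.

    A barcode is flagged when its top retained hit (either strand) is a
    nuclear-flagged record, or when its candidate species set excludes
    the majority species of the other identifying barcodes (disagreement
    of the top mitochondrial match).  Flagged barcodes are excluded from
    the final call.
    """
    calls = list(barcode_calls)
    for call in calls:
        if call.status not in (IDENTIFYING, ONE_STRAND_ONLY):
            continue
        # applies to one-strand barcodes too: they never contribute to the
        # call, but the per-barcode report should still say "numt"
        if any(
            h is not None and h.subject_molecule == "nuclear"
            for h in call.top_hits.values()
        ):
            call.status = NUMT
            call.numt_reason = "nuclear_top_hit"
    majority = _majority_species(c for c in calls if c.status == IDENTIFYING)
    if majority is not None:
        for call in calls:
            if call.status == IDENTIFYING and majority not in call.candidates:
                call.status = NUMT
                call.numt_reason = "cross_barcode_disagreement"
    return calls


def call_single_source(
    barcode_calls: Sequence[BarcodeCall],
    taxonomy: Taxonomy,
    require_all_barcodes: bool = True,
) -> SpeciesCall:
    """Integrate identifying barcodes into one call.

    If exactly one species is a candidate of every identifying barcode
    (or of a strict majority, when ``require_all_barcodes`` is False) the
    call is species-level.  Otherwise the call ascends to the lowest
    common ancestor of the pooled candidates and reports its rank.  With
    no identifying barcodes the level is ``none``.
    """
    calls = list(barcode_calls)
    identifying = [c for c in calls if c.status == IDENTIFYING]
    numt_flagged = tuple(c.barcode for c in calls if c.status == NUMT)
    if not identifying:
        return SpeciesCall(
            final_taxid=None, level="none", name=None,
            supporting_barcodes=(), numt_flagged_barcodes=numt_flagged,
            barcode_calls=tuple(calls),
        )
    votes: Counter = Counter()
    for call in identifying:
        for taxid in call.candidates:
            votes[taxid] += 1
    needed = len(identifying) if require_all_barcodes else len(identifying) // 2 + 1
    winners = sorted(t for t, v in votes.items() if v >= needed)
    if not require_all_barcodes and len(winners) > 1:
        # strict majority must be unique to call a species
        top = max(votes[t] for t in winners)
        winners = sorted(t for t in winners if votes[t] == top)
    supporting = tuple(c.barcode for c in identifying)
    if len(winners) == 1:
        taxid = winners[0]
        return SpeciesCall(
            final_taxid=taxid, level=taxonomy.rank(taxid), name=taxonomy.name(taxid),
            supporting_barcodes=supporting, numt_flagged_barcodes=numt_flagged,
            barcode_calls=tuple(calls),
        )
    pooled = sorted(votes)
    lca = taxonomy.lca(pooled)
    return SpeciesCall(
        final_taxid=lca.taxid, level=lca.rank, name=lca.name,
        supporting_barcodes=supporting, numt_flagged_barcodes=numt_flagged,
        barcode_calls=tuple(calls),
    )


@dataclass(frozen=True)
class ConsensusEvidence:
    """Retained classification of one consensus, for mixture calling."""

    barcode: str
    strand: str
    supporting_reads: int
    taxids: frozenset[int]


def call_mixture(
    evidence: Sequence[ConsensusEvidence],
    taxonomy: Taxonomy,
    min_barcodes: int = 2,
) -> MixtureReport:
    """Qualitative mixture presence calls.

    A species is reported iff at least ``min_barcodes`` barcodes each
    have both forward and reverse consensuses whose retained top hits
    include it.  Supporting-read totals are reported for transparency;
    no proportions are inferred.
    """
    per_species: dict[int, dict[str, set[str]]] = {}
    reads: dict[int, int] = {}
    for ev in evidence:
        for taxid in ev.taxids:
            per_species.setdefault(taxid, {}).setdefault(ev.barcode, set()).add(ev.strand)
    species_out = []
    for taxid in sorted(per_species):
        both = tuple(
            b for b in BARCODES
            if per_species[taxid].get(b, set()) >= {"forward", "reverse"}
        )
        if len(both) < min_barcodes:
            continue
        total = sum(
            ev.supporting_reads
            for ev in evidence
            if taxid in ev.taxids and ev.barcode in both
        )
        species_out.append(
            MixtureSpecies(
                taxid=taxid, name=taxonomy.name(taxid),
                supporting_barcodes=both, total_supporting_reads=total,
            )
        )
    return MixtureReport(species=tuple(species_out))


def derive_mixture_threshold(
    negative_control_supports: Sequence[int], floor: int = 21
) -> int:
    """Mixture supporting-read threshold from a negative control.

    Three times the highest cluster support seen in the negative control,
    never below the configured floor (a max of 7 gives 21, i.e. the
    ``> 20 supporting reads`` rule).  With no negative control the floor
    is returned.
    """
    if not negative_control_supports:
        warnings.warn("no negative-control clusters; using the configured floor")
        return floor
    return max(floor, 3 * max(negative_control_supports))
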