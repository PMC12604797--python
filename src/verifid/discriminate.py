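"""Panel-validation computations: K2P distances, neighbour-joining trees
with bootstrap, and per-barcode / combined species-resolvability scoring.

The Kimura two-parameter distance corrects separately for transitions
(proportion P) and transversions (proportion Q):

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Trees are built by Saitou-Nei neighbour joining with deterministic
tie-breaking and bootstrap supports from column resampling.  A species is
"resolved" by a barcode when its sequences form an exclusive clade — a
group separable from everything else by a single edge of the unrooted
tree; resolution is structural, with bootstrap supports reported but not
gating (trees were historically inspected visually for this purpose).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """K2P distance undefined: substitution saturation (log argument <= 0)."""


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two equal-length sequences.

    Sites where either base is not in {A, C, G, T} are skipped (pairwise
    deletion).  Raises :class:`SaturationError` when the correction's log
    arguments are non-positive, and ValueError with zero comparable sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("k2p_distance requires equal-length sequences")
    sites = transitions = transversions = 0
    for a, b in zip(seq_a, seq_b):
        if a not in "ACGT" or b not in "ACGT":
            continue
        sites += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated pair (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_matrix(labels: Sequence[str], sequences: Sequence[str]) -> DistanceMatrix:
    """Pairwise K2P distance matrix over aligned sequences.

    Vectorised but numerically identical to :func:`k2p_distance` applied
    pairwise (site counts are exact integers either way).
    """
    n = len(sequences)
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(n, -1)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    purine = np.isin(arr, np.frombuffer(b"AG", dtype=np.uint8))
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = valid[i] & valid[j]
        sites = int(ok.sum())
        if sites == 0:
            raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
        diff = (arr[i] != arr[j]) & ok
        ts = int((diff & (purine[i] == purine[j])).sum())
        tv = int(diff.sum()) - ts
        P, Q = ts / sites, tv / sites
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            raise SaturationError(
                f"saturated pair {labels[i]}/{labels[j]} (P={P:.3f}, Q={Q:.3f})"
            )
        mat[i, j] = mat[j, i] = -0.5 * math.log(w1 * math.sqrt(w2))
    return DistanceMatrix(mat, ids=list(labels))


# ---------------------------------------------------------------------------
# neighbour joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    The pair minimising the Q-criterion is joined at each step; exact
    ties break on the lexicographically smallest (label, label) pair.
    Negative branch lengths are clamped to zero on the tree (the raw
    value is preserved on each node as ``raw_length``).  Requires at
    least three taxa.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbour joining requires >= 3 taxa")
    d = {frozenset((a, b)): dm[a, b] for a, b in itertools.combinations(labels, 2)}
    nodes: dict[str, TreeNode] = {}
    for lab in labels:
        nodes[lab] = TreeNode(name=lab)
    active = sorted(labels)
    counter = itertools.count()

    def set_length(node: TreeNode, length: float) -> None:
        node.raw_length = length
        node.length = max(0.0, length)

    while len(active) > 3:
        r = len(active)
        totals = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best_pair: Optional[tuple[str, str]] = None
        best_q = math.inf
        for a, b in itertools.combinations(active, 2):
            q = (r - 2) * d[frozenset((a, b))] - totals[a] - totals[b]
            key = tuple(sorted((a, b)))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12
                and (best_pair is None or key < best_pair)
            ):
                best_q, best_pair = q, key
        a, b = best_pair  # type: ignore[misc]
        dab = d[frozenset((a, b))]
        va = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        vb = dab - va
        new_label = f"__internal_{next(counter)}"
        parent = TreeNode(name=None)
        set_length(nodes[a], va)
        set_length(nodes[b], vb)
        parent.extend([nodes[a], nodes[b]])
        nodes[new_label] = parent
        active = [x for x in active if x not in (a, b)]
        for c in active:
            d[frozenset((new_label, c))] = 0.5 * (
                d[frozenset((a, c))] + d[frozenset((b, c))] - dab
            )
        active.append(new_label)
        active.sort()

    a, b, c = active
    dab, dac, dbc = (
        d[frozenset((a, b))], d[frozenset((a, c))], d[frozenset((b, c))]
    )
    root = TreeNode(name=None)
    set_length(nodes[a], 0.5 * (dab + dac - dbc))
    set_length(nodes[b], 0.5 * (dab + dbc - dac))
    set_length(nodes[c], 0.5 * (dac + dbc - dab))
    root.extend([nodes[a], nodes[b], nodes[c]])
    root.length = None
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each given as the
    smaller-side leaf set (ties by lexicographic order)."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    n = len(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if 2 <= len(side) <= n - 2:
            other = all_leaves - side
            if len(side) < len(other) or (
                len(side) == len(other) and tuple(sorted(side)) < tuple(sorted(other))
            ):
                out.add(side)
            else:
                out.add(other)
    return out


def edge_leaf_sets(tree: TreeNode, require_positive: bool = False) -> set[frozenset[str]]:
    """Leaf sets separable by one edge (both sides; trivial edges included).

    With ``require_positive`` only edges of positive length qualify, so a
    group of sequences identical to outsiders (zero-length separation,
    arbitrary topology) is never considered an exclusive clade.
    """
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if require_positive and not (node.length or 0) > 0:
            continue
        side = frozenset(leaf.name for leaf in node.tips()) or frozenset({node.name})
        out.add(side)
        out.add(all_leaves - side)
    return out


def bootstrap_supports(
    labels: Sequence[str],
    sequences: Sequence[str],
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float], int]:
    """Column-resampling bootstrap supports for the NJ tree.

    Columns are resampled with replacement per replicate, the tree is
    rebuilt, and each original-tree bipartition's support is the fraction
    of successful replicates containing it.  Replicates hitting K2P
    saturation are skipped (and counted; a warning is emitted).  Returns
    (original tree with supports attached, supports, n_skipped).
    """
    length = len(sequences[0])
    if length < 1:
        raise ValueError("alignment must have at least one column")
    arr = np.array([list(s) for s in sequences])
    tree = nj_tree(k2p_matrix(labels, sequences))
    target = bipartitions(tree)
    hits = {bip: 0 for bip in target}
    rng = np.random.default_rng(seed)
    skipped = 0
    done = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        reseqs = ["".join(row) for row in arr[:, cols]]
        try:
            rep_tree = nj_tree(k2p_matrix(labels, reseqs))
        except (SaturationError, ValueError):
            skipped += 1
            continue
        done += 1
        rep_bips = bipartitions(rep_tree)
        for bip in target:
            if bip in rep_bips:
                hits[bip] += 1
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicate(s) skipped (K2P saturation)")
    supports = {bip: (hits[bip] / done if done else float("nan")) for bip in target}
    # annotate internal nodes for newick output
    all_leaves = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        comp = all_leaves - side
        canon = min((side, comp), key=lambda s: (len(s), tuple(sorted(s))))
        if canon in supports:
            node.name = f"{supports[canon]:.2f}"
    return tree, supports, skipped


# ---------------------------------------------------------------------------
# discrimination assessment


@dataclass
class BarcodeResolution:
    resolved: set[str] = field(default_factory=set)
    unresolved: set[str] = field(default_factory=set)
    incorrectly_placed: set[str] = field(default_factory=set)
    single_sequence: set[str] = field(default_factory=set)  # flagged subset
    data_deficient: set[str] = field(default_factory=set)


@dataclass
class DiscriminationReport:
    per_barcode: dict[str, BarcodeResolution]
    combined_resolved: set[str]
    combined_unresolved: set[str]
    combined_incorrect: set[str]
    data_deficient: set[str]
    trees: dict[str, TreeNode] = field(default_factory=dict)

    @property
    def combined_resolution_fraction(self) -> float:
        n = (
            len(self.combined_resolved)
            + len(self.combined_unresolved)
            + len(self.combined_incorrect)
        )
        return len(self.combined_resolved) / n if n else float("nan")


def _assess_one_barcode(
    rows: Sequence[tuple[str, str, str]]
) -> tuple[BarcodeResolution, Optional[TreeNode]]:
    ids = [r[0] for r in rows]
    species_of = {r[0]: r[1] for r in rows}
    seqs = [r[2] for r in rows]
    res = BarcodeResolution()
    by_species: dict[str, set[str]] = {}
    for sid, sp in species_of.items():
        by_species.setdefault(sp, set()).add(sid)

    dm = k2p_matrix(ids, seqs)
    tree = nj_tree(dm) if len(ids) >= 3 else None
    clades = edge_leaf_sets(tree, require_positive=True) if tree is not None else set()

    for sp, members in by_species.items():
        if len(members) == 1:
            # no conspecific: nearest-neighbour rule only (flagged)
            sid = next(iter(members))
            others = [o for o in ids if o != sid]
            res.single_sequence.add(sp)
            if not others or min(dm[sid, o] for o in others) > 0:
                res.resolved.add(sp)
            else:
                res.unresolved.add(sp)
            continue
        # incorrectly placed: some sequence lies strictly nearer a
        # heterospecific than any conspecific
        misplaced = False
        for sid in members:
            d_con = min(dm[sid, o] for o in members if o != sid)
            hetero = [o for o in ids if species_of[o] != sp]
            if hetero and min(dm[sid, o] for o in hetero) < d_con:
                misplaced = True
                break
        if misplaced:
            res.incorrectly_placed.add(sp)
        elif tree is not None and frozenset(members) in clades:
            res.resolved.add(sp)
        else:
            res.unresolved.add(sp)
    return res, tree


def assess_discrimination(
    alignments: dict[str, Sequence[tuple[str, str, str]]]
) -> DiscriminationReport:
    """Score species resolvability per barcode and under the combined rule.

    ``alignments`` maps barcode name to rows of (sequence_id,
    species_name, aligned_sequence).  Per barcode a species is resolved
    iff its sequences form an exclusive clade of the NJ tree, and
    incorrectly placed iff one of its sequences is nearer a
    heterospecific than any conspecific.  Combined rule: a species is
    resolved overall iff at least one barcode resolves it and no barcode
    places it incorrectly.  Species absent from every barcode are
    data-deficient, not unresolved.
    """
    per_barcode: dict[str, BarcodeResolution] = {}
    trees: dict[str, TreeNode] = {}
    all_species: set[str] = set()
    for barcode, rows in alignments.items():
        if not rows:
            per_barcode[barcode] = BarcodeResolution()
            continue
        resolution, tree = _assess_one_barcode(rows)
        per_barcode[barcode] = resolution
        if tree is not None:
            trees[barcode] = tree
        all_species |= {r[1] for r in rows}

    combined_resolved: set[str] = set()
    combined_unresolved: set[str] = set()
    combined_incorrect: set[str] = set()
    for sp in all_species:
        statuses = [
            (
                "incorrect" if sp in r.incorrectly_placed
                else "resolved" if sp in r.resolved
                else "unresolved"
            )
            for r in per_barcode.values()
            if sp in (r.resolved | r.unresolved | r.incorrectly_placed)
        ]
        if "incorrect" in statuses:
            combined_incorrect.add(sp)
        elif "resolved" in statuses:
            combined_resolved.add(sp)
        else:
            combined_unresolved.add(sp)
    # per-barcode coverage bookkeeping for species missing everywhere
    for barcode, rows in alignments.items():
        present = {r[1] for r in rows}
        per_barcode[barcode].data_deficient = all_species - present
    return DiscriminationReport(
        per_barcode=per_barcode,
        combined_resolved=combined_resolved,
        combined_unresolved=combined_unresolved,
        combined_incorrect=combined_incorrect,
        data_deficient=set(),
        trees=trees,
    )


def write_report_tsv(report: DiscriminationReport, path) -> None:
    """Flat species x barcode status table."""
    barcodes = sorted(report.per_barcode)
    species = sorted(
        report.combined_resolved | report.combined_unresolved | report.combined_incorrect
    )
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(barcodes) + "\tcombined\n")
        for sp in species:
            row = [sp]
            for b in barcodes:
                r = report.per_barcode[b]
                if sp in r.incorrectly_placed:
                    row.append("incorrect")
                elif sp in r.resolved:
                    row.append("resolved")
                elif sp in r.unresolved:
                    row.append("unresolved")
                else:
                    row.append("absent")
            if sp in report.combined_incorrect:
                row.append("incorrect")
            elif sp in report.combined_resolved:
                row.append("resolved")
            else:
                row.append("unresolved")
            fh.write("\t".join(row) + "\n")
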