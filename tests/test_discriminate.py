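"""K2P distances, neighbour joining, bootstrap, and resolvability scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from verifid import simulate as sim
from verifid.discriminate import (
    SaturationError,
    assess_discrimination,
    bipartitions,
    bootstrap_supports,
    k2p_distance,
    k2p_matrix,
    nj_tree,
)

# ---------------------------------------------------------------------------
# sequence constructors realising exact (P, Q) site counts


def _pq_pair(n_sites, n_ts, n_tv):
    a = "A" * n_sites
    b = (
        "G" * n_ts                      # A->G transitions
        + "C" * n_tv                    # A->C transversions
        + "A" * (n_sites - n_ts - n_tv)
    )
    return a, b


class TestK2PDistance:
    def test_identical_sequences_have_zero_distance(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p01_q005(self):
        a, b = _pq_pair(100, 10, 5)
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.17024, abs=1e-4)

    def test_saturation_raises(self):
        a, b = _pq_pair(100, 50, 0)  # P = 0.5, Q = 0: log argument hits zero
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_ambiguous_sites_skipped_pairwise(self):
        # the N column is ignored; remaining 4 sites have 1 transition
        assert k2p_distance("NACGT", "AACGC") == k2p_distance("ACGT", "ACGC")

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("NNN", "ACG")
        with pytest.raises(ValueError):
            k2p_distance("ACG", "ACGT")

    @given(st.text(alphabet="ACGT", min_size=10, max_size=60), st.integers(0, 2**31 - 1))
    def test_symmetry_and_self_distance(self, seq, seed):
        rng = np.random.default_rng(seed)
        other = sim.mutate(seq, 0.1, rng)
        assert k2p_distance(seq, seq) == 0.0
        try:
            assert k2p_distance(seq, other) == pytest.approx(
                k2p_distance(other, seq)
            )
        except SaturationError:
            pass

    def test_matrix_agrees_with_scalar_function(self, rng):
        seqs = [sim.random_sequence(80, rng)]
        for _ in range(4):
            seqs.append(sim.mutate(seqs[0], 0.1, rng))
        labels = [f"s{i}" for i in range(5)]
        dm = k2p_matrix(labels, seqs)
        for i, j in itertools.combinations(range(5), 2):
            assert dm[labels[i], labels[j]] == pytest.approx(
                k2p_distance(seqs[i], seqs[j]), abs=1e-12
            )

    def test_low_divergence_estimate_tracks_simulated_rate(self):
        rng = np.random.default_rng(77)
        true_d = 0.03
        estimates = []
        for _ in range(200):
            a = sim.random_sequence(500, rng)
            estimates.append(k2p_distance(a, sim.mutate(a, true_d, rng)))
        sem = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - true_d) < 3 * sem + 1e-3


# ---------------------------------------------------------------------------
# neighbour joining


def _dm(labels, entries):
    n = len(labels)
    mat = np.zeros((n, n))
    for (i, j), v in entries.items():
        mat[i, j] = mat[j, i] = v
    return DistanceMatrix(mat, ids=labels)


class TestNJTree:
    def test_three_taxon_closed_form(self):
        dm = _dm(["A", "B", "C"], {(0, 1): 0.2, (0, 2): 0.3, (1, 2): 0.4})
        tree = nj_tree(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.tips()}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_four_taxon_additive_recovery_with_exact_lengths(self):
        # tree ((A:0.1,B:0.1):0.1,(C:0.1,D:0.1))
        dm = _dm(
            ["A", "B", "C", "D"],
            {(0, 1): 0.2, (2, 3): 0.2, (0, 2): 0.3, (0, 3): 0.3, (1, 2): 0.3, (1, 3): 0.3},
        )
        tree = nj_tree(dm)
        assert bipartitions(tree) == {frozenset({"A", "B"})}
        lengths = {leaf.name: leaf.length for leaf in tree.tips()}
        assert all(v == pytest.approx(0.1) for v in lengths.values())
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert internal == [pytest.approx(0.1)]

    def test_zero_matrix_gives_star_with_zero_lengths(self):
        dm = _dm(["A", "B", "C", "D"], {})
        tree = nj_tree(dm)
        assert all((leaf.length or 0) == 0 for leaf in tree.traverse(include_self=False))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"]))

    def test_matches_reference_nj_on_perturbed_matrices(self, rng):
        labels = [f"t{i}" for i in range(6)]
        for _ in range(20):
            base = rng.uniform(0.05, 0.5, size=(6, 6))
            mat = (base + base.T) / 2
            np.fill_diagonal(mat, 0)
            dm = DistanceMatrix(mat, ids=labels)
            ours = bipartitions(nj_tree(dm))
            theirs = bipartitions(skbio_nj(dm))
            assert ours == theirs

    def test_negative_lengths_clamped_but_preserved(self):
        dm = _dm(["A", "B", "C", "D"],
                 {(0, 1): 0.1, (0, 2): 0.4, (0, 3): 0.45, (1, 2): 0.15,
                  (1, 3): 0.2, (2, 3): 0.1})
        tree = nj_tree(dm)
        for node in tree.traverse(include_self=False):
            assert node.length >= 0
            assert node.length == max(0.0, node.raw_length)


# ---------------------------------------------------------------------------
# additive-tree oracle: brute force over all topologies, least-squares fit


def _enumerate_topologies(leaves):
    """All unrooted binary topologies as adjacency dicts (leaf insertion)."""
    base = {100: {0, 1, 2}, 0: {100}, 1: {100}, 2: {100}}
    trees = [base]
    nxt = 101
    for leaf in range(3, len(leaves)):
        grown = []
        for adj in trees:
            edges = {
                tuple(sorted((u, v))) for u in adj for v in adj[u]
            }
            for u, v in edges:
                new = {k: set(s) for k, s in adj.items()}
                new[u].discard(v)
                new[v].discard(u)
                internal = nxt + leaf * 50
                new[internal] = {u, v, leaf}
                new[u].add(internal)
                new[v].add(internal)
                new[leaf] = {internal}
                grown.append(new)
        trees = grown
    return trees


def _tree_bipartitions(adj, n_leaves):
    out = set()
    edges = {tuple(sorted((u, v))) for u in adj for v in adj[u]}
    for u, v in edges:
        seen, stack = {v}, [u]
        visited = {u, v}
        side = set()
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.add(x)
            for y in adj[x]:
                if y not in visited:
                    visited.add(y)
                    stack.append(y)
        if 2 <= len(side) <= n_leaves - 2:
            comp = frozenset(range(n_leaves)) - side
            out.add(min(frozenset(side), comp, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def _ls_rss(adj, n_leaves, dvec_index, dvec):
    edges = sorted({tuple(sorted((u, v))) for u in adj for v in adj[u]})
    eidx = {e: k for k, e in enumerate(edges)}
    rows = []
    for (i, j), r in dvec_index.items():
        # BFS path from i to j
        prev = {i: None}
        stack = [i]
        while stack:
            x = stack.pop()
            if x == j:
                break
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    stack.append(y)
        row = np.zeros(len(edges))
        node = j
        while prev[node] is not None:
            row[eidx[tuple(sorted((node, prev[node])))]] = 1
            node = prev[node]
        rows.append(row)
    A = np.array(rows)
    x, *_ = np.linalg.lstsq(A, dvec, rcond=None)
    return float(np.sum((A @ x - dvec) ** 2))


def brute_force_best_topology(dm):
    labels = list(dm.ids)
    n = len(labels)
    dvec_index = {}
    dvec = []
    for r, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        dvec_index[(i, j)] = r
        dvec.append(dm[labels[i], labels[j]])
    best = None
    for adj in _enumerate_topologies(labels):
        rss = _ls_rss(adj, n, dvec_index, np.array(dvec))
        bips = frozenset(
            frozenset(labels[i] for i in side)
            for side in _tree_bipartitions(adj, n)
        )
        if best is None or rss < best[0] - 1e-12:
            best = (rss, bips)
    return best[1]


def _random_additive_dm(n_leaves, rng):
    """Distances realised on a random binary tree with positive lengths."""
    topo = _enumerate_topologies(list(range(n_leaves)))
    adj = topo[int(rng.integers(0, len(topo)))]
    edges = sorted({tuple(sorted((u, v))) for u in adj for v in adj[u]})
    lengths = {e: float(rng.uniform(0.05, 0.3)) for e in edges}
    labels = [f"L{i}" for i in range(n_leaves)]
    mat = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        prev = {i: None}
        stack = [i]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    stack.append(y)
        d, node = 0.0, j
        while prev[node] is not None:
            d += lengths[tuple(sorted((node, prev[node])))]
            node = prev[node]
        mat[i, j] = mat[j, i] = d
    true_bips = frozenset(
        frozenset(labels[i] for i in side) for side in _tree_bipartitions(adj, n_leaves)
    )
    return DistanceMatrix(mat, ids=labels), true_bips


class TestNJOracle:
    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_additive_matrices_recover_generating_topology(self, n_leaves):
        rng = np.random.default_rng(404 + n_leaves)
        for _ in range(25):
            dm, true_bips = _random_additive_dm(n_leaves, rng)
            nj_bips = frozenset(bipartitions(nj_tree(dm)))
            assert nj_bips == true_bips
            assert brute_force_best_topology(dm) == true_bips


# ---------------------------------------------------------------------------
# bootstrap


class TestBootstrap:
    def test_cleanly_separated_clusters_get_full_support(self, rng):
        a = sim.random_sequence(120, rng)
        b = sim.mutate(a, 0.4, rng)
        labels = ["a1", "a2", "b1", "b2"]
        seqs = [a, a, b, b]
        tree, supports, skipped = bootstrap_supports(labels, seqs, 50, seed=1)
        assert skipped == 0
        assert supports[frozenset({"a1", "a2"})] == pytest.approx(1.0)

    def test_supports_are_proportions_and_reproducible(self, rng):
        base = sim.random_sequence(100, rng)
        labels = [f"s{i}" for i in range(5)]
        seqs = [sim.mutate(base, 0.1, np.random.default_rng(i)) for i in range(5)]
        _, s1, _ = bootstrap_supports(labels, seqs, 30, seed=9)
        _, s2, _ = bootstrap_supports(labels, seqs, 30, seed=9)
        assert s1 == s2
        assert all(0.0 <= v <= 1.0 for v in s1.values())


# ---------------------------------------------------------------------------
# resolvability scoring


def _alignment_rows(species_seqs, copies=2, within=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for sp, seq in species_seqs.items():
        for c in range(copies):
            rows.append((f"{sp}.{c}", sp, sim.mutate(seq, within, rng)))
    return rows


class TestAssessDiscrimination:
    def test_distinct_species_all_resolved(self, rng):
        base = sim.random_sequence(150, rng)
        species = {f"Sp{i}": sim.mutate(base, 0.1, np.random.default_rng(i)) for i in range(3)}
        report = assess_discrimination({"COI": _alignment_rows(species)})
        assert report.per_barcode["COI"].resolved == {"Sp0", "Sp1", "Sp2"}
        assert report.combined_resolved == {"Sp0", "Sp1", "Sp2"}

    def test_shared_barcode_unresolved_but_combined_resolved(self, rng):
        base = sim.random_sequence(150, rng)
        other = sim.mutate(base, 0.15, rng)
        shared = {"SpA": base, "SpB": base, "SpC": other}
        distinct = {
            "SpA": base,
            "SpB": sim.mutate(base, 0.12, np.random.default_rng(5)),
            "SpC": other,
        }
        report = assess_discrimination(
            {"12S": _alignment_rows(shared), "COI": _alignment_rows(distinct)}
        )
        assert {"SpA", "SpB"} <= report.per_barcode["12S"].unresolved
        assert {"SpA", "SpB"} <= report.per_barcode["COI"].resolved
        assert report.combined_resolved == {"SpA", "SpB", "SpC"}

    def test_matches_nearest_neighbour_oracle_on_synthetic_panel(self):
        cfg = sim.SimulationConfig(n_species=20, sequences_per_species=3, seed=31)
        refset = sim.generate_reference_set(cfg)
        alignments = sim.generate_barcode_alignments(cfg, refset)
        report = assess_discrimination(alignments)
        for barcode, rows in alignments.items():
            dm = k2p_matrix([r[0] for r in rows], [r[2] for r in rows])
            species_of = {r[0]: r[1] for r in rows}
            ids = [r[0] for r in rows]
            oracle_misplaced = set()
            for sid in ids:
                sp = species_of[sid]
                con = [o for o in ids if o != sid and species_of[o] == sp]
                het = [o for o in ids if species_of[o] != sp]
                if con and het and min(dm[sid, o] for o in het) < min(
                    dm[sid, o] for o in con
                ):
                    oracle_misplaced.add(sp)
            assert report.per_barcode[barcode].incorrectly_placed == oracle_misplaced

    def test_single_sequence_species_flagged_and_scored_by_distinctness(self, rng):
        base = sim.random_sequence(120, rng)
        rows = [
            ("solo.0", "Solo", base),
            ("twin1.0", "Twin", sim.mutate(base, 0.15, rng)),
            ("twin1.1", "Twin", sim.mutate(base, 0.15, np.random.default_rng(8))),
        ]
        report = assess_discrimination({"COI": rows})
        res = report.per_barcode["COI"]
        assert "Solo" in res.single_sequence
        assert "Solo" in res.resolved

    def test_identical_heterospecific_single_sequences_unresolved(self):
        seq = "ACGT" * 30
        distinct = sim.mutate(seq, 0.2, np.random.default_rng(3))
        rows = [("a.0", "SpA", seq), ("b.0", "SpB", seq), ("c.0", "SpC", distinct)]
        report = assess_discrimination({"COI": rows})
        res = report.per_barcode["COI"]
        assert {"SpA", "SpB"} <= res.unresolved
        assert report.combined_unresolved >= {"SpA", "SpB"}
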