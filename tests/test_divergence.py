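"""Counting estimator oracles, ancestral reconstruction, saturation filter."""

import itertools
import math

import numpy as np
import pytest

from omegascan.divergence import (
    DivergenceRecord,
    branch_divergence,
    count_differences,
    count_sites,
    jukes_cantor,
    pairwise_divergence,
    reconstruct_ancestors,
    saturation_filter,
    tree_divergence,
)
from omegascan.errors import OmegascanError
from omegascan.genetics import CodonAlignment


# --- independent oracles ----------------------------------------------------


def oracle_sites(codon, code):
    """Site fractions by direct neighbor enumeration (independent of the
    implementation's looping structure)."""
    S = N = 0.0
    for pos in range(3):
        viable = []
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if not code.is_stop(alt):
                viable.append(alt)
        if viable:
            syn = sum(code.translate(v) == code.translate(codon) for v in viable)
            S += syn / len(viable)
            N += (len(viable) - syn) / len(viable)
    return S, N


def oracle_differences(a, b, code):
    """Pathway averages by recursive enumeration of substitution orders."""

    def paths(cur, remaining):
        if not remaining:
            return [(0, 0)]
        out = []
        for pos in remaining:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                continue
            step = 0 if code.translate(nxt) == code.translate(cur) else 1
            for nd, sd in paths(nxt, [p for p in remaining if p != pos]):
                out.append((nd + step, sd + (1 - step)))
        return out

    diff = [i for i in range(3) if a[i] != b[i]]
    # recursive enumeration counts each ordering once per permutation prefix
    results = paths(a, diff)
    if results:
        return (
            sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results),
        )
    nd = sd = 0
    for pos in diff:
        alt = a[:pos] + b[pos] + a[pos + 1 :]
        if not code.is_stop(alt) and code.translate(alt) == code.translate(a):
            sd += 1
        else:
            nd += 1
    return float(nd), float(sd)


# --- site counting ----------------------------------------------------------


class TestCountSites:
    @pytest.mark.parametrize(
        "codon,S,N",
        [
            ("TTT", 1 / 3, 8 / 3),  # Phe: only 3rd-position T->C is silent
            ("CTT", 1.0, 2.0),  # Leu 4-fold box: 3rd position fully silent
            ("TGG", 0.0, 3.0),  # Trp: stop-producing neighbors leave the denominators
        ],
    )
    def test_hand_derived_codons(self, code, codon, S, N):
        sc = count_sites(codon, code)
        assert sc.S == pytest.approx(S)
        assert sc.N == pytest.approx(N)

    def test_matches_enumeration_for_all_sense_codons(self, code):
        for codon in code.sense_codons:
            S, N = oracle_sites(codon, code)
            sc = count_sites(codon, code)
            assert sc.S == pytest.approx(S, abs=1e-12)
            assert sc.N == pytest.approx(N, abs=1e-12)
            assert sc.S + sc.N <= 3.0 + 1e-12

    def test_stop_codon_rejected(self, code):
        with pytest.raises(OmegascanError):
            count_sites("TAA", code)


class TestCountDifferences:
    @pytest.mark.parametrize(
        "a,b,nd,sd",
        [
            ("TTT", "TTT", 0.0, 0.0),
            ("TTT", "TTC", 0.0, 1.0),  # Phe->Phe silent
            ("TTT", "GTA", 1.5, 0.5),  # two pathways averaged
        ],
    )
    def test_hand_derived_pairs(self, code, a, b, nd, sd):
        assert count_differences(a, b, code) == (nd, sd)

    def test_matches_pathway_enumeration_for_all_pairs(self, code):
        for a, b in itertools.product(code.sense_codons, repeat=2):
            got = count_differences(a, b, code)
            want = oracle_differences(a, b, code)
            assert got[0] == pytest.approx(want[0], abs=1e-12), (a, b)
            assert got[1] == pytest.approx(want[1], abs=1e-12), (a, b)

    def test_total_differences_preserved(self, code):
        for a, b in itertools.product(code.sense_codons, repeat=2):
            nd, sd = count_differences(a, b, code)
            k = sum(x != y for x, y in zip(a, b))
            assert nd + sd == pytest.approx(k, abs=1e-12)


# --- pairwise divergence ----------------------------------------------------


class TestPairwise:
    def test_identical_sequences_zero_divergence(self, code):
        aln = CodonAlignment("x", [("a", "ATGCTT" * 5), ("b", "ATGCTT" * 5)])
        rec = pairwise_divergence(aln, "a", "b", code)
        assert rec.dN == 0.0 and rec.dS == 0.0
        assert math.isnan(rec.omega)

    def test_jukes_cantor_closed_form(self):
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert math.isnan(jukes_cantor(0.8))

    def test_saturated_proportion_flagged_not_raised(self, code):
        # maximally diverged short pair: pS or pN can exceed 3/4
        aln = CodonAlignment("x", [("a", "TTA"), ("b", "CTG")])
        rec = pairwise_divergence(aln, "a", "b", code)
        assert rec is not None  # never an exception

    def test_all_columns_unusable_returns_none(self, code):
        aln = CodonAlignment("x", [("a", "---"), ("b", "ATG")])
        assert pairwise_divergence(aln, "a", "b", code) is None


# --- ancestral reconstruction ----------------------------------------------


def brute_force_min_changes(tree, tip_states):
    internal = [n for n in tree.postorder_nodes() if tree.children(n)]
    observed = sorted(set(tip_states.values()))
    best = math.inf
    for assign in itertools.product(observed, repeat=len(internal)):
        amap = dict(zip(internal, assign), **tip_states)
        cost = sum(1 for b in tree.branches if amap[b.parent_id] != amap[b.child_id])
        best = min(best, cost)
    return best


class TestReconstruction:
    def test_uniform_column_reconstructs_uniform(self, code, tree):
        aln = CodonAlignment("x", [(t, "AAA") for t in tree.taxa])
        states, mask, changes = reconstruct_ancestors(aln, tree, code)
        aaa = code.sense_codons.index("AAA")
        for node, arr in states.items():
            assert arr.tolist() == [aaa]
        assert changes.tolist() == [0]

    def test_two_state_split_places_single_change(self, code, tree):
        seqs = {
            "nigrodunni": "AAA",
            "arawakana": "AAA",
            "dunni": "GGG",
            "similis": "GGG",
            "innubila": "GGG",
        }
        aln = CodonAlignment("x", list(seqs.items()))
        states, _, changes = reconstruct_ancestors(aln, tree, code)
        aaa = code.sense_codons.index("AAA")
        ggg = code.sense_codons.index("GGG")
        assert states["arawakana+nigrodunni"].tolist() == [aaa]
        assert states["dunni+similis"].tolist() == [ggg]
        assert states["root"].tolist() == [ggg]
        assert changes.tolist() == [1]

    def test_fitch_count_equals_brute_force(self, code, tree):
        rng = np.random.default_rng(3)
        ncols = 150
        taxa = sorted(tree.taxa)
        tips = {t: rng.integers(0, 61, ncols) for t in taxa}
        for t in taxa:  # thin diversity so parsimony sets vary
            m = rng.random(ncols) < 0.5
            tips[t][m] = tips[taxa[0]][m]
        sense = code.sense_codons
        aln = CodonAlignment(
            "x", [(t, "".join(sense[i] for i in tips[t])) for t in taxa]
        )
        _, _, changes = reconstruct_ancestors(aln, tree, code)
        for col in range(ncols):
            want = brute_force_min_changes(tree, {t: int(tips[t][col]) for t in taxa})
            assert changes[col] == want


# --- branch and tree records ------------------------------------------------


class TestBranchDivergence:
    def test_zero_length_branches_give_zero_divergence(self, code, tree):
        aln = CodonAlignment("x", [(t, "ATGCTTAAG" * 10) for t in tree.taxa])
        for rec in branch_divergence(aln, tree, code):
            assert rec.dN == 0.0 and rec.dS == 0.0

    def test_branch_nd_sums_match_fitch_changes(self, code, small_study):
        """Raw per-branch differences, summed, equal the change set implied
        by the reconstruction classified codon-by-codon."""
        from omegascan.divergence import count_differences

        aln = small_study.alignments[0]
        tree = small_study.tree
        states, mask, _ = reconstruct_ancestors(aln, tree, code)
        sense = code.sense_codons
        want_nd = want_sd = 0.0
        for b in tree.branches:
            p, c = states[b.parent_id], states[b.child_id]
            for i in range(p.size):
                if p[i] != c[i]:
                    nd, sd = count_differences(sense[p[i]], sense[c[i]], code)
                    want_nd += nd
                    want_sd += sd
        recs = branch_divergence(aln, tree, code)
        assert sum(r.Nd for r in recs) == pytest.approx(want_nd)
        assert sum(r.Sd for r in recs) == pytest.approx(want_sd)

    def test_tree_record_sums_branches(self, code, small_study):
        aln = small_study.alignments[1]
        recs = branch_divergence(aln, small_study.tree, code)
        tr = tree_divergence(recs)
        assert tr.scope == "tree"
        assert tr.dN == pytest.approx(sum(r.dN for r in recs))
        assert tr.dS == pytest.approx(sum(r.dS for r in recs))
        assert tr.dS >= max(r.dS for r in recs)

    def test_single_branch_tree_record_equals_branch(self, code, small_study):
        recs = branch_divergence(small_study.alignments[2], small_study.tree, code)
        one = tree_divergence(recs[:1])
        assert one.dN == recs[0].dN and one.dS == recs[0].dS

    def test_sister_relabel_symmetry(self, code, tree):
        """Swapping nigrodunni and arawakana in both data and tree permutes
        branch records but changes no numeric value."""
        rng = np.random.default_rng(9)
        sense = code.sense_codons
        seqs = {t: "".join(sense[i] for i in rng.integers(0, 61, 60)) for t in tree.taxa}
        aln = CodonAlignment("x", sorted(seqs.items()))
        swapped = dict(seqs)
        swapped["nigrodunni"], swapped["arawakana"] = (
            seqs["arawakana"],
            seqs["nigrodunni"],
        )
        aln2 = CodonAlignment("x", sorted(swapped.items()))
        recs = {r.scope: r for r in branch_divergence(aln, tree, code)}
        recs2 = {r.scope: r for r in branch_divergence(aln2, tree, code)}
        swap = {"nigrodunni": "arawakana", "arawakana": "nigrodunni"}
        for scope, rec in recs.items():
            other = recs2[swap.get(scope, scope)]
            assert (rec.Nd, rec.Sd) == (other.Nd, other.Sd), scope


class TestSaturationFilter:
    def test_per_scope_removal(self):
        recs = [
            DivergenceRecord("g1", "dunni", 1, 1, 0.3, 1.2, 0.25, None),
            DivergenceRecord("g1", "similis", 1, 1, 0.1, 0.3, 0.33, None),
        ]
        kept, log = saturation_filter(recs)
        assert [(r.gene_id, r.scope) for r in kept] == [("g1", "similis")]
        assert log.iloc[0].to_dict() == {"gene_id": "g1", "scope": "dunni", "dS": 1.2}

    def test_infinite_threshold_keeps_all(self):
        recs = [DivergenceRecord("g1", "tree", 1, 1, 0.3, 5.0, 0.06, None)]
        kept, log = saturation_filter(recs, threshold=math.inf)
        assert len(kept) == 1 and log.empty

    def test_undefined_ds_treated_as_saturated(self):
        recs = [DivergenceRecord("g1", "tree", 1, 1, 0.3, float("nan"), float("nan"), None)]
        kept, log = saturation_filter(recs)
        assert not kept and len(log) == 1
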