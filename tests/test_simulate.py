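"""Codon rate matrix, jump-process evolution, and study-level generation."""

import numpy as np
import pytest
from scipy import stats

from omegascan.errors import ConfigurationError, ParameterError
from omegascan.genetics import Branch, SpeciesTree
from omegascan.simulate import (
    SimulationConfig,
    build_rate_matrix,
    evolve_sequence,
    simulate_study,
    write_study,
)


def single_branch_tree(length=1.0):
    b = Branch("tip", "root", "tip", length, frozenset({"tip"}))
    return SpeciesTree([b], ["tip"])


class TestRateMatrix:
    def test_rows_sum_to_zero_and_offdiag_nonneg(self, code):
        m = build_rate_matrix(2.0, 0.5)
        off = m.Q.copy()
        np.fill_diagonal(off, 0.0)
        assert (off >= 0).all()
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-12

    def test_multi_nucleotide_changes_have_zero_rate(self, code):
        m = build_rate_matrix(2.0, 0.5)
        sense = code.sense_codons
        for i, a in enumerate(sense):
            for j, b in enumerate(sense):
                if i != j and sum(x != y for x, y in zip(a, b)) >= 2:
                    assert m.Q[i, j] == 0.0

    def test_omega_zero_blocks_all_nonsynonymous(self, code):
        m = build_rate_matrix(2.0, 0.0)
        sense = code.sense_codons
        for i, a in enumerate(sense):
            for j, b in enumerate(sense):
                if i != j and code.translate(a) != code.translate(b):
                    assert m.Q[i, j] == 0.0

    def test_unit_mean_rate_normalization(self):
        for omega in (0.1, 1.0, 3.0):
            m = build_rate_matrix(2.0, omega)
            assert float(m.frequencies @ -np.diag(m.Q)) == pytest.approx(1.0)

    def test_neutral_kappa_one_uniform_rates_all_equal(self, code):
        """kappa=1, omega=1, uniform frequencies: every allowed exchange
        shares one rate (inspected exhaustively)."""
        m = build_rate_matrix(1.0, 1.0)
        off = m.Q[m.Q > 0]
        assert np.allclose(off, off.flat[0])

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            build_rate_matrix(0.0, 1.0)
        with pytest.raises(ParameterError):
            build_rate_matrix(2.0, -0.5)


class TestEvolveSequence:
    def test_zero_length_branch_copies_root(self, tree):
        m = build_rate_matrix(2.0, 0.2)
        frozen = tree.with_lengths(0.0)
        root = np.arange(50, dtype=np.int64) % 61
        states = evolve_sequence(root, frozen, {b.branch_id: m for b in frozen.branches}, 1)
        for node, arr in states.items():
            assert (arr == root).all()

    def test_omega_zero_preserves_protein(self, code, tree):
        m = build_rate_matrix(2.0, 0.0)
        root = np.arange(100, dtype=np.int64) % 61
        states = evolve_sequence(root, tree, {b.branch_id: m for b in tree.branches}, 2)
        sense = code.sense_codons
        prot = [code.translate(sense[i]) for i in root]
        for node, arr in states.items():
            assert [code.translate(sense[i]) for i in arr] == prot

    def test_missing_branch_matrix_is_configuration_error(self, tree):
        with pytest.raises(ConfigurationError):
            evolve_sequence(np.zeros(3, dtype=np.int64), tree, {}, 0)

    def test_substitution_count_matches_poisson_oracle(self):
        """Single branch, unit-rate matrix: realized substitutions per codon
        agree with the Poisson expectation length x rate within 3 sd."""
        t, n = 0.05, 10_000
        tree = single_branch_tree(t)
        m = build_rate_matrix(2.0, 1.0)
        rng = np.random.default_rng(4)
        root = rng.integers(0, 61, n)
        states = evolve_sequence(root.astype(np.int64), tree, {"tip": m}, 5)
        # count nucleotide differences as a proxy for events (multiple hits
        # at these depths are ~0.1% of sites)
        from omegascan import standard_code

        sense = standard_code().sense_codons
        diffs = sum(
            sum(x != y for x, y in zip(sense[a], sense[b]))
            for a, b in zip(root, states["tip"])
        )
        lam = t * n
        assert abs(diffs - lam) < 3 * np.sqrt(lam) + 0.01 * lam

    def test_stationarity_of_codon_frequencies(self):
        """Evolving a long stationary sequence for time 1 leaves codon
        frequencies at their input values (chi-square goodness of fit)."""
        n = 30_000
        tree = single_branch_tree(1.0)
        m = build_rate_matrix(2.0, 0.3)
        rng = np.random.default_rng(6)
        root = rng.integers(0, 61, n).astype(np.int64)
        states = evolve_sequence(root, tree, {"tip": m}, 7)
        counts = np.bincount(states["tip"], minlength=61)
        chi2, p = stats.chisquare(counts, f_exp=np.full(61, n / 61))
        assert p > 0.01

    def test_determinism_same_seed_same_output(self, tree):
        m = build_rate_matrix(2.0, 0.2)
        mats = {b.branch_id: m for b in tree.branches}
        root = np.arange(200, dtype=np.int64) % 61
        s1 = evolve_sequence(root, tree, mats, 42)
        s2 = evolve_sequence(root, tree, mats, 42)
        assert all((s1[k] == s2[k]).all() for k in s1)


class TestSimulateStudy:
    def test_empty_study_is_valid(self, tmp_path):
        cfg = SimulationConfig(n_genes=0, category_sizes={}, seed=0)
        study = simulate_study(cfg)
        assert study.alignments == [] and study.annotations == []
        write_study(study, tmp_path)  # empty but well-formed outputs
        assert (tmp_path / "annotations.tsv").exists()

    def test_category_bookkeeping_in_truth_table(self):
        cfg = SimulationConfig(
            n_genes=120,
            category_sizes={"SFP": 50},
            branch_multipliers={"SFP": {"nigrodunni": 10.0, "arawakana": 10.0}},
            saturation_fraction=0.0,
            seed=1,
        )
        study = simulate_study(cfg)
        truth = study.truth
        base = truth.groupby("gene_id")["true_omega"].min()
        elevated = truth[truth.true_omega > 5 * truth.gene_id.map(base)]
        assert set(elevated.branch) == {"nigrodunni", "arawakana"}
        assert elevated.gene_id.nunique() == 50
        sfp = {a.gene_id for a in study.annotations if "SFP" in a.categories}
        assert set(elevated.gene_id) == sfp

    def test_oversized_categories_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=10, category_sizes={"SFP": 50})

    def test_neighborhood_density_supports_background_analysis(self):
        """Default layout: the median gene has >= 10 neighbors within 100 kbp."""
        cfg = SimulationConfig(
            n_genes=2000, category_sizes={}, branch_multipliers={}, seed=2
        )
        study = simulate_study(cfg)
        starts = {}
        for a in study.annotations:
            starts.setdefault(a.chromosome, []).append(a.start)
        counts = []
        for a in study.annotations:
            arr = np.asarray(starts[a.chromosome])
            counts.append(int((np.abs(arr - a.start) <= 100_000).sum()) - 1)
        assert np.median(counts) >= 10

    def test_truth_table_expected_ds_consistency(self, code):
        """Expected dS = branch length x synonymous rate fraction of the
        gene's branch matrix, recomputed independently."""
        cfg = SimulationConfig(
            n_genes=5, category_sizes={}, branch_multipliers={},
            saturation_fraction=0.0, seed=3,
        )
        study = simulate_study(cfg)
        sense = code.sense_codons
        syn = np.zeros((61, 61), dtype=bool)
        for i, a in enumerate(sense):
            for j, b in enumerate(sense):
                syn[i, j] = code.translate(a) == code.translate(b)
        lengths = {b.branch_id: b.length for b in study.tree.branches}
        for gid, group in study.truth.groupby("gene_id"):
            # per-branch expected dS = branch length x gene multiplier x
            # synonymous rate fraction; the unknown multiplier must be one
            # shared constant across all branches of the gene
            mults = []
            for row in group.itertuples():
                mm = build_rate_matrix(cfg.kappa, row.true_omega)
                off = mm.Q.copy()
                np.fill_diagonal(off, 0.0)
                frac = float(mm.frequencies @ (off * syn).sum(axis=1))
                mults.append(row.expected_dS / (lengths[row.branch] * frac))
            assert np.ptp(mults) < 1e-9 * max(mults)
            assert 0.05 < mults[0] < 20.0  # gamma multiplier, mean 1

    def test_saturated_genes_exceed_ds_one(self):
        cfg = SimulationConfig(
            n_genes=100, category_sizes={}, branch_multipliers={},
            saturation_fraction=0.1, seed=4,
        )
        study = simulate_study(cfg)
        per_gene_max = study.truth.groupby("gene_id")["expected_dS"].max()
        assert (per_gene_max > 1.0).sum() >= 5

    def test_byte_identical_outputs_for_identical_config(self, tmp_path):
        cfg = dict(n_genes=15, category_sizes={"SFP": 3}, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study(simulate_study(SimulationConfig(**cfg)), d1)
        write_study(simulate_study(SimulationConfig(**cfg)), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
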