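"""Synthetic study generator: codon alignments evolved on the species tree.

The generative model is a 61-state codon substitution process in the
Goldman–Yang parameterization: the instantaneous rate from codon i to codon
j is zero unless they differ at exactly one nucleotide, and otherwise
proportional to

    pi_j * kappa^[transition] * omega^[nonsynonymous],

globally rescaled so the stationary expected substitution rate is one per
codon per unit branch length. Sequences evolve along each branch by
explicit jump-process (Gillespie) sampling, so internal-node sequences are
available as ground truth for ancestral-reconstruction tests.

A simulated study mirrors the statistical shape of a dunni-group ortholog
set: thousands of genes with heterogeneous synonymous divergence (via a
gamma-distributed per-gene rate multiplier), gene-specific baseline omega
drawn from a log-normal law centered well below 1, designated fast
categories with branch-specific omega multipliers (a seminal-fluid-protein
-like category elevated on both nigrodunni and arawakana, a Toll-like
category on arawakana only, a JAK-STAT-like category on nigrodunni only),
genes laid out on chromosomes densely enough that 100 kbp neighborhoods
hold tens of genes, and a small minority of genes pushed past dS
saturation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .genetics import (
    CodonAlignment,
    GeneAnnotation,
    GeneticCode,
    SpeciesTree,
    standard_code,
    write_annotations,
    write_codon_alignment,
)

# ---------------------------------------------------------------------------
# Rate matrix
# ---------------------------------------------------------------------------


@dataclass
class CodonRateMatrix:
    """Normalized 61x61 instantaneous rate matrix over sense codons."""

    Q: np.ndarray
    kappa: float
    omega: float
    frequencies: np.ndarray

    @property
    def synonymous_fraction(self) -> float:
        """Fraction of the stationary substitution rate that is synonymous."""
        return self._syn_fraction

    def __post_init__(self) -> None:
        code = standard_code()
        syn = _structure(code).synonymous
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        total = float(self.frequencies @ off.sum(axis=1))
        syn_rate = float(self.frequencies @ (off * syn).sum(axis=1))
        self._syn_fraction = syn_rate / total if total > 0 else 0.0


@dataclass(frozen=True)
class _CodonStructure:
    single_nt: np.ndarray  # bool (61,61): differ at exactly one position
    transition: np.ndarray  # bool: that one difference is a transition
    synonymous: np.ndarray  # bool: same amino acid


_STRUCTURE_CACHE: dict[int, _CodonStructure] = {}


def _structure(code: GeneticCode) -> _CodonStructure:
    key = id(code)
    if key not in _STRUCTURE_CACHE:
        sense = code.sense_codons
        n = len(sense)
        single = np.zeros((n, n), dtype=bool)
        trans = np.zeros((n, n), dtype=bool)
        syn = np.zeros((n, n), dtype=bool)
        purines = {"A", "G"}
        for i, a in enumerate(sense):
            for j, b in enumerate(sense):
                diffs = [k for k in range(3) if a[k] != b[k]]
                if len(diffs) == 1:
                    single[i, j] = True
                    k = diffs[0]
                    trans[i, j] = (a[k] in purines) == (b[k] in purines)
                syn[i, j] = code.translate(a) == code.translate(b)
        _STRUCTURE_CACHE[key] = _CodonStructure(single, trans, syn)
    return _STRUCTURE_CACHE[key]


def build_rate_matrix(
    kappa: float,
    omega: float,
    frequencies: np.ndarray | None = None,
    code: GeneticCode | None = None,
) -> CodonRateMatrix:
    """Goldman–Yang-style codon rate matrix, normalized to unit mean rate."""
    code = code or standard_code()
    n = len(code.sense_codons)
    if kappa <= 0:
        raise ParameterError(f"kappa must be > 0, got {kappa}")
    if omega < 0:
        raise ParameterError(f"omega must be >= 0, got {omega}")
    if frequencies is None:
        frequencies = np.full(n, 1.0 / n)
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.shape != (n,) or (frequencies < 0).any():
        raise ParameterError("frequencies must be a nonnegative 61-vector")
    if abs(frequencies.sum() - 1.0) > 1e-9:
        raise ParameterError("codon frequencies must sum to 1 within 1e-9")
    st = _structure(code)
    Q = np.where(st.single_nt, frequencies[None, :], 0.0)
    Q = Q * np.where(st.transition, kappa, 1.0)
    Q = Q * np.where(st.synonymous, 1.0, omega)
    np.fill_diagonal(Q, 0.0)
    rates = Q.sum(axis=1)
    mean_rate = float(frequencies @ rates)
    if mean_rate > 0:
        Q = Q / mean_rate
        rates = rates / mean_rate
    Q[np.diag_indices(n)] = -rates
    return CodonRateMatrix(Q=Q, kappa=kappa, omega=omega, frequencies=frequencies)


# ---------------------------------------------------------------------------
# Jump-process evolution along the tree
# ---------------------------------------------------------------------------


def _evolve_branch(
    seq: np.ndarray, matrix: CodonRateMatrix, t: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve integer-coded codons for time t by Gillespie sampling."""
    out = seq.copy()
    n = out.size
    if t <= 0 or n == 0:
        return out
    exit_rates = -np.diag(matrix.Q)
    remaining = np.full(n, float(t))
    active = np.arange(n)
    while active.size:
        rates = exit_rates[out[active]]
        waits = np.where(rates > 0, rng.exponential(1.0, size=active.size) / np.maximum(rates, 1e-300), np.inf)
        jump = waits < remaining[active]
        jumpers = active[jump]
        remaining[jumpers] -= waits[jump]
        for idx in jumpers:
            row = matrix.Q[out[idx]].copy()
            row[out[idx]] = 0.0
            probs = row / row.sum()
            out[idx] = rng.choice(probs.size, p=probs)
        active = jumpers
    return out


def evolve_sequence(
    root: np.ndarray | Sequence[str],
    tree: SpeciesTree,
    matrices: Mapping[str, CodonRateMatrix],
    rng: np.random.Generator | int,
    code: GeneticCode | None = None,
) -> dict[str, np.ndarray]:
    """Evolve a root codon sequence down every branch of the tree.

    ``root`` is either an integer-coded array (sense-codon ranks) or a list
    of codon strings. Returns node id → integer-coded sequence for every
    node, including internal nodes and the root itself.
    """
    code = code or standard_code()
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if not isinstance(root, np.ndarray):
        index = {c: i for i, c in enumerate(code.sense_codons)}
        try:
            root = np.array([index[c] for c in root], dtype=np.int64)
        except KeyError as exc:
            raise ParameterError(f"root contains non-sense codon {exc.args[0]!r}") from None
    states: dict[str, np.ndarray] = {"root": np.asarray(root, dtype=np.int64)}
    for branch in tree.preorder_branches():
        if branch.branch_id not in matrices:
            raise ConfigurationError(f"no rate matrix assigned to branch {branch.branch_id!r}")
        states[branch.child_id] = _evolve_branch(
            states[branch.parent_id], matrices[branch.branch_id], branch.length, rng
        )
    return states


def states_to_alignment(
    gene_id: str,
    states: Mapping[str, np.ndarray],
    tree: SpeciesTree,
    code: GeneticCode | None = None,
) -> CodonAlignment:
    code = code or standard_code()
    sense = code.sense_codons
    seqs = [
        (taxon, "".join(sense[i] for i in states[taxon]))
        for taxon in sorted(tree.taxa)
    ]
    return CodonAlignment(gene_id=gene_id, sequences=seqs)


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------

#: default branch-specific omega multipliers for the designated fast
#: categories: SFP-like elevated on both nigrodunni and arawakana terminal
#: branches, Toll-like on arawakana only, JAK-STAT-like on nigrodunni only.
DEFAULT_BRANCH_MULTIPLIERS: dict[str, dict[str, float]] = {
    "SFP": {"nigrodunni": 10.0, "arawakana": 10.0},
    "Toll": {"arawakana": 10.0},
    "JAK-STAT": {"nigrodunni": 10.0},
}

DEFAULT_CATEGORY_SIZES: dict[str, int] = {"SFP": 50, "Toll": 40, "JAK-STAT": 40}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic study.

    Defaults describe the study-shaped baseline: 2000 genes of 100–500
    codons, transition/transversion ratio kappa = 2, log-normal baseline
    omega with median 0.15 (log-sd 0.8), gamma rate heterogeneity across
    genes, ~12 kbp mean gene spacing on 30 Mbp chromosomes, and 3% of genes
    pushed past dS saturation.
    """

    n_genes: int = 2000
    n_codons_range: tuple[int, int] = (100, 500)
    kappa: float = 2.0
    omega_distribution: tuple[str, tuple[float, ...]] = ("lognormal", (0.15, 0.8))
    branch_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BRANCH_MULTIPLIERS.items()}
    )
    codon_frequencies: np.ndarray | None = None
    tree: SpeciesTree | None = None
    chromosomes: tuple[tuple[str, int], ...] = (
        ("2L", 30_000_000),
        ("2R", 30_000_000),
        ("3L", 30_000_000),
    )
    gene_spacing: float = 12_000.0
    category_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SIZES)
    )
    rate_heterogeneity_shape: float = 3.0
    saturation_fraction: float = 0.03
    saturation_scale: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if sum(self.category_sizes.values()) > self.n_genes and self.n_genes > 0:
            raise ConfigurationError("category sizes exceed n_genes")
        if not (0.0 <= self.saturation_fraction <= 1.0):
            raise ConfigurationError("saturation_fraction must be in [0, 1]")
        if self.codon_frequencies is not None:
            f = np.asarray(self.codon_frequencies, dtype=float)
            if abs(f.sum() - 1.0) > 1e-9:
                raise ConfigurationError("codon frequencies must sum to 1 within 1e-9")

    def resolved_tree(self) -> SpeciesTree:
        return self.tree if self.tree is not None else SpeciesTree.default()


def _draw_omega(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    law, params = cfg.omega_distribution
    if law == "lognormal":
        median, log_sd = params
        return float(median * math.exp(rng.normal(0.0, log_sd)))
    if law == "constant":
        return float(params[0])
    raise ConfigurationError(f"unknown omega distribution {law!r}")


@dataclass
class StudyData:
    alignments: list[CodonAlignment]
    annotations: list[GeneAnnotation]
    truth: pd.DataFrame  # gene_id, branch, true_omega, expected_dS
    internal_states: dict[str, dict[str, np.ndarray]]  # gene_id -> node -> codes
    tree: SpeciesTree


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate alignments, annotations and the truth table for one study.

    The truth table records, for every gene and branch, the realized true
    omega on that branch and the expected synonymous divergence
    (branch length x gene rate multiplier x synonymous rate fraction of the
    branch's matrix, in synonymous substitutions per codon).
    """
    rng = np.random.default_rng(config.seed)
    code = standard_code()
    tree = config.resolved_tree()
    n = config.n_genes

    # category assignment: first genes get categories, then shuffle ids later
    gene_ids = [f"g{i:05d}" for i in range(n)]
    category_of: dict[str, str] = {}
    cursor = 0
    order = rng.permutation(n)
    for cat, size in config.category_sizes.items():
        for k in range(size):
            category_of[gene_ids[order[cursor + k]]] = cat
        cursor += size

    saturated = set()
    if config.saturation_fraction > 0 and n > 0:
        n_sat = int(round(config.saturation_fraction * n))
        # saturate only plain background genes so category signal stays intact
        plain = [g for g in gene_ids if g not in category_of]
        saturated = set(rng.choice(plain, size=min(n_sat, len(plain)), replace=False))

    # chromosome layout: exponential gaps, sequential fill
    annotations: list[GeneAnnotation] = []
    chrom_iter = iter(config.chromosomes)
    chrom_name, chrom_len = next(chrom_iter, ("chr1", 10**9))
    pos = 0
    for gid in gene_ids:
        pos += int(rng.exponential(config.gene_spacing)) + 1
        if pos > chrom_len:
            nxt = next(chrom_iter, None)
            if nxt is None:
                raise ConfigurationError("chromosomes too short for n_genes at this spacing")
            chrom_name, chrom_len = nxt
            pos = int(rng.exponential(config.gene_spacing)) + 1
        cats = frozenset([category_of[gid]]) if gid in category_of else frozenset()
        annotations.append(GeneAnnotation(gid, chrom_name, pos, cats))

    alignments: list[CodonAlignment] = []
    truth_rows: list[dict] = []
    internal: dict[str, dict[str, np.ndarray]] = {}
    freqs = (
        np.asarray(config.codon_frequencies, dtype=float)
        if config.codon_frequencies is not None
        else np.full(len(code.sense_codons), 1.0 / len(code.sense_codons))
    )
    matrix_cache: dict[float, CodonRateMatrix] = {}

    def matrix_for(omega: float) -> CodonRateMatrix:
        key = round(omega, 12)
        if key not in matrix_cache:
            matrix_cache[key] = build_rate_matrix(config.kappa, omega, freqs, code)
        return matrix_cache[key]

    lo, hi = config.n_codons_range
    for gid in gene_ids:
        n_codons = int(rng.integers(lo, hi + 1))
        baseline = _draw_omega(config, rng)
        rate_mult = float(rng.gamma(config.rate_heterogeneity_shape, 1.0 / config.rate_heterogeneity_shape))
        if gid in saturated:
            # scale so expected dS tops 1 on at least one branch (contract),
            # whatever the gene's baseline rate multiplier drew
            max_len = max(b.length for b in tree.branches)
            syn_frac = matrix_for(baseline).synonymous_fraction
            required = 1.2 / (max_len * syn_frac)
            rate_mult = max(rate_mult * config.saturation_scale, required)
        gene_tree = tree.with_lengths(rate_mult)
        mults = config.branch_multipliers.get(category_of.get(gid, ""), {})
        matrices = {}
        for br in gene_tree.branches:
            omega_b = baseline * mults.get(br.branch_id, 1.0)
            matrices[br.branch_id] = matrix_for(omega_b)
        root_seq = rng.choice(len(code.sense_codons), size=n_codons, p=freqs)
        states = evolve_sequence(root_seq.astype(np.int64), gene_tree, matrices, rng, code)
        alignments.append(states_to_alignment(gid, states, gene_tree, code))
        internal[gid] = states
        for br in gene_tree.branches:
            m = matrices[br.branch_id]
            truth_rows.append(
                {
                    "gene_id": gid,
                    "branch": br.branch_id,
                    "true_omega": m.omega,
                    "expected_dS": br.length * m.synonymous_fraction,
                }
            )

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "branch", "true_omega", "expected_dS"])
    return StudyData(
        alignments=alignments,
        annotations=annotations,
        truth=truth,
        internal_states=internal,
        tree=tree,
    )


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write alignments/, annotations.tsv, tree.nwk and truth.tsv."""
    outdir = Path(outdir)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    for stale in aln_dir.glob("*.fasta"):  # rerunning into the same directory
        stale.unlink()
    for aln in study.alignments:
        write_codon_alignment(aln, aln_dir / f"{aln.gene_id}.fasta")
    write_annotations(study.annotations, outdir / "annotations.tsv")
    (outdir / "tree.nwk").write_text(study.tree.to_newick() + "\n")
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
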