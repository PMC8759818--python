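"""Per-gene dN, dS and dN/dS — pairwise, per branch, and whole-tree.

The estimator is a counting method in the Nei–Gojobori tradition: fractional
synonymous/nonsynonymous *sites* are tallied per codon by enumerating the
nine single-nucleotide neighbors, fractional synonymous/nonsynonymous
*differences* between two codons are averaged over all orderings of the
single-nucleotide steps between them (pathways through stop codons are
excluded), and the raw proportions are corrected for multiple hits with the
Jukes–Cantor transform d = -(3/4)·ln(1 - (4/3)p).

Branch-specific rates come from Fitch parsimony: ancestral codon states are
reconstructed on the fixed species topology, and differences are counted
between the parent-node and child-node sequence of each branch.

Genes whose dS exceeds a saturation threshold (default 1.0) are removed
from the affected analysis scope, mirroring the practice of excluding
saturated genes whose dN/dS would be unreliable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import OmegascanError
from .genetics import CodonAlignment, GeneticCode, SpeciesTree, standard_code

log = logging.getLogger(__name__)

TREE_SCOPE = "tree"

#: flags attached to DivergenceRecord
FLAG_DS_SATURATED = "dS_saturated"  # pS >= 3/4, correction undefined
FLAG_DN_SATURATED = "dN_saturated"
FLAG_OMEGA_MISSING = "omega_missing"  # dS == 0 or undefined


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous (S) and nonsynonymous (N) site totals."""

    S: float
    N: float
    usable_codons: int


@dataclass
class DivergenceRecord:
    gene_id: str
    scope: str
    Nd: float
    Sd: float
    dN: float  # NaN when undefined
    dS: float
    omega: float  # NaN when missing/undefined
    site_counts: SiteCounts
    flags: tuple[str, ...] = ()

    @property
    def omega_defined(self) -> bool:
        return not math.isnan(self.omega)


# ---------------------------------------------------------------------------
# Codon-level counting tables
# ---------------------------------------------------------------------------


def _neighbors(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for nt in "ACGT":
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return out


def count_sites(codon: str, code: GeneticCode | None = None) -> SiteCounts:
    """Fractional synonymous/nonsynonymous sites of a single sense codon.

    Each of the three positions contributes a synonymous fraction equal to
    (synonymous single-nucleotide changes at that position) / (non-stop
    single-nucleotide changes at that position); nonsynonymous analogous.
    A position whose three changes all produce stops contributes zero to
    both totals.
    """
    code = code or standard_code()
    if not code.is_sense(codon):
        raise OmegascanError(f"count_sites requires a sense codon, got {codon!r}")
    aa = code.translate(codon)
    S = N = 0.0
    for pos in range(3):
        changes = [codon[:pos] + nt + codon[pos + 1 :] for nt in "ACGT" if nt != codon[pos]]
        viable = [c for c in changes if not code.is_stop(c)]
        if not viable:
            continue
        syn = sum(1 for c in viable if code.translate(c) == aa)
        S += syn / len(viable)
        N += (len(viable) - syn) / len(viable)
    return SiteCounts(S=S, N=N, usable_codons=1)


def count_differences(
    codon_a: str, codon_b: str, code: GeneticCode | None = None
) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) differences between two codons.

    Averages over all orderings of the single-nucleotide steps from
    ``codon_a`` to ``codon_b``, dropping any pathway that passes through a
    stop codon. If every pathway is blocked by stops, each differing
    position is classified by substituting it in isolation into ``codon_a``
    (stop-producing isolated changes count as nonsynonymous, the
    conservative default).
    """
    code = code or standard_code()
    for c in (codon_a, codon_b):
        if not code.is_sense(c):
            raise OmegascanError(f"count_differences requires sense codons, got {c!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    path_nd = []
    path_sd = []
    for order in permutations(diff):
        cur = codon_a
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(nxt) == code.translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            path_nd.append(nd)
            path_sd.append(sd)
    if path_nd:
        return (sum(path_nd) / len(path_nd), sum(path_sd) / len(path_sd))
    # all pathways blocked: classify each differing position in isolation
    nd = sd = 0
    for pos in diff:
        alt = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
        if not code.is_stop(alt) and code.translate(alt) == code.translate(codon_a):
            sd += 1
        else:
            nd += 1
    return (float(nd), float(sd))


@lru_cache(maxsize=None)
def counting_tables(code: GeneticCode | None = None):
    """Vectorized lookup tables over the 61 sense codons.

    Returns (s_sites, n_sites, ND, SD): per-codon fractional site vectors
    of shape (61,), and 61×61 pathway-averaged difference matrices indexed
    by lexicographic sense-codon rank.
    """
    code = code or standard_code()
    sense = code.sense_codons
    n = len(sense)
    s_sites = np.empty(n)
    n_sites = np.empty(n)
    for i, c in enumerate(sense):
        sc = count_sites(c, code)
        s_sites[i], n_sites[i] = sc.S, sc.N
    ND = np.zeros((n, n))
    SD = np.zeros((n, n))
    for i, a in enumerate(sense):
        for j, b in enumerate(sense):
            if i == j:
                continue
            nd, sd = count_differences(a, b, code)
            ND[i, j], SD[i, j] = nd, sd
    return s_sites, n_sites, ND, SD


# ---------------------------------------------------------------------------
# Divergence from encoded sequences
# ---------------------------------------------------------------------------


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p); NaN for p >= 3/4."""
    if p < 0:
        raise ValueError(p)
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _record_from_counts(
    gene_id: str, scope: str, Nd: float, Sd: float, S: float, N: float, usable: int
) -> DivergenceRecord:
    flags: list[str] = []
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    dN = jukes_cantor(pN)
    dS = jukes_cantor(pS)
    if math.isnan(dN):
        flags.append(FLAG_DN_SATURATED)
    if math.isnan(dS):
        flags.append(FLAG_DS_SATURATED)
    if math.isnan(dS) or dS == 0.0 or math.isnan(dN):
        omega = float("nan")
        flags.append(FLAG_OMEGA_MISSING)
    else:
        omega = dN / dS
    return DivergenceRecord(
        gene_id=gene_id,
        scope=scope,
        Nd=Nd,
        Sd=Sd,
        dN=dN,
        dS=dS,
        omega=omega,
        site_counts=SiteCounts(S=S, N=N, usable_codons=usable),
        flags=tuple(flags),
    )


def _pair_counts(a: np.ndarray, b: np.ndarray, code: GeneticCode):
    s_sites, n_sites, ND, SD = counting_tables(code)
    Nd = float(ND[a, b].sum())
    Sd = float(SD[a, b].sum())
    S = float((s_sites[a] + s_sites[b]).sum() / 2.0)
    N = float((n_sites[a] + n_sites[b]).sum() / 2.0)
    return Nd, Sd, S, N


def pairwise_divergence(
    alignment: CodonAlignment,
    taxon_a: str,
    taxon_b: str,
    code: GeneticCode | None = None,
) -> DivergenceRecord | None:
    """dN/dS between two taxa of one alignment over its usable columns.

    Returns None (with a logged warning) when no usable column exists.
    """
    code = code or standard_code()
    enc = alignment.encoded(code)
    a, b = enc[taxon_a], enc[taxon_b]
    mask = np.ones(alignment.n_codons, dtype=bool)
    for arr in enc.values():
        mask &= arr >= 0
    if not mask.any():
        log.warning("gene %s: no usable codon columns, skipped", alignment.gene_id)
        return None
    Nd, Sd, S, N = _pair_counts(a[mask], b[mask], code)
    return _record_from_counts(
        alignment.gene_id, f"{taxon_a}|{taxon_b}", Nd, Sd, S, N, int(mask.sum())
    )


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral reconstruction (bitmask-vectorized)
# ---------------------------------------------------------------------------

_BIT_INDEX_DTYPE = np.int64


def _lowest_set_bit_index(masks: np.ndarray) -> np.ndarray:
    low = masks & (~masks + np.uint64(1))
    # exact for bits 0..60: float64 represents these powers of two exactly
    return np.log2(low.astype(np.float64)).astype(_BIT_INDEX_DTYPE)


def reconstruct_ancestors(
    alignment: CodonAlignment,
    tree: SpeciesTree,
    code: GeneticCode | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Fitch-parsimony codon states at every node, over usable columns.

    Returns ``(states, mask, changes)`` where ``states`` maps node id →
    integer codon array of length n_usable (tips included), ``mask`` is the
    usable-column mask over the original alignment, and ``changes`` is the
    per-column minimum change count.

    Tie-breaking is deterministic: in the top-down pass a node keeps its
    parent's state when that state is in its Fitch set, otherwise it takes
    the lexicographically smallest codon of its set; the root takes the
    smallest codon of its set.
    """
    code = code or standard_code()
    enc = alignment.encoded(code)
    mask = np.ones(alignment.n_codons, dtype=bool)
    for t in tree.taxa:
        mask &= enc[t] >= 0
    ncol = int(mask.sum())
    if ncol == 0:
        return {}, mask, np.zeros(0, dtype=_BIT_INDEX_DTYPE)

    one = np.uint64(1)
    sets: dict[str, np.ndarray] = {}
    changes = np.zeros(ncol, dtype=_BIT_INDEX_DTYPE)
    # bottom-up: leaves are singleton sets; internal = intersection else union
    for node_id in tree.postorder_nodes():
        kids = tree.children(node_id)
        if not kids:  # leaf
            sets[node_id] = one << enc[node_id][mask].astype(np.uint64)
            continue
        acc = None
        for b in kids:
            acc = sets[b.child_id] if acc is None else acc  # first child
        left, right = (sets[b.child_id] for b in kids)
        inter = left & right
        empty = inter == 0
        changes += empty.astype(_BIT_INDEX_DTYPE)
        sets[node_id] = np.where(empty, left | right, inter)

    # top-down refinement
    states: dict[str, np.ndarray] = {}
    states["root"] = _lowest_set_bit_index(sets["root"])
    for branch in tree.preorder_branches():
        parent_state = states[branch.parent_id]
        child_set = sets[branch.child_id]
        parent_in_set = (child_set >> parent_state.astype(np.uint64)) & one
        smallest = _lowest_set_bit_index(child_set)
        states[branch.child_id] = np.where(parent_in_set.astype(bool), parent_state, smallest)
    return states, mask, changes


def branch_divergence(
    alignment: CodonAlignment,
    tree: SpeciesTree,
    code: GeneticCode | None = None,
) -> list[DivergenceRecord]:
    """One DivergenceRecord per branch of the species tree.

    Differences are counted between the reconstructed parent-node sequence
    and the child-node sequence; sites are the mean of the two node
    sequences' site counts.
    """
    code = code or standard_code()
    states, mask, _ = reconstruct_ancestors(alignment, tree, code)
    if not states:
        log.warning("gene %s: no usable codon columns, skipped", alignment.gene_id)
        return []
    usable = int(mask.sum())
    out = []
    for branch in tree.preorder_branches():
        parent = states[branch.parent_id]
        child = states[branch.child_id]
        Nd, Sd, S, N = _pair_counts(parent, child, code)
        out.append(
            _record_from_counts(alignment.gene_id, branch.branch_id, Nd, Sd, S, N, usable)
        )
    return out


def tree_divergence(branch_records: Sequence[DivergenceRecord]) -> DivergenceRecord:
    """Whole-tree record: dN and dS summed over branches.

    Branches whose corrected divergence is undefined (saturated) propagate a
    saturation flag; the sums then use only the defined branches and the
    record is flagged so the saturation filter treats the gene as saturated
    at tree scope.
    """
    if not branch_records:
        raise ValueError("tree_divergence requires at least one branch record")
    gene_id = branch_records[0].gene_id
    flags: set[str] = set()
    dN = dS = Nd = Sd = 0.0
    for rec in branch_records:
        Nd += rec.Nd
        Sd += rec.Sd
        if math.isnan(rec.dN):
            flags.add(FLAG_DN_SATURATED)
        else:
            dN += rec.dN
        if math.isnan(rec.dS):
            flags.add(FLAG_DS_SATURATED)
        else:
            dS += rec.dS
    if FLAG_DS_SATURATED in flags:
        dS_out = float("nan")
    else:
        dS_out = dS
    if FLAG_DN_SATURATED in flags:
        dN_out = float("nan")
    else:
        dN_out = dN
    if math.isnan(dS_out) or dS_out == 0.0 or math.isnan(dN_out):
        omega = float("nan")
        flags.add(FLAG_OMEGA_MISSING)
    else:
        omega = dN_out / dS_out
    sc = branch_records[0].site_counts
    return DivergenceRecord(
        gene_id=gene_id,
        scope=TREE_SCOPE,
        Nd=Nd,
        Sd=Sd,
        dN=dN_out,
        dS=dS_out,
        omega=omega,
        site_counts=sc,
        flags=tuple(sorted(flags)),
    )


# ---------------------------------------------------------------------------
# Saturation filter and table assembly
# ---------------------------------------------------------------------------


def saturation_filter(
    records: Iterable[DivergenceRecord], threshold: float = 1.0
) -> tuple[list[DivergenceRecord], pd.DataFrame]:
    """Remove, per analysis scope, genes with dS above the threshold.

    A gene is dropped from a scope iff its dS for that scope exceeds the
    threshold (or the corrected dS is undefined because p >= 3/4, the
    extreme form of saturation). Returns the retained records and a removal
    log DataFrame (gene_id, scope, dS).
    """
    kept: list[DivergenceRecord] = []
    removed: list[dict] = []
    for rec in records:
        saturated = math.isnan(rec.dS) or rec.dS > threshold
        if saturated:
            removed.append({"gene_id": rec.gene_id, "scope": rec.scope, "dS": rec.dS})
        else:
            kept.append(rec)
    log_df = pd.DataFrame(removed, columns=["gene_id", "scope", "dS"])
    return kept, log_df


def estimate_divergence(
    alignments: Iterable[CodonAlignment],
    tree: SpeciesTree,
    code: GeneticCode | None = None,
) -> list[DivergenceRecord]:
    """Branch records plus the whole-tree record for every alignment."""
    code = code or standard_code()
    out: list[DivergenceRecord] = []
    for aln in alignments:
        recs = branch_divergence(aln, tree, code)
        if not recs:
            continue
        out.extend(recs)
        out.append(tree_divergence(recs))
    return out


def records_to_table(records: Iterable[DivergenceRecord]) -> pd.DataFrame:
    """Flatten records to the divergence-table contract (TSV schema)."""
    rows = [
        {
            "gene_id": r.gene_id,
            "scope": r.scope,
            "Nd": r.Nd,
            "Sd": r.Sd,
            "S": r.site_counts.S,
            "N": r.site_counts.N,
            "dN": r.dN,
            "dS": r.dS,
            "omega": r.omega,
            "flags": ";".join(r.flags),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "scope", "Nd", "Sd", "S", "N", "dN", "dS", "omega", "flags"]
    )


DIVERGENCE_COLUMNS = ["gene_id", "scope", "Nd", "Sd", "S", "N", "dN", "dS", "omega", "flags"]


def table_to_records(df: pd.DataFrame) -> list[DivergenceRecord]:
    """Parse an externally produced divergence table (schema-checked)."""
    missing = set(DIVERGENCE_COLUMNS) - set(df.columns)
    if missing:
        raise OmegascanError(f"divergence table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        flags = tuple(f for f in str(row.flags).split(";") if f and f != "nan")
        out.append(
            DivergenceRecord(
                gene_id=row.gene_id,
                scope=row.scope,
                Nd=float(row.Nd),
                Sd=float(row.Sd),
                dN=float(row.dN),
                dS=float(row.dS),
                omega=float(row.omega),
                site_counts=SiteCounts(S=float(row.S), N=float(row.N), usable_codons=0),
                flags=flags,
            )
        )
    return out
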