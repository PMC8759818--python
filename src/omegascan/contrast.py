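"""Local-genomic-background rate contrasts and category-level tests.

Each focal gene's dN/dS on a branch is compared with the median dN/dS of
its *local background*: genes on the same chromosome within a physical
radius (default 100 kbp between start coordinates) and within a dS
tolerance (default 0.01) on that branch. The contrast
``delta = omega(focal) - median(omega(background))`` is positive when the
focal gene evolves faster than its neighborhood, which controls for
regional effects (mutation rate, recombination environment) that inflate
raw dN/dS comparisons.

Category-level inference: a one-sided one-sample t-test of the category's
deltas against zero (H1: mean > 0), a Wilcoxon rank-sum test of the
category genes' omegas against their pooled background genes' omegas, and
Benjamini–Hochberg FDR correction across the category x branch family.
Per-category Pearson correlations of deltas between two branches ask
whether the same genes drive the elevation on both lineages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .divergence import DivergenceRecord
from .genetics import GeneAnnotation

log = logging.getLogger(__name__)


@dataclass
class ContrastRecord:
    gene_id: str
    branch: str
    delta: float  # NaN when background empty
    n_background: int
    background_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.delta)


@dataclass
class CategoryTestResult:
    category: str
    branch: str
    n_genes: int
    mean_delta: float
    t_statistic: float
    p_t: float  # one-sided, H1: mean delta > 0
    wilcoxon_statistic: float
    p_w: float  # two-sided rank-sum, category omegas vs pooled background
    direction: str  # "higher" | "lower" | "equal"
    q_t: float = float("nan")  # BH-adjusted p_t, filled by category_tests


# ---------------------------------------------------------------------------
# Background extraction and per-gene contrasts
# ---------------------------------------------------------------------------


class BranchFrame:
    """Per-branch arrays (position, dS, omega) for fast neighborhood lookup."""

    def __init__(
        self,
        annotations: Sequence[GeneAnnotation],
        records: Iterable[DivergenceRecord],
    ):
        by_gene = {r.gene_id: r for r in records}
        rows = []
        for a in annotations:
            r = by_gene.get(a.gene_id)
            if r is None or not r.omega_defined or math.isnan(r.dS):
                continue
            rows.append((a.gene_id, a.chromosome, a.start, r.dS, r.omega))
        rows.sort(key=lambda t: (t[1], t[2], t[0]))
        self.gene_ids = [t[0] for t in rows]
        self.chromosome = np.array([t[1] for t in rows])
        self.start = np.array([t[2] for t in rows], dtype=np.int64)
        self.dS = np.array([t[3] for t in rows])
        self.omega = np.array([t[4] for t in rows])
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def neighborhood(
        self, gene_id: str, radius_bp: int, ds_tolerance: float
    ) -> np.ndarray:
        """Indices of background genes for a focal gene (excludes itself)."""
        i = self._index[gene_id]
        same_chrom = self.chromosome == self.chromosome[i]
        near = np.abs(self.start - self.start[i]) <= radius_bp
        similar = np.abs(self.dS - self.dS[i]) <= ds_tolerance
        mask = same_chrom & near & similar
        mask[i] = False
        return np.nonzero(mask)[0]


def local_background(
    focal: GeneAnnotation,
    frame: BranchFrame,
    radius_bp: int = 100_000,
    ds_tolerance: float = 0.01,
) -> set[str]:
    """Background gene ids for one focal gene on one branch.

    Genes on the same chromosome, within ``radius_bp`` of the focal start
    (inclusive), within ``ds_tolerance`` of the focal dS (inclusive), with a
    defined omega. May be empty; the contrast is then undefined.
    """
    if focal.gene_id not in frame:
        return set()
    idx = frame.neighborhood(focal.gene_id, radius_bp, ds_tolerance)
    return {frame.gene_ids[j] for j in idx}


def gene_contrast(
    focal_id: str, branch: str, frame: BranchFrame, radius_bp: int, ds_tolerance: float
) -> ContrastRecord:
    idx = frame.neighborhood(focal_id, radius_bp, ds_tolerance)
    if idx.size == 0:
        return ContrastRecord(focal_id, branch, float("nan"), 0)
    i = frame._index[focal_id]
    delta = float(frame.omega[i] - np.median(frame.omega[idx]))
    return ContrastRecord(
        focal_id,
        branch,
        delta,
        int(idx.size),
        frozenset(frame.gene_ids[j] for j in idx),
    )


def branch_contrasts(
    annotations: Sequence[GeneAnnotation],
    records: Iterable[DivergenceRecord],
    branch: str,
    radius_bp: int = 100_000,
    ds_tolerance: float = 0.01,
    gene_ids: Iterable[str] | None = None,
) -> list[ContrastRecord]:
    """ContrastRecords for every requested gene with data on this branch.

    ``records`` must already be restricted to the branch scope and to genes
    surviving the saturation filter there; genes with undefined omega never
    enter backgrounds (BranchFrame drops them).
    """
    frame = BranchFrame(annotations, records)
    targets = list(gene_ids) if gene_ids is not None else list(frame.gene_ids)
    out = []
    for gid in targets:
        if gid not in frame:
            continue
        rec = gene_contrast(gid, branch, frame, radius_bp, ds_tolerance)
        if not rec.defined:
            log.info("gene %s: empty background on branch %s", gid, branch)
        out.append(rec)
    return out


def contrasts_to_table(contrasts: Iterable[ContrastRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "branch": c.branch,
            "delta": c.delta,
            "n_background": c.n_background,
        }
        for c in contrasts
    ]
    return pd.DataFrame(rows, columns=["gene_id", "branch", "delta", "n_background"])


# ---------------------------------------------------------------------------
# Category tests
# ---------------------------------------------------------------------------


def _one_sided_t(deltas: np.ndarray) -> tuple[float, float]:
    """One-sample t against 0, H1: mean > 0, with the degenerate
    zero-variance cases resolved by the sign of the common value."""
    sd = float(np.std(deltas, ddof=1))
    mean = float(np.mean(deltas))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.5
        return (math.inf, 0.0) if mean > 0 else (-math.inf, 1.0)
    t, p = stats.ttest_1samp(deltas, 0.0, alternative="greater")
    return float(t), float(p)


def category_rate_test(
    category: str,
    branch: str,
    contrasts: Iterable[ContrastRecord],
    members: set[str],
    omega_by_gene: Mapping[str, float],
) -> CategoryTestResult | None:
    """Test whether a category evolves faster than its local background.

    Requires >= 2 category genes with a defined contrast on the branch;
    returns None (logged) otherwise. The Wilcoxon rank-sum compares the
    category genes' omegas against the pooled, deduplicated omegas of all
    their background genes (background genes that are themselves category
    members are excluded from the pool).
    """
    cat = [c for c in contrasts if c.gene_id in members and c.defined and c.branch == branch]
    if len(cat) < 2:
        log.info("category %s on %s: <2 usable genes, test omitted", category, branch)
        return None
    deltas = np.array([c.delta for c in cat])
    t, p_t = _one_sided_t(deltas)
    pooled_ids = set().union(*(c.background_ids for c in cat)) - members
    cat_omegas = np.array([omega_by_gene[c.gene_id] for c in cat])
    bg_omegas = np.array([omega_by_gene[g] for g in sorted(pooled_ids) if g in omega_by_gene])
    if bg_omegas.size >= 1:
        w, p_w = stats.ranksums(cat_omegas, bg_omegas)
        w, p_w = float(w), float(p_w)
    else:
        w, p_w = float("nan"), float("nan")
    mean_delta = float(np.mean(deltas))
    direction = "higher" if mean_delta > 0 else ("lower" if mean_delta < 0 else "equal")
    return CategoryTestResult(
        category=category,
        branch=branch,
        n_genes=len(cat),
        mean_delta=mean_delta,
        t_statistic=t,
        p_t=p_t,
        wilcoxon_statistic=w,
        p_w=p_w,
        direction=direction,
    )


def category_tests(
    memberships: Mapping[str, set[str]],
    contrasts_by_branch: Mapping[str, Sequence[ContrastRecord]],
    omega_by_branch: Mapping[str, Mapping[str, float]],
) -> list[CategoryTestResult]:
    """All category x branch tests, BH-adjusted as one family (q_t)."""
    results: list[CategoryTestResult] = []
    for branch in sorted(contrasts_by_branch):
        for category in sorted(memberships):
            res = category_rate_test(
                category,
                branch,
                contrasts_by_branch[branch],
                memberships[category],
                omega_by_branch[branch],
            )
            if res is not None:
                results.append(res)
    if results:
        _, q, _, _ = multipletests([r.p_t for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_t = float(qv)
    return results


def tests_to_table(results: Iterable[CategoryTestResult]) -> pd.DataFrame:
    rows = [
        {
            "category": r.category,
            "branch": r.branch,
            "n": r.n_genes,
            "mean_delta": r.mean_delta,
            "t": r.t_statistic,
            "p_t": r.p_t,
            "W": r.wilcoxon_statistic,
            "p_w": r.p_w,
            "q_t": r.q_t,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["category", "branch", "n", "mean_delta", "t", "p_t", "W", "p_w", "q_t", "direction"],
    )


# ---------------------------------------------------------------------------
# Between-branch correlation and diagnostics
# ---------------------------------------------------------------------------


def branch_correlation(
    category: str,
    branch_a: str,
    branch_b: str,
    contrasts_by_branch: Mapping[str, Sequence[ContrastRecord]],
    members: set[str],
) -> tuple[float, float, int, float] | None:
    """Pearson correlation of per-gene deltas between two branches.

    Returns (r, t, df, p) with t = r*sqrt(df)/sqrt(1-r^2), df = n-2,
    two-sided p; None when fewer than 3 genes have defined deltas on both
    branches or when either branch has zero variance.
    """
    da = {c.gene_id: c.delta for c in contrasts_by_branch[branch_a] if c.defined}
    db = {c.gene_id: c.delta for c in contrasts_by_branch[branch_b] if c.defined}
    genes = sorted(set(da) & set(db) & members)
    if len(genes) < 3:
        return None
    x = np.array([da[g] for g in genes])
    y = np.array([db[g] for g in genes])
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = float(stats.pearsonr(x, y).statistic)
    df = len(genes) - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, t, df, p


def normality_diagnostic(deltas: Sequence[float]) -> tuple[float, float] | None:
    """Shapiro–Wilk (W, p) of a delta sample; diagnostic only, never gates
    any downstream computation. None for n < 3 or constant samples."""
    x = np.asarray([d for d in deltas if not math.isnan(d)])
    if x.size < 3 or np.ptp(x) == 0:
        return None
    w, p = stats.shapiro(x)
    return float(w), float(p)
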