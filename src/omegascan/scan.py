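"""Windowed upper-percentile dN/dS outlier detection.

Genes are binned into dS windows (so that only genes of similar synonymous
divergence — and hence similar estimation variance and time depth — are
compared), and within each window the genes whose dN/dS strictly exceeds
the window's upper percentile (default 97.5th) are flagged as rapidly
evolving. The scan runs per branch, across the whole tree, and
conditionally between the two sister-species pairs, where each species'
genes are windowed by the *partner* species' value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .divergence import DivergenceRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and percentile rule for the outlier scan.

    Windows of ``width`` (in dS units) start every ``slide`` units and tile
    [0, max dS] as half-open intervals [k*slide, k*slide + width). Windows
    holding fewer than ``min_genes`` genes are merged upward with the next
    window until the minimum is met; a 97.5th percentile over a handful of
    points would be dominated by a single order statistic.
    """

    width: float = 0.001
    slide: float = 0.001
    percentile: float = 97.5
    min_genes: int = 40

    def __post_init__(self) -> None:
        if self.width <= 0 or self.slide <= 0 or self.slide > self.width:
            raise ValueError("need width > 0, slide > 0, slide <= width")
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must be in (0, 100)")
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")


#: preset matching the coarser window width quoted for the branch scans
WIDE_WINDOWS = WindowSpec(width=0.01, slide=0.01)


@dataclass(frozen=True)
class OutlierCall:
    gene_id: str
    scope: str
    window_index: int
    window_threshold: float
    is_outlier: bool


def _window_indices(value: float, spec: WindowSpec) -> range:
    """All window indices k with k*slide <= value < k*slide + width."""
    k_hi = math.floor(value / spec.slide + 1e-12)
    # smallest k whose half-open window still contains value: k*slide + width > value
    k_lo = max(0, math.floor((value - spec.width) / spec.slide + 1e-12) + 1)
    if k_lo > k_hi:
        k_lo = k_hi
    return range(k_lo, k_hi + 1)


def assign_windows(
    values: pd.Series | dict[str, float], spec: WindowSpec
) -> list[tuple[int, list[str]]]:
    """Bin genes by value into merged windows.

    ``values`` maps gene_id → windowing value (dS, or the partner species'
    dN/dS for the paired scan). Returns an ordered list of
    (block_index, gene list); blocks are maximal runs of consecutive raw
    windows merged upward until each holds at least ``min_genes`` distinct
    genes. A trailing underfull block is merged into the preceding one.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    raw: dict[int, list[str]] = {}
    for gid in sorted(values):
        v = values[gid]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        for k in _window_indices(float(v), spec):
            raw.setdefault(k, []).append(gid)
    if not raw:
        return []
    blocks: list[list[str]] = []
    current: list[str] = []
    seen: set[str] = set()
    for k in sorted(raw):
        for gid in raw[k]:
            if gid not in seen:
                current.append(gid)
                seen.add(gid)
        if len(current) >= spec.min_genes:
            blocks.append(current)
            current = []
            seen = set()
    if current:
        if blocks:
            blocks[-1].extend(g for g in current if g not in blocks[-1])
        else:
            blocks.append(current)
    return list(enumerate(blocks))


def percentile_outliers(
    records: Iterable[DivergenceRecord],
    spec: WindowSpec = WindowSpec(),
    window_on: str = "dS",
) -> list[OutlierCall]:
    """Flag genes above the windowed upper percentile of dN/dS.

    All records must share one scope; the saturation filter is assumed to
    have been applied already. The window threshold is the linear-
    interpolation percentile of the member omegas; outlier status requires
    omega strictly greater than the threshold, so degenerate windows where
    all omegas coincide yield no outliers.
    """
    recs = [r for r in records if r.omega_defined]
    if not recs:
        return []
    scopes = {r.scope for r in recs}
    if len(scopes) != 1:
        raise ValueError(f"records span multiple scopes: {sorted(scopes)}")
    scope = scopes.pop()
    omega = {r.gene_id: r.omega for r in recs}
    values = {r.gene_id: getattr(r, window_on) for r in recs}
    calls: list[OutlierCall] = []
    for block_idx, genes in assign_windows(values, spec):
        member_omegas = np.array([omega[g] for g in genes])
        threshold = float(np.percentile(member_omegas, spec.percentile, method="linear"))
        for g in genes:
            calls.append(
                OutlierCall(
                    gene_id=g,
                    scope=scope,
                    window_index=block_idx,
                    window_threshold=threshold,
                    is_outlier=bool(omega[g] > threshold),
                )
            )
    return calls


def paired_species_outliers(
    records_a: Iterable[DivergenceRecord],
    records_b: Iterable[DivergenceRecord],
    spec: WindowSpec = WindowSpec(),
    window_on: str = "omega",
) -> tuple[list[OutlierCall], list[OutlierCall]]:
    """Conditional outlier scan between the two species of a sister pair.

    For species A, genes are windowed by the partner species B's value
    (``window_on`` = "omega" per the study procedure; "dS" selectable) and
    the percentile threshold within each window is computed on A's omegas;
    roles then swap. Genes lacking a defined omega in either species are
    excluded and logged.
    """

    def index(recs: Iterable[DivergenceRecord]) -> dict[str, DivergenceRecord]:
        return {r.gene_id: r for r in recs}

    ra, rb = index(records_a), index(records_b)
    shared = sorted(set(ra) & set(rb))
    usable = [g for g in shared if ra[g].omega_defined and rb[g].omega_defined]
    dropped = sorted(set(ra) ^ set(rb)) + [g for g in shared if g not in usable]
    if dropped:
        log.info("paired scan: %d genes excluded (missing/undefined omega)", len(dropped))

    def scan(focal: dict, partner: dict, scope: str) -> list[OutlierCall]:
        values = {g: getattr(partner[g], window_on) for g in usable}
        omega = {g: focal[g].omega for g in usable}
        calls = []
        for block_idx, genes in assign_windows(values, spec):
            member = np.array([omega[g] for g in genes])
            threshold = float(np.percentile(member, spec.percentile, method="linear"))
            calls.extend(
                OutlierCall(g, scope, block_idx, threshold, bool(omega[g] > threshold))
                for g in genes
            )
        return calls

    scope_a = ra[usable[0]].scope if usable else "a"
    scope_b = rb[usable[0]].scope if usable else "b"
    calls_a = scan(ra, rb, f"{scope_a}|vs|{scope_b}")
    calls_b = scan(rb, ra, f"{scope_b}|vs|{scope_a}")
    return calls_a, calls_b


def outlier_gene_set(calls: Iterable[OutlierCall]) -> set[str]:
    """Genes flagged in at least one window."""
    return {c.gene_id for c in calls if c.is_outlier}


def calls_to_table(calls: Iterable[OutlierCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "scope": c.scope,
            "window_index": c.window_index,
            "threshold": c.window_threshold,
            "is_outlier": c.is_outlier,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "scope", "window_index", "threshold", "is_outlier"]
    )
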