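"""Stage orchestration: simulate → estimate → scan → contrast → enrich.

Each stage reads the TSV/FASTA contracts of the previous one from a single
output directory and writes its own outputs there, plus a run manifest
(config echo, seed, input checksums, package version). All outputs are
written deterministically: fixed column orders, sorted rows, fixed float
formatting — two runs with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .config import simulation_config, window_spec
from .contrast import (
    branch_contrasts,
    category_tests,
    contrasts_to_table,
    normality_diagnostic,
    branch_correlation,
    tests_to_table,
)
from .divergence import (
    DivergenceRecord,
    estimate_divergence,
    records_to_table,
    saturation_filter,
    table_to_records,
)
from .enrichment import enrichment_test, enrichment_to_table
from .errors import ConfigurationError
from .genetics import (
    SISTER_PAIRS,
    category_memberships,
    read_annotations,
    read_codon_alignments,
    read_memberships,
    read_tree,
)
from .scan import calls_to_table, outlier_gene_set, paired_species_outliers, percentile_outliers
from .simulate import simulate_study, write_study

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _resolve(outdir: Path, value: str) -> Path:
    p = Path(value)
    return p if p.is_absolute() else outdir / p


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(cfg: Mapping[str, Any], outdir: Path, stage: str, inputs: Sequence[Path]) -> None:
    def label(p: Path) -> str:
        try:
            return str(p.resolve().relative_to(outdir.resolve()))
        except ValueError:
            return p.name
    manifest = {
        "stage": stage,
        "seed": cfg.get("seed"),
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "input_checksums": {label(p): _checksum(p) for p in sorted(set(inputs)) if p.exists()},
    }
    (outdir / f"manifest_{stage}.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False)
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_simulate(cfg: Mapping[str, Any], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulation_config(cfg, seed=cfg.get("seed"))
    study = simulate_study(sim_cfg)
    write_study(study, outdir)
    log.info("simulate: %d genes written to %s", len(study.alignments), outdir)
    write_manifest(cfg, outdir, "simulate", [])


def _estimate_chunk(args) -> list[DivergenceRecord]:
    alignments, tree = args
    return estimate_divergence(alignments, tree)


def run_estimate(cfg: Mapping[str, Any], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    external = cfg["paths"].get("divergence_table")
    if external:
        ext_path = _resolve(outdir, external)
        if not ext_path.exists():
            raise ConfigurationError(f"external divergence table not found: {ext_path}")
        df = pd.read_csv(ext_path, sep="\t")
        table_to_records(df)  # schema check
        inputs = [ext_path]
    else:
        aln_dir = _resolve(outdir, cfg["paths"]["alignments"])
        tree_path = _resolve(outdir, cfg["paths"]["tree"])
        if not aln_dir.is_dir() or not any(aln_dir.iterdir()):
            raise ConfigurationError(f"alignment directory missing or empty: {aln_dir}")
        if not tree_path.exists():
            raise ConfigurationError(f"tree file not found: {tree_path}")
        tree = read_tree(tree_path)
        alignments = read_codon_alignments(aln_dir)
        threads = int(cfg.get("threads", 1))
        if threads > 1 and len(alignments) > 1:
            chunks = [alignments[i::threads] for i in range(threads)]
            with ProcessPoolExecutor(max_workers=threads) as pool:
                parts = list(pool.map(_estimate_chunk, [(c, tree) for c in chunks]))
            records = [r for part in parts for r in part]
        else:
            records = estimate_divergence(alignments, tree)
        df = records_to_table(records).sort_values(["gene_id", "scope"], kind="mergesort")
        inputs = [aln_dir, tree_path]
    _write_tsv(df, outdir / "divergence.tsv")
    threshold = float(cfg["divergence"]["saturation_threshold"])
    _, removal_log = saturation_filter(table_to_records(df), threshold)
    removal_log = removal_log.sort_values(["scope", "gene_id"], kind="mergesort")
    _write_tsv(removal_log, outdir / "saturation_log.tsv")
    log.info(
        "estimate: %d records, %d removed by saturation filter (dS > %g)",
        len(df),
        len(removal_log),
        threshold,
    )
    write_manifest(cfg, outdir, "estimate", inputs)


def _load_filtered(cfg: Mapping[str, Any], outdir: Path) -> dict[str, list[DivergenceRecord]]:
    """Divergence records per scope, after the per-scope saturation filter."""
    div_path = outdir / "divergence.tsv"
    if not div_path.exists():
        raise ConfigurationError(f"divergence table not found: {div_path} (run estimate first)")
    records = table_to_records(pd.read_csv(div_path, sep="\t"))
    kept, _ = saturation_filter(records, float(cfg["divergence"]["saturation_threshold"]))
    by_scope: dict[str, list[DivergenceRecord]] = {}
    for r in kept:
        by_scope.setdefault(r.scope, []).append(r)
    return by_scope


def run_scan(cfg: Mapping[str, Any], outdir: str | Path) -> None:
    outdir = Path(outdir)
    by_scope = _load_filtered(cfg, outdir)
    spec = window_spec(cfg)
    tables = []
    for scope in sorted(by_scope):
        calls = percentile_outliers(by_scope[scope], spec)
        log.info("scan: scope %s, %d genes, %d outliers", scope, len(by_scope[scope]),
                 len(outlier_gene_set(calls)))
        tables.append(calls_to_table(calls))
    for a, b in SISTER_PAIRS:
        if a in by_scope and b in by_scope:
            calls_a, calls_b = paired_species_outliers(
                by_scope[a], by_scope[b], spec, window_on=cfg["paired"]["window_on"]
            )
            tables.append(calls_to_table(calls_a))
            tables.append(calls_to_table(calls_b))
    df = pd.concat(tables, ignore_index=True) if tables else calls_to_table([])
    df = df.sort_values(["scope", "window_index", "gene_id"], kind="mergesort")
    _write_tsv(df, outdir / "outliers.tsv")
    write_manifest(cfg, outdir, "scan", [outdir / "divergence.tsv"])


def _load_annotations(cfg: Mapping[str, Any], outdir: Path):
    ann_path = _resolve(outdir, cfg["paths"]["annotations"])
    if not ann_path.exists():
        raise ConfigurationError(f"annotation table not found: {ann_path}")
    annotations = read_annotations(ann_path)
    mem_path = cfg["paths"].get("memberships")
    if mem_path:
        memberships = read_memberships(_resolve(outdir, mem_path))
    else:
        memberships = category_memberships(annotations)
    return annotations, memberships, ann_path


def run_contrast(cfg: Mapping[str, Any], outdir: str | Path) -> None:
    outdir = Path(outdir)
    by_scope = _load_filtered(cfg, outdir)
    annotations, memberships, ann_path = _load_annotations(cfg, outdir)
    radius = int(cfg["background"]["radius_bp"])
    tol = float(cfg["background"]["ds_tolerance"])
    contrasts_by_branch = {}
    omega_by_branch = {}
    for scope in sorted(by_scope):
        contrasts_by_branch[scope] = branch_contrasts(
            annotations, by_scope[scope], scope, radius, tol
        )
        omega_by_branch[scope] = {
            r.gene_id: r.omega for r in by_scope[scope] if r.omega_defined
        }
    all_contrasts = [c for recs in contrasts_by_branch.values() for c in recs]
    cdf = contrasts_to_table(all_contrasts).sort_values(["branch", "gene_id"], kind="mergesort")
    _write_tsv(cdf, outdir / "contrasts.tsv")

    results = category_tests(memberships, contrasts_by_branch, omega_by_branch)
    tdf = tests_to_table(results)
    shapiro_rows = []
    for r in results:
        deltas = [
            c.delta
            for c in contrasts_by_branch[r.branch]
            if c.gene_id in memberships[r.category] and c.defined
        ]
        diag = normality_diagnostic(deltas)
        shapiro_rows.append(
            {"shapiro_W": diag[0], "shapiro_p": diag[1]} if diag else
            {"shapiro_W": float("nan"), "shapiro_p": float("nan")}
        )
    tdf = pd.concat([tdf, pd.DataFrame(shapiro_rows)], axis=1)
    _write_tsv(tdf, outdir / "category_tests.tsv")

    corr_rows = []
    for a, b in SISTER_PAIRS:
        if a not in contrasts_by_branch or b not in contrasts_by_branch:
            continue
        for category in sorted(memberships):
            res = branch_correlation(category, a, b, contrasts_by_branch, memberships[category])
            if res is None:
                continue
            r_, t_, df_, p_ = res
            corr_rows.append(
                {"category": category, "branch_a": a, "branch_b": b,
                 "r": r_, "t": t_, "df": df_, "p": p_}
            )
    corr_df = pd.DataFrame(corr_rows, columns=["category", "branch_a", "branch_b", "r", "t", "df", "p"])
    _write_tsv(corr_df, outdir / "correlations.tsv")
    write_manifest(cfg, outdir, "contrast", [outdir / "divergence.tsv", ann_path])


def run_enrich(cfg: Mapping[str, Any], outdir: str | Path) -> None:
    outdir = Path(outdir)
    by_scope = _load_filtered(cfg, outdir)
    annotations, memberships, ann_path = _load_annotations(cfg, outdir)
    out_path = outdir / "outliers.tsv"
    if not out_path.exists():
        raise ConfigurationError(f"outlier table not found: {out_path} (run scan first)")
    odf = pd.read_csv(out_path, sep="\t")
    tables = []
    for scope, group in odf.groupby("scope", sort=True):
        base_scope = str(scope).split("|vs|")[0]
        if base_scope not in by_scope:
            continue
        universe = {r.gene_id for r in by_scope[base_scope] if r.omega_defined}
        outliers = set(group.loc[group["is_outlier"], "gene_id"]) & universe
        results = enrichment_test(
            outliers, universe, memberships, str(scope),
            underrepresentation=bool(cfg["enrichment"]["underrepresentation"]),
        )
        tables.append(enrichment_to_table(results))
    df = (
        pd.concat(tables, ignore_index=True)
        if tables
        else enrichment_to_table([])
    )
    df = df.sort_values(["scope", "q", "category"], kind="mergesort")
    _write_tsv(df, outdir / "enrichment.tsv")
    write_manifest(cfg, outdir, "enrich", [outdir / "divergence.tsv", out_path, ann_path])


STAGES = {
    "simulate": run_simulate,
    "estimate": run_estimate,
    "scan": run_scan,
    "contrast": run_contrast,
    "enrich": run_enrich,
}


def run_all(cfg: Mapping[str, Any], outdir: str | Path) -> None:
    for name in ("simulate", "estimate", "scan", "contrast", "enrich"):
        STAGES[name](cfg, outdir)
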