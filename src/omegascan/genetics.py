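"""Genetic-code tables, codon alignments, the species tree, and file readers.

The five study taxa are the four *Drosophila dunni*-group focal species
(nigrodunni, arawakana, dunni, similis) plus the *D. innubila* outgroup.
Every branch of the rooted species tree carries a stable string identifier
that downstream divergence records use as their ``scope`` key: the child
taxon label for terminal branches, and the ``+``-joined sorted leaf set for
internal branches (so the stem of the ingroup is
``arawakana+dunni+nigrodunni+similis``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .errors import ConfigurationError, FormatError, MalformedGeneError

STUDY_TAXA = ("nigrodunni", "arawakana", "dunni", "similis", "innubila")
OUTGROUP = "innubila"
SISTER_PAIRS = (("nigrodunni", "arawakana"), ("dunni", "similis"))

NUCLEOTIDES = "ACGT"


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A total map from the 64 codons over {A,C,G,T} to amino acids or stop.

    ``table`` maps every codon to a one-letter amino-acid symbol, with ``*``
    for stop codons. The standard code has 61 sense codons and the three
    stops TAA, TAG, TGA.
    """

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.table)}")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa == "*"))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """The sense codons in lexicographic order (the canonical state order
        used for codon integer encodings throughout the package)."""
        return tuple(sorted(c for c, aa in self.table.items() if aa != "*"))

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_sense(self, codon: str) -> bool:
        aa = self.table.get(codon)
        return aa is not None and aa != "*"

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon) == "*"


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    # Biopython's forward table omits stops; everything else is present.
    assert len(table) == 64
    return GeneticCode(table=table)


def codon_index(code: GeneticCode) -> dict[str, int]:
    """Codon → integer rank in the lexicographic sense-codon order."""
    return {c: i for i, c in enumerate(code.sense_codons)}


@dataclass
class CodonAlignment:
    """One ortholog group's aligned coding sequences.

    A codon column is *usable* iff every taxon's codon at that column is a
    sense codon over {A,C,G,T}: gaps, ambiguity characters and stop codons
    all make the column unusable for counting, but do not invalidate the
    alignment as a whole.
    """

    gene_id: str
    sequences: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MalformedGeneError(f"{self.gene_id}: alignment has no sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise MalformedGeneError(
                f"{self.gene_id}: sequences have unequal lengths {sorted(lengths)}"
            )
        (self.length,) = lengths
        if self.length % 3 != 0:
            raise MalformedGeneError(
                f"{self.gene_id}: alignment length {self.length} not divisible by 3"
            )
        taxa = [t for t, _ in self.sequences]
        if len(set(taxa)) != len(taxa):
            raise FormatError(f"{self.gene_id}: duplicate taxon label in alignment")

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.sequences]

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def sequence(self, taxon: str) -> str:
        for t, s in self.sequences:
            if t == taxon:
                return s
        raise KeyError(taxon)

    def codon(self, taxon: str, column: int) -> str:
        return self.sequence(taxon)[3 * column : 3 * column + 3]

    def usable_columns(self, code: GeneticCode | None = None) -> np.ndarray:
        """Boolean mask over codon columns; True where all taxa are sense."""
        code = code or standard_code()
        mask = np.ones(self.n_codons, dtype=bool)
        for _, seq in self.sequences:
            for col in range(self.n_codons):
                if mask[col] and not code.is_sense(seq[3 * col : 3 * col + 3]):
                    mask[col] = False
        return mask

    def encoded(self, code: GeneticCode | None = None) -> dict[str, np.ndarray]:
        """Integer-encode each sequence: sense-codon rank, or -1 if unusable."""
        code = code or standard_code()
        idx = codon_index(code)
        out: dict[str, np.ndarray] = {}
        for taxon, seq in self.sequences:
            arr = np.fromiter(
                (idx.get(seq[3 * c : 3 * c + 3], -1) for c in range(self.n_codons)),
                dtype=np.int64,
                count=self.n_codons,
            )
            out[taxon] = arr
        return out


@dataclass(frozen=True)
class Branch:
    """One branch of the rooted species tree.

    ``branch_id`` is the child taxon for terminal branches and the sorted
    ``+``-joined leaf set for internal ones. ``parent_id``/``child_id`` are
    node identifiers; a node is named after the branch above it and the root
    node is ``"root"``.
    """

    branch_id: str
    parent_id: str
    child_id: str
    length: float
    leafset: frozenset[str]

    @property
    def is_terminal(self) -> bool:
        return len(self.leafset) == 1


class SpeciesTree:
    """Rooted binary tree over the five study taxa.

    The default topology is ((nigrodunni,arawakana),(dunni,similis)) with
    innubila as the outgroup; after rooting on innubila the tree has eight
    branches (five terminal, the two sister-pair ancestors, and the ingroup
    stem).
    """

    def __init__(self, branches: Sequence[Branch], taxa: Sequence[str]):
        self.branches: list[Branch] = list(branches)
        self.taxa = list(taxa)
        self._by_id = {b.branch_id: b for b in self.branches}
        self._children: dict[str, list[Branch]] = {}
        for b in self.branches:
            self._children.setdefault(b.parent_id, []).append(b)
        for node in self._children:
            self._children[node].sort(key=lambda b: b.branch_id)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        expected_taxa: Sequence[str] = STUDY_TAXA,
        outgroup: str = OUTGROUP,
        label_map: Mapping[str, str] | None = None,
    ) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        canonical = _normalize_labels(labels, expected_taxa, label_map)
        for lf in tree.leaf_node_iter():
            lf.taxon.label = canonical[lf.taxon.label]
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length {edge.length} in tree")
        out_nodes = [lf for lf in tree.leaf_node_iter() if lf.taxon.label == outgroup]
        if not out_nodes:
            raise ConfigurationError(f"outgroup taxon {outgroup!r} absent from tree")
        out_node = out_nodes[0]
        root_kids = tree.seed_node.child_nodes()
        if not (len(root_kids) == 2 and out_node in root_kids):
            # place the root midway along the outgroup's edge so the tree
            # bifurcates into outgroup vs ingroup
            half = (out_node.edge.length or 0.0) / 2.0
            tree.reroot_at_edge(
                out_node.edge, length1=half, length2=half, update_bipartitions=False
            )
        tree.suppress_unifurcations()
        return cls._from_dendropy(tree, canonical.values())

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree, taxa: Iterable[str]) -> "SpeciesTree":
        branches: list[Branch] = []

        def leafset(node) -> frozenset[str]:
            return frozenset(lf.taxon.label for lf in node.leaf_iter())

        def branch_name(node) -> str:
            ls = leafset(node)
            return next(iter(ls)) if len(ls) == 1 else "+".join(sorted(ls))

        def node_id(node) -> str:
            return "root" if node.parent_node is None else branch_name(node)

        root = tree.seed_node
        # dendropy's outgroup re-rooting can leave the root with >2 children
        # when the source was an unrooted trifurcation; re-attach so the root
        # bifurcates into outgroup vs ingroup.
        if len(root.child_nodes()) > 2:
            tree.resolve_polytomies()
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            length = node.edge.length if node.edge.length is not None else 0.0
            branches.append(
                Branch(
                    branch_id=branch_name(node),
                    parent_id=node_id(node.parent_node),
                    child_id=branch_name(node),
                    length=float(length),
                    leafset=leafset(node),
                )
            )
        return cls(branches, sorted(taxa))

    @classmethod
    def default(
        cls,
        terminal_length: float = 0.1,
        internal_length: float = 0.05,
        outgroup_length: float = 0.3,
    ) -> "SpeciesTree":
        nwk = (
            f"((nigrodunni:{terminal_length},arawakana:{terminal_length}):{internal_length},"
            f"(dunni:{terminal_length},similis:{terminal_length}):{internal_length},"
            f"innubila:{outgroup_length});"
        )
        return cls.from_newick(nwk)

    # -- queries ---------------------------------------------------------

    @property
    def branch_ids(self) -> list[str]:
        return [b.branch_id for b in self.branches]

    def branch(self, branch_id: str) -> Branch:
        return self._by_id[branch_id]

    def children(self, node_id: str) -> list[Branch]:
        return self._children.get(node_id, [])

    def postorder_nodes(self) -> list[str]:
        """Node ids, children before parents, ending at 'root'."""
        order: list[str] = []

        def visit(node_id: str) -> None:
            for b in self.children(node_id):
                visit(b.child_id)
            order.append(node_id)

        visit("root")
        return order

    def preorder_branches(self) -> list[Branch]:
        order: list[Branch] = []

        def visit(node_id: str) -> None:
            for b in self.children(node_id):
                order.append(b)
                visit(b.child_id)

        visit("root")
        return order

    def with_lengths(self, scale: Mapping[str, float] | float) -> "SpeciesTree":
        """New tree with branch lengths multiplied by a scalar or per-branch map."""
        if isinstance(scale, (int, float)):
            scale = {b.branch_id: float(scale) for b in self.branches}
        branches = [
            Branch(b.branch_id, b.parent_id, b.child_id, b.length * scale.get(b.branch_id, 1.0), b.leafset)
            for b in self.branches
        ]
        return SpeciesTree(branches, self.taxa)

    def to_newick(self) -> str:
        def render(node_id: str) -> str:
            kids = self.children(node_id)
            if not kids:
                raise ValueError(node_id)
            parts = []
            for b in kids:
                sub = b.branch_id if b.is_terminal else render(b.child_id)
                parts.append(f"{sub}:{b.length:.10g}")
            return "(" + ",".join(parts) + ")"

        return render("root") + ";"


def _normalize_labels(
    labels: Sequence[str],
    expected: Sequence[str],
    label_map: Mapping[str, str] | None,
) -> dict[str, str]:
    """Map observed taxon labels onto the canonical study names.

    Matching is case-insensitive; an unambiguous prefix (``nig`` →
    ``nigrodunni``) is accepted; anything else requires an explicit entry in
    ``label_map``.
    """
    label_map = {k.lower(): v for k, v in (label_map or {}).items()}
    resolved: dict[str, str] = {}
    for lab in labels:
        key = lab.lower().replace("d.", "").replace("d_", "").strip("_ .")
        if key in label_map:
            resolved[lab] = label_map[key]
            continue
        hits = [t for t in expected if t == key]
        if not hits:
            hits = [t for t in expected if t.startswith(key)]
        if len(hits) != 1:
            raise ConfigurationError(
                f"taxon label {lab!r} does not match a study taxon; provide a label mapping"
            )
        resolved[lab] = hits[0]
    missing = set(expected) - set(resolved.values())
    if missing:
        raise ConfigurationError(f"tree is missing expected taxa: {sorted(missing)}")
    if len(set(resolved.values())) != len(resolved):
        raise FormatError("two tree labels resolve to the same study taxon")
    return resolved


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic location and functional-category labels for one gene.

    ``start`` is the 1-based start coordinate in bp; neighborhood distance is
    measured between start coordinates. ``categories`` may be empty (a plain
    background gene).
    """

    gene_id: str
    chromosome: str
    start: int
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"{self.gene_id}: start coordinate {self.start} < 1")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_codon_alignment(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path.name}: no FASTA records")
    try:
        return CodonAlignment(
            gene_id=gene_id or path.stem,
            sequences=[(r.id, str(r.seq).upper()) for r in records],
        )
    except (MalformedGeneError, FormatError) as exc:
        raise type(exc)(f"{path.name}: {exc}") from None


def read_codon_alignments(path: str | Path) -> list[CodonAlignment]:
    """Read every FASTA file in a directory; one CodonAlignment per file,
    gene_id taken from the file stem. Files are processed in sorted order."""
    path = Path(path)
    files = sorted(p for p in path.iterdir() if re.fullmatch(r".*\.(fa|fasta|fna)", p.name))
    return [read_codon_alignment(p) for p in files]


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in aln.sequences:
            fh.write(f">{taxon}\n{seq}\n")


def read_tree(path: str | Path, **kwargs) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text(), **kwargs)


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read the gene annotation TSV (gene_id, chromosome, start, categories).

    ``categories`` is a semicolon-delimited list, possibly empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "chromosome", "start", "categories"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation table missing columns {sorted(required - set(df.columns))}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id {dup!r} in annotation table")
    out = []
    for row in df.itertuples(index=False):
        raw = row.start.strip()
        if not re.fullmatch(r"\d+", raw):
            raise FormatError(f"{row.gene_id}: non-integer start {row.start!r}")
        cats = frozenset(c.strip() for c in row.categories.split(";") if c.strip())
        out.append(
            GeneAnnotation(
                gene_id=row.gene_id.strip(),
                chromosome=row.chromosome.strip(),
                start=int(raw),
                categories=cats,
            )
        )
    return out


def write_annotations(annotations: Sequence[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "gene_id": a.gene_id,
            "chromosome": a.chromosome,
            "start": a.start,
            "categories": ";".join(sorted(a.categories)),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "categories"]).to_csv(
        path, sep="\t", index=False
    )


def category_memberships(annotations: Sequence[GeneAnnotation]) -> dict[str, set[str]]:
    """Invert annotations into category → gene-id set."""
    out: dict[str, set[str]] = {}
    for a in annotations:
        for c in a.categories:
            out.setdefault(c, set()).add(a.gene_id)
    return out


def read_memberships(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column membership TSV (category, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"category", "gene_id"}.issubset(df.columns):
        raise FormatError("membership table needs columns: category, gene_id")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.category, set()).add(row.gene_id)
    return out
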