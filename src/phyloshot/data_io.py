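"""Readers, writers and cross-reference validation for the pipeline's inputs.

Four kinds of files flow into the annotation pipeline:

* a species phylogeny (Newick, branch lengths required),
* a reference database of short marker sequences (FASTA) plus a
  species -> genus/family/order taxonomy table (TSV),
* species co-occurrence data, either site x species assemblage lists (TSV)
  or presence grids at 1-degree resolution (TSV),
* demultiplexed, primer-trimmed eDNA reads (FASTA, optionally carrying
  usearch-style ``;size=N`` abundance annotations).

FASTA header convention for reference sequences: the first
whitespace-delimited token is ``accession|species_id``; if no ``|`` is
present the whole token is used as both sequence id and species id.
Species identifiers are case-sensitive exact strings everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RANKS = ("genus", "family", "order")


class DataValidationError(ValueError):
    """Raised when a loaded file violates a cross-reference invariant."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted, leaf-labelled phylogeny with non-negative branch lengths.

    Wraps a dendropy tree in flat arrays (parent pointers, branch lengths,
    children lists) for fast traversal.  The canonical species order used by
    every downstream table is ``self.taxa`` (sorted leaf labels).
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.blen = np.zeros(n, dtype=np.float64)
        self.children: list[list[int]] = [[] for _ in range(n)]
        leaf_labels: list[str] = []
        self._leaf_node: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                if nd.edge.length is None:
                    name = nd.taxon.label if nd.taxon else f"internal node #{i}"
                    raise DataValidationError(
                        f"missing branch length on the edge above {name!r}"
                    )
                if nd.edge.length < 0:
                    raise DataValidationError(
                        f"negative branch length ({nd.edge.length}) above node #{i}"
                    )
                self.blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise DataValidationError(f"leaf node #{i} has no label")
                label = nd.taxon.label.replace(" ", "_")
                if label in self._leaf_node:
                    raise DataValidationError(f"duplicate leaf label {label!r}")
                self._leaf_node[label] = i
                leaf_labels.append(label)
        self.taxa: list[str] = sorted(leaf_labels)
        self.taxon_index: dict[str, int] = {t: k for k, t in enumerate(self.taxa)}
        self._leafsets: Optional[list[np.ndarray]] = None

    # -- basic properties ---------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node (root has depth 0)."""
        n = self.n_nodes
        depth = np.zeros(n)
        for i in range(1, n):  # preorder: parent precedes child
            depth[i] = depth[self.parent[i]] + self.blen[i]
        return depth

    def leaf_sets(self) -> list[np.ndarray]:
        """For every node, the sorted taxa positions of its descendant leaves."""
        if self._leafsets is None:
            pos_of_node = {nd: self.taxon_index[lbl] for lbl, nd in self._leaf_node.items()}
            sets: list[Optional[list[int]]] = [None] * self.n_nodes
            for i in range(self.n_nodes - 1, -1, -1):  # reverse preorder = postorder-ish
                if not self.children[i]:
                    sets[i] = [pos_of_node[i]]
                else:
                    acc: list[int] = []
                    for c in self.children[i]:
                        acc.extend(sets[c])  # type: ignore[arg-type]
                    sets[i] = acc
            self._leafsets = [np.array(sorted(s), dtype=np.int64) for s in sets]  # type: ignore[arg-type]
        return self._leafsets

    def node_ages(self) -> np.ndarray:
        """Max distance from each node down to its descendant leaves.

        Equals time-before-present on an ultrametric tree.
        """
        ages = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 1, 0, -1):
            p = self.parent[i]
            ages[p] = max(ages[p], ages[i] + self.blen[i])
        return ages

    # -- distances ----------------------------------------------------------

    def patristic_matrix(self) -> np.ndarray:
        """All-pairs patristic distances, rows/cols in ``self.taxa`` order.

        Computed as depth(i) + depth(j) - 2 depth(lca(i, j)) by visiting every
        internal node once and pairing the leaf sets of its distinct child
        subtrees; O(n^2) total work.
        """
        n = self.n_leaves
        D = np.zeros((n, n))
        depth = self.node_depths()
        leaf_depth = np.zeros(n)
        for lbl, nd in self._leaf_node.items():
            leaf_depth[self.taxon_index[lbl]] = depth[nd]
        sets = self.leaf_sets()
        for u in range(self.n_nodes):
            ch = self.children[u]
            for a in range(len(ch)):
                for b in range(a + 1, len(ch)):
                    A, B = sets[ch[a]], sets[ch[b]]
                    block = leaf_depth[A][:, None] + leaf_depth[B][None, :] - 2 * depth[u]
                    D[np.ix_(A, B)] = block
                    D[np.ix_(B, A)] = block.T
        return D

    def sibling_leaf_sets(self, focal: str) -> list[np.ndarray]:
        """Leaf sets of the sibling subtrees at each branching on the
        root-to-``focal`` path (ordered leaf to root).

        At a polytomy the union of all non-focal child subtrees counts as the
        single sibling set of that branching.
        """
        if focal not in self._leaf_node:
            raise KeyError(f"unknown leaf {focal!r}")
        sets = self.leaf_sets()
        out: list[np.ndarray] = []
        node = self._leaf_node[focal]
        while self.parent[node] != -1:
            p = self.parent[node]
            sibs = [sets[c] for c in self.children[p] if c != node]
            if sibs:
                out.append(np.concatenate(sibs))
            node = p
        return out

    # -- IO -----------------------------------------------------------------

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy reports line/column in the message
            raise DataValidationError(f"malformed Newick: {exc}") from exc
        return cls(dtree)


def load_tree(path: str | Path) -> PhyloTree:
    """Parse a Newick file (branch lengths required) into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# Reference database + taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRecord:
    """One marker sequence attached to a species label."""

    sequence_id: str
    species_id: str
    sequence: str


class TaxonomyTable:
    """species_id -> (genus, family, order), total on all species in use."""

    def __init__(self, df: pd.DataFrame):
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise DataValidationError(f"taxonomy missing columns: {missing}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate species in taxonomy: {dups}")
        bad = df[list(RANKS)].map(lambda v: not isinstance(v, str) or not v)
        if bad.to_numpy().any():
            raise DataValidationError("taxonomy ranks must be non-empty strings")
        self.df = df[list(RANKS)].copy()

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.df.index

    def rank_of(self, species_id: str, rank: str) -> str:
        if rank == "species":
            return species_id
        try:
            return self.df.at[species_id, rank]
        except KeyError:
            raise DataValidationError(f"species {species_id!r} not in taxonomy")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 4:
            raise DataValidationError(
                "taxonomy TSV needs 4 columns: species, genus, family, order"
            )
        df.columns = ["species", *RANKS][: df.shape[1]]
        return cls(df.set_index("species"))

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.reset_index(names="species")
        out.to_csv(path, sep="\t", index=False)


def _species_from_header(token: str) -> str:
    return token.split("|", 1)[1] if "|" in token else token


def load_reference(
    fasta_path: str | Path, taxonomy: str | Path | TaxonomyTable
) -> tuple[list[ReferenceRecord], TaxonomyTable]:
    """Load reference sequences and check every species against the taxonomy."""
    tax = taxonomy if isinstance(taxonomy, TaxonomyTable) else TaxonomyTable.from_tsv(taxonomy)
    records: list[ReferenceRecord] = []
    unknown: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise DataValidationError(f"empty sequence for record {rec.id!r}")
        sp = _species_from_header(rec.id)
        if sp not in tax:
            unknown.add(sp)
        records.append(ReferenceRecord(rec.id, sp, seq))
    if unknown:
        raise DataValidationError(
            f"species in FASTA absent from taxonomy: {sorted(unknown)}"
        )
    return records, tax


def write_reference_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = r.sequence_id if "|" in r.sequence_id else f"{r.sequence_id}|{r.species_id}"
            fh.write(f">{header}\n{r.sequence}\n")


def reference_index(records: Iterable[ReferenceRecord]) -> dict[str, list[ReferenceRecord]]:
    """Group reference records by species."""
    idx: dict[str, list[ReferenceRecord]] = {}
    for r in records:
        idx.setdefault(r.species_id, []).append(r)
    return idx


# ---------------------------------------------------------------------------
# Assemblages and occurrence grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteAssemblage:
    """Set of species detected/observed together at one site."""

    site_id: str
    species_ids: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.species_ids)) != len(self.species_ids):
            raise DataValidationError(f"duplicate species within site {self.site_id!r}")

    @property
    def size(self) -> int:
        return len(self.species_ids)


def load_assemblages(
    path: str | Path,
    known_species: Optional[set[str]] = None,
    on_unknown: str = "drop",
) -> list[SiteAssemblage]:
    """Read (site_id, species_id) rows into one assemblage per site.

    Duplicate (site, species) rows collapse with a warning.  Species absent
    from ``known_species`` (e.g. a tree's leaf set) are dropped with a warning
    by default, or raise when ``on_unknown='error'``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["site_id", "species_id"],
                     skip_blank_lines=True)
    if df.empty:
        return []
    if df.iloc[0].tolist() == ["site_id", "species_id"]:
        df = df.iloc[1:]
    if known_species is not None:
        mask = df["species_id"].isin(known_species)
        if not mask.all():
            offenders = sorted(df.loc[~mask, "species_id"].unique())
            if on_unknown == "error":
                raise DataValidationError(f"unknown species in assemblages: {offenders}")
            logger.warning("dropping %d unknown species from assemblages: %s",
                           len(offenders), offenders[:10])
            df = df[mask]
    sites: list[SiteAssemblage] = []
    for site_id, grp in df.groupby("site_id", sort=True):
        sp = grp["species_id"].tolist()
        uniq = sorted(set(sp))
        if len(uniq) != len(sp):
            logger.warning("site %s: collapsed duplicate species rows", site_id)
        if uniq:
            sites.append(SiteAssemblage(str(site_id), tuple(uniq)))
    return sites


def write_assemblages(sites: Iterable[SiteAssemblage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            for sp in s.species_ids:
                fh.write(f"{s.site_id}\t{sp}\n")


@dataclass
class OccurrenceGrid:
    """Species presence on an integer lat/lon grid (1-degree cells)."""

    cells: dict[str, set[tuple[int, int]]] = field(default_factory=dict)

    def add(self, species_id: str, row: int, col: int) -> None:
        self.cells.setdefault(species_id, set()).add((int(row), int(col)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OccurrenceGrid":
        grid = cls()
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["species_id", "cell_row", "cell_col"])
        for sp, r, c in df.itertuples(index=False):
            grid.add(str(sp), int(r), int(c))
        return grid

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sp in sorted(self.cells):
                for r, c in sorted(self.cells[sp]):
                    fh.write(f"{sp}\t{r}\t{c}\n")


# ---------------------------------------------------------------------------
# eDNA reads
# ---------------------------------------------------------------------------

def load_reads(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a demultiplexed sample FASTA into (read_id, sequence, count) rows.

    usearch-style ``;size=N`` annotations on the header are honored; reads
    without one count as a single copy.
    """
    out: list[tuple[str, str, int]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        rid = rec.id
        for part in rid.split(";"):
            if part.startswith("size="):
                count = int(part[5:])
        out.append((rid, str(rec.seq).upper(), count))
    return out


def write_reads(reads: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, count in reads:
            suffix = f";size={count}" if count != 1 and ";size=" not in rid else ""
            fh.write(f">{rid}{suffix}\n{seq}\n")
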