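"""Taxonomy backbone, reference database and k-mer coverage evaluation.

The taxonomy is a rooted multi-rank tree in the style of the NCBI
``nodes.dmp``/``names.dmp`` dumps: every node has a ``taxon_id``, a
``parent_id`` (the root is its own parent), a rank drawn from an ordered
rank list, and a name.  It is the backbone for lowest-common-ancestor (LCA)
read assignment and for collating read counts at a chosen rank.

The reference database is a flat collection of taxon-linked nucleotide
sequences.  ``kmer_coverage`` measures how well the database represents a
query genome as the fraction of the query's distinct canonical k-mers that
occur anywhere in the database — a database-adequacy proxy that degrades
smoothly with divergence between the query and its nearest reference.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp, validate_sequence

DEFAULT_RANKS: tuple[str, ...] = (
    "root",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy (orphan, cycle, duplicate, bad rank)."""


class UnknownTaxonError(KeyError):
    """A taxon_id does not resolve in the taxonomy."""


@dataclasses.dataclass(frozen=True)
class TaxonNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str


class Taxonomy:
    """Rooted taxonomic tree with rank-aware ancestor queries.

    Parameters
    ----------
    nodes:
        TaxonNode records.  Exactly one node must be its own parent (the
        root); every other ``parent_id`` must resolve; a child's rank must
        never be above its parent's rank in ``ranks`` order.
    ranks:
        Ordered rank list, shallowest first.  Comparisons use list order.
    """

    def __init__(self, nodes: Iterable[TaxonNode], ranks: Sequence[str] = DEFAULT_RANKS):
        self.ranks = tuple(ranks)
        self._rank_index = {r: i for i, r in enumerate(self.ranks)}
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id}")
            if node.rank not in self._rank_index:
                raise TaxonomyError(f"unknown rank {node.rank!r} at taxon {node.taxon_id}")
            self.nodes[node.taxon_id] = node

        roots = [n for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0].taxon_id

        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"taxon {node.taxon_id} has parent_id {node.parent_id} "
                    "absent from the taxonomy"
                )

        # Depth computation doubles as cycle detection.
        self._depth: dict[int, int] = {self.root_id: 0}
        for tid in self.nodes:
            self._depth_of(tid)

        for node in self.nodes.values():
            if node.taxon_id == self.root_id:
                continue
            parent = self.nodes[node.parent_id]
            if self._rank_index[node.rank] < self._rank_index[parent.rank]:
                raise TaxonomyError(
                    f"taxon {node.taxon_id} has rank {node.rank!r} above its "
                    f"parent's rank {parent.rank!r}"
                )

    def _depth_of(self, taxon_id: int) -> int:
        if taxon_id in self._depth:
            return self._depth[taxon_id]
        chain = []
        tid = taxon_id
        while tid not in self._depth:
            if tid in chain:
                raise TaxonomyError(f"cycle detected through taxon {tid}")
            chain.append(tid)
            tid = self.nodes[tid].parent_id
        base = self._depth[tid]
        for i, t in enumerate(reversed(chain), start=1):
            self._depth[t] = base + i
        return self._depth[taxon_id]

    # -- queries ---------------------------------------------------------

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: int) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise UnknownTaxonError(f"unknown taxon_id {taxon_id}") from None

    def name(self, taxon_id: int) -> str:
        return self.node(taxon_id).name

    def depth(self, taxon_id: int) -> int:
        self.node(taxon_id)
        return self._depth[taxon_id]

    def path_to_root(self, taxon_id: int) -> list[int]:
        """Node ids from ``taxon_id`` up to and including the root."""
        self.node(taxon_id)
        path = [taxon_id]
        while path[-1] != self.root_id:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def is_ancestor_or_self(self, ancestor: int, descendant: int) -> bool:
        return ancestor in self.path_to_root(descendant)

    def lca(self, taxa: Iterable[int]) -> int:
        return lca(self, taxa)

    def ancestor_at_rank(self, taxon_id: int, rank: str) -> int | None:
        """The ancestor-or-self of ``taxon_id`` with the given rank, if any."""
        if rank not in self._rank_index:
            raise TaxonomyError(f"rank {rank!r} not in rank list")
        for tid in self.path_to_root(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def rank_is_above(self, rank_a: str, rank_b: str) -> bool:
        """True if rank_a is shallower than rank_b in the rank list."""
        return self._rank_index[rank_a] < self._rank_index[rank_b]

    def children(self, taxon_id: int) -> list[int]:
        return [
            n.taxon_id
            for n in self.nodes.values()
            if n.parent_id == taxon_id and n.taxon_id != taxon_id
        ]

    # -- TSV dumps -------------------------------------------------------

    def to_tsv(self, nodes_path: str | Path, names_path: str | Path) -> None:
        nodes = pd.DataFrame(
            [(n.taxon_id, n.parent_id, n.rank) for n in self.nodes.values()],
            columns=["taxon_id", "parent_id", "rank"],
        ).sort_values("taxon_id")
        names = pd.DataFrame(
            [(n.taxon_id, n.name) for n in self.nodes.values()],
            columns=["taxon_id", "name"],
        ).sort_values("taxon_id")
        nodes.to_csv(nodes_path, sep="\t", index=False)
        names.to_csv(names_path, sep="\t", index=False)


def read_taxonomy(
    nodes_path: str | Path,
    names_path: str | Path,
    ranks: Sequence[str] = DEFAULT_RANKS,
) -> Taxonomy:
    """Load a taxonomy from nodes/names TSV dumps, validating structure.

    Raises :class:`TaxonomyError` naming the offending row for orphan
    parents, duplicate ids and multiple roots.
    """
    nodes_df = pd.read_csv(nodes_path, sep="\t", dtype={"taxon_id": int, "parent_id": int})
    names_df = pd.read_csv(names_path, sep="\t", dtype={"taxon_id": int})
    name_map = dict(zip(names_df["taxon_id"], names_df["name"].astype(str)))
    nodes = [
        TaxonNode(
            taxon_id=int(row.taxon_id),
            parent_id=int(row.parent_id),
            rank=str(row.rank),
            name=name_map.get(int(row.taxon_id), f"taxon_{int(row.taxon_id)}"),
        )
        for row in nodes_df.itertuples()
    ]
    return Taxonomy(nodes, ranks=ranks)


def lca(taxonomy: Taxonomy, taxa: Iterable[int]) -> int:
    """Lowest common ancestor of a non-empty set of taxa.

    Returns the deepest node that is an ancestor-or-self of every input.
    Commutative and idempotent; ``lca({t}) == t``.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("lca of an empty taxon set is undefined")
    paths = [taxonomy.path_to_root(t)[::-1] for t in taxa]  # root-first
    shortest = min(len(p) for p in paths)
    result = taxonomy.root_id
    for i in range(shortest):
        level = {p[i] for p in paths}
        if len(level) == 1:
            result = level.pop()
        else:
            break
    return result


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RefSeq:
    seq_id: str
    taxon_id: int
    sequence: str


class ReferenceDB:
    """Taxon-linked nucleotide reference sequences.

    Sequences are validated to uppercase ACGTN.  If a taxonomy is supplied,
    every ``taxon_id`` must resolve in it.
    """

    def __init__(self, entries: Iterable[RefSeq], taxonomy: Taxonomy | None = None):
        self.entries: list[RefSeq] = []
        self.by_taxon: dict[int, list[int]] = {}
        self._by_seq_id: dict[str, int] = {}
        for e in entries:
            seq = validate_sequence(e.sequence, what=f"sequence {e.seq_id}")
            if taxonomy is not None and e.taxon_id not in taxonomy:
                raise UnknownTaxonError(
                    f"sequence {e.seq_id}: taxon_id {e.taxon_id} not in taxonomy"
                )
            if e.seq_id in self._by_seq_id:
                raise ValueError(f"duplicate seq_id {e.seq_id}")
            idx = len(self.entries)
            self.entries.append(RefSeq(e.seq_id, e.taxon_id, seq))
            self.by_taxon.setdefault(e.taxon_id, []).append(idx)
            self._by_seq_id[e.seq_id] = idx
        self._kmer_cache: dict[int, set[str]] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def sequence(self, seq_id: str) -> RefSeq:
        try:
            return self.entries[self._by_seq_id[seq_id]]
        except KeyError:
            raise KeyError(f"unknown seq_id {seq_id}") from None

    def sequences_of(self, taxon_id: int) -> list[RefSeq]:
        return [self.entries[i] for i in self.by_taxon.get(taxon_id, [])]

    def taxa(self) -> list[int]:
        return sorted(self.by_taxon)

    def kmer_set(self, k: int) -> set[str]:
        """Distinct canonical k-mers over all entries (N-containing skipped)."""
        if k not in self._kmer_cache:
            kmers: set[str] = set()
            for e in self.entries:
                kmers |= canonical_kmers(e.sequence, k)
            self._kmer_cache[k] = kmers
        return self._kmer_cache[k]

    # -- FASTA I/O (header convention: ``>seqid taxid=<id>``) -------------

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(e.sequence), id=e.seq_id, description=f"taxid={e.taxon_id}")
            for e in self.entries
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, taxonomy: Taxonomy | None = None) -> "ReferenceDB":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxid = None
            for field in rec.description.split():
                if field.startswith("taxid="):
                    taxid = int(field[len("taxid="):])
            if taxid is None:
                raise ValueError(f"FASTA record {rec.id} lacks a 'taxid=' field")
            entries.append(RefSeq(rec.id, taxid, str(rec.seq).upper()))
        return cls(entries, taxonomy=taxonomy)


def canonical_kmers(sequence: str, k: int) -> set[str]:
    """Distinct canonical k-mers of a sequence.

    The canonical form of a k-mer is the lexicographic minimum of the k-mer
    and its reverse complement, so a sequence and its reverse complement
    yield the same set.  Windows containing N are skipped.
    """
    seq = sequence.upper()
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(min(kmer, rc))
    return out


def kmer_coverage(db: ReferenceDB, query_genome: str, k: int = 31) -> float:
    """Fraction of a query genome's distinct canonical k-mers found in ``db``.

    Coverage counts distinct k-mers, not k-mer positions, so repeats do not
    inflate it.  Returns a value in [0, 1].
    """
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    query = validate_sequence(query_genome, what="query genome")
    if len(query) < k:
        raise ValueError(f"query length {len(query)} shorter than k={k}")
    qk = canonical_kmers(query, k)
    if not qk:
        raise ValueError("query has no N-free k-mers")
    dbk = db.kmer_set(k)
    return len(qk & dbk) / len(qk)


def kmer_coverage_report(
    db: ReferenceDB, queries: dict[int, str], k: int = 31
) -> pd.DataFrame:
    """Per-taxon coverage table: taxon_id, n_query_kmers, n_found, coverage."""
    rows = []
    dbk = db.kmer_set(k)
    for taxon_id in sorted(queries):
        qk = canonical_kmers(queries[taxon_id], k)
        n_found = len(qk & dbk)
        rows.append(
            {
                "taxon_id": taxon_id,
                "n_query_kmers": len(qk),
                "n_found": n_found,
                "coverage": n_found / len(qk) if qk else float("nan"),
            }
        )
    return pd.DataFrame(rows)
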