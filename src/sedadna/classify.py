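"""Read classification: gap-free alignment against the reference database,
per-read LCA assignment over 100%-identity hits, exclusive-alignment
confirmation for animal detections, control subtraction, checklist
filtering, and rank-level count-matrix collation.

Matching is an exhaustive gap-free k-mismatch scan over every reference on
both strands: at sedaDNA fragment lengths (30–90 bp) indels are rare enough
that gap-free matching is the conventional simplification, and exhaustive
scanning makes "every placement with ≤ max_mismatches" a guarantee rather
than a heuristic.  An ambiguous base N never counts as a match on either
side.  Coordinates are 0-based half-open internally; SAM export converts to
1-based.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode_read, encode_ref, revcomp, validate_sequence
from .taxdb import ReferenceDB, Taxonomy, lca

DEFAULT_MIN_READ_LENGTH = 30


@dataclasses.dataclass(frozen=True)
class Hit:
    """One gap-free placement of a read on a reference sequence."""

    read_id: str
    seq_id: str
    taxon_id: int
    start: int  # 0-based offset on the reference forward strand
    strand: str  # '+' or '-'
    mismatches: int
    read_length: int

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.read_length


@dataclasses.dataclass(frozen=True)
class Assignment:
    read_id: str
    taxon_id: int
    n_perfect_hits: int
    n_taxa_hit: int


@dataclasses.dataclass
class CountMatrix:
    """Taxa × samples read counts collated at one rank.

    ``counts`` is indexed by taxon_id with sample ids as columns;
    ``above_rank`` holds, per sample, reads whose assignment sits above the
    collation rank; ``log`` accumulates an auditable filter ledger.
    """

    rank: str
    counts: pd.DataFrame
    above_rank: pd.Series
    meta: pd.DataFrame | None = None
    log: list[str] = dataclasses.field(default_factory=list)

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.rank,
            self.counts.copy(),
            self.above_rank.copy(),
            None if self.meta is None else self.meta.copy(),
            list(self.log),
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _encoded_refs(db: ReferenceDB) -> list[np.ndarray]:
    cache = getattr(db, "_encoded_refs", None)
    if cache is None:
        cache = [encode_ref(e.sequence) for e in db.entries]
        db._encoded_refs = cache  # type: ignore[attr-defined]
    return cache


def best_placements(
    read: str,
    db: ReferenceDB,
    max_mismatches: int,
    read_id: str = "read",
) -> list[Hit]:
    """All gap-free placements of a read with ≤ ``max_mismatches``.

    Internal workhorse without :func:`match_read`'s parameter caps; used by
    damage profiling, which must place heavily deaminated reads.
    """
    seq = validate_sequence(read, what=f"read {read_id}")
    n = len(seq)
    encoded = {"+": encode_read(seq), "-": encode_read(revcomp(seq))}
    refs = _encoded_refs(db)
    hits: list[Hit] = []
    for idx, entry in enumerate(db.entries):
        ref_arr = refs[idx]
        if len(ref_arr) < n:
            continue
        windows = sliding_window_view(ref_arr, n)
        for strand in "+-":
            mism = (windows != encoded[strand]).sum(axis=1)
            for start in np.flatnonzero(mism <= max_mismatches):
                hits.append(
                    Hit(
                        read_id=read_id,
                        seq_id=entry.seq_id,
                        taxon_id=entry.taxon_id,
                        start=int(start),
                        strand=strand,
                        mismatches=int(mism[start]),
                        read_length=n,
                    )
                )
    return hits


def match_read(
    read: str,
    db: ReferenceDB,
    max_mismatches: int = 2,
    read_id: str = "read",
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
) -> list[Hit]:
    """Every (reference, offset, strand) placement with ≤ ``max_mismatches``.

    Gap-free; no indels are considered.  Reads shorter than
    ``min_read_length`` and slacks above 3 mismatches are rejected as
    parameter errors.
    """
    if len(read) < min_read_length:
        raise ValueError(
            f"read {read_id} length {len(read)} below minimum {min_read_length}"
        )
    if max_mismatches > 3:
        raise ValueError(f"max_mismatches must be <= 3, got {max_mismatches}")
    return best_placements(read, db, max_mismatches, read_id=read_id)


def assign_read(hits: Iterable[Hit], taxonomy: Taxonomy) -> Assignment | None:
    """LCA assignment over the 100%-identity hits of one read.

    Hits with any mismatch are discarded; if no perfect hit remains the
    read is unassigned (returns None); a single perfectly hit taxon is
    assigned directly; several taxa collapse to their lowest common
    ancestor.
    """
    perfect = [h for h in hits if h.mismatches == 0]
    if not perfect:
        return None
    taxa = {h.taxon_id for h in perfect}
    assigned = lca(taxonomy, taxa) if len(taxa) > 1 else next(iter(taxa))
    return Assignment(
        read_id=perfect[0].read_id,
        taxon_id=assigned,
        n_perfect_hits=len(perfect),
        n_taxa_hit=len(taxa),
    )


def classify_reads(
    reads: Iterable,
    db: ReferenceDB,
    taxonomy: Taxonomy,
    max_mismatches: int = 2,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
) -> tuple[list[Assignment], list[str]]:
    """Match and assign a read set; returns (assignments, unassigned ids).

    Reads with identical sequence are collapsed before matching (each
    unique sequence is assessed once) and their assignments re-expanded, so
    duplicates cannot change a call but are preserved in counts.  Reads
    shorter than ``min_read_length`` are skipped and reported unassigned.
    """
    by_seq: dict[str, list[str]] = {}
    order: list[tuple[str, str]] = []
    for r in reads:
        by_seq.setdefault(r.sequence, []).append(r.read_id)
        order.append((r.read_id, r.sequence))
    cache: dict[str, Assignment | None] = {}
    for seq, ids in by_seq.items():
        if len(seq) < min_read_length:
            cache[seq] = None
            continue
        hits = match_read(
            seq, db, max_mismatches, read_id=ids[0], min_read_length=min_read_length
        )
        cache[seq] = assign_read(hits, taxonomy)
    assignments: list[Assignment] = []
    unassigned: list[str] = []
    for read_id, seq in order:
        a = cache[seq]
        if a is None:
            unassigned.append(read_id)
        else:
            assignments.append(
                Assignment(read_id, a.taxon_id, a.n_perfect_hits, a.n_taxa_hit)
            )
    return assignments, unassigned


def exclusive_confirm(
    read: str, focal_taxon: int, db: ReferenceDB, slack: int = 2
) -> bool:
    """Exclusive-alignment confirmation for an animal detection.

    True iff the read has a perfect (0-mismatch) placement in the focal
    taxon's references AND no placement within ``slack`` mismatches in any
    other taxon's references.  Mutually exclusive across taxa by
    construction: a perfect hit in B is within slack of B for A's check.
    """
    if slack not in (1, 2):
        raise ValueError(f"slack must be 1 or 2, got {slack}")
    if not db.sequences_of(focal_taxon):
        raise KeyError(f"focal taxon {focal_taxon} has no reference sequences")
    hits = best_placements(read, db, slack)
    focal_perfect = any(
        h.taxon_id == focal_taxon and h.mismatches == 0 for h in hits
    )
    other_close = any(h.taxon_id != focal_taxon for h in hits)
    return focal_perfect and not other_close


# ---------------------------------------------------------------------------
# Collation and filtering
# ---------------------------------------------------------------------------


def collate_profile(
    assignments: Iterable[Assignment],
    taxonomy: Taxonomy,
    rank: str,
    sample_ids: dict[str, str],
) -> CountMatrix:
    """Collate assignments into a taxa × samples count matrix at one rank.

    A read contributes to the row that is the rank-level ancestor-or-self
    of its assigned taxon; reads assigned above the rank go to the
    per-sample ``above_rank`` ledger instead, so
    ``matrix.total() + above_rank.sum() == len(assignments)``.
    """
    if rank not in taxonomy.ranks:
        raise ValueError(f"rank {rank!r} not in the taxonomy's rank list")
    counts: dict[tuple[int, str], int] = {}
    above: dict[str, int] = {}
    samples_seen: list[str] = []
    for a in assignments:
        try:
            sample = sample_ids[a.read_id]
        except KeyError:
            raise KeyError(f"read {a.read_id} has no sample mapping") from None
        if sample not in samples_seen:
            samples_seen.append(sample)
        row = taxonomy.ancestor_at_rank(a.taxon_id, rank)
        if row is None:
            above[sample] = above.get(sample, 0) + 1
        else:
            counts[(row, sample)] = counts.get((row, sample), 0) + 1
    taxa = sorted({t for t, _ in counts})
    mat = pd.DataFrame(0, index=taxa, columns=samples_seen, dtype=int)
    for (t, s), c in counts.items():
        mat.loc[t, s] = c
    above_series = pd.Series(
        [above.get(s, 0) for s in samples_seen], index=samples_seen, dtype=int
    )
    return CountMatrix(rank=rank, counts=mat, above_rank=above_series)


def subtract_control_taxa(
    matrix: CountMatrix, control_matrices: list[CountMatrix]
) -> CountMatrix:
    """Remove every taxon detected in any laboratory control.

    The union of taxa with nonzero counts across the controls is dropped as
    whole rows from the sample matrix, regardless of sample counts; the
    removal is recorded in the matrix log.
    """
    for c in control_matrices:
        if c.rank != matrix.rank:
            raise ValueError(
                f"control rank {c.rank!r} does not match sample rank {matrix.rank!r}"
            )
    contaminants: set[int] = set()
    for c in control_matrices:
        present = c.counts.index[(c.counts > 0).any(axis=1)]
        contaminants.update(int(t) for t in present)
    out = matrix.copy()
    removed = sorted(contaminants & set(out.counts.index))
    out.counts = out.counts.drop(index=removed)
    out.log.append(
        f"control-subtraction: removed {len(removed)} taxa {removed} "
        f"(union over {len(control_matrices)} controls)"
    )
    return out


def checklist_filter(
    matrix: CountMatrix,
    checklist: set[str],
    taxonomy: Taxonomy,
    min_reads: int = 3,
    min_samples: int = 1,
) -> CountMatrix:
    """Authentication filters: regional checklist + conservative thresholds.

    Rows whose taxon name is not on the checklist are dropped and logged;
    per-sample counts below ``min_reads`` are zeroed; rows left nonzero in
    fewer than ``min_samples`` samples are dropped.
    """
    if min_reads < 1 or min_samples < 1:
        raise ValueError("min_reads and min_samples must be >= 1")
    out = matrix.copy()
    off_list = [t for t in out.counts.index if taxonomy.name(int(t)) not in checklist]
    out.counts = out.counts.drop(index=off_list)
    out.log.append(
        f"checklist: dropped {len(off_list)} off-checklist taxa "
        f"{[taxonomy.name(int(t)) for t in off_list]}"
    )
    zeroed = int((out.counts.to_numpy() < min_reads).sum() - (out.counts.to_numpy() == 0).sum())
    out.counts = out.counts.where(out.counts >= min_reads, 0)
    out.log.append(f"min_reads={min_reads}: zeroed {zeroed} sub-threshold cells")
    support = (out.counts > 0).sum(axis=1)
    weak = [t for t in out.counts.index if support[t] < min_samples]
    out.counts = out.counts.drop(index=weak)
    out.log.append(f"min_samples={min_samples}: dropped {len(weak)} weakly supported taxa")
    return out


# ---------------------------------------------------------------------------
# Hit I/O (SAM and TSV)
# ---------------------------------------------------------------------------


def hits_to_tsv(hits: Iterable[Hit], path: str | Path) -> None:
    pd.DataFrame(
        [
            (h.read_id, h.seq_id, h.taxon_id, h.start, h.strand, h.mismatches, h.read_length)
            for h in hits
        ],
        columns=["read_id", "seq_id", "taxon_id", "start", "strand", "mismatches", "read_length"],
    ).to_csv(path, sep="\t", index=False)


def hits_from_tsv(path: str | Path) -> list[Hit]:
    df = pd.read_csv(path, sep="\t")
    return [
        Hit(r.read_id, r.seq_id, int(r.taxon_id), int(r.start), r.strand,
            int(r.mismatches), int(r.read_length))
        for r in df.itertuples()
    ]


def hits_to_sam(
    hits: Iterable[Hit], db: ReferenceDB, reads: dict[str, str], path: str | Path
) -> None:
    """Write hits as SAM with the mismatch count in the NM tag.

    The stored SEQ is the reference-forward orientation (reverse-strand
    hits are flagged 16 and reverse-complemented, per SAM convention).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": e.seq_id, "LN": len(e.sequence)} for e in db.entries],
    }
    ref_index = {e.seq_id: i for i, e in enumerate(db.entries)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for h in hits:
            a = pysam.AlignedSegment(out.header)
            a.query_name = h.read_id
            seq = reads[h.read_id]
            a.query_sequence = revcomp(seq) if h.strand == "-" else seq
            a.flag = 16 if h.strand == "-" else 0
            a.reference_id = ref_index[h.seq_id]
            a.reference_start = h.start
            a.mapping_quality = 255
            a.cigarstring = f"{h.read_length}M"
            a.set_tag("NM", h.mismatches)
            out.write(a)


def hits_from_sam(path: str | Path, db: ReferenceDB) -> list[Hit]:
    taxon_of = {e.seq_id: e.taxon_id for e in db.entries}
    hits = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            hits.append(
                Hit(
                    read_id=a.query_name,
                    seq_id=a.reference_name,
                    taxon_id=taxon_of[a.reference_name],
                    start=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    mismatches=int(a.get_tag("NM")),
                    read_length=a.query_length,
                )
            )
    return hits
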