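"""Haplogroup placement of degraded read sets on a mitochondrial tree.

The reference panel provides a rooted tree and an ungapped multiple
alignment of its tips.  Branch-diagnostic markers are called by outgroup
polarization: a biallelic column whose derived-allele tips form exactly
one clade marks that clade's subtending branch.  An eDNA sample's reads
are mapped gap-free onto the alignment coordinate system and tallied at
marker positions; each branch then accumulates support (markers observed
derived) and conflict (markers observed ancestral), and every root-to-node
path is scored as path support minus path conflict minus derived
observations on off-path branches.  The best-scoring node is the
placement; tied nodes collapse to their common ancestor and are flagged
ambiguous.

Because C→T/G→A deamination can mimic or erase transition markers,
``transversions-only`` mode restricts scoring to damage-safe markers and
is the recommended mode for damaged samples.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode_read, encode_ref, is_transversion, revcomp
from .tree import RootedTree


@dataclasses.dataclass(frozen=True)
class BranchMarker:
    branch: str  # child-node id of the subtending branch
    position: int  # 0-based alignment column
    ancestral: str
    derived: str
    transversion: bool


@dataclasses.dataclass
class MarkerCallLog:
    n_columns: int = 0
    n_invariant: int = 0
    n_multiallelic: int = 0
    n_gapped: int = 0
    n_homoplasy: int = 0
    n_outgroup_private: int = 0
    homoplasy_columns: list[int] = dataclasses.field(default_factory=list)


def call_branch_markers(
    tree: RootedTree,
    alignment: dict[str, str],
    outgroup: str,
) -> tuple[list[BranchMarker], MarkerCallLog]:
    """Polarize alignment columns by the outgroup and map them to branches.

    For each biallelic, ungapped column the outgroup allele is taken as
    ancestral; if the set of tips carrying the other (derived) allele
    equals the tip set of exactly one clade, a marker is emitted on that
    clade's subtending branch.  Columns whose derived tips match no clade
    are homoplasious and logged; columns with >2 alleles or gaps are
    skipped and logged.
    """
    if outgroup not in alignment:
        raise ValueError(f"outgroup {outgroup!r} missing from the alignment")
    tips = [t for t in tree.tips() if t in alignment]
    if outgroup not in tips:
        raise ValueError(f"outgroup {outgroup!r} is not a tip of the tree")
    lengths = {len(alignment[t]) for t in tips}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    (ncol,) = lengths
    ingroup = [t for t in tips if t != outgroup]
    clade_to_branch = {
        tree.clade_tips(nid): nid
        for nid in tree.preorder()
        if nid != tree.root_id and nid != outgroup
    }
    log = MarkerCallLog(n_columns=ncol)
    markers: list[BranchMarker] = []
    for pos in range(ncol):
        column = {t: alignment[t][pos] for t in tips}
        if any(b in "-N" for b in column.values()):
            log.n_gapped += 1
            continue
        alleles = set(column.values())
        if len(alleles) == 1:
            log.n_invariant += 1
            continue
        if len(alleles) > 2:
            log.n_multiallelic += 1
            continue
        ancestral = column[outgroup]
        derived = (alleles - {ancestral}).pop()
        derived_tips = frozenset(t for t in ingroup if column[t] == derived)
        if not derived_tips:
            log.n_outgroup_private += 1
            continue
        branch = clade_to_branch.get(derived_tips)
        if branch is None:
            log.n_homoplasy += 1
            log.homoplasy_columns.append(pos)
            continue
        markers.append(
            BranchMarker(
                branch=branch,
                position=pos,
                ancestral=ancestral,
                derived=derived,
                transversion=is_transversion(ancestral, derived),
            )
        )
    return markers, log


# ---------------------------------------------------------------------------
# Read observations
# ---------------------------------------------------------------------------


def collect_observations(
    reads: Iterable,
    reference: str,
    markers: Sequence[BranchMarker],
    max_mismatches: int = 5,
) -> pd.DataFrame:
    """Map reads gap-free onto the alignment coordinates and tally alleles.

    Each read is placed at its unique best (fewest-mismatch) position on
    either strand of ``reference``; reads whose best placement is tied
    between positions, or worse than ``max_mismatches``, are skipped.  At
    every covered marker position the read's base is tallied as ancestral,
    derived or other; N bases are not tallied.

    Returns a DataFrame indexed by alignment position with columns
    n_ancestral / n_derived / n_other.
    """
    marker_pos = {m.position: m for m in markers}
    tall = {
        p: {"n_ancestral": 0, "n_derived": 0, "n_other": 0} for p in marker_pos
    }
    ref_arr = encode_ref(reference)
    for r in reads:
        seq = r.sequence
        n = len(seq)
        if n > len(reference):
            continue
        best_mm = max_mismatches + 1
        best: list[tuple[int, str]] = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            enc = encode_read(query)
            mism = (sliding_window_view(ref_arr, n) != enc).sum(axis=1)
            m_min = int(mism.min())
            if m_min < best_mm:
                best_mm = m_min
                best = [(int(i), strand) for i in np.flatnonzero(mism == m_min)]
            elif m_min == best_mm:
                best += [(int(i), strand) for i in np.flatnonzero(mism == m_min)]
        if best_mm > max_mismatches or len(best) != 1:
            continue
        start, strand = best[0]
        oriented = seq if strand == "+" else revcomp(seq)
        for pos in range(start, start + n):
            if pos not in tall:
                continue
            base = oriented[pos - start]
            if base == "N":
                continue
            m = marker_pos[pos]
            if base == m.ancestral:
                tall[pos]["n_ancestral"] += 1
            elif base == m.derived:
                tall[pos]["n_derived"] += 1
            else:
                tall[pos]["n_other"] += 1
    df = pd.DataFrame.from_dict(tall, orient="index").sort_index()
    df.index.name = "position"
    return df


# ---------------------------------------------------------------------------
# Placement scoring
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Placement:
    sample_id: str
    node_id: str | None  # None = unplaced
    score: float
    runner_up: float
    branch_support: dict[str, int]
    branch_conflict: dict[str, int]
    n_markers_observed: int
    ambiguous: bool
    mode: str

    @property
    def margin(self) -> float:
        return self.score - self.runner_up


def _majority_calls(
    markers: Sequence[BranchMarker], observations: pd.DataFrame, mode: str
) -> dict[str, tuple[int, int]]:
    """Per-branch (support, conflict) from per-position majority alleles.

    A marker position with reads is called derived or ancestral by
    majority; exact ties are discarded.  In transversions-only mode
    transition markers are ignored entirely.
    """
    per_branch: dict[str, tuple[int, int]] = {}
    for m in markers:
        if mode == "transversions-only" and not m.transversion:
            continue
        if m.position not in observations.index:
            continue
        row = observations.loc[m.position]
        n_der, n_anc = int(row.n_derived), int(row.n_ancestral)
        if n_der + n_anc == 0 or n_der == n_anc:
            continue
        s, c = per_branch.get(m.branch, (0, 0))
        if n_der > n_anc:
            per_branch[m.branch] = (s + 1, c)
        else:
            per_branch[m.branch] = (s, c + 1)
    return per_branch


def path_score(
    tree: RootedTree,
    node_id: str,
    support: dict[str, int],
    conflict: dict[str, int],
) -> float:
    """Score of placing a sample at ``node_id``.

    Σ(support − conflict) over branches on the root-to-node path, minus
    Σ support over off-path branches — so derived observations that the
    placement cannot explain count against it.
    """
    path = set(tree.branch_path(node_id))
    s_path = sum(support.get(b, 0) for b in path)
    c_path = sum(conflict.get(b, 0) for b in path)
    s_off = sum(v for b, v in support.items() if b not in path)
    return float(s_path - c_path - s_off)


def place_sample(
    tree: RootedTree,
    markers: Sequence[BranchMarker],
    observations: pd.DataFrame,
    mode: str = "all-sites",
    min_markers: int = 10,
    sample_id: str = "sample",
    exclude_nodes: Sequence[str] = (),
) -> Placement:
    """Best-scoring node for a sample's marker observations.

    Every node's root-to-node path is scored; the argmax is the placement.
    If several nodes tie at the maximum, the placement is their lowest
    common ancestor, flagged ambiguous (two equally supported sibling
    branches resolve to their parent).  Fewer than ``min_markers``
    majority-called marker observations → unplaced.  ``exclude_nodes``
    (e.g. the outgroup) are never placement candidates.
    """
    if mode not in ("all-sites", "transversions-only"):
        raise ValueError(f"unknown mode {mode!r}")
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    calls = _majority_calls(markers, observations, mode)
    support = {b: sc[0] for b, sc in calls.items()}
    conflict = {b: sc[1] for b, sc in calls.items()}
    n_obs = sum(s + c for s, c in calls.values())
    if n_obs < min_markers:
        return Placement(
            sample_id, None, float("nan"), float("nan"), support, conflict,
            n_obs, False, mode,
        )
    candidates = [n for n in tree.preorder() if n not in set(exclude_nodes)]
    scores = {n: path_score(tree, n, support, conflict) for n in candidates}
    best_score = max(scores.values())
    tied = [n for n, sc in scores.items() if sc == best_score]
    others = [sc for n, sc in scores.items() if n not in tied]
    runner_up = max(others) if others else best_score
    if len(tied) == 1:
        node, ambiguous = tied[0], False
    else:
        node, ambiguous = tree.lca(tied), True
    return Placement(
        sample_id=sample_id,
        node_id=node,
        score=best_score,
        runner_up=float(runner_up),
        branch_support=support,
        branch_conflict=conflict,
        n_markers_observed=n_obs,
        ambiguous=ambiguous,
        mode=mode,
    )


def haplogroup_of(
    placement: Placement, tree: RootedTree, clade_labels: dict[str, str]
) -> str:
    """Label of the deepest labelled clade containing the placement node.

    A placement above every labelled clade (e.g. at the shared root of two
    labelled sister clades) is "basal"; an unplaced sample is "unplaced".
    """
    if placement.node_id is None:
        return "unplaced"
    for nid in tree.path_to_root(placement.node_id):  # deepest first
        if nid in clade_labels:
            return clade_labels[nid]
    return "basal"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def markers_to_tsv(markers: Sequence[BranchMarker], path: str | Path) -> None:
    pd.DataFrame(
        [(m.branch, m.position, m.ancestral, m.derived, int(m.transversion)) for m in markers],
        columns=["branch", "position", "ancestral", "derived", "tv_flag"],
    ).to_csv(path, sep="\t", index=False)


def markers_from_tsv(path: str | Path) -> list[BranchMarker]:
    df = pd.read_csv(path, sep="\t")
    return [
        BranchMarker(str(r.branch), int(r.position), str(r.ancestral),
                     str(r.derived), bool(r.tv_flag))
        for r in df.itertuples()
    ]


def placements_to_tsv(
    placements: Sequence[Placement],
    tree: RootedTree,
    clade_labels: dict[str, str],
    path: str | Path,
) -> None:
    rows = []
    for p in placements:
        rows.append(
            {
                "sample": p.sample_id,
                "node": p.node_id if p.node_id is not None else "unplaced",
                "label": haplogroup_of(p, tree, clade_labels),
                "support": sum(p.branch_support.values()),
                "conflict": sum(p.branch_conflict.values()),
                "score": p.score,
                "margin": p.margin,
                "n_markers": p.n_markers_observed,
                "ambiguous": int(p.ambiguous),
                "mode": p.mode,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
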