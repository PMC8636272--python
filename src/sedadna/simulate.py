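"""Synthetic inputs for the pipeline: taxonomies, reference genomes,
damaged read sets with known truth, and mitochondrial marker panels.

The generator emulates the salient features of degraded sedimentary DNA:

* short fragments with a truncated log-normal length distribution;
* post-mortem cytosine deamination, read as C→T substitutions whose
  probability decays exponentially with distance from the 5′ fragment end
  (G→A mirrored at the 3′ end) — the single-strand overhang approximation;
* a uniform per-base sequencing-error floor applied after damage;
* reference databases in which congeneric species are diverged copies of a
  shared genus ancestor, so LCA behaviour under ambiguity is exercised;
* mitochondrial panels with mutations placed on known branches under
  infinite sites, so branch-marker recovery can be checked exactly.

Every operation takes an explicit seed and draws all randomness from a
single ``numpy`` generator, so identical arguments give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import optimize, stats

from ._seq import random_sequence, revcomp, validate_sequence
from .taxdb import ReferenceDB, RefSeq, Taxonomy, TaxonNode
from .tree import RootedTree, random_bifurcating_tree

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DamageModel:
    """Terminal deamination plus a uniform sequencing-error floor.

    ``p1_ct`` is the C→T probability at the first 5′ position; at 5′
    position ``i`` (1-based) the probability is ``p1_ct * exp(-lambda_decay
    * (i - 1))``.  ``p1_ga`` mirrors this from the 3′ end (defaults to
    ``p1_ct``).  ``seq_error`` substitutes any base with a uniformly chosen
    different base, after damage.
    """

    p1_ct: float = 0.3
    lambda_decay: float = 0.3
    p1_ga: float | None = None
    seq_error: float = 0.001

    def __post_init__(self):
        for name in ("p1_ct", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.p1_ga is not None and not 0.0 <= self.p1_ga <= 1.0:
            raise ValueError(f"p1_ga must be in [0,1], got {self.p1_ga}")
        if self.lambda_decay < 0:
            raise ValueError(f"lambda_decay must be >= 0, got {self.lambda_decay}")

    @property
    def ga3(self) -> float:
        return self.p1_ct if self.p1_ga is None else self.p1_ga

    @classmethod
    def none(cls) -> "DamageModel":
        """Damage and error switched off (reads are exact substrings)."""
        return cls(p1_ct=0.0, lambda_decay=0.0, p1_ga=0.0, seq_error=0.0)


@dataclasses.dataclass(frozen=True)
class FragmentModel:
    """Truncated log-normal fragment lengths.

    ``mean_len`` is the mean of the *truncated* distribution (the location
    parameter is solved so truncation does not shift the realized mean);
    ``sd_len`` sets the spread via the untruncated coefficient of
    variation.  Defaults emulate permafrost/lake sedaDNA: mean 55 bp,
    bounds [30, 150].
    """

    mean_len: float = 55.0
    sd_len: float = 15.0
    min_len: int = 30
    max_len: int = 150

    def __post_init__(self):
        if self.min_len < 20:
            raise ValueError(f"min_len must be >= 20, got {self.min_len}")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if not self.min_len <= self.mean_len <= self.max_len:
            raise ValueError("mean_len must lie within [min_len, max_len]")
        if self.sd_len <= 0:
            raise ValueError("sd_len must be positive")

    def _params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal, with mu solved so the
        truncated mean equals mean_len."""
        sigma = float(np.sqrt(np.log1p((self.sd_len / self.mean_len) ** 2)))
        a, b = float(self.min_len), float(self.max_len)

        def truncated_mean(mu: float) -> float:
            za = (np.log(a) - mu) / sigma
            zb = (np.log(b) - mu) / sigma
            mass = stats.norm.cdf(zb) - stats.norm.cdf(za)
            if mass < 1e-12:  # all mass beyond one bound
                return a if mu < np.log(a) else b
            shifted = stats.norm.cdf(zb - sigma) - stats.norm.cdf(za - sigma)
            return float(np.exp(mu + sigma**2 / 2) * shifted / mass)

        # The truncated mean is monotone in mu and spans (min_len, max_len);
        # bracket generously beyond the bounds' logs.
        lo, hi = np.log(a) - 6 * sigma, np.log(b) + 6 * sigma
        mu = optimize.brentq(lambda m: truncated_mean(m) - self.mean_len, lo, hi)
        return float(mu), sigma

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` integer lengths within [min_len, max_len]."""
        mu, sigma = self._params()
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        fa, fb = dist.cdf(self.min_len), dist.cdf(self.max_len)
        u = rng.uniform(fa, fb, size=n)
        lengths = np.rint(dist.ppf(u)).astype(int)
        return np.clip(lengths, self.min_len, self.max_len)


@dataclasses.dataclass
class Read:
    read_id: str
    sequence: str


class ReadSet:
    """Ordered collection of reads with FASTA/FASTQ I/O."""

    def __init__(self, reads: list[Read]):
        self.reads = list(reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __getitem__(self, i: int) -> Read:
        return self.reads[i]

    def sequences(self) -> dict[str, str]:
        return {r.read_id: r.sequence for r in self.reads}

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            (SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in self.reads),
            str(path),
            "fasta",
        )

    def to_fastq(self, path: str | Path, quality: int = 40) -> None:
        records = []
        for r in self.reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")

    @classmethod
    def from_file(cls, path: str | Path, fmt: str | None = None) -> "ReadSet":
        path = Path(path)
        if fmt is None:
            fmt = "fastq" if path.suffix in {".fq", ".fastq"} else "fasta"
        return cls(
            [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
        )


# ---------------------------------------------------------------------------
# Taxonomy + reference database generators
# ---------------------------------------------------------------------------


def make_taxonomy(
    n_families: int, genera_per_family: int, species_per_genus: int, seed: int = 0
) -> Taxonomy:
    """Balanced root/family/genus/species taxonomy with sequential ids.

    The seed is accepted for interface symmetry with the other generators;
    the topology is deterministic in the counts.
    """
    if min(n_families, genera_per_family, species_per_genus) < 1:
        raise ValueError("all counts must be >= 1")
    nodes = [TaxonNode(1, 1, "root", "root")]
    next_id = 2
    for f in range(1, n_families + 1):
        fam_id = next_id
        next_id += 1
        nodes.append(TaxonNode(fam_id, 1, "family", f"Family_{f}"))
        for g in range(1, genera_per_family + 1):
            gen_id = next_id
            next_id += 1
            nodes.append(TaxonNode(gen_id, fam_id, "genus", f"Genus_{f}_{g}"))
            for s in range(1, species_per_genus + 1):
                sp_id = next_id
                next_id += 1
                nodes.append(
                    TaxonNode(sp_id, gen_id, "species", f"Species_{f}_{g}_{s}")
                )
    return Taxonomy(nodes)


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate`` to a different base."""
    if rate == 0:
        return sequence
    arr = np.array(list(sequence))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def make_reference_db(
    taxonomy: Taxonomy,
    genome_length: int = 1000,
    divergence_between_species: float = 0.05,
    seed: int = 0,
) -> ReferenceDB:
    """One genome per species; congeners diverge from a shared genus ancestor.

    Each species genome is the genus ancestor with independent per-site
    substitutions at rate ``divergence_between_species``; different genera
    (and families) get independent random ancestors.  Realized pairwise
    congener divergence is recorded on the returned database as
    ``realized_divergence[(sp_a, sp_b)]`` (Hamming fraction).
    """
    if genome_length < 200:
        raise ValueError(f"genome_length must be >= 200, got {genome_length}")
    if not 0.0 <= divergence_between_species <= 0.5:
        raise ValueError(
            f"divergence must be in [0, 0.5], got {divergence_between_species}"
        )
    rng = np.random.default_rng(seed)
    entries: list[RefSeq] = []
    species_by_genus: dict[int, list[int]] = {}
    for tid in sorted(taxonomy.nodes):
        node = taxonomy.nodes[tid]
        if node.rank == "species":
            species_by_genus.setdefault(node.parent_id, []).append(tid)
    genomes: dict[int, str] = {}
    for genus_id in sorted(species_by_genus):
        ancestor = random_sequence(genome_length, rng)
        for sp in species_by_genus[genus_id]:
            genome = _mutate(ancestor, divergence_between_species, rng)
            genomes[sp] = genome
            entries.append(RefSeq(f"ref_{sp}", sp, genome))
    db = ReferenceDB(entries, taxonomy=taxonomy)
    realized: dict[tuple[int, int], float] = {}
    for genus_id, species in species_by_genus.items():
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                diff = sum(x != y for x, y in zip(genomes[a], genomes[b]))
                realized[(a, b)] = diff / genome_length
    db.realized_divergence = realized  # type: ignore[attr-defined]
    return db


# ---------------------------------------------------------------------------
# Damaged read simulation
# ---------------------------------------------------------------------------


def apply_damage(
    fragment: str, dmg: DamageModel, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str, str]]]:
    """Damage then error a fragment (given in its own 5′→3′ orientation).

    Returns the modified sequence and the substitution list
    ``(position, from, to, kind)`` with 0-based read positions and kind in
    {"ct5", "ga3", "err"}.
    """
    arr = list(fragment)
    subs: list[tuple[int, str, str, str]] = []
    n = len(arr)
    if dmg.p1_ct > 0:
        for i in range(n):
            if arr[i] == "C" and rng.random() < dmg.p1_ct * np.exp(-dmg.lambda_decay * i):
                subs.append((i, "C", "T", "ct5"))
                arr[i] = "T"
    if dmg.ga3 > 0:
        for j in range(n):
            i = n - 1 - j  # j = distance from the 3' end
            if arr[i] == "G" and rng.random() < dmg.ga3 * np.exp(-dmg.lambda_decay * j):
                subs.append((i, "G", "A", "ga3"))
                arr[i] = "A"
    if dmg.seq_error > 0:
        hits = np.flatnonzero(rng.random(n) < dmg.seq_error)
        for i in hits:
            old = arr[i]
            choices = [b for b in _BASES if b != old]
            new = choices[rng.integers(0, 3)]
            subs.append((int(i), old, new, "err"))
            arr[i] = new
    return "".join(arr), subs


def _format_subs(subs: list[tuple[int, str, str, str]]) -> str:
    return ";".join(f"{p}:{a}>{b}:{k}" for p, a, b, k in subs)


def simulate_sample_reads(
    db: ReferenceDB,
    abundance: dict[int, float],
    n_reads: int,
    frag: FragmentModel | None = None,
    dmg: DamageModel | None = None,
    seed: int = 0,
    read_prefix: str = "r",
) -> tuple[ReadSet, pd.DataFrame]:
    """Draw reads from taxon genomes proportional to abundance weights.

    Each read picks a taxon (multinomially by weight), one of its reference
    sequences uniformly, a start position uniformly, and a strand
    uniformly; damage and error are applied in the fragment's own
    orientation.  Returns the reads and a truth table with one row per read
    (taxon, reference, position, strand, substitutions).
    """
    frag = frag or FragmentModel()
    dmg = dmg or DamageModel()
    taxa = sorted(abundance)
    if not taxa:
        raise ValueError("abundance map is empty")
    weights = np.array([abundance[t] for t in taxa], dtype=float)
    if (weights < 0).any():
        raise ValueError("abundance weights must be non-negative")
    if weights.sum() == 0:
        raise ValueError("at least one abundance weight must be positive")
    for t in taxa:
        if not db.sequences_of(t):
            raise KeyError(f"taxon {t} has no reference sequences in the database")
    rng = np.random.default_rng(seed)
    p = weights / weights.sum()
    taxon_draws = rng.choice(len(taxa), size=n_reads, p=p)
    lengths = frag.sample(n_reads, rng)

    reads: list[Read] = []
    truth_rows = []
    for i in range(n_reads):
        taxon = taxa[taxon_draws[i]]
        refs = db.sequences_of(taxon)
        ref = refs[rng.integers(0, len(refs))] if len(refs) > 1 else refs[0]
        length = int(min(lengths[i], len(ref.sequence)))
        start = int(rng.integers(0, len(ref.sequence) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = ref.sequence[start : start + length]
        if strand == "-":
            fragment = revcomp(fragment)
        seq, subs = apply_damage(fragment, dmg, rng)
        read_id = f"{read_prefix}{i:06d}"
        reads.append(Read(read_id, seq))
        truth_rows.append(
            {
                "read_id": read_id,
                "taxon_id": taxon,
                "seq_id": ref.seq_id,
                "start": start,
                "strand": strand,
                "length": length,
                "substitutions": _format_subs(subs),
            }
        )
    return ReadSet(reads), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Mitochondrial panels
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MitoPanel:
    """Reference mitochondrial phylogeny with branch-placed mutations.

    ``branch_sites[child_node_id]`` lists the ``(position, ancestral,
    derived)`` substitutions on the branch subtending that node.  Generated
    under infinite sites, so every site segregates for exactly one branch;
    ``homoplasy_sites`` (populated by :func:`inject_homoplasy`) lists extra
    sites whose derived tips match no clade.
    """

    tree: RootedTree
    root_sequence: str
    branch_sites: dict[str, list[tuple[int, str, str]]]
    outgroup: str
    homoplasy_sites: list[tuple[int, str, str, frozenset]] = dataclasses.field(
        default_factory=list
    )

    @property
    def genome_length(self) -> int:
        return len(self.root_sequence)

    def haplotype(self, node_id: str) -> str:
        """Root sequence edited by the mutations on the root-to-node path."""
        if node_id not in self.tree:
            raise KeyError(f"unknown node id {node_id}")
        arr = list(self.root_sequence)
        for branch in self.tree.branch_path(node_id):
            for pos, _anc, der in self.branch_sites.get(branch, []):
                arr[pos] = der
        for pos, _anc, der, tipset in self.homoplasy_sites:
            if self.tree.is_tip(node_id) and node_id in tipset:
                arr[pos] = der
        return "".join(arr)

    def tip_alignment(self) -> dict[str, str]:
        return {tip: self.haplotype(tip) for tip in self.tree.tips()}

    def marker_truth(self) -> pd.DataFrame:
        rows = [
            {"branch": b, "position": p, "ancestral": a, "derived": d}
            for b, sites in sorted(self.branch_sites.items())
            for p, a, d in sorted(sites)
        ]
        return pd.DataFrame(rows)

    def write(self, prefix: str | Path) -> None:
        """Write Newick tree, tip-alignment FASTA and marker-truth TSV."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}.nwk").write_text(self.tree.to_newick() + "\n")
        records = [
            SeqRecord(Seq(seq), id=tip, description="")
            for tip, seq in self.tip_alignment().items()
        ]
        SeqIO.write(records, f"{prefix}.fasta", "fasta")
        self.marker_truth().to_csv(f"{prefix}.markers.tsv", sep="\t", index=False)


def simulate_mito_panel(
    n_tips: int,
    mutations_per_branch: int = 5,
    genome_length: int = 5000,
    seed: int = 0,
) -> MitoPanel:
    """Random rooted bifurcating panel with branch-diagnostic mutations.

    Every branch except the outgroup terminal branch receives exactly
    ``mutations_per_branch`` substitutions at globally distinct sites
    (infinite sites).  Outgroup-branch mutations are omitted because
    outgroup polarization cannot distinguish them from ingroup-stem
    mutations; the outgroup therefore carries the ancestral allele at every
    marker site.
    """
    if mutations_per_branch < 1:
        raise ValueError("mutations_per_branch must be >= 1")
    rng = np.random.default_rng(seed)
    tree = random_bifurcating_tree(n_tips, rng)
    branches = [
        nid for nid in tree.preorder() if nid != tree.root_id and nid != "OUT"
    ]
    n_sites_needed = mutations_per_branch * len(branches)
    if n_sites_needed > genome_length:
        raise ValueError(
            f"{n_sites_needed} mutations exceed genome_length {genome_length}"
        )
    root_seq = random_sequence(genome_length, rng)
    sites = rng.permutation(genome_length)[:n_sites_needed]
    branch_sites: dict[str, list[tuple[int, str, str]]] = {}
    cursor = 0
    for branch in branches:
        muts = []
        for _ in range(mutations_per_branch):
            pos = int(sites[cursor])
            cursor += 1
            anc = root_seq[pos]
            der = [b for b in _BASES if b != anc][rng.integers(0, 3)]
            muts.append((pos, anc, der))
        branch_sites[branch] = muts
    return MitoPanel(tree, root_seq, branch_sites, outgroup="OUT")


def inject_homoplasy(panel: MitoPanel, n_sites: int, seed: int = 0) -> MitoPanel:
    """Add sites whose derived tips span two clades (matching no clade).

    Used to exercise the marker caller's homoplasy rejection path.  Returns
    a new panel; the original is untouched.
    """
    rng = np.random.default_rng(seed)
    used = {p for sites in panel.branch_sites.values() for p, _, _ in sites}
    used |= {p for p, _, _, _ in panel.homoplasy_sites}
    free = [p for p in range(panel.genome_length) if p not in used]
    if n_sites > len(free):
        raise ValueError("not enough free sites for homoplasy injection")
    tree = panel.tree
    ingroup_tips = [t for t in tree.tips() if t != panel.outgroup]
    clades = {tree.clade_tips(nid) for nid in tree.preorder() if nid != tree.root_id}
    new_sites = []
    positions = rng.permutation(len(free))[:n_sites]
    for idx in positions:
        pos = free[int(idx)]
        # pick a 2-tip set that is not a clade (rejection sampling)
        for _ in range(100):
            pair = frozenset(
                np.array(ingroup_tips)[rng.choice(len(ingroup_tips), 2, replace=False)]
            )
            if pair not in clades:
                break
        else:  # pragma: no cover - only on pathological topologies
            continue
        anc = panel.root_sequence[pos]
        der = [b for b in _BASES if b != anc][rng.integers(0, 3)]
        new_sites.append((pos, anc, der, pair))
    return MitoPanel(
        panel.tree,
        panel.root_sequence,
        panel.branch_sites,
        panel.outgroup,
        panel.homoplasy_sites + new_sites,
    )


def simulate_mito_reads(
    panel: MitoPanel,
    source_node: str,
    mean_coverage: float,
    frag: FragmentModel | None = None,
    dmg: DamageModel | None = None,
    seed: int = 0,
    read_prefix: str = "m",
) -> tuple[ReadSet, pd.DataFrame]:
    """Tile the haplotype of ``source_node`` at roughly the given coverage.

    ``source_node`` may be a tip or an internal node (ancestral haplotype =
    root sequence plus the path mutations above the node).  The read count
    is Poisson with mean ``coverage * genome_length / mean_fragment_len``.
    """
    frag = frag or FragmentModel()
    dmg = dmg or DamageModel()
    haplotype = panel.haplotype(source_node)  # raises KeyError if unknown
    rng = np.random.default_rng(seed)
    n_reads = int(rng.poisson(mean_coverage * len(haplotype) / frag.mean_len))
    lengths = frag.sample(n_reads, rng)
    reads: list[Read] = []
    truth_rows = []
    for i in range(n_reads):
        length = int(min(lengths[i], len(haplotype)))
        start = int(rng.integers(0, len(haplotype) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = haplotype[start : start + length]
        if strand == "-":
            fragment = revcomp(fragment)
        seq, subs = apply_damage(fragment, dmg, rng)
        read_id = f"{read_prefix}{i:06d}"
        reads.append(Read(read_id, seq))
        truth_rows.append(
            {
                "read_id": read_id,
                "source_node": source_node,
                "start": start,
                "strand": strand,
                "length": length,
                "substitutions": _format_subs(subs),
            }
        )
    return ReadSet(reads), pd.DataFrame(
        truth_rows,
        columns=["read_id", "source_node", "start", "strand", "length", "substitutions"],
    )


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
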