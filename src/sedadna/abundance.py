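"""Corrected relative abundances.

Raw assigned-read counts confound true abundance with sequencing depth,
per-taxon identification efficiency (how often a read truly from a taxon
survives alignment + LCA collation back to that taxon, which depends on
how much of its genome is shared with relatives) and per-sample
degradation state (shorter, more damaged fragments identify less often).

Efficiency is estimated by simulation: reads are drawn from a taxon's own
references under the sample's fragment/damage condition, pushed through
the full classification pipeline, and the recovered fraction is the
efficiency.  Counts are then divided by efficiency and renormalized within
each sample — the minimal estimator that cancels depth, matches
degradation through condition-specific efficiencies, and removes the
per-taxon identification bias.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .classify import CountMatrix, classify_reads, collate_profile
from .simulate import DamageModel, FragmentModel, simulate_sample_reads
from .taxdb import ReferenceDB, Taxonomy

Condition = tuple[FragmentModel, DamageModel]


def estimate_efficiency(
    db: ReferenceDB,
    taxonomy: Taxonomy,
    taxon: int,
    condition: Condition,
    n_sim: int = 1000,
    rank: str = "species",
    seed: int = 0,
    max_mismatches: int = 0,
) -> float:
    """Fraction of simulated reads from ``taxon`` recovered at ``rank``.

    Simulates ``n_sim`` reads from the taxon's references under the given
    (fragment, damage) condition, classifies them end-to-end, and collates
    at ``rank``; the efficiency is the fraction of simulated reads whose
    assignment lands on the taxon's own rank-level lineage.
    """
    if n_sim < 500:
        raise ValueError(f"n_sim must be >= 500 for a stable estimate, got {n_sim}")
    # A rank-level taxon (e.g. a genus) owns the references of its subtree.
    sources = [
        t for t in db.taxa() if taxonomy.is_ancestor_or_self(taxon, t)
    ]
    if not sources:
        raise KeyError(f"taxon {taxon} has no reference sequences in its subtree")
    frag, dmg = condition
    reads, _truth = simulate_sample_reads(
        db, {t: 1.0 for t in sources}, n_sim, frag=frag, dmg=dmg, seed=seed,
        read_prefix=f"eff{taxon}_",
    )
    assignments, _un = classify_reads(reads, db, taxonomy, max_mismatches=max_mismatches)
    target = taxonomy.ancestor_at_rank(taxon, rank)
    if target is None:
        raise ValueError(f"taxon {taxon} has no ancestor at rank {rank!r}")
    n_ok = sum(
        1
        for a in assignments
        if taxonomy.ancestor_at_rank(a.taxon_id, rank) == target
    )
    return n_ok / n_sim


@dataclasses.dataclass
class EfficiencyTable:
    """Per (taxon, condition) recovery fractions with simulation sizes."""

    table: pd.DataFrame  # columns: taxon_id, condition_id, e, n_sim

    @classmethod
    def build(
        cls,
        db: ReferenceDB,
        taxonomy: Taxonomy,
        taxa: list[int],
        conditions: dict[str, Condition],
        n_sim: int = 1000,
        rank: str = "species",
        seed: int = 0,
        max_mismatches: int = 0,
    ) -> "EfficiencyTable":
        rows = []
        for ci, (cond_id, condition) in enumerate(sorted(conditions.items())):
            for ti, taxon in enumerate(sorted(taxa)):
                e = estimate_efficiency(
                    db,
                    taxonomy,
                    taxon,
                    condition,
                    n_sim=n_sim,
                    rank=rank,
                    seed=seed + 1000 * ci + ti,
                    max_mismatches=max_mismatches,
                )
                rows.append(
                    {"taxon_id": taxon, "condition_id": cond_id, "e": e, "n_sim": n_sim}
                )
        return cls(pd.DataFrame(rows))

    def efficiency(self, taxon: int, condition_id: str) -> float | None:
        sel = self.table[
            (self.table.taxon_id == taxon) & (self.table.condition_id == condition_id)
        ]
        if sel.empty:
            return None
        return float(sel.iloc[0].e)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EfficiencyTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclasses.dataclass
class RelativeAbundance:
    """Taxa × samples fractions; columns sum to 1 over retained taxa."""

    fractions: pd.DataFrame
    excluded: list[tuple[int, str, str]] = dataclasses.field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        out = self.fractions.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


def normalize_abundance(
    counts: CountMatrix,
    efficiencies: EfficiencyTable,
    sample_conditions: dict[str, str] | None = None,
) -> RelativeAbundance:
    """Efficiency-corrected, depth-free relative abundances.

    For taxon t in sample s with raw count r and condition-matched
    efficiency e:  a_{t,s} = (r/e) / Σ_u (r_u/e_u).  Sequencing depth
    cancels in the within-sample normalization; degradation enters through
    the sample's condition.  Taxa with e = 0 (or no efficiency estimate)
    while r > 0 are excluded from the sample's denominator and reported in
    ``excluded``.
    """
    samples = list(counts.counts.columns)
    taxa = [int(t) for t in counts.counts.index]
    conditions = sample_conditions or {s: "default" for s in samples}
    frac = pd.DataFrame(0.0, index=counts.counts.index, columns=samples)
    excluded: list[tuple[int, str, str]] = []
    for s in samples:
        cond = conditions.get(s, "default")
        corrected: dict[int, float] = {}
        for t in taxa:
            r = float(counts.counts.loc[t, s])
            e = efficiencies.efficiency(t, cond)
            if r == 0:
                corrected[t] = 0.0
                continue
            if e is None:
                excluded.append((t, s, "no efficiency estimate"))
            elif e == 0:
                excluded.append((t, s, "efficiency is zero"))
            else:
                corrected[t] = r / e
        total = sum(corrected.values())
        if total > 0:
            for t, v in corrected.items():
                frac.loc[t, s] = v / total
    return RelativeAbundance(fractions=frac, excluded=excluded)
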