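"""End-to-end orchestration: configuration, chronology, and the demo run.

``run_pipeline`` wires the modules into one seeded, reproducible run on
synthetic data: generate a taxonomy/reference database and per-sample
damaged read sets (plus laboratory controls carrying contaminant taxa),
classify and collate at a rank, subtract control taxa, apply checklist
thresholds, estimate damage profiles and ancient/modern decisions,
efficiency-correct abundances, compute community statistics, and (when a
mitochondrial panel is configured) place samples on the panel tree.  Every
artefact is a TSV/JSON text file listed in a manifest with content hashes;
re-running the same config reproduces identical bytes.

Sample ages are consumed as already-calibrated years BP; undated sample
depths are aged by strict piecewise-linear interpolation between dated
horizons (no silent extrapolation, stratigraphic inversions rejected).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import authenticate as auth_mod
from . import classify as classify_mod
from . import community as community_mod
from . import placement as placement_mod
from .abundance import EfficiencyTable, normalize_abundance
from .classify import checklist_filter, classify_reads, collate_profile, subtract_control_taxa
from .community import (
    axis_correlations,
    bin_assemblages,
    dissimilarity_matrix,
    growthform_proportions,
    nmds,
    shannon,
    turnover_series,
)
from .simulate import (
    DamageModel,
    FragmentModel,
    make_reference_db,
    make_taxonomy,
    simulate_mito_panel,
    simulate_mito_reads,
    simulate_sample_reads,
)


# ---------------------------------------------------------------------------
# Age–depth chronology
# ---------------------------------------------------------------------------


class AgeDepthError(ValueError):
    """Base for chronology-model errors."""


class StratigraphicInversionError(AgeDepthError):
    """Ages decrease with depth between two dated points."""


class ExtrapolationError(AgeDepthError):
    """Query depth outside the dated range (no silent extrapolation)."""


def age_depth_interpolate(
    dated: list[tuple[float, float]], query_depth: float
) -> float:
    """Piecewise-linear age (years BP) at a depth, from dated horizons.

    ``dated`` is a list of (depth_cm, age_years) with strictly increasing
    depths and non-decreasing ages (no stratigraphic inversions — the
    precondition for building a model at all).  Queries outside the dated
    range raise :class:`ExtrapolationError`.
    """
    model = AgeDepthModel(dated)
    return model.age_at(query_depth)


@dataclasses.dataclass
class AgeDepthModel:
    """Linear age–depth model with per-segment sedimentation rates."""

    dated: list[tuple[float, float]]

    def __post_init__(self):
        if len(self.dated) < 2:
            raise AgeDepthError("need at least 2 dated points")
        depths = [d for d, _ in self.dated]
        ages = [a for _, a in self.dated]
        for (d0, a0), (d1, a1) in zip(self.dated, self.dated[1:]):
            if d1 <= d0:
                raise AgeDepthError(
                    f"depths must be strictly increasing: {d0} then {d1}"
                )
            if a1 < a0:
                raise StratigraphicInversionError(
                    f"age decreases with depth between ({d0} cm, {a0} yr) "
                    f"and ({d1} cm, {a1} yr)"
                )
        self._depths = np.array(depths, dtype=float)
        self._ages = np.array(ages, dtype=float)

    def age_at(self, depth: float) -> float:
        if depth < self._depths[0] or depth > self._depths[-1]:
            raise ExtrapolationError(
                f"depth {depth} cm outside dated range "
                f"[{self._depths[0]}, {self._depths[-1]}]"
            )
        return float(np.interp(depth, self._depths, self._ages))

    def sedimentation_rates(self) -> pd.DataFrame:
        """cm/yr per dated segment (inf where ages are equal)."""
        rows = []
        for (d0, a0), (d1, a1) in zip(self.dated, self.dated[1:]):
            rate = (d1 - d0) / (a1 - a0) if a1 > a0 else float("inf")
            rows.append(
                {"depth_top": d0, "depth_bottom": d1, "age_top": a0,
                 "age_bottom": a1, "rate_cm_per_yr": rate}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "taxonomy": {"n_families": 3, "genera_per_family": 2, "species_per_genus": 2},
    "reference_db": {"genome_length": 1000, "divergence": 0.08},
    "fragments": {"mean_len": 55.0, "sd_len": 15.0, "min_len": 30, "max_len": 150},
    "damage": {"p1_ct": 0.25, "lambda_decay": 0.3, "seq_error": 0.002},
    "samples": {
        "n_samples": 8,
        "reads_per_sample": 400,
        "contamination_fraction": 0.05,
        "core_depth_cm": 200.0,
        "dated_ages": [500.0, 20500.0],
    },
    "controls": {"n_controls": 2, "reads_per_control": 120},
    "classify": {"max_mismatches": 2, "rank": "genus", "min_reads": 3, "min_samples": 1},
    "authenticate": {
        "min_terminal_rate": 0.05,
        "alpha": 0.05,
        "profile_depth": 25,
        "max_mismatches": 8,
    },
    "abundance": {"n_sim": 500},
    "community": {
        "bin_width": 5000.0,
        "nmds_k": 2,
        "nmds_starts": 8,
        "nmds_max_iter": 200,
    },
    "placement": {
        "enabled": True,
        "n_tips": 6,
        "mutations_per_branch": 4,
        "genome_length": 3000,
        "coverage": 8.0,
        "mode": "all-sites",
        "min_markers": 10,
    },
}


class ConfigError(ValueError):
    pass


def _merge_validate(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in given and isinstance(dval, dict):
            gval = given[key]
            if not isinstance(gval, dict):
                raise ConfigError(f"config key {path}{key} must be a mapping")
            out[key] = _merge_validate(dval, gval, f"{path}{key}.")
        elif key in given:
            out[key] = given[key]
        else:
            out[key] = dval
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    values: dict

    @classmethod
    def from_dict(cls, given: dict) -> "RunConfig":
        return cls(_merge_validate(DEFAULT_CONFIG, given))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        given = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(given, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(given)

    def __getitem__(self, key: str):
        return self.values[key]


def _subseed(seed: int, stage: int) -> int:
    # Deterministic per-stage seeds, kept below 2**31.
    return (seed * 2654435761 + stage * 97 + 13) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full synthetic-data pipeline into ``outdir``.

    The last family of the generated taxonomy is reserved as the
    contaminant pool: its species seed the laboratory controls and a small
    fraction of each sample's reads, and control subtraction must remove
    them.  Returns the run directory; every output is listed in
    ``manifest.json`` with a sha256 content hash.
    """
    cfg = config.values
    seed = int(cfg["seed"])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: world generation -------------------------------------
    taxcfg = cfg["taxonomy"]
    taxonomy = make_taxonomy(
        taxcfg["n_families"], taxcfg["genera_per_family"], taxcfg["species_per_genus"]
    )
    db = make_reference_db(
        taxonomy,
        genome_length=cfg["reference_db"]["genome_length"],
        divergence_between_species=cfg["reference_db"]["divergence"],
        seed=_subseed(seed, 1),
    )
    taxonomy.to_tsv(out / "taxonomy.nodes.tsv", out / "taxonomy.names.tsv")
    db.to_fasta(out / "reference_db.fasta")

    families = sorted(
        t for t, n in taxonomy.nodes.items() if n.rank == "family"
    )
    contaminant_family = families[-1]
    species = sorted(t for t, n in taxonomy.nodes.items() if n.rank == "species")
    contaminant_species = [
        s for s in species
        if taxonomy.ancestor_at_rank(s, "family") == contaminant_family
    ]
    native_species = [s for s in species if s not in contaminant_species]
    native_genera = sorted(
        {taxonomy.ancestor_at_rank(s, "genus") for s in native_species}
    )
    checklist = {taxonomy.name(g) for g in native_genera}

    frag = FragmentModel(**cfg["fragments"])
    dmg = DamageModel(**cfg["damage"])

    # --- stage 2: chronology and per-sample truth ----------------------
    scfg = cfg["samples"]
    n_samples = int(scfg["n_samples"])
    core_depth = float(scfg["core_depth_cm"])
    a_top, a_bot = (float(x) for x in scfg["dated_ages"])
    chron = AgeDepthModel([(0.0, a_top), (core_depth, a_bot)])
    depths = np.linspace(0.0, core_depth, n_samples)
    ages = {f"S{i + 1}": chron.age_at(d) for i, d in enumerate(depths)}
    meta = pd.DataFrame(
        {
            "sample_id": list(ages),
            "site_id": "site_1",
            "region": "synthetic-region",
            "depth_cm": depths,
            "age_bp": [ages[s] for s in ages],
            "material": "lake sediment",
        }
    )
    meta.to_csv(out / "sample_metadata.tsv", sep="\t", index=False, float_format="%.6g")
    chron.sedimentation_rates().to_csv(
        out / "sedimentation_rates.tsv", sep="\t", index=False, float_format="%.6g"
    )

    rng = np.random.default_rng(_subseed(seed, 2))
    truth_abund = {}
    all_reads = []
    sample_of_read: dict[str, str] = {}
    contam_frac = float(scfg["contamination_fraction"])
    for i, sample in enumerate(ages):
        weights = rng.dirichlet(np.ones(len(native_species)))
        ab = {sp: float((1 - contam_frac) * w) for sp, w in zip(native_species, weights)}
        for sp in contaminant_species:
            ab[sp] = contam_frac / len(contaminant_species)
        truth_abund[sample] = ab
        reads, _truth = simulate_sample_reads(
            db, ab, int(scfg["reads_per_sample"]), frag=frag, dmg=dmg,
            seed=_subseed(seed, 10 + i), read_prefix=f"{sample}_",
        )
        all_reads.extend(reads)
        for r in reads:
            sample_of_read[r.read_id] = sample
    pd.DataFrame(
        [
            {"sample_id": s, "taxon_id": t, "true_weight": w}
            for s, ab in truth_abund.items()
            for t, w in sorted(ab.items())
        ]
    ).to_csv(out / "true_abundances.tsv", sep="\t", index=False, float_format="%.6g")

    # --- stage 3: classification ---------------------------------------
    ccfg = cfg["classify"]
    rank = ccfg["rank"]
    assignments, unassigned = classify_reads(
        all_reads, db, taxonomy, max_mismatches=int(ccfg["max_mismatches"])
    )
    raw = collate_profile(assignments, taxonomy, rank, sample_of_read)
    raw.to_tsv(out / "counts.raw.tsv")

    # --- stage 4: controls + filters -----------------------------------
    control_mats = []
    for j in range(int(cfg["controls"]["n_controls"])):
        c_ab = {sp: 1.0 for sp in contaminant_species}
        c_reads, _ = simulate_sample_reads(
            db, c_ab, int(cfg["controls"]["reads_per_control"]), frag=frag, dmg=dmg,
            seed=_subseed(seed, 50 + j), read_prefix=f"CTRL{j + 1}_",
        )
        c_assign, _ = classify_reads(
            c_reads, db, taxonomy, max_mismatches=int(ccfg["max_mismatches"])
        )
        control_mats.append(
            collate_profile(
                c_assign, taxonomy, rank, {r.read_id: f"CTRL{j + 1}" for r in c_reads}
            )
        )
    decontaminated = subtract_control_taxa(raw, control_mats)
    filtered = checklist_filter(
        decontaminated, checklist, taxonomy,
        min_reads=int(ccfg["min_reads"]), min_samples=int(ccfg["min_samples"]),
    )
    filtered.to_tsv(out / "counts.filtered.tsv")
    (out / "filter_ledger.txt").write_text("\n".join(filtered.log) + "\n")

    # --- stage 5: damage authentication --------------------------------
    # Damage profiling admits mismatched alignments (the deamination signal
    # IS a mismatch), so it works from each read's best placement rather
    # than from the perfect-hit LCA assignments: a read contributes to a
    # taxon's profile when all its fewest-mismatch placements fall inside
    # that taxon's rank-level subtree.
    acfg = cfg["authenticate"]
    read_seq = {r.read_id: r.sequence for r in all_reads}
    profile_hits_of: dict[int, list[classify_mod.Hit]] = {}
    for r in all_reads:
        placed = classify_mod.best_placements(
            r.sequence, db, int(acfg["max_mismatches"]), read_id=r.read_id
        )
        if not placed:
            continue
        best_mm = min(h.mismatches for h in placed)
        best = [h for h in placed if h.mismatches == best_mm]
        groups = {taxonomy.ancestor_at_rank(h.taxon_id, rank) for h in best}
        if len(groups) == 1:
            g = groups.pop()
            if g is not None and g in filtered.counts.index:
                profile_hits_of.setdefault(g, []).append(best[0])
    decisions = []
    for g in sorted(profile_hits_of):
        hits = profile_hits_of[g]
        profile = auth_mod.damage_profile(
            hits, read_seq, db, P=int(acfg["profile_depth"])
        )
        decision = auth_mod.is_ancient(
            profile,
            min_terminal_rate=float(acfg["min_terminal_rate"]),
            alpha=float(acfg["alpha"]),
        )
        decisions.append(
            {
                "taxon_id": g,
                "name": taxonomy.name(g),
                "decision": {True: "ancient", False: "modern", None: "undetermined"}[
                    decision.decision
                ],
                "terminal_ct": decision.terminal_rate,
                "baseline_ct": decision.baseline_rate,
                "p_value": decision.p_value,
                "n_terminal": decision.n_terminal,
            }
        )
        profile.to_tsv(out / f"damage_profile.taxon{g}.tsv")
    pd.DataFrame(decisions).to_csv(
        out / "damage_decisions.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # --- stage 6: abundance correction ---------------------------------
    retained = [int(t) for t in filtered.counts.index]
    eff = EfficiencyTable.build(
        db, taxonomy, retained, {"default": (frag, dmg)},
        n_sim=int(cfg["abundance"]["n_sim"]), rank=rank,
        seed=_subseed(seed, 70), max_mismatches=0,
    )
    eff.to_tsv(out / "efficiencies.tsv")
    rel = normalize_abundance(filtered, eff)
    rel.to_tsv(out / "relative_abundance.tsv")

    # --- stage 7: community statistics ---------------------------------
    mcfg = cfg["community"]
    shannon_rows = [
        {"sample_id": s, "shannon_nats": shannon(rel.fractions[s].to_numpy())}
        for s in rel.fractions.columns
        if rel.fractions[s].sum() > 0
    ]
    pd.DataFrame(shannon_rows).to_csv(
        out / "shannon.tsv", sep="\t", index=False, float_format="%.6g"
    )
    bins = bin_assemblages(filtered.counts, ages, float(mcfg["bin_width"]))
    turn = turnover_series(bins)
    turn.to_csv(out / "turnover.tsv", sep="\t", index=False, float_format="%.6g")
    sample_assemblages = [
        community_mod.Assemblage(
            label=s,
            taxa=frozenset(int(t) for t in filtered.counts.index if filtered.counts.loc[t, s] > 0),
        )
        for s in filtered.counts.columns
    ]
    D = dissimilarity_matrix(sample_assemblages)
    ordn = nmds(
        D, k=int(mcfg["nmds_k"]), n_starts=int(mcfg["nmds_starts"]),
        max_iter=int(mcfg["nmds_max_iter"]), seed=_subseed(seed, 80),
    )
    ordn.to_tsv(out / "nmds.tsv", sample_ids=list(filtered.counts.columns))
    variables = rel.fractions.T
    variables.columns = [taxonomy.name(int(t)) for t in variables.columns]
    corr = axis_correlations(ordn, variables)
    corr.to_csv(out / "axis_correlations.tsv", sep="\t", index=False, float_format="%.6g")

    form_rng = np.random.default_rng(_subseed(seed, 85))
    forms = list(community_mod.GROWTH_FORMS)
    traits = {
        int(g): forms[int(form_rng.integers(0, len(forms)))] for g in native_genera
    }
    pd.DataFrame(
        [{"taxon_id": t, "form": f} for t, f in sorted(traits.items())]
    ).to_csv(out / "traits.tsv", sep="\t", index=False)
    props, unclassified = growthform_proportions(rel.fractions, traits)
    props.index.name = "form"
    props.to_csv(out / "growthforms.tsv", sep="\t", float_format="%.6g")

    # --- stage 8: mitochondrial placement ------------------------------
    pcfg = cfg["placement"]
    if pcfg["enabled"]:
        panel = simulate_mito_panel(
            int(pcfg["n_tips"]), int(pcfg["mutations_per_branch"]),
            int(pcfg["genome_length"]), seed=_subseed(seed, 90),
        )
        panel.write(out / "mito_panel")
        markers, _log = placement_mod.call_branch_markers(
            panel.tree, panel.tip_alignment(), panel.outgroup
        )
        placement_mod.markers_to_tsv(markers, out / "mito_markers.tsv")
        tips = [t for t in panel.tree.tips() if t != panel.outgroup]
        internal = [
            n for n in panel.tree.preorder()
            if not panel.tree.is_tip(n) and n != panel.tree.root_id
        ]
        sources = [tips[0], internal[-1]]
        placements = []
        for si, source in enumerate(sources):
            m_reads, _ = simulate_mito_reads(
                panel, source, float(pcfg["coverage"]), frag=frag, dmg=dmg,
                seed=_subseed(seed, 91 + si), read_prefix=f"mito{si}_",
            )
            obs = placement_mod.collect_observations(
                m_reads, panel.root_sequence, markers, max_mismatches=8
            )
            placements.append(
                placement_mod.place_sample(
                    panel.tree, markers, obs, mode=str(pcfg["mode"]),
                    min_markers=int(pcfg["min_markers"]),
                    sample_id=f"eDNA_{source}",
                    exclude_nodes=[panel.outgroup],
                )
            )
        clade_labels = {nid: f"clade_{nid}" for nid in internal}
        placement_mod.placements_to_tsv(
            placements, panel.tree, clade_labels, out / "placements.tsv"
        )

    # --- manifest -------------------------------------------------------
    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": cfg,
        "seed": seed,
        "n_reads_total": len(all_reads),
        "n_assigned": len(assignments),
        "n_unassigned": len(unassigned),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n"
    )
    return out
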