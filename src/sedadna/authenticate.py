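"""Ancient-DNA authentication from terminal deamination profiles.

Post-mortem cytosine deamination converts C to U, read as C→T near the 5′
end of a fragment and (on the complementary strand) G→A near the 3′ end.
Modern contaminant DNA lacks this signature, so an elevated terminal C→T
rate relative to the fragment interior authenticates a taxon's reads as
ancient.  This module estimates the positional mismatch profile from
gap-free placements of taxon-assigned reads and applies an explicit
decision rule: the terminal rate must clear a floor and a one-sided exact
binomial test must reject equality with the pooled interior baseline.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp
from .classify import Hit
from .taxdb import ReferenceDB

DEFAULT_PROFILE_DEPTH = 25


@dataclasses.dataclass
class DamageProfile:
    """Positional C→T (5′) and G→A (3′) mismatch fractions.

    Position arrays are 1-based from the respective read end (index 0 of
    the array = position 1).  ``ct5[i]`` is NaN where ``n_obs5[i] == 0``.
    """

    ct5: np.ndarray
    ga3: np.ndarray
    n_obs5: np.ndarray
    n_obs3: np.ndarray
    k_ct5: np.ndarray  # T counts behind ct5, kept for exact tests
    k_ga3: np.ndarray

    @property
    def depth(self) -> int:
        return len(self.ct5)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "position": np.arange(1, self.depth + 1),
                "ct5": self.ct5,
                "ga3": self.ga3,
                "n_obs5": self.n_obs5,
                "n_obs3": self.n_obs3,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclasses.dataclass(frozen=True)
class AncientDecision:
    """Outcome of the damage test; ``decision`` is None when undetermined."""

    decision: bool | None
    terminal_rate: float
    baseline_rate: float
    rate_ratio: float
    p_value: float
    n_terminal: int
    k_terminal: int

    def to_json(self, path: str | Path, taxon: str | None = None) -> None:
        payload = dataclasses.asdict(self)
        if taxon is not None:
            payload = {"taxon": taxon, **payload}
        Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def damage_profile(
    hits: Iterable[Hit],
    reads: dict[str, str],
    db: ReferenceDB,
    P: int = DEFAULT_PROFILE_DEPTH,
    max_mismatches: int | None = None,
) -> DamageProfile:
    """Tally positional C→T / G→A mismatch fractions over a set of hits.

    For each hit the aligned reference segment is re-oriented into the
    read's own 5′→3′ frame (reverse-strand hits are complemented), so
    deamination stays at the fragment's biological ends.  Position ``i``
    from the 5′ end counts reference-C sites and the subset read as T;
    mirrored for reference-G read-A from the 3′ end.  Sites where the read
    base is N are excluded from numerator and denominator.  Reads shorter
    than ``P`` contribute only their existing positions.
    """
    n5 = np.zeros(P, dtype=int)
    k5 = np.zeros(P, dtype=int)
    n3 = np.zeros(P, dtype=int)
    k3 = np.zeros(P, dtype=int)
    for h in hits:
        if max_mismatches is not None and h.mismatches > max_mismatches:
            continue
        read = reads[h.read_id]
        ref_entry = db.sequence(h.seq_id)
        ref_seg = ref_entry.sequence[h.start : h.start + h.read_length]
        if h.strand == "-":
            ref_seg = revcomp(ref_seg)  # into read orientation
        L = h.read_length
        for i in range(min(P, L)):
            rb, qb = ref_seg[i], read[i]
            if qb == "N":
                continue
            if rb == "C":
                n5[i] += 1
                if qb == "T":
                    k5[i] += 1
        for j in range(min(P, L)):
            rb, qb = ref_seg[L - 1 - j], read[L - 1 - j]
            if qb == "N":
                continue
            if rb == "G":
                n3[j] += 1
                if qb == "A":
                    k3[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(n5 > 0, k5 / np.maximum(n5, 1), np.nan)
        ga3 = np.where(n3 > 0, k3 / np.maximum(n3, 1), np.nan)
    return DamageProfile(ct5=ct5, ga3=ga3, n_obs5=n5, n_obs3=n3, k_ct5=k5, k_ga3=k3)


def is_ancient(
    profile: DamageProfile,
    min_terminal_rate: float = 0.05,
    baseline_positions: range = range(11, 26),
    alpha: float = 0.05,
    min_obs: int = 10,
) -> AncientDecision:
    """Decide whether a damage profile supports ancient origin.

    True iff the position-1 C→T rate is at least ``min_terminal_rate`` AND
    a one-sided exact binomial test of the position-1 T count against the
    pooled baseline rate (C→T over ``baseline_positions``) rejects at
    ``alpha``.  Fewer than ``min_obs`` position-1 observations yields an
    undetermined decision (``decision is None``), distinct from False.
    """
    if 1 in baseline_positions:
        raise ValueError("baseline_positions must not include position 1")
    base_idx = [p - 1 for p in baseline_positions if p - 1 < profile.depth]
    n1 = int(profile.n_obs5[0])
    k1 = int(profile.k_ct5[0])
    n_base = int(profile.n_obs5[base_idx].sum())
    k_base = int(profile.k_ct5[base_idx].sum())
    baseline_rate = k_base / n_base if n_base > 0 else 0.0
    if n1 < min_obs:
        return AncientDecision(None, np.nan, baseline_rate, np.nan, np.nan, n1, k1)
    terminal_rate = k1 / n1
    p_value = float(
        stats.binomtest(k1, n1, min(baseline_rate, 1.0), alternative="greater").pvalue
    )
    ratio = terminal_rate / baseline_rate if baseline_rate > 0 else np.inf
    decision = bool(terminal_rate >= min_terminal_rate and p_value < alpha)
    return AncientDecision(
        decision=decision,
        terminal_rate=float(terminal_rate),
        baseline_rate=float(baseline_rate),
        rate_ratio=float(ratio),
        p_value=p_value,
        n_terminal=n1,
        k_terminal=k1,
    )


def fit_sample_condition(profile: DamageProfile, read_lengths: Iterable[int]):
    """Summarize a sample's degradation state for efficiency matching.

    Returns (mean fragment length, terminal C→T rate) — the two axes along
    which identification efficiency varies; used to bin samples into
    simulation conditions for abundance correction.
    """
    lengths = np.fromiter(read_lengths, dtype=float)
    mean_len = float(lengths.mean()) if lengths.size else float("nan")
    ct1 = float(profile.ct5[0]) if profile.n_obs5[0] > 0 else float("nan")
    return mean_len, ct1
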