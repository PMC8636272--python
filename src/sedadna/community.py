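"""Community dynamics over time-stamped taxonomic profiles.

Covers the vegetation-history statistics of the pipeline: Shannon
diversity, incidence-based dissimilarity between assemblages, binned
temporal turnover (consecutive-interval dissimilarity), non-metric
multidimensional scaling (NMDS) with Kruskal stress-1, Pearson taxon–axis
correlations, and growth-form composition from a genus-level trait table.

NMDS is the in-house numerical core here: random starts, alternating
isotonic (monotone) regression of configuration distances on dissimilarity
ranks with primary tie-breaking, and Guttman-transform configuration
updates, keeping the per-iteration stress trace so monotone descent is
checkable.  The reported solution is the lowest-stress completed start,
centred and principal-axis rotated with a deterministic sign convention.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

#: Named turnover presets: pan-Arctic synthesis vs regional series.
BIN_PRESETS = {"pan_arctic": 2000.0, "regional": 5000.0}

GROWTH_FORMS = ("tree", "shrub", "dwarf-shrub", "forb", "graminoid", "aquatic")


# ---------------------------------------------------------------------------
# Diversity and dissimilarity
# ---------------------------------------------------------------------------


def shannon(abundances: Sequence[float]) -> float:
    """Shannon diversity H = −Σ p ln p (nats), zero terms skipped."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclasses.dataclass
class Assemblage:
    """A labelled set of taxa (e.g. genera in a time bin)."""

    label: str
    taxa: frozenset
    abundances: dict | None = None

    @property
    def empty(self) -> bool:
        return len(self.taxa) == 0


def beta_dissimilarity(a: Assemblage, b: Assemblage, method: str = "sorensen") -> float:
    """Incidence (or abundance) dissimilarity between two assemblages.

    Default is Sørensen 1 − 2a/(2a + b + c) over shared/unique taxon
    counts; "jaccard" and abundance-based "braycurtis" are selectable.
    Both assemblages empty → ValueError (undefined).
    """
    if a.empty and b.empty:
        raise ValueError("dissimilarity of two empty assemblages is undefined")
    if method == "braycurtis":
        if a.abundances is None or b.abundances is None:
            raise ValueError("braycurtis needs abundances on both assemblages")
        taxa = sorted(set(a.abundances) | set(b.abundances))
        x = np.array([a.abundances.get(t, 0.0) for t in taxa])
        y = np.array([b.abundances.get(t, 0.0) for t in taxa])
        return float(np.abs(x - y).sum() / (x + y).sum())
    shared = len(a.taxa & b.taxa)
    only_a = len(a.taxa - b.taxa)
    only_b = len(b.taxa - a.taxa)
    if method == "sorensen":
        return 1.0 - 2 * shared / (2 * shared + only_a + only_b)
    if method == "jaccard":
        return 1.0 - shared / (shared + only_a + only_b)
    raise ValueError(f"unknown method {method!r}")


def bin_assemblages(
    counts: pd.DataFrame,
    ages: dict[str, float],
    bin_width: float,
    age_range: tuple[float, float] | None = None,
) -> list[Assemblage]:
    """Combine samples into half-open age bins [t, t + width).

    ``counts`` is taxa × samples; a taxon is present in a bin if present
    (count > 0) in any sample whose age falls in the bin.  Bins are
    anchored at age 0; empty bins are emitted as placeholders.  Samples
    missing from ``ages`` (or with non-finite age) are excluded.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    usable = {
        s: ages[s] for s in counts.columns if s in ages and np.isfinite(ages[s])
    }
    if age_range is None:
        if not usable:
            raise ValueError("no samples with finite ages")
        lo = np.floor(min(usable.values()) / bin_width) * bin_width
        n_bins = int(np.floor((max(usable.values()) - lo) / bin_width)) + 1
    else:
        lo, hi = age_range
        n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    out: list[Assemblage] = []
    for start in edges[:-1]:
        end = start + bin_width
        members = [s for s, t in usable.items() if start <= t < end]
        taxa = frozenset(
            int(t) for t in counts.index if (counts.loc[t, members] > 0).any()
        ) if members else frozenset()
        out.append(Assemblage(label=f"[{start:g},{end:g})", taxa=taxa))
    return out


def turnover_series(
    assemblages: Sequence[Assemblage], method: str = "sorensen"
) -> pd.DataFrame:
    """Dissimilarity between each pair of consecutive assemblages.

    Pairs involving an empty bin get NaN (undefined), keeping the series
    aligned with the bin sequence.
    """
    if len(assemblages) < 2:
        raise ValueError("need at least 2 assemblages for turnover")
    rows = []
    for prev, nxt in zip(assemblages, assemblages[1:]):
        if prev.empty or nxt.empty:
            beta = np.nan
        else:
            beta = beta_dissimilarity(prev, nxt, method=method)
        rows.append({"from_bin": prev.label, "to_bin": nxt.label, "beta": beta})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Ordination:
    points: np.ndarray  # samples × k, centred, principal-axis rotated
    stress: float  # Kruskal stress-1 of the reported solution
    n_starts: int
    converged: bool
    stress_trace: list[float]  # per-iteration stress of the winning start
    start_stresses: list[float]  # final stress of every completed start

    def to_tsv(self, path: str | Path, sample_ids: Sequence[str] | None = None) -> None:
        k = self.points.shape[1]
        df = pd.DataFrame(self.points, columns=[f"NMDS{i + 1}" for i in range(k)])
        df.insert(0, "sample", sample_ids if sample_ids is not None else range(len(df)))
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _monotone_fit(d: np.ndarray, diss: np.ndarray) -> np.ndarray:
    # Primary approach to ties: within tied dissimilarities, order by the
    # current configuration distances so the fit is free to follow them.
    order = np.lexsort((d, diss))
    fitted = isotonic_regression(d[order]).x
    dhat = np.empty_like(d)
    dhat[order] = fitted
    return dhat


def nmds(
    dissimilarity: np.ndarray,
    k: int = 3,
    n_starts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    Each random start alternates isotonic regression of configuration
    distances on the dissimilarity ranks with a Guttman-transform
    configuration update, stopping when the stress improvement falls below
    ``tol`` (or would increase, in which case the previous configuration is
    kept, so the recorded trace is non-increasing).  The lowest-stress
    completed start is reported.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.isfinite(D).all():
        raise ValueError("dissimilarity contains non-finite values")
    if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    n = D.shape[0]
    if k >= n - 1:
        raise ValueError(f"k={k} must be < n-1={n - 1}")
    diss = squareform(D, checks=False)
    degenerate = bool(np.ptp(diss) == 0)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, list[float], bool] | None = None
    start_stresses: list[float] = []
    eps = 1e-12
    for _ in range(n_starts):
        X = rng.normal(size=(n, k))
        prev_stress = np.inf
        trace: list[float] = []
        converged = False
        for _it in range(max_iter):
            d = pdist(X)
            dhat = _monotone_fit(d, diss)
            stress = _stress1(d, dhat)
            if stress > prev_stress:
                break  # keep the previous configuration; trace stays monotone
            trace.append(stress)
            X_prev = X
            if prev_stress - stress < tol:
                converged = True
                break
            prev_stress = stress
            # Guttman transform with ratios dhat/d
            ratio = squareform(dhat / np.maximum(d, eps), checks=False)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = B @ X / n
        final_stress = trace[-1] if trace else np.inf
        start_stresses.append(final_stress)
        if best is None or final_stress < best[0]:
            best = (final_stress, X_prev, trace, converged)

    assert best is not None
    stress, X, trace, converged = best
    # Centre and rotate onto principal axes with a deterministic sign fix.
    X = X - X.mean(axis=0)
    _u, _s, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for j in range(X.shape[1]):
        i_max = int(np.argmax(np.abs(X[:, j])))
        if X[i_max, j] < 0:
            X[:, j] = -X[:, j]
    ord_ = Ordination(
        points=X,
        stress=stress,
        n_starts=n_starts,
        converged=converged,
        stress_trace=trace,
        start_stresses=start_stresses,
    )
    ord_.degenerate = degenerate  # type: ignore[attr-defined]
    return ord_


# ---------------------------------------------------------------------------
# Axis correlations and growth forms
# ---------------------------------------------------------------------------


def axis_correlations(
    ordination: Ordination,
    variables: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each variable with each ordination axis.

    ``variables`` is samples × variables, row-aligned with the ordination
    points.  For each pair: r, t = r·√((n−2)/(1−r²)), two-sided p from the
    t distribution with n−2 df; significant ⇔ p < alpha (optionally
    Benjamini–Hochberg adjusted first; off by default).  Constant
    variables are flagged and never significant.
    """
    X = ordination.points
    n = X.shape[0]
    if len(variables) != n:
        raise ValueError("variables rows must align with ordination samples")
    if n < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for var in variables.columns:
        v = variables[var].to_numpy(dtype=float)
        constant = bool(np.ptp(v) == 0)
        for axis in range(X.shape[1]):
            if constant:
                rows.append(
                    {
                        "variable": var,
                        "axis": f"NMDS{axis + 1}",
                        "r": np.nan,
                        "t": np.nan,
                        "p": np.nan,
                        "significant": False,
                        "flagged_constant": True,
                    }
                )
                continue
            r, p = stats.pearsonr(v, X[:, axis])
            with np.errstate(divide="ignore"):
                t = r * np.sqrt((n - 2) / max(1 - r**2, 1e-300))
            rows.append(
                {
                    "variable": var,
                    "axis": f"NMDS{axis + 1}",
                    "r": float(r),
                    "t": float(t),
                    "p": float(p),
                    "significant": False,
                    "flagged_constant": False,
                }
            )
    out = pd.DataFrame(rows)
    valid = ~out.p.isna()
    if bh_correct and valid.any():
        p = out.loc[valid, "p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_i in range(m - 1, -1, -1):
            running = min(running, p[order[rank_i]] * m / (rank_i + 1))
            adj[order[rank_i]] = running
        out.loc[valid, "p_adj"] = adj
        out.loc[valid, "significant"] = adj < alpha
    else:
        out.loc[valid, "significant"] = out.loc[valid, "p"] < alpha
    return out


def growthform_proportions(
    abundances: pd.DataFrame, traits: dict[int, str]
) -> tuple[pd.DataFrame, list[int]]:
    """Per-sample abundance proportions by plant growth form.

    ``abundances`` is taxa × samples (fractions or counts); ``traits`` maps
    genus taxon_id → growth form from the controlled vocabulary.  Genera
    absent from the trait table are excluded from the denominator and
    returned as the unclassified ledger.
    """
    for t, form in traits.items():
        if form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth form {form!r} for taxon {t}")
    classified = [t for t in abundances.index if int(t) in traits]
    unclassified = [int(t) for t in abundances.index if int(t) not in traits]
    forms = sorted({traits[int(t)] for t in classified})
    out = pd.DataFrame(0.0, index=forms, columns=abundances.columns)
    for t in classified:
        out.loc[traits[int(t)]] += abundances.loc[t].astype(float)
    totals = out.sum(axis=0)
    nonzero = totals > 0
    out.loc[:, nonzero] = out.loc[:, nonzero] / totals[nonzero]
    return out, unclassified


def read_trait_table(path: str | Path) -> dict[int, str]:
    """Trait TSV (taxon_id, form) → mapping."""
    df = pd.read_csv(path, sep="\t")
    return {int(r.taxon_id): str(r.form) for r in df.itertuples()}


def dissimilarity_matrix(
    assemblages: Sequence[Assemblage], method: str = "sorensen"
) -> np.ndarray:
    """Pairwise dissimilarity matrix over non-empty assemblages."""
    n = len(assemblages)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = beta_dissimilarity(
                assemblages[i], assemblages[j], method=method
            )
    return D
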