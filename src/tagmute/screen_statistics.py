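"""Quantitative screen statistics.

* in-frame enrichment: exact one-sided binomial test against a null in-frame
  fraction of 1/3 (a random indel length preserves frame one time in three),
  with a one-sided 95% Clopper-Pearson lower bound;
* cut-site proximity: Monte-Carlo test of the fraction of unique indels
  within ``window_bp`` (default 5) of the nearest predicted cut site, null
  positions uniform over the assayed interval(s), add-one p-value estimator;
* per-base mutation density for tiling screens: mutant reads / coverage x
  1000, coverage filter strictly > 500 reads;
* minimal resistance mutation: intersection of affected residues across
  in-frame alleles;
* locus copy-number from allele-fraction quantisation;
* microirradiation recruitment-curve normalisation (background subtracted,
  maximum scaled to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mutation_calling import IN_FRAME, Allele

__all__ = [
    "PoolEnrichment",
    "ProximityResult",
    "BaseDensity",
    "RecruitmentCurve",
    "inframe_enrichment_test",
    "mc_proximity_test",
    "per_base_density",
    "allele_affected_bases",
    "derive_minimal_mutation",
    "estimate_locus_copy_number",
    "normalize_recruitment_curve",
    "min_distance_to_cut",
]


@dataclass(frozen=True)
class PoolEnrichment:
    pool: str
    k_inframe: int
    n_total: int
    null_p0: float
    p_value: float
    ci_low: float
    ci_high: float
    unit: str = "alleles"


def inframe_enrichment_test(k: int, n: int, p0: float = 1 / 3, pool: str = "", unit: str = "alleles") -> PoolEnrichment:
    """Exact one-sided binomial test, alternative p(in-frame) > p0.

    p = P(X >= k | n, p0); the 95% interval is one-sided exact
    (Clopper-Pearson lower bound, upper bound fixed at 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    res = stats.binomtest(k, n, p0, alternative="greater")
    ci_low = 0.0 if k == 0 else float(stats.beta.ppf(0.05, k, n - k + 1))
    return PoolEnrichment(pool, k, n, p0, float(res.pvalue), ci_low, 1.0, unit)


@dataclass(frozen=True)
class ProximityResult:
    window_bp: int
    frac_indels_within: float
    frac_reads_within: float
    n_iterations: int
    p_value: float
    null_mean: float
    seed: int


def min_distance_to_cut(position: int, cut_sites: list[int]) -> int:
    return min(abs(position - c) for c in cut_sites)


def mc_proximity_test(
    indel_positions: list[tuple[int, float]],
    cut_sites: list[int],
    interval: tuple[int, int],
    window_bp: int = 5,
    n_iterations: int = 10_000,
    seed: int = 0,
) -> ProximityResult:
    """Monte-Carlo test of indel clustering near predicted cut sites.

    ``indel_positions`` pairs each unique indel's 3'-shifted start (coding
    position) with its read weight. The observed statistic is the unweighted
    fraction of unique indels whose nearest-cut distance is <= window_bp
    (the read-weighted fraction is reported alongside). The null draws the
    same number of positions uniformly over ``interval`` (the assayed coding
    interval, 1-based closed); p = (1 + #draws >= observed) / (1 + n).
    """
    if not cut_sites:
        raise ValueError("cut-site list is empty")
    if not indel_positions:
        raise ValueError("need at least one indel")
    if n_iterations < 1000:
        raise ValueError("n_iterations must be >= 1000")
    lo, hi = interval
    cuts = np.asarray(sorted(cut_sites))
    positions = np.array([p for p, _ in indel_positions])
    weights = np.array([w for _, w in indel_positions], dtype=float)

    def frac_within(pos: np.ndarray) -> np.ndarray:
        d = np.min(np.abs(pos[..., None] - cuts[None, :]), axis=-1)
        return (d <= window_bp).mean(axis=-1)

    observed = float(frac_within(positions))
    wsum = weights.sum()
    d_obs = np.min(np.abs(positions[:, None] - cuts[None, :]), axis=1)
    frac_reads = float(weights[d_obs <= window_bp].sum() / wsum) if wsum > 0 else 0.0

    rng = np.random.default_rng(seed)
    null_pos = rng.integers(lo, hi + 1, size=(n_iterations, len(positions)))
    null_frac = frac_within(null_pos)
    p = (1 + int((null_frac >= observed - 1e-12).sum())) / (1 + n_iterations)
    return ProximityResult(
        window_bp=window_bp,
        frac_indels_within=observed,
        frac_reads_within=frac_reads,
        n_iterations=n_iterations,
        p_value=p,
        null_mean=float(null_frac.mean()),
        seed=seed,
    )


@dataclass(frozen=True)
class BaseDensity:
    c_pos: int
    mutant_reads: int
    coverage: int
    density: float
    pass_filter: bool


def allele_affected_bases(allele: Allele) -> set[int]:
    """Coding bases an allele's variants touch.

    Deletions: every deleted base; insertions: the two flanking bases;
    substitutions/delins: the replaced bases.
    """
    bases: set[int] = set()
    for v in allele.variants:
        if v.kind == "insertion":
            bases.update({v.c_start, v.c_end})
        else:
            bases.update(range(v.c_start, v.c_end + 1))
    return bases


def per_base_density(
    allele_table: pd.DataFrame,
    per_base_coverage: dict[int, int],
    min_coverage: int = 500,
    inframe_only: bool = True,
) -> list[BaseDensity]:
    """Per-base mutant-read density: m / C x 1000.

    m at a base is the summed read count of (by default in-frame) mutant
    alleles whose variants affect that base; C the total coverage there.
    Bases pass the filter only with coverage strictly greater than
    ``min_coverage``.
    """
    m: dict[int, int] = {pos: 0 for pos in per_base_coverage}
    for _, row in allele_table.iterrows():
        allele: Allele = row["allele"]
        if inframe_only and allele.frame_class != IN_FRAME:
            continue
        if not allele.variants:
            continue
        for b in allele_affected_bases(allele):
            if b in m:
                m[b] += int(row["read_count"])
            elif per_base_coverage.get(b, 0) == 0:
                raise ValueError(f"mutant reads at base {b} but zero coverage")
    out = []
    for pos in sorted(per_base_coverage):
        cov = per_base_coverage[pos]
        if cov == 0 and m[pos] > 0:
            raise ValueError(f"mutant reads at base {pos} but zero coverage")
        d = (m[pos] / cov * 1000.0) if cov else 0.0
        out.append(BaseDensity(pos, m[pos], cov, d, cov > min_coverage))
    return out


@dataclass(frozen=True)
class MinimalMutation:
    residues: frozenset[int]
    label: str
    flags: tuple[str, ...] = ()


def derive_minimal_mutation(alleles: list[Allele], protein: str | None = None) -> MinimalMutation:
    """Smallest shared protein alteration across in-frame resistance alleles.

    Intersects the affected residues of every allele; a non-empty core is
    labelled in table style (e.g. ``119_120delKS`` when all alleles delete
    those residues). An empty intersection returns the modal affected residue
    flagged ``no_common_core``.
    """
    if not alleles:
        raise ValueError("no alleles supplied")
    sets = []
    for a in alleles:
        if a.protein_change is None:
            raise ValueError("alleles must be protein-annotated")
        sets.append(set(a.protein_change.affected_residues))
    core = set.intersection(*sets)
    if not core:
        counts: dict[int, int] = {}
        for s in sets:
            for r in s:
                counts[r] = counts.get(r, 0) + 1
        modal = min(r for r, c in counts.items() if c == max(counts.values()))
        return MinimalMutation(frozenset({modal}), str(modal), ("no_common_core",))
    lo, hi = min(core), max(core)
    aa = protein[lo - 1 : hi] if protein else ""
    all_deletions = all(
        len(a.variants) >= 1 and all(v.kind == "deletion" for v in a.variants) for a in alleles
    )
    if lo == hi:
        label = f"{lo}del{aa}" if all_deletions else f"{lo}{aa}"
    else:
        label = f"{lo}_{hi}del{aa}" if all_deletions else f"{lo}_{hi}{aa}"
    return MinimalMutation(frozenset(core), label)


def estimate_locus_copy_number(allele_fractions: list[float], max_copies: int = 8) -> int:
    """Copy number N in 1..max_copies whose 1/N grid best fits the fractions.

    Minimises the maximum absolute deviation of each fraction from its
    nearest multiple of 1/N; ties broken toward smaller N.
    """
    if not (1 <= max_copies <= 12):
        raise ValueError("max_copies must lie in 1..12")
    fr = np.asarray(allele_fractions, dtype=float)
    if np.any(fr < 0) or np.any(fr > 1):
        raise ValueError("fractions must lie in [0, 1]")
    total = fr.sum()
    if not (0.98 <= total <= 1.02):
        # include any wild-type remainder so the vector sums to 1
        if total < 0.98:
            fr = np.append(fr, 1.0 - total)
        else:
            raise ValueError(f"fractions sum to {total:.3f}, expected ~1")
    best_n, best_cost = 1, np.inf
    for n in range(1, max_copies + 1):
        grid = np.arange(n + 1) / n
        cost = float(np.max(np.min(np.abs(fr[:, None] - grid[None, :]), axis=1)))
        if cost < best_cost - 1e-12:
            best_n, best_cost = n, cost
    return best_n


@dataclass(frozen=True)
class RecruitmentCurve:
    timepoints: tuple[float, ...]
    raw_signal: tuple[float, ...]
    background: tuple[float, ...]
    normalized: tuple[float, ...]
    flags: tuple[str, ...] = ()


def normalize_recruitment_curve(
    raw: list[float] | np.ndarray,
    background: list[float] | np.ndarray,
    timepoints: list[float] | np.ndarray | None = None,
) -> RecruitmentCurve:
    """Background-subtracted recruitment signal with the maximum scaled to 1."""
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if raw.shape != background.shape:
        raise ValueError("raw and background series differ in length")
    if raw.size < 2:
        raise ValueError("need at least two points")
    t = np.arange(raw.size, dtype=float) if timepoints is None else np.asarray(timepoints, dtype=float)
    corrected = raw - background
    peak = corrected.max()
    flags: tuple[str, ...] = ()
    if peak <= 0:
        normalized = np.zeros_like(corrected)
        flags = ("no_signal",)
    else:
        normalized = corrected / peak
    return RecruitmentCurve(tuple(t), tuple(raw), tuple(background), tuple(normalized), flags)
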