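"""Cutoff-free mutation-density-over-age analysis.

Rather than dichotomizing the cohort at a fixed adult age cutoff, mutation
frequency is profiled continuously over age: boundary-reflected Gaussian
kernel density estimates of the ages of mutated cases and of all cases are
combined into a smoothed frequency curve, and a per-gene, per-tail
permutation enrichment test asks whether mutated cases concentrate at
young or old ages when patients are ranked by age.

The enrichment statistic is the classic unweighted running sum: walking
down the age ranking, the sum gains ``1/n_members`` at each mutated case
and loses ``1/n_nonmembers`` otherwise; the score is the maximum of this
walk.  Significance comes from permuting mutation labels over patients
(exhaustive enumeration when the number of distinct member placements is
small enough).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

__all__ = [
    "AgeDensityCurve",
    "EnrichmentResult",
    "TransitionSummary",
    "silverman_bandwidth",
    "reflected_kde",
    "running_sum_es",
    "age_rank_enrichment",
    "gene_age_curve",
    "transition_summary",
]


def silverman_bandwidth(values) -> float:
    """Silverman's rule-of-thumb bandwidth on the unreflected data."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0:
        raise ValueError("degenerate data: zero spread")
    return 0.9 * scale * n ** (-1 / 5)


def reflected_kde(values, support, bandwidth: float | None = None, grid_size: int = 512):
    """Gaussian KDE with data reflection at both support boundaries.

    The data are augmented by their mirror images about ``lo`` and ``hi``,
    the kernel density of the augmented sample is evaluated on a uniform
    grid inside ``[lo, hi]``, and the result is renormalized to integrate
    to 1 on the support.  Reflection removes the edge decay a plain KDE
    shows at natural boundaries such as age 0.

    Returns ``(grid, density)``.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = float(support[0]), float(support[1])
    if hi <= lo:
        raise ValueError("degenerate support")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("values outside support")
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    aug = np.concatenate([x, 2 * lo - x, 2 * hi - x])
    grid = np.linspace(lo, hi, grid_size)
    # vectorized Gaussian kernel sum over the augmented sample
    z = (grid[:, None] - aug[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (aug.size * h * np.sqrt(2 * np.pi))
    dens *= 3.0  # augmented sample carries triple mass
    area = np.trapezoid(dens, grid)
    return grid, dens / area


def running_sum_es(member_positions: np.ndarray, n: int, n_members: int) -> float:
    """Maximum of the unweighted running sum given sorted 0-based member ranks."""
    n_non = n - n_members
    k = np.arange(1, n_members + 1)
    p = np.sort(np.asarray(member_positions))
    # running sum immediately after the k-th member:
    # k member steps of +1/m and (p_k + 1 - k) non-member steps of -1/n_non
    vals = k / n_members - (p + 1 - k) / n_non
    return float(vals.max())


@dataclass
class EnrichmentResult:
    gene: str
    tail: str  # 'young' or 'old'
    es: float
    p_perm: float
    n_perm: int
    exhaustive: bool = False


def age_rank_enrichment(
    ages,
    mutated,
    tail: str = "young",
    n_perm: int = 100_000,
    seed: int | None = None,
    gene: str = "",
    max_exhaustive: int = 200_000,
) -> EnrichmentResult:
    """One-sided permutation enrichment of mutated cases at one age extreme.

    Patients are ranked by age (ascending for ``tail='young'``, descending
    for ``'old'``; ties broken by stable input order) and the running-sum
    score of the mutated set is compared against scores under random
    member placements.  ``p = (1 + #{es* >= es}) / (n_perm + 1)``; when the
    number of distinct placements ``C(n, m)`` is at most
    ``max_exhaustive``, complete enumeration replaces sampling and the p
    becomes the exact fraction.
    """
    ages = np.asarray(ages, dtype=float)
    member = np.asarray(mutated, dtype=bool)
    n = ages.size
    if n != member.size or n < 2:
        raise ValueError("ages and membership must align, length >= 2")
    m = int(member.sum())
    if m == 0 or m == n:
        raise ValueError("need at least one member and one non-member")
    if tail not in ("young", "old"):
        raise ValueError(f"tail must be 'young' or 'old', got {tail!r}")
    key = ages if tail == "young" else -ages
    order = np.argsort(key, kind="stable")
    ranked_member = member[order]
    obs_pos = np.flatnonzero(ranked_member)
    es = running_sum_es(obs_pos, n, m)

    n_placements = comb(n, m)
    if n_placements <= max_exhaustive:
        from itertools import combinations

        n_ge = 0
        for combo in combinations(range(n), m):
            n_ge += running_sum_es(np.array(combo), n, m) >= es - 1e-12
        p = n_ge / n_placements
        return EnrichmentResult(gene=gene, tail=tail, es=es, p_perm=p,
                                n_perm=n_placements, exhaustive=True)

    rng = np.random.default_rng(seed)
    # vectorized: sample m member ranks per permutation without replacement
    u = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(u, m - 1, axis=1)[:, :m], axis=1)
    k = np.arange(1, m + 1)
    vals = k[None, :] / m - (pos + 1 - k[None, :]) / (n - m)
    es_null = vals.max(axis=1)
    n_ge = int((es_null >= es - 1e-12).sum())
    p = (1 + n_ge) / (n_perm + 1)
    return EnrichmentResult(gene=gene, tail=tail, es=es, p_perm=p,
                            n_perm=n_perm, exhaustive=False)


@dataclass
class AgeDensityCurve:
    """Per-gene mutation density over age with the derived frequency curves."""

    gene: str
    age_grid: np.ndarray
    density_mutated: np.ndarray
    density_all: np.ndarray
    smoothed_frequency: np.ndarray  # estimate of P(mutated | age)
    relative_to_children: np.ndarray  # normalized to the mean over ages <= 18
    bandwidth_mutated: float = float("nan")
    bandwidth_all: float = float("nan")


def gene_age_curve(
    ages,
    mutated,
    gene: str = "",
    support=None,
    bandwidth: float | None = None,
    grid_size: int = 512,
    pediatric_cutoff: float = 18.0,
) -> AgeDensityCurve:
    """Smoothed mutation-frequency-over-age curve for one gene.

    ``smoothed_frequency(age) = prevalence * density_mutated / density_all``
    estimates the probability of carrying a mutation at a given age;
    ``relative_to_children`` rescales it by its mean over the pediatric
    range.  Support defaults to ``[0, max age]`` since age 0 is a natural
    boundary.

    Both densities share one bandwidth (Silverman's rule on all ages by
    default), which makes the ratio a boundary-corrected Nadaraya-Watson
    regression of mutation status on age; per-density bandwidths would let
    kernel-width mismatch distort the ratio where cases are sparse.
    """
    ages = np.asarray(ages, dtype=float)
    member = np.asarray(mutated, dtype=bool)
    if support is None:
        support = (0.0, float(ages.max()))
    bw_all = silverman_bandwidth(ages) if bandwidth is None else bandwidth
    bw_mut = bw_all
    grid, dens_all = reflected_kde(ages, support, bw_all, grid_size)
    _, dens_mut = reflected_kde(ages[member], support, bw_mut, grid_size)
    prevalence = member.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = prevalence * dens_mut / dens_all
    freq[~np.isfinite(freq)] = np.nan
    ped = grid <= pediatric_cutoff
    ped_mean = np.nanmean(freq[ped]) if ped.any() else np.nan
    rel = freq / ped_mean
    return AgeDensityCurve(
        gene=gene, age_grid=grid, density_mutated=dens_mut, density_all=dens_all,
        smoothed_frequency=freq, relative_to_children=rel,
        bandwidth_mutated=float(bw_mut), bandwidth_all=float(bw_all),
    )


@dataclass
class TransitionSummary:
    intervals: dict  # gene -> (age_start, age_end) or None when no transition
    midpoints: dict  # gene -> midpoint age (transitioning genes only)
    median_transition_age: float


def _crossing_age(grid, curve, level, below: bool, start: float = 18.0):
    """First grid age beyond ``start`` where the curve crosses a level."""
    beyond = grid > start
    idx = np.flatnonzero(beyond & ((curve <= level) if below else (curve >= level)))
    return float(grid[idx[0]]) if idx.size else None


def transition_summary(
    curves,
    upper: float = 0.8,
    lower: float = 0.6,
    adult_reference_age: float = 55.0,
) -> TransitionSummary:
    """Per-gene age-transition intervals and the cohort median transition age.

    For genes whose mutation frequency declines with age, the transition
    interval runs from the first adult age where the relative-to-children
    curve drops below ``upper`` (80% of the pediatric mean) to where it
    drops below ``lower`` (60%).  Adult-enriched genes are handled
    symmetrically on the rising side: the frequency curve is normalized to
    its mean over ages >= ``adult_reference_age`` (the old-age plateau) and
    the interval runs from the ``lower`` to the ``upper`` crossing.  Genes
    without an ordered crossing pair are flagged as having no transition
    and excluded from the median.
    """
    intervals, midpoints = {}, {}
    for c in curves:
        grid = c.age_grid
        freq = c.smoothed_frequency
        old_mask = grid >= adult_reference_age
        old_mean = np.nanmean(freq[old_mask]) if old_mask.any() else np.nanmean(freq[-10:])
        ped_mean = np.nanmean(freq[grid <= 18.0])
        # a transition requires real plateau contrast: the low plateau must sit
        # below the `lower` fraction of the high one, otherwise the gene is flat
        if old_mean < ped_mean:  # declining gene
            if old_mean / ped_mean >= lower:
                intervals[c.gene] = None
                continue
            rel = c.relative_to_children
            a0 = _crossing_age(grid, rel, upper, below=True)
            a1 = _crossing_age(grid, rel, lower, below=True)
        else:  # rising gene: symmetric crossings of the adult-plateau fractions
            if old_mean == 0 or ped_mean / old_mean >= lower:
                intervals[c.gene] = None
                continue
            rel_old = freq / old_mean
            a0 = _crossing_age(grid, rel_old, lower, below=False)
            a1 = _crossing_age(grid, rel_old, upper, below=False)
        if a0 is None or a1 is None or a1 < a0:
            intervals[c.gene] = None
            continue
        intervals[c.gene] = (a0, a1)
        midpoints[c.gene] = 0.5 * (a0 + a1)
    med = float(np.median(list(midpoints.values()))) if midpoints else float("nan")
    return TransitionSummary(intervals=intervals, midpoints=midpoints,
                             median_transition_age=med)
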