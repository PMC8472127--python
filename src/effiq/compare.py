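"""Rank-based inter-system comparison of eDQE/eNEQ curves.

The reported curves are split into a low- and a high-frequency bin, the
three systems compared per bin with a Kruskal-Wallis test, and — only when
that global test is significant at 5% (hierarchical testing) — pairwise with
Wilcoxon-Mann-Whitney tests, without multiplicity adjustment.

The Mann-Whitney statistic is reported in the min(U_a, U_b) convention (so
complete separation prints U = 0), with midrank tie handling, a
tie-corrected normal Z approximation, and an optional exact-permutation
p-value for small samples.

Caveat (printed in the report footer): adjacent frequency points of one
curve are statistically dependent, which makes these tests anti-conservative;
the procedure is replicated as specified, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .io import FrequencySeries

__all__ = [
    "FreqBinSpec",
    "ComparisonReport",
    "bin_curve",
    "kruskal_wallis",
    "mann_whitney",
    "pairwise_report",
]

DEFAULT_BINS = {
    "eDQE": ((0.00, 1.00), (1.15, 2.15)),
    "eNEQ": ((0.00, 1.25), (1.35, 2.55)),
}

_CAVEAT = (
    "Note: adjacent frequency points are statistically dependent; these "
    "rank tests are anti-conservative and exploratory (alpha = 0.05, no "
    "multiplicity adjustment)."
)


@dataclass
class FreqBinSpec:
    """Low/high frequency ranges (mm^-1, inclusive) for one metric."""

    metric: str = "eDQE"
    low_range: tuple[float, float] | None = None
    high_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.low_range is None or self.high_range is None:
            if self.metric not in DEFAULT_BINS:
                raise ValidationError(f"no default bins for metric {self.metric!r}")
            low, high = DEFAULT_BINS[self.metric]
            self.low_range = self.low_range or low
            self.high_range = self.high_range or high
        for rng in (self.low_range, self.high_range):
            if rng[0] >= rng[1]:
                raise ValidationError("bin ranges must be ascending")
        if self.high_range[0] <= self.low_range[1]:
            raise ValidationError("low and high ranges must be disjoint and ordered")


@dataclass
class PairResult:
    pair: tuple[str, str]
    u: float
    z: float
    p: float
    n: tuple[int, int]


@dataclass
class BinResult:
    range_mm: tuple[float, float]
    n_per_group: dict[str, int]
    n_total: int
    h: float
    df: int
    p: float
    pairwise: list[PairResult] | None  # None when the global test was not significant


@dataclass
class ComparisonReport:
    metric: str
    bins: list[BinResult] = field(default_factory=list)
    caveat: str = _CAVEAT

    def to_markdown(self) -> str:
        lines = [f"## {self.metric} comparison", ""]
        for b in self.bins:
            lines.append(
                f"**{b.range_mm[0]:.2f}-{b.range_mm[1]:.2f} mm^-1** "
                f"(n = {b.n_total}): Kruskal-Wallis H = {b.h:.2f}, "
                f"df = {b.df}, p = {b.p:.3g}"
            )
            if b.pairwise is None:
                lines.append("  pairwise comparisons suppressed (global test not significant)")
            else:
                for pr in b.pairwise:
                    lines.append(
                        f"  {pr.pair[0]} vs {pr.pair[1]}: U = {pr.u:.2f}, "
                        f"Z = {pr.z:.2f}, p = {pr.p:.3g}"
                    )
            lines.append("")
        lines.append(self.caveat)
        return "\n".join(lines)


def bin_curve(curve: FrequencySeries, frange: tuple[float, float]) -> np.ndarray:
    """Curve values at grid points inside the inclusive frequency range."""
    lo, hi = frange
    mask = (curve.frequencies >= lo - 1e-9) & (curve.frequencies <= hi + 1e-9)
    if not mask.any():
        raise ValidationError(f"no grid points in range [{lo:g}, {hi:g}] mm^-1")
    return curve.values[mask]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H across >= 2 groups; (H, df, p)."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValidationError("empty group")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.ptp(pooled) == 0:  # all values identical: H = 0 by convention
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def _u_min_and_ties(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, m = a.size, b.size
    r_a = ranks[:n].sum()
    u_a = r_a - n * (n + 1) / 2.0
    u_b = n * m - u_a
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return min(u_a, u_b), tie_sum


def mann_whitney(a, b, *, exact: bool = False) -> tuple[float, float, float]:
    """Wilcoxon-Mann-Whitney test; returns (U, Z, two-sided p).

    U is min(U_a, U_b) with midrank ties; Z uses the tie-corrected normal
    approximation and carries a negative sign (shift away from the null
    mean nm/2), matching the usual statistical-software printout.  The
    p-value applies the standard continuity correction (half a unit of U)
    to the normal tail, as R's wilcox.test does, so it tracks the exact
    discrete tail probability closely; Z itself is reported uncorrected.
    With ``exact=True`` (n + m <= 12 recommended) the p-value is the exact
    permutation tail probability P(U <= U_obs).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty sample")
    n, m = a.size, b.size
    u, tie_sum = _u_min_and_ties(a, b)
    big_n = n + m
    var = n * m / 12.0 * ((big_n + 1) - tie_sum / (big_n * (big_n - 1)))
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        sd = np.sqrt(var)
        z = (u - n * m / 2.0) / sd
        shifted = u - n * m / 2.0 + 0.5  # continuity correction toward the mean
        p = 1.0 if shifted >= 0 else min(1.0, 2.0 * stats.norm.sf(-shifted / sd))
    if exact:
        # pooled midranks are split-invariant, so enumerate rank-sum splits only
        ranks = stats.rankdata(np.concatenate([a, b]))
        nm = n * m
        offset = n * (n + 1) / 2.0
        total = comb(big_n, n)
        count = 0
        for picks in combinations(range(big_n), n):
            u_a = sum(ranks[i] for i in picks) - offset
            if min(u_a, nm - u_a) <= u + 1e-12:
                count += 1
        p = count / total
    return float(u), float(z), float(p)


def pairwise_report(
    systems: dict[str, FrequencySeries],
    spec: FreqBinSpec | None = None,
    *,
    alpha: float = 0.05,
    exact: bool = False,
) -> ComparisonReport:
    """Hierarchical comparison of (three) systems' curves per frequency bin.

    Kruskal-Wallis first; pairwise Mann-Whitney for every pair only when the
    global test is significant at ``alpha``.  All curves must share a grid.
    """
    if len(systems) < 2:
        raise ValidationError("need at least two systems")
    spec = spec or FreqBinSpec()
    labels = list(systems)
    ref = systems[labels[0]]
    for lbl in labels[1:]:
        c = systems[lbl]
        if c.frequencies.shape != ref.frequencies.shape or not np.allclose(
            c.frequencies, ref.frequencies
        ):
            raise ValidationError(f"curve {lbl!r} is on a mismatched frequency grid")
    report = ComparisonReport(metric=spec.metric)
    for frange in (spec.low_range, spec.high_range):
        samples = {lbl: bin_curve(systems[lbl], frange) for lbl in labels}
        h, df, p = kruskal_wallis(list(samples.values()))
        pairwise = None
        if p < alpha:
            pairwise = []
            for la, lb in combinations(labels, 2):
                u, z, pp = mann_whitney(samples[la], samples[lb], exact=exact)
                pairwise.append(
                    PairResult((la, lb), u, z, pp, (samples[la].size, samples[lb].size))
                )
        report.bins.append(
            BinResult(
                range_mm=frange,
                n_per_group={lbl: samples[lbl].size for lbl in labels},
                n_total=sum(s.size for s in samples.values()),
                h=h,
                df=df,
                p=p,
                pairwise=pairwise,
            )
        )
    return report
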