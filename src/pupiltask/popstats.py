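"""Population-level inference respecting the site/unit hierarchy.

Units recorded on one array are not independent samples: a single recording
with spuriously large effects could bias a flat test.  The hierarchical
bootstrap resamples recording sites with replacement and then units within
each sampled site, giving location tests and correlation p-values that
account for this nesting.  A permutation test checks whether task- and
pupil-modulated unit populations overlap more than expected under
independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_STATISTICS = {
    "mean": np.mean,
    "median": np.median,
}


@dataclass
class BootstrapResult:
    estimate: float
    ci: tuple
    p: float
    p_at_floor: bool
    n_iter: int

    def p_text(self) -> str:
        """'< 1/n_iter' notation when no bootstrap crossing occurred."""
        return f"< {1.0 / self.n_iter:g}" if self.p_at_floor else f"{self.p:g}"


def _resample_indices(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sites with replacement, then units within each sampled site."""
    sites = np.unique(groups)
    idx_by_site = {s: np.flatnonzero(groups == s) for s in sites}
    picked = rng.choice(sites, size=len(sites), replace=True)
    out = []
    for s in picked:
        idx = idx_by_site[s]
        out.append(rng.choice(idx, size=len(idx), replace=True))
    return np.concatenate(out)


def hierarchical_bootstrap(values: np.ndarray, groups: np.ndarray,
                           statistic: str = "mean", n_iter: int = 10000,
                           seed: int = 0, values2: np.ndarray | None = None
                           ) -> BootstrapResult:
    """Two-sided location test of a grouped statistic against zero.

    ``statistic`` is 'mean' or 'median'; with ``values2`` the test applies to
    the paired differences ``values - values2``.  p = 2*min(frac<=0, frac>=0)
    over the bootstrap distribution, floored at 1/n_iter (reported via
    ``p_at_floor``).  A single group falls back to a flat bootstrap with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    if values2 is not None:
        values = values - np.asarray(values2, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    stat = _STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    if len(np.unique(groups)) < 2:
        warnings.warn("single site: falling back to a flat bootstrap")
        groups = np.arange(len(values))  # every unit its own site == flat resampling
    if np.all(values == values[0]) and values[0] == 0:
        return BootstrapResult(estimate=0.0, ci=(0.0, 0.0), p=1.0,
                               p_at_floor=False, n_iter=n_iter)
    dist = np.empty(n_iter)
    for i in range(n_iter):
        idx = _resample_indices(groups, rng)
        dist[i] = stat(values[idx])
    est = float(stat(values))
    ci = (float(np.percentile(dist, 2.5)), float(np.percentile(dist, 97.5)))
    frac_le = np.mean(dist <= 0)
    frac_ge = np.mean(dist >= 0)
    p = 2 * min(frac_le, frac_ge)
    floor = 1.0 / n_iter
    at_floor = p < floor
    return BootstrapResult(estimate=est, ci=ci, p=float(max(p, floor)),
                           p_at_floor=bool(at_floor), n_iter=n_iter)


def bootstrap_correlation(x: np.ndarray, y: np.ndarray, groups: np.ndarray,
                          n_iter: int = 10000, seed: int = 0
                          ) -> tuple[float, BootstrapResult]:
    """Pearson correlation with a hierarchical-bootstrap p-value versus zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    rng = np.random.default_rng(seed)
    g = groups
    if len(np.unique(g)) < 2:
        warnings.warn("single site: falling back to a flat bootstrap")
        g = np.arange(len(x))
    dist = np.empty(n_iter)
    for i in range(n_iter):
        idx = _resample_indices(g, rng)
        xi, yi = x[idx], y[idx]
        if xi.std() == 0 or yi.std() == 0:
            dist[i] = 0.0
        else:
            dist[i] = np.corrcoef(xi, yi)[0, 1]
    r = float(np.corrcoef(x, y)[0, 1])
    ci = (float(np.percentile(dist, 2.5)), float(np.percentile(dist, 97.5)))
    p = 2 * min(np.mean(dist <= 0), np.mean(dist >= 0))
    floor = 1.0 / n_iter
    at_floor = p < floor
    return r, BootstrapResult(estimate=r, ci=ci, p=float(max(p, floor)),
                              p_at_floor=bool(at_floor), n_iter=n_iter)


def independence_permutation_test(sig_task: np.ndarray, sig_pupil: np.ndarray,
                                  n_iter: int = 10000, seed: int = 0,
                                  exact: bool | None = None) -> float:
    """One-sided enrichment test for joint task+pupil modulation.

    The observed count of units flagged for both effects is compared with the
    null distribution obtained by permuting one flag vector; p is the fraction
    of permutations whose joint count is >= the observed count.  With
    ``exact`` (default: automatic for <= 8 units) all permutations are
    enumerated, making the p-value exact rather than Monte Carlo.
    """
    a = np.asarray(sig_task, dtype=bool)
    b = np.asarray(sig_pupil, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must share a length")
    obs = int(np.sum(a & b))
    n = len(b)
    if exact is None:
        exact = n <= 8
    if exact:
        from itertools import permutations

        total = 0
        count = 0
        for perm in permutations(range(n)):
            total += 1
            if int(np.sum(a & b[list(perm)])) >= obs:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_iter):
        perm = rng.permutation(n)
        if int(np.sum(a & b[perm])) >= obs:
            count += 1
    return count / n_iter
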