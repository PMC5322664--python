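"""Pairwise r-squared and the expected LD-decay regression.

For a pair of biallelic sites with haploid frequencies p1, p2 and joint
frequency p11, linkage disequilibrium is D = p11 - p1*p2 and
r^2 = D^2 / (p1*(1-p1)*p2*(1-p2)), identical to the squared Pearson
correlation of the two 0/1 strain vectors on complete cases.

Decay with distance is summarised by fitting, over all within-contig pairs,
the drift-sampling expectation of r^2 (Hill & Weir; the form popularised by
Remington et al. for distance regressions):

    E(r^2) = (10 + C) / ((2 + C)(11 + C))
             * [ 1 + (3 + C)(12 + 12C + C^2) / (n (2 + C)(11 + C)) ]

with C = rho * d, rho the population-scaled recombination parameter per bp
and n the number of sampled haplotypes. The fitted curve's half-decay
distance (where E(r^2) falls to half its zero-distance value) is the
per-lineage LD summary: long half-decay marks predominant selfing, because
selfing suppresses effective recombination by the factor 1 - F.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from andromix.genotypes_io import MISSING, HaplotypeMatrix

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """All pair distances equal, or too few pairs to fit."""


@dataclass
class LDPairTable:
    """Within-contig site pairs: columns contig, pos1, pos2, distance_bp, r2."""

    pairs: pd.DataFrame
    lineage: str
    n: int  # haplotypes used
    n_skipped: int = 0  # pairs skipped (too few complete cases / monomorphic)


@dataclass
class DecayFit:
    rho_per_bp: float
    n: int
    sse: float
    e_r2_at_zero: float
    half_decay_bp: float
    n_pairs: int
    converged: bool = True


def expected_r2(C, n: int):
    """Expected r^2 at scaled distance C = rho * d for n sampled haplotypes."""
    if n < 2:
        raise ValueError("n must be >= 2")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be >= 0")
    first = (10 + C) / ((2 + C) * (11 + C))
    second = 1 + ((3 + C) * (12 + 12 * C + C ** 2)) / (n * (2 + C) * (11 + C))
    out = first * second
    return float(out) if out.ndim == 0 else out


def _pair_r2(x, y):
    """r^2 between two 0/1 haploid vectors (no missing)."""
    p1 = x.mean()
    p2 = y.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return np.nan
    d = (x & y).mean() - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


def pairwise_r2(matrix: HaplotypeMatrix, min_pair_n: int = 4,
                min_mac: int = 2, lineage: str | None = None) -> LDPairTable:
    """All within-contig pairwise r^2 values, complete cases per pair.

    Sites with minor-allele count below ``min_mac`` are excluded first: a
    singleton's r^2 with any other site is bounded near 1/(n-1) and carries
    no linkage information, only flat noise that destabilises the decay fit
    (``min_mac=1`` restores bare polymorphism filtering). Pairs with fewer
    than ``min_pair_n`` complete cases, or with either site monomorphic in
    the complete-case subset, are skipped and counted. Between-contig pairs
    are never computed.
    """
    if matrix.n_strains < 2:
        raise ValueError("need >= 2 strains")
    if min_mac > 1:
        called = matrix.alleles != MISSING
        ones = ((matrix.alleles == 1) & called).sum(axis=0)
        mac = np.minimum(ones, called.sum(axis=0) - ones)
        matrix = matrix.take_sites(np.flatnonzero(mac >= min_mac))
    if lineage is None:
        uniq = sorted(set(matrix.lineages))
        lineage = uniq[0] if len(uniq) == 1 else "+".join(uniq)
    records = []
    n_skipped = 0
    for contig in matrix.contig_ids():
        cols = np.flatnonzero(matrix.contigs == contig)
        if cols.size < 2:
            continue
        sub = matrix.alleles[:, cols]
        pos = matrix.positions[cols]
        has_missing = np.any(sub == MISSING)
        if not has_missing:
            # vectorized D^2 / (p1 q1 p2 q2) over all column pairs
            a = sub.astype(float)
            p = a.mean(axis=0)
            p11 = (a.T @ a) / a.shape[0]
            dmat = p11 - np.outer(p, p)
            pq = p * (1 - p)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = dmat ** 2 / np.outer(pq, pq)
            iu, ju = np.triu_indices(cols.size, k=1)
            vals = r2[iu, ju]
            ok = np.isfinite(vals)
            n_skipped += int((~ok).sum())
            for a, b, v in zip(iu[ok], ju[ok], vals[ok]):
                records.append((contig, int(pos[a]), int(pos[b]),
                                int(abs(pos[b] - pos[a])), float(v)))
        else:
            called = sub != MISSING
            for a in range(cols.size - 1):
                for b in range(a + 1, cols.size):
                    both = called[:, a] & called[:, b]
                    if both.sum() < min_pair_n:
                        n_skipped += 1
                        continue
                    x = sub[both, a].astype(bool)
                    y = sub[both, b].astype(bool)
                    v = _pair_r2(x, y)
                    if np.isnan(v):
                        n_skipped += 1
                        continue
                    records.append((contig, int(pos[a]), int(pos[b]),
                                    int(abs(pos[b] - pos[a])), float(v)))
    if n_skipped:
        logger.info("skipped %d site pair(s)", n_skipped)
    pairs = pd.DataFrame(records, columns=["contig", "pos1", "pos2",
                                           "distance_bp", "r2"])
    return LDPairTable(pairs=pairs, lineage=lineage, n=matrix.n_strains,
                       n_skipped=n_skipped)


def _sse(rho, d, r2, n):
    return float(np.sum((r2 - expected_r2(rho * d, n)) ** 2))


def fit_decay(table: LDPairTable, binned: bool = False,
              n_bins: int = 50) -> DecayFit:
    """Least-squares fit of rho >= 0 to the (distance, r^2) cloud.

    The default fits raw unbinned pairs; ``binned=True`` averages r^2 in
    log-spaced distance bins first (variance stabilisation). Minimisation is
    a deterministic multi-start: a log-spaced grid over rho (plus the rho=0
    boundary) refined by bounded scalar minimisation on log10(rho).
    """
    pairs = table.pairs
    if len(pairs) < 10:
        raise DegenerateDesignError("need >= 10 pairs to fit")
    d = pairs["distance_bp"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if np.unique(d).size < 2:
        raise DegenerateDesignError("degenerate design: all distances equal")
    if binned:
        edges = np.geomspace(d.min(), d.max() + 1, n_bins + 1)
        idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
        dm, rm = [], []
        for b in range(n_bins):
            in_bin = idx == b
            if in_bin.any():
                dm.append(d[in_bin].mean())
                rm.append(r2[in_bin].mean())
        d, r2 = np.array(dm), np.array(rm)
    n = table.n

    # multi-start grid on log10(rho), refined locally
    grid = np.concatenate([[0.0], np.geomspace(1e-10, 1e-1, 60)])
    sse_grid = np.array([_sse(rho, d, r2, n) for rho in grid])
    best = int(np.argmin(sse_grid))
    rho_hat, sse_hat = grid[best], sse_grid[best]
    converged = True
    if best > 0:
        u0 = np.log10(grid[best])
        res = minimize_scalar(
            lambda u: _sse(10.0 ** u, d, r2, n),
            bounds=(u0 - 0.5, u0 + 0.5), method="bounded",
            options={"xatol": 1e-12},
        )
        converged = bool(res.success)
        if res.fun <= sse_hat:
            rho_hat, sse_hat = 10.0 ** res.x, float(res.fun)
    fit = DecayFit(rho_per_bp=float(rho_hat), n=n, sse=float(sse_hat),
                   e_r2_at_zero=expected_r2(0.0, n),
                   half_decay_bp=np.nan, n_pairs=len(d), converged=converged)
    fit.half_decay_bp = half_decay_distance(fit)
    return fit


def half_decay_distance(fit: DecayFit, tol_bp: float = 1.0) -> float:
    """Distance at which the fitted curve reaches half its zero-distance
    value, by bisection on the monotone-decreasing E(r^2); inf when rho = 0
    or when the large-C asymptote 1/n never falls below the half target."""
    target = 0.5 * fit.e_r2_at_zero
    if fit.rho_per_bp <= 0:
        warnings.warn("rho = 0: LD does not decay; half-decay is infinite",
                      stacklevel=2)
        return float("inf")
    if 1.0 / fit.n >= target:
        warnings.warn("sampling floor 1/n exceeds half target; half-decay "
                      "undefined (infinite)", stacklevel=2)
        return float("inf")
    lo, hi = 0.0, 1.0
    while expected_r2(fit.rho_per_bp * hi, fit.n) > target:
        hi *= 2.0
        if hi > 1e15:  # pragma: no cover - guarded by the 1/n check
            return float("inf")
    while hi - lo > tol_bp:
        mid = 0.5 * (lo + hi)
        if expected_r2(fit.rho_per_bp * mid, fit.n) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def decay_report(fits: dict, tables: dict | None = None,
                 out_prefix: str | None = None) -> pd.DataFrame:
    """Per-lineage summary table (and optional scatter+curve plot).

    ``fits`` maps lineage -> DecayFit; ``tables`` (optional) maps lineage ->
    LDPairTable for the scatter overlay. Rows are sorted by lineage label.
    """
    rows = [
        {"lineage": lin, "n": f.n, "n_pairs": f.n_pairs,
         "rho_per_bp": f.rho_per_bp, "sse": f.sse,
         "half_decay_bp": f.half_decay_bp}
        for lin, f in sorted(fits.items())
    ]
    report = pd.DataFrame(rows)
    if out_prefix is not None:
        report.to_csv(f"{out_prefix}decay_fits.tsv", sep="\t", index=False)
        if tables:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, len(fits), squeeze=False,
                                     figsize=(4 * len(fits), 3.2))
            for ax, (lin, f) in zip(axes[0], sorted(fits.items())):
                tab = tables.get(lin)
                if tab is not None and len(tab.pairs):
                    ax.plot(tab.pairs["distance_bp"], tab.pairs["r2"], ".",
                            ms=1, alpha=0.2, color="steelblue")
                    dmax = tab.pairs["distance_bp"].max()
                    xs = np.linspace(1, dmax, 400)
                    ax.plot(xs, expected_r2(f.rho_per_bp * xs, f.n), "r-")
                ax.set_title(f"lineage {lin}")
                ax.set_xlabel("distance (bp)")
                ax.set_ylabel(r"$r^2$")
            fig.tight_layout()
            fig.savefig(f"{out_prefix}decay.png", dpi=120)
            plt.close(fig)
    return report
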