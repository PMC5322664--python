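"""Haplotype copying-model painting and chunk-count coancestry.

Each strain's haplotype is modelled as a mosaic copied from the other
strains (a simplified Li & Stephens copying model): a hidden Markov chain
over donor identities with uniform initial distribution, distance-dependent
switching, and a miscopy emission probability. Between consecutive sites
separated by g bp the chain recombines with probability
1 - exp(-recomb_scale * g), landing uniformly on any donor; a switch that
lands on the current donor does not start a new chunk (chunks are maximal
same-donor runs). Emission probability is 1 - theta on an allele match and
theta on a mismatch; missing alleles are uninformative.

The expected number of chunks a recipient copies from each donor -- the
entry of the coancestry ("chunkcounts") matrix -- is the posterior
probability the first site copies from that donor plus the expected number
of intervals on which the chain switches onto it from elsewhere. Elevated
between-lineage chunk counts are the admixture signal.

This is deliberately a simplified analogue of full chromosome-painting
machinery (no per-donor copying propensities, haploid only, no MCMC
clustering of the coancestry matrix): the target is the qualitative
chunkcounts/heat-map/admixture readout on labelled lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from andromix.genotypes_io import MISSING, HaplotypeMatrix


class PaintingError(RuntimeError):
    pass


@dataclass
class PaintingParams:
    """recomb_scale: per-bp switch intensity; miscopy_prob: emission theta."""

    recomb_scale: float = 1e-5
    miscopy_prob: float = 0.05
    em_iterations: int = 10
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self):
        if self.recomb_scale < 0:
            raise ValueError("recomb_scale must be >= 0")
        if not 0.0 < self.miscopy_prob < 0.5:
            raise ValueError("miscopy_prob must be in (0, 0.5)")


@dataclass
class PaintingResult:
    chunk_counts: np.ndarray  # per donor
    loglik: float
    expected_mismatch: float  # posterior-weighted mismatching emissions
    n_emissions: float  # posterior-weighted informative emissions
    posteriors: np.ndarray | None = None  # (n_sites, n_donors) if requested


@dataclass
class CoancestryMatrix:
    """Recipient x donor expected chunk counts; diagonal fixed at zero."""

    values: np.ndarray
    strains: list
    lineages: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains,
                            columns=self.strains)


def _emissions(recipient, donors, theta):
    """(n_sites, n_donors) emission probabilities; missing -> 1."""
    match = donors.T == recipient[:, None]
    probs = np.where(match, 1.0 - theta, theta)
    uninformative = (recipient[:, None] == MISSING) | (donors.T == MISSING)
    return np.where(uninformative, 1.0, probs), ~uninformative


def paint_haplotype(recipient, donors, positions,
                    params: PaintingParams,
                    return_posteriors: bool = False) -> PaintingResult:
    """Paint one recipient against a donor panel on a single contig.

    Scaled forward-backward over donor states; returns expected chunk counts
    per donor and the data log-likelihood.
    """
    recipient = np.asarray(recipient, dtype=np.int8)
    donors = np.asarray(donors, dtype=np.int8)
    positions = np.asarray(positions, dtype=np.int64)
    n_donors, n_sites = donors.shape
    if n_donors < 1:
        raise PaintingError("need at least one donor")
    if n_sites < 2:
        raise PaintingError("need at least two sites")
    if recipient.shape != (n_sites,) or positions.shape != (n_sites,):
        raise PaintingError("recipient/positions shape mismatch")

    theta = params.miscopy_prob
    emis, informative = _emissions(recipient, donors, theta)
    gaps = np.diff(positions).astype(float)
    switch = 1.0 - np.exp(-params.recomb_scale * gaps)

    # scaled forward
    alpha = np.empty((n_sites, n_donors))
    scales = np.empty(n_sites)
    a = emis[0] / n_donors
    scales[0] = a.sum()
    alpha[0] = a / scales[0]
    for l in range(1, n_sites):
        s = switch[l - 1]
        pred = (1.0 - s) * alpha[l - 1] + s / n_donors
        a = pred * emis[l]
        scales[l] = a.sum()
        if not np.isfinite(scales[l]) or scales[l] <= 0:
            raise PaintingError(f"non-finite likelihood at site index {l}")
        alpha[l] = a / scales[l]
    loglik = float(np.log(scales).sum())

    # scaled backward
    beta = np.empty((n_sites, n_donors))
    beta[-1] = 1.0
    for l in range(n_sites - 2, -1, -1):
        s = switch[l]
        nxt = emis[l + 1] * beta[l + 1]
        beta[l] = ((1.0 - s) * nxt + (s / n_donors) * nxt.sum()) / scales[l + 1]

    gamma = alpha * beta  # rows sum to 1

    # expected chunks: start + switches arriving from a different donor
    counts = gamma[0].copy()
    for l in range(n_sites - 1):
        s = switch[l]
        arrive = (s / n_donors) * (1.0 - alpha[l]) * emis[l + 1] * beta[l + 1] \
            / scales[l + 1]
        counts += arrive

    mismatch_post = float(
        (gamma * informative * (donors.T != recipient[:, None])).sum()
    )
    return PaintingResult(
        chunk_counts=counts,
        loglik=loglik,
        expected_mismatch=mismatch_post,
        n_emissions=float((gamma * informative).sum()),
        posteriors=gamma if return_posteriors else None,
    )


def _paint_all(matrix: HaplotypeMatrix, params: PaintingParams):
    """Paint every strain against all others, per contig; returns
    (values, total loglik, total expected mismatch, total emissions)."""
    n = matrix.n_strains
    values = np.zeros((n, n))
    total_ll = 0.0
    total_mis = 0.0
    total_em = 0
    for contig in matrix.contig_ids():
        cols = np.flatnonzero(matrix.contigs == contig)
        if cols.size < 2:
            continue
        alle = matrix.alleles[:, cols]
        pos = matrix.positions[cols]
        for i in range(n):
            donors_idx = np.array([j for j in range(n) if j != i])
            res = paint_haplotype(alle[i], alle[donors_idx], pos, params)
            values[i, donors_idx] += res.chunk_counts
            total_ll += res.loglik
            total_mis += res.expected_mismatch
            total_em += res.n_emissions
    return values, total_ll, total_mis, total_em


def coancestry_matrix(matrix: HaplotypeMatrix,
                      params: PaintingParams) -> CoancestryMatrix:
    """All-vs-all painting: every strain is a potential donor to every other.

    Per-contig paintings are summed, so each row totals at least one chunk
    per painted contig.
    """
    if matrix.n_strains < 3:
        raise PaintingError("need >= 3 strains for coancestry painting")
    try:
        values, _, _, _ = _paint_all(matrix, params)
    except PaintingError as err:
        raise PaintingError(f"painting failed: {err}") from err
    return CoancestryMatrix(values=values, strains=list(matrix.strains),
                            lineages=list(matrix.lineages))


def estimate_painting_params(matrix: HaplotypeMatrix,
                             initial: PaintingParams) -> PaintingParams:
    """Coordinate-ascent fit of (miscopy_prob, recomb_scale).

    Each round updates theta to the posterior expected mismatch fraction
    (the Baum-Welch emission update) and then maximises the total
    log-likelihood over recomb_scale by bounded search on the log scale,
    keeping the new value only when it does not decrease the likelihood.
    The likelihood trace across rounds is recorded on the returned params
    and must be non-decreasing (internal error otherwise).
    """
    from scipy.optimize import minimize_scalar

    params = replace(initial, loglik_trace=[])
    if params.em_iterations == 0:
        return initial
    _, ll, _, _ = _paint_all(matrix, params)
    trace = [ll]
    for _ in range(params.em_iterations):
        _, _, mis, em = _paint_all(matrix, params)
        if em > 0:
            theta = float(np.clip(mis / em, 1e-4, 0.5 - 1e-4))
            params = replace(params, miscopy_prob=theta)

        u0 = np.log10(max(params.recomb_scale, 1e-12))

        def neg_ll(u):
            trial = replace(params, recomb_scale=10.0 ** u)
            return -_paint_all(matrix, trial)[1]

        res = minimize_scalar(neg_ll, bounds=(u0 - 2.0, u0 + 2.0),
                              method="bounded", options={"xatol": 1e-3})
        _, ll_theta, _, _ = _paint_all(matrix, params)
        if -res.fun >= ll_theta:
            params = replace(params, recomb_scale=float(10.0 ** res.x))
            ll_new = float(-res.fun)
        else:
            ll_new = ll_theta
        if ll_new < trace[-1] - 1e-6:
            raise PaintingError(
                f"likelihood decreased during EM: {trace[-1]} -> {ll_new}"
            )
        trace.append(ll_new)
    return replace(params, loglik_trace=trace)


def aggregate_by_lineage(cm: CoancestryMatrix,
                         out_prefix: str | None = None) -> pd.DataFrame:
    """Mean chunk count from recipients of lineage i to donors of lineage j
    (diagonal strain pairs excluded); optionally writes a heat-map with
    strains sorted by lineage."""
    lineages = np.asarray(cm.lineages)
    labels = sorted(set(cm.lineages))
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for li in labels:
        rows = np.flatnonzero(lineages == li)
        for lj in labels:
            cols = np.flatnonzero(lineages == lj)
            block = cm.values[np.ix_(rows, cols)]
            if li == lj:
                k = len(rows)
                total = block.sum()  # diagonal is zero by construction
                denom = k * (len(cols) - 1)
            else:
                total = block.sum()
                denom = block.size
            out.loc[li, lj] = total / denom if denom else np.nan
    if out_prefix is not None:
        out.to_csv(f"{out_prefix}lineage_coancestry.tsv", sep="\t")
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = np.argsort(lineages, kind="stable")
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(cm.values[np.ix_(order, order)], cmap="viridis")
        ticks = []
        for li in labels:
            members = np.flatnonzero(lineages[order] == li)
            ticks.append((members.mean(), li))
        ax.set_xticks([t for t, _ in ticks])
        ax.set_xticklabels([l for _, l in ticks])
        ax.set_yticks([t for t, _ in ticks])
        ax.set_yticklabels([l for _, l in ticks])
        ax.set_title("coancestry (expected chunk counts)")
        fig.colorbar(im, ax=ax, label="chunks")
        fig.tight_layout()
        fig.savefig(f"{out_prefix}coancestry_heatmap.png", dpi=120)
        plt.close(fig)
    return out


def admixture_fractions(cm: CoancestryMatrix, strain: str) -> pd.Series:
    """Per-donor-lineage fraction of the strain's chunk-count row.

    The row is summed within each donor lineage (the strain itself carries a
    zero diagonal, so its own lineage excludes self) and normalised to 1.
    """
    if strain not in cm.strains:
        raise KeyError(f"unknown strain {strain!r}")
    i = cm.strains.index(strain)
    row = cm.values[i]
    total = row.sum()
    if total <= 0:
        raise PaintingError(f"zero chunk-count row for strain {strain!r}")
    lineages = np.asarray(cm.lineages)
    labels = sorted(set(cm.lineages))
    fractions = pd.Series(
        {l: row[lineages == l].sum() / total for l in labels}, name=strain
    )
    return fractions


def admixture_flags(cm: CoancestryMatrix,
                    threshold: float = 0.25) -> pd.DataFrame:
    """Admixture candidates: strains whose largest non-own-lineage coancestry
    fraction exceeds ``threshold``."""
    rows = []
    for strain, own in zip(cm.strains, cm.lineages):
        frac = admixture_fractions(cm, strain)
        foreign = frac.drop(own) if own in frac.index else frac
        top = foreign.idxmax() if len(foreign) else None
        top_frac = float(foreign.max()) if len(foreign) else 0.0
        rows.append({
            "strain": strain, "lineage": own,
            "own_fraction": float(frac.get(own, 0.0)),
            "top_foreign_lineage": top, "top_foreign_fraction": top_frac,
            "admixture_candidate": top_frac > threshold,
        })
    return pd.DataFrame(rows)
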