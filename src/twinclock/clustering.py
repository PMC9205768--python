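"""Cancer-cell-fraction estimation, Dirichlet-mixture clustering, pigeonhole
lineage assignment.

VAFs are converted to cancer cell fractions (CCF) by adjusting for sample
purity rho, local total copy number CN_t and mutation multiplicity m:

    CCF = VAF * (rho * CN_t + cn_normal * (1 - rho)) / (rho * m)

Mutations are then clustered by CCF in one or two sample dimensions with a
truncated stick-breaking Dirichlet-process mixture whose emission is binomial
on read counts: a mutation assigned to a cluster at location pi (CCF) in
sample d contributes alt ~ Binomial(depth, pi * rho_d * m / (rho_d * CN_t +
2 * (1 - rho_d))). The binomial emission makes sequencing depth inform
assignment uncertainty, as in DPClust-style subclonal reconstruction.

Lineage assignment uses the pigeonhole principle: within one sample, two
clusters each above CCF 0.5 must overlap in cells, hence lie on the same
cell lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

CLUSTER_MIN_FRACTION = 0.01
PIGEONHOLE_CCF = 0.5
#: cluster locations may exceed 1 slightly (multiplicity/CN misestimation)
CCF_LOCATION_MAX = 1.3
STICK_TRUNCATION = 20


# ---------------------------------------------------------------------------
# multiplicity and CCF
# ---------------------------------------------------------------------------

def estimate_multiplicity(vaf: float, purity: float, cn_total: int,
                          cn_normal: int = 2) -> int:
    """Integer number of mutated chromosome copies per tumor cell.

    m = round(vaf * (rho*CN_t + cn_normal*(1-rho)) / rho), half-up at ties,
    clamped to [1, CN_t]; returns 0 only for vaf == 0. CN_t == 0 (homozygous
    deletion) is unmappable and raises.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must lie in [0, 1]")
    if cn_total == 0:
        raise ValueError("CN_t = 0: site unmappable (homozygous deletion)")
    if vaf == 0.0:
        return 0
    raw = vaf * (purity * cn_total + cn_normal * (1.0 - purity)) / purity
    m = int(np.floor(raw + 0.5))  # round half up
    return int(min(max(m, 1), cn_total))


def compute_ccf(vaf: float, purity: float, cn_total: int, multiplicity: int,
                cn_normal: int = 2) -> float:
    """CCF = vaf * (rho*CN_t + cn_normal*(1-rho)) / (rho * m).

    Values above 1 are returned as-is (flagged by callers downstream); with
    rho=1, CN_t=2, m=1 this reduces to CCF = 2*vaf exactly.
    """
    if purity <= 0.0:
        raise ValueError("purity must be positive")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    return vaf * (purity * cn_total + cn_normal * (1.0 - purity)) / (purity * multiplicity)


@dataclass
class CcfRecord:
    """Per-variant CCF input for clustering; one entry per sample dimension."""

    key: tuple
    alt: np.ndarray      # (n_dims,) alt read counts
    depth: np.ndarray    # (n_dims,) total depths (>=1)
    cn_total: np.ndarray # (n_dims,) total copy number
    multiplicity: np.ndarray  # (n_dims,)
    ccf: np.ndarray      # (n_dims,) point estimates


def build_ccf_records(
    table: pd.DataFrame,
    purity: tuple[float, ...],
    sample_suffixes: tuple[str, ...] = ("a", "b"),
    cn_normal: int = 2,
) -> list[CcfRecord]:
    """Assemble CcfRecords from a per-variant table.

    Expects columns ``alt_<s>``/``depth_<s>`` per sample suffix and either a
    ``cn_total`` column or per-sample ``cn_total_<s>``. A variant absent from
    a sample is encoded there as alt=0 at that sample's local depth, the
    convention multidimensional clustering needs to place axis clusters.
    """
    records = []
    for row in table.itertuples(index=False):
        alt, depth, cn, mult, ccf = [], [], [], [], []
        for s, rho in zip(sample_suffixes, purity):
            a = int(getattr(row, f"alt_{s}"))
            d = max(1, int(getattr(row, f"depth_{s}")))
            c = int(getattr(row, f"cn_total_{s}", getattr(row, "cn_total", 2)))
            vaf = a / d
            m = estimate_multiplicity(vaf, rho, c, cn_normal) if a > 0 else 1
            m = max(m, 1)
            alt.append(a); depth.append(d); cn.append(c); mult.append(m)
            ccf.append(compute_ccf(vaf, rho, c, m, cn_normal))
        records.append(CcfRecord(
            key=(row.chrom, row.pos, row.ref, row.alt),
            alt=np.array(alt), depth=np.array(depth), cn_total=np.array(cn),
            multiplicity=np.array(mult), ccf=np.array(ccf),
        ))
    return records


# ---------------------------------------------------------------------------
# Dirichlet-process binomial mixture (truncated stick-breaking Gibbs)
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """Fitted mixture: per-cluster CCF locations, weights and assignments."""

    locations: np.ndarray        # (n_clusters, n_dims)
    weights: np.ndarray          # (n_clusters,)
    assignments: np.ndarray      # (n_records,) cluster indices into locations
    keys: list                   # record keys, aligned with assignments
    location_draws: np.ndarray   # (n_draws, n_clusters, n_dims)
    n_dims: int = 1

    @property
    def n_clusters(self) -> int:
        return len(self.weights)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"ccf_{d}": self.locations[:, d] for d in range(self.n_dims)}
        counts = np.bincount(self.assignments, minlength=self.n_clusters)
        return pd.DataFrame({"cluster": np.arange(self.n_clusters), **cols,
                             "weight": self.weights, "n": counts})


def _success_probs(locations: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Expected VAF per (record, cluster, dim): pi_cd * scale_rd, clipped."""
    p = locations[None, :, :] * scale[:, None, :]
    return np.clip(p, 1e-9, 1.0 - 1e-9)


def cluster_ccf(
    records: list[CcfRecord],
    purity: tuple[float, ...],
    n_dims: int = 1,
    concentration: float = 1.0,
    iters: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    truncation: int = STICK_TRUNCATION,
    n_chains: int = 3,
    cn_normal: int = 2,
) -> ClusterSolution:
    """Fit the truncated-DP binomial mixture by Gibbs sampling.

    Sweeps: cluster assignments (categorical), stick-breaking weights
    (conjugate Beta), cluster locations (adaptive random-walk Metropolis,
    uniform prior on [0, 1.3]). ``n_chains`` independent chains are run and
    their post-burn-in co-clustering (posterior similarity) matrices pooled;
    the reported partition is the average-linkage consensus of that matrix
    with the number of clusters chosen by Binder loss. This point estimate
    is immune to label switching and robust to a single chain parking a
    satellite component. ``location_draws`` are conditional posterior draws
    of the cluster locations at the consensus partition, and the reported
    locations are their means.
    """
    if len(records) < 5:
        raise ValueError("need at least 5 records for a stable mixture fit")
    n = len(records)
    K = truncation

    alt = np.stack([r.alt[:n_dims] for r in records])          # (n, D)
    depth = np.stack([r.depth[:n_dims] for r in records])
    mult = np.stack([r.multiplicity[:n_dims] for r in records])
    cn = np.stack([r.cn_total[:n_dims] for r in records])
    rho = np.asarray(purity[:n_dims], dtype=float)
    # per-record, per-dim VAF produced by one unit of CCF
    scale = mult * rho[None, :] / (cn * rho[None, :] + cn_normal * (1.0 - rho[None, :]))
    log_binom_const = (gammaln(depth + 1) - gammaln(alt + 1)
                       - gammaln(depth - alt + 1)).sum(axis=1)

    def loglik_matrix(locations: np.ndarray) -> np.ndarray:
        """(n, K) binomial log likelihood of each record under each cluster."""
        p = _success_probs(locations, scale)  # (n, K, D)
        ll = alt[:, None, :] * np.log(p) + (depth - alt)[:, None, :] * np.log1p(-p)
        return ll.sum(axis=2) + log_binom_const[:, None]

    # init: seeding from observed CCFs spread over quantiles (jittered per chain)
    obs_ccf = np.clip(np.stack([r.ccf[:n_dims] for r in records]), 0.0, CCF_LOCATION_MAX)
    q = np.linspace(0.05, 0.95, K)
    base_locations = np.stack(
        [np.quantile(obs_ccf[:, d], q) for d in range(n_dims)], axis=1)

    psm = np.zeros((n, n))
    n_psm = 0
    psm_thin = 5

    def run_chain(rng: np.random.Generator) -> int:
        nonlocal psm, n_psm
        locations = np.clip(
            base_locations + rng.normal(0, 0.03, base_locations.shape),
            0.0, CCF_LOCATION_MAX)
        log_w = np.full(K, -np.log(K))
        prop_sd = np.full((K, n_dims), 0.05)
        acc = np.zeros((K, n_dims))
        kept = 0
        for it in range(iters):
            # 1. assignments
            ll = loglik_matrix(locations)
            logits = ll + log_w[None, :]
            gumb = rng.gumbel(size=logits.shape)
            z = np.argmax(logits + gumb, axis=1)

            # 2. stick-breaking weights
            counts = np.bincount(z, minlength=K)
            tail = counts[::-1].cumsum()[::-1]
            v = rng.beta(1.0 + counts[:-1], concentration + tail[1:])
            v = np.append(np.clip(v, 1e-12, 1 - 1e-12), 1.0)
            log_w = np.log(v) + np.concatenate([[0.0], np.cumsum(np.log1p(-v[:-1]))])

            # 3. locations: a few RW-Metropolis tries per cluster-dim
            for k in range(K):
                members = z == k
                for d in range(n_dims):
                    if not members.any():
                        locations[k, d] = rng.uniform(0.0, CCF_LOCATION_MAX)
                        continue
                    cur = locations[k, d]
                    cur_ll = _dim_loglik(alt, depth, scale, members, d, cur)
                    for _ in range(3):
                        prop = cur + rng.normal(0.0, prop_sd[k, d])
                        if not 0.0 <= prop <= CCF_LOCATION_MAX:
                            continue
                        prop_ll = _dim_loglik(alt, depth, scale, members, d, prop)
                        if np.log(rng.random()) < prop_ll - cur_ll:
                            cur, cur_ll = prop, prop_ll
                            acc[k, d] += 1.0 / 3.0
                    locations[k, d] = cur
            if it < burn_in and it and it % 50 == 0:
                rate = acc / 50.0
                prop_sd *= np.where(rate < 0.2, 0.7, np.where(rate > 0.5, 1.4, 1.0))
                prop_sd = np.clip(prop_sd, 1e-4, 0.3)
                acc[:] = 0.0

            if it >= burn_in and (it - burn_in) % psm_thin == 0:
                psm += z[:, None] == z[None, :]
                kept += 1
        return kept

    for c in range(n_chains):
        n_psm += run_chain(np.random.default_rng(seed + 1000 * c))
    rng = np.random.default_rng(seed)

    z = _consensus_partition(psm / n_psm)
    z = _merge_refine(z, alt, depth, scale, concentration)
    n_clusters = int(z.max()) + 1
    counts = np.bincount(z, minlength=n_clusters)
    weights = counts / counts.sum()

    # conditional posterior draws of locations at the consensus partition
    init = np.stack(
        [np.clip(obs_ccf[z == k].mean(axis=0), 0.0, CCF_LOCATION_MAX)
         for k in range(n_clusters)])
    draws = _conditional_location_draws(
        alt, depth, scale, z, init, n_draws=200, rng=rng)

    return ClusterSolution(
        locations=draws.mean(axis=0), weights=weights, assignments=z,
        keys=[r.key for r in records], location_draws=draws, n_dims=n_dims,
    )


def _consensus_partition(psm: np.ndarray, max_clusters: int = 12) -> np.ndarray:
    """Binder-optimal consensus of a posterior similarity matrix.

    Candidate partitions are average-linkage dendrogram cuts of 1 - PSM; the
    reported one minimizes the Binder loss
    sum_{i<j} |1[z_i = z_j] - psm_ij|, the standard similarity-matrix point
    estimate for Dirichlet-process mixtures (immune to label switching).
    """
    from scipy.cluster.hierarchy import cut_tree, linkage
    from scipy.spatial.distance import squareform

    dist = 1.0 - psm
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    n = len(psm)
    cuts = cut_tree(tree, n_clusters=list(range(1, min(max_clusters, n) + 1)))
    best_loss, labels = np.inf, cuts[:, 0]
    iu = np.triu_indices(n, k=1)
    for col in range(cuts.shape[1]):
        z = cuts[:, col]
        same = z[:, None] == z[None, :]
        loss = np.abs(same[iu].astype(float) - psm[iu]).sum()
        if loss < best_loss - 1e-9:
            best_loss, labels = loss, z
    # relabel by decreasing size for determinism
    order = np.argsort([-np.sum(labels == k) for k in range(labels.max() + 1)],
                       kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(k)] for k in labels])


def _cluster_marginal_loglik(alt, depth, scale, members) -> float:
    """Location-integrated binomial log likelihood of one cluster.

    Integrates the product binomial likelihood over the uniform location
    prior on [0, CCF_LOCATION_MAX], per dimension, on a fine grid.
    """
    total = 0.0
    grid = np.linspace(0.0, CCF_LOCATION_MAX, 2000)
    for d in range(alt.shape[1]):
        p = np.clip(grid[:, None] * scale[members, d][None, :], 1e-9, 1 - 1e-9)
        a = alt[members, d][None, :]
        dep = depth[members, d][None, :]
        ll = (a * np.log(p) + (dep - a) * np.log1p(-p)).sum(axis=1)
        m = ll.max()
        total += m + math.log(
            np.trapezoid(np.exp(ll - m), grid) / CCF_LOCATION_MAX)
    return total


def _merge_refine(z: np.ndarray, alt, depth, scale, concentration: float
                  ) -> np.ndarray:
    """Greedy merges that increase the collapsed partition posterior.

    The Gibbs chain can park a satellite component on the noise tail of a
    large cluster and stay there (a quasi-mode); the collapsed posterior —
    Chinese-restaurant partition prior times the location-integrated
    likelihood — scores such partitions below the merged one. Merging pairs
    while that score increases removes exactly those artifacts and stops as
    soon as clusters are genuinely separated.
    """
    z = z.copy()
    labels = list(np.unique(z))
    marg = {k: _cluster_marginal_loglik(alt, depth, scale, z == k) for k in labels}

    def merge_gain(k1: int, k2: int) -> float:
        m = (z == k1) | (z == k2)
        n1, n2 = int((z == k1).sum()), int((z == k2).sum())
        joint = _cluster_marginal_loglik(alt, depth, scale, m)
        # CRP terms: alpha * (n_k - 1)! per cluster
        prior = (gammaln(n1 + n2) - gammaln(n1) - gammaln(n2)
                 - math.log(concentration))
        return joint - marg[k1] - marg[k2] + prior

    improved = True
    while improved and len(labels) > 1:
        improved = False
        best = (0.0, None)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                gain = merge_gain(labels[i], labels[j])
                if gain > best[0]:
                    best = (gain, (labels[i], labels[j]))
        if best[1] is not None:
            k1, k2 = best[1]
            z[z == k2] = k1
            labels.remove(k2)
            marg[k1] = _cluster_marginal_loglik(alt, depth, scale, z == k1)
            improved = True
    # compact relabel by decreasing size
    order = sorted(labels, key=lambda k: -int((z == k).sum()))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[int(k)] for k in z])


def _dim_loglik(alt, depth, scale, members, d: int, loc: float) -> float:
    p = np.clip(loc * scale[members, d], 1e-9, 1 - 1e-9)
    a = alt[members, d]
    dep = depth[members, d]
    return float((a * np.log(p) + (dep - a) * np.log1p(-p)).sum())


def _conditional_location_draws(alt, depth, scale, z, locations, n_draws, rng,
                                thin: int = 3) -> np.ndarray:
    n_clusters, n_dims = locations.shape
    sd = np.full((n_clusters, n_dims), 0.02)
    draws = np.empty((n_draws, n_clusters, n_dims))
    for t in range(n_draws * thin):
        for k in range(n_clusters):
            members = z == k
            for d in range(n_dims):
                cur = locations[k, d]
                prop = cur + rng.normal(0.0, sd[k, d])
                if not 0.0 <= prop <= CCF_LOCATION_MAX:
                    continue
                if (np.log(rng.random())
                        < _dim_loglik(alt, depth, scale, members, d, prop)
                        - _dim_loglik(alt, depth, scale, members, d, cur)):
                    locations[k, d] = prop
        if t % thin == thin - 1:
            draws[t // thin] = locations
    return draws


# ---------------------------------------------------------------------------
# pruning, intervals, pigeonhole
# ---------------------------------------------------------------------------

def prune_clusters(
    solution: ClusterSolution,
    records: list[CcfRecord],
    purity: tuple[float, ...],
    min_fraction: float = CLUSTER_MIN_FRACTION,
    cn_normal: int = 2,
) -> ClusterSolution:
    """Remove clusters holding < ``min_fraction`` of mutations (strict <).

    Members of removed clusters are reassigned to the highest-likelihood
    surviving cluster; weights are recomputed from the new memberships.
    """
    keep = np.flatnonzero(solution.weights >= min_fraction)
    if keep.size == 0:
        raise ValueError("all clusters fall below the pruning threshold")
    if keep.size == solution.n_clusters:
        return solution
    n_dims = solution.n_dims
    alt = np.stack([r.alt[:n_dims] for r in records])
    depth = np.stack([r.depth[:n_dims] for r in records])
    mult = np.stack([r.multiplicity[:n_dims] for r in records])
    cn = np.stack([r.cn_total[:n_dims] for r in records])
    rho = np.asarray(purity[:n_dims], dtype=float)
    scale = mult * rho[None, :] / (cn * rho[None, :] + cn_normal * (1.0 - rho[None, :]))

    locs = solution.locations[keep]
    p = _success_probs(locs, scale)
    ll = (alt[:, None, :] * np.log(p)
          + (depth - alt)[:, None, :] * np.log1p(-p)).sum(axis=2)
    remap = {int(old): i for i, old in enumerate(keep)}
    new_z = np.empty_like(solution.assignments)
    for r, old in enumerate(solution.assignments):
        new_z[r] = remap[int(old)] if int(old) in remap else int(np.argmax(ll[r]))
    counts = np.bincount(new_z, minlength=keep.size)
    return ClusterSolution(
        locations=locs, weights=counts / counts.sum(), assignments=new_z,
        keys=solution.keys, location_draws=solution.location_draws[:, keep, :],
        n_dims=n_dims,
    )


def binomial_ccf_interval(
    alt: int, depth: int, expected_vaf: float,
    purity: float = 1.0, cn_total: int = 2, multiplicity: int = 1,
    cn_normal: int = 2, level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Binomial tail probability and an equal-tailed CCF interval.

    The tail probability is the binomial CDF of ``alt`` successes in
    ``depth`` trials at ``expected_vaf``. The interval is the Clopper-Pearson
    equal-tailed interval on the VAF mapped through the CCF formula.
    """
    if not 0.0 <= expected_vaf <= 1.0:
        raise ValueError("expected_vaf must lie in [0, 1]")
    if not 0 <= alt <= depth:
        raise ValueError("need 0 <= alt <= depth")
    tail = float(stats.binom.cdf(alt, depth, expected_vaf))
    lo, hi = stats.binomtest(alt, depth).proportion_ci(
        confidence_level=level, method="exact")
    to_ccf = lambda v: compute_ccf(float(v), purity, cn_total, multiplicity, cn_normal)
    return tail, (to_ccf(lo), to_ccf(hi))


def assign_lineages_pigeonhole(
    solution: ClusterSolution, threshold: float = PIGEONHOLE_CCF
) -> pd.DataFrame:
    """Label clusters by the pigeonhole principle.

    Within one sample, clusters with CCF > 0.5 jointly exceed the cell
    population, so they must overlap: they lie on the same cell lineage.
    Labels: ``ancestral`` (CCF > 0.5 in every sample — the shared clone),
    ``lineage_a``/``lineage_b`` (CCF > 0.5 in that sample only), and
    ``indeterminate`` (never above 0.5; pigeonhole inapplicable). Invariant
    to cluster reordering.
    """
    locs = np.atleast_2d(solution.locations)
    n_dims = solution.n_dims
    labels = []
    for k in range(solution.n_clusters):
        high = locs[k, :n_dims] > threshold
        if high.all() and n_dims > 1:
            labels.append("ancestral")
        elif n_dims == 1:
            labels.append("lineage_a" if high[0] else "indeterminate")
        elif high[0]:
            labels.append("lineage_a")
        elif high[1]:
            labels.append("lineage_b")
        else:
            labels.append("indeterminate")
    df = solution.to_frame()
    df["label"] = labels
    return df
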