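"""Cancer-cell fractions and prevalence clustering.

Read counts are converted to cancer-cell fractions (CCF) using the sample's
purity rho and the allele-specific copy number (major, minor) at the locus:
the expected VAF of a mutation at multiplicity m and CCF phi is

    xi = rho * m * phi / (rho * (major + minor) + 2 * (1 - rho)),

so phi_hat inverts that relation at the observed VAF, clamped to [0, 1].
Multiplicity is estimated by rounding vaf/rho * (rho*CN + 2*(1-rho)) and
clamping to [1, major].

Mutations are then grouped into prevalence clusters with an EM fit of a
K-component binomial mixture: component k has a per-sample prevalence
vector phi_k, and alt_is ~ Binomial(depth_is, xi(phi_ks)). K is selected by
BIC over 1..max_clusters, each fit taking the best of several k-means-style
seeded restarts. Clusters closer than the merge distance (max-norm on the
prevalence vectors) are merged, then the retention rules apply: a cluster
is kept when it has more than five mutations and prevalence >= 0.2 in at
least one sample, and counts as present in a sample when its prevalence
there is at least 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crcrelapse.config import PipelineConfig
from crcrelapse.variants import MutationTable, lookup_segments


# ---------------------------------------------------------------------------
# CCF point estimates
# ---------------------------------------------------------------------------

def compute_multiplicity(vaf: float, purity: float, major: int,
                         minor: int) -> int:
    """Estimated mutation multiplicity, clamped to [1, major]."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if major < 1 or minor < 0 or major < minor:
        raise ValueError("need major >= max(minor, 1); mutations on fully "
                         "deleted segments are excluded upstream")
    cn = major + minor
    raw = vaf / purity * (purity * cn + 2.0 * (1.0 - purity))
    return int(np.clip(round(raw), 1, major))


def compute_ccf(alt: int, depth: int, purity: float, major: int, minor: int,
                m: int) -> tuple[float, bool]:
    """CCF estimate and a flag marking clamping of values above 1.05."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if purity <= 0:
        raise ValueError("purity must be positive")
    cn = major + minor
    raw = (alt / depth) * (purity * cn + 2.0 * (1.0 - purity)) / (purity * m)
    return float(np.clip(raw, 0.0, 1.0)), bool(raw > 1.05)


@dataclass
class CCFEstimate:
    """Per-(mutation, sample) VAF, multiplicity, copy state and clamped CCF."""

    vaf: pd.DataFrame
    multiplicity: pd.DataFrame
    major: pd.DataFrame
    total_cn: pd.DataFrame
    ccf: pd.DataFrame
    clamped: pd.DataFrame

    def clamp_rate(self) -> float:
        return float(self.clamped.to_numpy().mean())


def estimate_ccf(table: MutationTable, segments: pd.DataFrame) -> CCFEstimate:
    """Vectorized CCF estimation over all tumor samples.

    Mutations must be covered by a segment with major >= 1 in every tumor
    sample (the deconvolution input filter guarantees coverage; loci on
    fully deleted segments are excluded upstream).
    """
    tumor = table.tumor_samples()
    major, minor = lookup_segments(table, segments)
    major, minor = major[tumor], minor[tumor]
    if major.isna().any().any():
        raise ValueError("mutations without segment cover; apply the "
                         "deconvolution input filter first")
    if (major < 1).any().any():
        raise ValueError("mutations on fully deleted segments (major = 0) "
                         "must be excluded upstream")
    vaf = table.vaf()[tumor]
    rho = table.meta.loc[tumor, "purity"].to_numpy()[None, :]
    cn = major.to_numpy() + minor.to_numpy()
    denom = rho * cn + 2.0 * (1.0 - rho)
    mult = np.clip(np.rint(vaf.to_numpy() / rho * denom), 1,
                   np.maximum(major.to_numpy(), 1)).astype(int)
    # harmonize multiplicity across samples: the sample where the mutation
    # is most clonal carries the informative estimate (rounding in samples
    # where the clone is subclonal collapses m to 1 and would double the
    # CCF there); still capped by each sample's major allele count
    mult = np.minimum(mult.max(axis=1, keepdims=True),
                      np.maximum(major.to_numpy(), 1)).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = vaf.to_numpy() * denom / (rho * mult)
    ccf = np.clip(raw, 0.0, 1.0)
    idx, cols = table.muts.index, tumor
    return CCFEstimate(
        vaf=vaf,
        multiplicity=pd.DataFrame(mult, index=idx, columns=cols),
        major=pd.DataFrame(major.to_numpy().astype(int), index=idx,
                           columns=cols),
        total_cn=pd.DataFrame(cn, index=idx, columns=cols),
        ccf=pd.DataFrame(ccf, index=idx, columns=cols),
        clamped=pd.DataFrame(raw > 1.05, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# Binomial-mixture clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterPrevalence:
    """Clusters x samples prevalence matrix plus assignments.

    ``prevalence``: rows = cluster ids, columns = samples; ``assignment``:
    mutation id -> cluster id; ``sizes``: mutations per cluster;
    ``bic``: fit score of the selected model (lower is better).
    """

    prevalence: pd.DataFrame
    assignment: pd.Series
    bic: float

    @property
    def k(self) -> int:
        return len(self.prevalence)

    @property
    def sizes(self) -> pd.Series:
        return (self.assignment.value_counts()
                .reindex(self.prevalence.index, fill_value=0))


def _genotype_logliks(alt, depth, a_cand, phi):
    """Log-likelihood of every mutation under one prevalence vector,
    profiled over the latent multiplicity genotype.

    ``a_cand`` has shape (n, S, G): candidate expected-VAF factors per
    genotype g (xi = a * phi), with duplicated columns where a sample's
    major allele caps the multiplicity. The genotype is chosen by maximum
    likelihood per (mutation, cluster), the convention the deconvolution
    tools use. Binomial coefficients are constant across clusters and
    omitted. Returns (loglik (n,), best genotype index (n,)).
    """
    xi = np.clip(a_cand * phi[None, :, None], 1e-9, 1 - 1e-9)
    ll = (alt[:, :, None] * np.log(xi)
          + (depth - alt)[:, :, None] * np.log1p(-xi)).sum(axis=1)
    g_best = np.argmax(ll, axis=1)
    return ll[np.arange(ll.shape[0]), g_best], g_best


def _em_fit(alt, depth, a_cand, phi0, max_iter=200, tol=1e-7):
    """EM for a K-component binomial mixture with latent multiplicities."""
    n = alt.shape[0]
    k = phi0.shape[0]
    idx = np.arange(n)
    phi = phi0.copy()
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for _ in range(max_iter):
        lls, gs = zip(*(_genotype_logliks(alt, depth, a_cand, phi[j])
                        for j in range(k)))
        ll_k = np.stack(lls, axis=1) \
            + np.log(np.maximum(weights, 1e-12))[None, :]
        mx = ll_k.max(axis=1, keepdims=True)
        post = np.exp(ll_k - mx)
        norm = post.sum(axis=1, keepdims=True)
        post /= norm
        total_ll = float((np.log(norm).ravel() + mx.ravel()).sum())
        weights = post.mean(axis=0)
        # responsibility-weighted ratio estimator per (cluster, sample),
        # at each mutation's ML genotype for that cluster
        for j in range(k):
            r = post[:, j][:, None]
            a_eff = a_cand[idx, :, gs[j]]
            num = (r * alt).sum(axis=0)
            den = (r * depth * a_eff).sum(axis=0)
            phi[j] = np.clip(np.where(den > 0, num / np.maximum(den, 1e-12),
                                      0.0), 0.0, 1.0)
        if abs(total_ll - prev_ll) < tol * max(1.0, abs(total_ll)):
            break
        prev_ll = total_ll
    lls, _ = zip(*(_genotype_logliks(alt, depth, a_cand, phi[j])
                   for j in range(k)))
    ll_k = np.stack(lls, axis=1) \
        + np.log(np.maximum(weights, 1e-12))[None, :]
    mx = ll_k.max(axis=1, keepdims=True)
    total_ll = float((np.log(np.exp(ll_k - mx).sum(axis=1)) + mx.ravel()).sum())
    # deterministic tie-break: lowest cluster index on equal responsibility
    resp = ll_k - mx
    assign = np.argmax(np.isclose(resp, resp.max(axis=1, keepdims=True)),
                       axis=1)
    return phi, weights, assign, total_ll


def _kmeans_seed(ccf, k, rng):
    """k-means++-style seeding of prevalence vectors on the CCF matrix."""
    n = ccf.shape[0]
    first = int(rng.integers(n))
    centers = [ccf[first]]
    for _ in range(1, k):
        d2 = np.min([((ccf - c) ** 2).sum(axis=1) for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(ccf[int(rng.integers(n))])
            continue
        centers.append(ccf[int(rng.choice(n, p=d2 / total))])
    return np.clip(np.array(centers), 0.0, 1.0)


def cluster_mutations(table: MutationTable, ccf: CCFEstimate,
                      config: PipelineConfig | None = None,
                      seed: int = 0,
                      max_clusters: int | None = None,
                      restarts: int | None = None) -> ClusterPrevalence:
    """EM clustering of mutations into prevalence clusters; K by BIC.

    ``max_clusters``/``restarts`` default to the config values and can be
    lowered for small problems. Deterministic given the seed.
    """
    config = config or PipelineConfig()
    max_clusters = max_clusters or config.max_clusters
    restarts = restarts or config.restarts
    samples = list(ccf.ccf.columns)
    alt = table.alt[samples].to_numpy(dtype=float)
    depth = table.depth[samples].to_numpy(dtype=float)
    if len(alt) == 0:
        raise ValueError("no mutations to cluster")
    if (depth.sum(axis=0) == 0).any():
        raise ValueError("a sample has zero depth at every mutation")
    rho = table.meta.loc[samples, "purity"].to_numpy()[None, :]
    # candidate expected-VAF factors per multiplicity genotype:
    # xi = a*phi with a = rho*m / (rho*CN + 2(1-rho)); the genotype index g
    # maps to per-sample multiplicity min(g+1, major_s), so mutations on
    # gained segments can be explained at any multiplicity up to the major
    # allele (latent, resolved inside the EM)
    cn = ccf.total_cn[samples].to_numpy(dtype=float)
    major = ccf.major[samples].to_numpy(dtype=int)
    g_max = int(min(4, max(1, major.max())))
    denom = rho * cn + 2.0 * (1.0 - rho)
    a_cand = np.stack(
        [np.clip(rho * np.minimum(g + 1, major) / denom, 1e-6, 1.0)
         for g in range(g_max)], axis=2)

    ccf_mat = ccf.ccf.to_numpy()
    n = ccf_mat.shape[0]
    rng = np.random.default_rng(seed)
    best = None
    for k in range(1, min(max_clusters, n) + 1):
        best_k = None
        n_restarts = 1 if k == 1 else restarts
        for _ in range(n_restarts):
            phi0 = _kmeans_seed(ccf_mat, k, rng)
            fit = _em_fit(alt, depth, a_cand, phi0)
            if best_k is None or fit[3] > best_k[3]:
                best_k = fit
        phi, weights, assign, ll = best_k
        n_params = k * len(samples) + (k - 1)
        bic = -2.0 * ll + n_params * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, phi, assign)
    bic, phi, assign = best
    used = sorted(set(assign))
    remap = {old: new for new, old in enumerate(used)}
    prevalence = pd.DataFrame(phi[used], index=range(len(used)),
                              columns=samples)
    assignment = pd.Series([remap[a] for a in assign],
                           index=ccf.ccf.index, name="cluster")
    return ClusterPrevalence(prevalence=prevalence, assignment=assignment,
                             bic=float(bic))


def merge_close_clusters(cp: ClusterPrevalence,
                         max_dist: float = 0.1) -> ClusterPrevalence:
    """Merge clusters whose prevalence vectors differ by < max_dist (max-norm).

    Merging is iterative (closest pair first); the merged prevalence is the
    size-weighted mean. Applied before the retention rules, mirroring the
    cluster-collapsing step of lineage tools.
    """
    prev = cp.prevalence.copy()
    assign = cp.assignment.copy()
    while len(prev) > 1:
        sizes = assign.value_counts().reindex(prev.index, fill_value=0)
        ids = list(prev.index)
        best_pair, best_d = None, max_dist
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = float((prev.loc[a] - prev.loc[b]).abs().max())
                if d < best_d:
                    best_pair, best_d = (a, b), d
        if best_pair is None:
            break
        a, b = best_pair
        wa, wb = sizes[a], sizes[b]
        prev.loc[a] = (wa * prev.loc[a] + wb * prev.loc[b]) / max(wa + wb, 1)
        prev = prev.drop(index=b)
        assign[assign == b] = a
    remap = {old: new for new, old in enumerate(prev.index)}
    prev.index = [remap[i] for i in prev.index]
    assign = assign.map(remap)
    return ClusterPrevalence(prevalence=prev, assignment=assign, bic=cp.bic)


def filter_clusters(cp: ClusterPrevalence,
                    config: PipelineConfig | None = None
                    ) -> tuple[ClusterPrevalence, pd.DataFrame]:
    """Retention and presence rules.

    Retained: size > ``cluster_min_size`` AND max prevalence >=
    ``cluster_max_prev``. Present in a sample: prevalence >=
    ``cluster_presence``. Empty retention is allowed (returned empty).
    """
    config = config or PipelineConfig()
    sizes = cp.sizes
    keep = [cid for cid in cp.prevalence.index
            if sizes[cid] > config.cluster_min_size
            and cp.prevalence.loc[cid].max() >= config.cluster_max_prev]
    prev = cp.prevalence.loc[keep]
    assign = cp.assignment[cp.assignment.isin(keep)]
    presence = prev >= config.cluster_presence
    return (ClusterPrevalence(prevalence=prev, assignment=assign,
                              bic=cp.bic), presence)
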