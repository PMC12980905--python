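"""Tumor-microenvironment scoring from bulk expression.

Three rank-based procedures operate on a genes x samples matrix:

* single-sample gene-set enrichment (ssGSEA): a per-sample running-sum
  score over the ranked gene list, weighting in-set genes by rank^alpha;
* the CERNO test: for a gene set S within a ranked gene list,
  F = -2 * sum_{i in S} ln(r_i / N) follows a chi-square law with 2|S|
  degrees of freedom under the null of uniform ranks;
* nearest-template prediction (NTP) into consensus molecular subtypes
  (CMS1-4): cosine distance of a sample's centered expression over each
  class's marker genes to the template weight vector, with significance by
  random same-size gene sets and Benjamini-Hochberg control across classes.

Raw counts are normalized to log2 counts-per-million. Because every
downstream score is rank-based, results are invariant to any strictly
monotone normalization, which is what makes this simple normalization an
adequate stand-in for variance stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a unit label."""

    values: pd.DataFrame
    unit: str = "raw counts"  # or "normalized"
    normalization_note: str = ""

    def __post_init__(self) -> None:
        if self.unit == "raw counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be nonnegative")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression entries must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))


def read_gmt(path: str) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], tuple(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: list[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_expression(counts: ExpressionMatrix | pd.DataFrame,
                         mode: str = "per_patient",
                         patients: pd.Series | None = None) -> ExpressionMatrix:
    """Log2 counts-per-million normalization.

    ``mode`` is ``per_patient`` or ``whole_cohort``; CPM is computed per
    sample either way (the grouping is recorded and used for validation),
    so the two modes differ only through the grouping. All-zero samples
    are rejected.
    """
    if mode not in ("per_patient", "whole_cohort"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    df = counts.values if isinstance(counts, ExpressionMatrix) else counts
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    cpm = df / totals * 1e6
    logcpm = np.log2(cpm + 1.0)
    note = f"log2-CPM ({mode}); stand-in for variance stabilization"
    return ExpressionMatrix(values=logcpm, unit="normalized",
                            normalization_note=note)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(expr: ExpressionMatrix | pd.DataFrame, gene_set: GeneSet,
                 alpha: float = 0.25) -> pd.Series:
    """Per-sample single-sample enrichment score of one gene set.

    Genes are ranked per sample by expression (descending; ties get average
    ranks). Walking down the ranked list, the running in-set ECDF weighted
    by rank^alpha is compared with the uniform out-of-set ECDF; the score is
    the sum of the differences over all list positions.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    n = len(df.index)
    if n < 2:
        raise ValueError("need at least 2 genes")
    members = [g for g in gene_set.genes if g in df.index]
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no gene in the matrix")
    in_set = df.index.isin(members)
    n_out = n - in_set.sum()
    scores = {}
    for s in df.columns:
        x = df[s].to_numpy(dtype=float)
        # average ranks, largest expression -> rank n
        r = stats.rankdata(x, method="average")
        order = np.lexsort((np.arange(n), -r))  # descending, stable
        inset_o = in_set[order]
        w = r[order] ** alpha
        w_in = np.where(inset_o, w, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~inset_o) / max(n_out, 1)
        scores[s] = float(np.sum(p_in - p_out))
    return pd.Series(scores, name=gene_set.name)


def ssgsea_matrix(expr: ExpressionMatrix | pd.DataFrame,
                  gene_sets: list[GeneSet], alpha: float = 0.25) -> pd.DataFrame:
    """ssGSEA scores for many sets: rows = gene sets, columns = samples."""
    return pd.DataFrame({gs.name: ssgsea_score(expr, gs, alpha)
                         for gs in gene_sets}).T


# ---------------------------------------------------------------------------
# CERNO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CernoResult:
    statistic: float
    df: int
    p_value: float


def rank_genes(stat: pd.Series, absolute: bool = False) -> pd.Series:
    """Ranks 1..N by a per-gene differential statistic, descending.

    Rank 1 = largest statistic (or largest magnitude when ``absolute``).
    Ties receive average ranks.
    """
    values = stat.abs() if absolute else stat
    return pd.Series(stats.rankdata(-values.to_numpy(), method="average"),
                     index=stat.index)


def signal_to_noise(expr: pd.DataFrame, group_a: list[str],
                    group_b: list[str]) -> pd.Series:
    """Golub signal-to-noise ratio per gene: (mean_a - mean_b)/(sd_a + sd_b).

    Standard deviations are floored at 0.2 * |mean| (and at 0.2 absolute)
    to avoid degenerate denominators, as in the GSEA convention.
    """
    a, b = expr[group_a], expr[group_b]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa = np.maximum(a.std(axis=1, ddof=1), np.maximum(0.2 * ma.abs(), 0.2))
    sb = np.maximum(b.std(axis=1, ddof=1), np.maximum(0.2 * mb.abs(), 0.2))
    return (ma - mb) / (sa + sb)


def cerno_test(gene_ranks: pd.Series, gene_set: GeneSet) -> CernoResult:
    """CERNO: F = -2 sum ln(r_i/N) ~ chi2(2|S|) under uniform ranks."""
    members = [g for g in gene_set.genes if g in gene_ranks.index]
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no ranked gene")
    n = len(gene_ranks)
    r = gene_ranks.loc[members].to_numpy(dtype=float)
    f = float(-2.0 * np.sum(np.log(r / n)))
    df = 2 * len(members)
    return CernoResult(statistic=f, df=df,
                       p_value=float(stats.chi2.sf(f, df)))


# ---------------------------------------------------------------------------
# Nearest-template prediction (CMS)
# ---------------------------------------------------------------------------

def read_templates(path: str) -> pd.DataFrame:
    """Read a template table: columns gene, class, weight (TSV)."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "class", "weight"}
    if missing := need - set(df.columns):
        raise ValueError(f"template table missing columns {sorted(missing)}")
    return df


def _template_distance(x: np.ndarray, w: np.ndarray) -> float:
    """1 - cosine similarity between centered expression and centered weights.

    Both vectors run over the union of all classes' marker genes; ``w``
    carries the class's weights on its own markers and zero elsewhere, so
    centering makes the comparison a correlation-like contrast of in-class
    versus out-of-class markers.
    """
    xc = x - x.mean()
    wc = w - w.mean()
    nx, nw = np.linalg.norm(xc), np.linalg.norm(wc)
    if nx == 0 or nw == 0:
        return 1.0
    return float(1.0 - xc @ wc / (nx * nw))


def ntp_classify(expr: ExpressionMatrix | pd.DataFrame,
                 templates: pd.DataFrame, n_perm: int = 1000,
                 seed: int = 0, fdr: float = 0.05,
                 center_genes: bool = True) -> pd.DataFrame:
    """Nearest-template CMS call per sample.

    For each class, the distance is 1 - cosine between the sample's
    gene-centered expression over the class's marker genes and the marker
    weights. The permutation p-value is the fraction of ``n_perm`` random
    same-size gene sets (with the same weights) at distance <= the observed
    one. p-values are BH-adjusted across classes; a sample whose best class
    does not reach ``fdr`` is left unclassified.

    With ``center_genes`` (default) each gene is centered across samples
    first, removing per-gene baselines (skipped for single-sample input).
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if center_genes and df.shape[1] > 1:
        df = df.sub(df.mean(axis=1), axis=0)
    classes = sorted(templates["class"].unique())
    if len(classes) < 2:
        raise ValueError("need templates for at least 2 classes")
    # union of all marker genes; per-class weights, zero off-class
    union: list[str] = []
    for cls in classes:
        sub = templates[templates["class"] == cls]
        genes = [g for g in sub["gene"] if g in df.index]
        if not genes:
            raise ValueError(f"template {cls!r} has no expressed gene")
        union.extend(g for g in genes if g not in union)
    weights = {}
    tm = templates.set_index(["class", "gene"])["weight"]
    for cls in classes:
        weights[cls] = np.array([tm.get((cls, g), 0.0) for g in union])
    rng = np.random.default_rng(seed)
    all_genes = df.index.to_numpy()
    rows = []
    for s in df.columns:
        x_full = df[s]
        x_obs = x_full.loc[union].to_numpy(dtype=float)
        # one shared pool of permuted gene draws for all classes
        perm_x = np.stack([
            x_full.loc[rng.choice(all_genes, size=len(union),
                                  replace=False)].to_numpy(dtype=float)
            for _ in range(n_perm)])
        dists, pvals = {}, {}
        for cls in classes:
            w = weights[cls]
            d_obs = _template_distance(x_obs, w)
            perm = np.array([_template_distance(perm_x[i], w)
                             for i in range(n_perm)])
            pvals[cls] = (1.0 + np.sum(perm <= d_obs)) / (n_perm + 1.0)
            dists[cls] = d_obs
        adj = dict(zip(classes,
                       multipletests([pvals[c] for c in classes],
                                     method="fdr_bh")[1]))
        best = min(classes, key=lambda c: dists[c])
        call = best if adj[best] <= fdr else "unclassified"
        row = {"sample": s, "predicted": call}
        for c in classes:
            row[f"dist_{c}"] = dists[c]
            row[f"p_{c}"] = pvals[c]
            row[f"fdr_{c}"] = adj[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Infiltration shift report
# ---------------------------------------------------------------------------

def infiltration_report(expr: ExpressionMatrix | pd.DataFrame,
                        gene_sets: list[GeneSet], meta: pd.DataFrame,
                        fdr: float = 0.05, alpha: float = 0.25,
                        statistic: str = "snr") -> pd.DataFrame:
    """Per-patient (and pooled) relapse-vs-metastasis gene-set shift table.

    For each patient with >= 2 samples per condition, genes are ranked by
    the per-gene differential statistic (default: signal-to-noise ratio,
    relapse minus metastasis, descending; ``statistic='abs_snr'`` ranks by
    magnitude) and each gene set is tested with CERNO; p-values are
    BH-adjusted across sets within each patient. The direction column is
    the sign of the mean ssGSEA score shift. A pooled row set (patient
    '__cohort__') repeats the test over all usable samples together.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    absolute = statistic == "abs_snr"
    scores = ssgsea_matrix(df, gene_sets, alpha=alpha)

    def _rows(label: str, met: list[str], rel: list[str]) -> list[dict]:
        snr = signal_to_noise(df, rel, met)
        ranks = rank_genes(snr, absolute=absolute)
        recs = []
        for gs in gene_sets:
            res = cerno_test(ranks, gs)
            shift = float(scores.loc[gs.name, rel].mean()
                          - scores.loc[gs.name, met].mean())
            recs.append({"patient": label, "gene_set": gs.name,
                         "mean_shift": shift,
                         "direction": "increased" if shift > 0 else
                                      ("decreased" if shift < 0 else "none"),
                         "statistic": res.statistic, "p_value": res.p_value})
        padj = multipletests([r["p_value"] for r in recs], method="fdr_bh")[1]
        for r, q in zip(recs, padj):
            r["p_adj"] = q
            r["significant"] = bool(q <= fdr)
        return recs

    out: list[dict] = []
    usable_met, usable_rel = [], []
    for patient, grp in meta.groupby("patient"):
        met = [s for s in grp.index
               if grp.loc[s, "tissue"] == "metastasis" and s in df.columns]
        rel = [s for s in grp.index
               if grp.loc[s, "tissue"] == "relapse" and s in df.columns]
        if len(met) < 2 or len(rel) < 2:
            import warnings
            warnings.warn(f"patient {patient!r} skipped: <2 samples in a "
                          "condition", stacklevel=2)
            continue
        usable_met += met
        usable_rel += rel
        out.extend(_rows(str(patient), met, rel))
    if usable_met and usable_rel:
        out.extend(_rows("__cohort__", usable_met, usable_rel))
    return pd.DataFrame(out)
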