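"""Ground-truthed synthetic CRLM relapse cohorts.

Emulates the study's sampling design so every downstream stage can be
tested without access to patient data: per patient one FFPE primary sample
(P_A, artifact-bearing, low purity), three metastasis samples (L_A, L_B,
L_C), three relapse samples (LR_A, LR_B, LR_C) and one matched normal, all
at ~450x mean exome depth.

Each patient carries a clone tree with a designated relapsing clone under
one of three seeding scenarios:

* ``shared`` - the relapsing clone is already detectable in exactly one
  metastasis sample before resection;
* ``private_sequential`` - the relapsing clone is confined to the relapse,
  but an ancestor is present in all liver samples and absent from the
  primary (sequential dissemination through the first metastasis);
* ``private_branchoff`` - metastasis and relapse lineages are sibling
  branches under a primary-resident clone (independent seeding).

Read counts are binomial around the purity- and copy-number-adjusted
expected VAF xi = rho * m * phi / (rho * CN_t + 2 * (1 - rho)); depths are
Poisson with a floor of one read. Copy-number truth is a per-branch event
list in the same event model the phylogeny module scores; mutational
spectra are clone-specific (clock-like everywhere, a fluorouracil-like
spectrum on the relapsing branch); expression matrices carry gene-set mean
shifts and CMS-template mixtures with recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crcrelapse import cnphylo, signatures
from crcrelapse.cnphylo import CNEvent, CNProfile, apply_events
from crcrelapse.expression import ExpressionMatrix, GeneSet
from crcrelapse.variants import MutationTable

SCENARIOS = ("shared", "private_sequential", "private_branchoff")
TUMOR_SAMPLES = ("P_A", "L_A", "L_B", "L_C", "LR_A", "LR_B", "LR_C")
MET_SAMPLES = ("L_A", "L_B", "L_C")
RELAPSE_SAMPLES = ("LR_A", "LR_B", "LR_C")

#: a few recurrent colorectal driver genes used for driver-flag demos
DRIVER_GENES = ("APC", "TP53", "KRAS", "SMAD4", "ARID1A", "FAT4", "NCOR2")


# ---------------------------------------------------------------------------
# Clone trees
# ---------------------------------------------------------------------------

@dataclass
class TrueCloneTree:
    """Ground-truth clone tree of one synthetic patient.

    ``phi`` holds per-clone, per-sample lineage prevalences (fraction of
    tumor cells in the clone's subtree); the germline root (id 0) is
    implicit. By construction a child's phi never exceeds its parent's in
    any sample and sibling phis never sum above the parent's.
    """

    scenario: str
    parent: dict[int, int]
    phi: pd.DataFrame
    mutations: dict[int, list[str]]
    spectrum: dict[int, str]
    relapsing_clone: int
    profiles: dict[int, CNProfile] = field(default_factory=dict)
    branch_events: dict[int, list[CNEvent]] = field(default_factory=dict)

    @property
    def clones(self) -> list[int]:
        return sorted(self.parent)

    def children(self, clone: int) -> list[int]:
        return [c for c, p in self.parent.items() if p == clone]

    def depth(self, clone: int) -> int:
        d = 0
        while clone != 0:
            clone = self.parent[clone]
            d += 1
        return d

    def subtree(self, clone: int) -> set[int]:
        out = {clone}
        stack = [clone]
        while stack:
            for ch in self.children(stack.pop()):
                out.add(ch)
                stack.append(ch)
        return out

    def ancestors(self, clone: int) -> list[int]:
        out = []
        c = self.parent[clone]
        while c != 0:
            out.append(c)
            c = self.parent[c]
        return out

    def exclusive_fraction(self) -> pd.DataFrame:
        """Fraction of tumor cells whose most derived clone is each clone."""
        frac = self.phi.copy()
        for clone in self.clones:
            for ch in self.children(clone):
                frac.loc[clone] -= self.phi.loc[ch]
        return frac.clip(lower=0.0)

    def validate(self) -> None:
        for clone, par in self.parent.items():
            if par != 0:
                if (self.phi.loc[clone] > self.phi.loc[par] + 1e-9).any():
                    raise AssertionError(f"phi of clone {clone} exceeds parent")
        for clone in self.clones:
            kids = self.children(clone)
            if kids:
                s = self.phi.loc[kids].sum(axis=0)
                if (s > self.phi.loc[clone] + 1e-9).any():
                    raise AssertionError(f"children of {clone} oversubscribe phi")
        trunk = [c for c, p in self.parent.items() if p == 0]
        for t in trunk:
            if not np.allclose(self.phi.loc[t], 1.0):
                raise AssertionError("truncal clone must have phi 1 everywhere")
        rc = self.relapsing_clone
        if (self.phi.loc[rc, list(RELAPSE_SAMPLES)] < 0.3 - 1e-9).any():
            raise AssertionError("relapsing clone phi < 0.3 in a relapse sample")
        met_pos = (self.phi.loc[rc, list(MET_SAMPLES)] > 0).sum()
        if self.scenario == "shared":
            if met_pos != 1 or self.phi.loc[rc, list(MET_SAMPLES)].max() < 0.15:
                raise AssertionError("shared scenario: relapsing clone must "
                                     "have phi >= 0.15 in exactly one metastasis")
        else:
            if met_pos != 0:
                raise AssertionError("private scenario: relapsing clone must "
                                     "be absent from all metastases")

    def truth_pattern(self) -> str:
        return "shared" if self.scenario == "shared" else "private"


def simulate_clone_tree(n_clones: int, scenario: str, seed: int,
                        muts_per_clone: float = 110.0) -> TrueCloneTree:
    """Simulate a ground-truth clone tree for one patient.

    The first four clones realize the scenario scaffold (truncal clone,
    metastasis-restricted clone, relapsing clone, one sibling); additional
    clones attach at random positions, drawing their prevalences from the
    parent's unallocated headroom so the ISA sum condition holds exactly.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    if n_clones < 4:
        raise ValueError("need n_clones >= 4 to realize a scenario")
    rng = np.random.default_rng(seed)
    samples = list(TUMOR_SAMPLES)
    phi = pd.DataFrame(0.0, index=range(1, n_clones + 1), columns=samples)
    parent: dict[int, int] = {1: 0}
    phi.loc[1] = 1.0  # truncal clone

    # Every relapse is seeded by the relapsing clone alone, so the clone
    # (and every ancestor) is clonal in all relapse samples: phi = 1.
    rc = 3
    if scenario == "shared":
        parent[2] = 1  # metastasis-restricted clone
        phi.loc[2, ["L_A", "L_B"]] = rng.uniform(0.4, 0.8, size=2)
        parent[rc] = 1  # relapsing clone: one metastasis + all relapses
        phi.loc[rc, "L_C"] = rng.uniform(0.55, 0.85)
        phi.loc[rc, list(RELAPSE_SAMPLES)] = 1.0
        parent[4] = rc  # relapse-restricted subclone
        phi.loc[4, list(RELAPSE_SAMPLES)] = rng.uniform(0.3, 0.6, size=3)
    elif scenario == "private_sequential":
        parent[2] = 1  # liver ancestor: all liver samples, not the primary
        a = rng.uniform(0.5, 0.9, size=3)
        phi.loc[2, list(MET_SAMPLES)] = a
        phi.loc[2, list(RELAPSE_SAMPLES)] = 1.0
        parent[rc] = 2  # relapsing clone: relapse-only
        phi.loc[rc, list(RELAPSE_SAMPLES)] = 1.0
        parent[4] = 2  # metastasis-restricted sibling
        phi.loc[4, list(MET_SAMPLES)] = rng.uniform(0.3, 1.0, size=3) * a
    else:  # private_branchoff
        parent[2] = 1  # metastasis lineage
        phi.loc[2, list(MET_SAMPLES)] = rng.uniform(0.4, 0.9, size=3)
        parent[rc] = 1  # relapse lineage, sibling of the metastasis lineage
        phi.loc[rc, list(RELAPSE_SAMPLES)] = 1.0
        parent[4] = 2  # subclone within the metastasis lineage
        phi.loc[4, ["L_A", "L_B"]] = (rng.uniform(0.3, 0.7)
                                      * phi.loc[2, ["L_A", "L_B"]])

    rc_subtree_parents = {rc, 4} if scenario == "shared" else {rc}
    for clone in range(5, n_clones + 1):
        for _ in range(50):
            p = int(rng.choice(sorted(parent)))
            head = phi.loc[p] - phi.loc[[c for c in parent if parent[c] == p]
                                        ].sum(axis=0)
            support = [s for s in samples
                       if head[s] > 0.1 and rng.random() < 0.6]
            in_rc_subtree = p in rc_subtree_parents
            if not in_rc_subtree and set(RELAPSE_SAMPLES) <= set(support):
                support.remove(str(rng.choice(RELAPSE_SAMPLES)))
            if support:
                f = rng.uniform(0.3, 0.7)
                vals = f * head[support]
                vals = vals[vals >= 0.05]
                if len(vals):
                    parent[clone] = p
                    phi.loc[clone, vals.index] = vals
                    if in_rc_subtree:
                        rc_subtree_parents.add(clone)
                    break
        else:  # no headroom anywhere usable: tiny met-restricted clone
            parent[clone] = 1
            phi.loc[clone, "L_A"] = 0.0

    mutations = {}
    for clone in sorted(parent):
        n_mut = max(8, int(rng.poisson(muts_per_clone)))
        mutations[clone] = [f"clone{clone}_m{i}" for i in range(n_mut)]
    spectrum = {clone: ("fivefu" if clone == rc else
                        ("clock_a" if clone % 2 else "clock_b"))
                for clone in parent}
    tree = TrueCloneTree(scenario=scenario, parent=parent, phi=phi,
                         mutations=mutations, spectrum=spectrum,
                         relapsing_clone=rc)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

def expected_vaf(phi: float, purity: float, total_cn: float,
                 multiplicity: float) -> float:
    """xi = rho*m*phi / (rho*CN_t + 2*(1-rho)); must lie in [0, 1]."""
    xi = purity * multiplicity * phi / (purity * total_cn
                                        + 2.0 * (1.0 - purity))
    if xi > 1.0 + 1e-9 or xi < 0.0:
        raise ValueError(
            f"inconsistent phi/multiplicity/copy-number combination: "
            f"expected VAF {xi:.3f} outside [0, 1] "
            f"(phi={phi}, purity={purity}, CN={total_cn}, m={multiplicity})")
    return min(xi, 1.0)


def simulate_reads(phi: float, purity: float, total_cn: int,
                   multiplicity: int, mean_depth: float,
                   seed: int | np.random.Generator) -> tuple[int, int]:
    """Draw (depth, alt) for one mutation in one sample.

    Depth is Poisson around ``mean_depth`` floored at one read; alt reads
    are binomial at the expected VAF.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    xi = expected_vaf(phi, purity, total_cn, multiplicity)
    depth = max(1, int(rng.poisson(mean_depth)))
    alt = int(rng.binomial(depth, xi))
    return depth, alt


# ---------------------------------------------------------------------------
# Copy-number profiles along the tree
# ---------------------------------------------------------------------------

def make_segmentation(n_segments: int, n_chromosomes: int = 5,
                      segment_mb: int = 10) -> pd.DataFrame:
    """Synthetic shared segmentation: columns chrom, start, end (1-based)."""
    if n_segments < 4:
        raise ValueError("need n_segments >= 4")
    per = int(np.ceil(n_segments / n_chromosomes))
    rows = []
    seg = 0
    for c in range(1, n_chromosomes + 1):
        for k in range(per):
            if seg >= n_segments:
                break
            rows.append({"chrom": f"chr{c}",
                         "start": k * segment_mb * 10**6 + 1,
                         "end": (k + 1) * segment_mb * 10**6})
            seg += 1
    return pd.DataFrame(rows)


def _random_event(rng: np.random.Generator, chroms: tuple[str, ...],
                  major: np.ndarray, minor: np.ndarray) -> CNEvent | None:
    chrom_arr = np.asarray(chroms)
    for _ in range(30):
        chrom = str(rng.choice(sorted(set(chroms))))
        idx = np.flatnonzero(chrom_arr == chrom)
        i, j = sorted(rng.choice(idx, size=2, replace=True))
        allele = "major" if rng.random() < 0.5 else "minor"
        direction = "gain" if rng.random() < 0.6 else "loss"
        target = major if allele == "major" else minor
        if (target[i:j + 1] >= 1).all():
            return CNEvent(allele, chrom, int(i), int(j), direction)
    return None


def simulate_cn_profiles(tree: TrueCloneTree, n_segments: int,
                         wgd_on_relapse_branch: bool = False,
                         seed: int = 0, n_chromosomes: int = 5,
                         relapse_gain_chrom: str | None = None
                         ) -> dict[int, CNProfile]:
    """Per-clone allele-specific profiles by inheritance plus branch events.

    Every branch receives 0-3 random segmental +/-1 events; the relapsing
    branch receives at least two, plus a whole-chromosome major-allele gain
    of ``relapse_gain_chrom`` when given (a chromosome-13-like gain) and a
    leading WGD when ``wgd_on_relapse_branch`` is set. Branch event lists
    are recorded in ``tree.branch_events``; replaying them from the root
    reproduces each clone's profile exactly.
    """
    rng = np.random.default_rng(seed)
    segs = make_segmentation(n_segments, n_chromosomes)
    chroms = tuple(segs["chrom"])
    germline = cnphylo.diploid_profile("germline", chroms)
    profiles: dict[int, CNProfile] = {}
    events: dict[int, list[CNEvent]] = {}
    rc = tree.relapsing_clone
    order = sorted(tree.clones, key=tree.depth)
    for clone in order:
        par = tree.parent[clone]
        base = germline if par == 0 else profiles[par]
        branch: list[CNEvent] = []
        major, minor = base.major.copy(), base.minor.copy()
        if clone == rc and wgd_on_relapse_branch:
            branch.append(CNEvent.wgd())
            major, minor = major * 2, minor * 2
        if clone == rc and relapse_gain_chrom is not None:
            idx = np.flatnonzero(np.asarray(chroms) == relapse_gain_chrom)
            if idx.size == 0:
                raise ValueError(f"no such chromosome {relapse_gain_chrom!r}")
            # gain each run of non-deleted segments (zero-copy segments
            # cannot be regained under the event model)
            run: list[int] = []
            for i in [*idx, -1]:
                if i >= 0 and major[i] >= 1:
                    run.append(int(i))
                    continue
                if run:
                    ev = CNEvent("major", relapse_gain_chrom, run[0],
                                 run[-1], "gain")
                    branch.append(ev)
                    major, minor = cnphylo.apply_event(major, minor, chroms,
                                                       ev)
                run = []
        n_events = int(rng.integers(0, 4))
        if clone == rc:
            n_events = max(n_events, 2 - sum(e.direction != "wgd"
                                             for e in branch))
        for _ in range(n_events):
            ev = _random_event(rng, chroms, major, minor)
            if ev is None:
                continue
            branch.append(ev)
            major, minor = cnphylo.apply_event(major, minor, chroms, ev)
        profiles[clone] = CNProfile(f"clone{clone}", chroms, major, minor)
        events[clone] = branch
    tree.profiles = profiles
    tree.branch_events = events
    return profiles


def sample_cn_profiles(tree: TrueCloneTree) -> dict[str, CNProfile]:
    """Observed per-sample profiles: cell-fraction-weighted, rounded.

    Stands in for the rounded clonal copy-number call a tool like Sequenza
    reports for a bulk tumor sample.
    """
    if not tree.profiles:
        raise ValueError("run simulate_cn_profiles first")
    frac = tree.exclusive_fraction()
    chroms = next(iter(tree.profiles.values())).chroms
    n = len(chroms)
    out = {}
    for s in tree.phi.columns:
        wm = np.zeros(n)
        wn = np.zeros(n)
        total = 0.0
        for clone in tree.clones:
            f = float(frac.loc[clone, s])
            if f <= 0:
                continue
            wm += f * tree.profiles[clone].major
            wn += f * tree.profiles[clone].minor
            total += f
        if total <= 0:  # sample without tumor signal: diploid call
            wm, wn, total = np.ones(n), np.ones(n), 1.0
        out[s] = CNProfile(s, chroms,
                           np.rint(wm / total).astype(int),
                           np.rint(wn / total).astype(int))
    return out


# ---------------------------------------------------------------------------
# Signature mixtures
# ---------------------------------------------------------------------------

def simulate_signature_mixture(exposures, catalog: pd.DataFrame,
                               n_mutations: int, seed: int) -> pd.Series:
    """Multinomial SBS-96 counts from a signature mixture."""
    catalog = signatures.validate_catalog(catalog)
    w = pd.Series(exposures, dtype=float).reindex(catalog.columns).fillna(0.0)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("exposure vector is not normalizable")
    w = w / w.sum()
    p = catalog.to_numpy() @ w.to_numpy()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(n_mutations), p) if n_mutations else \
        np.zeros(len(p), dtype=int)
    return pd.Series(counts, index=catalog.index)


# ---------------------------------------------------------------------------
# FFPE artifacts
# ---------------------------------------------------------------------------

def inject_ffpe_artifacts(table: MutationTable, rate: int,
                          seed: int) -> MutationTable:
    """Add primary-only false-positive variants (C>T-enriched contexts).

    ``rate`` artifacts are added per primary sample, each with zero alt
    reads in every non-primary sample and a C>T substitution typical of
    formalin fixation. Truth labels mark them (``is_artifact``).
    """
    if rate < 0:
        raise ValueError("artifact rate must be >= 0")
    primaries = table.primary_samples()
    if not primaries:
        raise ValueError("table has no primary sample")
    if rate == 0:
        return table
    rng = np.random.default_rng(seed)
    muts = table.muts.copy()
    if "is_artifact" not in muts.columns:
        muts["is_artifact"] = False
    mean_depth = table.depth.to_numpy().mean()
    ct_channels = [ch for ch in signatures.SBS96_CHANNELS if "[C>T]" in ch]
    new_rows, new_depth, new_alt = [], [], []
    ids = []
    for p_i, prim in enumerate(primaries):
        for k in range(int(rate)):
            ch = str(rng.choice(ct_channels))
            ctx, ref, alt = signatures.channel_parts(ch)
            mid = f"ffpe_{p_i}_{k}"
            ids.append(mid)
            new_rows.append({
                "chrom": "chr1",
                "pos": int(rng.integers(1, 4 * 10**7)),
                "ref": ref, "alt": alt, "alt_base": alt, "context": ctx,
                "gene": "FFPE", "effect": "silent", "driver": False,
                "clone": -1, "is_artifact": True,
            })
            depth_row, alt_row = [], []
            for s in table.samples:
                d = max(1, int(rng.poisson(mean_depth)))
                if s == prim:
                    vaf = rng.uniform(0.08, 0.25)
                    a = max(int(rng.binomial(d, vaf)),
                            int(np.ceil(0.05 * d)))
                else:
                    a = 0
                depth_row.append(d)
                alt_row.append(a)
            new_depth.append(depth_row)
            new_alt.append(alt_row)
    add = pd.DataFrame(new_rows, index=pd.Index(ids, name="mutation"))
    muts = pd.concat([muts, add])
    muts["is_artifact"] = muts["is_artifact"].fillna(False).astype(bool)
    depth = pd.concat([table.depth, pd.DataFrame(
        new_depth, index=ids, columns=table.samples)])
    alt = pd.concat([table.alt, pd.DataFrame(
        new_alt, index=ids, columns=table.samples)])
    return MutationTable(muts=muts, depth=depth, alt=alt, meta=table.meta)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def build_cms_templates(genes, n_classes: int = 4,
                        markers_per_class: int = 25,
                        seed: int = 0) -> pd.DataFrame:
    """Synthetic CMS-like marker templates (gene, class, weight).

    Disjoint marker sets per class with positive weights; a stand-in shaped
    like published CMS marker templates, not derived from them.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    if n_classes * markers_per_class > len(genes):
        raise ValueError("not enough genes for the requested templates")
    chosen = rng.choice(genes, size=n_classes * markers_per_class,
                        replace=False)
    rows = []
    for k in range(n_classes):
        for g in chosen[k * markers_per_class:(k + 1) * markers_per_class]:
            rows.append({"gene": g, "class": f"CMS{k + 1}",
                         "weight": float(rng.uniform(0.5, 1.5))})
    return pd.DataFrame(rows)


@dataclass
class SimulatedExpression:
    expr: ExpressionMatrix
    templates: pd.DataFrame | None
    shifted_sets: dict[str, dict[str, float]]
    groups: dict[str, str]


def simulate_expression(n_genes: int, groups: dict[str, str],
                        shifted_sets: dict[GeneSet, dict[str, float]] | None,
                        cms_mixture: dict[str, dict[str, float]] | None,
                        seed: int,
                        templates: pd.DataFrame | None = None,
                        template_strength: float = 2.5,
                        noise_sd: float = 1.0) -> SimulatedExpression:
    """Log-scale expression with planted gene-set shifts and CMS mixtures.

    ``shifted_sets`` maps gene sets to per-group shifts in units of the
    within-group standard deviation (= ``noise_sd``); ``cms_mixture`` maps
    samples to per-class template weights. Truth (which sets are shifted,
    the templates) travels in the returned object.
    """
    rng = np.random.default_rng(seed)
    samples = list(groups)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(7.0, 1.5, size=n_genes)
    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes,
                                                            len(samples)))
    df = pd.DataFrame(x, index=gene_ids, columns=samples)
    shifted_truth: dict[str, dict[str, float]] = {}
    for gs, effects in (shifted_sets or {}).items():
        missing = set(gs.genes) - set(gene_ids)
        if missing:
            raise ValueError(f"gene set {gs.name!r} references absent genes: "
                             f"{sorted(missing)[:5]}")
        shifted_truth[gs.name] = dict(effects)
        for s in samples:
            eff = effects.get(groups[s], 0.0)
            if eff:
                df.loc[list(gs.genes), s] += eff * noise_sd
    if cms_mixture is not None:
        if templates is None:
            templates = build_cms_templates(gene_ids, seed=seed)
        tmpl = templates.pivot_table(index="gene", columns="class",
                                     values="weight", fill_value=0.0)
        for s, mix in cms_mixture.items():
            for cls, w in mix.items():
                if cls not in tmpl.columns:
                    raise ValueError(f"unknown template class {cls!r}")
                df.loc[tmpl.index, s] += (w * template_strength
                                          * tmpl[cls].to_numpy())
    expr = ExpressionMatrix(values=df, unit="normalized",
                            normalization_note="simulated log-scale")
    return SimulatedExpression(expr=expr, templates=templates,
                               shifted_sets=shifted_truth, groups=dict(groups))


# ---------------------------------------------------------------------------
# Patient and cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class PatientSim:
    """One synthetic patient: truth tree plus observed data artifacts."""

    patient: str
    scenario: str
    tree: TrueCloneTree
    table: MutationTable
    segments: pd.DataFrame       # long format: sample, chrom, start, end, major, minor
    purity: pd.Series
    seed: int

    def truth_pattern(self) -> str:
        return self.tree.truth_pattern()


def _catalog_channel_draw(rng, catalog, column, size):
    p = catalog[column].to_numpy()
    return rng.choice(catalog.index.to_numpy(), size=size, p=p)


def simulate_patient(patient: str, scenario: str, seed: int,
                     n_clones: int = 5, mean_depth: float = 450.0,
                     liver_purity: tuple[float, float] = (0.4, 0.8),
                     primary_purity: tuple[float, float] = (0.2, 0.5),
                     ffpe_rate: int = 20, n_segments: int = 20,
                     muts_per_clone: float = 110.0,
                     wgd_on_relapse: bool = False,
                     relapse_gain_chrom: str | None = "chr5",
                     include_primary: bool = True,
                     catalog: pd.DataFrame | None = None) -> PatientSim:
    """Simulate one patient end to end (tree, CN, reads, artifacts).

    Defaults mirror the study conditions: ~450x mean depth, liver purities
    uniform on (0.4, 0.8), a low-purity FFPE primary carrying about 20
    artifact calls, five clones over 20 segments, and a whole-chromosome
    major-allele gain on the relapsing branch.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=6)
    catalog = catalog if catalog is not None else signatures.synthetic_catalog()
    tree = simulate_clone_tree(n_clones, scenario, int(sub[0]),
                               muts_per_clone=muts_per_clone)
    simulate_cn_profiles(tree, n_segments, wgd_on_relapse_branch=wgd_on_relapse,
                         seed=int(sub[1]), relapse_gain_chrom=relapse_gain_chrom)
    seg_def = make_segmentation(n_segments)
    chroms = tuple(seg_def["chrom"])
    sample_profiles = sample_cn_profiles(tree)

    tumor_names = [s for s in TUMOR_SAMPLES
                   if include_primary or s != "P_A"]
    full = {s: f"{patient}_{s}" for s in tumor_names}
    normal = f"{patient}_N"
    purity = pd.Series(index=[*full.values(), normal], dtype=float)
    for s in tumor_names:
        lo, hi = primary_purity if s == "P_A" else liver_purity
        purity[full[s]] = rng.uniform(lo, hi)
    purity[normal] = 1.0

    meta = pd.DataFrame({
        "patient": patient,
        "tissue": [("primary" if s == "P_A" else
                    "metastasis" if s.startswith("L_") else "relapse")
                   for s in tumor_names] + ["normal"],
        "purity": purity.to_numpy(),
    }, index=pd.Index([*full.values(), normal], name="sample"))

    # --- mutations -------------------------------------------------------
    rng_m = np.random.default_rng(int(sub[2]))
    rows, ids = [], []
    for clone in tree.clones:
        n_mut = len(tree.mutations[clone])
        segs = rng_m.integers(0, n_segments, size=n_mut)
        channels = _catalog_channel_draw(rng_m, catalog,
                                         tree.spectrum[clone], n_mut)
        # standard timing convention: multiplicity can exceed 1 only when
        # the gain is on the mutation's own branch (a gain on an ancestor
        # branch predates the mutation, which then arises on one copy)
        gained = set()
        for ev in tree.branch_events.get(clone, []):
            if ev.direction == "gain" and ev.allele == "major":
                gained.update(range(ev.start, ev.end + 1))
            if ev.direction == "wgd":
                gained.update(range(n_segments))
        new_ids = []
        for k in range(n_mut):
            seg = int(segs[k])
            ctx, ref, alt = signatures.channel_parts(str(channels[k]))
            pos = (int(seg_def.loc[seg, "start"])
                   + int(rng_m.integers(0, 10**7 - 1)))
            mid = f"{patient}:{seg_def.loc[seg, 'chrom']}:{pos}"
            if mid in set(ids):
                continue
            major_c = int(tree.profiles[clone].major[seg])
            if seg in gained and major_c > 1:
                mult = int(rng_m.integers(1, major_c + 1))
            else:
                mult = 1
            driver_gene = rng_m.random() < 0.04
            gene = (str(rng_m.choice(DRIVER_GENES)) if driver_gene
                    else f"GENE{int(rng_m.integers(0, 2000))}")
            rows.append({
                "chrom": seg_def.loc[seg, "chrom"], "pos": pos,
                "ref": ref, "alt": alt, "alt_base": alt, "context": ctx,
                "gene": gene,
                "effect": "non-silent" if rng_m.random() < 0.75 else "silent",
                "driver": False, "clone": clone, "is_artifact": False,
                "segment": seg, "multiplicity": mult,
            })
            ids.append(mid)
            new_ids.append(mid)
        tree.mutations[clone] = new_ids
    muts = pd.DataFrame(rows, index=pd.Index(ids, name="mutation"))

    # --- read counts -----------------------------------------------------
    rng_r = np.random.default_rng(int(sub[3]))
    depth = pd.DataFrame(0, index=muts.index, columns=meta.index, dtype=int)
    alt = pd.DataFrame(0, index=muts.index, columns=meta.index, dtype=int)
    n = len(muts)
    seg_idx = muts["segment"].to_numpy()
    clone_idx = muts["clone"].to_numpy()
    mult = muts["multiplicity"].to_numpy()
    for s_local, s_full in [*full.items(), (None, normal)]:
        rho = float(purity[s_full])
        d = np.maximum(1, rng_r.poisson(mean_depth, size=n))
        if s_local is None:
            a = np.zeros(n, dtype=int)
        else:
            prof = sample_profiles[s_local]
            cn = prof.total()[seg_idx]
            major_s = prof.major[seg_idx]
            phis = tree.phi.loc[:, s_local]
            phi = phis.reindex(clone_idx).to_numpy()
            m_eff = np.minimum(mult, major_s)
            xi = np.where(
                m_eff > 0,
                rho * m_eff * phi / (rho * cn + 2.0 * (1.0 - rho)),
                0.0)
            if (xi > 1.0 + 1e-9).any() or (xi < 0).any():
                raise AssertionError("expected VAF outside [0,1] in truth")
            a = rng_r.binomial(d, np.clip(xi, 0.0, 1.0))
        depth[s_full] = d
        alt[s_full] = a

    table = MutationTable(muts=muts, depth=depth, alt=alt, meta=meta)
    if include_primary and ffpe_rate > 0:
        table = inject_ffpe_artifacts(table, ffpe_rate, int(sub[4]))

    # --- per-sample segment table ---------------------------------------
    seg_rows = []
    for s_local, s_full in full.items():
        prof = sample_profiles[s_local]
        for i in range(n_segments):
            seg_rows.append({
                "sample": s_full, "chrom": seg_def.loc[i, "chrom"],
                "start": int(seg_def.loc[i, "start"]),
                "end": int(seg_def.loc[i, "end"]),
                "major": int(prof.major[i]), "minor": int(prof.minor[i]),
            })
    segments = pd.DataFrame(seg_rows)
    # phi columns renamed to full sample ids (normal has no tumor cells)
    tree.phi = tree.phi.rename(columns=full)
    return PatientSim(patient=patient, scenario=scenario, tree=tree,
                      table=table, segments=segments, purity=purity,
                      seed=seed)


@dataclass
class CohortTruth:
    patients: list[PatientSim]
    seed: int

    def meta(self) -> pd.DataFrame:
        return pd.concat([p.table.meta for p in self.patients])


def simulate_cohort(n_patients: int = 9, seed: int = 0,
                    scenarios: tuple[str, ...] | None = None,
                    **patient_kwargs) -> CohortTruth:
    """Simulate a cohort, cycling the three seeding scenarios.

    The default nine patients mirror the study design (three per scenario;
    one primary + six liver samples + one normal each).
    """
    scenarios = scenarios or SCENARIOS
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_patients)
    patients = []
    for i in range(n_patients):
        scen = scenarios[i % len(scenarios)]
        patients.append(simulate_patient(f"P{i + 1:02d}", scen,
                                         int(seeds[i]), **patient_kwargs))
    return CohortTruth(patients=patients, seed=seed)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTruth, outdir: str) -> None:
    """Write VCFs, purity table, segments, and a truth bundle (JSON)."""
    import os

    from crcrelapse.variants import write_vcf

    os.makedirs(outdir, exist_ok=True)
    purity_rows, seg_frames, truth = [], [], {}
    for p in cohort.patients:
        write_vcf(p.table, os.path.join(outdir, f"{p.patient}.vcf"))
        for s in p.table.samples:
            purity_rows.append({
                "sample": s, "patient": p.patient,
                "tissue": p.table.meta.loc[s, "tissue"],
                "purity": float(p.table.meta.loc[s, "purity"]),
            })
        seg_frames.append(p.segments)
        truth[p.patient] = {
            "scenario": p.scenario,
            "pattern": p.truth_pattern(),
            "relapsing_clone": p.tree.relapsing_clone,
            "parent": {str(k): v for k, v in p.tree.parent.items()},
            "phi": {str(c): p.tree.phi.loc[c].round(6).to_dict()
                    for c in p.tree.clones},
            "seed": p.seed,
        }
    pd.DataFrame(purity_rows).to_csv(
        os.path.join(outdir, "purity.tsv"), sep="\t", index=False)
    pd.concat(seg_frames).to_csv(
        os.path.join(outdir, "segments.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
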