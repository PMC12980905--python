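"""Per-patient orchestration of the DNA-side analysis.

Chains the published stage order: deconvolution input filter -> CCF
estimation -> prevalence clustering -> cluster retention -> clone-tree
search -> relapsing-clone call and pattern -> parsimony sample tree
cross-validation -> copy-number tree, monophyly test and branch-event
mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crcrelapse import ccf as ccf_mod
from crcrelapse import cnphylo, lineage, variants
from crcrelapse.config import PipelineConfig
from crcrelapse.variants import MutationTable


@dataclass
class PatientResult:
    patient: str
    clusters: "ccf_mod.ClusterPrevalence | None"
    cluster_presence: pd.DataFrame | None
    tree: "lineage.LineageTree | None"
    call: "lineage.RelapseCall | None"
    sample_tree: "lineage.SampleTree | None" = None
    sampletree_compatible: bool | None = None
    cn_tree: object | None = None
    cn_monophyletic: bool | None = None
    cn_branch_events: list | None = None

    @property
    def pattern(self) -> str | None:
        return self.call.pattern if (self.call and self.call.is_call) else None


def _drop_deleted_segments(table: MutationTable,
                           segments: pd.DataFrame) -> MutationTable:
    """Remove mutations on segments with major allele 0 in a tumor sample
    (their CCF is undefined there); mirrors the upstream exclusion of loci
    without usable allele-specific states."""
    major, _ = variants.lookup_segments(table, segments)
    ok = (major[table.tumor_samples()] >= 1).all(axis=1)
    return table.subset(table.muts.index[ok])


def deconvolve_patient(table: MutationTable, segments: pd.DataFrame,
                       config: PipelineConfig | None = None, seed: int = 0,
                       max_clusters: int | None = None,
                       restarts: int | None = None):
    """Filter, estimate CCFs, cluster, merge and retain clusters."""
    config = config or PipelineConfig()
    decon = variants.select_deconvolution_input(table, segments, config)
    decon = _drop_deleted_segments(decon, segments)
    est = ccf_mod.estimate_ccf(decon, segments)
    cp = ccf_mod.cluster_mutations(decon, est, config, seed=seed,
                                   max_clusters=max_clusters,
                                   restarts=restarts)
    cp = ccf_mod.merge_close_clusters(cp, config.cluster_merge_dist)
    retained, presence = ccf_mod.filter_clusters(cp, config)
    return decon, est, retained, presence


def run_patient(table: MutationTable, segments: pd.DataFrame,
                config: PipelineConfig | None = None, seed: int = 0,
                max_clusters: int | None = None, restarts: int | None = None,
                with_sample_tree: bool = True,
                with_cn_tree: bool = False,
                allow_wgd: bool = True) -> PatientResult:
    """Run the clonal-evolution pipeline for one patient's table."""
    config = config or PipelineConfig()
    patient = str(table.meta["patient"].iloc[0])
    decon, est, retained, presence = deconvolve_patient(
        table, segments, config, seed=seed, max_clusters=max_clusters,
        restarts=restarts)
    if retained.k == 0:
        return PatientResult(patient=patient, clusters=retained,
                             cluster_presence=presence, tree=None, call=None)
    dag = lineage.build_constraint_graph(retained.prevalence,
                                         config.tree_epsilon)
    tree = lineage.search_best_tree(dag, retained.prevalence,
                                    config.tree_epsilon)
    call = lineage.identify_relapsing_clone(tree, presence, table.meta)
    result = PatientResult(patient=patient, clusters=retained,
                           cluster_presence=presence, tree=tree, call=call)
    if with_sample_tree and call.is_call:
        st_input = variants.select_sampletree_input(table, segments, config)
        if len(st_input.muts) and len(st_input.tumor_samples()) >= 2:
            pres = variants.call_presence(st_input, config)
            result.sample_tree = lineage.build_sample_tree(pres,
                                                           st_input.meta)
            primaries = tuple(st_input.primary_samples())
            result.sampletree_compatible = lineage.crossvalidate_sampletree(
                call, result.sample_tree, presence, ignore=primaries)
    if with_cn_tree and call.is_call:
        result = _cn_stage(result, table, segments, presence, call, allow_wgd)
    return result


def cn_profiles_from_segments(segments: pd.DataFrame,
                              samples: list[str]) -> list[cnphylo.CNProfile]:
    """Per-sample profiles over the shared segmentation of one patient."""
    first = segments[segments["sample"] == samples[0]].sort_values(
        ["chrom", "start"])
    chroms = tuple(first["chrom"])
    key = first[["chrom", "start", "end"]].reset_index(drop=True)
    profiles = []
    for s in samples:
        seg = segments[segments["sample"] == s].sort_values(["chrom", "start"])
        if not seg[["chrom", "start", "end"]].reset_index(drop=True).equals(key):
            raise ValueError(f"sample {s} is not on the shared segmentation")
        profiles.append(cnphylo.CNProfile(
            s, chroms, seg["major"].to_numpy(), seg["minor"].to_numpy()))
    return profiles


def _cn_stage(result: PatientResult, table: MutationTable,
              segments: pd.DataFrame, presence: pd.DataFrame,
              call: "lineage.RelapseCall", allow_wgd: bool) -> PatientResult:
    """Copy-number tree over the liver samples, rooted at a diploid normal."""
    liver = table.liver_samples()
    profiles = cn_profiles_from_segments(segments, liver)
    normal_id = [s for s in table.samples
                 if table.meta.loc[s, "tissue"] == "normal"][0]
    profiles.append(cnphylo.diploid_profile(normal_id, profiles[0].chroms))
    dist = cnphylo.pairwise_distance_matrix(profiles, allow_wgd=allow_wgd)
    cn_tree = cnphylo.build_cn_tree(dist, normal_id)
    carriers = [s for s in liver if presence.loc[call.relapsing_cluster, s]]
    result.cn_tree = cn_tree
    if carriers:
        mono = cnphylo.check_monophyly(cn_tree, carriers)
        result.cn_monophyletic = mono
        if mono:
            events, _, _ = cnphylo.map_branch_events(
                cn_tree, carriers, profiles, allow_wgd=allow_wgd)
            result.cn_branch_events = events
    return result
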