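"""Pipeline thresholds.

All mutation- and cluster-level thresholds used across the DNA side of the
pipeline live here so that every filter cites a single source of defaults.
"""

from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """Thresholds for variant filtering, clustering and tree building.

    Attributes
    ----------
    presence_vaf : float
        A mutation is present in a sample when VAF >= this and at least
        ``presence_min_alt`` alternative reads support it.
    presence_min_alt : int
        Minimum alt reads for the global presence rule (>= 1).
    decon_min_alt : int
        Clonal-deconvolution input requires *more than* this many alt reads
        in at least one liver (metastasis/relapse) sample (strict >).
    min_depth_all : int
        Minimum depth required in every sample for deconvolution and
        sample-tree input.
    depth_rule_tumor_only : bool
        If True (default) the all-samples depth rule is applied to tumor
        samples only; if False the matched normal must also satisfy it.
    cluster_min_size : int
        Clusters are retained when they carry *more than* this many
        mutations (strict >).
    cluster_max_prev : float
        Clusters are retained when their prevalence reaches at least this
        value in at least one sample.
    cluster_presence : float
        A cluster counts as present in a sample when its prevalence is at
        least this value.
    tree_epsilon : float
        Prevalence slack used in both the ancestry condition and the
        sum (crossing) condition of clone-tree search.
    cluster_merge_dist : float
        Clusters whose prevalence vectors differ by less than this value
        (max-norm) are merged before filtering.
    max_clusters : int
        Upper bound on the number of mutation clusters considered.
    restarts : int
        Random restarts of the mixture-model fit.
    signature_cap : int
        Maximum number of signatures attributed per sample.
    fdr_level : float
        Benjamini-Hochberg false-discovery-rate level for gene-set and
        CMS calls.
    """

    presence_vaf: float = 0.05
    presence_min_alt: int = 1
    decon_min_alt: int = 5
    min_depth_all: int = 100
    depth_rule_tumor_only: bool = True
    cluster_min_size: int = 5
    cluster_max_prev: float = 0.2
    cluster_presence: float = 0.1
    tree_epsilon: float = 0.25
    cluster_merge_dist: float = 0.1
    max_clusters: int = 15
    restarts: int = 100
    signature_cap: int = 10
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.presence_vaf < 1:
            raise ValueError("presence_vaf must be in (0, 1)")
        if self.presence_min_alt < 1:
            raise ValueError("presence_min_alt must be >= 1")
        if self.min_depth_all < 0:
            raise ValueError("min_depth_all must be >= 0")
        if not 0 <= self.cluster_presence <= self.cluster_max_prev <= 1:
            raise ValueError("need 0 <= cluster_presence <= cluster_max_prev <= 1")
        if not 0 <= self.tree_epsilon <= 1:
            raise ValueError("tree_epsilon must be in [0, 1]")
        if self.max_clusters < 1 or self.restarts < 1:
            raise ValueError("max_clusters and restarts must be >= 1")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
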