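"""Multi-sample somatic mutation tables and the mutation-level filtering rules.

The central container is :class:`MutationTable`: per-mutation annotations
plus per-(mutation, sample) depth and alt-read counts, joined to sample
metadata (patient, tissue class, purity). All presence, input-selection and
categorization rules of the DNA analysis operate on this container:

* presence: VAF >= 0.05 and at least one alternative read;
* clonal-deconvolution input: > 5 alt reads in >= 1 liver sample, depth >=
  100 in all samples, not primary-only, allele-specific copy number
  available in every tumor sample;
* sample-tree input: max VAF >= 0.05, depth >= 100 everywhere, not
  primary-only, not in a copy-number-loss region (total CN < 2) in any
  sample;
* mutation categories over the six liver samples: public / private to the
  metastasis / private to the relapse / shared;
* driver flagging: non-silent mutations in a driver-gene compendium;
* fusion-candidate downstream filter: high confidence, > 1 split read for
  both mates, >= 1 discordant mate pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from crcrelapse.config import PipelineConfig

TISSUES = ("primary", "metastasis", "relapse", "normal")
LIVER_TISSUES = ("metastasis", "relapse")


def _validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    required = {"patient", "tissue", "purity"}
    if missing := required - set(meta.columns):
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    bad = set(meta["tissue"]) - set(TISSUES)
    if bad:
        raise ValueError(f"unknown tissue classes: {sorted(bad)}")
    n_normal = meta[meta.tissue == "normal"].groupby("patient").size()
    for patient, n in n_normal.items():
        if n != 1:
            raise ValueError(f"patient {patient!r} has {n} normal samples, expected 1")
    return meta


@dataclass
class MutationTable:
    """Per-mutation annotations with per-sample read counts.

    Parameters
    ----------
    muts : DataFrame indexed by mutation id with columns
        chrom, pos (1-based), ref, alt, gene, effect ('silent'/'non-silent'),
        driver (bool); optional extra truth columns pass through untouched.
    depth, alt : DataFrames (mutation x sample) of total and alt read counts.
    meta : DataFrame indexed by sample id with columns patient, tissue, purity.
    """

    muts: pd.DataFrame
    depth: pd.DataFrame
    alt: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = _validate_meta(self.meta)
        if not self.muts.index.is_unique:
            raise ValueError("mutation ids must be unique")
        if list(self.depth.columns) != list(self.alt.columns):
            raise ValueError("depth and alt must share sample columns")
        missing = set(self.depth.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        if ((self.alt.to_numpy() > self.depth.to_numpy()).any()
                or (self.alt.to_numpy() < 0).any()):
            raise ValueError("need 0 <= alt <= depth everywhere")

    @property
    def samples(self) -> list[str]:
        return list(self.depth.columns)

    def tumor_samples(self) -> list[str]:
        return [s for s in self.samples if self.meta.loc[s, "tissue"] != "normal"]

    def liver_samples(self) -> list[str]:
        return [s for s in self.samples
                if self.meta.loc[s, "tissue"] in LIVER_TISSUES]

    def primary_samples(self) -> list[str]:
        return [s for s in self.samples if self.meta.loc[s, "tissue"] == "primary"]

    def vaf(self) -> pd.DataFrame:
        """VAF = alt/depth; entries with depth 0 are set to 0 (absent)."""
        d = self.depth.to_numpy(dtype=float)
        a = self.alt.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(d > 0, a / np.where(d > 0, d, 1.0), 0.0)
        return pd.DataFrame(v, index=self.depth.index, columns=self.depth.columns)

    def subset(self, mutation_ids) -> "MutationTable":
        return replace(
            self,
            muts=self.muts.loc[mutation_ids],
            depth=self.depth.loc[mutation_ids],
            alt=self.alt.loc[mutation_ids],
        )


@dataclass
class FusionCandidate:
    gene_pair: str
    confidence: str
    split_reads1: int
    split_reads2: int
    discordant_mates: int

    def __post_init__(self) -> None:
        if min(self.split_reads1, self.split_reads2, self.discordant_mates) < 0:
            raise ValueError("read counts must be >= 0")


# ---------------------------------------------------------------------------
# VCF I/O (pysam; per-sample AD and DP FORMAT fields)
# ---------------------------------------------------------------------------

def write_vcf(table: MutationTable, path: str) -> None:
    """Write the table as an uncompressed multi-sample VCF with AD/DP."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(table.muts["chrom"]):
        header.contigs.add(str(chrom), length=500_000_000)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.info.add("GENE", "1", "String", "Gene symbol")
    header.info.add("EFF", "1", "String", "Effect class")
    for s in table.samples:
        header.add_sample(s)
    order = table.muts.sort_values(["chrom", "pos"]).index
    with pysam.VariantFile(path, "w", header=header) as vf:
        for mid in order:
            row = table.muts.loc[mid]
            rec = vf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])), id=str(mid),
            )
            rec.info["GENE"] = str(row.get("gene", "."))
            rec.info["EFF"] = str(row.get("effect", "."))
            for s in table.samples:
                dp = int(table.depth.at[mid, s])
                ad = int(table.alt.at[mid, s])
                rec.samples[s]["AD"] = (dp - ad, ad)
                rec.samples[s]["DP"] = dp
            vf.write(rec)


def read_vcf(path: str, meta: pd.DataFrame) -> MutationTable:
    """Read a multi-sample VCF with per-sample AD (and optionally DP).

    Raises ValueError when the AD FORMAT field is missing or when a VCF
    sample is absent from ``meta``.
    """
    with pysam.VariantFile(path) as vf:
        if "AD" not in vf.header.formats:
            raise ValueError(f"{path}: VCF lacks the AD FORMAT field")
        samples = list(vf.header.samples)
        missing = set(samples) - set(meta.index)
        if missing:
            raise ValueError(f"VCF samples absent from metadata: {sorted(missing)}")
        rows, depth_rows, alt_rows, ids = [], [], [], []
        for rec in vf:
            mid = rec.id or f"{rec.contig}:{rec.pos}:{rec.alleles[1]}"
            ids.append(mid)
            rows.append({
                "chrom": rec.contig, "pos": rec.pos,
                "ref": rec.alleles[0], "alt": rec.alleles[1],
                "gene": rec.info.get("GENE", "."),
                "effect": rec.info.get("EFF", "."),
            })
            d, a = [], []
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    raise ValueError(f"{path}: missing AD for {mid}/{s}")
                dp = rec.samples[s].get("DP")
                total = int(dp) if dp is not None else int(sum(x or 0 for x in ad))
                d.append(total)
                a.append(int(ad[1] or 0))
            depth_rows.append(d)
            alt_rows.append(a)
    muts = pd.DataFrame(rows, index=pd.Index(ids, name="mutation"))
    muts["driver"] = False
    depth = pd.DataFrame(depth_rows, index=muts.index, columns=samples, dtype=int)
    alt = pd.DataFrame(alt_rows, index=muts.index, columns=samples, dtype=int)
    return MutationTable(muts=muts, depth=depth, alt=alt,
                         meta=meta.loc[samples].copy())


# ---------------------------------------------------------------------------
# Segment lookup
# ---------------------------------------------------------------------------

def lookup_segments(table: MutationTable, segments: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each (mutation, sample) to its covering allele-specific segment.

    ``segments`` has columns sample, chrom, start, end (1-based inclusive),
    major, minor. Returns (major, minor) DataFrames aligned to the table's
    read-count matrices, NaN where no segment covers the locus.
    """
    idx, cols = table.muts.index, table.samples
    major = pd.DataFrame(np.nan, index=idx, columns=cols)
    minor = pd.DataFrame(np.nan, index=idx, columns=cols)
    for (sample, chrom), seg in segments.groupby(["sample", "chrom"], sort=False):
        if sample not in set(cols):
            continue
        sel = table.muts["chrom"] == chrom
        if not sel.any():
            continue
        seg = seg.sort_values("start")
        pos = table.muts.loc[sel, "pos"].to_numpy()
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos <= ends[np.clip(j, 0, len(ends) - 1)])
        mids = table.muts.index[sel]
        major.loc[mids[ok], sample] = seg["major"].to_numpy()[j[ok]]
        minor.loc[mids[ok], sample] = seg["minor"].to_numpy()[j[ok]]
    return major, minor


# ---------------------------------------------------------------------------
# Presence and input-selection rules
# ---------------------------------------------------------------------------

def call_presence(table: MutationTable,
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """Boolean presence matrix: VAF >= threshold and alt >= min alt reads."""
    config = config or PipelineConfig()
    vaf = table.vaf().to_numpy()
    alt = table.alt.to_numpy()
    present = (vaf >= config.presence_vaf) & (alt >= config.presence_min_alt)
    return pd.DataFrame(present, index=table.depth.index,
                        columns=table.depth.columns)


def _depth_rule_samples(table: MutationTable, config: PipelineConfig) -> list[str]:
    return table.tumor_samples() if config.depth_rule_tumor_only else table.samples


def _primary_only(table: MutationTable, config: PipelineConfig) -> pd.Series:
    """Mutations present in >= 1 primary sample and no liver sample."""
    presence = call_presence(table, config)
    prim = table.primary_samples()
    liver = table.liver_samples()
    if not prim:
        return pd.Series(False, index=table.muts.index)
    in_prim = presence[prim].any(axis=1)
    in_liver = presence[liver].any(axis=1) if liver else False
    return in_prim & ~in_liver


def select_deconvolution_input(table: MutationTable, segments: pd.DataFrame,
                               config: PipelineConfig | None = None
                               ) -> MutationTable:
    """Input filter for clonal deconvolution.

    Keeps mutations supported by more than ``decon_min_alt`` alt reads in at
    least one liver sample, with depth >= ``min_depth_all`` in all (tumor)
    samples, not found exclusively in the primary samples, and covered by an
    allele-specific copy-number segment in every tumor sample.
    """
    config = config or PipelineConfig()
    liver = table.liver_samples()
    if not liver:
        raise ValueError("table contains no metastasis/relapse samples")
    keep = (table.alt[liver] > config.decon_min_alt).any(axis=1)
    keep &= (table.depth[_depth_rule_samples(table, config)]
             >= config.min_depth_all).all(axis=1)
    keep &= ~_primary_only(table, config)
    major, _ = lookup_segments(table, segments)
    keep &= major[table.tumor_samples()].notna().all(axis=1)
    return table.subset(table.muts.index[keep])


def select_sampletree_input(table: MutationTable, segments: pd.DataFrame,
                            config: PipelineConfig | None = None
                            ) -> MutationTable:
    """Input filter for parsimony sample trees.

    Keeps mutations with max VAF >= the presence threshold, depth >=
    ``min_depth_all`` everywhere, not primary-only, and not overlapping a
    segment with total copy number below 2 in any tumor sample.
    """
    config = config or PipelineConfig()
    if not table.liver_samples():
        raise ValueError("table contains no metastasis/relapse samples")
    keep = (table.vaf() >= config.presence_vaf).any(axis=1)
    keep &= (table.depth[_depth_rule_samples(table, config)]
             >= config.min_depth_all).all(axis=1)
    keep &= ~_primary_only(table, config)
    major, minor = lookup_segments(table, segments)
    total = major[table.tumor_samples()] + minor[table.tumor_samples()]
    keep &= ~(total < 2).any(axis=1)
    return table.subset(table.muts.index[keep])


# ---------------------------------------------------------------------------
# Categories, drivers, fusions
# ---------------------------------------------------------------------------

def classify_mutation_categories(presence: pd.DataFrame,
                                 meta: pd.DataFrame) -> pd.Series:
    """Label each mutation over one patient's liver samples.

    ``public`` = present in all liver samples; ``met_private`` = only in
    metastasis sample(s); ``relapse_private`` = only in relapse sample(s);
    ``shared`` = in at least one of each but not all. Mutations absent from
    every liver sample get the empty label ''. Primary/normal columns are
    ignored. The four labels partition the classified mutations.
    """
    tissue = meta.loc[presence.columns, "tissue"]
    met = presence.columns[tissue == "metastasis"]
    rel = presence.columns[tissue == "relapse"]
    if len(met) + len(rel) == 0:
        raise ValueError("patient has no liver samples")
    in_met = presence[met].any(axis=1) if len(met) else pd.Series(False, presence.index)
    in_rel = presence[rel].any(axis=1) if len(rel) else pd.Series(False, presence.index)
    all_liver = presence[list(met) + list(rel)].all(axis=1)
    label = pd.Series("", index=presence.index, dtype=object)
    label[in_met & ~in_rel] = "met_private"
    label[in_rel & ~in_met] = "relapse_private"
    label[in_met & in_rel] = "shared"
    label[all_liver] = "public"
    return label


def flag_drivers(table: MutationTable, driver_genes) -> MutationTable:
    """Flag non-silent mutations in the driver-gene compendium."""
    genes = {g.strip() for g in driver_genes if str(g).strip()}
    if not genes:
        import warnings
        warnings.warn("empty driver-gene list: no mutation flagged", stacklevel=2)
    muts = table.muts.copy()
    muts["driver"] = muts["gene"].isin(genes) & (muts["effect"] == "non-silent")
    return replace(table, muts=muts)


def load_driver_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def filter_fusion_candidates(candidates: list[FusionCandidate]
                             ) -> list[FusionCandidate]:
    """Downstream fusion filter: high confidence, > 1 split read for both
    mates, and at least one discordant supporting read pair."""
    return [c for c in candidates
            if c.confidence == "high"
            and c.split_reads1 > 1 and c.split_reads2 > 1
            and c.discordant_mates >= 1]
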