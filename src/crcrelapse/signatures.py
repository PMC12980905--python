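"""SBS-96 mutational spectra: counting and catalog refitting.

Single-base substitutions are binned into the 96 pyrimidine-centered
trinucleotide channels (six substitution classes x 16 flanking contexts).
Per-sample spectra are refit against a signature catalog by nonnegative
least squares, with a pruning loop that zeroes signatures contributing less
than a minimum fraction of the total exposure. The refit is verified
against the Karush-Kuhn-Tucker conditions: at the optimum the gradient of
the residual must vanish on active signatures and be nonnegative on
signatures at zero.

Presence of a mutation in a sample, for spectrum counting, uses the
stricter rule VAF >= 0.05 AND more than one alternative read (the global
presence rule requires only one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
#: Fixed channel order (pyrimidine-centered), substitution-major as in the
#: standard COSMIC catalog layout.
SBS96_CHANNELS = tuple(
    f"{f}[{sub}]{t}" for sub in SUBSTITUTIONS for f in BASES for t in BASES
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_for(context: str, ref: str, alt: str) -> str:
    """Map a trinucleotide context and substitution to its SBS-96 channel.

    ``context`` is the reference trinucleotide centered on the mutated base.
    Purine-centered substitutions are mapped to the reverse-complement
    (pyrimidine-centered) channel.
    """
    context, ref, alt = context.upper(), ref.upper(), alt.upper()
    if len(context) != 3 or context[1] != ref or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"malformed context/alleles: {context} {ref}>{alt}")
    if any(b not in BASES for b in context + alt):
        raise ValueError(f"non-ACGT base in context/alleles: {context} {ref}>{alt}")
    if ref in "AG":  # purine-centered: flip strand
        context, ref, alt = _revcomp(context), _revcomp(ref), _revcomp(alt)
    ch = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if ch not in _CHANNEL_INDEX:
        raise ValueError(f"not a substitution channel: {ch}")
    return ch


_CHANNEL_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def channel_parts(channel: str) -> tuple[str, str, str]:
    """Return (context, ref, alt) for a pyrimidine-centered channel."""
    f, rest = channel[0], channel[2:]
    ref, alt, t = rest[0], rest[2], rest[4]
    return f + ref + t, ref, alt


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def signature_presence(table) -> pd.DataFrame:
    """Presence rule for spectrum counting: VAF >= 0.05 and alt > 1."""
    vaf = table.vaf()
    return (vaf >= 0.05) & (table.alt > 1)


def count_sbs96(muts: pd.DataFrame, presence: pd.DataFrame) -> pd.DataFrame:
    """Per-sample SBS-96 spectra.

    ``muts`` must carry ``context``, ``ref`` and ``alt_base`` columns;
    only single-base substitutions are counted (indels are skipped).
    ``presence`` is a boolean (mutation x sample) matrix; a mutation adds
    one count to its channel in every sample where it is present.
    """
    counts = pd.DataFrame(0, index=list(SBS96_CHANNELS),
                          columns=presence.columns, dtype=int)
    snv = muts.index[(muts["ref"].str.len() == 1)
                     & (muts["alt_base"].str.len() == 1)]
    channels = {
        mid: channel_for(muts.at[mid, "context"], muts.at[mid, "ref"],
                         muts.at[mid, "alt_base"])
        for mid in snv
    }
    for s in presence.columns:
        present = presence.loc[snv, s]
        for mid in snv[present.to_numpy()]:
            counts.at[channels[mid], s] += 1
    return counts


# ---------------------------------------------------------------------------
# Catalog I/O and the bundled synthetic catalog
# ---------------------------------------------------------------------------

def read_catalog(path: str) -> pd.DataFrame:
    """Read a COSMIC-format tab-delimited catalog (Type column + signatures)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = None
    cat = df.reindex(list(SBS96_CHANNELS))
    if cat.isna().any().any():
        raise ValueError(f"{path}: catalog does not cover all 96 channels")
    return validate_catalog(cat)


def write_catalog(catalog: pd.DataFrame, path: str) -> None:
    out = catalog.copy()
    out.index.name = "Type"
    out.to_csv(path, sep="\t")


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    if list(catalog.index) != list(SBS96_CHANNELS):
        catalog = catalog.reindex(list(SBS96_CHANNELS))
    sums = catalog.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("catalog columns must each sum to 1")
    if (catalog.to_numpy() < 0).any():
        raise ValueError("catalog entries must be nonnegative")
    return catalog


def synthetic_catalog() -> pd.DataFrame:
    """A small fixed four-signature catalog for simulation and tests.

    Synthetic signature shapes (not COSMIC estimates):

    * ``clock_a`` - deamination-like, C>T concentrated at NpCpG;
    * ``clock_b`` - broad, mildly tilted background;
    * ``fivefu``  - fluorouracil/ROS-like, T>G (and some T>A) at NpTpT;
    * ``flat``    - uniform.
    """
    n = len(SBS96_CHANNELS)
    cat = pd.DataFrame(0.0, index=list(SBS96_CHANNELS),
                       columns=["clock_a", "clock_b", "fivefu", "flat"])
    for ch in SBS96_CHANNELS:
        ctx, ref, alt = channel_parts(ch)
        sub = f"{ref}>{alt}"
        # clock_a: 80% on C>T at NpCpG, 15% on other C>T, 5% background
        if sub == "C>T" and ctx[2] == "G":
            cat.at[ch, "clock_a"] = 0.80 / 4
        elif sub == "C>T":
            cat.at[ch, "clock_a"] = 0.15 / 12
        else:
            cat.at[ch, "clock_a"] = 0.05 / 80
        # fivefu: 70% on T>G at NpTpT, 20% on T>A at NpTpT, 10% background
        if sub == "T>G" and ctx[2] == "T":
            cat.at[ch, "fivefu"] = 0.70 / 4
        elif sub == "T>A" and ctx[2] == "T":
            cat.at[ch, "fivefu"] = 0.20 / 4
        else:
            cat.at[ch, "fivefu"] = 0.10 / 88
        cat.at[ch, "flat"] = 1.0 / n
    # clock_b: deterministic mild tilt, normalized below
    idx = np.arange(n)
    cat["clock_b"] = 1.0 + 0.6 * np.cos(2 * np.pi * idx / 19.0)
    cat["clock_b"] /= cat["clock_b"].sum()
    return validate_catalog(cat)


# ---------------------------------------------------------------------------
# Refitting
# ---------------------------------------------------------------------------

@dataclass
class SignatureExposure:
    """NNLS exposures of one spectrum against a catalog.

    ``exposures`` is on the mutation-count scale; ``pruned`` lists
    signatures zeroed by the minimum-fraction pruning loop.
    """

    exposures: pd.Series
    residual: float
    pruned: tuple[str, ...] = ()

    def fractions(self) -> pd.Series:
        total = self.exposures.sum()
        if total == 0:
            return self.exposures * 0.0
        return self.exposures / total


def kkt_satisfied(counts: np.ndarray, catalog: np.ndarray, w: np.ndarray,
                  tol: float = 1e-6) -> bool:
    """KKT conditions for min ||counts - catalog @ w||^2 s.t. w >= 0.

    The gradient g = 2 A^T (A w - b) must be ~0 where w > 0 and >= 0
    where w = 0 (scaled tolerance).
    """
    g = 2.0 * catalog.T @ (catalog @ w - counts)
    scale = max(1.0, float(np.abs(counts).sum()))
    active = w > tol * scale
    return bool(np.all(np.abs(g[active]) <= tol * scale * 10)
                and np.all(g[~active] >= -tol * scale * 10))


def refit_exposures(counts, catalog: pd.DataFrame,
                    min_fraction: float = 0.05) -> SignatureExposure:
    """Refit a 96-channel spectrum against a catalog by NNLS with pruning.

    Signatures whose exposure is below ``min_fraction`` of the total are
    zeroed and the remaining set refit, until all retained signatures clear
    the threshold (or none remain). The final solution is KKT-verified on
    its support.
    """
    catalog = validate_catalog(catalog)
    b = np.asarray(counts, dtype=float).ravel()
    if b.shape[0] != len(SBS96_CHANNELS):
        raise ValueError("counts must have 96 channels")
    if (b < 0).any():
        raise ValueError("counts must be nonnegative")
    names = list(catalog.columns)
    active = list(names)
    w_full = pd.Series(0.0, index=names)
    while active:
        A = catalog[active].to_numpy()
        w, rnorm = nnls(A, b)
        if not kkt_satisfied(b, A, w):  # pragma: no cover - solver guarantee
            raise RuntimeError("NNLS solution failed KKT verification")
        total = w.sum()
        if total == 0:
            w_full[:] = 0.0
            break
        low = [name for name, wi in zip(active, w) if wi < min_fraction * total]
        w_full[:] = 0.0
        w_full[active] = w
        if not low:
            break
        active = [name for name in active if name not in low]
    pruned = tuple(name for name in names if name not in active)
    resid = float(np.linalg.norm(catalog.to_numpy() @ w_full.to_numpy() - b))
    return SignatureExposure(exposures=w_full, residual=resid, pruned=pruned)


def detect_signature_presence(exposures: pd.DataFrame | SignatureExposure,
                              min_fraction: float = 0.05):
    """Presence flags: exposure fraction >= ``min_fraction``.

    Accepts either a single :class:`SignatureExposure` (returns a boolean
    Series) or a (signature x sample) exposure DataFrame (returns a boolean
    DataFrame of the same shape).
    """
    if isinstance(exposures, SignatureExposure):
        return exposures.fractions() >= min_fraction
    totals = exposures.sum(axis=0)
    frac = exposures / totals.where(totals > 0, 1.0)
    return frac >= min_fraction


def refit_samples(counts: pd.DataFrame, catalog: pd.DataFrame,
                  min_fraction: float = 0.05) -> pd.DataFrame:
    """Refit every sample column of a (channel x sample) count matrix."""
    out = {}
    for s in counts.columns:
        out[s] = refit_exposures(counts[s].to_numpy(), catalog,
                                 min_fraction).exposures
    return pd.DataFrame(out)


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))
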