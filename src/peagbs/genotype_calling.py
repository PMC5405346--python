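"""Genotype calling from allele read depths with fraction thresholds.

GBS read depths are too shallow for likelihood-based callers to add much in a
mostly inbred panel, so calls are made from the fraction ``f`` of reads
carrying the "alternate" (less-sequenced) allele at a cell:

* ``f < hom_max``                -> homozygous for the cell's majority allele,
* ``hom_max <= f < het_min``     -> missing (ambiguous),
* ``f >= het_min``               -> heterozygous,

with defaults ``hom_max = 0.05`` and ``het_min = 0.10``.  Zero-depth cells are
missing before any fraction is computed.  The interval boundaries are
half-open: the exact 5% point is ambiguous, the exact 10% point heterozygous.

By default "alternate" means the less-sequenced allele *within each cell*; a
``global-minor`` mode instead anchors the fraction to the locus-wise minor
allele (by total reads) with symmetric bands.  Both are exposed because the
convention is a genuine degree of freedom in depth-threshold callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    AlleleDepthMatrix,
    GenotypeMatrix,
)

HOM = "HOM"
HET_CALL = "HET"
MISSING_CALL = "MISSING"


@dataclass(frozen=True)
class CallThresholds:
    """Fraction thresholds for the three-way call rule."""

    hom_max: float = 0.05
    het_min: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.hom_max <= self.het_min < 1:
            raise ValueError(
                f"need 0 < hom_max <= het_min < 1, got "
                f"hom_max={self.hom_max}, het_min={self.het_min}"
            )


def call_genotype(
    depth_major: int, depth_alt: int, t: CallThresholds = CallThresholds()
) -> str:
    """Call a single cell from its two allele depths.

    Returns ``"HOM"`` (of the cell's majority allele), ``"HET"`` or
    ``"MISSING"``.  The alternate fraction is computed from the less-sequenced
    allele, so the result is symmetric in the two arguments.
    """
    if depth_major < 0 or depth_alt < 0:
        raise ValueError("read depths must be non-negative")
    total = depth_major + depth_alt
    if total == 0:
        return MISSING_CALL
    f = min(depth_major, depth_alt) / total
    if f < t.hom_max:
        return HOM
    if f < t.het_min:
        return MISSING_CALL
    return HET_CALL


def call_matrix(
    adm: AlleleDepthMatrix,
    t: CallThresholds = CallThresholds(),
    mode: str = "per-cell",
) -> GenotypeMatrix:
    """Call every cell of a depth matrix and attach per-locus statistics.

    Homozygous calls are resolved to allele A or allele B by which allele
    carries the cell's reads.  ``mode="global-minor"`` instead measures the
    fraction of the locus-wise minor allele (by summed reads) in each cell,
    with symmetric bands around both homozygous states.
    """
    a, b = adm.depth_a, adm.depth_b
    total = a + b
    covered = total > 0
    safe_total = np.maximum(total, 1)
    calls = np.full(a.shape, MISSING, dtype=np.int8)

    if mode == "per-cell":
        f = np.minimum(a, b) / safe_total
        hom = covered & (f < t.hom_max)
        calls[hom & (a >= b)] = HOM_A
        calls[hom & (b > a)] = HOM_B
        calls[covered & (f >= t.het_min)] = HET
    elif mode == "global-minor":
        minor_is_b = b.sum(axis=1) <= a.sum(axis=1)
        minor_depth = np.where(minor_is_b[:, None], b, a)
        f = minor_depth / safe_total
        hom_major = covered & (f < t.hom_max)
        hom_minor = covered & (f > 1 - t.hom_max)
        het = covered & (f >= t.het_min) & (f <= 1 - t.het_min)
        maj_code = np.broadcast_to(
            np.where(minor_is_b, HOM_A, HOM_B)[:, None], a.shape
        )
        min_code = np.broadcast_to(
            np.where(minor_is_b, HOM_B, HOM_A)[:, None], a.shape
        )
        calls[hom_major] = maj_code[hom_major]
        calls[hom_minor] = min_code[hom_minor]
        calls[het] = HET
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_cov = covered.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(
            n_cov > 0, total.sum(axis=1) / np.maximum(n_cov, 1), np.nan
        )
    return GenotypeMatrix(adm.loci, adm.accessions, calls, mean_depth)


@dataclass
class DepthSummary:
    """Per-SNP depth/missingness statistics and depth-stratified SNP counts."""

    per_snp: pd.DataFrame  # index locus; columns mean_depth, pct_missing
    min_depth: int
    n_snps: int
    n_snps_at_min_depth: int
    avg_depth: float
    avg_pct_missing: float
    avg_depth_at_min_depth: float
    avg_pct_missing_at_min_depth: float

    def to_frame(self) -> pd.DataFrame:
        """Two-row summary: all SNPs and the depth >= ``min_depth`` stratum."""
        return pd.DataFrame(
            {
                "snp_count": [self.n_snps, self.n_snps_at_min_depth],
                "avg_read_depth": [self.avg_depth, self.avg_depth_at_min_depth],
                "avg_pct_missing": [
                    self.avg_pct_missing,
                    self.avg_pct_missing_at_min_depth,
                ],
            },
            index=["all_markers", f"read_depth_ge_{self.min_depth}"],
        )


def depth_summary(
    adm: AlleleDepthMatrix,
    gm: GenotypeMatrix,
    min_depth: int = 5,
    criterion: str = "per-cell",
) -> DepthSummary:
    """Summarize read depth and missingness per SNP.

    ``criterion`` controls what "read depth >= d" means for a SNP:
    ``per-cell`` (default) requires every cell with a non-missing genotype to
    have total depth >= d; ``mean`` requires the SNP's mean covered depth
    >= d.  Mean depth is taken over covered (depth > 0) cells.
    """
    if adm.loci != gm.loci or adm.accessions != gm.accessions:
        raise ValueError("depth matrix and genotype matrix are not aligned")
    total = adm.total_depth()
    covered = total > 0
    n_cov = covered.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(
            n_cov > 0, total.sum(axis=1) / np.maximum(n_cov, 1), np.nan
        )
    pct_missing = (gm.calls == MISSING).mean(axis=1) * 100.0

    called = gm.calls != MISSING
    if criterion == "per-cell":
        masked = np.where(called, total, np.iinfo(np.int64).max)
        min_called_depth = masked.min(axis=1)
        at_depth = called.any(axis=1) & (min_called_depth >= min_depth)
    elif criterion == "mean":
        at_depth = ~np.isnan(mean_depth) & (mean_depth >= min_depth)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    per_snp = pd.DataFrame(
        {"mean_depth": mean_depth, "pct_missing": pct_missing}, index=gm.loci
    )
    sub = per_snp[at_depth]
    return DepthSummary(
        per_snp=per_snp,
        min_depth=min_depth,
        n_snps=gm.n_loci,
        n_snps_at_min_depth=int(at_depth.sum()),
        avg_depth=float(np.nanmean(mean_depth)) if gm.n_loci else float("nan"),
        avg_pct_missing=float(pct_missing.mean()) if gm.n_loci else float("nan"),
        avg_depth_at_min_depth=(
            float(sub["mean_depth"].mean()) if len(sub) else float("nan")
        ),
        avg_pct_missing_at_min_depth=(
            float(sub["pct_missing"].mean()) if len(sub) else float("nan")
        ),
    )
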