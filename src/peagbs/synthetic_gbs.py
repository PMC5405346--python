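"""Synthetic GBS collections with known truth.

Emulates the statistical regime of a large, mostly inbred germplasm
collection genotyped at shallow depth: a few hundred accessions in 4-6
genetic groups whose allele frequencies diverge around a shared ancestral
frequency (Balding-Nichols Beta draws), residual heterozygosity well below
1%, locus-specific negative-binomial read depth with mean ~4 and a heavy
right tail, tag dropout, per-read base miscalls, two partially overlapping
SNP catalogs and a binary trait controlled by one major locus.

With the defaults (mean depth 4, dispersion 0.5, tag dropout 0.2) roughly
47% of genotypes end up missing after depth-threshold calling: 20% dropout
plus the ~33% zero mass of NB(4, 0.5) on the surviving cells, plus a small
ambiguous-fraction contribution.

All randomness flows from a single seed through named per-stage streams, so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    STACKS,
    STACKS_TAG_LENGTH,
    UNEAK,
    UNEAK_TAG_LENGTH,
    AlleleDepthMatrix,
    GenotypeMatrix,
    GroupTable,
    TagCatalog,
    TagRecord,
)

_STREAMS = {
    "population": 0,
    "depths": 1,
    "catalogs": 2,
    "trait": 3,
    "mask": 4,
}

_BASES = np.array(list("ACGT"))


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulated collection.

    ``accessions_per_group`` may be one integer (equal group sizes) or one
    count per group.  ``divergence`` is the Balding-Nichols F-like parameter
    spreading group allele frequencies around the ancestral frequency.
    """

    n_groups: int = 5
    accessions_per_group: int | tuple[int, ...] = 86
    n_loci: int = 3000
    divergence: float = 0.15
    residual_het_rate: float = 0.005
    mean_depth: float = 4.0
    depth_dispersion: float = 0.5
    missing_tag_rate: float = 0.2
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_loci < 1:
            raise ValueError("n_groups and n_loci must be >= 1")
        sizes = self.group_sizes
        if len(sizes) != self.n_groups or any(s < 1 for s in sizes):
            raise ValueError(
                "accessions_per_group must be a positive int or one positive "
                "count per group"
            )
        for name in ("divergence", "residual_het_rate", "missing_tag_rate",
                     "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be > 0")

    @property
    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.accessions_per_group, int):
            return (self.accessions_per_group,) * self.n_groups
        return tuple(int(s) for s in self.accessions_per_group)

    @property
    def n_accessions(self) -> int:
        return sum(self.group_sizes)


@dataclass
class SimTruth:
    """Ground truth for one simulated collection."""

    genotypes: GenotypeMatrix  # no missing calls
    catalog: TagCatalog  # 64 bp consensus tag + allele pair per locus
    group_freqs: np.ndarray  # (n_loci, n_groups) allele-B frequencies
    ancestral_freqs: np.ndarray  # (n_loci,)
    groups: GroupTable
    causal_locus: str
    causal_penetrance: tuple[float, float, float] = (1.0, 1.0, 0.0)
    config: SimConfig | None = None


def simulate_population(cfg: SimConfig) -> SimTruth:
    """Draw group allele frequencies and true genotypes.

    Per locus the ancestral allele-B frequency is Uniform(0.05, 0.95); group
    frequencies are Balding-Nichols Beta draws around it with spread set by
    ``divergence`` (identical across groups at divergence 0).  Genotypes are
    drawn with enough autozygosity that the expected heterozygosity equals
    ``residual_het_rate`` wherever that is attainable.

    The designated causal locus is the one whose realized minor allele
    frequency is closest to 0.3 (a comfortably common allele for the binary
    trait proof-of-concept).
    """
    rng = _rng(cfg.seed, "population")
    L, G = cfg.n_loci, cfg.n_groups
    p = rng.uniform(0.05, 0.95, size=L)
    F = cfg.divergence
    if F == 0:
        q = np.tile(p[:, None], (1, G))
    else:
        scale = (1 - F) / F
        q = rng.beta(
            np.tile((p * scale)[:, None], (1, G)),
            np.tile(((1 - p) * scale)[:, None], (1, G)),
        )
        q = np.clip(q, 1e-6, 1 - 1e-6)

    sizes = cfg.group_sizes
    blocks = []
    for g, size in enumerate(sizes):
        qg = q[:, g][:, None]
        # autozygosity probability chosen so E[het] = residual_het_rate
        with np.errstate(divide="ignore", invalid="ignore"):
            f_auto = 1.0 - cfg.residual_het_rate / (2 * qg * (1 - qg))
        f_auto = np.clip(np.where(np.isfinite(f_auto), f_auto, 1.0), 0.0, 1.0)
        auto = rng.random((L, size)) < f_auto
        a1 = rng.random((L, size)) < qg
        a2 = rng.random((L, size)) < qg
        blocks.append(np.where(auto, 2 * a1, a1.astype(np.int8) + a2))
    calls = np.concatenate(blocks, axis=1).astype(np.int8)

    loci = [f"TP{i + 1:06d}" for i in range(L)]
    accessions = [f"ACC{i + 1:04d}" for i in range(cfg.n_accessions)]
    labels = np.repeat([f"G{g + 1}" for g in range(G)], sizes)
    groups = GroupTable(
        pd.DataFrame(
            {"group": labels, "available": True, "membership_q": 1.0},
            index=pd.Index(accessions, name="accession"),
        )
    )
    gm = GenotypeMatrix(loci, accessions, calls)

    # per-locus allele pair and 64 bp consensus tag, allele A at the offset
    tags = rng.integers(0, 4, size=(L, UNEAK_TAG_LENGTH))
    offsets = rng.integers(0, UNEAK_TAG_LENGTH, size=L)
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(L)])
    records = []
    for i, locus in enumerate(loci):
        seq = tags[i].copy()
        seq[offsets[i]] = allele_idx[i, 0]
        records.append(
            TagRecord(
                locus,
                "".join(_BASES[seq]),
                int(offsets[i]),
                str(_BASES[allele_idx[i, 0]]),
                str(_BASES[allele_idx[i, 1]]),
                UNEAK,
            )
        )
    catalog = TagCatalog(records)

    fb = calls.mean(axis=1) / 2.0
    maf = np.minimum(fb, 1 - fb)
    causal = loci[int(np.argmin(np.abs(maf - 0.3)))]
    return SimTruth(
        genotypes=gm,
        catalog=catalog,
        group_freqs=q,
        ancestral_freqs=p,
        groups=groups,
        causal_locus=causal,
        config=cfg,
    )


def simulate_read_depths(truth: SimTruth, cfg: SimConfig) -> AlleleDepthMatrix:
    """Draw per-cell allele read depths for the true genotypes.

    A cell drops out entirely with probability ``missing_tag_rate``; otherwise
    its total depth is negative binomial with the configured mean and
    dispersion (dispersion is the NB shape r, so variance = m + m^2/r).
    Reads then split between the two alleles: Binomial(depth, 1/2) for
    heterozygotes, Binomial(depth, error_rate) to the wrong allele for
    homozygotes.
    """
    rng = _rng(cfg.seed, "depths")
    gm = truth.genotypes
    shape = gm.calls.shape
    r = cfg.depth_dispersion
    p_nb = r / (r + cfg.mean_depth)
    depth = rng.negative_binomial(r, p_nb, size=shape)
    depth[rng.random(shape) < cfg.missing_tag_rate] = 0

    b_reads = np.zeros(shape, dtype=np.int64)
    het = gm.calls == 1
    b_reads[het] = rng.binomial(depth[het], 0.5)
    hom_a = gm.calls == 0
    b_reads[hom_a] = rng.binomial(depth[hom_a], cfg.error_rate)
    hom_b = gm.calls == 2
    b_reads[hom_b] = depth[hom_b] - rng.binomial(depth[hom_b], cfg.error_rate)
    a_reads = depth - b_reads
    return AlleleDepthMatrix(gm.loci, gm.accessions, a_reads, b_reads)


def simulate_dual_catalogs(
    truth: SimTruth,
    overlap_fraction: float,
    cfg: SimConfig,
    n_mismatches: int = 0,
) -> tuple[TagCatalog, TagCatalog, dict[str, str]]:
    """Split the truth loci into two partially overlapping SNP catalogs.

    A fraction ``overlap_fraction`` of loci appear in both catalogs: the
    UNEAK copy is the 64 bp truth tag, the Stacks copy an 80 bp tag embedding
    it at a random offset with ``n_mismatches`` injected substitutions (never
    at the SNP position).  Remaining loci are split evenly between the two
    catalogs as private loci.  Returns the two catalogs and the ground-truth
    pairing ``{uneak_id: stacks_id}``.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if n_mismatches < 0:
        raise ValueError("n_mismatches must be >= 0")
    rng = _rng(cfg.seed, "catalogs")
    loci = truth.catalog.loci
    order = rng.permutation(len(loci))
    n_shared = int(round(overlap_fraction * len(loci)))
    shared = [loci[i] for i in order[:n_shared]]
    rest = [loci[i] for i in order[n_shared:]]
    uneak_only = rest[: len(rest) // 2]
    stacks_only = rest[len(rest) // 2:]

    pad = STACKS_TAG_LENGTH - UNEAK_TAG_LENGTH

    def embed(rec: TagRecord, stacks_id: str) -> TagRecord:
        core = np.array([ "ACGT".index(c) for c in rec.tag_sequence])
        if n_mismatches:
            sites = [i for i in range(len(core)) if i != rec.snp_offset]
            for pos in rng.choice(sites, size=min(n_mismatches, len(sites)),
                                  replace=False):
                core[pos] = (core[pos] + rng.integers(1, 4)) % 4
        start = int(rng.integers(0, pad + 1))
        flank = rng.integers(0, 4, size=pad)
        seq = np.concatenate([flank[:start], core, flank[start:]])
        return TagRecord(
            stacks_id,
            "".join(_BASES[seq]),
            start + rec.snp_offset,
            rec.allele_a,
            rec.allele_b,
            STACKS,
        )

    uneak_records = [truth.catalog[l] for l in shared + uneak_only]
    shared_map = {l: "ST" + l[2:] for l in shared}
    stacks_records = [embed(truth.catalog[l], shared_map[l]) for l in shared]
    stacks_records += [embed(truth.catalog[l], "ST" + l[2:]) for l in stacks_only]

    order_u = {l: i for i, l in enumerate(loci)}
    uneak_records.sort(key=lambda r: order_u[r.locus_id])
    stacks_records.sort(key=lambda r: order_u["TP" + r.locus_id[2:]])
    return TagCatalog(uneak_records), TagCatalog(stacks_records), shared_map


def simulate_binary_trait(
    truth: SimTruth,
    causal_locus: str | None = None,
    penetrance: Sequence[float] = (1.0, 1.0, 0.0),
    seed: int | None = None,
    na_rate: float = 0.0,
) -> pd.Series:
    """Draw one binary phenotype per accession from a penetrance table.

    ``penetrance`` gives P(trait = 1 | genotype) for (homozygous major,
    heterozygous, homozygous minor) at the causal locus, major/minor taken
    from the true allele frequencies.  ``na_rate`` masks phenotypes at random
    (scored NaN).  The default penetrance makes the trait fully recessive for
    the minor allele.
    """
    locus = causal_locus if causal_locus is not None else truth.causal_locus
    gm = truth.genotypes
    if locus not in gm.loci:
        raise KeyError(f"unknown causal locus {locus!r}")
    pen = np.asarray(penetrance, dtype=float)
    if pen.shape != (3,) or (pen < 0).any() or (pen > 1).any():
        raise ValueError("penetrance must be three probabilities")
    cfg_seed = truth.config.seed if truth.config is not None else 0
    rng = _rng(cfg_seed if seed is None else seed, "trait")
    i = gm.loci.index(locus)
    dose_b = gm.calls[i].astype(int)
    fb = dose_b.mean() / 2.0
    idx = dose_b if fb <= 0.5 else 2 - dose_b  # index by minor-allele dosage
    y = (rng.random(gm.n_accessions) < pen[idx]).astype(float)
    if na_rate:
        y[rng.random(gm.n_accessions) < na_rate] = np.nan
    return pd.Series(y, index=pd.Index(gm.accessions, name="accession"),
                     name="value")


def mask_missing(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set a random fraction of calls to missing (missing-at-random mask)."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    rng = _rng(seed, "mask")
    calls = gm.calls.copy()
    calls[rng.random(calls.shape) < rate] = MISSING
    return GenotypeMatrix(gm.loci, gm.accessions, calls, gm.mean_depth)
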