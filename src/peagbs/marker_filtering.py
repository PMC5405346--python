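"""Marker exclusion rules, the first-SNP-per-tag rule and the catalog union.

A SNP is retained when its minor allele frequency, call rate and
heterozygosity rate all clear their thresholds (defaults 0.01 / 0.2 / 0.25).
The heterozygosity ceiling exists to discard paralog-collapsed loci, which
masquerade as wildly heterozygous SNPs in an otherwise inbred panel.

Two reference-free SNP catalogs (64 bp UNEAK tags, 80 bp Stacks tags) are
merged by locating each UNEAK tag inside Stacks tags with a bounded-edit
infix alignment; paired loci keep the UNEAK genotypes, unpaired loci pass
through from either side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    GenotypeMatrix,
    TagCatalog,
    TagRecord,
)

logger = logging.getLogger(__name__)

# exclusion attribution order: the first failing rule owns the exclusion
RULE_ORDER = ("call_rate", "maf", "het_rate")


@dataclass(frozen=True)
class FilterThresholds:
    min_maf: float = 0.01
    min_call_rate: float = 0.2
    max_het_rate: float = 0.25
    min_taxa_per_tag: int = 5

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_call_rate", "max_het_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_taxa_per_tag < 0:
            raise ValueError("min_taxa_per_tag must be >= 0")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    excluded_by: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.excluded_by.values()) != self.n_input:
            raise ValueError("filter report counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = {"input": self.n_input, "retained": self.n_retained}
        rows.update({f"excluded_{r}": self.excluded_by.get(r, 0) for r in RULE_ORDER})
        return pd.DataFrame({"count": rows})


def passing_mask(gm: GenotypeMatrix, t: FilterThresholds) -> np.ndarray:
    """Boolean mask of loci that clear every threshold."""
    return (
        (gm.call_rate() >= t.min_call_rate)
        & (gm.maf() >= t.min_maf)
        & (gm.het_rate() <= t.max_het_rate)
    )


def filter_markers(
    gm: GenotypeMatrix, t: FilterThresholds = FilterThresholds()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci failing any rule; attribute each exclusion to its first
    failing rule in the order call_rate, maf, het_rate."""
    fails = {
        "call_rate": gm.call_rate() < t.min_call_rate,
        "maf": gm.maf() < t.min_maf,
        "het_rate": gm.het_rate() > t.max_het_rate,
    }
    attributed = np.zeros(gm.n_loci, dtype=bool)
    excluded_by: dict[str, int] = {}
    for rule in RULE_ORDER:
        new = fails[rule] & ~attributed
        excluded_by[rule] = int(new.sum())
        attributed |= new
    keep = ~attributed
    report = FilterReport(gm.n_loci, int(keep.sum()), excluded_by)
    return gm.subset_loci(keep), report


def first_snp_per_tag(
    catalog: TagCatalog, gm: GenotypeMatrix, t: FilterThresholds = FilterThresholds()
) -> TagCatalog:
    """Keep, per tag sequence, only the first (lowest-offset) SNP that passes
    the marker filters; tags with no passing SNP contribute nothing."""
    passing = set(np.array(gm.loci)[passing_mask(gm, t)])
    by_tag: dict[str, list[TagRecord]] = {}
    for rec in catalog:
        by_tag.setdefault(rec.tag_sequence, []).append(rec)
    kept: list[TagRecord] = []
    for recs in by_tag.values():
        for rec in sorted(recs, key=lambda r: r.snp_offset):
            if rec.locus_id in passing:
                kept.append(rec)
                break
    order = {r.locus_id: i for i, r in enumerate(catalog)}
    kept.sort(key=lambda r: order[r.locus_id])
    return TagCatalog(kept)


def tag_taxa_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Number of accessions with a non-missing call, per locus (surrogate for
    a pipeline's minimum-taxa-per-tag prefilter)."""
    return (gm.calls != MISSING).sum(axis=1)


@dataclass(frozen=True)
class MatchParams:
    """Acceptance rule for pairing a 64 bp tag inside an 80 bp tag.

    ``min_identity`` over an alignment covering at least ``min_overlap`` bases
    of the shorter tag; with the defaults this accepts up to 3 mismatches over
    a full 64 bp overlap.
    """

    min_identity: float = 0.95
    min_overlap: int = 60


def _infix_matches(query: str, target: str, max_dist: int):
    """Yield (edit_distance, start) placements of ``query`` inside ``target``."""
    res = edlib.align(query, target, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return
    for start, _end in res["locations"]:
        yield res["editDistance"], (start or 0)


def union_catalogs(
    uneak: tuple[TagCatalog, GenotypeMatrix],
    stacks: tuple[TagCatalog, GenotypeMatrix],
    match_params: MatchParams = MatchParams(),
) -> tuple[TagCatalog, GenotypeMatrix, pd.DataFrame]:
    """Merge two filtered SNP catalogs into their union.

    Loci are paired when the UNEAK tag aligns inside the Stacks tag at
    ``min_identity`` or better over ``min_overlap`` bases, the SNP offsets
    coincide under the alignment and the allele pairs agree.  Paired loci
    appear once, with the UNEAK genotypes; unpaired loci from both catalogs
    pass through.  Returns the merged catalog, merged genotypes, and the pair
    list (columns ``uneak_id``, ``stacks_id``, ``identity``) for audit.

    Candidate pairing is all-vs-all (bounded-edit infix alignment per pair),
    adequate for catalog sizes in the tens of thousands.
    """
    cat_u, gm_u = uneak
    cat_s, gm_s = stacks
    if set(gm_u.accessions) != set(gm_s.accessions):
        raise ValueError("both catalogs must cover the same accessions")
    gm_s = gm_s.subset_accessions(gm_u.accessions)

    candidates: list[tuple[float, str, str]] = []
    for ru in cat_u:
        qlen = len(ru.tag_sequence)
        if qlen < match_params.min_overlap:
            continue
        max_dist = math.floor((1 - match_params.min_identity) * qlen)
        for rs in cat_s:
            if {ru.allele_a, ru.allele_b} != {rs.allele_a, rs.allele_b}:
                continue
            for dist, start in _infix_matches(
                ru.tag_sequence, rs.tag_sequence, max_dist
            ):
                if rs.snp_offset == start + ru.snp_offset:
                    candidates.append((1 - dist / qlen, ru.locus_id, rs.locus_id))
                    break

    # best-identity greedy matching; ties broken lexicographically
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    per_uneak: dict[str, int] = {}
    for ident, uid, _sid in candidates:
        per_uneak[uid] = per_uneak.get(uid, 0) + 1
    for uid, n in per_uneak.items():
        if n > 1:
            logger.warning(
                "tag %s matches %d partner tags; keeping best identity", uid, n
            )
    matched_u: dict[str, tuple[str, float]] = {}
    matched_s: set[str] = set()
    for ident, uid, sid in candidates:
        if uid in matched_u or sid in matched_s:
            continue
        matched_u[uid] = (sid, ident)
        matched_s.add(sid)

    keep_stacks = [l for l in cat_s.loci if l not in matched_s]
    merged_catalog = TagCatalog(list(cat_u) + [cat_s[l] for l in keep_stacks])
    gm_s_keep = gm_s.subset_loci(keep_stacks)
    calls = np.vstack([gm_u.calls, gm_s_keep.calls])
    if gm_u.mean_depth is not None and gm_s_keep.mean_depth is not None:
        md = np.concatenate([gm_u.mean_depth, gm_s_keep.mean_depth])
    else:
        md = None
    merged_gm = GenotypeMatrix(
        gm_u.loci + keep_stacks, gm_u.accessions, calls, md
    )
    pair_list = pd.DataFrame(
        [(uid, sid, ident) for uid, (sid, ident) in sorted(matched_u.items())],
        columns=["uneak_id", "stacks_id", "identity"],
    )
    return merged_catalog, merged_gm, pair_list
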