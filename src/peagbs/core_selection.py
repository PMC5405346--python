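"""Allele-coverage core-collection selection.

A core collection is a small accession subset that retains a target fraction
of the alleles observed in the full collection.  Selection is a deterministic
greedy set cover — repeatedly add the eligible accession contributing the
most not-yet-covered alleles — followed by one backward pass dropping any
accession whose removal keeps coverage above target.  An intensity sweep
caps the core at decreasing fractions of the eligible accessions and returns
the smallest core that still meets the coverage target, reporting alongside
it the fraction of SNPs whose within-core minor allele frequency stays at or
above the collection's original MAF threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class CoreSet:
    """A selected core with its realized diversity statistics."""

    accessions: list[str]
    coverage: float
    maf_retention: float
    target_met: bool = True
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must lie in [0, 1]")

    @property
    def size(self) -> int:
        return len(self.accessions)


def _presence(gm: GenotypeMatrix) -> np.ndarray:
    """(n_accessions, 2 * n_loci) booleans: accession carries allele A / B."""
    calls = gm.calls
    a = (calls == 0) | (calls == 1)
    b = (calls == 1) | (calls == 2)
    return np.concatenate([a, b], axis=0).T


def coverage(gm: GenotypeMatrix, subset: Sequence[str]) -> float:
    """Fraction of alleles observed in the full matrix that are also
    observed in ``subset``."""
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    pres = _presence(gm)
    full = pres.any(axis=0)
    sub = pres[gm.accession_indices(subset)].any(axis=0)
    return float((sub & full).sum() / max(full.sum(), 1))


def maf_retention(
    gm: GenotypeMatrix, subset: Sequence[str], maf_threshold: float = 0.01
) -> float:
    """Fraction of SNPs whose minor allele frequency within ``subset`` is at
    least ``maf_threshold`` (the full collection's original filter)."""
    sub = gm.subset_accessions(list(subset))
    return float((sub.maf() >= maf_threshold).mean())


def greedy_core(
    gm: GenotypeMatrix,
    target_coverage: float,
    eligible: Sequence[str] | None = None,
    max_size: int | None = None,
) -> CoreSet:
    """Greedy allele set cover with backward pruning.

    Adds, at each step, the eligible accession covering the most not-yet-
    covered alleles (ties broken by higher call rate, then lexicographic id),
    stopping once coverage reaches ``target_coverage``; a backward pass then
    removes accessions whose removal keeps the target met.  With
    ``max_size`` set, selection stops at that size even if the target is
    unmet (``target_met`` flags the outcome); without it, an unreachable
    target raises with the maximum achievable coverage in the message.
    """
    if not 0 <= target_coverage <= 1:
        raise ValueError("target_coverage must lie in [0, 1]")
    elig = list(eligible) if eligible is not None else list(gm.accessions)
    if not elig:
        raise ValueError("no eligible accessions")
    pres = _presence(gm)
    full = pres.any(axis=0)
    n_alleles = int(full.sum())
    elig_idx = gm.accession_indices(elig)
    max_cov = float((pres[elig_idx].any(axis=0) & full).sum() / max(n_alleles, 1))
    if max_size is None and max_cov < target_coverage:
        raise ValueError(
            f"target coverage {target_coverage:.3f} unreachable; eligible "
            f"accessions achieve at most {max_cov:.4f}"
        )

    # tie-break keys: call rate descending, then accession id ascending
    call_rates = (gm.calls != MISSING).mean(axis=0)
    order_key = {
        a: (-call_rates[i], a) for a, i in zip(elig, elig_idx)
    }
    remaining = dict(zip(elig, elig_idx))
    covered = np.zeros_like(full)
    selected: list[str] = []
    needed = target_coverage * n_alleles - 1e-9
    cap = max_size if max_size is not None else len(elig)
    while (
        (covered.sum() < needed or not selected)
        and len(selected) < cap
        and remaining
    ):
        uncovered = full & ~covered
        names = list(remaining)
        idx = np.fromiter((remaining[a] for a in names), dtype=int)
        gains = pres[idx][:, uncovered].sum(axis=1)
        best_gain = gains.max()
        best = min(
            (names[k] for k in np.flatnonzero(gains == best_gain)),
            key=order_key.__getitem__,
        )
        selected.append(best)
        covered |= pres[remaining.pop(best)]

    # backward pass, in addition order
    if len(selected) > 1:
        for acc in list(selected):
            trial = [a for a in selected if a != acc]
            if not trial:
                continue
            cov = (pres[gm.accession_indices(trial)].any(axis=0) & full).sum()
            if cov >= needed:
                selected = trial

    cov = coverage(gm, selected)
    return CoreSet(
        accessions=selected,
        coverage=cov,
        maf_retention=maf_retention(gm, selected),
        target_met=cov >= target_coverage - 1e-12,
    )


def intensity_sweep(
    gm: GenotypeMatrix,
    target_coverage: float = 0.95,
    eligible: Sequence[str] | None = None,
    intensities: Sequence[float] | None = None,
) -> CoreSet:
    """Run the greedy core at decreasing sampling intensities.

    Intensity ``i`` caps the core at ``ceil(i * n_eligible)`` accessions;
    intensities default to 0.95 down to 0.05 in steps of 0.05.  The smallest
    core meeting ``target_coverage`` is returned; if none does, the
    best-coverage core is returned with ``target_met=False``.
    """
    elig = list(eligible) if eligible is not None else list(gm.accessions)
    if intensities is None:
        intensities = [round(0.95 - 0.05 * k, 2) for k in range(19)]
    intensities = sorted(intensities, reverse=True)
    best: CoreSet | None = None
    fallback: CoreSet | None = None
    for i in intensities:
        cap = int(np.ceil(i * len(elig)))
        if cap < 1:
            continue
        core = greedy_core(gm, target_coverage, elig, max_size=cap)
        core.intensity = i
        if core.target_met:
            if best is None or core.size < best.size:
                best = core
        elif fallback is None or core.coverage > fallback.coverage:
            fallback = core
    if best is not None:
        return best
    assert fallback is not None
    return fallback
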