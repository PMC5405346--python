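"""Group-wise private-allele accounting and probabilistic PCA.

Groups of unequal size and unequal missingness cannot be compared directly on
raw private-allele counts, so each group is first downsampled to a common
"score", where an accession contributes ``1 - (proportion missing data)`` and
a group's score is the sum over its chosen accessions.  Accessions are added
in random order until the score reaches the threshold band; the procedure is
repeated (default 100 iterations) and per-pair unique-allele counts averaged.

Population structure is summarized by probabilistic PCA (PPCA): an EM fit of
the latent linear-Gaussian model that tolerates missing genotypes, with the
final axes taken from an SVD of the EM-completed matrix so the complete-data
case coincides exactly with classical PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, GroupTable

logger = logging.getLogger(__name__)

#: sentinel comparison set: every accession outside the focal group
ALL_OTHERS = "__others__"


@dataclass(frozen=True)
class DownsampleSpec:
    """Missing-data-score downsampling parameters.

    ``score_threshold`` defaults to the minimum total group score (the rule
    that produced the published 7.59 for the group with the least data);
    iterating stops once the cumulative score lands in
    ``threshold +/- tolerance``.
    """

    score_threshold: float | None = None
    tolerance: float = 0.5
    n_iterations: int = 100
    seed: int = 0
    max_restarts: int = 1000

    def __post_init__(self) -> None:
        if self.score_threshold is not None and self.score_threshold <= 0:
            raise ValueError("score_threshold must be > 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class UniqueAlleleResult:
    group: str
    comparison: str
    counts: np.ndarray  # per-iteration unique-allele counts
    mean: float
    sd: float


def accession_score(gm: GenotypeMatrix, accession: str) -> float:
    """``1 - (proportion missing data)`` for one accession."""
    j = gm.accession_indices([accession])[0]
    return 1.0 - float((gm.calls[:, j] == MISSING).mean())


def accession_scores(gm: GenotypeMatrix) -> pd.Series:
    miss = (gm.calls == MISSING).mean(axis=0)
    return pd.Series(1.0 - miss, index=gm.accessions, name="score")


def downsample_by_score(
    scores: pd.Series,
    threshold: float,
    tolerance: float,
    rng: np.random.Generator,
    max_restarts: int = 1000,
) -> list[str]:
    """Randomly accumulate accessions until the summed score lands in
    ``[threshold - tolerance, threshold + tolerance]``.

    Accessions are taken in uniformly random order without replacement; if
    one addition overshoots the band the ordering is discarded and a fresh
    one drawn (a restart), up to ``max_restarts`` times.
    """
    vals = scores.to_numpy(dtype=float)
    names = list(scores.index)
    if vals.sum() < threshold - tolerance:
        raise ValueError(
            f"total score {vals.sum():.3f} cannot reach "
            f"{threshold - tolerance:.3f}"
        )
    for _ in range(max_restarts):
        order = rng.permutation(len(vals))
        cum = 0.0
        chosen: list[str] = []
        for i in order:
            chosen.append(names[i])
            cum += vals[i]
            if cum >= threshold - tolerance:
                if cum <= threshold + tolerance:
                    return chosen
                break  # overshot the band: restart with a new ordering
    raise RuntimeError(
        f"no ordering reached [{threshold - tolerance:.3f}, "
        f"{threshold + tolerance:.3f}] within {max_restarts} restarts; "
        "the score band may be narrower than the largest single score"
    )


def downsample_group(
    gm: GenotypeMatrix, group_members: Sequence[str], spec: DownsampleSpec
) -> list[str]:
    """Downsample one group of accessions to the spec's score band."""
    if spec.score_threshold is None:
        raise ValueError("spec.score_threshold is required for a single group")
    scores = accession_scores(gm).loc[list(group_members)]
    rng = np.random.default_rng(spec.seed)
    return downsample_by_score(
        scores, spec.score_threshold, spec.tolerance, rng, spec.max_restarts
    )


def _observed_alleles(gm: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """(n_loci, 2) booleans: allele A / allele B observed in the subset."""
    calls = gm.calls[:, idx]
    a = ((calls == 0) | (calls == 1)).any(axis=1)
    b = ((calls == 1) | (calls == 2)).any(axis=1)
    return np.column_stack([a, b])


def unique_alleles(
    gm: GenotypeMatrix,
    group_subset: Sequence[str],
    comparison_subset: Sequence[str],
) -> int:
    """Count alleles observed in the group but not in the comparison set.

    An allele is observed when at least one non-missing call carries at least
    one copy; missing calls carry no alleles (so absence of evidence in the
    comparison counts as absence).
    """
    if len(group_subset) == 0:
        raise ValueError("group subset must be non-empty")
    g = _observed_alleles(gm, gm.accession_indices(group_subset))
    if len(comparison_subset) == 0:
        return int(g.sum())
    c = _observed_alleles(gm, gm.accession_indices(comparison_subset))
    return int((g & ~c).sum())


def standardized_unique_alleles(
    gm: GenotypeMatrix,
    groups: GroupTable,
    comparison_sets: Mapping[str, Sequence[str] | str] | None = None,
    spec: DownsampleSpec = DownsampleSpec(),
    downsample_comparison: bool = True,
) -> list[UniqueAlleleResult]:
    """Average unique-allele counts over downsampling iterations.

    Every group (focal and comparison alike) is downsampled once per
    iteration; each focal group is then compared against the union of the
    downsampled members of each comparison set.  A comparison set is either
    a list of group labels or :data:`ALL_OTHERS`; the focal group is always
    excluded from its own comparison set.
    """
    labels = groups.labels
    members = {
        lab: [a for a in groups.members(lab) if a in set(gm.accessions)]
        for lab in labels
    }
    empty = [lab for lab in labels if not members[lab]]
    if empty:
        raise ValueError(f"groups with no genotyped members: {empty}")
    scores = accession_scores(gm)
    totals = {lab: float(scores.loc[members[lab]].sum()) for lab in labels}
    T = (
        spec.score_threshold
        if spec.score_threshold is not None
        else min(totals.values())
    )
    for lab, tot in totals.items():
        if tot < T - spec.tolerance:
            raise ValueError(
                f"group {lab!r} total score {tot:.3f} cannot reach "
                f"{T - spec.tolerance:.3f}"
            )
    if comparison_sets is None:
        comparison_sets = {"All others": ALL_OTHERS}

    rng = np.random.default_rng(spec.seed)
    counts: dict[tuple[str, str], list[int]] = {
        (f, c): [] for f in labels for c in comparison_sets
    }
    for _ in range(spec.n_iterations):
        try:
            ds = {
                lab: downsample_by_score(
                    scores.loc[members[lab]], T, spec.tolerance, rng,
                    spec.max_restarts,
                )
                for lab in labels
            }
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"downsampling failed: {exc}") from exc
        for focal in labels:
            for name, cset in comparison_sets.items():
                comp_labels = (
                    [l for l in labels if l != focal]
                    if cset == ALL_OTHERS
                    else [l for l in cset if l != focal]
                )
                pool = ds if downsample_comparison else members
                comp = [a for l in comp_labels for a in pool[l]]
                counts[(focal, name)].append(
                    unique_alleles(gm, ds[focal], comp)
                )

    results = []
    for (focal, name), vals in counts.items():
        arr = np.array(vals)
        results.append(
            UniqueAlleleResult(
                focal, name, arr, float(arr.mean()), float(arr.std(ddof=0))
            )
        )
    return results


def unique_allele_table(results: Sequence[UniqueAlleleResult]) -> pd.DataFrame:
    """Pivot results to a groups x comparison-sets table of mean counts."""
    df = pd.DataFrame(
        [(r.group, r.comparison, r.mean) for r in results],
        columns=["group", "comparison", "mean"],
    )
    out = df.pivot(index="group", columns="comparison", values="mean")
    order = {r.group: i for i, r in enumerate(results)}
    return out.loc[sorted(out.index, key=lambda g: order[g])]


# ---------------------------------------------------------------------------
# probabilistic PCA
# ---------------------------------------------------------------------------

@dataclass
class PPCAResult:
    scores: np.ndarray  # (n_accessions, n_components)
    loadings: np.ndarray  # (n_loci_used, n_components)
    explained_variance: np.ndarray
    sigma2: float
    n_iter: int
    converged: bool
    accessions: list[str]


def ppca_scores(
    gm: GenotypeMatrix,
    n_components: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
) -> PPCAResult:
    """Probabilistic PCA of minor-allele dosage with missing genotypes.

    Genotypes are coded 0/1/2 as minor-allele dosage and centered on observed
    column means.  The latent model ``x = W z + eps`` is fit by EM, with
    missing entries re-imputed from the current reconstruction at each step
    (the observed-entry reconstruction error is non-increasing across
    iterations).  Final components come from an SVD of the completed matrix:
    ordered by explained variance, the largest-magnitude loading of each
    component made positive.  Non-convergence is a warning, not an error.
    """
    dose = gm.minor_dosage().T.astype(float)  # accessions x loci
    dose[dose < 0] = np.nan
    obs = ~np.isnan(dose)
    keep = obs.any(axis=0)
    X = dose[:, keep]
    obs = obs[:, keep]
    n, d = X.shape
    q = int(n_components)
    if not 0 < q < min(n, d):
        raise ValueError(
            f"n_components must lie in (0, {min(n, d)}), got {q}"
        )
    mu = np.nanmean(X, axis=0)
    Xc = np.where(obs, X - mu, 0.0)

    rng = np.random.default_rng(seed)
    W = rng.normal(scale=0.01, size=(d, q))
    sigma2 = 1.0
    prev_obj = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        M = W.T @ W + sigma2 * np.eye(q)
        Minv = np.linalg.inv(M)
        EZ = Xc @ W @ Minv
        SumEzz = n * sigma2 * Minv + EZ.T @ EZ
        W_new = np.linalg.solve(SumEzz.T, (Xc.T @ EZ).T).T
        recon = EZ @ W_new.T
        sigma2 = max(
            (np.sum(Xc * Xc) - 2 * np.sum(recon * Xc)
             + np.trace(SumEzz @ (W_new.T @ W_new))) / (n * d),
            1e-12,
        )
        W = W_new
        Xc = np.where(obs, Xc, recon)  # E-step imputation of missing entries
        obj = float(np.mean((Xc - recon)[obs] ** 2))
        if np.isfinite(prev_obj) and prev_obj - obj <= tol * max(prev_obj, 1e-12):
            converged = True
            break
        prev_obj = obj
    if not converged:
        logger.warning("PPCA did not converge in %d iterations", max_iter)

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :q] * S[:q]
    loadings = Vt[:q].T
    for j in range(q):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    explained = S[:q] ** 2 / max(n - 1, 1)
    return PPCAResult(
        scores, loadings, explained, float(sigma2), n_iter, converged,
        list(gm.accessions),
    )
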