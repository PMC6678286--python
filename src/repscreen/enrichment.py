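"""Weighted-KS gene set enrichment analysis of a ranked drug profile.

Used to ask whether a drug-induced ranking is the *reverse* of a gene set of
interest (e.g. a stemness module): a negative enrichment score with a small
permutation p-value means the set concentrates among the genes the drug
down-regulates. The null is built from random gene sets of the same size
drawn from the profile (a drug ranking has no sample replicates, so
phenotype permutation is not available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import PerturbationReference
from .errors import InputError

__all__ = [
    "RankedProfile",
    "EnrichmentResult",
    "gsea_es",
    "gsea_p",
    "profile_from_reference",
]


@dataclass
class RankedProfile:
    """Genes ordered by descending association score, with aligned weights."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise InputError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate genes in ranked profile")
        if not np.all(np.isfinite(self.scores)):
            raise InputError("scores must be finite")
        if np.any(np.diff(self.scores) > 1e-12):
            raise InputError("profile must be ordered by non-increasing score")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment score, permutation p-value, and leading-edge genes."""

    es: float
    p_perm: float
    n_perm: int
    leading_edge: tuple[str, ...]


def _running_sum(
    in_set: np.ndarray, scores: np.ndarray, weight_p: float
) -> np.ndarray:
    """Weighted-KS running sum over the profile positions."""
    n = in_set.size
    n_hit = int(in_set.sum())
    weights = np.abs(scores) ** weight_p
    hit_total = weights[in_set].sum()
    if hit_total == 0:  # all hit weights zero: fall back to unweighted steps
        steps_hit = in_set / n_hit
    else:
        steps_hit = np.where(in_set, weights / hit_total, 0.0)
    steps_miss = np.where(~in_set, 1.0 / (n - n_hit), 0.0)
    return np.cumsum(steps_hit - steps_miss)


def gsea_es(
    profile: RankedProfile,
    gene_set: set[str] | list[str] | tuple[str, ...],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Enrichment score of a gene set in a ranked profile.

    Walking down the profile, hits increment the running sum by
    ``|score|^weight_p`` (normalised over hits) and misses decrement it by
    ``1/(N - N_hit)``; the ES is the running-sum value of maximal absolute
    deviation from zero. The leading edge contains the hit genes at or before
    the extremum (at or after it, for a negative ES).

    Returns ``(es, running_sum, leading_edge)``.
    """
    members = set(gene_set)
    in_set = np.asarray([g in members for g in profile.genes])
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise InputError("gene set does not intersect the profile")
    if n_hit == len(profile):
        raise InputError("gene set covers the whole profile; miss step undefined")
    rs = _running_sum(in_set, profile.scores, weight_p)
    i_max = int(np.argmax(np.abs(rs)))
    es = float(rs[i_max])
    genes = np.asarray(profile.genes)
    if es >= 0:
        leading = tuple(genes[: i_max + 1][in_set[: i_max + 1]])
    else:
        leading = tuple(genes[i_max:][in_set[i_max:]])
    return es, rs, leading


def gsea_p(
    profile: RankedProfile,
    gene_set: set[str] | list[str] | tuple[str, ...],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> EnrichmentResult:
    """Permutation significance of a gene-set enrichment score.

    The null draws ``n_perm`` random gene sets of the same size from the
    profile (seeded); the two-sided p-value is add-one corrected:
    ``(#{|ES_null| >= |ES|} + 1) / (n_perm + 1)``.
    """
    es, _, leading = gsea_es(profile, gene_set, weight_p=weight_p)
    members = set(gene_set) & set(profile.genes)
    size = len(members)
    n = len(profile)
    rng = np.random.default_rng(seed)
    exceed = 0
    in_set = np.zeros(n, dtype=bool)
    for _ in range(n_perm):
        in_set[:] = False
        in_set[rng.choice(n, size=size, replace=False)] = True
        rs = _running_sum(in_set, profile.scores, weight_p)
        if np.max(np.abs(rs)) >= abs(es) - 1e-12:
            exceed += 1
    p = (exceed + 1.0) / (n_perm + 1.0)
    return EnrichmentResult(es=es, p_perm=p, n_perm=n_perm, leading_edge=leading)


def profile_from_reference(ref: PerturbationReference, drug: str) -> RankedProfile:
    """Ranked profile of a drug: per-probe mean rank across its instances,
    converted to a descending score ``n - mean_rank`` (high score = the drug
    up-regulates the probe)."""
    mask = np.asarray(ref.drug_labels) == drug
    if not mask.any():
        raise InputError(f"drug {drug!r} not present in the reference")
    mean_rank = ref.ranks[mask].mean(axis=0)
    scores = ref.n_probes - mean_rank
    order = np.argsort(-scores, kind="stable")
    return RankedProfile(
        genes=[ref.probe_universe[j] for j in order], scores=scores[order]
    )
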