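"""Connectivity scoring of up/down signatures against a perturbation reference.

The reference emulates a CMap-style build: each *instance* is one treatment
experiment, recorded as a full ranking of the probe universe (rank 1 = the
probe most up-regulated by the drug). A query signature is scored per
instance with a signed two-tail Kolmogorov–Smirnov statistic for its up and
down tags, the two are combined into a connectivity score (zero when they
agree in sign), scores are scaled to [-1, 1] across instances, and each drug
receives an enrichment score and permutation p-value for where its instances
fall in the score ordering. A *reversal* drug — one that pushes the tumor
signature back toward normal — has negative connectivity and negative
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, QueryError
from .signatures import GeneSignature

__all__ = [
    "PerturbationReference",
    "ks_score",
    "instance_connectivity",
    "scale_scores",
    "drug_enrichment",
    "query",
]

logger = logging.getLogger(__name__)


@dataclass
class PerturbationReference:
    """Drug-perturbation instances over a shared probe universe.

    ``ranks`` has shape ``(n_instances, n_probes)``; row *i* holds the rank of
    every probe in instance *i* and must be a permutation of ``1..n_probes``.
    """

    probe_universe: list[str]
    instance_ids: list[str]
    drug_labels: list[str]
    ranks: np.ndarray
    planted_drug: str | None = None
    _probe_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int64)
        n_inst, n_probes = len(self.instance_ids), len(self.probe_universe)
        if self.ranks.shape != (n_inst, n_probes):
            raise InputError(
                f"rank matrix shape {self.ranks.shape} does not match "
                f"{n_inst} instances x {n_probes} probes"
            )
        if len(self.drug_labels) != n_inst:
            raise InputError("one drug label required per instance")
        expected = np.arange(1, n_probes + 1)
        sorted_rows = np.sort(self.ranks, axis=1)
        if not np.array_equal(sorted_rows, np.broadcast_to(expected, self.ranks.shape)):
            bad = int(
                np.nonzero((sorted_rows != expected).any(axis=1))[0][0]
            )
            raise InputError(
                f"instance {self.instance_ids[bad]!r}: ranks are not a "
                f"permutation of 1..{n_probes} (ties or gaps present)"
            )
        self._probe_index = {p: j for j, p in enumerate(self.probe_universe)}

    @property
    def n_probes(self) -> int:
        return len(self.probe_universe)

    @property
    def n_instances(self) -> int:
        return len(self.instance_ids)

    @property
    def drugs(self) -> list[str]:
        return sorted(set(self.drug_labels))

    def probe_indices(self, probes: list[str] | tuple[str, ...]) -> np.ndarray:
        """Column indices of the given probes, dropping unknown ones."""
        idx = [self._probe_index[p] for p in probes if p in self._probe_index]
        dropped = len(probes) - len(idx)
        if dropped:
            logger.info("dropped %d signature probes absent from the universe", dropped)
        return np.asarray(idx, dtype=np.int64)


def _ks_from_sorted_positions(v: np.ndarray, n: int) -> np.ndarray:
    """Signed two-tail KS statistic from sorted tag positions.

    ``v`` has shape (..., t) with each row the ascending positions (1-based)
    of the t tags within a ranking of length n. Returns ``a`` when the tags
    concentrate at the top of the ranking, ``-b`` when at the bottom.
    """
    t = v.shape[-1]
    j = np.arange(1, t + 1, dtype=float)
    a = (j / t - v / n).max(axis=-1)
    b = (v / n - (j - 1) / t).max(axis=-1)
    return np.where(a > b, a, -b)


def ks_score(tags: list[str] | tuple[str, ...], ranking: dict[str, int] | pd.Series) -> float:
    """Signed two-tail KS statistic of a tag set within one instance ranking.

    ``ranking`` maps every probe of the universe to its rank (1 = most
    up-regulated by the drug). With V(j) the ascending-sorted tag ranks,
    ``a = max_j [j/t - V(j)/n]`` and ``b = max_j [V(j)/n - (j-1)/t]``; the
    statistic is ``a`` if ``a > b`` else ``-b``. Positive values mean the tags
    sit near the top of the drug's ranking.
    """
    if len(tags) == 0:
        raise InputError("ks_score requires a non-empty tag set")
    if isinstance(ranking, pd.Series):
        ranking = ranking.to_dict()
    n = len(ranking)
    if len(tags) >= n:
        raise InputError("tag set must be a strict subset of the universe")
    try:
        v = np.sort(np.asarray([ranking[tag] for tag in tags], dtype=float))
    except KeyError as exc:
        raise InputError(f"tag {exc.args[0]!r} not in the probe universe") from exc
    return float(_ks_from_sorted_positions(v, n))


def instance_connectivity(
    sig: GeneSignature, ranks_row: np.ndarray, up_idx: np.ndarray, down_idx: np.ndarray
) -> tuple[float, float, float]:
    """(ks_up, ks_down, raw score) for one instance.

    The raw connectivity score is ``ks_up - ks_down`` when the two statistics
    disagree in sign, else 0 (the instance neither matches nor reverses the
    signature coherently).
    """
    if up_idx.size == 0 and down_idx.size == 0:
        raise QueryError("signature has no probes in the reference universe")
    n = ranks_row.size
    ks_up = float(_ks_from_sorted_positions(np.sort(ranks_row[up_idx]).astype(float), n)) if up_idx.size else 0.0
    ks_down = float(_ks_from_sorted_positions(np.sort(ranks_row[down_idx]).astype(float), n)) if down_idx.size else 0.0
    raw = ks_up - ks_down if np.sign(ks_up) != np.sign(ks_down) else 0.0
    return ks_up, ks_down, raw


def scale_scores(raw: np.ndarray) -> np.ndarray:
    """Scale raw connectivity scores to [-1, 1].

    Positive scores are divided by the maximum positive score and negative
    scores by the magnitude of the minimum; zeros stay zero. A side with no
    scores is left untouched.
    """
    raw = np.asarray(raw, dtype=float)
    scaled = raw.copy()
    pos, neg = raw > 0, raw < 0
    if pos.any():
        scaled[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        scaled[neg] = raw[neg] / (-raw[neg].min())
    return scaled


def _score_all_instances(sig: GeneSignature, ref: PerturbationReference) -> pd.DataFrame:
    """Per-instance ks_up/ks_down/raw/scaled table for a signature."""
    up_idx = ref.probe_indices(sig.up)
    down_idx = ref.probe_indices(sig.down)
    if up_idx.size == 0 and down_idx.size == 0:
        raise QueryError("signature has no probes in the reference universe")
    n = ref.n_probes
    if up_idx.size:
        ks_up = _ks_from_sorted_positions(np.sort(ref.ranks[:, up_idx], axis=1).astype(float), n)
    else:
        ks_up = np.zeros(ref.n_instances)
    if down_idx.size:
        ks_down = _ks_from_sorted_positions(np.sort(ref.ranks[:, down_idx], axis=1).astype(float), n)
    else:
        ks_down = np.zeros(ref.n_instances)
    raw = np.where(np.sign(ks_up) != np.sign(ks_down), ks_up - ks_down, 0.0)
    return pd.DataFrame(
        {
            "instance_id": ref.instance_ids,
            "drug": ref.drug_labels,
            "ks_up": ks_up,
            "ks_down": ks_down,
            "raw": raw,
            "scaled": scale_scores(raw),
        }
    )


def _enrichment_null(t: int, n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null |enrichment| distribution for t instances among n, by sampling."""
    # t positions without replacement per draw, vectorised over draws
    draws = np.argpartition(rng.random((n_perm, n)), t - 1, axis=1)[:, :t] + 1.0
    draws.sort(axis=1)
    return np.abs(_ks_from_sorted_positions(draws, n))


def drug_enrichment(
    sig: GeneSignature,
    ref: PerturbationReference,
    drug: str,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Enrichment of one drug's instances in the connectivity ordering.

    Instances are ordered by descending scaled score (seeded random
    tie-break); the drug's enrichment is the signed KS statistic of its
    instance positions in that ordering, and its p-value the add-one-corrected
    fraction of ``n_perm`` random position draws at least as extreme in
    absolute value.
    """
    table = _score_all_instances(sig, ref)
    return _enrichment_from_table(table, drug, n_perm=n_perm, seed=seed)


def _instance_order(table: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Positions (1-based) of each instance in the descending-score ordering."""
    scaled = table["scaled"].to_numpy()
    tiebreak = rng.random(scaled.size)
    order = np.lexsort((tiebreak, -scaled))
    positions = np.empty(scaled.size, dtype=np.int64)
    positions[order] = np.arange(1, scaled.size + 1)
    return positions


def _enrichment_from_table(
    table: pd.DataFrame, drug: str, n_perm: int, seed: int,
    _null_cache: dict | None = None,
) -> tuple[float, float]:
    if drug not in set(table["drug"]):
        raise QueryError(f"drug {drug!r} not present in the reference")
    rng = np.random.default_rng(seed)
    positions = _instance_order(table, rng)
    mine = np.sort(positions[(table["drug"] == drug).to_numpy()]).astype(float)
    t, n = mine.size, len(table)
    es = float(_ks_from_sorted_positions(mine, n))
    if t == n:  # the drug owns every instance: nothing to discriminate
        return es, 1.0
    key = (t, n)
    if _null_cache is not None and key in _null_cache:
        null = _null_cache[key]
    else:
        null = _enrichment_null(t, n, n_perm, rng)
        if _null_cache is not None:
            _null_cache[key] = null
    p = (float((null >= abs(es) - 1e-12).sum()) + 1.0) / (n_perm + 1.0)
    return es, p


def query(
    sig: GeneSignature,
    ref: PerturbationReference,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score a signature against every drug in the reference.

    Returns one row per drug with columns ``drug, n_instances, mean_scaled,
    enrichment, p, hit``; ``hit`` is true when the enrichment is negative
    (signature reversal) and its permutation p-value is below ``alpha``.
    """
    if sig.is_empty:
        raise QueryError("cannot query an empty signature")
    table = _score_all_instances(sig, ref)
    null_cache: dict = {}
    rows = []
    for drug in ref.drugs:
        es, p = _enrichment_from_table(table, drug, n_perm=n_perm, seed=seed, _null_cache=null_cache)
        sub = table.loc[table["drug"] == drug, "scaled"]
        rows.append(
            {
                "drug": drug,
                "n_instances": int(len(sub)),
                "mean_scaled": float(sub.mean()),
                "enrichment": es,
                "p": p,
                "hit": bool(es < 0 and p < alpha),
            }
        )
    return pd.DataFrame(rows)
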