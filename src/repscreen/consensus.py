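"""Consensus screening funnel over cohorts, selection methods and queries.

Each cohort contributes one top-100 query, one SAM query, and one volcano
query per leave-one-patient-out sub-dataset. A drug is a *hit* in a query
when its enrichment is negative with p below alpha; per method, drugs whose
hit frequency is strictly greater than the threshold (20% by default) are
retained, and the final candidates are the drugs retained by all three
methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import signatures as sig_mod
from .cohort import PairedExpressionCohort
from .connectivity import PerturbationReference, query
from .errors import EmptySignatureError, ScreeningError
from .signatures import GeneSignature

__all__ = [
    "ScreenParams",
    "METHODS",
    "build_signatures",
    "run_screen",
    "tabulate_consensus",
    "report",
]

logger = logging.getLogger(__name__)

METHODS = ("top100", "volcano", "sam")


@dataclass(frozen=True)
class ScreenParams:
    """Tunable parameters of the screening funnel (defaults are the
    published rules: two-fold gate, p < 1e-4 volcano, SAM FDR 0 with 100
    permutations and the <1000-probe cap, alpha 0.05, frequency > 20%)."""

    floor: float = 50.0
    top_n: int = 100
    min_fold: float = 2.0
    p_thresh: float = 1e-4
    sam_n_perm: int = 100
    sam_target_fdr: float = 0.0
    sam_max_size: int = 1000
    alpha: float = 0.05
    threshold: float = 0.20
    query_n_perm: int = 10000


def build_signatures(
    cohorts: dict[str, PairedExpressionCohort],
    params: ScreenParams = ScreenParams(),
    seed: int = 0,
) -> list[GeneSignature]:
    """All signatures of the screen: per cohort, one top-100, one SAM, and one
    volcano per leave-one-out sub-dataset. Cohorts are floored first. Empty
    volcano sub-signatures are dropped with a log line (they cannot be
    queried); a method empty across *all* cohorts raises ScreeningError."""
    out: list[GeneSignature] = []
    for cid in sorted(cohorts):
        cohort = sig_mod.preprocess_floor(cohorts[cid], floor=params.floor)
        try:
            out.append(
                sig_mod.select_top_n(
                    cohort, n=params.top_n, min_fold=params.min_fold, source=(cid, "full")
                )
            )
        except EmptySignatureError:
            logger.warning("cohort %s: no top-%d signature", cid, params.top_n)
        _, sam_sig = sig_mod.select_sam(
            cohort,
            n_perm=params.sam_n_perm,
            target_fdr=params.sam_target_fdr,
            max_size=params.sam_max_size,
            seed=seed,
            source=(cid, "full"),
        )
        if sam_sig.is_empty:
            logger.warning("cohort %s: SAM called no probes", cid)
        else:
            out.append(sam_sig)
        for vsig in sig_mod.leave_one_out_signatures(
            cohort, p_thresh=params.p_thresh, min_fold=params.min_fold, cohort_id=cid
        ):
            if vsig.is_empty:
                logger.info("cohort %s: empty volcano signature (left out %s)", cid, vsig.source[1])
            else:
                out.append(vsig)
    for method in METHODS:
        if not any(s.method == method for s in out):
            raise ScreeningError(f"method {method!r} produced no signatures in any cohort")
    return out


def run_screen(
    cohorts: dict[str, PairedExpressionCohort],
    ref: PerturbationReference,
    params: ScreenParams = ScreenParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Run every query of the funnel and tabulate the consensus.

    Returns one row per drug with, for each method, ``hits_<m>``,
    ``queries_<m>``, ``frequency_<m>`` and ``passes_<m>`` (frequency strictly
    greater than the threshold), plus ``mean_enrichment`` over all queries
    and the ``final`` three-way intersection flag.
    """
    sigs = build_signatures(cohorts, params=params, seed=seed)
    drugs = ref.drugs
    hits = {m: pd.Series(0, index=drugs) for m in METHODS}
    queries = {m: 0 for m in METHODS}
    enrich_sum = pd.Series(0.0, index=drugs)
    n_queries = 0
    for i, sig in enumerate(sigs):
        res = query(
            sig, ref, alpha=params.alpha, n_perm=params.query_n_perm, seed=seed + i
        ).set_index("drug")
        queries[sig.method] += 1
        n_queries += 1
        hits[sig.method] = hits[sig.method].add(res["hit"].astype(int), fill_value=0)
        enrich_sum = enrich_sum.add(res["enrichment"], fill_value=0.0)
        logger.info(
            "query %d: cohort=%s sub=%s method=%s size=%d hits=%d",
            i, sig.source[0], sig.source[1], sig.method, sig.size, int(res["hit"].sum()),
        )
    return tabulate_consensus(
        drugs, hits, queries, enrich_sum / n_queries, threshold=params.threshold
    )


def tabulate_consensus(
    drugs: list[str],
    hits: dict[str, pd.Series],
    queries: dict[str, int],
    mean_enrichment: pd.Series,
    threshold: float = 0.20,
) -> pd.DataFrame:
    """Assemble the consensus table from per-method hit counts.

    A method is passed when ``hits/queries`` is *strictly* greater than the
    threshold (a drug hitting exactly 20% of queries is not retained); the
    final flag is the intersection over all methods with at least one query.
    """
    table = pd.DataFrame(index=pd.Index(drugs, name="drug"))
    final = pd.Series(True, index=drugs)
    for m in METHODS:
        q = queries[m]
        freq = hits[m] / q if q else pd.Series(np.nan, index=drugs)
        passes = (freq > threshold) & (q > 0)
        table[f"hits_{m}"] = hits[m].astype(int)
        table[f"queries_{m}"] = q
        table[f"frequency_{m}"] = freq
        table[f"passes_{m}"] = passes
        final &= passes
    table["mean_enrichment"] = mean_enrichment
    table["final"] = final
    return table.reset_index()


def report(table: pd.DataFrame) -> pd.DataFrame:
    """Ranked candidate list: final candidates first, then by mean hit
    frequency (descending), then by more-negative mean enrichment, then by
    drug label."""
    if table.empty:
        raise ScreeningError("cannot report an empty consensus table")
    freq_cols = [c for c in table.columns if c.startswith("frequency_")]
    out = table.copy()
    out["mean_frequency"] = out[freq_cols].mean(axis=1)
    out = out.sort_values(
        by=["final", "mean_frequency", "mean_enrichment", "drug"],
        ascending=[False, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return out
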