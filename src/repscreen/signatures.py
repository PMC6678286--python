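"""Gene-signature selection from paired tumor/normal cohorts.

Three selection methods produce disjoint up/down probe lists for querying a
drug-perturbation reference:

* ``top100`` — the probes with the highest absolute mean log2 tumor/normal
  ratio among those changing at least ``min_fold``-fold (default two-fold).
* ``volcano`` — joint paired t-test p-value and fold-change thresholding,
  optionally applied leave-one-patient-out to yield one signature per
  sub-dataset.
* ``sam`` — paired significance analysis of microarrays: a regularised
  per-probe statistic with a sign-flip permutation null, selected at the
  smallest threshold whose estimated false discovery rate reaches the target
  (zero by default), capped below 1000 probesets.

All ratios are computed on the log2 scale after the intensity floor has been
applied (sub-floor intensities rounded up to the floor value).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import DEFAULT_FLOOR, PairedExpressionCohort
from .errors import EmptySignatureError, InputError

__all__ = [
    "GeneSignature",
    "SamResult",
    "preprocess_floor",
    "probe_log_ratios",
    "paired_t",
    "select_top_n",
    "select_volcano",
    "leave_one_out_signatures",
    "select_sam",
]


@dataclass(frozen=True)
class GeneSignature:
    """Disjoint up/down probe lists tagged with their selection method.

    ``source`` records (cohort id, sub-dataset id) — the sub-dataset id is
    ``"full"`` except for leave-one-out signatures, where it names the
    excluded patient.
    """

    up: tuple[str, ...]
    down: tuple[str, ...]
    method: str
    source: tuple[str, str] = ("cohort", "full")

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise InputError("up and down signature lists must be disjoint")

    @property
    def size(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def is_empty(self) -> bool:
        return self.size == 0


@dataclass
class SamResult:
    """Per-probe SAM statistics and the selected threshold.

    ``d`` is the regularised paired statistic mean(diff) / (s + s0); ``s`` the
    per-probe standard error of the mean difference; ``s0`` the exchangeability
    constant (log2-intensity units) chosen by the percentile rule; ``delta``
    the selection half-width; ``fdr_estimate`` the median-permutation FDR at
    that delta; ``called`` the selected probes.
    """

    d: np.ndarray
    s: np.ndarray
    s0: float
    delta: float
    fdr_estimate: float
    called: tuple[str, ...]


def preprocess_floor(
    cohort: PairedExpressionCohort, floor: float = DEFAULT_FLOOR
) -> PairedExpressionCohort:
    """Round every intensity below ``floor`` up to ``floor``.

    Low array intensities are dominated by background; flooring them keeps
    ratios of near-background probes from exploding. Returns a new cohort with
    ``floor_applied`` set; all other fields are unchanged.
    """
    if floor <= 0:
        raise InputError(f"floor must be positive, got {floor}")
    return replace(
        cohort,
        intensities=np.maximum(cohort.intensities, float(floor)),
        floor_applied=True,
    )


def probe_log_ratios(
    cohort: PairedExpressionCohort,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe paired log2 ratios.

    Returns ``(mean_ratio, diffs)`` where ``diffs`` has shape
    ``(n_probes, n_patients)`` with entry ``log2(tumor) - log2(normal)`` for
    each patient (patients in sorted-id order) and ``mean_ratio`` is its
    row mean.
    """
    if cohort.n_patients == 0:
        raise InputError("cohort has no paired patients")
    tumor, normal = cohort.paired_columns()
    diffs = np.log2(tumor) - np.log2(normal)
    return diffs.mean(axis=1), diffs


def paired_t(d_vector: np.ndarray) -> tuple[float, float]:
    """Paired t-test on a per-patient difference vector.

    Returns ``(t, p)`` with ``t = mean(d) / (sd(d)/sqrt(P))`` and a two-sided
    p-value from Student's t with ``P - 1`` degrees of freedom. Zero-variance
    vectors are degenerate: p = 0 when the mean is nonzero (infinitely
    concordant), p = 1 when all differences are zero.
    """
    d = np.asarray(d_vector, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise InputError("paired_t needs a 1-d difference vector of length >= 2")
    t, p = _paired_t_matrix(d[None, :])
    return float(t[0]), float(p[0])


def _paired_t_matrix(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised paired t over rows of a probes x patients difference matrix."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_sd = sd == 0
    inf_t = np.where(mean > 0, np.inf, -np.inf)
    t = np.where(zero_sd, np.where(mean == 0, 0.0, inf_t), t)
    p = np.where(zero_sd, np.where(mean == 0, 1.0, 0.0), p)
    return t, p


def _require_floored(cohort: PairedExpressionCohort) -> None:
    if not cohort.floor_applied:
        raise InputError("cohort must be floor-preprocessed before selection")


def _partition(
    probe_ids: np.ndarray, ratios: np.ndarray, mask: np.ndarray
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    up = tuple(probe_ids[mask & (ratios > 0)])
    down = tuple(probe_ids[mask & (ratios < 0)])
    return up, down


def select_top_n(
    cohort: PairedExpressionCohort,
    n: int = 100,
    min_fold: float = 2.0,
    source: tuple[str, str] = ("cohort", "full"),
) -> GeneSignature:
    """Top-``n`` probes by absolute mean log2 ratio among >= ``min_fold`` changers.

    Probes are first gated at ``|mean log2 ratio| >= log2(min_fold)``, then the
    ``n`` largest absolute ratios are kept (``n`` counts up and down probes
    together). Ties are broken by probe id for determinism.
    """
    _require_floored(cohort)
    mean_ratio, _ = probe_log_ratios(cohort)
    probe_ids = np.asarray(cohort.probe_ids)
    gate = np.abs(mean_ratio) >= np.log2(min_fold)
    gate &= mean_ratio != 0  # a zero ratio has no direction
    if not gate.any():
        raise EmptySignatureError(
            f"no probe changes at least {min_fold}-fold; the cohort carries no signal"
        )
    cand = np.flatnonzero(gate)
    order = np.lexsort((probe_ids[cand], -np.abs(mean_ratio[cand])))
    keep = cand[order[:n]]
    mask = np.zeros(cohort.n_probes, dtype=bool)
    mask[keep] = True
    up, down = _partition(probe_ids, mean_ratio, mask)
    return GeneSignature(up=up, down=down, method="top100", source=source)


def select_volcano(
    cohort: PairedExpressionCohort,
    p_thresh: float = 1e-4,
    min_fold: float = 2.0,
    source: tuple[str, str] = ("cohort", "full"),
) -> GeneSignature:
    """Volcano selection: paired t p < ``p_thresh`` and >= ``min_fold`` change.

    May return an empty signature when nothing passes; downstream queries
    reject empty signatures explicitly.
    """
    _require_floored(cohort)
    if cohort.n_patients < 3:
        raise InputError("volcano selection needs at least 3 patients")
    mean_ratio, diffs = probe_log_ratios(cohort)
    _, p = _paired_t_matrix(diffs)
    mask = (p < p_thresh) & (np.abs(mean_ratio) >= np.log2(min_fold)) & (mean_ratio != 0)
    up, down = _partition(np.asarray(cohort.probe_ids), mean_ratio, mask)
    return GeneSignature(up=up, down=down, method="volcano", source=source)


def leave_one_out_signatures(
    cohort: PairedExpressionCohort,
    p_thresh: float = 1e-4,
    min_fold: float = 2.0,
    cohort_id: str = "cohort",
) -> list[GeneSignature]:
    """One volcano signature per leave-one-patient-out sub-dataset.

    Excluding a whole patient (both samples) preserves the pairing structure;
    the excluded patient's id becomes the signature's sub-dataset id.
    """
    if cohort.n_patients < 4:
        raise InputError("leave-one-out needs at least 4 patients")
    return [
        select_volcano(
            cohort.drop_patient(patient),
            p_thresh=p_thresh,
            min_fold=min_fold,
            source=(cohort_id, patient),
        )
        for patient in cohort.patients
    ]


# --- paired SAM ---------------------------------------------------------------

_S0_PERCENTILES = np.arange(0, 101, 5)
_N_S_WINDOWS = 100
_DELTA_GRID_SIZE = 512


def _sam_stat(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean difference and its standard error per probe (one-class SAM)."""
    n = diffs.shape[1]
    r = diffs.mean(axis=1)
    s = diffs.std(axis=1, ddof=1) / np.sqrt(n)
    return r, s


def _regularised_d(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / denom
    # probes with zero spread and zero mean are null, not infinite
    return np.where(denom == 0, 0.0, d)


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Percentile rule: the s-percentile minimising the coefficient of
    variation of the spread of d across windows of s.

    The spread in each window is a median-absolute-deviation; ties between
    percentiles break toward the smaller one.
    """
    order = np.argsort(s, kind="stable")
    n = s.size
    edges = np.linspace(0, n, _N_S_WINDOWS + 1).astype(int)
    best_cv, best_s0 = np.inf, float(np.percentile(s, 0))
    for pct in _S0_PERCENTILES:
        s0 = float(np.percentile(s, pct))
        d = _regularised_d(r, s, s0)[order]
        mads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                w = d[lo:hi]
                mads.append(np.median(np.abs(w - np.median(w))))
        v = np.asarray(mads)
        if v.size == 0 or v.mean() == 0:
            continue
        cv = v.std(ddof=0) / v.mean()
        if cv < best_cv - 1e-12:  # strict improvement -> smaller pct wins ties
            best_cv, best_s0 = cv, s0
    return best_s0


def _cuts_for_deltas(
    d_sorted: np.ndarray, dbar: np.ndarray, deltas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric cut points for each candidate half-width delta.

    For a delta, ``cut_up`` is the smallest positive observed d whose excess
    over the permutation expectation reaches delta (+inf when none);
    ``cut_low`` the analogue on the negative side (-inf when none).
    """
    diff = d_sorted - dbar
    up_ok = (diff[None, :] >= deltas[:, None]) & (d_sorted > 0)[None, :]
    any_up = up_ok.any(axis=1)
    cut_up = np.where(any_up, d_sorted[np.argmax(up_ok, axis=1)], np.inf)
    low_ok = (diff[None, :] <= -deltas[:, None]) & (d_sorted < 0)[None, :]
    any_low = low_ok.any(axis=1)
    last_low = d_sorted.size - 1 - np.argmax(low_ok[:, ::-1], axis=1)
    cut_low = np.where(any_low, d_sorted[last_low], -np.inf)
    return cut_up, cut_low


def select_sam(
    cohort: PairedExpressionCohort,
    n_perm: int = 100,
    target_fdr: float = 0.0,
    max_size: int = 1000,
    seed: int = 0,
    source: tuple[str, str] = ("cohort", "full"),
    fdr_statistic: str = "mean",
) -> tuple[SamResult, GeneSignature]:
    """Paired SAM selection at a target permutation FDR.

    The paired design reduces to a one-class analysis of per-patient log2
    differences: d_i = mean(diff_i) / (s_i + s0), with the null generated by
    ``n_perm`` random sign-flips of the patient difference columns. For each
    candidate half-width delta, probes beyond the expected-order-statistic
    band are called, and the FDR is the permutation false-call count
    (averaged across permutations) over the observed call count. The smallest
    delta meeting ``target_fdr`` is chosen; if the call set still reaches
    ``max_size``, delta is raised until it does not.

    ``fdr_statistic`` selects how false calls are summarised across
    permutations: ``"mean"`` (the original formulation; an FDR of zero then
    demands that *no* permutation places a statistic beyond the cuts) or
    ``"median"`` (a laxer variant under which the single most extreme
    observed probe is called whenever it beats the median permutation
    extreme, i.e. about half the time on pure-null data).
    """
    if fdr_statistic not in {"mean", "median"}:
        raise InputError(f"fdr_statistic must be 'mean' or 'median', got {fdr_statistic!r}")
    _require_floored(cohort)
    if cohort.n_patients < 4:
        raise InputError("SAM needs at least 4 patients")
    _, diffs = probe_log_ratios(cohort)
    n_probes, n_pat = diffs.shape
    r, s = _sam_stat(diffs)
    s0 = _choose_s0(r, s)
    d = _regularised_d(r, s, s0)

    if np.all(d == 0):
        result = SamResult(d=d, s=s, s0=s0, delta=0.0, fdr_estimate=0.0, called=())
        return result, GeneSignature(up=(), down=(), method="sam", source=source)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_pat))
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]

    # permutation statistics, each sorted; accumulate the expected order stats
    perm_sorted = np.empty((n_perm, n_probes))
    for b in range(n_perm):
        flipped = diffs * signs[b]
        rb, sb = _sam_stat(flipped)
        perm_sorted[b] = np.sort(_regularised_d(rb, sb, s0))
    dbar = perm_sorted.mean(axis=0)

    gaps = np.abs(d_sorted - dbar)
    qs = np.linspace(0.0, 1.0, _DELTA_GRID_SIZE)
    grid = np.unique(np.concatenate([[0.0], np.quantile(gaps, qs)]))

    cut_up, cut_low = _cuts_for_deltas(d_sorted, dbar, grid)
    # calls among observed statistics, false calls per permutation row
    n_called = (
        d_sorted.size
        - np.searchsorted(d_sorted, cut_up, side="left")
        + np.searchsorted(d_sorted, cut_low, side="right")
    )
    false_per_b = np.empty((n_perm, grid.size))
    for b in range(n_perm):
        row = perm_sorted[b]
        false_per_b[b] = (
            row.size
            - np.searchsorted(row, cut_up, side="left")
            + np.searchsorted(row, cut_low, side="right")
        )
    summarise = np.mean if fdr_statistic == "mean" else np.median
    false_calls = summarise(false_per_b, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr_grid = np.where(n_called == 0, 0.0, false_calls / np.maximum(n_called, 1))

    ok = fdr_grid <= target_fdr
    if not ok.any():  # no delta meets the target: call nothing
        result = SamResult(d=d, s=s, s0=s0, delta=float(grid[-1]), fdr_estimate=1.0, called=())
        return result, GeneSignature(up=(), down=(), method="sam", source=source)
    i = int(np.argmax(ok))  # smallest qualifying delta
    while n_called[i] >= max_size and i + 1 < grid.size:
        i += 1  # raise delta until the call set is below the size cap
    delta, fdr = float(grid[i]), float(fdr_grid[i])
    cut_up, cut_low = float(cut_up[i]), float(cut_low[i])
    called_mask = (d >= cut_up) | (d <= cut_low)
    probe_ids = np.asarray(cohort.probe_ids)
    up = tuple(probe_ids[called_mask & (d > 0)])
    down = tuple(probe_ids[called_mask & (d < 0)])
    result = SamResult(
        d=d,
        s=s,
        s0=s0,
        delta=delta,
        fdr_estimate=fdr,
        called=tuple(probe_ids[called_mask]),
    )
    return result, GeneSignature(up=up, down=down, method="sam", source=source)
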