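"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline end to end:

* paired tumor/normal cohorts with planted differentially expressed probes
  (log-normal intensities, shared per-patient baselines, per-sample noise);
* a drug-perturbation rank reference in which one designated drug *reverses*
  the planted signature (planted tumor-up probes pushed into the bottom
  decile of its rankings, tumor-down probes into the top decile) while all
  decoy drugs rank probes uniformly at random;
* dose-response and constant-ratio combination series drawn from the
  median-effect model with known slope and median-effect dose.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PairedExpressionCohort
from .connectivity import PerturbationReference
from .errors import ConfigurationError, InputError
from .synergy import FA_CLIP as _FA_CLIP
from .synergy import DoseResponseSeries

__all__ = [
    "SimulationConfig",
    "generate_paired_cohort",
    "generate_study",
    "generate_reference",
    "generate_dose_response",
    "generate_combination",
    "DoseResponseSeries",
    "PLANTED_DRUG",
]

#: Label of the designated signature-reversing drug in synthetic references.
PLANTED_DRUG = "planted-reversal"


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic paired cohort.

    Defaults emulate a lung-adenocarcinoma microarray cohort: 24 patients
    (48 arrays), 5000 probesets with a log2-normal baseline N(8, 1), one
    hundred planted up- and one hundred planted down-regulated probes at a
    log2 effect of 1.5 (≈2.8-fold), per-sample noise SD 0.5 and a
    per-patient baseline shift SD 0.5 shared by the two arrays of a patient.
    """

    n_patients: int = 24
    n_probes: int = 5000
    n_up: int = 100
    n_down: int = 100
    effect_size: float = 1.5
    noise_sd: float = 0.5
    patient_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.n_probes < 1:
            raise ConfigurationError(f"n_probes must be >= 1, got {self.n_probes}")
        if self.n_up < 0 or self.n_down < 0:
            raise ConfigurationError("n_up and n_down must be non-negative")
        if self.n_up + self.n_down > self.n_probes:
            raise ConfigurationError(
                f"n_up + n_down = {self.n_up + self.n_down} exceeds n_probes = {self.n_probes}"
            )
        if self.effect_size <= 0:
            raise ConfigurationError(f"effect_size must be > 0, got {self.effect_size}")
        if self.noise_sd < 0 or self.patient_sd < 0:
            raise ConfigurationError("noise_sd and patient_sd must be >= 0")


def _probe_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"probe_{i:0{width}d}" for i in range(n)]


def generate_paired_cohort(
    cfg: SimulationConfig,
    planted: tuple[list[str], list[str]] | None = None,
) -> PairedExpressionCohort:
    """Simulate a paired tumor/normal cohort with planted signal.

    On the log2 scale each probe draws a baseline, each patient a shared
    baseline shift applied to both of their samples, and each measurement
    independent noise; planted up (down) probes add +effect_size
    (-effect_size) to the tumor sample only, so the expected paired log2
    ratio is exactly ±effect_size. Intensities are 2**(log2 value), hence
    strictly positive with a realistic sub-floor left tail.

    ``planted`` optionally fixes the planted probe identities (used to share
    ground truth across the cohorts of a study); by default they are drawn
    from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    probes = _probe_ids(cfg.n_probes)
    probe_arr = np.asarray(probes)

    if planted is None:
        chosen = rng.choice(cfg.n_probes, size=cfg.n_up + cfg.n_down, replace=False)
        up_ids = sorted(probe_arr[chosen[: cfg.n_up]])
        down_ids = sorted(probe_arr[chosen[cfg.n_up :]])
    else:
        up_ids, down_ids = sorted(planted[0]), sorted(planted[1])
        known = set(probes)
        if not set(up_ids) <= known or not set(down_ids) <= known:
            raise InputError("planted probes must belong to the generated universe")
        if set(up_ids) & set(down_ids):
            raise InputError("planted up and down sets must be disjoint")
    up_mask = np.isin(probe_arr, up_ids)
    down_mask = np.isin(probe_arr, down_ids)
    effect = np.where(up_mask, cfg.effect_size, 0.0) - np.where(down_mask, cfg.effect_size, 0.0)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_probes)
    shifts = rng.normal(0.0, cfg.patient_sd, size=cfg.n_patients)

    width = len(str(cfg.n_patients))
    sample_ids: list[str] = []
    pairing: dict[str, tuple[str, str]] = {}
    cols = np.empty((cfg.n_probes, 2 * cfg.n_patients))
    for k in range(cfg.n_patients):
        pid = f"patient_{k:0{width}d}"
        t_id, n_id = f"{pid}_T", f"{pid}_N"
        base_k = baseline + shifts[k]
        cols[:, 2 * k] = base_k + effect + rng.normal(0.0, cfg.noise_sd, cfg.n_probes)
        cols[:, 2 * k + 1] = base_k + rng.normal(0.0, cfg.noise_sd, cfg.n_probes)
        sample_ids += [t_id, n_id]
        pairing[pid] = (t_id, n_id)

    return PairedExpressionCohort(
        probe_ids=probes,
        intensities=np.exp2(cols),
        sample_ids=sample_ids,
        pairing=pairing,
        platform_label="synthetic",
        planted_up=list(up_ids),
        planted_down=list(down_ids),
    )


def generate_study(
    cfg: SimulationConfig, n_cohorts: int = 3
) -> list[PairedExpressionCohort]:
    """Several cohorts of the same disease: shared planted probes, independent
    patients and noise (cohort k uses seed ``cfg.seed + k``)."""
    first = generate_paired_cohort(cfg)
    planted = (first.planted_up or [], first.planted_down or [])
    cohorts = [first]
    for k in range(1, n_cohorts):
        cfg_k = SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
        cohorts.append(generate_paired_cohort(cfg_k, planted=planted))
    return cohorts


def generate_reference(
    probe_universe: list[str],
    planted_up: list[str],
    planted_down: list[str],
    n_drugs: int = 50,
    instances_per_drug: int = 4,
    reversal_strength: float = 0.8,
    seed: int = 0,
) -> PerturbationReference:
    """Perturbation reference with one planted signature-reversing drug.

    Every instance is a full permutation of the probe universe. For the
    planted drug a fraction ``reversal_strength`` of the planted tumor-up
    probes is placed uniformly in the bottom decile of its ranking (the drug
    down-regulates them) and the same fraction of tumor-down probes in the
    top decile; all remaining probes, and every decoy-drug instance, are
    ranked uniformly at random.
    """
    if not 0.0 <= reversal_strength <= 1.0:
        raise ConfigurationError(f"reversal_strength must be in [0, 1], got {reversal_strength}")
    if n_drugs < 1 or instances_per_drug < 1:
        raise ConfigurationError("n_drugs and instances_per_drug must be >= 1")
    universe = list(probe_universe)
    index = {p: j for j, p in enumerate(universe)}
    for p in list(planted_up) + list(planted_down):
        if p not in index:
            raise InputError(f"planted probe {p!r} not in the reference universe")
    n = len(universe)
    decile = max(1, n // 10)
    rng = np.random.default_rng(seed)

    width = len(str(n_drugs))
    drug_names = [PLANTED_DRUG] + [f"decoy_{i:0{width}d}" for i in range(1, n_drugs)]
    up_idx = np.asarray([index[p] for p in planted_up], dtype=np.int64)
    down_idx = np.asarray([index[p] for p in planted_down], dtype=np.int64)

    instance_ids: list[str] = []
    drug_labels: list[str] = []
    rows = []
    for drug in drug_names:
        for r in range(instances_per_drug):
            instance_ids.append(f"{drug}.{r}")
            drug_labels.append(drug)
            if drug == PLANTED_DRUG:
                rows.append(
                    _planted_instance(n, decile, up_idx, down_idx, reversal_strength, rng)
                )
            else:
                rows.append(rng.permutation(n) + 1)
    return PerturbationReference(
        probe_universe=universe,
        instance_ids=instance_ids,
        drug_labels=drug_labels,
        ranks=np.vstack(rows),
        planted_drug=PLANTED_DRUG,
    )


def _planted_instance(
    n: int,
    decile: int,
    up_idx: np.ndarray,
    down_idx: np.ndarray,
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n_up = int(round(strength * up_idx.size))
    n_down = int(round(strength * down_idx.size))
    chosen_up = rng.choice(up_idx, size=n_up, replace=False) if n_up else np.empty(0, dtype=np.int64)
    chosen_down = rng.choice(down_idx, size=n_down, replace=False) if n_down else np.empty(0, dtype=np.int64)
    ranks = np.zeros(n, dtype=np.int64)
    bottom = rng.choice(np.arange(n - decile + 1, n + 1), size=n_up, replace=False)
    top = rng.choice(np.arange(1, decile + 1), size=n_down, replace=False)
    ranks[chosen_up] = bottom
    ranks[chosen_down] = top
    free = ranks == 0
    used = set(bottom.tolist()) | set(top.tolist())
    remaining = np.asarray([r for r in range(1, n + 1) if r not in used], dtype=np.int64)
    ranks[free] = rng.permutation(remaining)
    return ranks


# --- dose-response ------------------------------------------------------------


def median_effect_fa(doses: np.ndarray, m: float, dm: float) -> np.ndarray:
    """Fraction affected under the median-effect model fa/fu = (D/Dm)^m."""
    ratio = (np.asarray(doses, dtype=float) / dm) ** m
    return ratio / (1.0 + ratio)


def generate_dose_response(
    m: float,
    dm: float,
    doses: list[float] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug: str = "drug",
) -> DoseResponseSeries:
    """Viability series from the median-effect model, noisy on the logit scale.

    Gaussian noise of SD ``noise_sd`` is added to log10(fa/(1-fa)) — the scale
    on which the model is linear in log dose — and fa is clipped to
    (1e-6, 1-1e-6).
    """
    if m == 0:
        raise ConfigurationError("slope m must be nonzero")
    if dm <= 0:
        raise ConfigurationError(f"median-effect dose must be positive, got {dm}")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise InputError("all doses must be positive")
    rng = np.random.default_rng(seed)
    fa = median_effect_fa(doses, m, dm)
    if noise_sd > 0:
        logit = np.log10(fa / (1.0 - fa)) + rng.normal(0.0, noise_sd, size=fa.shape)
        fa = 10.0**logit / (1.0 + 10.0**logit)
    fa = np.clip(fa, _FA_CLIP, 1.0 - _FA_CLIP)
    return DoseResponseSeries(drug=drug, doses=doses, fa=fa)


def generate_combination(
    m1: float,
    dm1: float,
    m2: float,
    dm2: float,
    ratio: float,
    total_doses: list[float] | np.ndarray,
    mode: str = "additive",
    potency_shift: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponseSeries:
    """Constant-ratio combination series with a known interaction.

    For total dose D the components are d1 = D/(1+ratio) and d2 = D·ratio/(1+ratio)
    (``ratio`` = d2/d1). In ``additive`` mode the fraction affected solves the
    Loewe additivity condition d1/Dx1(fa) + d2/Dx2(fa) = 1 exactly, so the
    combination index is 1 by construction. ``synergistic`` (``antagonistic``)
    mode evaluates the additive curve at D·potency_shift (D/potency_shift),
    i.e. the mixture behaves as if ``potency_shift``-fold more (less) potent,
    driving CI below (above) 1.
    """
    from scipy.optimize import brentq

    if ratio <= 0:
        raise ConfigurationError("ratio must be positive")
    if mode not in {"additive", "synergistic", "antagonistic"}:
        raise ConfigurationError(f"unknown combination mode {mode!r}")
    total = np.asarray(total_doses, dtype=float)
    if np.any(total <= 0):
        raise InputError("all doses must be positive")
    shift = {"additive": 1.0, "synergistic": potency_shift, "antagonistic": 1.0 / potency_shift}[mode]

    def loewe_fa(d_total: float) -> float:
        d1 = d_total / (1.0 + ratio)
        d2 = d_total * ratio / (1.0 + ratio)

        def g(fa: float) -> float:
            dx1 = dm1 * (fa / (1.0 - fa)) ** (1.0 / m1)
            dx2 = dm2 * (fa / (1.0 - fa)) ** (1.0 / m2)
            return d1 / dx1 + d2 / dx2 - 1.0

        return brentq(g, _FA_CLIP, 1.0 - _FA_CLIP, xtol=1e-14, rtol=1e-15)

    fa = np.asarray([loewe_fa(d * shift) for d in total])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        logit = np.log10(fa / (1.0 - fa)) + rng.normal(0.0, noise_sd, size=fa.shape)
        fa = 10.0**logit / (1.0 + 10.0**logit)
    fa = np.clip(fa, _FA_CLIP, 1.0 - _FA_CLIP)
    return DoseResponseSeries(
        drug="combination",
        doses=total,
        fa=fa,
        d1=total / (1.0 + ratio),
        d2=total * ratio / (1.0 + ratio),
    )
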