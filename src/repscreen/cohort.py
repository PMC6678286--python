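"""Paired tumor/normal expression cohorts.

The atomic measurement unit is the probeset; a cohort holds a probes x samples
intensity matrix together with the patient pairing (each patient contributes
exactly one tumor and one adjacent-normal sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

#: Default intensity floor: sub-floor array intensities are rounded up to this
#: value before any ratio is computed.
DEFAULT_FLOOR = 50.0


@dataclass
class PairedExpressionCohort:
    """Probeset x sample intensity matrix with tumor/normal pairing.

    Parameters
    ----------
    probe_ids
        Ordered probe identifiers (opaque strings), unique.
    intensities
        Array of shape ``(n_probes, n_samples)`` of strictly positive
        intensities on the raw (linear) scale.
    sample_ids
        Column labels of ``intensities``.
    pairing
        Mapping ``patient_id -> (tumor_sample_id, normal_sample_id)``.
    platform_label
        Free-text platform annotation.
    floor_applied
        Whether :func:`repscreen.signatures.preprocess_floor` has run.
    planted_up, planted_down
        Ground-truth differentially expressed probes for synthetic cohorts
        (tumor-up and tumor-down); ``None`` for real data.
    """

    probe_ids: list[str]
    intensities: np.ndarray
    sample_ids: list[str]
    pairing: dict[str, tuple[str, str]]
    platform_label: str = ""
    floor_applied: bool = False
    planted_up: list[str] | None = None
    planted_down: list[str] | None = None
    _sample_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise InputError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise InputError("duplicate probe identifiers in cohort")
        if not np.all(self.intensities > 0):
            raise InputError("cohort intensities must be strictly positive")
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}
        seen: set[str] = set()
        for patient, (tum, norm) in self.pairing.items():
            for s in (tum, norm):
                if s not in self._sample_index:
                    raise InputError(f"pairing for patient {patient!r} references unknown sample {s!r}")
                if s in seen:
                    raise InputError(f"sample {s!r} appears in more than one pair")
                seen.add(s)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_patients(self) -> int:
        return len(self.pairing)

    @property
    def patients(self) -> list[str]:
        """Patient identifiers in sorted order (deterministic)."""
        return sorted(self.pairing)

    def paired_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (tumor, normal) matrices aligned as probes x patients."""
        pts = self.patients
        t_idx = [self._sample_index[self.pairing[p][0]] for p in pts]
        n_idx = [self._sample_index[self.pairing[p][1]] for p in pts]
        return self.intensities[:, t_idx], self.intensities[:, n_idx]

    def drop_patient(self, patient_id: str) -> "PairedExpressionCohort":
        """Cohort with one patient (both samples) removed; pairing preserved."""
        if patient_id not in self.pairing:
            raise InputError(f"unknown patient {patient_id!r}")
        drop = set(self.pairing[patient_id])
        keep = [j for j, s in enumerate(self.sample_ids) if s not in drop]
        return replace(
            self,
            intensities=self.intensities[:, keep],
            sample_ids=[self.sample_ids[j] for j in keep],
            pairing={p: v for p, v in self.pairing.items() if p != patient_id},
        )
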