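"""Readers and writers for the pipeline's text formats.

Formats: GCT 1.2 expression matrices (with a pairing sidecar TSV), GRP probe
lists, GMT gene-set collections, the TSV rank matrix + instance metadata of a
perturbation reference, and dose-response CSVs. Readers reject malformed
files rather than repairing them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PairedExpressionCohort
from .connectivity import PerturbationReference
from .errors import ParseError
from .signatures import GeneSignature
from .synergy import DoseResponseSeries

__all__ = [
    "read_gct",
    "write_gct",
    "read_pairing",
    "write_pairing",
    "read_grp",
    "write_grp",
    "read_gmt",
    "write_gmt",
    "read_signature",
    "write_signature",
    "read_reference",
    "write_reference",
    "read_dose_response",
    "write_dose_response",
]


# --- GCT / pairing ------------------------------------------------------------

def read_gct(path: str | Path, pairing_path: str | Path) -> PairedExpressionCohort:
    """Read a GCT 1.2 (or headered TSV) expression matrix plus pairing sidecar.

    The sidecar is a TSV with columns patient_id, tumor_sample, normal_sample.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    if lines[0].strip() == "#1.2":
        if len(lines) < 3:
            raise ParseError(f"{path}: truncated GCT header")
        try:
            n_probes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
        except ValueError as exc:
            raise ParseError(f"{path}: line 2: malformed dimensions line") from exc
        header = lines[2].split("\t")
        if len(header) != n_samples + 2:
            raise ParseError(
                f"{path}: line 3: header names {len(header) - 2} samples, dims line says {n_samples}"
            )
        body = lines[3:]
        if len(body) != n_probes:
            raise ParseError(
                f"{path}: line {len(lines)}: {len(body)} data rows, dims line says {n_probes}"
            )
        sample_ids = header[2:]
        desc_cols = 1
    else:  # plain TSV: probe_id then sample columns
        header = lines[0].split("\t")
        sample_ids = header[1:]
        body = lines[1:]
        desc_cols = 0

    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for i, line in enumerate(body):
        parts = line.split("\t")
        if len(parts) != len(sample_ids) + 1 + desc_cols:
            raise ParseError(f"{path}: line {i + 2 + 2 * desc_cols}: wrong column count")
        probe = parts[0]
        if probe in set(probe_ids):
            raise ParseError(f"{path}: duplicate probe {probe!r}")
        probe_ids.append(probe)
        try:
            rows.append([float(x) for x in parts[1 + desc_cols :]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 2 + 2 * desc_cols}: non-numeric intensity") from exc

    pairing = read_pairing(pairing_path)
    return PairedExpressionCohort(
        probe_ids=probe_ids,
        intensities=np.asarray(rows),
        sample_ids=sample_ids,
        pairing=pairing,
    )


def write_gct(cohort: PairedExpressionCohort, path: str | Path) -> None:
    """Write a cohort as GCT 1.2 (Description column repeats the probe id)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{cohort.n_probes}\t{len(cohort.sample_ids)}\n")
        fh.write("Name\tDescription\t" + "\t".join(cohort.sample_ids) + "\n")
        for i, probe in enumerate(cohort.probe_ids):
            values = "\t".join(f"{x:.6f}" for x in cohort.intensities[i])
            fh.write(f"{probe}\t{probe}\t{values}\n")


def read_pairing(path: str | Path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "tumor_sample", "normal_sample"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: pairing sidecar needs columns {sorted(required)}")
    return {
        r.patient_id: (r.tumor_sample, r.normal_sample) for r in df.itertuples()
    }


def write_pairing(cohort: PairedExpressionCohort, path: str | Path) -> None:
    rows = [
        {"patient_id": p, "tumor_sample": t, "normal_sample": n}
        for p, (t, n) in sorted(cohort.pairing.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- GRP / GMT ----------------------------------------------------------------

def read_grp(path: str | Path) -> list[str]:
    """Read a GRP probe list: one id per line, '#' comments and blanks skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if not out:
        raise ParseError(f"{path}: GRP file contains no identifiers")
    return out


def write_grp(probes: list[str] | tuple[str, ...], path: str | Path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in probes))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT collection: set name, description, then members, tab-separated."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {i}: GMT needs name, description, members")
        members = [m for m in parts[2:] if m]
        if not members:
            raise ParseError(f"{path}: line {i}: gene set {parts[0]!r} is empty")
        sets[parts[0]] = members
    if not sets:
        raise ParseError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_signature(up_path: str | Path, down_path: str | Path, method: str = "top100") -> GeneSignature:
    return GeneSignature(
        up=tuple(read_grp(up_path)), down=tuple(read_grp(down_path)), method=method
    )


def write_signature(sig: GeneSignature, out_dir: str | Path, name: str) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    up_path, down_path = out_dir / f"{name}_up.grp", out_dir / f"{name}_down.grp"
    write_grp(sig.up, up_path)
    write_grp(sig.down, down_path)
    return up_path, down_path


# --- perturbation reference ---------------------------------------------------

def write_reference(ref: PerturbationReference, rank_path: str | Path, meta_path: str | Path) -> None:
    """Rank matrix TSV (rows = probes, columns = instances) + metadata TSV."""
    pd.DataFrame(
        ref.ranks.T, index=pd.Index(ref.probe_universe, name="probe_id"),
        columns=ref.instance_ids,
    ).to_csv(rank_path, sep="\t")
    pd.DataFrame(
        {"instance_id": ref.instance_ids, "drug": ref.drug_labels, "batch": 1}
    ).to_csv(meta_path, sep="\t", index=False)


def read_reference(rank_path: str | Path, meta_path: str | Path) -> PerturbationReference:
    ranks = pd.read_csv(rank_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"instance_id": str, "drug": str})
    if not {"instance_id", "drug"} <= set(meta.columns):
        raise ParseError(f"{meta_path}: metadata needs instance_id and drug columns")
    if list(ranks.columns) != list(meta["instance_id"]):
        raise ParseError(f"{rank_path}: instance columns do not match {meta_path}")
    # construction validates that each instance is a tie-free permutation
    return PerturbationReference(
        probe_universe=list(ranks.index.astype(str)),
        instance_ids=list(ranks.columns),
        drug_labels=list(meta["drug"]),
        ranks=ranks.to_numpy().T,
    )


# --- dose-response ------------------------------------------------------------

def read_dose_response(path: str | Path, drug: str | None = None) -> DoseResponseSeries:
    """CSV with columns dose, fa (and optionally drug, d1, d2)."""
    df = pd.read_csv(path)
    if not {"dose", "fa"} <= set(df.columns):
        raise ParseError(f"{path}: dose-response CSV needs dose and fa columns")
    if drug is None:
        drug = str(df["drug"].iloc[0]) if "drug" in df.columns else Path(path).stem
    kwargs = {}
    if {"d1", "d2"} <= set(df.columns):
        kwargs = {"d1": df["d1"].to_numpy(float), "d2": df["d2"].to_numpy(float)}
    return DoseResponseSeries(
        drug=drug, doses=df["dose"].to_numpy(float), fa=df["fa"].to_numpy(float), **kwargs
    )


def write_dose_response(series: DoseResponseSeries, path: str | Path) -> None:
    df = series.to_frame()
    if series.d1 is not None:
        df["d1"], df["d2"] = series.d1, series.d2
    # full precision: constant-ratio designs are checked to 1e-9 on re-read
    df.to_csv(path, index=False, float_format="%.17g")
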