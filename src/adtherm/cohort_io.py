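"""Reading, writing and validating cohort recordings on disk.

A cohort directory holds:

* ``signals.csv`` — long format, one row per (pixel, time point), header
  ``dog_id,mass_id,region,pixel_row,pixel_col,time_s,temp_c`` with
  region in {site, control};
* ``manifest.json`` — labels, tumor type names, the protocol, and an echo
  of the generating config (when the cohort was simulated).

Floats are written with ``repr`` round-trip precision, UTF-8, LF endings.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CohortConfig, MassRecord, Protocol, ThermalSignal

__all__ = ["write_cohort", "read_cohort", "validate_cohort_files"]

SIGNAL_COLUMNS = ["dog_id", "mass_id", "region", "pixel_row", "pixel_col", "time_s", "temp_c"]


def _signal_rows(record: MassRecord, region: str, grid, grid_side: int):
    for idx, signal in enumerate(grid):
        row, col = divmod(idx, grid_side)
        for t, temp in zip(signal.times, signal.temperatures):
            yield (record.dog_id, record.mass_id, region, row, col, repr(float(t)), repr(float(temp)))


def write_cohort(
    records: list[MassRecord],
    out_dir: str | Path,
    protocol: Protocol | None = None,
    config: CohortConfig | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write a cohort to ``out_dir`` (created if absent); returns the path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if protocol is None and config is not None:
        protocol = config.protocol

    with open(out / "signals.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(SIGNAL_COLUMNS) + "\n")
        for record in records:
            side = record.grid_side
            for region, grid in (("site", record.site_grid), ("control", record.control_grid)):
                for row in _signal_rows(record, region, grid, side):
                    fh.write(",".join(str(v) for v in row) + "\n")

    manifest = {
        "masses": [
            {
                "dog_id": r.dog_id,
                "mass_id": r.mass_id,
                "label": r.label,
                "tumor_type_name": r.tumor_type_name,
            }
            for r in records
        ],
        "protocol": dataclasses.asdict(protocol) if protocol is not None else None,
        "config": _config_dict(config) if config is not None else None,
        "config_hash": config_hash,
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _config_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["masses_per_dog_probs"] = list(d["masses_per_dog_probs"])
    return d


def read_cohort(cohort_dir: str | Path) -> tuple[list[MassRecord], dict]:
    """Read a cohort directory back into MassRecords plus the manifest dict."""
    cohort_dir = Path(cohort_dir)
    df = pd.read_csv(cohort_dir / "signals.csv", float_precision="round_trip")
    with open(cohort_dir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)

    proto = manifest.get("protocol")
    if proto is not None:
        heat_end = Protocol(**proto).heat_end_index
    else:
        heat_end = None

    labels = {m["mass_id"]: m for m in manifest["masses"]}
    records = []
    for mass_id, mass_df in df.groupby("mass_id", sort=False):
        meta = labels[mass_id]
        grids = {}
        for region, region_df in mass_df.groupby("region"):
            pixels = []
            for (row, col), pix_df in region_df.groupby(["pixel_row", "pixel_col"]):
                times = pix_df["time_s"].to_numpy()
                order = np.argsort(times)
                times = times[order]
                temps = pix_df["temp_c"].to_numpy()[order]
                he = heat_end if heat_end is not None else len(times)
                pixels.append(((row, col), ThermalSignal(times, temps, he)))
            pixels.sort(key=lambda item: item[0])  # row-major
            grids[region] = tuple(sig for _, sig in pixels)
        records.append(
            MassRecord(
                dog_id=meta["dog_id"],
                mass_id=mass_id,
                site_grid=grids["site"],
                control_grid=grids["control"],
                label=meta["label"],
                tumor_type_name=meta.get("tumor_type_name", ""),
            )
        )
    return records, manifest


def validate_cohort_files(cohort_dir: str | Path) -> list[dict]:
    """Check a cohort directory; returns a machine-readable list of issues.

    Issues (each a dict with ``kind``, ``detail`` and, where applicable,
    ``mass_id``) are data, not exceptions: an empty list means the cohort
    passed.  Checks: CSV schema, grid completeness (grid_side^2 pixels per
    region), label presence, and time-axis uniformity.
    """
    cohort_dir = Path(cohort_dir)
    issues: list[dict] = []
    csv_path = cohort_dir / "signals.csv"
    manifest_path = cohort_dir / "manifest.json"
    if not csv_path.exists():
        return [{"kind": "missing_file", "detail": str(csv_path)}]
    if not manifest_path.exists():
        return [{"kind": "missing_file", "detail": str(manifest_path)}]

    df = pd.read_csv(csv_path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        return [{"kind": "bad_schema", "detail": f"missing columns: {missing}"}]

    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    proto = manifest.get("protocol")
    expected_pixels = Protocol(**proto).n_pixels if proto else None

    manifest_masses = {m["mass_id"]: m for m in manifest.get("masses", [])}
    for mass_id, meta in manifest_masses.items():
        if meta.get("label") not in ("benign", "malignant"):
            issues.append(
                {"kind": "missing_label", "mass_id": mass_id,
                 "detail": f"label={meta.get('label')!r}"}
            )

    for mass_id, mass_df in df.groupby("mass_id", sort=False):
        if mass_id not in manifest_masses:
            issues.append(
                {"kind": "unlisted_mass", "mass_id": str(mass_id),
                 "detail": "mass present in signals.csv but not in manifest"}
            )
        for region in ("site", "control"):
            region_df = mass_df[mass_df["region"] == region]
            if region_df.empty:
                issues.append(
                    {"kind": "missing_region", "mass_id": str(mass_id), "detail": region}
                )
                continue
            pixel_groups = region_df.groupby(["pixel_row", "pixel_col"])
            n_pixels = pixel_groups.ngroups
            if expected_pixels is not None and n_pixels != expected_pixels:
                issues.append(
                    {"kind": "incomplete_grid", "mass_id": str(mass_id),
                     "detail": f"{region}: {n_pixels} pixels, expected {expected_pixels}"}
                )
            lengths = pixel_groups.size()
            if lengths.nunique() > 1:
                issues.append(
                    {"kind": "incomplete_grid", "mass_id": str(mass_id),
                     "detail": f"{region}: unequal sample counts across pixels"}
                )
            for (row, col), pix_df in pixel_groups:
                t = np.sort(pix_df["time_s"].to_numpy())
                if len(t) >= 3:
                    dt = np.diff(t)
                    if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * max(dt.mean(), 1e-12):
                        issues.append(
                            {"kind": "non_uniform_sampling", "mass_id": str(mass_id),
                             "detail": f"{region} pixel ({row},{col})"}
                        )
    return issues
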