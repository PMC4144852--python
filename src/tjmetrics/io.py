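"""File formats: multi-channel TIFF + sidecar JSON, truth-network JSON, and
the CSV schemas for electrophysiology records, flux series and morphometry
outputs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .barrier import ElectroRecord, IonSolution
from .network import JunctionNetwork
from .simulate.monolayer import MonolayerSpec, SyntheticImage

ELECTRO_COLUMNS = [
    "raw_resistance_ohm",
    "blank_resistance_ohm",
    "raw_potential_mV",
    "blank_potential_mV",
    "area_cm2",
    "apical_na_mM",
    "apical_k_mM",
    "apical_cl_mM",
    "basolateral_na_mM",
    "basolateral_k_mM",
    "basolateral_cl_mM",
    "temperature_K",
]


# ------------------------------------------------------------------- images


def write_image(path: str | Path, image: SyntheticImage) -> None:
    """Write channels as a multi-page TIFF plus a sidecar JSON with the
    generator spec, seed, channel names and pixel size."""
    path = Path(path)
    stack = np.stack([image.channels[name] for name in sorted(image.channels)])
    res = 1.0 / image.pixel_size_um  # pixels per micrometre
    tifffile.imwrite(
        path,
        stack.astype(np.float32),
        resolution=(res, res),
        metadata={"axes": "CYX", "unit": "um"},
    )
    sidecar = {
        "pixel_size_um": image.pixel_size_um,
        "channel_names": sorted(image.channels),
        "spec": dataclasses.asdict(image.spec),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path: str | Path) -> tuple[dict[str, np.ndarray], float, dict]:
    """Read a TIFF written by :func:`write_image`.

    Returns (channels, pixel_size_um, sidecar dict)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i] for i, name in enumerate(sidecar["channel_names"])}
    return channels, float(sidecar["pixel_size_um"]), sidecar


def write_network(path: str | Path, network: JunctionNetwork) -> None:
    Path(path).write_text(network.to_json())


def read_network(path: str | Path) -> JunctionNetwork:
    return JunctionNetwork.from_json(Path(path).read_text())


# ------------------------------------------------------------------ electro


def electro_records_to_frame(records: list[ElectroRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "raw_resistance_ohm": r.raw_resistance_ohm,
                "blank_resistance_ohm": r.blank_resistance_ohm,
                "raw_potential_mV": r.raw_potential_mV,
                "blank_potential_mV": r.blank_potential_mV,
                "area_cm2": r.area_cm2,
                "apical_na_mM": r.apical.na_mM,
                "apical_k_mM": r.apical.k_mM,
                "apical_cl_mM": r.apical.cl_mM,
                "basolateral_na_mM": r.basolateral.na_mM,
                "basolateral_k_mM": r.basolateral.k_mM,
                "basolateral_cl_mM": r.basolateral.cl_mM,
                "temperature_K": r.temperature_K,
            }
        )
    return pd.DataFrame(rows, columns=ELECTRO_COLUMNS)


def electro_records_from_frame(df: pd.DataFrame) -> list[ElectroRecord]:
    missing = set(ELECTRO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"electro CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ElectroRecord(
                raw_resistance_ohm=float(row.raw_resistance_ohm),
                blank_resistance_ohm=float(row.blank_resistance_ohm),
                raw_potential_mV=float(row.raw_potential_mV),
                blank_potential_mV=float(row.blank_potential_mV),
                area_cm2=float(row.area_cm2),
                apical=IonSolution(
                    na_mM=float(row.apical_na_mM),
                    k_mM=float(row.apical_k_mM),
                    cl_mM=float(row.apical_cl_mM),
                ),
                basolateral=IonSolution(
                    na_mM=float(row.basolateral_na_mM),
                    k_mM=float(row.basolateral_k_mM),
                    cl_mM=float(row.basolateral_cl_mM),
                ),
                temperature_K=float(row.temperature_K),
            )
        )
    return records


def write_electro_csv(path: str | Path, records: list[ElectroRecord]) -> None:
    electro_records_to_frame(records).to_csv(path, index=False)


def read_electro_csv(path: str | Path) -> list[ElectroRecord]:
    return electro_records_from_frame(pd.read_csv(path))


# --------------------------------------------------------------------- flux


def write_flux_csv(path: str | Path, times_h, fluorescence, C0_mM, area_cm2) -> None:
    df = pd.DataFrame({"time_h": times_h, "fluorescence": fluorescence})
    df["C0_mM"] = C0_mM
    df["area_cm2"] = area_cm2
    df.to_csv(path, index=False)


def read_flux_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, float]:
    df = pd.read_csv(path)
    for col in ("time_h", "fluorescence", "C0_mM", "area_cm2"):
        if col not in df.columns:
            raise ValueError(f"flux CSV missing column {col!r}")
    return (
        df["time_h"].to_numpy(float),
        df["fluorescence"].to_numpy(float),
        float(df["C0_mM"].iloc[0]),
        float(df["area_cm2"].iloc[0]),
    )


def write_standards_csv(path: str | Path, amounts_nmol, fluorescence) -> None:
    pd.DataFrame(
        {"amount_nmol": amounts_nmol, "fluorescence": fluorescence}
    ).to_csv(path, index=False)


def read_standards_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["amount_nmol"].to_numpy(float), df["fluorescence"].to_numpy(float)


# -------------------------------------------------------------- morphometry


def morphometry_to_frame(network: JunctionNetwork, morphometry, window_membership=None):
    """Per-side CSV rows: side_id, L_TJ_um, L_St_um, border, window_ids."""
    memb: dict[int, list[int]] = {}
    if window_membership:
        for w_idx, ids in enumerate(window_membership):
            for sid in ids:
                memb.setdefault(sid, []).append(w_idx)
    rows = []
    for sid, m in sorted(morphometry.items()):
        rows.append(
            {
                "side_id": sid,
                "L_TJ_um": m.L_TJ_um,
                "L_St_um": m.L_St_um,
                "border": network.sides[sid].border,
                "window_ids": ";".join(map(str, memb.get(sid, []))),
            }
        )
    return pd.DataFrame(rows)
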