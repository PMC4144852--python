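"""End-to-end orchestration: simulate -> measure -> barrier -> compare.

The pipeline is driven by a single JSON-able config dict and emits a
machine-readable report (JSON) plus per-stage CSVs.  Every seed is derived
deterministically from the config's base seed, so identical configs yield
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .barrier import FluxSeries, analyze_record, dextran_papp, fit_standard_curve
from .io import morphometry_to_frame
from .morphometry import extract_network, sample_windows, segment_junctions
from .morphometry.zigzag import clone_zigzag_summary, compute_zigzag_index
from .network import measure_sides, truth_zigzag_index
from .simulate import (
    ElectroSpec,
    FluxSpec,
    MonolayerSpec,
    generate_electro_dataset,
    generate_flux_dataset,
    generate_monolayer,
)
from .stats import students_t_test

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "sample_seed"]


def sample_seed(base_seed: int, clone_idx: int, sample_idx: int, salt: int = 0) -> int:
    """Deterministic per-sample seed derivation from one base seed."""
    return int(
        np.random.SeedSequence([base_seed, clone_idx, sample_idx, salt]).generate_state(1)[0]
    )


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _monolayer_spec(overrides: dict[str, Any], seed: int) -> MonolayerSpec:
    try:
        return MonolayerSpec(**{**overrides, "seed": seed})
    except (TypeError, ValueError) as exc:
        raise PipelineError("simulate", f"bad monolayer spec: {exc}") from exc


def _measure_sample(
    spec: MonolayerSpec, window_cfg: dict[str, Any], measure_cfg: dict[str, Any], seed: int
) -> dict[str, Any]:
    image = generate_monolayer(spec)
    channel = image.channels["junction"]
    try:
        mask = segment_junctions(
            channel,
            spec.pixel_size_um,
            threshold_method=measure_cfg.get("threshold_method", "otsu"),
            threshold_value=measure_cfg.get("threshold_value"),
            min_object_px=measure_cfg.get("min_object_px", 20),
        )
        network = extract_network(
            mask,
            spec.pixel_size_um,
            prune_spur_um=measure_cfg.get("prune_spur_um", 1.0),
            intensity=channel if measure_cfg.get("subpixel_refine", True) else None,
        )
    except ValueError as exc:
        raise PipelineError("measure", str(exc)) from exc
    morph = measure_sides(network.interior_sides())
    side_sets, windows = sample_windows(
        network,
        field_size_um=(spec.field_width_um, spec.field_height_um),
        window_area_um2=window_cfg.get("window_area_um2", 840.0),
        n_windows=window_cfg.get("n_windows", 5),
        seed=seed,
    )
    indices = [compute_zigzag_index(ids, morph, win) for ids, win in zip(side_sets, windows)]
    return {
        "truth_index": truth_zigzag_index(image.truth),
        "window_values": [zi.value for zi in indices],
        "window_n_sides": [zi.n_sides for zi in indices],
        "network": network,
        "morphometry": morph,
        "side_sets": side_sets,
    }


def run_pipeline(config: dict[str, Any], out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full analysis described by ``config``; return the report.

    Config keys: ``seed`` (int), ``clones`` (list of {name, n_samples,
    monolayer, [electro], [flux]}), ``windows`` ({n_windows,
    window_area_um2}), ``measure`` (segmentation/extraction options),
    ``comparisons`` (pairs of clone names; default: every clone vs the
    first one).
    """
    if "clones" not in config or not config["clones"]:
        raise PipelineError("config", "config must name at least one clone")
    base_seed = int(config.get("seed", 0))
    window_cfg = config.get("windows", {})
    measure_cfg = config.get("measure", {})

    report: dict[str, Any] = {
        "version": __version__,
        "config": config,
        "clones": {},
        "comparisons": [],
    }
    clone_values: dict[str, list[float]] = {}
    frames = {}

    for ci, clone in enumerate(config["clones"]):
        name = clone.get("name", f"clone{ci}")
        n_samples = int(clone.get("n_samples", 1))
        if n_samples < 1:
            raise PipelineError("config", f"clone {name}: n_samples must be >= 1")
        per_sample_windows = []
        truth_indices = []
        logger.info("clone %s: %d samples", name, n_samples)
        for si in range(n_samples):
            seed = sample_seed(base_seed, ci, si)
            spec = _monolayer_spec(clone.get("monolayer", {}), seed)
            res = _measure_sample(spec, window_cfg, measure_cfg, sample_seed(base_seed, ci, si, 1))
            per_sample_windows.append(res["window_values"])
            truth_indices.append(res["truth_index"])
            if out_dir is not None:
                frames[f"{name}_sample{si}_sides.csv"] = morphometry_to_frame(
                    res["network"], res["morphometry"], res["side_sets"]
                )
        summary = clone_zigzag_summary(per_sample_windows)
        clone_values[name] = list(summary.sample_values)
        report["clones"][name] = {
            "zigzag": {
                "sample_values": list(summary.sample_values),
                "mean": summary.mean,
                "se": summary.se,
                "n": summary.n,
            },
            "truth_indices": truth_indices,
            "per_sample_window_values": per_sample_windows,
        }

        if "electro" in clone:
            espec = ElectroSpec(**{**clone["electro"], "seed": sample_seed(base_seed, ci, 0, 2)})
            results = [analyze_record(r) for r in generate_electro_dataset(espec)]
            report["clones"][name]["barrier"] = {
                "TER_ohm_cm2": [r.TER_ohm_cm2 for r in results],
                "beta": [r.beta for r in results],
                "P_Na_cm_s": [r.P_Na_cm_s for r in results],
                "P_Cl_cm_s": [r.P_Cl_cm_s for r in results],
                "dispersion_kind": "sd",
            }
        if "flux" in clone:
            fspec = FluxSpec(**{**clone["flux"], "seed": sample_seed(base_seed, ci, 0, 3)})
            raw = generate_flux_dataset(fspec)
            curve = fit_standard_curve(raw.standard_amounts_nmol, raw.standard_fluorescence)
            series = FluxSeries(
                times_h=raw.times_h,
                Q_nmol=np.asarray(curve.apply(raw.fluorescence)),
                C0_mM=raw.C0_mM,
                area_cm2=raw.area_cm2,
            )
            report["clones"][name]["P_app_cm_s"] = dextran_papp(series)

    pairs = config.get(
        "comparisons",
        [
            [config["clones"][0].get("name", "clone0"), c.get("name", f"clone{i}")]
            for i, c in enumerate(config["clones"])
            if i > 0
        ],
    )
    for a, b in pairs:
        if a not in clone_values or b not in clone_values:
            raise PipelineError("compare", f"unknown clone in comparison ({a}, {b})")
        cmp = students_t_test(clone_values[a], clone_values[b], a, b, dispersion_kind="se")
        report["comparisons"].append(dataclasses.asdict(cmp))

    report["notes"] = ["no multiple-testing correction applied"]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        for fname, df in frames.items():
            df.to_csv(out / fname, index=False)
    return report
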