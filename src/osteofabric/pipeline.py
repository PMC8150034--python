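"""End-to-end orchestration: phantom/scan → filters → labels → metrics →
compactness fit → anisotropy field → feature row.

The run config is a flat mapping (YAML on disk) with per-stage blocks;
each run writes its artifacts plus a provenance record (config hash,
package version, timestamps) and skips stages whose outputs already
exist under an unchanged config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compactness import fit_sigmoid, observed_compactness, radial_profile, compute_centres
from .fabric import (
    build_lattice,
    da_histogram,
    coherence,
    filter_high,
    map_anisotropy,
)
from .morphometry import metrics_table
from .phantom import PhantomSpec, make_long_bone
from .preprocess import FilterChainConfig, run_filter_chain
from .segment import (
    SegmentationConfig,
    denoise_trabecular,
    find_midshaft,
    segment_compartments,
)
from .volume_io import (
    LABEL_TRABECULAR,
    VoxelVolume,
    export_histogram,
    export_vector_field,
    read_volume,
    write_volume,
)

__all__ = ["run_all", "load_config", "config_hash", "analyse_volume"]

log = logging.getLogger("osteofabric")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    known = {"input", "output_dir", "seed", "log_level", "phantom", "preprocess",
             "segment", "fabric", "compactness", "spacing_um"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _jsonable(obj):
    if is_dataclass(obj):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def analyse_volume(
    vol: VoxelVolume,
    filter_config: FilterChainConfig | None = None,
    seg_config: SegmentationConfig | None = None,
    fabric_config: dict | None = None,
) -> dict:
    """Library-level end-to-end analysis of one (isotropic) volume.

    Returns a dict with the label volume, midshaft selection, metric
    table, compactness fit, anisotropy field, histogram and coherence
    summary.  This is the unit the CLI pipeline wraps.
    """
    fabric_config = fabric_config or {}
    seg_config = seg_config or SegmentationConfig()
    # the smoothed (mean-shift) volume is a QC output only; skip it here
    _, _, bone_mask = run_filter_chain(vol, filter_config, with_smoothing=False)
    label = segment_compartments(bone_mask, vol.spacing, seg_config)
    label = denoise_trabecular(label, seg_config.min_component)
    midshaft = find_midshaft(label)
    metrics = metrics_table(label, midshaft.slice_index)

    section = np.isin(label.labels[:, :, midshaft.slice_index], [1, 2])
    centres = compute_centres(section)
    profile = radial_profile(section, centres.ontogenetic_centre)
    fit = fit_sigmoid(profile, scope="global")
    cg = observed_compactness(section)

    trab = label.labels == LABEL_TRABECULAR
    result: dict = {
        "label": label,
        "midshaft": midshaft,
        "metrics": metrics,
        "centres": centres,
        "sigmoid_fit": fit,
        "Cg": cg,
    }
    if trab.any():
        tb_th_um = metrics["Tb.Th"] * 1000.0
        lattice = build_lattice(label, tb_th_um, fabric_config.get("spacing_um"))
        field = map_anisotropy(
            label, lattice, min_normals=fabric_config.get("min_normals", 50)
        )
        hist = da_histogram(field, bin_width=fabric_config.get("bin_width", 0.05))
        high = filter_high(field, fabric_config.get("high_da_threshold", 0.65))
        result.update(
            {
                "lattice": lattice,
                "field": field,
                "histogram": hist,
                "high_field": high,
                "coherence": coherence(high),
                "Ani.M": hist.mode,
            }
        )
        result["metrics"]["Ani.M"] = hist.mode if hist.mode is not None else float("nan")
    result["metrics"]["Cg"] = cg
    result["metrics"]["Rmin"] = fit.min_asymptote
    result["metrics"]["Rmax"] = fit.max_asymptote
    result["metrics"]["P"] = fit.p
    result["metrics"]["S"] = fit.s
    return result


def run_all(config: dict | str | Path) -> dict:
    """Run the pipeline described by a config mapping or YAML path.

    Input is either ``input:`` (a volume on disk; ``spacing_um`` required
    for plain TIFF) or ``phantom:`` (a PhantomSpec block).  Artifacts:
    ``labels.nrrd``, ``metrics.csv``, ``fit.json``, ``field.csv``,
    ``field.vtk``, ``hist.csv``, ``run.log`` and ``provenance.json`` in
    ``output_dir``.  Stages are skipped when their outputs exist and the
    config hash matches the recorded provenance.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(config.get("output_dir", "osteofabric_out"))
    out.mkdir(parents=True, exist_ok=True)
    level = getattr(logging, str(config.get("log_level", "info")).upper())
    logging.basicConfig(level=level)
    chash = config_hash(config)
    prov_path = out / "provenance.json"
    artifacts = ["labels.nrrd", "metrics.csv", "fit.json", "field.csv", "field.vtk", "hist.csv"]
    if prov_path.exists():
        prov = json.loads(prov_path.read_text())
        if prov.get("config_hash") == chash and all((out / a).exists() for a in artifacts):
            log.info("outputs up to date for config %s; skipping", chash)
            return {"output_dir": out, "skipped": True}

    t0 = time.time()
    if "phantom" in config:
        spec = PhantomSpec(**config["phantom"])
        vol, _ = make_long_bone(spec)
    elif "input" in config:
        vol = read_volume(config["input"], config.get("spacing_um"))
    else:
        raise ValueError("config needs either 'input' or 'phantom'")

    fcfg = FilterChainConfig(**config.get("preprocess", {}))
    scfg = SegmentationConfig(**config.get("segment", {}))
    res = analyse_volume(vol, fcfg, scfg, config.get("fabric", {}))

    write_volume(res["label"], out / "labels.nrrd")
    import pandas as pd

    pd.DataFrame([res["metrics"]]).to_csv(out / "metrics.csv", index=False)
    fit_payload = {
        "global": _jsonable(res["sigmoid_fit"]),
        "Cg": res["Cg"],
        "centres": _jsonable(res["centres"]),
        "midshaft_slice": res["midshaft"].slice_index,
    }
    (out / "fit.json").write_text(json.dumps(fit_payload, indent=2))
    if "field" in res:
        export_vector_field(res["field"], out / "field.csv", "csv")
        export_vector_field(res["field"], out / "field.vtk", "vtk-legacy")
        export_histogram(res["histogram"], out / "hist.csv")
    else:
        for a in ("field.csv", "field.vtk", "hist.csv"):
            (out / a).write_text("")
    prov = {
        "config_hash": chash,
        "version": __version__,
        "seconds": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": _jsonable(config),
    }
    prov_path.write_text(json.dumps(prov, indent=2))
    (out / "run.log").write_text(
        f"osteofabric {__version__} config={chash} elapsed={prov['seconds']}s\n"
    )
    res["output_dir"] = out
    res["skipped"] = False
    return res
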