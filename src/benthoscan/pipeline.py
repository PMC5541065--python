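"""End-to-end transect run: one config in, a manifest of artifacts out.

Stages: true-color rendering, gray-board reflectance correction, derivative
index maps, topographic profile + rugosity, and classification per
(algorithm x feature mode) with validation metrics. Every artifact lands in
the output directory and is listed in ``manifest.json`` together with input
checksums and the run seed, so identical config + inputs reproduce identical
metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import classify as cls
from .cube_io import SpectralCube, read_envi, save_png, to_rgb, write_envi
from .radiometry import board_spectrum, to_reflectance, true_color
from .spectrometry import INDEX_REGISTRY, index_map
from .topography import fuse_bottom_profile, read_track_csv, rugosity

logger = logging.getLogger("benthoscan")

__all__ = ["RunConfig", "run_transect", "PipelineError"]

BOARD_LABEL = "Reference"


def reference_board_spectrum(cube, annotations) -> tuple[np.ndarray, np.ndarray]:
    """Board spectrum over the union of all 'Reference' polygons.

    Several small reference polygons (e.g. a board at each transect end, or
    sparse patches on one board) are pooled into one pixel mask before
    averaging; the >= 25 pixel requirement applies to the union.
    """
    from .classify import _rasterize_polygon

    polys = [v for v, label in annotations.regions if label == BOARD_LABEL]
    if not polys:
        raise ValueError(f"no '{BOARD_LABEL}' polygon in annotations")
    mask = np.zeros(cube.shape[:2], dtype=bool)
    for poly in polys:
        mask |= _rasterize_polygon(np.asarray(poly, dtype=float), cube.shape[:2])
    return board_spectrum(cube, mask)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and knobs for one transect analysis run."""

    cube_path: str
    annotation_path: str
    track_path: str | None = None
    transect_length: float = 25.0
    indices: tuple[str, ...] = ("chl_670", "coral_rededge_700", "chromo_580", "phyco_605")
    algorithms: tuple[str, ...] = ("perceptron", "mahalanobis", "svm_linear")
    modes: tuple[str, ...] = ("hsi", "rgb")
    board_albedo: float = 1.0
    seed: int = 0
    out_dir: str = "benthoscan_out"

    @classmethod
    def from_yaml(cls_, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("indices", "algorithms", "modes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls_(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_transect(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the artifact manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "inputs": {},
        "artifacts": {},
        "metrics": {},
        "timings_s": {},
        "partial": False,
    }
    for name, path in (("cube", config.cube_path), ("annotations", config.annotation_path),
                       ("track", config.track_path)):
        if path is not None:
            if not os.path.exists(path):
                raise PipelineError("config", f"input '{name}' not found: {path}")
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            logger.info("stage %s ...", name)
            try:
                out = fn()
            except Exception as err:  # noqa: BLE001 - stage name is the contract
                manifest["partial"] = True
                _write_manifest(manifest, config.out_dir)
                raise PipelineError(name, str(err)) from err
            manifest["timings_s"][name] = round(time.time() - t0, 3)
            return out

        return wrap

    cube = stage("read_cube")(lambda: read_envi(config.cube_path))
    annotations = stage("read_annotations")(
        lambda: cls.read_annotation_json(config.annotation_path)
    )

    def _render():
        img = to_rgb(cube)
        path = os.path.join(config.out_dir, "scene_rgb.png")
        save_png(img, path)
        return path

    manifest["artifacts"]["scene_rgb"] = stage("render")(_render)

    def _reflectance():
        board, _cv = reference_board_spectrum(cube, annotations)
        rcube, qc_mask = to_reflectance(cube, board, board_albedo=config.board_albedo)
        rpath = os.path.join(config.out_dir, "reflectance.hdr")
        write_envi(rcube, rpath)
        tc_path = os.path.join(config.out_dir, "scene_truecolor.png")
        save_png(true_color(rcube), tc_path)
        manifest["artifacts"]["true_color"] = tc_path
        manifest["metrics"]["out_of_gamut_fraction"] = float(qc_mask.mean())
        return rcube, rpath

    rcube, rpath = stage("reflectance")(_reflectance)
    manifest["artifacts"]["reflectance_cube"] = rpath

    def _indices():
        paths = {}
        for name in config.indices:
            imap = index_map(rcube, INDEX_REGISTRY[name])
            path = os.path.join(config.out_dir, f"index_{name}.png")
            save_png(imap.values, path)
            paths[name] = path
        return paths

    manifest["artifacts"]["index_maps"] = stage("index_maps")(_indices)

    if config.track_path is not None:

        def _topo():
            track = read_track_csv(config.track_path)
            profile = fuse_bottom_profile(track, config.transect_length)
            rug = rugosity(profile)
            payload = {
                "distance_m": profile.distance.tolist(),
                "bottom_depth_m": profile.bottom_depth.tolist(),
                "rugosity": rug if np.isscalar(rug) else np.asarray(rug).tolist(),
            }
            path = os.path.join(config.out_dir, "topography.json")
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
            manifest["metrics"]["rugosity"] = payload["rugosity"]
            return path

        manifest["artifacts"]["topography"] = stage("topography")(_topo)

    def _classify():
        labels = cls.rasterize_annotations(annotations, cube.shape[:2])
        outputs = {}
        for mode in config.modes:
            ds = cls.extract_dataset(rcube, labels, mode=mode, image_id=annotations.image_id)
            train, val = cls.split_dataset(ds, seed=config.seed)
            for algorithm in config.algorithms:
                model = cls.train_classifier(train, algorithm, seed=config.seed)
                report = cls.evaluate(model, val)
                label_map, qc = cls.predict_map(model, rcube)
                key = f"{algorithm}_{mode}"
                map_path = os.path.join(config.out_dir, f"map_{key}.png")
                _save_label_png(label_map, map_path)
                metrics_path = os.path.join(config.out_dir, f"metrics_{key}.json")
                payload = report.to_dict()
                payload.update({"seed": config.seed, "qc": qc, "algorithm": algorithm, "mode": mode})
                with open(metrics_path, "w") as fh:
                    json.dump(payload, fh, indent=1, sort_keys=True)
                outputs[key] = {"map": map_path, "metrics": metrics_path}
                manifest["metrics"][f"accuracy_{key}"] = payload["accuracy"]
        legend_path = os.path.join(config.out_dir, "legend.json")
        with open(legend_path, "w") as fh:
            json.dump({i: n for i, n in enumerate(sorted(labels.legend.values()))}, fh, indent=1)
        outputs["legend"] = legend_path
        return outputs

    manifest["artifacts"]["classification"] = stage("classification")(_classify)
    _write_manifest(manifest, config.out_dir)
    return manifest


def _save_label_png(label_map, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    k = max(len(label_map.legend), 1)
    norm = label_map.indices.astype(float) / max(k - 1, 1)
    plt.imsave(path, matplotlib.colormaps["tab20"](norm))


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
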