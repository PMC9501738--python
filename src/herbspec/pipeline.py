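"""End-to-end orchestration: simulate/ingest -> calibrate -> extract -> PCA
-> train the three discriminant models -> evaluate, from one config.

Every stage logs its row/band counts into a run manifest so a re-run with
the same seeds reproduces the outputs. Exactly one input source must be
set: a synthetic recipe, a directory of ENVI cubes, or a spectra table.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
import pickle
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .chemometrics import fit_pca, cumulative_variance
from .classifiers import (
    CnnSpec,
    fit_cnn,
    stratified_split,
    train_plsda,
    train_svm_rbf,
)
from .cube_io import read_envi, calibrate, ReferencePair
from .evaluation import report, format_report
from .extraction import (
    DEFAULT_SEGMENTATION_NM,
    DEFAULT_WINDOW_NM,
    crop_wavelengths,
    denoise_table,
    extract_pixel_spectra,
    mean_spectrum,
    select_band,
    threshold_mask,
)
from .synthdata import SyntheticConfig, simulate_spectra_table
from .tables import SpectraTable, read_spectra_csv, write_spectra_csv

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("herbspec")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """One-file recipe for a full study run; seeds are always explicit."""

    out_dir: str
    synthetic: SyntheticConfig | None = None
    cube_dir: str | None = None
    spectra_file: str | None = None
    segmentation_nm: float = DEFAULT_SEGMENTATION_NM
    window_nm: tuple[float, float] | None = DEFAULT_WINDOW_NM
    denoise: dict | None = field(default_factory=lambda: {"family": "db6", "level": 3})
    split_ratio: tuple[int, int] = (4, 1)
    split_seed: int = 0
    models: tuple[str, ...] = ("plsda", "svm_rbf", "cnn")
    pca_components: int = 10
    plsda_components: int | str = "auto"
    svm_seed: int = 0
    cnn_spec: CnnSpec | None = None
    cnn_epochs: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sources = [s is not None for s in
                   (self.synthetic, self.cube_dir, self.spectra_file)]
        if sum(sources) != 1:
            raise ValueError("exactly one input source must be configured")

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("image_shape", "clean_window"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        if "cnn_spec" in raw and raw["cnn_spec"] is not None:
            spec = dict(raw["cnn_spec"])
            if "filters" in spec:
                spec["filters"] = tuple(spec["filters"])
            raw["cnn_spec"] = CnnSpec(**spec)
        for key in ("window_nm", "split_ratio", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def ingest_cube_directory(cube_dir: str, segmentation_nm: float) -> SpectraTable:
    """Read ``class<k>_*.hdr`` sample cubes (with sibling ``*.white.hdr`` /
    ``*.dark.hdr`` references), calibrate, segment at the contrast band and
    return one mean ROI spectrum per cube."""
    headers = sorted(
        h for h in glob.glob(os.path.join(cube_dir, "class*_*.hdr"))
        if not h.endswith((".white.hdr", ".dark.hdr"))
    )
    if not headers:
        raise FileNotFoundError(f"no class*_*.hdr cubes found in {cube_dir}")
    rows, labels, prov = [], [], []
    wl = None
    for hdr in headers:
        stem = hdr[:-4]
        label = int(os.path.basename(stem).split("_")[0].removeprefix("class"))
        raw = read_envi(hdr)
        refs = ReferencePair(
            white=read_envi(stem + ".white.hdr").values,
            dark=read_envi(stem + ".dark.hdr").values,
        )
        refl = calibrate(raw, refs)
        mask = threshold_mask(select_band(refl, segmentation_nm))
        rows.append(mean_spectrum(extract_pixel_spectra(refl, mask)))
        labels.append(label)
        prov.append(os.path.basename(stem))
        wl = refl.wavelengths
    return SpectraTable(np.stack(rows), wl, labels=np.array(labels), provenance=prov)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages in order; returns the run manifest."""
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "seeds": {
        "split": config.split_seed, "svm": config.svm_seed,
    }}
    stage = "ingest"
    try:
        if config.synthetic is not None:
            table = simulate_spectra_table(config.synthetic)
            manifest["seeds"]["synthetic"] = config.synthetic.seed
        elif config.cube_dir is not None:
            table = ingest_cube_directory(config.cube_dir, config.segmentation_nm)
        else:
            table = read_spectra_csv(config.spectra_file)
        manifest["stages"]["ingest"] = {
            "rows": table.n_samples, "bands": table.n_bands,
        }
        logger.info("ingest: %d rows x %d bands", table.n_samples, table.n_bands)

        if config.window_nm is not None:
            stage = "crop"
            table = crop_wavelengths(table, *config.window_nm)
            manifest["stages"]["crop"] = {
                "rows": table.n_samples, "bands": table.n_bands,
                "window_nm": list(config.window_nm),
            }

        if config.denoise is not None:
            stage = "denoise"
            table = denoise_table(table, **config.denoise)
            manifest["stages"]["denoise"] = dict(config.denoise)

        stage = "write_spectra"
        spectra_path = os.path.join(config.out_dir, "spectra.csv")
        write_spectra_csv(table, spectra_path)

        stage = "pca"
        k = min(config.pca_components, table.n_samples - 1, table.n_bands)
        pca = fit_pca(table, k)
        np.savetxt(os.path.join(config.out_dir, "pca_scores.csv"),
                   pca.scores, delimiter=",")
        np.savetxt(os.path.join(config.out_dir, "pca_loadings.csv"),
                   pca.loadings, delimiter=",")
        np.savetxt(os.path.join(config.out_dir, "pca_explained_pct.csv"),
                   pca.explained_pct, delimiter=",")
        manifest["stages"]["pca"] = {
            "k": k,
            "explained_pct": [round(float(v), 4) for v in pca.explained_pct],
            "cumulative_2": round(cumulative_variance(pca, min(2, k)), 4),
        }
        logger.info("pca: first components explain %s%%",
                    manifest["stages"]["pca"]["explained_pct"][:2])

        if not config.models:
            manifest["stages"]["models"] = {"skipped": "no model specs configured"}
            _write_manifest(manifest, config.out_dir)
            return manifest

        if table.labels is None:
            raise ValueError("model training requires a labelled table")

        stage = "split"
        split = stratified_split(table.labels, config.split_ratio, config.split_seed)
        with open(os.path.join(config.out_dir, "split.json"), "w") as fh:
            json.dump({"train_rows": split.train_rows.tolist(),
                       "test_rows": split.test_rows.tolist(),
                       "seed": split.seed}, fh)
        manifest["stages"]["split"] = {
            "train": len(split.train_rows), "test": len(split.test_rows),
        }
        logger.info("split: %d train / %d test",
                    len(split.train_rows), len(split.test_rows))

        Xtr, ytr = table.X[split.train_rows], table.labels[split.train_rows]
        trained = []
        for name in config.models:
            stage = f"train:{name}"
            if name == "plsda":
                clf = train_plsda(Xtr, ytr, n_components=config.plsda_components)
            elif name == "svm_rbf":
                clf = train_svm_rbf(Xtr, ytr, seed=config.svm_seed)
            elif name == "cnn":
                clf = fit_cnn(Xtr, ytr, spec=config.cnn_spec,
                              epochs=config.cnn_epochs, seed=config.split_seed)
            else:
                raise ValueError(f"unknown model {name!r}")
            trained.append(clf)
            with open(os.path.join(config.out_dir, f"model_{name}.pkl"), "wb") as fh:
                pickle.dump(clf, fh)
            manifest["stages"][stage] = {"hyperparams": _jsonable(clf.hyperparams)}
            logger.info("trained %s: %s", name, clf.hyperparams)

        stage = "evaluate"
        reports = report(trained, split, table)
        text = format_report(reports)
        with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
            fh.write(text + "\n")
        manifest["stages"]["evaluate"] = {
            "rows": [
                {"model": r.model_kind, "partition": r.partition,
                 "precision": round(r.macro_precision, 4),
                 "recall": round(r.macro_recall, 4),
                 "f": round(r.macro_f, 4),
                 "accuracy": round(r.accuracy, 4)}
                for r in reports
            ]
        }
        logger.info("evaluation:\n%s", text)
        _write_manifest(manifest, config.out_dir)
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, config.out_dir)
        raise PipelineError(stage, exc, manifest) from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
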