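"""End-to-end orchestration: synthesize -> segment -> features -> select ->
evaluate (-> agreement), driven by one TOML config.

Every stage writes its artifact (manifest, masks, features.csv, tree.json,
report/), and ``run.json`` records the config hash, master seed, package
versions and stage timings, so a run is reproducible bit-for-bit from its
config file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import preprocess, synthetic
from .evaluation import evaluate_conditions
from .tree import GainRatioTree
from .wavelet import DecompositionSpec, entropy_vector

__all__ = ["RunConfig", "load_config", "extract_features", "run_pipeline"]

logger = logging.getLogger("pneumotex")

T_COLUMNS = [f"T{i}" for i in range(1, 9)]


@dataclasses.dataclass
class RunConfig:
    """Flat run configuration; defaults mirror the standard analysis."""

    out_dir: str = "pneumotex_run"
    seed: int = 0
    # cohort
    n_normal: int = 60
    stage_counts: dict = dataclasses.field(
        default_factory=lambda: {"I": 40, "II": 12, "III": 8})
    width: int = 256
    height: int = 256
    # preprocessing / features
    lung_polarity: str = "bright"
    masked: bool = True
    basis: str = "db7"
    levels: int = 8
    boundary_mode: str = "periodization"
    # tree
    min_samples_leaf: int = 2
    max_depth: int = 10
    min_gain: float = 1e-6
    # svm / cv
    kernels: tuple = ("gaussian", "linear", "polynomial")
    q: int = 3
    sigma2: float = 0.1
    c_reg: float = 1.0
    k_folds: int = 5
    # optional modality-staging CSV (case_id,gold,stage_a,stage_b)
    staging_csv: str | None = None

    def hash(self) -> str:
        """Digest of the analysis parameters (output location excluded, so
        re-running the same analysis elsewhere reproduces the same hash)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a flat TOML file into a :class:`RunConfig`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "kernels" in raw:
        raw["kernels"] = tuple(raw["kernels"])
    return RunConfig(**raw)


def extract_features(manifest: pd.DataFrame,
                     spec: DecompositionSpec = DecompositionSpec(),
                     masked: bool = True, polarity: str = "bright",
                     mask_dir: str | Path | None = None,
                     feature_intensities: str = "original") -> pd.DataFrame:
    """Per-image feature table ``image_id,label,T1..T8`` (plus H and p).

    Each image is histogram-equalized and segmented (when ``masked``); the
    wavelet-entropy vector is then computed inside the lung mask.  By default
    texture features use the *original* intensities
    (``feature_intensities="original"``): equalization flattens the global
    intensity ranks, which is what Otsu segmentation wants, but it rescales
    local texture amplitudes and thereby suppresses the nodular signal the
    features are meant to capture.  Pass ``"enhanced"`` to compute features
    on the equalized image instead.  When ``mask_dir`` is given, lung masks
    are written there as 0/255 PNGs.
    """
    if feature_intensities not in ("original", "enhanced"):
        raise ValueError("feature_intensities must be 'original' or 'enhanced'")
    rows = []
    for rec in manifest.itertuples(index=False):
        img = preprocess.read_image(rec.path)
        enhanced = preprocess.enhance(img)
        feature_img = img if feature_intensities == "original" else enhanced
        mask = None
        if masked:
            mask = preprocess.segment_lung_fields(enhanced, polarity=polarity)
            feature_img = preprocess.apply_mask(feature_img, mask)
            if mask_dir is not None:
                preprocess.write_mask(Path(mask_dir) / f"{rec.image_id}_mask.png", mask)
        fv = entropy_vector(feature_img, spec, mask=mask)
        row = {"image_id": rec.image_id, "label": int(rec.label)}
        for i in range(spec.levels):
            row[f"T{i + 1}"] = fv.log_features[i]
        for i in range(spec.levels):
            row[f"H{i + 1}"] = fv.entropies[i]
        for i in range(spec.levels):
            row[f"p{i + 1}"] = fv.relative_energies[i]
        rows.append(row)
    return pd.DataFrame(rows)


def select_features(features: pd.DataFrame, feature_columns: list[str],
                    **tree_params) -> tuple[GainRatioTree, list[str]]:
    """Fit the gain-ratio tree once on the full table; return it and the
    selected column names (falling back to the full set for a leaf-only
    tree)."""
    X = features[feature_columns].to_numpy(dtype=float)
    y = features["label"].to_numpy(dtype=int)
    model = GainRatioTree(**tree_params).fit(X, y)
    cols = [feature_columns[j] for j in model.selected_features_]
    if not cols:
        logger.warning("decision tree selected no features; using the full set")
        cols = list(feature_columns)
    return model, cols


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns a summary dict (paths, selected features, metric rows).  Any
    stage failure is re-raised naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_meta = {"config_hash": config.hash(), "seed": config.seed,
                "config": dataclasses.asdict(config), "stages": {}}
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _Timer()

    with stage("synthesize"):
        manifest = synthetic.generate_cohort(
            out, config.n_normal, config.stage_counts,
            config.width, config.height, config.seed)

    spec = DecompositionSpec(config.basis, config.levels, config.boundary_mode)
    with stage("features"):
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        features = extract_features(manifest, spec, masked=config.masked,
                                    polarity=config.lung_polarity,
                                    mask_dir=mask_dir)
        t_cols = [f"T{i}" for i in range(1, config.levels + 1)]
        features.to_csv(out / "features.csv", index=False,
                        float_format="%.12g")

    with stage("select"):
        tree_model, subset_cols = select_features(
            features, t_cols, min_samples_leaf=config.min_samples_leaf,
            max_depth=config.max_depth, min_gain=config.min_gain)
        tree_payload = json.loads(tree_model.to_json())
        tree_payload.update(config_hash=config.hash(), seed=config.seed,
                            selected_columns=subset_cols)
        (out / "tree.json").write_text(json.dumps(tree_payload, indent=2))

    with stage("evaluate"):
        report_dir = out / "report"
        report_dir.mkdir(exist_ok=True)
        metrics = evaluate_conditions(
            features, t_cols, subset_cols, kernels=tuple(config.kernels),
            k=config.k_folds, seed=config.seed, C=config.c_reg,
            q=config.q, sigma2=config.sigma2)
        metrics.to_csv(report_dir / "metrics.csv", index=False,
                       float_format="%.12g")
        (report_dir / "metrics.json").write_text(json.dumps(
            {"config_hash": config.hash(), "seed": config.seed,
             "rows": metrics.to_dict(orient="records")}, indent=2))

    agreement_out = None
    if config.staging_csv:
        with stage("agreement"):
            staging = pd.read_csv(config.staging_csv, dtype=str)
            report = agr.agreement_report(staging)
            report.update(config_hash=config.hash(), seed=config.seed)
            (out / "agreement.json").write_text(json.dumps(report, indent=2))
            agreement_out = report

    run_meta["stages"] = timings
    run_meta["versions"] = _versions()
    run_meta["selected_features"] = subset_cols
    (out / "run.json").write_text(json.dumps(run_meta, indent=2, default=str))

    return {
        "out_dir": str(out),
        "manifest": manifest,
        "features": features,
        "selected_features": subset_cols,
        "metrics": metrics,
        "agreement": agreement_out,
        "config_hash": config.hash(),
    }


def _versions() -> dict:
    import pywt
    import scipy
    import skimage
    import sklearn

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "pywt": pywt.__version__,
            "scikit-image": skimage.__version__, "sklearn": sklearn.__version__}
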