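"""Image, feature-table and model file I/O."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.util import img_as_float

from . import features, filters
from .lssvm import SMKLSSVMClassifier

__all__ = [
    "read_gray_image",
    "write_gray_image",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]

FEATURE_TABLE_VERSION = 1


def read_gray_image(path) -> np.ndarray:
    """Read PNG/TIFF as a float image in [0, 1]; color becomes luminance."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = rgb2gray(img_as_float(arr))
    elif arr.ndim == 2:
        arr = img_as_float(arr)
    else:
        raise OSError(f"unsupported image layout {arr.shape} in {path}")
    return np.clip(np.asarray(arr, dtype=float), 0.0, 1.0)


def write_gray_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit PNG/TIFF."""
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (img * 65535.0 + 0.5).astype(np.uint16))


def _config_to_dict(cfg: filters.FilterBankConfig) -> dict:
    return {
        "orders": list(cfg.orders),
        "scales": list(cfg.scales),
        "n_directions": cfg.n_directions,
        "boundary_mode": cfg.boundary_mode,
    }


def _config_from_dict(d: dict) -> filters.FilterBankConfig:
    return filters.FilterBankConfig(
        orders=tuple(d["orders"]),
        scales=tuple(d["scales"]),
        n_directions=int(d["n_directions"]),
        boundary_mode=d.get("boundary_mode", "reflect"),
    )


def write_feature_table(path, ids, X, config: filters.FilterBankConfig, labels=None) -> None:
    """Feature CSV (one row per image) plus a JSON sidecar with the bank config."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(X), columns=features.feature_names(config))
    df.insert(0, "image", list(ids))
    if labels is not None:
        df.insert(1, "label", np.asarray(labels))
    df.to_csv(path, index=False)
    sidecar = {"version": FEATURE_TABLE_VERSION, "filter_bank": _config_to_dict(config)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_table(path):
    """Returns (ids, X, labels or None, FilterBankConfig or None)."""
    path = Path(path)
    df = pd.read_csv(path)
    ids = df.pop("image").tolist()
    labels = df.pop("label").to_numpy() if "label" in df.columns else None
    config = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        config = _config_from_dict(json.loads(sidecar.read_text())["filter_bank"])
    return ids, df.to_numpy(dtype=float), labels, config


def save_model(path, model: SMKLSSVMClassifier) -> None:
    """Persist a fitted classifier as structured JSON."""
    payload = {
        "params": model.get_params(),
        "classes": np.asarray(model.classes_).tolist(),
        "support": model.support_.tolist(),
        "dual_coef": model.dual_coef_.tolist(),
        "intercept": model.intercept_,
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
        "support_vectors": model.support_vectors_.tolist(),
        "n_features_in": model.n_features_in_,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> SMKLSSVMClassifier:
    d = json.loads(Path(path).read_text())
    model = SMKLSSVMClassifier(**d["params"])
    model.classes_ = np.asarray(d["classes"])
    model.support_ = np.asarray(d["support"], dtype=int)
    model.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
    model.intercept_ = float(d["intercept"])
    model.mean_ = np.asarray(d["mean"], dtype=float)
    model.scale_ = np.asarray(d["scale"], dtype=float)
    model.support_vectors_ = np.asarray(d["support_vectors"], dtype=float)
    model.n_features_in_ = int(d["n_features_in"])
    return model
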