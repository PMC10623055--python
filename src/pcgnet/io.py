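"""File I/O: images, label maps, checkpoints and run artifacts.

Grayscale images round-trip as 16-bit PNG (scaled to [0, 1]), float NIfTI or
NPY; label maps as paletteless integer PNG/NIfTI/NPY.  NIfTI pixel spacing is
honoured and handed to preprocessing.  Checkpoints are single ``.npz``
archives holding every parameter tensor (by path), the batch-norm running
statistics, a JSON echo of the configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from . import nn

PNG_SCALE = 65535.0


def write_image(path, array, spacing=1.0, is_label=False):
    """Write a 2-D array; format chosen by extension (.png/.nii/.nii.gz/.npy)."""
    path = Path(path)
    array = np.asarray(array)
    if array.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {array.shape}")
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix == ".png":
        if is_label:
            Image.fromarray(array.astype(np.uint16)).save(path)  # 16-bit grayscale
        else:
            scaled = np.clip(array, 0.0, 1.0) * PNG_SCALE
            Image.fromarray(scaled.astype(np.uint16)).save(path)
    elif suffix in (".nii", ".nii.gz"):
        data = array.astype(np.int16 if is_label else np.float32)
        affine = np.diag([spacing, spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(data[:, :, None], affine), str(path))
    elif suffix == ".npy":
        np.save(path, array)
    else:
        raise ValueError(f"unknown image extension {suffix!r} (use .png/.nii/.nii.gz/.npy)")
    return path


def read_image(path, is_label=False):
    """Read a 2-D image; returns ``(array, spacing_mm)``."""
    path = Path(path)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix == ".png":
        arr = np.asarray(Image.open(path))
        if is_label:
            return arr.astype(np.int16), 1.0
        return (arr.astype(np.float32) / PNG_SCALE), 1.0
    if suffix in (".nii", ".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        if data.ndim != 2:
            raise ValueError(
                f"{path.name}: expected a 2-D NIfTI slice, got shape {data.shape}; "
                "extract a slice first"
            )
        spacing = float(img.header.get_zooms()[0])
        return (data.astype(np.int16) if is_label else data.astype(np.float32)), spacing
    if suffix == ".npy":
        arr = np.load(path)
        return (arr.astype(np.int16) if is_label else arr.astype(np.float32)), 1.0
    raise ValueError(f"unknown image extension {suffix!r} (use .png/.nii/.nii.gz/.npy)")


def write_meta(path, meta: dict):
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, params, bn_state=None, config=None, seed=None, extra=None):
    """Single-file weight archive with config echo and seed."""
    arrays = {f"param::{p}": leaf for p, leaf in nn.tree_leaves(params)}
    if bn_state is not None:
        for key, (m, v) in bn_state.stats.items():
            arrays[f"bnmean::{key}"] = m
            arrays[f"bnvar::{key}"] = v
    from . import __version__

    meta = {
        "config": _config_dict(config),
        "seed": seed,
        "version": __version__,
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta, default=_json_default).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return Path(path)


def _config_dict(config):
    if config is None:
        return None
    if dataclasses.is_dataclass(config):
        return dataclasses.asdict(config)
    return dict(config)


def load_checkpoint(path):
    """Returns ``(params, bn_state, meta)``; params as a nested dict tree."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        params: dict = {}
        bn = nn.BNState()
        for key in data.files:
            if key.startswith("param::"):
                _tree_set(params, key[len("param::") :].split("/"), data[key])
            elif key.startswith("bnmean::"):
                bn.stats.setdefault(key[len("bnmean::") :], [None, None])
                bn.stats[key[len("bnmean::") :]][0] = data[key]
            elif key.startswith("bnvar::"):
                bn.stats.setdefault(key[len("bnvar::") :], [None, None])
                bn.stats[key[len("bnvar::") :]][1] = data[key]
        bn.stats = {k: (m, v) for k, (m, v) in bn.stats.items()}
    params = _listify(params)
    return params, bn, meta


def _tree_set(tree, keys, value):
    for k in keys[:-1]:
        tree = tree.setdefault(k, {})
    tree[keys[-1]] = value


def _listify(tree):
    """Convert dicts whose keys are consecutive integers back into lists."""
    if not isinstance(tree, dict):
        return tree
    out = {k: _listify(v) for k, v in tree.items()}
    keys = list(out)
    if keys and all(k.isdigit() for k in keys):
        order = sorted(keys, key=int)
        if [int(k) for k in order] == list(range(len(order))):
            return [out[k] for k in order]
    return out
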