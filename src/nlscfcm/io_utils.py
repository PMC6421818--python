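"""Image and report I/O.

Readers accept 8/16-bit PNG/TIFF, 32-bit float TIFF, and single-slice
NIfTI (.nii/.nii.gz); writers mirror these plus JSON metadata.  Phantom
bundles are written as image (16-bit TIFF), labels (8-bit PNG), bias
(32-bit float TIFF), and a JSON truth record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def load_image(path):
    """Read a 2-D grayscale image as float64.

    Multichannel inputs are averaged to one channel; single-slice NIfTI
    volumes are squeezed to 2-D.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError("expected a single-slice NIfTI image")
        return np.asarray(data, float)
    if name.endswith((".tif", ".tiff")):
        import tifffile
        data = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio
        data = iio.imread(str(path))
    data = np.asarray(data, float)
    if data.ndim == 3:
        data = data.mean(axis=-1)
    if data.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return data


def save_float_tiff(path, array):
    import tifffile
    tifffile.imwrite(str(path), np.asarray(array, np.float32),
                     photometric="minisblack")


def save_labels_png(path, labels):
    import imageio.v3 as iio
    lab = np.asarray(labels)
    if lab.max() > 255:
        raise ValueError("more than 256 labels cannot be stored as 8-bit PNG")
    iio.imwrite(str(path), lab.astype(np.uint8))


def save_image_png16(path, image):
    """Store an intensity image as 16-bit PNG (rescaled to full range)."""
    import imageio.v3 as iio
    x = np.asarray(image, float)
    hi = x.max()
    scaled = (x / hi * 65535.0) if hi > 0 else x
    iio.imwrite(str(path), scaled.astype(np.uint16))


def write_json(path, obj):
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def write_phantom_bundle(out_dir, truth, observed, meta=None):
    """Write a phantom (observed image, labels, bias, truth metadata)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_float_tiff(out / "image.tiff", observed)
    save_image_png16(out / "image.png", observed)
    save_labels_png(out / "labels.png", truth.labels)
    save_float_tiff(out / "bias.tiff", truth.bias)
    record = {
        "class_intensities": truth.class_intensities,
        "noise_sigma": truth.noise_sigma,
    }
    if meta:
        record.update(meta)
    write_json(out / "truth.json", record)
    return out


def write_segmentation(out_dir, result, params=None):
    """Write a SegmentationResult (labels, bias, corrected, memberships,
    trace, resolved parameters)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_labels_png(out / "labels.png", result.labels)
    save_float_tiff(out / "bias.tiff", result.bias)
    save_float_tiff(out / "corrected.tiff", result.corrected_image)
    save_float_tiff(out / "memberships.tiff", result.memberships)
    write_json(out / "trace.json", {
        "objective": result.objective_trace,
        "centers": [list(map(float, v)) for v in result.center_history],
        "iterations_run": result.iterations_run,
        "converged": bool(result.converged),
        "method": result.method,
    })
    if params is not None:
        write_json(out / "params.json", params)
    return out


def load_config(path):
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text) or {}
    return json.loads(text)
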