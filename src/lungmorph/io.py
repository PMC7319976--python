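"""Reading and writing images, IF channel stacks and result tables.

Images are plain TIFF/PNG via tifffile/imageio.  Multichannel IF fields are
stored either as a multi-page TIFF with channel names in the page
descriptions, or as a directory of single-channel PNGs with a YAML
manifest.  All tables are CSV through pandas.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .cells import IFField
from .segmentation import HistologyImage


def read_image(path, pixel_size: float) -> HistologyImage:
    """Read a TIFF/PNG histology image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return HistologyImage(arr, pixel_size, source_id=path.stem)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary/label mask as a single-channel PNG or TIFF."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_if_field(path, field: IFField) -> None:
    """Write an IF field as a multi-page TIFF, one page per channel.

    Channel names travel in the page description tags; pixel size and
    compartment in the shaped metadata.
    """
    names = sorted(field.channels)
    stack = np.stack([field.channels[n].astype(np.uint8) * 255 for n in names])
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={
            "channels": names,
            "pixel_size_um": field.pixel_size,
            "compartment": field.compartment,
            "image_id": field.image_id,
            "mouse_id": field.mouse_id,
        },
    )


def read_if_field(path) -> IFField:
    """Read an IF field written by :func:`write_if_field`."""
    with tifffile.TiffFile(path) as tf:
        meta = tf.shaped_metadata[0]
        stack = tf.asarray()
    channels = {n: stack[i] > 0 for i, n in enumerate(meta["channels"])}
    return IFField(
        channels,
        float(meta["pixel_size_um"]),
        meta["compartment"],
        image_id=meta.get("image_id", ""),
        mouse_id=meta.get("mouse_id", ""),
    )


def write_if_field_dir(directory, field: IFField) -> None:
    """Write an IF field as single-channel PNGs plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "pixel_size_um": field.pixel_size,
        "compartment": field.compartment,
        "image_id": field.image_id,
        "mouse_id": field.mouse_id,
        "channels": {},
    }
    for name, mask in field.channels.items():
        fname = f"{name}.png"
        iio.imwrite(directory / fname, mask.astype(np.uint8) * 255)
        manifest["channels"][name] = fname
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def read_if_field_dir(directory) -> IFField:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    channels = {
        name: iio.imread(directory / fname) > 0
        for name, fname in manifest["channels"].items()
    }
    return IFField(
        channels,
        float(manifest["pixel_size_um"]),
        manifest["compartment"],
        image_id=manifest.get("image_id", ""),
        mouse_id=manifest.get("mouse_id", ""),
    )
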