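"""Volume and transform serialization.

NRRD carries its own spacing metadata and is the preferred on-disk format
(read and written through SimpleITK).  TIFF stacks are supported for
interoperability but carry no 3D spacing, so they require a JSON sidecar
(``<name>.spacing.json``); a missing sidecar is an error, never a silent
default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .volume import Volume

__all__ = ["read_volume", "write_volume", "SUPPORTED_EXTENSIONS"]

SUPPORTED_EXTENSIONS = (".nrrd", ".nhdr", ".tif", ".tiff")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".spacing.json")


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume; NRRD embeds spacing, TIFF gets a JSON sidecar."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".nrrd", ".nhdr"):
        img = sitk.GetImageFromArray(vol.data)   # keeps (z, y, x) memory order
        img.SetSpacing(tuple(vol.spacing[::-1]))  # SimpleITK wants (x, y, z)
        img.SetOrigin(tuple(vol.origin[::-1]))
        sitk.WriteImage(img, str(path), useCompression=False)
    elif ext in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.data, photometric="minisblack")
        _sidecar_path(path).write_text(
            json.dumps(
                {"spacing_um_zyx": list(vol.spacing),
                 "origin_um_zyx": list(vol.origin),
                 "channel_tag": vol.channel_tag},
                indent=1,
            )
        )
    else:
        raise ValueError(
            f"unsupported extension {ext!r}; supported: {', '.join(SUPPORTED_EXTENSIONS)}"
        )
    return path


def read_volume(path: str | Path, channel_tag: str = "") -> Volume:
    """Read a volume; fails if spacing metadata cannot be recovered."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".nrrd", ".nhdr"):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = tuple(img.GetSpacing()[::-1])
        origin = tuple(img.GetOrigin()[::-1])
        return Volume(data, spacing, origin, channel_tag)
    if ext in (".tif", ".tiff"):
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"TIFF volume {path} has no spacing sidecar {sidecar.name}; "
                "3D voxel spacing must be explicit"
            )
        meta = json.loads(sidecar.read_text())
        return Volume(
            tifffile.imread(path),
            tuple(meta["spacing_um_zyx"]),
            tuple(meta.get("origin_um_zyx", (0.0, 0.0, 0.0))),
            channel_tag or meta.get("channel_tag", ""),
        )
    raise ValueError(
        f"unsupported extension {ext!r}; supported: {', '.join(SUPPORTED_EXTENSIONS)}"
    )


def write_transform(transform, directory: str | Path, stem: str = "transform") -> Path:
    """Serialize a spatial transform: affine as JSON, field as NRRD vectors."""
    from .registration import SpatialTransform  # local import to avoid a cycle

    assert isinstance(transform, SpatialTransform)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "affine_matrix": np.asarray(transform.matrix).tolist(),
        "affine_offset": np.asarray(transform.offset).tolist(),
        "has_field": transform.field is not None,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    if transform.field is not None:
        arr = np.moveaxis(transform.field, 0, -1).astype(np.float32)
        img = sitk.GetImageFromArray(arr, isVector=True)
        img.SetSpacing(tuple(np.asarray(transform.field_spacing)[::-1]))
        sitk.WriteImage(img, str(directory / f"{stem}_field.nrrd"), useCompression=False)
    return directory / f"{stem}.json"


def read_transform(directory: str | Path, stem: str = "transform"):
    from .registration import SpatialTransform

    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    field = None
    field_spacing = None
    if meta["has_field"]:
        img = sitk.ReadImage(str(directory / f"{stem}_field.nrrd"))
        field = np.moveaxis(sitk.GetArrayFromImage(img), -1, 0).astype(float)
        field_spacing = tuple(img.GetSpacing()[::-1])
    return SpatialTransform(
        matrix=np.asarray(meta["affine_matrix"], float),
        offset=np.asarray(meta["affine_offset"], float),
        field=field,
        field_spacing=field_spacing,
    )
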