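"""Calibrated image-stack and table I/O, config loading, structured logging.

Stacks travel as :class:`ImageStack` — a T[,Z],Y,X array plus spatial and
temporal calibration — written to multi-page TIFF with a JSON sidecar
(``<stem>.json``) carrying the calibration.  Tables are plain CSV via pandas
with full float precision.  Axis convention: T, then Z if present, then Y,
then X; pixel coordinates are 0-based with the physical origin at the centre
of pixel (0, 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Type, TypeVar

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ValidationError

log = logging.getLogger("spherox")

DEFAULT_PIXEL_SIZE_UM = 1.0


def configure_logging(level: str = "INFO") -> None:
    """Timestamped, level-tagged, key=value log lines on stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s level=%(levelname)s module=%(name)s %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


@dataclass
class ImageStack:
    """Dimensioned grayscale pixel data with calibration metadata.

    ``data`` has shape (T, Y, X) or (T, Z, Y, X); intensities are
    non-negative.  ``timestamps_min`` is strictly increasing with length T.
    ``z_spacing_um`` is None for single-slice (no Z axis) stacks.
    """

    data: np.ndarray
    pixel_size_um: float
    timestamps_min: np.ndarray
    z_spacing_um: Optional[float] = None
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.timestamps_min = np.asarray(self.timestamps_min, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"data must be (T,Y,X) or (T,Z,Y,X), got shape {self.data.shape}"
            )
        has_z = self.data.ndim == 4
        if has_z and self.z_spacing_um is None:
            raise ValueError("4D stack requires z_spacing_um")
        if not has_z and self.z_spacing_um is not None:
            raise ValueError("z_spacing_um given but data has no Z axis")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.z_spacing_um is not None and not self.z_spacing_um > 0:
            raise ValueError(f"z_spacing_um must be > 0, got {self.z_spacing_um}")
        if self.timestamps_min.ndim != 1 or len(self.timestamps_min) != self.data.shape[0]:
            raise ValueError(
                f"timestamps length {self.timestamps_min.shape} does not match "
                f"T={self.data.shape[0]}"
            )
        if len(self.timestamps_min) > 1 and not np.all(np.diff(self.timestamps_min) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1] if self.data.ndim == 4 else 1

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def frame(self, t: int, z: Optional[int] = None) -> np.ndarray:
        """2D slice at frame ``t`` (and slice ``z`` for 4D stacks)."""
        if self.data.ndim == 3:
            if z not in (None, 0):
                raise ValueError("stack has no Z axis")
            return self.data[t]
        if z is None:
            raise ValueError("4D stack: specify z")
        return self.data[t, z]

    def astype_float(self) -> "ImageStack":
        """Copy with float64 data (analysis is done in float)."""
        return replace(self, data=self.data.astype(np.float64))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack to multi-page TIFF + JSON calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    meta = {
        "axes": "TZYX" if stack.data.ndim == 4 else "TYX",
        "pixel_size_um": stack.pixel_size_um,
        "z_spacing_um": stack.z_spacing_um,
        "timestamps_min": [float(t) for t in stack.timestamps_min],
        "channel_label": stack.channel_label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    log.info("wrote stack path=%s shape=%s", path, stack.data.shape)
    return path


def read_stack(path: str | Path, axes: Optional[str] = None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack, recovering calibration from the sidecar.

    Missing calibration falls back to documented defaults
    (``pixel_size_um=1.0``, unit-spaced timestamps) with a logged warning.
    2D single-frame files become T=1 stacks.  If the axis order cannot be
    inferred from the dimensionality (5D+ data), ``axes`` must be given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise IOError(f"could not read TIFF {path}: {exc}") from exc

    if data.ndim == 2:
        data = data[None]
    elif data.ndim not in (3, 4):
        if axes is None:
            raise ValueError(
                f"ambiguous {data.ndim}-D data in {path}: pass an explicit axes "
                "spec such as 'TZYX'"
            )
        raise ValueError(f"unsupported axes {axes} for shape {data.shape}")

    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        pixel_size = DEFAULT_PIXEL_SIZE_UM
        log.warning(
            "missing calibration path=%s key=pixel_size_um default=%s",
            path,
            pixel_size,
        )
    timestamps = meta.get("timestamps_min")
    if timestamps is None:
        timestamps = np.arange(data.shape[0], dtype=float)
        if data.shape[0] > 1:
            log.warning("missing calibration path=%s key=timestamps_min default=frame-index", path)
    z_spacing = meta.get("z_spacing_um") if data.ndim == 4 else None
    if data.ndim == 4 and z_spacing is None:
        z_spacing = DEFAULT_PIXEL_SIZE_UM
        log.warning("missing calibration path=%s key=z_spacing_um default=%s", path, z_spacing)

    return ImageStack(
        data=data,
        pixel_size_um=float(pixel_size),
        timestamps_min=np.asarray(timestamps, dtype=float),
        z_spacing_um=z_spacing,
        channel_label=str(meta.get("channel_label", "")),
    )


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> Path:
    """Write records to CSV: header always present, floats at full precision,
    deterministic row order (input order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            schema = tuple(records[0].keys())
            for i, rec in enumerate(records):
                if tuple(rec.keys()) != schema:
                    raise ValueError(
                        f"heterogeneous record schemas: row 0 has {schema}, "
                        f"row {i} has {tuple(rec.keys())}"
                    )
            df = pd.DataFrame.from_records(records, columns=list(schema))
        else:
            df = pd.DataFrame()
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys."""


def _no_duplicates(loader: _StrictLoader, node: yaml.MappingNode, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise yaml.YAMLError(
                f"duplicate key {key!r} at line {key_node.start_mark.line + 1}"
            )
        seen.add(key)
    return loader.construct_mapping(node, deep=deep)  # type: ignore[arg-type]


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates
)

M = TypeVar("M", bound=BaseModel)


def load_config(path: str | Path, model: Type[M]) -> M:
    """Load and validate a YAML config into ``model``.

    Every parameter is checked against its type/range invariant before any
    computation; unknown and duplicate keys are rejected; validation errors
    name the offending key, value, and constraint.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.load(path.read_text(), Loader=_StrictLoader)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return model.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            f" (got {err.get('input')!r})"
            for err in exc.errors()
        )
        raise ValueError(f"invalid config {path}: {details}") from exc
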