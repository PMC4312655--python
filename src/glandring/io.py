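"""Readers and writers for stacks, masks, bags, matrices and reports.

Conventions used throughout: pixel coordinates are 0-based (row, column);
masks use 0 = background; probability stacks are stored as multi-page
float32 TIFF (one page per class, values in [0, 1]) and computed on in
float64; label images are 16-bit PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from glandring.core_maps import ProbabilityMapStack
from glandring.mil import Bag, DissimilarityMatrix


def read_stack(path: str | Path, normalize: bool = False) -> ProbabilityMapStack:
    """Read a probability-map stack from a multi-page TIFF."""
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - surface a uniform error
        raise ValueError(f"cannot read stack from {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a multi-page TIFF (K pages), got shape {arr.shape}")
    stack = ProbabilityMapStack(np.moveaxis(arr, 0, 2))
    if normalize:
        from glandring.core_maps import normalize_stack

        stack = normalize_stack(stack)
    return stack


def write_stack(stack: ProbabilityMapStack, path: str | Path) -> None:
    """Write a stack as multi-page float32 TIFF, one page per class."""
    pages = np.moveaxis(stack.values, 2, 0).astype(np.float32)
    tifffile.imwrite(str(path), pages, photometric="minisblack")


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 8-bit PNG (0/255)."""
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(str(path))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path))) > 0


def write_labels(label_image: np.ndarray, path: str | Path) -> None:
    """Write a region label image as 16-bit PNG."""
    arr = np.asarray(label_image)
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many regions for 16-bit PNG")
    Image.fromarray(arr.astype(np.uint16)).save(str(path))


def write_bags(bags: list[Bag], path: str | Path) -> None:
    """Serialize bags as JSON: bag_id, label, instance matrix."""
    payload = [
        {"bag_id": b.bag_id, "label": b.label, "instances": b.instances.tolist()}
        for b in bags
    ]
    Path(path).write_text(json.dumps(payload))


def read_bags(path: str | Path) -> list[Bag]:
    payload = json.loads(Path(path).read_text())
    return [
        Bag(d["bag_id"], np.asarray(d["instances"]), label=d.get("label"))
        for d in payload
    ]


def write_dissimilarity(D: DissimilarityMatrix, path: str | Path) -> None:
    """CSV with bag ids as header row and index column."""
    pd.DataFrame(D.values, index=D.bag_ids, columns=D.bag_ids).to_csv(str(path))


def read_dissimilarity(path: str | Path) -> DissimilarityMatrix:
    df = pd.read_csv(str(path), index_col=0)
    return DissimilarityMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Write a JSON report stamped with the package version.

    The caller's dict should carry its config echo and seeds; this writer
    adds the software version so reruns are attributable.
    """
    from glandring import __version__

    out = dict(report)
    out.setdefault("software_version", __version__)
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonable))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
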