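"""File I/O helpers: images, truth sidecars, CSV tables with provenance.

Every CSV written by the pipeline starts with two comment lines: a
timestamp line (the only line allowed to differ between identical runs)
and a provenance line carrying the tool version, a config hash and the
seed, so outputs are auditable and byte-comparable minus one line.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .imagetraits import CrossSectionImage
from .synthgen import GroundTruthRecord

__all__ = [
    "config_hash",
    "provenance_lines",
    "write_csv_with_provenance",
    "read_csv_skip_comments",
    "write_image",
    "read_image",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "write_genotype_matrix",
    "read_genotype_matrix",
]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(config: dict, seed: int | None) -> list[str]:
    ts = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return [
        f"# generated: {ts}",
        f"# stalktraits v{__version__} | config_sha256={config_hash(config)} | seed={seed}",
    ]


def write_csv_with_provenance(
    df: pd.DataFrame, path: str | Path, config: dict, seed: int | None, index: bool = False
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, index=index)


def read_csv_skip_comments(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_image(image: CrossSectionImage, path: str | Path) -> None:
    """Write a single-channel 8-bit TIFF or PNG, chosen by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = image.to_uint8()
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def read_image(path: str | Path, scale_cm_per_px: float) -> CrossSectionImage:
    return CrossSectionImage.from_file(path, scale_cm_per_px)


def write_truth_sidecar(truth: GroundTruthRecord, image_path: str | Path) -> Path:
    out = Path(image_path).with_suffix(".truth.json")
    out.write_text(truth.to_json())
    return out


def read_truth_sidecar(image_path: str | Path) -> GroundTruthRecord:
    return GroundTruthRecord.from_json(Path(image_path).with_suffix(".truth.json").read_text())


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited sites x individuals matrix, '.' marking missing."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index_label="site")


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site", dtype=str, comment="#")
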