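"""File formats: TIFF image stacks, 8-bit masks, TSV tables with
provenance headers, BED intervals, chromosome sizes and polygon CSVs.

All tables are tab-separated UTF-8 with a header row; lines starting with
``#`` before the header carry provenance (package version and config
hash) and are skipped on read. Masks are written as 8-bit TIFF with
values 0/255.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_channels",
    "read_channels",
    "write_mask",
    "read_mask",
    "write_label_map",
    "read_label_map",
    "write_table",
    "read_table",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_polygon_csv",
    "read_polygon_csv",
]


def write_channels(path: str | Path, channels: Mapping[str, np.ndarray]) -> None:
    """Write named channels as a multi-page 32-bit float TIFF.

    Channel names are stored in the page descriptions so the stack can be
    read back into a named dict.
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, img in channels.items():
            tif.write(
                np.asarray(img, dtype=np.float32),
                description=name,
                contiguous=False,
            )


def read_channels(path: str | Path) -> dict[str, np.ndarray]:
    """Read a multi-page TIFF back into ``{channel name: float array}``."""
    out: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(str(path)) as tif:
        for i, page in enumerate(tif.pages):
            name = page.description or f"channel_{i}"
            out[name] = page.asarray().astype(float)
    return out


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit TIFF (0/255)."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    tifffile.imwrite(str(path), arr)


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer label image (e.g. a phase label map) as 8-bit TIFF."""
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint8))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.uint8)


def write_table(
    path: str | Path,
    table: pd.DataFrame,
    provenance: Sequence[str] = (),
    float_format: str = "%.10g",
) -> None:
    """Write a tidy TSV with optional ``#``-prefixed provenance header lines.

    The fixed float format keeps repeated runs byte-identical.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a (chromosome, start, end[, name]) frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=range(3), dtype={0: str}
    )
    df.columns = ["chromosome", "start", "end"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    intervals[["chromosome", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-size TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    return dict(zip(df[0], df[1].astype(int)))


def write_polygon_csv(path: str | Path, vertices: np.ndarray) -> None:
    """Write polygon vertices as a two-column (x, y) CSV."""
    pd.DataFrame(np.asarray(vertices, float), columns=["x", "y"]).to_csv(
        path, index=False
    )


def read_polygon_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x", "y"]].to_numpy(dtype=float)
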