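"""Shared readers and writers for the pipeline's on-disk formats.

Images travel as single- or multi-page TIFF, interval data as 3+ column BED
(0-based, half-open), and tabular data as TSV/CSV.  All writers are
deterministic: identical in-memory objects produce byte-identical files, which
the pipeline manifest relies on.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile
import yaml

PathLike = Union[str, Path]

# full round-trip precision for float columns in text tables
_FLOAT_FMT = "%.17g"


def read_image(path: PathLike) -> np.ndarray:
    """Read a single- or multi-page TIFF into an array (pages stacked on axis 0)."""
    return tifffile.imread(str(path))


def write_image(path: PathLike, image: np.ndarray) -> None:
    """Write an array as TIFF without time-stamped metadata (deterministic bytes)."""
    image = np.asarray(image)
    tifffile.imwrite(str(path), image, software=None, photometric="minisblack")


def read_table(path: PathLike, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV table; the separator is inferred from the extension."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def write_table(table: pd.DataFrame, path: PathLike, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_bed(path: PathLike) -> pd.DataFrame:
    """Read a BED file into columns (chrom, start, end), validating each line.

    Coordinates are 0-based half-open.  Malformed lines (fewer than 3 fields,
    non-integer or negative coordinates, start >= end) raise ``ValueError``
    naming the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: expected >= 3 fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"BED line {lineno}: require 0 <= start < end, got [{start}, {end})"
                )
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(intervals: pd.DataFrame, path: PathLike) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


class RunConfig:
    """Validated configuration of a pipeline run, loaded from a single YAML file.

    Known top-level keys: ``seed`` (mandatory), ``outdir``, ``stages``, and one
    parameter block per stage.  Unknown keys are rejected so typos fail loudly.
    """

    STAGES = ("simulate", "quantify", "doseresponse", "spatial", "smfish", "enrich")
    _KNOWN = {"seed", "outdir", "stages"} | set(STAGES)

    def __init__(self, data: dict):
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        unknown = set(data) - self._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config requires an explicit 'seed'")
        self.seed = int(data["seed"])
        self.outdir = Path(data.get("outdir", "switchquant_out"))
        self.stages = list(data.get("stages", self.STAGES))
        bad = [s for s in self.stages if s not in self.STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        self.params = {s: dict(data.get(s, {})) for s in self.STAGES}

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
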