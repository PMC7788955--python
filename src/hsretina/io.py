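"""Hyperspectral cube and cohort-manifest I/O.

Cubes are stored either as ENVI pairs (a plain-text ``.hdr`` header carrying
the wavelength list next to a raw binary payload) or as multi-page TIFF files
(one page per band) with the wavelength grid in a JSON sidecar.  Acquisition
provenance (mouse, genotype class, age, field) travels in a JSON sidecar for
both formats so that a written cube round-trips bit-exactly, metadata
included.

The cohort manifest is a CSV assigning every cube file to a mouse, a genotype
class (``AD`` amyloid model vs ``CO`` wild-type control), an age and one of
the eight retinal sampling fields (four quadrants x central/peripheral).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CLASS_LABELS",
    "QUADRANTS",
    "FormatError",
    "ManifestError",
    "WavelengthGrid",
    "CubeMeta",
    "HyperCube",
    "CohortManifest",
    "eccentricity_of",
    "quadrant_of",
    "load_cube",
    "write_cube",
    "load_manifest",
    "write_manifest",
]

CLASS_LABELS = ("AD", "CO")

#: Quadrant order for fields (1,2), (3,4), (5,6), (7,8): clockwise from superior.
QUADRANTS = ("superior", "nasal", "inferior", "temporal")

VALID_FIELD_IDS = tuple(range(1, 9))


class FormatError(ValueError):
    """A cube file is internally inconsistent (bands, wavelengths, payload)."""


class ManifestError(ValueError):
    """A cohort manifest violates its consistency rules."""


def eccentricity_of(field_id: int) -> str:
    """Even-numbered fields sample the peripheral retina, odd the central."""
    if field_id not in VALID_FIELD_IDS:
        raise ManifestError(f"field_id must be in 1..8, got {field_id}")
    return "peripheral" if field_id % 2 == 0 else "central"


def quadrant_of(field_id: int) -> str:
    if field_id not in VALID_FIELD_IDS:
        raise ManifestError(f"field_id must be in 1..8, got {field_id}")
    return QUADRANTS[(field_id - 1) // 2]


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-centre wavelengths (nm) shared by all cubes of a cohort."""

    nm: tuple

    def __init__(self, nm: Iterable[float]):
        nm = tuple(float(v) for v in nm)
        if len(nm) == 0:
            raise FormatError("wavelength grid must contain at least one band")
        arr = np.asarray(nm)
        if not np.all(np.diff(arr) > 0):
            raise FormatError("wavelengths must be strictly ascending")
        if arr.min() <= 300 or arr.max() >= 1100:
            raise FormatError(
                "wavelengths outside (300, 1100) nm are not plausible for a "
                "visible/NIR sensor"
            )
        object.__setattr__(self, "nm", nm)

    @property
    def band_count(self) -> int:
        return len(self.nm)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.nm, dtype=float)

    @classmethod
    def default_visible(cls, band_count: int = 70,
                        lo: float = 471.0, hi: float = 691.0) -> "WavelengthGrid":
        """Evenly spaced band centres over the visible acquisition range."""
        return cls(np.linspace(lo, hi, band_count))


@dataclass(frozen=True)
class CubeMeta:
    """Provenance of one imaged field."""

    mouse_id: str
    class_label: str
    age_months: float
    field_id: int

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ManifestError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if self.field_id not in VALID_FIELD_IDS:
            raise ManifestError(f"field_id must be in 1..8, got {self.field_id}")

    @property
    def eccentricity(self) -> str:
        return eccentricity_of(self.field_id)

    @property
    def quadrant(self) -> str:
        return quadrant_of(self.field_id)

    def to_dict(self) -> dict:
        return {
            "mouse_id": self.mouse_id,
            "class_label": self.class_label,
            "age_months": self.age_months,
            "field_id": self.field_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CubeMeta":
        return cls(
            mouse_id=str(d["mouse_id"]),
            class_label=str(d["class_label"]),
            age_months=float(d["age_months"]),
            field_id=int(d["field_id"]),
        )


@dataclass
class HyperCube:
    """One imaged field: height x width x band intensity array plus its grid.

    Values are unitless relative intensities.  Raw cubes are nonnegative;
    normalized cubes reuse this container and may carry values outside
    [0, 1] prior to outlier masking.
    """

    data: np.ndarray
    grid: WavelengthGrid
    meta: CubeMeta | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(
                f"cube data must be 3-D (h, w, bands), got shape {self.data.shape}"
            )
        h, w, b = self.data.shape
        if h < 1 or w < 1:
            raise FormatError("cube spatial dimensions must be >= 1")
        if b != self.grid.band_count:
            raise FormatError(
                f"band dimension {b} does not match wavelength grid "
                f"({self.grid.band_count} bands)"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("cube contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


# ---------------------------------------------------------------------------
# ENVI header + raw binary
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}
_ENVI_CODES = {np.dtype("<f4"): 4, np.dtype("<f8"): 5}


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` lines of an ENVI header."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic line)")
    # join brace-delimited values that may span lines
    body = text.split("\n", 1)[1] if "\n" in text else ""
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", body,
                         flags=re.M | re.S):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _envi_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _read_envi(path: Path) -> HyperCube:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "5"))
        interleave = fields.get("interleave", "bsq").lower()
        wavelengths = _envi_list(fields["wavelength"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    if len(wavelengths) != bands:
        raise FormatError(
            f"header lists {len(wavelengths)} wavelengths for {bands} bands"
        )
    grid = WavelengthGrid(wavelengths)
    dtype = _ENVI_DTYPES[dtype_code]
    raw = np.fromfile(path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"payload holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    meta = _load_meta_sidecar(path)
    return HyperCube(np.ascontiguousarray(data), grid, meta)


def _write_envi(cube: HyperCube, path: Path) -> None:
    h, w, b = cube.data.shape
    dtype = np.dtype("<f8")
    hdr = path.with_suffix(".hdr")
    wl = ", ".join(repr(v) for v in cube.grid.nm)  # full float precision
    hdr.write_text(
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    cube.data.transpose(2, 0, 1).astype(dtype).tofile(path)


# ---------------------------------------------------------------------------
# multi-page TIFF + JSON wavelength sidecar
# ---------------------------------------------------------------------------

def _read_tiff(path: Path) -> HyperCube:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"TIFF cube requires a wavelength sidecar {sidecar.name}"
        )
    info = json.loads(sidecar.read_text())
    grid = WavelengthGrid(info["wavelength_nm"])
    if pages.shape[0] != grid.band_count:
        raise FormatError(
            f"TIFF holds {pages.shape[0]} pages for {grid.band_count} bands"
        )
    meta = CubeMeta.from_dict(info["meta"]) if info.get("meta") else None
    return HyperCube(np.ascontiguousarray(pages.transpose(1, 2, 0)), grid, meta)


def _write_tiff(cube: HyperCube, path: Path) -> None:
    tifffile.imwrite(path, cube.data.transpose(2, 0, 1),
                     photometric="minisblack")
    info = {"wavelength_nm": list(cube.grid.nm),
            "meta": cube.meta.to_dict() if cube.meta else None}
    _sidecar_path(path).write_text(json.dumps(info, indent=1))


def _load_meta_sidecar(path: Path) -> CubeMeta | None:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        if info.get("meta"):
            return CubeMeta.from_dict(info["meta"])
    return None


def _write_meta_sidecar(cube: HyperCube, path: Path) -> None:
    if cube.meta is not None:
        _sidecar_path(path).write_text(
            json.dumps({"meta": cube.meta.to_dict()}, indent=1)
        )


def load_cube(path, format: str | None = None) -> HyperCube:
    """Read a hyperspectral cube; values are returned unscaled.

    ``format`` is ``"envi"`` or ``"tiff"``; if omitted it is inferred from
    the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cube file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "tiff":
        return _read_tiff(path)
    raise ValueError(f"unknown cube format {fmt!r}")


def write_cube(cube: HyperCube, path, format: str | None = None) -> Path:
    """Write a cube such that :func:`load_cube` round-trips it bit-exactly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "envi":
        _write_envi(cube, path)
        _write_meta_sidecar(cube, path)
    elif fmt == "tiff":
        _write_tiff(cube, path)
    else:
        raise ValueError(f"unknown cube format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    return "envi"


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("cube_path", "mouse_id", "class_label", "age_months", "field_id")


@dataclass
class CohortManifest:
    """Validated table of cubes with mouse/class/age/field assignments."""

    table: pd.DataFrame
    grid: WavelengthGrid | None = None

    def __post_init__(self):
        df = pd.DataFrame(self.table).copy()
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        df["mouse_id"] = df["mouse_id"].astype(str)
        df["class_label"] = df["class_label"].astype(str)
        df["age_months"] = df["age_months"].astype(float)
        df["field_id"] = df["field_id"].astype(int)
        bad_class = sorted(set(df["class_label"]) - set(CLASS_LABELS))
        if bad_class:
            raise ManifestError(f"unknown class labels: {bad_class}")
        bad_fields = sorted(set(df["field_id"]) - set(VALID_FIELD_IDS))
        if bad_fields:
            raise ManifestError(f"field_id values outside 1..8: {bad_fields}")
        classes_per_mouse = df.groupby("mouse_id")["class_label"].nunique()
        conflicted = classes_per_mouse[classes_per_mouse > 1].index.tolist()
        if conflicted:
            raise ManifestError(
                f"mice listed under both classes: {conflicted}"
            )
        dup = df.duplicated(subset=["mouse_id", "field_id"])
        if dup.any():
            pairs = df.loc[dup, ["mouse_id", "field_id"]].values.tolist()
            raise ManifestError(f"duplicate (mouse_id, field_id) rows: {pairs}")
        df["eccentricity"] = df["field_id"].map(eccentricity_of)
        df["quadrant"] = df["field_id"].map(quadrant_of)
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mouse_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["mouse_id"]))

    def class_of(self, mouse_id: str) -> str:
        rows = self.table[self.table["mouse_id"] == mouse_id]
        if rows.empty:
            raise ManifestError(f"mouse {mouse_id!r} not in manifest")
        return rows["class_label"].iloc[0]

    def rows(self):
        return self.table.itertuples(index=False)


def load_manifest(path, grid: WavelengthGrid | None = None) -> CohortManifest:
    """Read and validate a cohort manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    return CohortManifest(df, grid=grid)


def write_manifest(manifest: CohortManifest, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.table[list(MANIFEST_COLUMNS)].to_csv(path, index=False)
    return path
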