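"""Synthetic retinal hypercube cohorts with known amyloid ground truth.

The generator emulates what the scoring pipeline assumes about transmission
imaging of wholemounted retinas: a smooth positive baseline transmission
spectrum B(lambda); a Rayleigh-scattering amyloid signature that attenuates
short wavelengths preferentially, A(lambda; c) = exp(-kappa * c *
(lambda_ref / lambda)^4), with the per-mouse burden c drawn lognormally
around a class mean; a peripheral > central burden gradient (even-numbered
fields carry rho times the mouse burden); and multiplicative i.i.d.
Gaussian acquisition noise, clipped below at zero.

Every cohort is a pure function of its :class:`SimParams` — the same
parameter file reproduces every voxel — and the drawn burdens are returned
as a :class:`SyntheticTruth` so recovery can be checked against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .io import (CohortManifest, CubeMeta, HyperCube, WavelengthGrid,
                 eccentricity_of, write_cube, write_manifest)

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "baseline_spectrum",
    "amyloid_attenuation",
    "generate_cube",
    "generate_cohort",
]


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic cohort.

    Defaults follow the reference acquisition design: 70 visible bands over
    471–691 nm, eight fields per mouse (four quadrants, central and
    peripheral), eight mice per genotype group.  Frames default to 64 x 48
    pixels, a size parameter standing in for full 2048 x 1536 sensor frames.

    mu_ad, mu_co
        Class-mean amyloid burdens (unitless); a class mean of 0 yields an
        exactly burden-free group.  Per-mouse burdens are
        LogNormal(ln mu, tau).
    kappa
        Scattering strength per unit burden at the reference wavelength.
    rho
        Peripheral burden multiplier (>= 1); 1 removes the spatial gradient.
    noise_sd
        Multiplicative per-voxel noise sd; 0 removes noise.
    drift_sd
        Optional per-cube illumination drift (band-correlated multiplicative
        term), off by default.
    n_planted_outliers, planted_block
        Per-cube count of deliberately out-of-range pixel blocks (block edge
        ``planted_block`` input pixels, aligned so that downsampling by
        1/planted_block turns each block into exactly one out-of-range
        pixel); used for masking checks.
    """

    band_count: int = 70
    lambda_min: float = 471.0
    lambda_max: float = 691.0
    frame_height: int = 64
    frame_width: int = 48
    n_ad: int = 8
    n_co: int = 8
    age_months: float = 18.0
    mu_ad: float = 1.2
    mu_co: float = 0.0
    tau: float = 0.3
    kappa: float = 0.08
    lambda_ref: float = 550.0
    rho: float = 1.5
    noise_sd: float = 0.05
    drift_sd: float = 0.0
    baseline_offset: float = 0.55
    baseline_amplitude: float = 0.45
    baseline_center: float = 560.0
    baseline_scale: float = 60.0
    n_planted_outliers: int = 0
    planted_block: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.band_count < 1:
            raise ValueError("band_count must be >= 1")
        if self.lambda_min >= self.lambda_max:
            raise ValueError("lambda_min must be below lambda_max")
        if self.frame_height < 1 or self.frame_width < 1:
            raise ValueError("frame dimensions must be >= 1")
        if self.n_ad < 1 or self.n_co < 1:
            raise ValueError("need at least one mouse per class")
        if self.mu_ad < 0 or self.mu_co < 0:
            raise ValueError("class burden means must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.rho < 1:
            raise ValueError("peripheral multiplier rho must be >= 1")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.baseline_offset <= 0:
            raise ValueError("baseline offset must be positive")
        if self.baseline_offset + min(0.0, self.baseline_amplitude) <= 0:
            raise ValueError("baseline parameters yield non-positive values")
        if self.n_planted_outliers < 0:
            raise ValueError("n_planted_outliers must be >= 0")
        if self.n_planted_outliers > 0:
            if self.planted_block < 1:
                raise ValueError("planted_block must be >= 1")
            if (self.frame_height % self.planted_block
                    or self.frame_width % self.planted_block):
                raise ValueError(
                    "frame dimensions must be divisible by planted_block "
                    "when planting outliers"
                )
            blocks = ((self.frame_height // self.planted_block)
                      * (self.frame_width // self.planted_block))
            if self.n_planted_outliers > blocks:
                raise ValueError(
                    f"frame too small: {blocks} blocks available for "
                    f"{self.n_planted_outliers} planted outliers"
                )

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(
            np.linspace(self.lambda_min, self.lambda_max, self.band_count))

    @classmethod
    def three_month_like(cls, **overrides) -> "SimParams":
        """Small early-stage effect confined to the shortest wavelengths."""
        return cls(**{"mu_ad": 0.4, "age_months": 3.0, **overrides})

    @classmethod
    def eighteen_month_like(cls, **overrides) -> "SimParams":
        """Larger late-stage effect extending toward 600 nm."""
        return cls(**{"mu_ad": 1.2, "age_months": 18.0, **overrides})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: burdens, planted outliers, params."""

    burdens: dict                 # mouse_id -> true burden c
    field_burdens: dict           # (mouse_id, field_id) -> effective burden
    planted_outliers: dict        # (mouse_id, field_id) -> list of (y, x) blocks
    params: SimParams

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "burdens": self.burdens,
            "field_burdens": {f"{m}:{f}": v
                              for (m, f), v in self.field_burdens.items()},
            "planted_outliers": {f"{m}:{f}": v
                                 for (m, f), v in self.planted_outliers.items()},
            "params": asdict(self.params),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def baseline_spectrum(grid: WavelengthGrid, params: SimParams) -> np.ndarray:
    """Smooth positive baseline transmission B(lambda).

    A logistic ramp rising toward long wavelengths: transmission through the
    mounted tissue is lower at the blue end.  Deterministic in the
    parameters; the first differences are bounded by
    amplitude * d_lambda / (4 * scale).
    """
    lam = grid.as_array()
    b = params.baseline_offset + params.baseline_amplitude / (
        1.0 + np.exp(-(lam - params.baseline_center) / params.baseline_scale))
    if np.any(b <= 0):
        raise ValueError("baseline parameters produced non-positive values")
    return b


def amyloid_attenuation(grid: WavelengthGrid, c: float, kappa: float,
                        lambda_ref: float) -> np.ndarray:
    """Rayleigh-type attenuation factor A(lambda; c) in (0, 1].

    Beer–Lambert-style exponential with the lambda^-4 Rayleigh wavelength
    dependence: short wavelengths are attenuated more, and doubling the
    burden squares the factor.
    """
    if c < 0:
        raise ValueError("burden c must be >= 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    lam = grid.as_array()
    return np.exp(-kappa * c * (lambda_ref / lam) ** 4)


#: Multiple of the local baseline used for planted out-of-range blocks; far
#: enough above the 1.5 outlier threshold to survive averaging and noise.
_PLANT_FACTOR = 6.0


def generate_cube(burden: float, meta: CubeMeta, params: SimParams,
                  rng: np.random.Generator,
                  plant_outliers: bool | None = None
                  ) -> tuple[HyperCube, list]:
    """One noisy field image for a given effective burden.

    Returns the cube and the list of planted outlier block positions (block
    coordinates on the grid of ``planted_block``-sized tiles; empty when
    nothing was planted).
    """
    grid = params.grid()
    base = baseline_spectrum(grid, params) * amyloid_attenuation(
        grid, burden, params.kappa, params.lambda_ref)
    h, w = params.frame_height, params.frame_width
    data = np.broadcast_to(base, (h, w, grid.band_count)).copy()
    if params.drift_sd > 0:
        data *= 1.0 + params.drift_sd * rng.standard_normal()
    if params.noise_sd > 0:
        data *= 1.0 + params.noise_sd * rng.standard_normal(data.shape)
    np.clip(data, 0.0, None, out=data)
    planted: list = []
    if plant_outliers is None:
        plant_outliers = params.n_planted_outliers > 0
    if plant_outliers and params.n_planted_outliers > 0:
        blk = params.planted_block
        nby, nbx = h // blk, w // blk
        flat = rng.choice(nby * nbx, size=params.n_planted_outliers,
                          replace=False)
        for pos in flat:
            by, bx = int(pos) // nbx, int(pos) % nbx
            data[by * blk:(by + 1) * blk, bx * blk:(bx + 1) * blk, 0] = \
                _PLANT_FACTOR * base[0]
            planted.append((by, bx))
    return HyperCube(data, grid, meta), planted


def generate_cohort(params: SimParams, out_dir=None, format: str = "envi"
                    ) -> tuple[list, CohortManifest, SyntheticTruth]:
    """Generate a full cohort: per-mouse burdens, 8 fields per mouse.

    Per-mouse burdens are LogNormal(ln mu_class, tau), or exactly 0 when the
    class mean is 0; peripheral (even-numbered) fields carry rho times the
    mouse burden.  Sub-streams are derived deterministically per cube, so
    the cohort is reproducible piecewise from the seed.

    When ``out_dir`` is given, cubes, the manifest CSV and the truth JSON
    are written there; otherwise everything stays in memory and the manifest
    carries in-memory placeholder paths.
    """
    root = np.random.SeedSequence(params.seed)
    burden_ss, cube_root = root.spawn(2)
    burden_rng = np.random.default_rng(burden_ss)

    mice = [(f"AD{i + 1:02d}", "AD") for i in range(params.n_ad)] + \
           [(f"CO{i + 1:02d}", "CO") for i in range(params.n_co)]
    burdens: dict[str, float] = {}
    for mouse_id, cls in mice:
        mu = params.mu_ad if cls == "AD" else params.mu_co
        if mu == 0.0:
            burdens[mouse_id] = 0.0
        else:
            burdens[mouse_id] = float(
                burden_rng.lognormal(np.log(mu), params.tau))

    cube_streams = cube_root.spawn(len(mice) * 8)
    cubes, rows = [], []
    field_burdens: dict = {}
    planted_map: dict = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    suffix = ".tif" if format == "tiff" else ".img"
    k = 0
    for mouse_id, cls in mice:
        for field_id in range(1, 9):
            mult = params.rho if eccentricity_of(field_id) == "peripheral" else 1.0
            c_eff = burdens[mouse_id] * mult
            field_burdens[(mouse_id, field_id)] = c_eff
            meta = CubeMeta(mouse_id, cls, params.age_months, field_id)
            rng = np.random.default_rng(cube_streams[k])
            k += 1
            cube, planted = generate_cube(c_eff, meta, params, rng)
            planted_map[(mouse_id, field_id)] = planted
            if out_path is not None:
                fname = f"{mouse_id}_f{field_id}{suffix}"
                write_cube(cube, out_path / fname, format=format)
                cube_path = fname
            else:
                cube_path = f"<memory>/{mouse_id}_f{field_id}"
            cubes.append(cube)
            rows.append({
                "cube_path": cube_path,
                "mouse_id": mouse_id,
                "class_label": cls,
                "age_months": params.age_months,
                "field_id": field_id,
            })
    import pandas as pd
    manifest = CohortManifest(pd.DataFrame(rows), grid=params.grid())
    truth = SyntheticTruth(burdens, field_burdens, planted_map, params)
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.csv")
        truth.to_json(out_path / "truth.json")
    return cubes, manifest, truth
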