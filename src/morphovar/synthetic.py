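"""Synthetic landmark samples with known structure.

The generator emulates a Procrustes-scale 3D landmark study: a fixed
template (points spread on an ellipsoid or cube lattice), isotropic
per-landmark Gaussian noise whose standard deviation can be inflated inside
named partitions (localized variability, the signal the variation test is
built to detect), optional allometry (a shape direction coupled to log
centroid size), and per-group mean offsets. Specimens are emitted in "raw"
digitizing space — randomly rotated, translated and scaled — so the full
pipeline from superimposition onward is exercised, not just post-alignment
arithmetic.

Every draw is reproducible from the spec's seed, and the returned truth
record stores all generating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import Configuration, MorphovarError, Partition, Sample

__all__ = [
    "SimulationSpec",
    "Allometry",
    "make_template",
    "simulate_sample",
    "shape_tangent_direction",
]

GEOMETRIES = ("ellipsoid_lattice", "cube_lattice")


def make_template(L: int, geometry: str = "ellipsoid_lattice", seed: int | None = None) -> Configuration:
    """Deterministic, well-spread 3D template: centroid at the origin, unit
    centroid size.

    ``ellipsoid_lattice`` places L points on a 1 : 0.7 : 0.55 ellipsoid via
    the Fibonacci spiral; ``cube_lattice`` fills an m³ grid (for L = 8, the
    vertices of a cube). The template is a pure function of (L, geometry);
    ``seed`` is accepted for interface symmetry with the sampler.
    """
    if L < 8:
        raise MorphovarError(f"template needs L >= 8 landmarks, got {L}")
    if geometry == "ellipsoid_lattice":
        i = np.arange(L)
        z = 1.0 - 2.0 * (i + 0.5) / L
        r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        pts *= np.array([1.0, 0.7, 0.55])
    elif geometry == "cube_lattice":
        m = 2
        while m**3 < L:
            m += 1
        g = np.arange(m, dtype=float)
        grid = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
        pts = grid[:L]
    else:
        raise MorphovarError(f"unknown geometry {geometry!r}; expected one of {GEOMETRIES}")
    pts = pts - pts.mean(axis=0)
    cs = np.sqrt((pts**2).sum())
    if cs == 0:
        raise MorphovarError("degenerate template")
    return Configuration("template", pts / cs)


def shape_tangent_direction(
    template: Configuration, rng: np.random.Generator
) -> np.ndarray:
    """A random unit 3L-vector orthogonal to the template's similarity modes
    (3 translations, 3 infinitesimal rotations, uniform scaling).

    Shape effects applied along such a direction are not absorbed by
    Procrustes superimposition, so generated signals (allometry, group
    offsets) survive GPA and can be recovered downstream.
    """
    x = template.coords
    L = x.shape[0]
    basis = []
    for k in range(3):  # translations
        t = np.zeros((L, 3))
        t[:, k] = 1.0
        basis.append(t.ravel())
    basis.append(x.ravel())  # scaling (radial) mode
    for k in range(3):  # rotation generators: e_k × x_i
        e = np.zeros(3)
        e[k] = 1.0
        basis.append(np.cross(np.broadcast_to(e, x.shape), x).ravel())
    Q, _ = np.linalg.qr(np.column_stack(basis))
    v = rng.standard_normal(3 * L)
    v -= Q @ (Q.T @ v)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise MorphovarError("degenerate random direction")
    return v / nrm


@dataclass
class Allometry:
    """Allometric component: shape shifts along ``direction`` by
    ``slope × (log size − mean log size)``.

    ``direction`` is a unit 3L-vector; None draws one in the similarity
    tangent space of the template.
    """

    slope: float
    direction: np.ndarray | None = None
    size_range: tuple[float, float] = (0.8, 1.25)


@dataclass
class SimulationSpec:
    """All generating parameters for one synthetic sample.

    Defaults mirror a single-population landmark study at digitizing
    precision: ``base_sd = 0.01`` Procrustes units of isotropic per-landmark
    noise, sizes within ±10% of the template. ``inflation`` maps partitions
    to multiplicative noise-sd factors ≥ 1 (localized excess variability).
    """

    n: int
    template: Configuration | None = None
    L: int = 100
    geometry: str = "ellipsoid_lattice"
    base_sd: float = 0.01
    inflation: Mapping[Partition, float] | Sequence[tuple[Partition, float]] = dc_field(
        default_factory=dict
    )
    allometry: Allometry | None = None
    group_offsets: Mapping[str, np.ndarray] | None = None
    groups: Sequence[str] | None = None
    size_range: tuple[float, float] = (0.9, 1.1)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise MorphovarError("need n >= 2 specimens")
        if self.base_sd <= 0:
            raise MorphovarError("base_sd must be > 0")
        items = (
            list(self.inflation.items())
            if isinstance(self.inflation, Mapping)
            else list(self.inflation)
        )
        for part, factor in items:
            if factor < 1:
                raise MorphovarError(
                    f"inflation factor for {part.name!r} must be >= 1, got {factor}"
                )
        self.inflation = items
        if self.group_offsets is not None:
            if self.groups is None:
                raise MorphovarError("group_offsets given but no group assignment")
            if len(self.groups) != self.n:
                raise MorphovarError(
                    f"{len(self.groups)} group labels for n = {self.n}"
                )
            unknown = set(self.groups) - set(self.group_offsets)
            if unknown:
                raise MorphovarError(f"groups without an offset: {sorted(unknown)}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def simulate_sample(spec: SimulationSpec) -> tuple[Sample, dict]:
    """Draw a landmark sample from ``spec``; returns the sample plus a truth
    record holding every generating parameter (sufficient, with the seed, to
    re-create the sample exactly)."""
    # two independent child streams so that supplying the drawn direction
    # explicitly (as the truth record does) reproduces the sample exactly
    dir_seed, data_seed = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(data_seed)
    template = spec.template or make_template(spec.L, spec.geometry)
    L = template.n_landmarks

    sd = np.full(L, spec.base_sd)
    for part, factor in spec.inflation:
        part.validate_against(L)
        sd[part.indices] = np.maximum(sd[part.indices], spec.base_sd * factor)

    allo_dir = None
    slope = 0.0
    size_range = spec.size_range
    if spec.allometry is not None:
        slope = spec.allometry.slope
        size_range = spec.allometry.size_range
        if spec.allometry.direction is not None:
            allo_dir = np.asarray(spec.allometry.direction, float)
            allo_dir = allo_dir / np.linalg.norm(allo_dir)
        else:
            allo_dir = shape_tangent_direction(template, np.random.default_rng(dir_seed))

    sizes = rng.uniform(size_range[0], size_range[1], size=spec.n)
    log_centered = np.log(sizes) - np.log(sizes).mean()

    configs = []
    groups = list(spec.groups) if spec.groups is not None else None
    for i in range(spec.n):
        shape = template.coords.copy()
        if spec.group_offsets is not None:
            off = np.asarray(spec.group_offsets[groups[i]], float).reshape(L, 3)
            shape = shape + off
        if allo_dir is not None:
            shape = shape + slope * log_centered[i] * allo_dir.reshape(L, 3)
        shape = shape + rng.normal(0.0, sd[:, None], size=(L, 3))
        raw = sizes[i] * shape
        raw = raw @ _random_rotation(rng) + rng.normal(0.0, 1.0, size=3)
        configs.append(Configuration(f"sim_{i + 1:03d}", raw, template.landmark_ids))

    meta = pd.DataFrame({"size_true": sizes})
    if groups is not None:
        meta["species"] = groups
    sample = Sample(configs, meta)
    truth = {
        "seed": spec.seed,
        "n": spec.n,
        "L": L,
        "geometry": spec.geometry if spec.template is None else "custom",
        "base_sd": spec.base_sd,
        "sd_per_landmark": sd.tolist(),
        "inflated": {p.name: (p.indices + 1).tolist() for p, _ in spec.inflation},
        "inflation_factors": {p.name: f for p, f in spec.inflation},
        "allometry_slope": slope,
        "allometry_direction": None if allo_dir is None else allo_dir.tolist(),
        "size_range": list(size_range),
        "sizes": sizes.tolist(),
        "groups": groups,
        "group_offsets": None
        if spec.group_offsets is None
        else {g: np.asarray(v, float).ravel().tolist() for g, v in spec.group_offsets.items()},
        "template": template.coords.tolist(),
    }
    return sample, truth
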