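"""Synthetic multi-site phantoms with the statistical structure the
classification framework assumes.

Three generators cover the pipeline end to end: ROI time-series phantoms
with block-correlated signal, class-dependent connectivity differences,
per-site baseline shifts, linear drift and white noise; voxel-level 4D
phantoms that exercise ReHo and ROI extraction; and labeled feature tables
with a planted informative subset for the selection and classification
stages.  Every generator is a pure function of its spec (including the
seed), so identical calls produce identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureMatrix
from .timeseries import Parcellation, RoiTimecourses, Volume4D

__all__ = [
    "PhantomSpec",
    "TableSpec",
    "generate_roi_phantom",
    "generate_voxel_phantom",
    "generate_feature_table",
    "generate_multimodal",
]


@dataclass
class PhantomSpec:
    """Study conditions for the ROI time-series phantom.

    Defaults give a desk-scale multi-site cohort: 60 subjects (15 per class
    per site at 2 sites), 30 ROIs in blocks of 5 with within-block
    correlation 0.5, 150 time points at TR = 2 s.  The patient class gets
    ``delta_r`` added to the correlation of ``n_affected_edges``
    between-block edges.  Sites differ by an additive baseline shift and a
    multiplicative scale; low-frequency structure is a random linear drift
    and measurement noise is white Gaussian.
    """

    n_per_class_per_site: int = 15
    n_sites: int = 2
    n_rois: int = 30
    n_timepoints: int = 150
    tr: float = 2.0
    block_size: int = 5
    within_block_r: float = 0.5
    n_affected_edges: int = 10
    delta_r: float = 0.3
    site_shift: tuple[float, ...] = (0.0, 0.5)
    site_scale: tuple[float, ...] = (1.0, 1.1)
    drift_amplitude: float = 0.1
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois % self.block_size:
            raise ValueError("n_rois must be a multiple of block_size")
        if len(self.site_shift) < self.n_sites or len(self.site_scale) < self.n_sites:
            raise ValueError("need a site_shift and site_scale per site")


@dataclass
class TableSpec:
    """Generic labeled feature table with a planted informative subset.

    Informative features are shifted by +/- effect_size/2 (in SD units)
    between the two classes; the rest are pure standard-normal noise.
    """

    n_per_class: tuple[int, int] = (40, 40)
    n_features: int = 500
    n_informative: int = 10
    effect_size: float = 1.0
    n_sites: int = 0
    site_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")


def _block_correlation(spec: PhantomSpec) -> np.ndarray:
    m, b = spec.n_rois, spec.block_size
    C = np.zeros((m, m))
    for start in range(0, m, b):
        C[start : start + b, start : start + b] = spec.within_block_r
    np.fill_diagonal(C, 1.0)
    return C


def affected_edges(spec: PhantomSpec) -> list[tuple[int, int]]:
    """The between-block ROI pairs carrying the class effect (0-based).

    Edges are vertex-disjoint (ROI k with ROI k + m/2), so the perturbation's
    spectral norm is exactly ``|delta_r|`` and positive-definiteness is
    guaranteed whenever ``|delta_r| < 1 - within_block_r``.
    """
    half = spec.n_rois // 2
    if spec.n_affected_edges > half:
        raise ValueError("n_affected_edges cannot exceed n_rois / 2")
    if half < spec.block_size:
        raise ValueError("phantom needs at least two blocks for between-block edges")
    return [(k, k + half) for k in range(spec.n_affected_edges)]


def _class_correlation(spec: PhantomSpec, patient: bool) -> np.ndarray:
    C = _block_correlation(spec)
    if patient and spec.delta_r != 0.0:
        for i, j in affected_edges(spec):
            C[i, j] += spec.delta_r
            C[j, i] = C[i, j]
            if not -1.0 < C[i, j] < 1.0:
                raise ValueError(
                    f"delta_r={spec.delta_r} pushes correlation of edge ({i},{j}) "
                    f"to {C[i, j]}, outside (-1, 1)"
                )
    try:
        chol = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"target correlation matrix is not positive definite "
            f"(delta_r={spec.delta_r})"
        ) from err
    return chol


def generate_roi_phantom(
    spec: PhantomSpec,
) -> tuple[list[RoiTimecourses], np.ndarray, pd.DataFrame]:
    """Per-subject ROI time courses, signed labels (+1 patient / -1 control),
    and a phenotype table (id, site, dx, qc)."""
    rng = np.random.default_rng(spec.seed)
    chol = {False: _class_correlation(spec, False), True: _class_correlation(spec, True)}
    n, m = spec.n_timepoints, spec.n_rois
    t = np.linspace(-0.5, 0.5, n)

    subjects: list[RoiTimecourses] = []
    rows = []
    labels = []
    sid = 0
    for site in range(spec.n_sites):
        for patient in (False, True):
            for _ in range(spec.n_per_class_per_site):
                z = rng.standard_normal((n, m))
                series = z @ chol[patient].T
                slope = rng.normal(0.0, spec.drift_amplitude, size=m)
                series = series + np.outer(t, slope)
                if spec.noise_sd > 0:
                    series = series + rng.normal(0.0, spec.noise_sd, size=(n, m))
                series = series * spec.site_scale[site] + spec.site_shift[site]
                subjects.append(RoiTimecourses(data=series))
                labels.append(1 if patient else -1)
                rows.append(
                    {
                        "id": f"sub-{sid:04d}",
                        "site": f"site{site}",
                        "dx": "ADHD-C" if patient else "TDC",
                        "qc": 1,
                    }
                )
                sid += 1
    return subjects, np.array(labels), pd.DataFrame(rows)


def generate_voxel_phantom(
    spec: PhantomSpec,
    roi_shape: tuple[int, int, int] = (3, 3, 3),
    voxel_noise_sd: float = 0.3,
    patient: bool = False,
    seed: int | None = None,
) -> tuple[Volume4D, Parcellation, RoiTimecourses]:
    """A single-subject 4D volume whose ROIs are boxes sharing one signal.

    Each ROI is a ``roi_shape`` box on a lattice (one-voxel gaps, so boxes
    never overlap); every voxel in a box carries the ROI signal plus
    independent Gaussian noise.  Returns the volume, the parcellation, and
    the generating ROI signals (the ground truth for extraction).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chol = _class_correlation(spec, patient)
    n, m = spec.n_timepoints, spec.n_rois
    signals = rng.standard_normal((n, m)) @ chol.T

    per_axis = int(np.ceil(m ** (1.0 / 3.0)))
    bx, by, bz = roi_shape
    shape = (per_axis * (bx + 1) + 1, per_axis * (by + 1) + 1, per_axis * (bz + 1) + 1)
    if per_axis**3 < m:
        raise ValueError("ROI layout does not fit the volume")
    labels = np.zeros(shape, dtype=int)
    data = np.zeros(shape + (n,))
    roi = 0
    for ix in range(per_axis):
        for iy in range(per_axis):
            for iz in range(per_axis):
                if roi >= m:
                    break
                x0, y0, z0 = 1 + ix * (bx + 1), 1 + iy * (by + 1), 1 + iz * (bz + 1)
                box = (slice(x0, x0 + bx), slice(y0, y0 + by), slice(z0, z0 + bz))
                if np.any(labels[box] != 0):
                    raise ValueError("ROI boxes overlap")
                labels[box] = roi + 1
                noise = rng.normal(0.0, voxel_noise_sd, size=(bx, by, bz, n))
                data[box] = signals[:, roi].reshape(1, 1, 1, n) + noise
                roi += 1
    mask = labels > 0
    vol = Volume4D(data=data, voxel_size=(3.0, 3.0, 3.0), tr=spec.tr, mask=mask)
    return vol, Parcellation(labels=labels), RoiTimecourses(data=signals)


def generate_feature_table(
    spec: TableSpec, modality: str = "synthetic"
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Feature matrix, signed labels (+1/-1), and planted informative indices."""
    rng = np.random.default_rng(spec.seed)
    n_pos, n_neg = spec.n_per_class
    n = n_pos + n_neg
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    X = rng.standard_normal((n, spec.n_features))
    informative = np.arange(spec.n_informative)
    X[:, informative] += np.where(y > 0, spec.effect_size / 2.0, -spec.effect_size / 2.0)[
        :, None
    ]
    if spec.n_sites > 0 and spec.site_offset_sd > 0:
        sites = np.tile(np.arange(spec.n_sites), n // spec.n_sites + 1)[:n]
        offsets = rng.normal(0.0, spec.site_offset_sd, size=(spec.n_sites, spec.n_features))
        X = X + offsets[sites]
    fm = FeatureMatrix(
        X=X,
        feature_ids=[f"f{i:04d}" for i in range(spec.n_features)],
        subject_ids=[f"sub-{i:04d}" for i in range(n)],
        modality=modality,
    )
    return fm, y, informative


def generate_multimodal(
    specs: dict[str, TableSpec], seed: int = 0
) -> tuple[dict[str, FeatureMatrix], np.ndarray, dict[str, np.ndarray]]:
    """One feature table per modality over a shared subject list.

    Every spec must agree on ``n_per_class``; labels are generated once and
    shared, and each modality gets an independent seed derived from ``seed``.
    """
    if not specs:
        raise ValueError("need at least one modality spec")
    sizes = {name: s.n_per_class for name, s in specs.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"modalities disagree on subject counts: {sizes}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    tables: dict[str, FeatureMatrix] = {}
    planted: dict[str, np.ndarray] = {}
    y_shared: np.ndarray | None = None
    for (name, spec), child in zip(sorted(specs.items()), children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        spec_seeded = TableSpec(
            n_per_class=spec.n_per_class,
            n_features=spec.n_features,
            n_informative=spec.n_informative,
            effect_size=spec.effect_size,
            n_sites=spec.n_sites,
            site_offset_sd=spec.site_offset_sd,
            seed=child_seed,
        )
        fm, y, info = generate_feature_table(spec_seeded, modality=name)
        tables[name] = fm
        planted[name] = info
        y_shared = y
    return tables, y_shared, planted
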