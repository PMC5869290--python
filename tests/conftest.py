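"""Shared fixtures: the default spectral axis, a small fast phantom, and one
session-scoped end-to-end pipeline run reused by every downstream test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from spectromics3d import phantom as ph
from spectromics3d import pipeline as pl
from spectromics3d.spectral import default_axis


@pytest.fixture(scope="session")
def axis():
    return default_axis()


def small_phantom_spec(seed: int = 7, **overrides) -> ph.PhantomSpec:
    """A compact phantom for I/O and CLI tests (fast, ~16 sections)."""
    defaults = dict(
        shape=(20, 28, 40),
        left_hemisphere=ph.Ellipsoid((10.0, 13.0, 11.0), (8.0, 9.0, 8.0)),
        right_hemisphere=ph.Ellipsoid((10.0, 13.0, 28.0), (8.0, 9.0, 8.0)),
        cerebellum=ph.Ellipsoid((17.0, 13.0, 20.0), (2.5, 5.0, 7.0)),
        tumor=ph.Ellipsoid((9.0, 12.0, 28.0), (4.0, 4.0, 4.0)),
        seed=seed,
    )
    defaults.update(overrides)
    return ph.PhantomSpec(**defaults)


@dataclass
class PhantomRun:
    """One full phantom experiment plus its analysis results."""

    spec: ph.PhantomSpec
    volume: object
    truth: ph.GroundTruth
    ir_slices: list
    label_images: list
    result: pl.PipelineResult

    @property
    def tumor_truth_on_cube(self) -> np.ndarray:
        return self.truth.tumor_mask[self.result.cube.section_indices]

    @property
    def tumor_truth_on_labels(self) -> np.ndarray:
        return self.truth.tumor_mask[self.truth.label_planes]


@pytest.fixture(scope="session")
def phantom_run() -> PhantomRun:
    """The study-condition phantom run: default geometry and chemistry,
    cutting distortions at their default statistics, noise at 2% of the
    amide I amplitude, followed by the complete analysis chain."""
    spec = ph.PhantomSpec(seed=1)
    volume, truth = ph.generate_reference_volume(spec)
    ir, labels, truth = ph.generate_section_series(volume, truth, spec)
    result = pl.run_analysis(ir, labels, truth.label_planes, volume, pl.PipelineConfig())
    return PhantomRun(spec, volume, truth, ir, labels, result)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
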