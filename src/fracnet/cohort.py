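"""Synthetic two-group cohorts of ROI time series.

The generator emulates a resting-state study of two groups (e.g.
patients vs controls) with a modular coupling structure: ROIs are
partitioned into modules, each module has one shared latent signal,
and ROI i in module m of a subject with within-module coupling c is

    series_i = sqrt(c) * signal_m + sqrt(1 - c) * noise_i,

with all latent signals and noises unit-variance white Gaussian (or
AR(1) when temporal smoothing is requested).  The expected pairwise
correlation is exactly c within a module and 0 between modules, so
group differences in coupling propagate through connectivity, graph
construction and topology metrics in a controlled way.

Defaults mirror a typical 90-region atlas study: 90 ROIs, 230 retained
volumes, 17 vs 18 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ROITimeSeries
from .surrogates import logistic_pair

__all__ = [
    "CohortSpec",
    "Subject",
    "Cohort",
    "even_partition",
    "generate_cohort",
    "paired_fixture",
    "FIXTURE_KINDS",
]


def even_partition(n_roi: int, n_modules: int) -> np.ndarray:
    """Assign ROIs to modules as evenly as possible, in label order."""
    if not (1 <= n_modules <= n_roi):
        raise ValueError("module count must lie in [1, n_roi]")
    return np.sort(np.arange(n_roi) % n_modules)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic two-group cohort."""

    n_subjects: tuple = (17, 18)
    coupling: tuple = (0.6, 0.3)
    n_roi: int = 90
    n_time: int = 230
    n_modules: int = 6
    ar_coeff: float = 0.0
    partition: np.ndarray | None = None
    seed: int = 0
    group_names: tuple = ("A", "B")

    def __post_init__(self):
        if len(self.n_subjects) != 2 or any(n < 2 for n in self.n_subjects):
            raise ValueError("need two groups with at least 2 subjects each")
        if len(self.coupling) != 2 or any(not (0.0 <= c < 1.0) for c in self.coupling):
            raise ValueError("couplings must lie in [0, 1)")
        if self.n_time < 32:
            raise ValueError("n_time must be >= 32")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        part = (
            even_partition(self.n_roi, self.n_modules)
            if self.partition is None
            else np.asarray(self.partition, dtype=int)
        )
        if part.shape != (self.n_roi,):
            raise ValueError("partition must assign every ROI to a module")
        if part.min() < 0:
            raise ValueError("module indices must be nonnegative")
        object.__setattr__(self, "partition", part)
        object.__setattr__(self, "n_modules", int(part.max()) + 1)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    data: ROITimeSeries


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    subjects: tuple

    def group(self, name: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == name]


def _unit_ar1(rng: np.random.Generator, shape, phi: float) -> np.ndarray:
    """White or AR(1) rows with unit marginal variance."""
    e = rng.standard_normal(shape)
    if phi == 0.0:
        return e
    out = np.empty_like(e)
    out[..., 0] = e[..., 0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + scale * e[..., t]
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw every subject's ROI-by-time matrix; reproducible given
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    labels = tuple(f"ROI{i + 1:03d}" for i in range(spec.n_roi))
    subjects = []
    for g_idx, (name, n_sub, c) in enumerate(
        zip(spec.group_names, spec.n_subjects, spec.coupling)
    ):
        for k in range(n_sub):
            signals = _unit_ar1(rng, (spec.n_modules, spec.n_time), spec.ar_coeff)
            noise = _unit_ar1(rng, (spec.n_roi, spec.n_time), spec.ar_coeff)
            series = np.sqrt(c) * signals[spec.partition] + np.sqrt(1.0 - c) * noise
            subjects.append(
                Subject(
                    subject_id=f"{name}{k + 1:02d}",
                    group=name,
                    data=ROITimeSeries(values=series, labels=labels),
                )
            )
    return Cohort(spec=spec, subjects=tuple(subjects))


FIXTURE_KINDS = (
    "identical",
    "linear",
    "noisy-linear",
    "independent",
    "logistic-linear",
    "logistic-chaotic",
)


def paired_fixture(kind: str, seed: int, length: int = 256):
    """Canonical small (x, y) pairs used across the test suite.

    Kinds: ``identical`` (y = x), ``linear`` (positive affine map),
    ``noisy-linear`` (x plus mild noise), ``independent`` (two
    independent white series), ``logistic-linear`` (shared-parameter
    logistic orbits near the period-doubling onset, A = 3.05) and
    ``logistic-chaotic`` (deep chaotic regime, A = 3.95).
    """
    rng = np.random.default_rng(seed)
    if kind == "identical":
        x = rng.standard_normal(length)
        return x, x.copy()
    if kind == "linear":
        x = rng.standard_normal(length)
        return x, 0.5 * x + 1.0
    if kind == "noisy-linear":
        x = rng.standard_normal(length)
        return x, x + 0.5 * rng.standard_normal(length)
    if kind == "independent":
        return rng.standard_normal(length), rng.standard_normal(length)
    if kind == "logistic-linear":
        x0a, x0b = rng.uniform(0.01, 0.99, size=2)
        return logistic_pair(3.05, float(x0a), float(x0b), length)
    if kind == "logistic-chaotic":
        x0a, x0b = rng.uniform(0.01, 0.99, size=2)
        return logistic_pair(3.95, float(x0a), float(x0b), length)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
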