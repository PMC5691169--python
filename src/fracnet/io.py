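"""File formats: delimited-text matrices, NIfTI ROI extraction and run
configuration.

Matrices travel as tab-separated text.  The first row is a header of
ROI labels (preceded by an empty corner cell); each data row starts
with its ROI label.  Square matrices are validated symmetric on read.
Time-series matrices (ROIs x time) use the same layout with ``t0,
t1, ...`` column names.  Values are printed at full precision so a
write/read round-trip is the identity.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .network import ROITimeSeries, WeightedMatrix

__all__ = [
    "write_matrix",
    "read_weighted_matrix",
    "write_timeseries",
    "read_timeseries",
    "extract_roi_timeseries",
    "RunConfig",
]

_FMT = "%.17g"


def _write_table(path, labels, col_names, values) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["", *map(str, col_names)]) + "\n")
        for label, row in zip(labels, values):
            fh.write(str(label) + "\t" + "\t".join(_FMT % v for v in row) + "\n")


def _read_table(path):
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header plus at least one data row")
    header = lines[0].split("\t")[1:]
    labels, rows = [], []
    width = None
    for ln in lines[1:]:
        cells = ln.split("\t")
        labels.append(cells[0])
        try:
            row = [float(c) for c in cells[1:]]
        except ValueError as err:
            raise ValueError(f"{path}: non-numeric cell in row {cells[0]!r}: {err}")
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(f"{path}: ragged row {cells[0]!r}")
        rows.append(row)
    if width != len(header):
        raise ValueError(
            f"{path}: header lists {len(header)} columns but rows have {width}"
        )
    return labels, header, np.asarray(rows, dtype=float)


def write_matrix(path, w: WeightedMatrix) -> None:
    """Write a square weighted matrix as labelled TSV."""
    _write_table(path, w.labels, w.labels, w.values)


def read_weighted_matrix(path, measure: str = "") -> WeightedMatrix:
    """Read a square, symmetric labelled TSV matrix."""
    labels, header, values = _read_table(path)
    if labels != header:
        raise ValueError(f"{path}: row labels do not match the header labels")
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square: {values.shape}")
    if not np.allclose(values, values.T, atol=1e-10, rtol=0.0):
        i, j = np.unravel_index(
            np.argmax(np.abs(values - values.T)), values.shape
        )
        raise ValueError(
            f"{path}: matrix is asymmetric, e.g. ({labels[i]}, {labels[j]})"
        )
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return WeightedMatrix(values=values, labels=tuple(labels), measure=measure)


def write_timeseries(path, ts: ROITimeSeries) -> None:
    """Write an ROI-by-time matrix as labelled TSV."""
    cols = [f"t{t}" for t in range(ts.n_time)]
    _write_table(path, ts.labels, cols, ts.values)


def read_timeseries(path) -> ROITimeSeries:
    labels, _, values = _read_table(path)
    return ROITimeSeries(values=values, labels=tuple(labels))


def extract_roi_timeseries(func4d, atlas, labels=None) -> ROITimeSeries:
    """Average the 4-D functional signal over each atlas region.

    ``func4d`` and ``atlas`` are NIfTI images (or paths); their voxel
    grids must match exactly.  One ROI row per nonzero atlas label, in
    ascending label order; entry t is the mean over the region's voxels
    at volume t.  An explicitly requested label with no voxels is an
    error naming that label.
    """
    func_img = nib.load(str(func4d)) if isinstance(func4d, (str, Path)) else func4d
    atlas_img = nib.load(str(atlas)) if isinstance(atlas, (str, Path)) else atlas
    func = np.asarray(func_img.dataobj, dtype=float)
    lab = np.asarray(atlas_img.dataobj)
    lab = np.rint(lab).astype(np.int64)
    if func.ndim != 4:
        raise ValueError(f"functional image must be 4-D, got shape {func.shape}")
    if lab.shape != func.shape[:3]:
        raise ValueError(
            f"atlas grid {lab.shape} does not match functional grid {func.shape[:3]}"
        )
    if not np.allclose(func_img.affine, atlas_img.affine, atol=1e-4):
        raise ValueError("functional and atlas affines differ; images must be aligned")
    if lab.min() < 0:
        raise ValueError("atlas labels must be nonnegative integers")
    present = np.unique(lab)
    present = present[present > 0]
    if labels is None:
        wanted = present
    else:
        wanted = np.asarray(sorted(int(l) for l in labels))
        missing = sorted(set(wanted.tolist()) - set(present.tolist()))
        if missing:
            raise ValueError(f"atlas label(s) with no voxels: {missing}")
    if wanted.size < 2:
        raise ValueError("need at least 2 nonzero atlas labels")
    n_t = func.shape[3]
    flat_lab = lab.ravel()
    flat_func = func.reshape(-1, n_t)
    series = np.empty((wanted.size, n_t), dtype=float)
    for i, l in enumerate(wanted):
        mask = flat_lab == l
        series[i] = flat_func[mask].mean(axis=0)
    return ROITimeSeries(values=series, labels=tuple(str(l) for l in wanted))


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one CLI stage, serialized next to its
    outputs so any run can be reproduced bit-for-bit."""

    command: str
    params: dict

    def save(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(
                {"command": self.command, "params": self.params},
                fh,
                sort_keys=True,
            )

    @classmethod
    def load(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "command" not in raw or "params" not in raw:
            raise ValueError(f"{path}: not a run-config file")
        return cls(command=raw["command"], params=raw["params"])
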