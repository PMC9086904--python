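"""Readers and writers for ROI voxel samples, morphological networks, and cohorts.

ROI ordering is the single source of truth: every matrix produced downstream
indexes against the ordered label list carried by :class:`RoiSampleSet`.
Internal indexing is 0-based; external files carry region names and the
conventional 1-based atlas label IDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-12


def default_roi_names() -> list[str]:
    """The packaged 116-region (AAL-style) name list, in label-ID order."""
    ref = resources.files("morphnet.data") / "aal116_labels.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df["name"].tolist()


@dataclass
class RoiSampleSet:
    """Per-subject map from ROI label to its vector of voxel GM values."""

    subject_id: str
    roi_labels: list[str]
    samples: list[np.ndarray]

    def __post_init__(self):
        if len(self.roi_labels) != len(self.samples):
            raise ValueError("roi_labels and samples length mismatch")
        self.samples = [np.asarray(s, dtype=float).ravel() for s in self.samples]

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def flagged_rois(self) -> list[str]:
        """Labels whose sample vector has fewer than 2 values."""
        return [lab for lab, s in zip(self.roi_labels, self.samples) if s.size < 2]


@dataclass
class MorphNetwork:
    """Symmetric KLS matrix with ROI names; values in [0, 1], zero diagonal."""

    subject_id: str
    roi_labels: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"matrix must be square, got shape {m.shape}")
        if m.shape[0] != len(self.roi_labels):
            raise ValueError("matrix size does not match roi_labels")
        if np.max(np.abs(m - m.T)) > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance {SYMMETRY_TOL}")
        m = (m + m.T) / 2.0
        if np.any(np.diag(m) != 0):
            raise ValueError("matrix diagonal must be zero")
        if m.min() < 0 or m.max() > 1:
            bad = m.min() if m.min() < 0 else m.max()
            raise ValueError(f"value outside [0,1]: {bad}")
        self.matrix = m

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def extract_roi_samples(
    gm_image,
    atlas_image,
    expected_labels: list[int] | None = None,
    roi_names: list[str] | None = None,
    subject_id: str = "subject",
) -> RoiSampleSet:
    """Extract per-ROI GM voxel values from a GM map and an integer atlas.

    Voxels with GM value <= 0 are treated as background and excluded.
    ROIs are ordered by atlas label ID. A label expected but absent from the
    atlas yields an empty (flagged) vector; a label present in the atlas but
    not in the expected list is an error.
    """
    gm = _load_volume(gm_image)
    atlas = _load_volume(atlas_image)
    if gm.shape != atlas.shape:
        raise ValueError(f"image grids differ: GM {gm.shape} vs atlas {atlas.shape}")
    atlas = np.round(atlas).astype(int)

    if roi_names is None:
        roi_names = default_roi_names()
    if expected_labels is None:
        expected_labels = list(range(1, len(roi_names) + 1))
    if len(expected_labels) != len(roi_names):
        raise ValueError("expected_labels and roi_names length mismatch")

    present = set(np.unique(atlas)) - {0}
    unexpected = sorted(present - set(expected_labels))
    if unexpected:
        raise ValueError(f"atlas contains unexpected label(s): {unexpected}")

    samples = []
    for lab in expected_labels:
        vals = gm[atlas == lab]
        samples.append(vals[vals > 0].astype(float))
    return RoiSampleSet(subject_id=subject_id, roi_labels=list(roi_names), samples=samples)


def _load_volume(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        image = nib.load(str(image))
    if isinstance(image, np.ndarray):
        return np.asarray(image, dtype=float)
    return np.asarray(image.get_fdata(), dtype=float)


def export_nifti(
    sample_sets: list[RoiSampleSet],
    out_dir,
    expected_labels: list[int] | None = None,
) -> dict:
    """Write a synthetic label volume plus one GM map per subject.

    ROI r is assigned a contiguous block of voxels sized for the largest
    sample vector of that ROI across subjects; padding voxels carry GM value
    0 and are dropped again on read, so extract -> export -> extract is the
    identity on positive sample values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not sample_sets:
        raise ValueError("no subjects to export")
    labels = sample_sets[0].roi_labels
    n_rois = len(labels)
    if expected_labels is None:
        expected_labels = list(range(1, n_rois + 1))
    block = [max(ss.samples[r].size for ss in sample_sets) for r in range(n_rois)]
    total = int(np.sum(block))
    side = int(np.ceil(total ** (1.0 / 3.0)))
    shape = (side, side, int(np.ceil(total / (side * side))))

    atlas_flat = np.zeros(int(np.prod(shape)), dtype=np.int16)
    starts = np.concatenate([[0], np.cumsum(block)])
    for r in range(n_rois):
        atlas_flat[starts[r]:starts[r + 1]] = expected_labels[r]
    atlas_img = nib.Nifti1Image(atlas_flat.reshape(shape), affine=np.eye(4))
    atlas_path = out_dir / "atlas.nii"
    nib.save(atlas_img, str(atlas_path))

    gm_paths = {}
    for ss in sample_sets:
        gm_flat = np.zeros(int(np.prod(shape)), dtype=np.float64)
        for r in range(n_rois):
            vals = ss.samples[r]
            gm_flat[starts[r]:starts[r] + vals.size] = vals
        img = nib.Nifti1Image(gm_flat.reshape(shape), affine=np.eye(4))
        path = out_dir / f"{ss.subject_id}_gm.nii"
        nib.save(img, str(path))
        gm_paths[ss.subject_id] = path
    return {"atlas": atlas_path, "gm": gm_paths, "shape": shape}


# ---------------------------------------------------------------------------
# tabular round-trips
# ---------------------------------------------------------------------------

def write_roi_table(sample_set: RoiSampleSet, path) -> None:
    """TSV with columns (roi_label, voxel_value), one row per voxel."""
    rows = []
    for lab, vals in zip(sample_set.roi_labels, sample_set.samples):
        for v in vals:
            rows.append((lab, v))
    df = pd.DataFrame(rows, columns=["roi_label", "voxel_value"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_roi_table(path, subject_id: str | None = None,
                   roi_labels: list[str] | None = None) -> RoiSampleSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"roi_label", "voxel_value"} - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) in ROI table: {sorted(missing)}")
    if not np.issubdtype(df["voxel_value"].dtype, np.number):
        raise ValueError("non-numeric voxel_value entries in ROI table")
    if subject_id is None:
        subject_id = Path(path).stem.removesuffix("_samples")
    if roi_labels is None:
        # preserve order of first appearance
        roi_labels = list(dict.fromkeys(df["roi_label"].astype(str)))
    grouped = {str(k): v["voxel_value"].to_numpy(dtype=float)
               for k, v in df.groupby("roi_label", sort=False)}
    samples = [grouped.get(lab, np.empty(0)) for lab in roi_labels]
    return RoiSampleSet(subject_id=subject_id, roi_labels=roi_labels, samples=samples)


def write_network(network: MorphNetwork, path) -> None:
    """Network TSV: header row and index column both carry ROI names."""
    df = pd.DataFrame(network.matrix, index=network.roi_labels,
                      columns=network.roi_labels)
    df.to_csv(path, sep="\t", index_label="roi", float_format="%.17g")


def read_network(path, subject_id: str | None = None) -> MorphNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("network row and column labels disagree")
    m = df.to_numpy(dtype=float)
    if np.max(np.abs(m - m.T)) > SYMMETRY_TOL:
        raise ValueError(f"asymmetric matrix beyond tolerance {SYMMETRY_TOL}")
    if m.min() < 0 or m.max() > 1:
        bad = m.min() if m.min() < 0 else m.max()
        raise ValueError(f"value outside [0,1]: {bad}")
    if subject_id is None:
        subject_id = Path(path).stem.removesuffix("_network")
    return MorphNetwork(subject_id=subject_id,
                        roi_labels=[str(c) for c in df.columns],
                        matrix=m)


def write_cohort_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("cohort table must contain subject_id and group columns")
    return df


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
        fh.write("\n")
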