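"""DCE-MRI series handling: loading, subtractive volumes, timepoint selection.

A dynamic contrast-enhanced (DCE) breast MRI exam is a 4D acquisition: one
pre-contrast 3D volume (``t_0``) followed by ``N_p - 1`` post-contrast volumes
(``t_1 .. t_{N_p-1}``) on the same voxel grid.  Subtracting the pre-contrast
volume from every post-contrast volume isolates contrast enhancement, and the
time course of that enhancement (wash-in / wash-out) carries diagnostic
information.  Because patients differ in the number of acquired volumes, four
canonical subtractive timepoints are selected per patient: the first, the
second, a mid-course one and the last.

Volumes are indexed ``(x=row, y=column, z=slice)``, 0-based, with half-open
crop intervals throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DCESeries",
    "SubtractiveStack",
    "compute_subtractives",
    "select_timepoints",
    "make_stack",
    "load_patient",
    "load_cohort",
    "save_series",
    "encode_label",
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
]

LABEL_POSITIVE = 1  # LN+ : at least one metastatic axillary node
LABEL_NEGATIVE = 0  # LN- : all axillary nodes clear

#: accepted metadata label tokens -> integer class
_LABEL_TOKENS = {
    "LN+": LABEL_POSITIVE,
    "LN-": LABEL_NEGATIVE,
    "LN−": LABEL_NEGATIVE,  # unicode minus
    "1": LABEL_POSITIVE,
    "0": LABEL_NEGATIVE,
}


def encode_label(token) -> int:
    """Map a lymph-node-status label token to the integer class (LN+ -> 1)."""
    if isinstance(token, (int, np.integer)) and token in (0, 1):
        return int(token)
    key = str(token).strip()
    if key not in _LABEL_TOKENS:
        raise ValueError(
            f"unknown lymph-node label token {token!r}; expected one of "
            f"{sorted(set(_LABEL_TOKENS))}"
        )
    return _LABEL_TOKENS[key]


@dataclass
class DCESeries:
    """One patient's ordered DCE acquisitions plus lesion mask and metadata.

    ``acquisitions[0]`` is the pre-contrast volume ``t_0``; the remaining
    entries are the post-contrast volumes in acquisition order.  ``spacing``
    gives the physical voxel size in mm along (row, column, between-slice).
    """

    patient_id: str
    acquisitions: list[np.ndarray]
    spacing: tuple[float, float, float]
    mask: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if len(self.acquisitions) < 2:
            raise ValueError(
                f"patient {self.patient_id}: need a pre-contrast and at least "
                f"one post-contrast volume, got {len(self.acquisitions)}"
            )
        shape = self.acquisitions[0].shape
        for i, vol in enumerate(self.acquisitions):
            if vol.ndim != 3:
                raise ValueError(f"acquisition {i} is not a 3D volume")
            if vol.shape != shape:
                raise ValueError(
                    f"patient {self.patient_id}: acquisition {i} shape "
                    f"{vol.shape} != {shape}"
                )
        if self.mask.shape != shape:
            raise ValueError(
                f"patient {self.patient_id}: mask shape {self.mask.shape} "
                f"!= acquisition shape {shape}"
            )
        self.mask = np.asarray(self.mask) > 0
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.label = encode_label(self.label)

    @property
    def n_acquisitions(self) -> int:
        """Total number of acquired volumes ``N_p`` (pre-contrast included)."""
        return len(self.acquisitions)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.acquisitions[0].shape


@dataclass
class SubtractiveStack:
    """The four selected subtractive volumes of one patient, channel-stacked.

    ``channels`` has shape ``(4, X, Y, Z)`` holding, in order, the first,
    second, mid-course and last subtractive volumes.  ``source_indices`` are
    the 1-based subtractive indices they came from (i.e. ``s_i = t_i - t_0``).
    """

    patient_id: str
    channels: np.ndarray
    source_indices: tuple[int, int, int, int]
    spacing: tuple[float, float, float]
    mask: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4 or self.channels.shape[0] != 4:
            raise ValueError(
                f"expected 4 channel volumes, got array of shape {self.channels.shape}"
            )
        if tuple(self.channels.shape[1:]) != tuple(self.mask.shape):
            raise ValueError(
                f"channel grid {self.channels.shape[1:]} != mask grid {self.mask.shape}"
            )
        idx = tuple(int(i) for i in self.source_indices)
        if len(idx) != 4 or any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"source indices must be 4 strictly increasing, got {idx}")
        self.source_indices = idx
        self.mask = np.asarray(self.mask) > 0


def compute_subtractives(series: DCESeries) -> list[np.ndarray]:
    """Return the subtractive series ``s_i = t_i - t_0`` for i = 1..N_p-1.

    Negative values are preserved; the (0,1) normalization applied at the
    bounding stage maps the sample minimum to 0.
    """
    t0 = series.acquisitions[0].astype(np.float32)
    return [a.astype(np.float32) - t0 for a in series.acquisitions[1:]]


def select_timepoints(n_subtractives: int) -> tuple[int, int, int, int]:
    """Pick the four canonical subtractive indices (1-based).

    Returns ``(1, 2, m, n)`` where ``m`` is the floor of the median of the
    integer range ``[3, n-1]`` (and 3 when ``n == 4``): the first, second,
    mid-course and last subtractive volumes, preserving wash-in and wash-out
    information regardless of how many volumes were acquired.
    """
    n = int(n_subtractives)
    if n < 4:
        raise ValueError(
            f"need at least 4 subtractive volumes (5 acquisitions), got {n}"
        )
    i_m = (3 + (n - 1)) // 2  # floor of the median of [3, n-1]; ties -> earlier
    return (1, 2, i_m, n)


def make_stack(series: DCESeries) -> SubtractiveStack:
    """Build the 4-channel :class:`SubtractiveStack` for one patient."""
    subs = compute_subtractives(series)
    idx = select_timepoints(len(subs))
    channels = np.stack([subs[i - 1] for i in idx], axis=0)
    return SubtractiveStack(
        patient_id=series.patient_id,
        channels=channels,
        source_indices=idx,
        spacing=series.spacing,
        mask=series.mask,
        label=series.label,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _spacing_affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_series(series: DCESeries, out_dir: str | Path) -> pd.DataFrame:
    """Write one patient as per-timepoint NIfTI files plus the mask.

    Returns the metadata rows (one per acquisition) describing the files, in
    the same schema :func:`load_patient` consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = _spacing_affine(series.spacing)
    mask_file = out_dir / f"{series.patient_id}_mask.nii.gz"
    nib.save(nib.Nifti1Image(series.mask.astype(np.uint8), affine), mask_file)
    rows = []
    for i, vol in enumerate(series.acquisitions):
        f = out_dir / f"{series.patient_id}_t{i:02d}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), f)
        rows.append(
            {
                "patient_id": series.patient_id,
                "acquisition_index": i,
                "file": str(f),
                "mask_file": str(mask_file),
                "label": "LN+" if series.label == LABEL_POSITIVE else "LN-",
            }
        )
    return pd.DataFrame(rows)


def load_patient(metadata_rows: pd.DataFrame, base_dir: str | Path | None = None) -> DCESeries:
    """Load one patient's :class:`DCESeries` from its metadata rows.

    ``metadata_rows`` must contain the columns ``patient_id``,
    ``acquisition_index``, ``file``, ``mask_file`` and ``label``; acquisition
    order is taken from the explicit index column, never from file names.
    """
    required = {"patient_id", "acquisition_index", "file", "mask_file", "label"}
    missing = required - set(metadata_rows.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    rows = metadata_rows.sort_values("acquisition_index")
    pids = rows["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected rows for one patient, got {list(pids)}")
    idx = rows["acquisition_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError(
            f"patient {pids[0]}: acquisition_index must be 0..N_p-1, got {idx.tolist()}"
        )
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    vols, spacings = [], []
    for _, row in rows.iterrows():
        img = nib.load(_resolve(row["file"]))
        vols.append(np.asanyarray(img.dataobj).astype(np.float32))
        spacings.append(tuple(float(z) for z in img.header.get_zooms()[:3]))
    mask_files = rows["mask_file"].unique()
    if len(mask_files) != 1:
        raise ValueError(f"patient {pids[0]}: multiple mask files listed")
    mask_img = nib.load(_resolve(mask_files[0]))
    mask = np.asanyarray(mask_img.dataobj)
    labels = {encode_label(l) for l in rows["label"]}
    if len(labels) != 1:
        raise ValueError(f"patient {pids[0]}: inconsistent labels across rows")
    return DCESeries(
        patient_id=str(pids[0]),
        acquisitions=vols,
        spacing=spacings[0],
        mask=mask,
        label=labels.pop(),
    )


def load_cohort(metadata_csv: str | Path) -> list[DCESeries]:
    """Load every patient listed in a cohort metadata CSV."""
    metadata_csv = Path(metadata_csv)
    meta = pd.read_csv(metadata_csv, dtype={"patient_id": str})
    base = metadata_csv.parent
    return [
        load_patient(rows, base_dir=base)
        for _, rows in meta.groupby("patient_id", sort=True)
    ]
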