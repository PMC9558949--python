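"""Synthetic DCE-MRI phantom cohorts with the statistical structure the
classification method assumes.

Each phantom patient is a smooth random parenchyma background imaged at a
variable number of timepoints (one pre-contrast, then post-contrast volumes).
Ellipsoidal mass-like lesions enhance according to one of the three classic
signal-intensity curve types — I (progressive rise), II (plateau), III
(wash-out) — so the subtractive channels carry wash-in/wash-out kinetics.
Tumors are unifocal, multifocal (nearby foci) or multicentric (distant
foci), and the lesion masks are the exact ellipsoids.

The class-conditional signal is planted where the method hypothesizes it
lives: LN+ patients receive a high-frequency texture of amplitude ``delta``
in a 2-voxel peritumoral rim around every lesion and, for multi-lesion
patients, along the parenchyma between lesion centroids.  With ``delta = 0``
the label carries no image information and any classifier should stay at
chance.  Clinical covariates are drawn per class from the frequencies of the
155-lesion clinical cohort, so the cohort statistics module sees realistic
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .clinical_stats import COHORT_TABLES, VARIABLE_CATEGORIES
from .dce_data import DCESeries, make_stack, save_series
from .evaluation import roc_auc

__all__ = ["PhantomConfig", "generate_cohort", "planted_signal_check", "rim_statistic"]

#: cohort-derived curve-type frequencies (I, II, III): 21/69/65 of 155
_CURVE_PROBS = {"LN+": (3 / 27, 10 / 27, 14 / 27), "LN-": (18 / 128, 59 / 128, 51 / 128)}


@dataclass
class PhantomConfig:
    """Generator settings; defaults emulate the clinical study conditions.

    * 155 patients at the 27:128 LN+:LN- class ratio;
    * anisotropic voxels of 0.7 x 0.7 x 2.4 mm;
    * 5-8 acquisitions per patient (pre-contrast included);
    * unifocal/multifocal/multicentric layout mix of 70/20/10 %;
    * lesion radii 3-7 mm, curve-type frequencies from the clinical cohort;
    * ``delta``: amplitude of the label-correlated peritumoral texture, as a
      fraction of the lesion enhancement amplitude (0 = null cohort);
    * ``noise``: standard deviation of the additive acquisition noise.
    """

    n_patients: int = 155
    pos_fraction: float = 27 / 155
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (0.7, 0.7, 2.4)
    n_acquisitions_range: tuple[int, int] = (5, 8)
    focality_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    lesion_radius_mm: tuple[float, float] = (3.0, 7.0)
    delta: float = 0.5
    noise: float = 0.02
    rim_voxels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.n_acquisitions_range = tuple(int(n) for n in self.n_acquisitions_range)
        self.focality_probs = tuple(float(p) for p in self.focality_probs)
        self.lesion_radius_mm = tuple(float(r) for r in self.lesion_radius_mm)
        if self.n_patients < 2 or not 0 < self.pos_fraction < 1:
            raise ValueError("need n_patients >= 2 and pos_fraction in (0, 1)")
        if self.delta < 0 or self.noise < 0:
            raise ValueError("delta and noise must be non-negative")
        if any(s <= 0 for s in self.spacing) or any(n < 8 for n in self.grid_shape):
            raise ValueError(f"invalid grid/spacing: {self.grid_shape}, {self.spacing}")
        r_vox = max(
            self.lesion_radius_mm[1] / s for s in self.spacing
        )
        if 2 * r_vox + 2 * self.rim_voxels >= min(self.grid_shape):
            raise ValueError(
                f"grid {self.grid_shape} too small for lesion radius "
                f"{self.lesion_radius_mm[1]} mm at spacing {self.spacing}"
            )


def _ellipsoid_mask(grid_shape, center_vox, radii_vox) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=np.float32)
    d2 = sum(
        ((coords[a] - center_vox[a]) / radii_vox[a]) ** 2 for a in range(3)
    )
    return d2 <= 1.0


def _curve_value(curve_type: str, tau: float) -> float:
    """Enhancement fraction at normalized time ``tau`` in (0, 1]."""
    if curve_type == "I":  # progressive rise, peak at the last acquisition
        return tau**0.8
    if curve_type == "II":  # rapid wash-in then plateau
        return 1.0 - np.exp(-5.0 * tau)
    if curve_type == "III":  # early peak then wash-out
        x = tau / 0.25
        return x * np.exp(1.0 - x)
    raise ValueError(f"unknown curve type {curve_type!r}")


def _sample_categorical(rng, options, probs) -> str:
    return options[int(rng.choice(len(options), p=np.asarray(probs) / np.sum(probs)))]


def _sample_covariates(rng, label: int) -> dict[str, str]:
    """Draw clinical covariates from the per-class cohort frequencies."""
    col = 0 if label == 1 else 1
    out = {}
    for var, rows in COHORT_TABLES.items():
        if var == "IS_curve":
            continue  # tied to the assigned kinetic curve type
        counts = [r[col] for r in rows]
        out[var] = _sample_categorical(rng, VARIABLE_CATEGORIES[var], counts)
    return out


def _separated(c, r, placed, gap=2.0) -> bool:
    """Axis-separation test guaranteeing disjoint ellipsoid masks."""
    for co, ro in placed:
        if not any(abs(c[a] - co[a]) > r[a] + ro[a] + gap for a in range(3)):
            return False
    return True


def _place_lesions(rng, cfg: PhantomConfig, focality: str, margin_vox):
    """Draw (center, voxel radii) per lesion; components never touch.

    Multifocal cases place nearby foci, multicentric ones mutually distant
    foci; placements are rejection-sampled under an axis-separation
    criterion so connected-component labeling always recovers the planted
    lesion count.
    """
    lo = np.asarray(margin_vox, dtype=float)
    hi = np.asarray(cfg.grid_shape, dtype=float) - margin_vox
    span = hi - lo
    spacing = np.asarray(cfg.spacing)
    r_lo, r_hi = cfg.lesion_radius_mm

    def _radii():
        return np.maximum(rng.uniform(r_lo, r_hi, size=3) / spacing, 1.0)

    def _center():
        return lo + rng.random(3) * span

    n = 1 if focality == "unifocal" else (2 if focality == "multifocal" else int(rng.integers(2, 4)))
    placed = [(_center(), _radii())]
    for _ in range(n - 1):
        r = _radii()
        for attempt in range(200):
            c = _center()
            if not _separated(c, r, placed):
                continue
            if focality == "multifocal":
                # nearby focus: same breast region
                if np.linalg.norm((c - placed[0][0]) / span) < 0.5:
                    break
            else:
                # distant focus: different region
                if all(np.linalg.norm((c - co) / span) > 0.45 for co, _ in placed):
                    break
        else:
            r = np.maximum(r * 0.6, 1.0)  # crowded grid: shrink and place anywhere
            for attempt in range(200):
                c = _center()
                if _separated(c, r, placed):
                    break
            else:
                continue  # give up on this focus
        placed.append((c, r))
    return placed


def _segment_mask(grid_shape, a, b) -> np.ndarray:
    """Voxels along the straight segment between two points, 1-voxel dilated."""
    n = int(np.ceil(np.linalg.norm(np.asarray(b) - np.asarray(a)))) * 2 + 2
    pts = np.linspace(a, b, n)
    mask = np.zeros(grid_shape, dtype=bool)
    idx = np.clip(np.round(pts).astype(int), 0, np.asarray(grid_shape) - 1)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return ndimage.binary_dilation(mask, iterations=1)


def generate_patient(rng: np.random.Generator, cfg: PhantomConfig, pid: str, label: int):
    """Generate one phantom patient; returns (DCESeries, covariate dict)."""
    shape = cfg.grid_shape
    spacing = np.asarray(cfg.spacing)
    n_acq = int(rng.integers(cfg.n_acquisitions_range[0], cfg.n_acquisitions_range[1] + 1))
    focality = _sample_categorical(rng, ("unifocal", "multifocal", "multicentric"),
                                   cfg.focality_probs)
    curve_type = _sample_categorical(
        rng, VARIABLE_CATEGORIES["IS_curve"], _CURVE_PROBS["LN+" if label else "LN-"]
    )

    # static anatomy: smooth parenchyma background
    background = 0.4 + 0.15 * ndimage.gaussian_filter(
        rng.normal(0, 1, shape), sigma=4.0
    ).astype(np.float32)

    # lesions: ellipsoids with physical radii, squashed by the voxel spacing
    r_hi = cfg.lesion_radius_mm[1]
    margin_vox = r_hi / spacing + cfg.rim_voxels + 1
    placed = _place_lesions(rng, cfg, focality, margin_vox)
    centers = [c for c, _ in placed]
    mask = np.zeros(shape, dtype=bool)
    components = []
    for c, radii_vox in placed:
        comp = _ellipsoid_mask(shape, c, radii_vox)
        components.append(comp)
        mask |= comp

    # label-correlated texture support: peritumoral rim + inter-lesion tracks
    rim = ndimage.binary_dilation(mask, iterations=cfg.rim_voxels) & ~mask
    signal_support = rim.copy()
    if label == 1 and len(centers) > 1:
        for a, b in zip(centers, centers[1:]):
            signal_support |= _segment_mask(shape, a, b) & ~mask
    texture = rng.normal(0, 1, shape).astype(np.float32)

    amplitude = float(rng.uniform(0.8, 1.2))
    lesion_field = amplitude * mask.astype(np.float32)
    planted = (
        cfg.delta * amplitude * texture * signal_support if label == 1 else 0.0
    )

    acquisitions = [
        (background + cfg.noise * rng.normal(0, 1, shape)).astype(np.float32)
    ]
    for i in range(1, n_acq):
        tau = i / (n_acq - 1)
        enh = float(_curve_value(curve_type, tau))
        vol = background + enh * lesion_field + enh * planted
        vol = vol + cfg.noise * rng.normal(0, 1, shape)
        acquisitions.append(vol.astype(np.float32))

    series = DCESeries(
        patient_id=pid,
        acquisitions=acquisitions,
        spacing=tuple(cfg.spacing),
        mask=mask,
        label=label,
    )
    covars = _sample_covariates(rng, label)
    covars["IS_curve"] = curve_type
    covars["focality"] = focality
    covars["n_lesions"] = len(components)
    return series, covars


def generate_cohort(
    cfg: PhantomConfig, out_dir: str | Path | None = None
) -> tuple[list[DCESeries], pd.DataFrame]:
    """Generate a full phantom cohort.

    Returns the in-memory series list plus a patient-level metadata table
    (label, clinical covariates, focality).  With ``out_dir`` set, also
    writes one NIfTI per acquisition, the masks, and a ``metadata.csv`` in
    the acquisition-level schema the loader consumes.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pos = int(round(cfg.n_patients * cfg.pos_fraction))
    labels = [1] * n_pos + [0] * (cfg.n_patients - n_pos)
    series_list, meta_rows, file_rows = [], [], []
    for i, label in enumerate(labels):
        pid = f"P{i:04d}"
        series, covars = generate_patient(rng, cfg, pid, label)
        series_list.append(series)
        meta_rows.append(
            {"patient_id": pid, "label": "LN+" if label else "LN-", **covars}
        )
        if out_dir is not None:
            rows = save_series(series, out_dir)
            for col, val in covars.items():
                rows[col] = val
            file_rows.append(rows)
    metadata = pd.DataFrame(meta_rows)
    if out_dir is not None:
        files = pd.concat(file_rows, ignore_index=True)
        # store paths relative to the cohort directory
        out_dir = Path(out_dir)
        for col in ("file", "mask_file"):
            files[col] = [str(Path(p).relative_to(out_dir)) for p in files[col]]
        files.to_csv(out_dir / "metadata.csv", index=False)
    return series_list, metadata


def rim_statistic(series: DCESeries, rim_voxels: int = 2) -> float:
    """Peritumoral texture energy of one patient.

    Standard deviation of the mean subtractive channel inside the 2-voxel
    rim around the lesions — the simplest statistic sensitive to the
    planted peritumoral signal.
    """
    stack = make_stack(series)
    rim = ndimage.binary_dilation(series.mask, iterations=rim_voxels) & ~series.mask
    mean_channel = stack.channels.mean(axis=0)
    return float(np.std(mean_channel[rim]))


def planted_signal_check(series_list: list[DCESeries]) -> float:
    """AUC of the rim-texture-energy statistic against the true labels.

    This oracle classifier upper-bounds what a well-trained network should
    approach on a planted-signal cohort and sits near 0.5 on a null cohort.
    """
    truth = [s.label for s in series_list]
    scores = [rim_statistic(s) for s in series_list]
    auc, *_ = roc_auc(truth, scores)
    return auc
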