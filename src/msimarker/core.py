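"""Central in-memory containers for the imaging pipeline.

A mass-spectrometry-imaging (MSI) experiment acquires one full mass spectrum
per pixel of a tissue section.  The pipeline carries three tissue groups
(thoracic aneurysm TAA, abdominal aneurysm AAA, post-stent-graft EVAR) and
two annotated aortic-wall layers (tunica media, tunica adventitia) per
section.  :class:`MSIDataset` holds one section; :class:`PeakMatrix` holds
the aligned spectra-by-feature intensity table the statistics operate on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNANNOTATED = "unannotated"

__all__ = [
    "Spectrum",
    "MSIDataset",
    "Feature",
    "PeakMatrix",
    "PeptideRecord",
    "save_dataset",
    "load_dataset",
    "UNANNOTATED",
]


@dataclass(frozen=True)
class Spectrum:
    """A single pixel's mass spectrum: an m/z axis and intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.ndim != 1 or intensity.ndim != 1:
            raise ValueError("spectrum arrays must be one-dimensional")
        if mz.shape != intensity.shape:
            raise ValueError(
                f"m/z axis ({mz.size}) and intensities ({intensity.size}) differ in length"
            )
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        """Total ion count (sum of intensities)."""
        return float(self.intensity.sum())


class MSIDataset:
    """One tissue section: a grid of spectra with coordinates and labels.

    Parameters
    ----------
    spectra
        One :class:`Spectrum` per pixel.  Sections acquired in continuous
        mode share a single m/z axis; processed-mode data may carry a
        distinct axis per pixel.
    coordinates
        Integer ``(x, y)`` grid index per pixel, 0-based, unique.
    section_id
        Identifier of the tissue section.
    group
        Cohort group of the section (e.g. ``"TAA"``, ``"AAA"``, ``"EVAR"``).
    region_labels
        Per-pixel wall-layer label: ``"media"``, ``"adventitia"`` or
        ``"unannotated"`` (default for every pixel).
    """

    def __init__(
        self,
        spectra: Sequence[Spectrum],
        coordinates: np.ndarray,
        section_id: str,
        group: str,
        region_labels: Sequence[str] | None = None,
    ) -> None:
        self.spectra = list(spectra)
        coords = np.asarray(coordinates, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coordinates must be an (n, 2) integer array")
        if coords.shape[0] != len(self.spectra):
            raise ValueError("one coordinate required per spectrum")
        if len({tuple(c) for c in coords.tolist()}) != coords.shape[0]:
            raise ValueError(f"coordinates not unique within section {section_id!r}")
        self.coordinates = coords
        self.section_id = str(section_id)
        self.group = str(group)
        if region_labels is None:
            region_labels = [UNANNOTATED] * len(self.spectra)
        labels = np.asarray(region_labels, dtype=object)
        if labels.shape[0] != len(self.spectra):
            raise ValueError("one region label required per spectrum")
        self.region_labels = labels

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def shared_axis(self) -> np.ndarray | None:
        """The common m/z axis, or ``None`` if pixels carry distinct axes."""
        if not self.spectra:
            return None
        axis = self.spectra[0].mz
        for s in self.spectra[1:]:
            if s.mz is not axis and not np.array_equal(s.mz, axis):
                return None
        return axis

    def intensity_matrix(self) -> np.ndarray:
        """Stack per-pixel intensities into an (n_pixels, n_points) array.

        Requires a shared m/z axis.
        """
        if self.shared_axis is None:
            raise ValueError(
                f"section {self.section_id!r} has per-pixel m/z axes; resample first"
            )
        return np.stack([s.intensity for s in self.spectra])

    @classmethod
    def from_grid(
        cls,
        mz_axis: np.ndarray,
        intensities: np.ndarray,
        coordinates: np.ndarray,
        section_id: str,
        group: str,
        region_labels: Sequence[str] | None = None,
    ) -> "MSIDataset":
        """Build a continuous-mode section from a shared axis and a 2-D array."""
        mz_axis = np.asarray(mz_axis, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        spectra = [Spectrum(mz_axis, row) for row in intensities]
        return cls(spectra, coordinates, section_id, group, region_labels)


@dataclass(frozen=True)
class Feature:
    """An aligned m/z interval: a center and a half-width (Da)."""

    center_mz: float
    half_width: float

    @property
    def low(self) -> float:
        return self.center_mz - self.half_width

    @property
    def high(self) -> float:
        return self.center_mz + self.half_width

    @property
    def width(self) -> float:
        return 2.0 * self.half_width


class PeakMatrix:
    """Spectra-by-feature intensity table with per-row metadata.

    ``meta`` carries one row per spectrum with columns
    ``section``, ``group``, ``region``, ``x``, ``y``.
    """

    META_COLUMNS = ("section", "group", "region", "x", "y")

    def __init__(self, features: Sequence[Feature], intensity: np.ndarray, meta: pd.DataFrame):
        features = list(features)
        intensity = np.asarray(intensity, dtype=float)
        if intensity.ndim != 2:
            raise ValueError("intensity must be 2-D (spectra x features)")
        if intensity.shape[1] != len(features):
            raise ValueError("one intensity column required per feature")
        if len(meta) != intensity.shape[0]:
            raise ValueError("one metadata row required per spectrum")
        missing = [c for c in self.META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        centers = np.array([f.center_mz for f in features])
        if centers.size > 1:
            if not np.all(np.diff(centers) > 0):
                raise ValueError("feature centers must be strictly increasing")
            highs = centers[:-1] + np.array([f.half_width for f in features[:-1]])
            lows = centers[1:] - np.array([f.half_width for f in features[1:]])
            if np.any(highs > lows):
                raise ValueError("feature intervals overlap")
        self.features = features
        self.intensity = intensity
        self.meta = meta.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensity.shape[1]

    @property
    def feature_mz(self) -> np.ndarray:
        return np.array([f.center_mz for f in self.features])

    def subset_rows(self, index: np.ndarray) -> "PeakMatrix":
        """Row-subset (new object; features unchanged)."""
        index = np.asarray(index)
        return PeakMatrix(self.features, self.intensity[index], self.meta.iloc[index])

    def to_frame(self) -> pd.DataFrame:
        cols = {f"{f.center_mz:.3f}": self.intensity[:, j] for j, f in enumerate(self.features)}
        out = self.meta.copy()
        out.insert(0, "spectrum_id", [f"{s}:{x},{y}" for s, x, y in
                                      zip(self.meta["section"], self.meta["x"], self.meta["y"])])
        return pd.concat([out, pd.DataFrame(cols, index=out.index)], axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PeptideRecord:
    """One LC-MS/MS identification row (search-engine CSV export)."""

    sequence: str
    mh_calc: float
    mowse: float
    gene: str
    protein_name: str = ""
    oxidations: int = 0

    def __post_init__(self) -> None:
        if self.mh_calc <= 0:
            raise ValueError(f"mh_calc must be positive, got {self.mh_calc}")


# ---------------------------------------------------------------------------
# Serialized grid format (the package's canonical on-disk dataset form):
# one .npz per section holding the shared axis, the intensity grid and a JSON
# metadata blob.  Round-trips bit-for-bit.

def save_dataset(dataset: MSIDataset, path: str | Path) -> None:
    axis = dataset.shared_axis
    if axis is None:
        raise ValueError("serialized grid format requires a shared m/z axis")
    meta = {
        "section_id": dataset.section_id,
        "group": dataset.group,
        "region_labels": list(map(str, dataset.region_labels)),
    }
    np.savez(
        path,
        mz_axis=axis,
        intensities=dataset.intensity_matrix(),
        coordinates=dataset.coordinates,
        meta=np.array(json.dumps(meta)),
    )


def load_dataset(path: str | Path) -> MSIDataset:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return MSIDataset.from_grid(
            z["mz_axis"],
            z["intensities"],
            z["coordinates"],
            meta["section_id"],
            meta["group"],
            meta["region_labels"],
        )


def save_peak_matrix(matrix: PeakMatrix, path: str | Path) -> None:
    np.savez(
        path,
        centers=np.array([f.center_mz for f in matrix.features]),
        half_widths=np.array([f.half_width for f in matrix.features]),
        intensity=matrix.intensity,
        meta=np.array(matrix.meta.to_json(orient="split")),
    )


def load_peak_matrix(path: str | Path) -> PeakMatrix:
    import io as _io

    with np.load(path, allow_pickle=False) as z:
        features = [Feature(c, h) for c, h in zip(z["centers"], z["half_widths"])]
        meta = pd.read_json(_io.StringIO(str(z["meta"])), orient="split")
        return PeakMatrix(features, z["intensity"], meta)


def concat_meta(datasets: Iterable[MSIDataset]) -> pd.DataFrame:
    """Per-spectrum metadata frame across sections (row order = input order)."""
    rows = []
    for ds in datasets:
        for (x, y), region in zip(ds.coordinates, ds.region_labels):
            rows.append((ds.section_id, ds.group, region, int(x), int(y)))
    return pd.DataFrame(rows, columns=list(PeakMatrix.META_COLUMNS))
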