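"""Readers and writers for the standard formats the pipeline touches.

Covers imzML (continuous and processed dialects, via pyimzml), the
annotation CSV mapping polygons or explicit pixel lists to wall-layer
regions, and the search-engine identification CSV.  The package's own
serialized grid format lives in :mod:`msimarker.core`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .core import MSIDataset, PeptideRecord, Spectrum, UNANNOTATED

__all__ = ["read_imzml", "write_imzml", "import_annotations",
           "read_annotation_csv", "read_id_table", "MOWSE_MIN"]

logger = logging.getLogger(__name__)

# search-engine acceptance rule: identifications at or below this score are
# dropped at read time (strictly greater than 13 passes)
MOWSE_MIN = 13.0

_ID_COLUMNS = ("sequence", "mh_calc", "score", "gene")


def write_imzml(datasets: Sequence[MSIDataset] | MSIDataset, path: str | Path,
                mode: str = "continuous") -> None:
    """Write sections to one imzML file (pixel coordinates offset per section).

    ``mode`` is the imzML dialect: ``"continuous"`` (shared axis) or
    ``"processed"`` (per-pixel axes).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if isinstance(datasets, MSIDataset):
        datasets = [datasets]
    with ImzMLWriter(str(path), mode=mode) as writer:
        x_off = 0
        for ds in datasets:
            for spec, (x, y) in zip(ds.spectra, ds.coordinates):
                # imzML coordinates are 1-based
                writer.addSpectrum(spec.mz, spec.intensity, (int(x) + 1 + x_off, int(y) + 1, 1))
            if len(ds):
                x_off += int(ds.coordinates[:, 0].max()) + 2


def read_imzml(path: str | Path, section_id: str | None = None,
               group: str = UNANNOTATED) -> MSIDataset:
    """Load an imzML file as one section with unannotated pixels.

    Region and group labels stay at their defaults until annotations are
    imported.  A malformed spectrum raises a parse error naming the pixel
    index.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    parser = ImzMLParser(str(path))
    spectra: list[Spectrum] = []
    coords: list[tuple[int, int]] = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        try:
            mz, inten = parser.getspectrum(i)
            spectra.append(Spectrum(np.asarray(mz, float), np.asarray(inten, float)))
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"failed to parse pixel {i} of {path.name}: {exc}") from exc
        coords.append((int(x) - 1, int(y) - 1))
    return MSIDataset(
        spectra,
        np.array(coords, dtype=int).reshape(-1, 2),
        section_id or path.stem,
        group,
    )


# ---------------------------------------------------------------------------
# Annotations


def read_annotation_csv(path: str | Path) -> pd.DataFrame:
    """Read an annotation table.

    Two row forms are accepted (mixed freely):

    * polygon rows — columns ``section_id``, ``region``, ``vertices`` with
      vertices encoded ``"x1,y1;x2,y2;..."`` in pixel units;
    * pixel rows — columns ``section_id``, ``region``, ``x``, ``y``.
    """
    df = pd.read_csv(path)
    if "section_id" not in df.columns or "region" not in df.columns:
        raise ValueError("annotation table needs 'section_id' and 'region' columns")
    return df


def import_annotations(dataset: MSIDataset, annotations: pd.DataFrame) -> MSIDataset:
    """Apply region annotations to one section (later rows win on overlap).

    A pixel belongs to a polygon region when its center lies strictly
    inside the polygon (half-open pixel semantics).  Explicit pixel rows
    outside the grid produce a warning and are skipped.  Pixels covered by
    no annotation stay unannotated.  Returns a new dataset.
    """
    labels = dataset.region_labels.copy()
    coord_index = {tuple(c): i for i, c in enumerate(dataset.coordinates.tolist())}
    if "section_id" in annotations.columns:
        rows = annotations[annotations["section_id"] == dataset.section_id]
    else:
        rows = annotations

    for _, row in rows.iterrows():
        region = str(row["region"])
        vertices = row.get("vertices")
        if isinstance(vertices, str) and vertices.strip():
            poly = Polygon(
                tuple(float(v) for v in pair.split(","))
                for pair in vertices.strip().split(";")
            )
            for (x, y), i in coord_index.items():
                if poly.contains(Point(x, y)):
                    labels[i] = region
        else:
            key = (int(row["x"]), int(row["y"]))
            if key not in coord_index:
                warnings.warn(
                    f"annotation pixel {key} outside grid of section "
                    f"{dataset.section_id!r}; skipped"
                )
                continue
            labels[coord_index[key]] = region
    return MSIDataset(dataset.spectra, dataset.coordinates, dataset.section_id,
                      dataset.group, labels)


# ---------------------------------------------------------------------------
# Identification table


def read_id_table(path: str | Path) -> list[PeptideRecord]:
    """Read a search-export CSV into peptide records.

    Required columns: ``sequence``, ``mh_calc``, ``score``, ``gene``
    (``protein_name`` and ``oxidations`` optional).  Rows with MOWSE score
    <= 13 are dropped, with the dropped count logged.
    """
    df = pd.read_csv(path)
    missing = [c for c in _ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"identification table missing columns {missing}; "
            f"expected header {list(_ID_COLUMNS) + ['protein_name', 'oxidations']}"
        )
    n_before = len(df)
    df = df[df["score"] > MOWSE_MIN]
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d identifications at MOWSE <= %s", dropped, MOWSE_MIN)
    return [
        PeptideRecord(
            sequence=str(r.sequence),
            mh_calc=float(r.mh_calc),
            mowse=float(r.score),
            gene=str(r.gene),
            protein_name=str(getattr(r, "protein_name", "") or ""),
            oxidations=int(getattr(r, "oxidations", 0) or 0),
        )
        for r in df.itertuples(index=False)
    ]
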