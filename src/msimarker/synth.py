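"""Synthetic MSI sections and companion identification tables with known truth.

The generator emulates the study design end to end: three cohort groups
(TAA, AAA, EVAR) of formalin-fixed aortic sections, a 50 um raster, tryptic
peptide peaks in the 600-3200 m/z window, the tunica media and adventitia
as contiguous bands of each section, and group-by-region multiplicative
effects on log-normal peak intensities.  Every planted peptide is known, so
downstream discovery, segmentation and matching can be tested for recovery
of the ground truth.

Peaks are Gaussian in m/z (default SD 0.05 Da) at the peptide's theoretical
MH+ plus per-pixel jitter; spectra additionally carry a slowly decaying
baseline and additive detector noise (clipped at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import MSIDataset, PeptideRecord, UNANNOTATED
from .match import MONOISOTOPIC_RESIDUE_MASSES, peptide_mh

__all__ = ["PanelPeptide", "SimulationConfig", "default_panel",
           "simulate_dataset", "simulate_id_table", "write_id_table"]

_REGIONS = ("media", "adventitia")


@dataclass(frozen=True)
class PanelPeptide:
    """Ground-truth peptide planted in every simulated spectrum.

    ``effects`` maps (group, region) to a multiplicative intensity shift;
    unlisted combinations default to 1.  ``oxidations`` counts oxidized
    methionines included in the theoretical MH+.
    """

    sequence: str
    gene: str
    mowse: float
    base_intensity: float = 100.0
    oxidations: int = 0
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    protein_name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(MONOISOTOPIC_RESIDUE_MASSES)
        if bad:
            raise ValueError(f"non-canonical residues {sorted(bad)} in {self.sequence!r}")
        if self.oxidations > self.sequence.count("M"):
            raise ValueError("more oxidations than methionines")
        if self.mowse <= 0:
            raise ValueError("mowse must be positive")

    @property
    def mh(self) -> float:
        return peptide_mh(self.sequence, self.oxidations)

    def effect(self, group: str, region: str) -> float:
        return float(self.effects.get((group, region), 1.0))


def default_panel() -> list[PanelPeptide]:
    """A small panel mirroring the biology of the aortic-wall study.

    Contractile-apparatus and extracellular-matrix peptides are suppressed
    four-fold in the media of EVAR sections (the direction the method is
    meant to detect); two peptides carry no effect anywhere and act as
    built-in negative controls.
    """
    evar_down = {("EVAR", "media"): 0.25}
    return [
        PanelPeptide("AGFAGDDAPR", "ACTA2", 88.6, 120.0, effects=evar_down,
                     protein_name="Actin, aortic smooth muscle"),
        PanelPeptide("SYELPDGQVITIGNER", "ACTA2", 28.1, 90.0, effects=evar_down,
                     protein_name="Actin, aortic smooth muscle"),
        PanelPeptide("GPAGPQGPR", "COL1A1", 49.1, 150.0, effects=evar_down,
                     protein_name="Collagen alpha-1(I) chain"),
        PanelPeptide("GFSGLDGAK", "COL1A1", 43.9, 110.0, effects=evar_down,
                     protein_name="Collagen alpha-1(I) chain"),
        PanelPeptide("SLEAQAEK", "TPM1", 30.3, 80.0, effects=evar_down,
                     protein_name="Tropomyosin alpha-1 chain"),
        PanelPeptide("KATDAEADVASLNR", "TPM1", 39.4, 70.0, effects=evar_down,
                     protein_name="Tropomyosin alpha-1 chain"),
        PanelPeptide("LGPLQVAR", "ETFB", 55.3, 95.0, effects=evar_down,
                     protein_name="Electron transfer flavoprotein subunit beta"),
        PanelPeptide("LSVISVEDPPQR", "ETFB", 51.1, 85.0, effects=evar_down,
                     protein_name="Electron transfer flavoprotein subunit beta"),
        PanelPeptide("DNIQGITKPAIR", "H4C1", 45.6, 100.0,
                     protein_name="Histone H4"),
        PanelPeptide("YEINVLR", "TNNT2", 26.7, 60.0,
                     protein_name="Troponin T, cardiac muscle"),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated experiment.

    groups
        (name, number of sections) per cohort group; the study design is
        five sections per group.
    grid_shape
        (nx, ny) pixels per section.
    raster_um
        Pixel spacing in micrometres (acquisition raster).
    mz_range / mz_step
        m/z axis bounds (Da) and sampling step.
    peak_sigma
        Gaussian peak width (SD, Da) in m/z.
    baseline_level / noise_sd
        Chemical-baseline amplitude and additive noise SD (intensity units).
    mz_jitter_sd
        Per-pixel peak-position jitter (Da).
    intensity_sigma
        SD of the log-normal multiplicative intensity variation.
    roi_fractions
        Fraction of each section's rows labeled media resp. adventitia
        (contiguous bands; the remainder stays unannotated).
    """

    seed: int = 0
    groups: tuple[tuple[str, int], ...] = (("TAA", 5), ("AAA", 5), ("EVAR", 5))
    grid_shape: tuple[int, int] = (24, 24)
    raster_um: float = 50.0
    mz_range: tuple[float, float] = (600.0, 3200.0)
    mz_step: float = 0.1
    panel: tuple[PanelPeptide, ...] = field(default_factory=lambda: tuple(default_panel()))
    peak_sigma: float = 0.05
    baseline_level: float = 2.0
    noise_sd: float = 1.0
    mz_jitter_sd: float = 0.02
    intensity_sigma: float = 0.5
    roi_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"media": 0.45, "adventitia": 0.45}
    )

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range low must be below high")
        fr = dict(self.roi_fractions)
        if any(not 0 <= v <= 1 for v in fr.values()) or sum(fr.values()) > 1 + 1e-9:
            raise ValueError("roi_fractions must lie in [0,1] and sum to <= 1")
        if set(fr) - set(_REGIONS):
            raise ValueError(f"unknown regions {set(fr) - set(_REGIONS)}")
        for p in self.panel:
            if not lo <= p.mh <= hi:
                raise ValueError(
                    f"panel peptide {p.sequence!r} has MH+ {p.mh:.3f} Da outside "
                    f"the m/z range {lo}-{hi}"
                )

    @property
    def mz_axis(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(round((hi - lo) / self.mz_step)) + 1
        return lo + self.mz_step * np.arange(n)


def _region_labels(config: SimulationConfig) -> np.ndarray:
    """Contiguous horizontal bands: media on top, adventitia below."""
    nx, ny = config.grid_shape
    fr = dict(config.roi_fractions)
    n_media = int(round(fr.get("media", 0.0) * ny))
    n_adv = int(round(fr.get("adventitia", 0.0) * ny))
    n_adv = min(n_adv, ny - n_media)
    rows = np.full(ny, UNANNOTATED, dtype=object)
    rows[:n_media] = "media"
    rows[n_media:n_media + n_adv] = "adventitia"
    # pixel order is x-major within each row (y, x) scan
    return np.repeat(rows, nx)


def _section_spectra(config: SimulationConfig, group: str, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axis = config.mz_axis
    nx, ny = config.grid_shape
    n_px = nx * ny
    labels = _region_labels(config)

    lo = config.mz_range[0]
    baseline = config.baseline_level * np.exp(-(axis - lo) / 800.0)
    X = np.tile(baseline, (n_px, 1))
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)

    half = max(5.0 * config.peak_sigma + 5.0 * config.mz_jitter_sd, config.mz_step)
    for pep in config.panel:
        eff = np.array([pep.effect(group, str(r)) for r in labels])
        amps = pep.base_intensity * eff
        if config.intensity_sigma > 0:
            amps = amps * rng.lognormal(0.0, config.intensity_sigma, size=n_px)
        centers = np.full(n_px, pep.mh)
        if config.mz_jitter_sd > 0:
            centers = centers + rng.normal(0.0, config.mz_jitter_sd, size=n_px)
        a = np.searchsorted(axis, pep.mh - half)
        b = np.searchsorted(axis, pep.mh + half, side="right")
        window = axis[a:b]
        X[:, a:b] += amps[:, None] * np.exp(
            -0.5 * ((window[None, :] - centers[:, None]) / config.peak_sigma) ** 2
        )
    np.clip(X, 0.0, None, out=X)

    ys, xs = np.divmod(np.arange(n_px), nx)
    coords = np.column_stack([xs, ys])
    return X, coords, labels


def simulate_dataset(config: SimulationConfig) -> list[MSIDataset]:
    """Generate one :class:`MSIDataset` per section, deterministically.

    Randomness is threaded from ``config.seed`` through one substream per
    section, so the same config reproduces bit-identical data and sections
    are independent of each other's sizes.
    """
    axis = config.mz_axis
    children = np.random.SeedSequence(config.seed).spawn(
        sum(n for _, n in config.groups)
    )
    out: list[MSIDataset] = []
    k = 0
    for group, n_sections in config.groups:
        for i in range(n_sections):
            rng = np.random.default_rng(children[k])
            k += 1
            X, coords, labels = _section_spectra(config, group, rng)
            out.append(
                MSIDataset.from_grid(axis, X, coords, f"{group}_{i + 1}", group, labels)
            )
    return out


_DECOY_ALPHABET = "ACDEFGHILMNPQSTVWY"  # K/R reserved for the tryptic terminus


def simulate_id_table(
    config: SimulationConfig,
    decoy_fraction: float = 0.0,
    min_decoy_distance: float = 1.5,
) -> list[PeptideRecord]:
    """Identification records for the panel, plus optional decoys.

    Decoys are random tryptic-like sequences whose MH+ keeps at least
    ``min_decoy_distance`` Da from every panel mass, so they can never be
    matched to a planted peak at the default tolerance.  Their count is
    ``round(decoy_fraction * panel size)``, reproducible from the seed.
    """
    records = [
        PeptideRecord(p.sequence, p.mh, p.mowse, p.gene, p.protein_name, p.oxidations)
        for p in config.panel
    ]
    n_decoys = int(round(decoy_fraction * len(config.panel)))
    if n_decoys:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(10_000)[-1])
        panel_mh = np.array([p.mh for p in config.panel])
        made = 0
        while made < n_decoys:
            length = int(rng.integers(6, 16))
            seq = "".join(rng.choice(list(_DECOY_ALPHABET), size=length)) + \
                  ("K" if rng.random() < 0.5 else "R")
            mh = peptide_mh(seq)
            if panel_mh.size and np.min(np.abs(panel_mh - mh)) < min_decoy_distance:
                continue
            made += 1
            records.append(
                PeptideRecord(seq, mh, float(np.round(rng.uniform(14, 80), 2)),
                              f"DECOY{made}", "synthetic decoy")
            )
    return records


def write_id_table(records: Sequence[PeptideRecord], path) -> None:
    """Write records as the search-export CSV the reader consumes."""
    import pandas as pd

    pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "mh_calc": [r.mh_calc for r in records],
            "score": [r.mowse for r in records],
            "gene": [r.gene for r in records],
            "protein_name": [r.protein_name for r in records],
            "oxidations": [r.oxidations for r in records],
        }
    ).to_csv(path, index=False)
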