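import numpy as np
import pandas as pd
import pytest

from msimarker.core import Feature, PeakMatrix
from msimarker.preprocess import run as preprocess_run
from msimarker.synth import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    """Two sections (TAA, EVAR), 200 media pixels each, default panel.

    The default panel suppresses eight peptides four-fold in the EVAR
    media, leaving two null controls.
    """
    return SimulationConfig(
        seed=11,
        groups=(("TAA", 1), ("EVAR", 1)),
        grid_shape=(20, 20),
        mz_range=(600.0, 1850.0),
        mz_step=0.05,
        roi_fractions={"media": 0.5, "adventitia": 0.5},
    )


@pytest.fixture(scope="session")
def planted_matrix(planted_config) -> PeakMatrix:
    return preprocess_run(simulate_dataset(planted_config))


def banded_config(seed: int = 29, grid=(16, 16)) -> SimulationConfig:
    """One section whose media and adventitia bands differ by 2x effects.

    Twelve peptide features (six elevated per layer) approximate the
    feature richness real sections provide for correlation-based
    segmentation.
    """
    from msimarker.synth import PanelPeptide

    media_up = {("TAA", "media"): 2.0}
    adv_up = {("TAA", "adventitia"): 2.0}
    seqs_m = ["AGFAGDDAPR", "SLEAQAEK", "LGPLQVAR", "DSYVGDEAQSK",
              "ALAAAGYDVEK", "VLIAAHGNSLR"]
    seqs_a = ["GPAGPQGPR", "GFSGLDGAK", "DNIQGITKPAIR", "GEAGPQGPR",
              "GSEGPQGVR", "YEINVLR"]
    panel = tuple(
        [PanelPeptide(s, f"GM{i}", 30.0, 100.0, effects=media_up)
         for i, s in enumerate(seqs_m)]
        + [PanelPeptide(s, f"GA{i}", 30.0, 100.0, effects=adv_up)
           for i, s in enumerate(seqs_a)]
    )
    return SimulationConfig(
        seed=seed, groups=(("TAA", 1),), grid_shape=grid,
        mz_range=(600.0, 1400.0), mz_step=0.05, panel=panel,
        roi_fractions={"media": 0.5, "adventitia": 0.5},
    )


def make_peak_matrix(X: np.ndarray, groups, region: str = "media",
                     spacing: float = 0.5) -> PeakMatrix:
    """Wrap a raw intensity array as a PeakMatrix with synthetic features."""
    n, p = X.shape
    feats = [Feature(600.0 + spacing * j, 0.15) for j in range(p)]
    meta = pd.DataFrame(
        {
            "section": ["s1"] * n,
            "group": list(groups),
            "region": [region] * n,
            "x": np.arange(n),
            "y": np.zeros(n, dtype=int),
        }
    )
    return PeakMatrix(feats, X, meta)
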