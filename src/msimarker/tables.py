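"""Packaged reference tables.

Two small fixtures ship with the package: the clinical cohort table of the
15 aneurysm patients (subgroup, age, maximum aneurysm diameter,
comorbidities) and the tunica-media candidate table pairing discriminative
MALDI-MSI m/z values with their LC-MS/MS peptide identifications and
per-comparison ROC AUCs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import PeptideRecord

__all__ = ["load_cohort_table", "load_candidate_table", "candidate_records",
           "AUC_COLUMNS"]

# comparison label -> AUC column of the candidate table; orientation is
# "first group vs second", AUC > 0.5 meaning higher in the first group
AUC_COLUMNS = {
    "AAA vs EVAR": "auc_aaa_vs_evar",
    "AAA vs TAA": "auc_aaa_vs_taa",
    "EVAR vs TAA": "auc_evar_vs_taa",
}


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("msimarker.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, **kwargs)


def load_cohort_table() -> pd.DataFrame:
    """The 15-patient cohort table (5 TAA, 5 AAA, 5 EVAR; all male)."""
    return _read("aortic_cohort.csv")


def load_candidate_table() -> pd.DataFrame:
    """The 47-row tunica-media candidate table.

    Columns: feature ``mz``, three per-comparison ``auc_*`` columns,
    LC-MS/MS ``mh_calc``, MOWSE ``score``, peptide ``sequence``, ``gene``
    and ``protein``.
    """
    return _read("media_candidates.tsv", sep="\t")


def candidate_records(table: pd.DataFrame | None = None) -> list[PeptideRecord]:
    """The candidate table's identification rows as peptide records."""
    df = load_candidate_table() if table is None else table
    return [
        PeptideRecord(
            sequence=str(r.sequence),
            mh_calc=float(r.mh_calc),
            mowse=float(r.score),
            gene=str(r.gene),
            protein_name=str(r.protein),
        )
        for r in df.itertuples(index=False)
    ]
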