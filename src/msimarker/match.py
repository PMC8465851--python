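"""Matching of MALDI-MSI m/z features to LC-MS/MS peptide identifications.

This module implements the in-house matching procedure: theoretical
monoisotopic MH+ computation for tryptic peptides (with optional methionine
oxidation), tolerance pairing of imaging features to identification records,
deterministic tie-breaking, an ion-image correlation filter, and the
protein-level validation rule requiring at least two peptide values from the
same protein to pass the discriminative AUC criterion.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PeptideRecord

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASSES", "WATER", "PROTON", "OXIDATION",
    "peptide_mh", "MatchConfig", "MatchedPeptide", "ProteinCall",
    "match_features", "call_proteins", "match_report",
]

# Monoisotopic residue (amino-acid minus water) masses in Da.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565
PROTON = 1.007276
OXIDATION = 15.994915  # one oxygen, variable Met modification


def peptide_mh(sequence: str, oxidations: int = 0) -> float:
    """Monoisotopic MH+ of a peptide, in Da.

    Sum of residue masses plus one water (termini) plus one proton, plus
    ``oxidations`` x 15.994915 for oxidized methionines.

    Raises
    ------
    ValueError
        On a non-canonical residue (naming its position) or if
        ``oxidations`` exceeds the methionine count.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER + PROTON
    for i, aa in enumerate(sequence):
        try:
            total += MONOISOTOPIC_RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {i + 1} of {sequence!r}"
            ) from None
    n_met = sequence.count("M")
    if oxidations < 0 or oxidations > n_met:
        raise ValueError(
            f"{oxidations} oxidations requested but {sequence!r} has {n_met} Met"
        )
    return total + oxidations * OXIDATION


def best_oxidation_fit(sequence: str, target_mh: float, max_ox: int = 2) -> tuple[int, float]:
    """Oxidation count (0..min(max_ox, #Met)) minimizing |MH+ - target|.

    Returns ``(n_oxidations, mh)``.
    """
    n = min(max_ox, sequence.count("M"))
    choices = [(k, peptide_mh(sequence, k)) for k in range(n + 1)]
    return min(choices, key=lambda kv: abs(kv[1] - target_mh))


@dataclass(frozen=True)
class MatchConfig:
    """Settings of the feature-to-identification matcher.

    tolerance_da
        Maximal absolute mass difference (strict) between a MALDI feature
        m/z and a peptide's calculated MH+.
    min_peptides_per_protein
        Distinct (feature, sequence) pairs required to validate a protein.
    correlation_min
        Absolute Pearson threshold between a candidate feature's ion image
        and the mean image of the same gene's other matched features.
    oxidation_max
        Maximal number of variable Met oxidations considered.
    """

    tolerance_da: float = 1.0
    min_peptides_per_protein: int = 2
    correlation_min: float = 0.1
    oxidation_max: int = 2

    def __post_init__(self) -> None:
        if self.tolerance_da <= 0:
            raise ValueError("tolerance_da must be positive")
        if self.min_peptides_per_protein < 1:
            raise ValueError("min_peptides_per_protein must be >= 1")


@dataclass(frozen=True)
class MatchedPeptide:
    """A (feature m/z, identification record) pairing within tolerance.

    ``tie_rank`` records the candidate's rank within its (feature, gene)
    group after sorting by MOWSE score (descending), then |delta mass|,
    then MH+ — the provenance of the selection order.
    """

    feature_mz: float
    record: PeptideRecord
    delta_mass: float
    tie_rank: int = 0


@dataclass(frozen=True)
class ProteinCall:
    """Gene-level validated call for one group comparison."""

    gene: str
    comparison: str
    direction: str  # "increased" or "decreased" (in group_a relative to group_b)
    supporting: tuple[tuple[float, str], ...]  # qualifying (feature m/z, sequence)
    reported: tuple[tuple[float, str], ...]    # all matched pairs of the gene
    n_support: int


def match_features(
    feature_mzs: Sequence[float],
    records: Sequence[PeptideRecord],
    images: Mapping[float, np.ndarray] | None = None,
    config: MatchConfig = MatchConfig(),
) -> list[MatchedPeptide]:
    """Pair imaging features with identification records within tolerance.

    Each record is assigned to the feature closest to its calculated MH+
    (ties: lower m/z) provided |feature m/z - MH+| is strictly below
    ``tolerance_da``; records with no feature in tolerance stay unmatched.
    A feature may thus collect records of several genes and several
    sequences of one gene.  Within a (feature, gene) group, records sharing
    a sequence are collapsed to the best one (highest MOWSE, then smallest
    |delta|, then lowest MH+) and the surviving candidates are ranked in
    that order (``tie_rank``).

    When ion images are supplied and a gene has matched >= 2 distinct
    features, candidates whose image correlates with the mean image of the
    gene's other features at |Pearson| <= ``correlation_min`` are dropped.
    """
    matches: list[MatchedPeptide] = []
    mz_sorted = sorted(float(mz) for mz in feature_mzs)
    per_gene_feature: dict[tuple[str, float], list[tuple[PeptideRecord, float]]] = defaultdict(list)
    for rec in records:
        if not mz_sorted:
            break
        mz = min(mz_sorted, key=lambda v: (abs(v - rec.mh_calc), v))
        delta = mz - rec.mh_calc
        if abs(delta) < config.tolerance_da:
            per_gene_feature[(rec.gene, mz)].append((rec, delta))

    for (gene, mz), cands in sorted(per_gene_feature.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        best_by_seq: dict[str, tuple[PeptideRecord, float]] = {}
        for rec, delta in cands:
            key = rec.sequence
            if key not in best_by_seq or _better(rec, delta, *best_by_seq[key]):
                best_by_seq[key] = (rec, delta)
        ranked = sorted(
            best_by_seq.values(),
            key=lambda rd: (-rd[0].mowse, abs(rd[1]), rd[0].mh_calc),
        )
        for rank, (rec, delta) in enumerate(ranked):
            matches.append(MatchedPeptide(mz, rec, delta, tie_rank=rank))

    if images is not None:
        matches = _image_correlation_filter(matches, images, config)
    return matches


def _better(rec: PeptideRecord, delta: float, other: PeptideRecord, other_delta: float) -> bool:
    return (-rec.mowse, abs(delta), rec.mh_calc) < (-other.mowse, abs(other_delta), other.mh_calc)


def _image_correlation_filter(
    matches: list[MatchedPeptide],
    images: Mapping[float, np.ndarray],
    config: MatchConfig,
) -> list[MatchedPeptide]:
    by_gene: dict[str, list[MatchedPeptide]] = defaultdict(list)
    for m in matches:
        by_gene[m.record.gene].append(m)
    kept: list[MatchedPeptide] = []
    for gene, group in by_gene.items():
        feats = sorted({m.feature_mz for m in group})
        if len(feats) < 2:
            kept.extend(group)
            continue
        for m in group:
            others = [images[f] for f in feats if f != m.feature_mz and f in images]
            if m.feature_mz not in images or not others:
                kept.append(m)
                continue
            ref = np.mean(others, axis=0)
            img = np.asarray(images[m.feature_mz], dtype=float)
            if img.std() == 0 or ref.std() == 0:
                warnings.warn(f"zero-variance ion image for {gene} at {m.feature_mz}; kept")
                kept.append(m)
                continue
            r = float(np.corrcoef(img, ref)[0, 1])
            if abs(r) > config.correlation_min:
                kept.append(m)
    kept.sort(key=lambda m: (m.feature_mz, m.record.gene, m.tie_rank))
    return kept


def call_proteins(
    matches: Sequence[MatchedPeptide],
    stats: pd.DataFrame,
    comparison: str = "",
    config: MatchConfig = MatchConfig(),
    auc_low: float = 0.4,
    auc_high: float = 0.6,
    p_max: float = 0.001,
) -> list[ProteinCall]:
    """Protein-level validation of matched peptide values for one comparison.

    ``stats`` needs columns ``feature_mz`` and ``auc``; an optional
    ``p_value`` column is honored (candidate tables listing only AUCs for
    features that already passed the p gate may omit it).  A distinct
    (feature, sequence) pair qualifies when its feature's AUC is <=
    ``auc_low`` or >= ``auc_high`` (inclusive on both sides) and its p-value
    passes.  Genes with at least ``min_peptides_per_protein`` qualifying
    pairs are called, directed by the AUC side of the qualifying majority;
    the call also reports every matched pair of the gene, qualifying or not.

    The result is invariant to the order of ``matches``.
    """
    auc_by_mz = dict(zip(stats["feature_mz"].astype(float), stats["auc"].astype(float)))
    if "p_value" in stats.columns:
        p_by_mz = dict(zip(stats["feature_mz"].astype(float), stats["p_value"].astype(float)))
    else:
        p_by_mz = {}

    by_gene: dict[str, dict[tuple[float, str], float]] = defaultdict(dict)
    for m in matches:
        by_gene[m.record.gene].setdefault((float(m.feature_mz), m.record.sequence), 0.0)

    calls: list[ProteinCall] = []
    for gene in sorted(by_gene):
        pairs = sorted(by_gene[gene].keys())
        qualifying = []
        sides = []
        for mz, seq in pairs:
            if mz not in auc_by_mz:
                continue
            auc = auc_by_mz[mz]
            if p_by_mz and not (p_by_mz.get(mz, 0.0) < p_max):
                continue
            if auc >= auc_high:
                qualifying.append((mz, seq))
                sides.append(+1)
            elif auc <= auc_low:
                qualifying.append((mz, seq))
                sides.append(-1)
        if len(qualifying) >= config.min_peptides_per_protein:
            direction = "increased" if sum(sides) > 0 else "decreased"
            calls.append(
                ProteinCall(
                    gene=gene,
                    comparison=comparison,
                    direction=direction,
                    supporting=tuple(qualifying),
                    reported=tuple(pairs),
                    n_support=len(qualifying),
                )
            )
    return calls


def match_report(matches: Sequence[MatchedPeptide], stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabular match report (feature m/z, MH+, delta, score, sequence, gene)."""
    rows = [
        {
            "feature_mz": m.feature_mz,
            "mh_calc": m.record.mh_calc,
            "delta_mass": m.delta_mass,
            "mowse": m.record.mowse,
            "sequence": m.record.sequence,
            "gene": m.record.gene,
            "protein": m.record.protein_name,
            "tie_rank": m.tie_rank,
        }
        for m in matches
    ]
    out = pd.DataFrame(rows)
    if stats is not None and len(out):
        out = out.merge(stats, on="feature_mz", how="left")
    return out
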