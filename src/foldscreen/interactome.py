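"""Interactome analytics on the aggregated protein x fold call matrix.

Aggregates per-fold interactor calls into a binary matrix with enrichment
values, then derives positional binding preferences (which transcript regions
a protein's bound folds come from), binding promiscuity, shared/exclusive
interactors of mRNAs carrying several folds, and Puf3-recognition-motif scans
of transcript regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from foldscreen.fold_catalog import RegionClass
from foldscreen.silac_screen import EnrichmentRecord

PUF3_CANONICAL = "UGUAAAUA"
#: Contiguous sub-words of the canonical motif accepted as "similar" hits.
PUF3_SIMILAR_DEFAULT = ("UGUAAAU", "GUAAAUA", "UGUAAA", "GUAAAU")


@dataclass
class InteractionMatrix:
    """Binary protein x fold call matrix with per-call enrichment values."""

    called: pd.DataFrame  # bool, proteins x folds
    enrichment: pd.DataFrame  # float, NaN where not called

    @property
    def proteins(self) -> list[str]:
        return list(self.called.index)

    @property
    def folds(self) -> list[str]:
        return list(self.called.columns)

    def folds_per_protein(self) -> pd.Series:
        return self.called.sum(axis=1)

    def binders_per_fold(self) -> pd.Series:
        return self.called.sum(axis=0)


@dataclass(frozen=True)
class MotifHit:
    gene: str
    region: str
    motif: str
    kind: str  # "canonical" | "similar"
    offset: int


def build_matrix(call_sets: Mapping[str, list[EnrichmentRecord]]) -> InteractionMatrix:
    """Assemble the interaction matrix from per-fold called records.

    ``call_sets`` maps fold_id to that fold's records; only ``called`` records
    enter the matrix. Conflicting duplicate calls (same protein and fold,
    different enrichment) raise.
    """
    cells: dict[tuple[str, str], float] = {}
    for fold_id, records in call_sets.items():
        for rec in records:
            if not rec.called:
                continue
            key = (rec.protein_id, fold_id)
            if key in cells and cells[key] != rec.enrichment_value:
                raise ValueError(
                    f"conflicting duplicate call for {rec.protein_id} on {fold_id}"
                )
            cells[key] = rec.enrichment_value
    proteins = sorted({p for p, _ in cells})
    folds = list(call_sets.keys())
    called = pd.DataFrame(False, index=proteins, columns=folds, dtype=bool)
    enrich = pd.DataFrame(np.nan, index=proteins, columns=folds, dtype=float)
    for (p, f), v in cells.items():
        called.loc[p, f] = True
        enrich.loc[p, f] = v
    return InteractionMatrix(called=called, enrichment=enrich)


def positional_preferences(
    matrix: InteractionMatrix, fold_classes: Mapping[str, RegionClass]
) -> pd.DataFrame:
    """Venn categories of interactors by the transcript regions they bind.

    Every interactor with at least one call is assigned the non-empty subset
    of {5'UTR, CDS, 3'UTR} covered by its bound folds; the seven category
    counts partition the interactor set. Returns one row per interactor with
    a frozen-set style category string (e.g. ``"5UTR+CDS"``).
    """
    missing = [f for f in matrix.folds if f not in fold_classes]
    if missing:
        raise ValueError(f"folds without a region class: {missing}")
    order = [RegionClass.FIVE_UTR, RegionClass.CDS, RegionClass.THREE_UTR]
    rows = []
    for protein in matrix.proteins:
        bound = matrix.called.loc[protein]
        classes = {fold_classes[f] for f in matrix.folds if bound[f]}
        if not classes:
            continue
        label = "+".join(c.value for c in order if c in classes)
        rows.append({"protein_id": protein, "venn_category": label})
    return pd.DataFrame(rows)


def venn_counts(preferences: pd.DataFrame) -> pd.Series:
    return preferences["venn_category"].value_counts()


def promiscuity_profile(
    matrix: InteractionMatrix,
    selective_max: int = 1,
    promiscuous_min: int = 20,
) -> pd.DataFrame:
    """Per-protein target-fold counts with a selectivity class.

    ``selective`` proteins recognize at most ``selective_max`` folds (a single
    fold by default), ``promiscuous`` ones at least ``promiscuous_min``;
    everything in between is ``intermediate``.
    """
    counts = matrix.folds_per_protein()

    def classify(n: int) -> str:
        if n <= selective_max:
            return "selective"
        if n >= promiscuous_min:
            return "promiscuous"
        return "intermediate"

    return pd.DataFrame(
        {
            "protein_id": counts.index,
            "n_folds": counts.to_numpy(int),
            "class": [classify(int(n)) for n in counts],
        }
    ).reset_index(drop=True)


def overlap_delimitation(
    matrix: InteractionMatrix, fold_genes: Mapping[str, str]
) -> pd.DataFrame:
    """Shared vs fold-exclusive interactors for mRNAs with multiple folds.

    For every gene carrying >= 2 folds: interactors common to all of its
    folds, and for each fold the interactors seen on no other fold of the
    same gene. Union of shared and exclusives plus the mid-frequency rest
    reconstructs each fold's call set.
    """
    by_gene: dict[str, list[str]] = {}
    for fold in matrix.folds:
        by_gene.setdefault(fold_genes.get(fold, fold), []).append(fold)
    rows = []
    for gene, folds in by_gene.items():
        if len(folds) < 2:
            continue
        sets = {f: set(matrix.called.index[matrix.called[f]]) for f in folds}
        shared = set.intersection(*sets.values())
        for f in folds:
            others = set().union(*(sets[g] for g in folds if g != f))
            rows.append(
                {
                    "gene": gene,
                    "fold_id": f,
                    "n_folds_on_gene": len(folds),
                    "shared": sorted(shared),
                    "exclusive": sorted(sets[f] - others),
                    "all_interactors": sorted(sets[f]),
                }
            )
    return pd.DataFrame(rows)


def scan_puf3_motif(
    regions: Iterable[tuple[str, str, str]],
    canonical: str = PUF3_CANONICAL,
    similar: Sequence[str] = PUF3_SIMILAR_DEFAULT,
) -> list[MotifHit]:
    """Scan transcript regions for the Puf3 recognition motif.

    ``regions`` yields (gene, region_label, rna_sequence) triples. All exact
    canonical occurrences are reported; occurrences of the shorter "similar"
    variants are reported only where they do not overlap a canonical hit.
    """
    hits: list[MotifHit] = []
    for gene, region, seq in regions:
        seq = seq.upper().replace("T", "U")
        canon_spans = []
        for off in _find_all(seq, canonical):
            canon_spans.append((off, off + len(canonical)))
            hits.append(MotifHit(gene, region, canonical, "canonical", off))
        for variant in similar:
            for off in _find_all(seq, variant):
                span = (off, off + len(variant))
                if any(span[0] < ce and cs < span[1] for cs, ce in canon_spans):
                    continue
                hits.append(MotifHit(gene, region, variant, "similar", off))
    return hits


def _find_all(seq: str, sub: str) -> list[int]:
    out, start = [], 0
    while True:
        idx = seq.find(sub, start)
        if idx == -1:
            return out
        out.append(idx)
        start = idx + 1


def length_bias_report(
    matrix: InteractionMatrix, fold_lengths: Mapping[str, int]
) -> dict[str, float]:
    """Rank correlation of binder count with fold length (bias check).

    A strong positive correlation would indicate unspecific background
    scaling with bait size.
    """
    binders = matrix.binders_per_fold()
    lengths = np.array([fold_lengths[f] for f in matrix.folds], dtype=float)
    rho, p = stats.spearmanr(binders.to_numpy(float), lengths)
    return {"rho": float(rho), "p_value": float(p), "n_folds": len(matrix.folds)}
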