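"""RNA-binding-protein feature analysis of an interactor set.

Compares a candidate interactor set against measured-proteome and
predicted-proteome backgrounds: biochemical property shifts (t-tests with
BH-FDR), amino-acid composition, Fisher enrichment of annotations (GO terms,
Pfam RNA-binding domains), intrinsic-disorder content, and a tiered
classification into known RNA binders, RNA-related proteins, proteins whose
human orthologs are RNA-related, and unexplained candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

RBP_TIERS = ("RNA_binding", "RNA_related", "ortholog_RNA", "unknown")


@dataclass(frozen=True)
class EnrichmentTest:
    annotation_label: str
    a: int  # in set, annotated
    b: int  # in set, not annotated
    c: int  # background only, annotated
    d: int  # background only, not annotated
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def compare_property(
    interactors: Mapping[str, Sequence[float]],
    background_measured: Mapping[str, Sequence[float]],
    background_predicted: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Welch t-tests of each property against both backgrounds, BH-corrected.

    Each mapping gives property name -> values for that group. Properties with
    fewer than 3 finite values in either group of a comparison, or a constant
    pooled sample, are reported with NaN statistics. q-values are computed
    jointly across every (property, background) test in the run.
    """
    rows = []
    for prop in interactors:
        x = _clean(interactors[prop])
        for bg_name, bg in (
            ("measured", background_measured),
            ("predicted", background_predicted),
        ):
            if prop not in bg:
                continue
            y = _clean(bg[prop])
            if len(x) < 3 or len(y) < 3:
                warnings.warn(f"{prop} vs {bg_name}: fewer than 3 values", stacklevel=2)
                t = p = float("nan")
            elif np.ptp(x) == 0 and np.ptp(y) == 0:
                t = p = float("nan")
            else:
                t, p = stats.ttest_ind(x, y, equal_var=False)
            rows.append(
                {
                    "property": prop,
                    "background": bg_name,
                    "mean_set": float(np.mean(x)) if len(x) else float("nan"),
                    "mean_background": float(np.mean(y)) if len(y) else float("nan"),
                    "t_statistic": float(t),
                    "p_value": float(p),
                }
            )
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    ok = table["p_value"].notna()
    if ok.any():
        table.loc[ok, "q_value"] = multipletests(
            table.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    return table


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def aa_composition(
    seq_set: Iterable[str], background_set: Iterable[str], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-residue log2 frequency enrichment of a sequence set over background.

    Frequencies are computed over pooled residues of each set; non-standard
    residues go to an ``other`` bin with a warning; zero counts are handled by
    the pseudocount.
    """

    def counts(seqs: Iterable[str]) -> tuple[dict[str, int], int]:
        c = {aa: 0 for aa in AMINO_ACIDS}
        other = 0
        for seq in seqs:
            for ch in seq.upper():
                if ch in c:
                    c[ch] += 1
                else:
                    other += 1
        return c, other

    set_counts, set_other = counts(seq_set)
    bg_counts, bg_other = counts(background_set)
    if set_other or bg_other:
        warnings.warn(
            f"non-standard residues counted as 'other' (set {set_other}, "
            f"background {bg_other})",
            stacklevel=2,
        )
    n_set = sum(set_counts.values())
    n_bg = sum(bg_counts.values())
    if n_set == 0 or n_bg == 0:
        raise ValueError("empty sequence set")
    rows = []
    denom_set = n_set + pseudocount * len(AMINO_ACIDS)
    denom_bg = n_bg + pseudocount * len(AMINO_ACIDS)
    for aa in AMINO_ACIDS:
        f_set = (set_counts[aa] + pseudocount) / denom_set
        f_bg = (bg_counts[aa] + pseudocount) / denom_bg
        rows.append(
            {
                "aa": aa,
                "freq_set": set_counts[aa] / n_set,
                "freq_background": bg_counts[aa] / n_bg,
                "log2_enrichment": float(np.log2(f_set / f_bg)),
            }
        )
    return pd.DataFrame(rows)


def annotation_enrichment(
    set_ids: set[str],
    background_ids: set[str],
    annotation: Mapping[str, bool],
    label: str = "annotation",
) -> EnrichmentTest:
    """Two-sided Fisher exact test of an annotation within a set vs background.

    The set must be contained in the background; the 2x2 table contrasts set
    members with the remaining background. The odds ratio is the sample
    cross-product, with a Haldane 0.5 correction when any cell is zero.
    """
    if not set_ids:
        raise ValueError("empty set")
    if not set_ids <= background_ids:
        raise ValueError("set must be a subset of the background")
    rest = background_ids - set_ids
    a = sum(1 for i in set_ids if annotation.get(i, False))
    b = len(set_ids) - a
    c = sum(1 for i in rest if annotation.get(i, False))
    d = len(rest) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)
    return EnrichmentTest(
        annotation_label=label, a=a, b=b, c=c, d=d,
        odds_ratio=float(oddsr), p_value=float(p),
    )


def disorder_fraction(disorder_probs: Sequence[float]) -> float:
    """Fraction of residues with predicted disorder probability above 0.5."""
    arr = np.asarray(disorder_probs, dtype=float)
    if arr.size == 0:
        raise ValueError("empty disorder vector")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("disorder probabilities must lie in [0, 1]")
    return float(np.mean(arr > 0.5))


def classify_rbp(
    protein_id: str,
    go_terms: Iterable[str],
    rna_related_terms: Iterable[str],
    rbd_pfam_domains: Iterable[str] = (),
    pfam_domains: Iterable[str] = (),
    ortholog_go_terms: Iterable[str] = (),
    ortholog_rna_related_terms: Iterable[str] = (),
) -> str:
    """Tiered classification of one protein.

    Tier order: ``RNA_binding`` when any molecular-function GO term contains
    the string "RNA binding" (case-insensitive) or the protein carries a
    curated Pfam RNA-binding domain; ``RNA_related`` when a GO term is on the
    curated RNA-related list; ``ortholog_RNA`` when the human ortholog meets
    either criterion; ``unknown`` otherwise.
    """
    go = [t.lower() for t in go_terms]
    if any("rna binding" in t for t in go):
        return "RNA_binding"
    rbd = set(rbd_pfam_domains)
    if rbd and any(d in rbd for d in pfam_domains):
        return "RNA_binding"
    related = {t.lower() for t in rna_related_terms}
    if any(t in related for t in go):
        return "RNA_related"
    ortho_go = [t.lower() for t in ortholog_go_terms]
    ortho_related = {t.lower() for t in ortholog_rna_related_terms}
    if any("rna binding" in t for t in ortho_go) or any(
        t in ortho_related for t in ortho_go
    ):
        return "ortholog_RNA"
    return "unknown"


def classify_rbp_set(
    proteins: Iterable[str],
    go_map: Mapping[str, set[str]],
    rna_related_terms: Iterable[str],
    **kwargs,
) -> pd.DataFrame:
    rna_related = list(rna_related_terms)
    rows = [
        {
            "protein_id": p,
            "tier": classify_rbp(p, go_map.get(p, set()), rna_related, **kwargs),
        }
        for p in proteins
    ]
    return pd.DataFrame(rows)
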