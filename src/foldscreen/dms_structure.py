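"""Structure scoring of RNA regions from three-condition DMS reactivity.

Dimethyl-sulfate (DMS) probing marks unpaired bases with high reactivity.
A structured region concentrates reactivity in a few loop bases, so the Gini
coefficient of its per-base reactivity vector approaches 1, while an
unstructured region has evenly spread signal (Gini near 0). Profiles from
in vivo, in vitro (refolded) and denatured conditions are normalized to the
most reactive base of each region, the denatured signal is subtracted as a
sequence-bias control, and in vivo / in vitro agreement is summarized by a
Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from foldscreen.fold_catalog import RegionClass

BACKGROUND_CATEGORIES = ("intergenic", "5UTR", "3UTR", "CDS")


@dataclass(frozen=True)
class DmsProfile:
    """Per-base reactivities of one region in the three probing conditions."""

    region_id: str
    vivo: np.ndarray
    vitro: np.ndarray
    denatured: np.ndarray

    def __post_init__(self) -> None:
        for name in ("vivo", "vitro", "denatured"):
            vec = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, vec)
            if vec.ndim != 1 or vec.size == 0:
                raise ValueError(f"{self.region_id}: {name} must be a non-empty vector")
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValueError(f"{self.region_id}: {name} must be finite and >= 0")
        if not (len(self.vivo) == len(self.vitro) == len(self.denatured)):
            raise ValueError(f"{self.region_id}: condition vectors differ in length")

    def __len__(self) -> int:
        return len(self.vivo)


@dataclass(frozen=True)
class StructureScore:
    region_id: str
    rho_vivo_vitro: float  # NaN when undefined (constant profile)
    gini_vivo: float
    gini_vitro: float


def normalize_profile(raw: np.ndarray) -> np.ndarray:
    """Scale reactivities proportionally to the most reactive base (max -> 1).

    An all-zero ("unreactive") vector is returned unchanged with a warning.
    """
    vec = np.asarray(raw, dtype=float)
    if vec.size == 0:
        raise ValueError("empty reactivity vector")
    if np.any(vec < 0):
        raise ValueError("reactivities must be non-negative")
    peak = vec.max()
    if peak == 0:
        warnings.warn("unreactive region: all-zero profile left unchanged", stacklevel=2)
        return vec.copy()
    return vec / peak


def subtract_denatured(norm_cond: np.ndarray, norm_denat: np.ndarray) -> np.ndarray:
    """Subtract the denatured (sequence-bias) signal, clipping at zero."""
    a = np.asarray(norm_cond, dtype=float)
    b = np.asarray(norm_denat, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return np.clip(a - b, 0.0, None)


def vivo_vitro_agreement(corr_vivo: np.ndarray, corr_vitro: np.ndarray) -> float:
    """Spearman rank correlation between the corrected condition profiles.

    Returns NaN when either vector is constant (correlation undefined).
    """
    a = np.asarray(corr_vivo, dtype=float)
    b = np.asarray(corr_vitro, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 positions")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector.

    Population definition G = sum_ij |x_i - x_j| / (2 n^2 mean(x)), bounded by
    [0, (n-1)/n]; 0 for a constant vector. NaN when the mean is zero.
    Computed in O(n log n) via the sorted-rank identity.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if np.any(x < 0):
        raise ValueError("values must be non-negative")
    total = x.sum()
    if total == 0:
        return float("nan")
    n = x.size
    xs = np.sort(x)
    # sum_ij |xi - xj| = 2 * sum_i (2i - n + 1) * x_(i), i zero-based ascending
    ranks = 2 * np.arange(n) - n + 1
    return float((ranks * xs).sum() / (n * total))


def score_profile(
    profile: DmsProfile, *, subtract: bool = True
) -> StructureScore:
    """Normalize, optionally denatured-subtract, and score one region.

    Normalization precedes subtraction. ``subtract=False`` scores the raw
    normalized signal instead of the denatured-corrected one.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vivo = normalize_profile(profile.vivo)
        vitro = normalize_profile(profile.vitro)
        denat = normalize_profile(profile.denatured)
    if subtract:
        vivo = subtract_denatured(vivo, denat)
        vitro = subtract_denatured(vitro, denat)
    rho = vivo_vitro_agreement(vivo, vitro) if len(profile) >= 3 else float("nan")
    return StructureScore(
        region_id=profile.region_id,
        rho_vivo_vitro=rho,
        gini_vivo=gini(vivo) if vivo.sum() > 0 else float("nan"),
        gini_vitro=gini(vitro) if vitro.sum() > 0 else float("nan"),
    )


def score_profiles(
    profiles: list[DmsProfile], *, subtract: bool = True
) -> pd.DataFrame:
    rows = [
        {
            "region_id": s.region_id,
            "rho_vivo_vitro": s.rho_vivo_vitro,
            "gini_vivo": s.gini_vivo,
            "gini_vitro": s.gini_vitro,
        }
        for s in (score_profile(p, subtract=subtract) for p in profiles)
    ]
    return pd.DataFrame(rows)


def background_comparison(
    fold_scores: list[StructureScore],
    fold_lengths: list[int],
    region_signal: dict[str, np.ndarray],
    category_intervals: dict[str, list[tuple[str, int, int]]],
    n_random: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare fold Gini coefficients with randomly sampled genomic regions.

    ``region_signal`` maps chromosome -> per-base reactivity track;
    ``category_intervals`` maps each of the four location categories
    (intergenic, 5UTR, 3UTR, CDS) to genomic intervals available for sampling.
    ``n_random`` regions, each of the fold set's mean length, are drawn split
    evenly across categories, and their Gini distribution is compared with the
    fold distribution by a two-sided Mann-Whitney rank-sum test.

    Returns a tidy frame with one row per region (folds and background) with
    columns group, category, gini, plus attrs ``rank_sum_p``.
    """
    if n_random <= 0:
        raise ValueError("n_random must be positive")
    missing = [c for c in BACKGROUND_CATEGORIES if c not in category_intervals]
    if missing:
        raise ValueError(f"missing background categories: {missing}")
    rng = np.random.default_rng(seed)
    fold_ginis = np.array(
        [s.gini_vivo for s in fold_scores if np.isfinite(s.gini_vivo)], dtype=float
    )
    if fold_ginis.size == 0:
        raise ValueError("no finite fold Gini coefficients")
    # length-matched: fixed at the fold set's mean region length
    win = int(round(float(np.mean(fold_lengths))))
    per_cat = n_random // len(BACKGROUND_CATEGORIES)
    remainder = n_random - per_cat * len(BACKGROUND_CATEGORIES)
    rows = [
        {"group": "fold", "category": "fold", "gini": g} for g in fold_ginis
    ]
    for k, cat in enumerate(BACKGROUND_CATEGORIES):
        want = per_cat + (1 if k < remainder else 0)
        ivs = [
            (chrom, s, e)
            for chrom, s, e in category_intervals[cat]
            if e - s >= win
        ]
        if not ivs:
            raise ValueError(f"no interval of length >= {win} in category {cat!r}")
        for _ in range(want):
            chrom, s, e = ivs[rng.integers(len(ivs))]
            start = int(rng.integers(s, e - win + 1))
            window = np.asarray(region_signal[chrom][start : start + win], dtype=float)
            g = gini(window) if window.sum() > 0 else float("nan")
            rows.append({"group": "background", "category": cat, "gini": g})
    out = pd.DataFrame(rows)
    bg = out.loc[out["group"] == "background", "gini"].dropna()
    if len(bg) >= 2 and fold_ginis.size >= 2:
        _, p = stats.mannwhitneyu(fold_ginis, bg, alternative="two-sided")
    else:
        p = float("nan")
    out.attrs["rank_sum_p"] = float(p)
    return out


def read_signal_table(path) -> list[DmsProfile]:
    """Read a headered TSV (region_id, pos, vivo, vitro, denatured)."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for rid, grp in df.groupby("region_id", sort=False):
        grp = grp.sort_values("pos")
        profiles.append(
            DmsProfile(
                region_id=str(rid),
                vivo=grp["vivo"].to_numpy(float),
                vitro=grp["vitro"].to_numpy(float),
                denatured=grp["denatured"].to_numpy(float),
            )
        )
    return profiles
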