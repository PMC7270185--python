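"""SILAC label-swap pull-down screen: parsing, orientation and interactor calling.

Each RNA fold is compared against a generic control bait in two pull-downs
with exchanged isotope labels (forward and reverse experiments). Ratios are
stored *oriented*: positive log2 values always mean enrichment on the fold
bait, so the reverse experiment's raw ratio is negated at parse time. A true
binder is enriched in both orientations; the stringent filter requires a
two-fold enrichment (log2 ratio > 1) in each, and the flexible filter instead
requires the candidate's Euclidean distance to the origin in the
(forward, reverse) plane to exceed that of the Puf3 positive control on the
control bait.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default MaxQuant proteinGroups column map.
DEFAULT_COLUMNS = {
    "id": "Majority protein IDs",
    "ratio": "Ratio H/L normalized",
    "ratio_count": "Ratio H/L count",
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
}

CONTROL_BINDERS = ("Puf3", "Lsg1", "Sui3", "Gcd11")


@dataclass(frozen=True)
class PulldownMeasurement:
    """One protein's oriented log2 SILAC ratio in one orientation."""

    protein_id: str
    fold_id: str
    orientation: str  # "forward" | "reverse"
    log2_ratio: float  # oriented: fold-bait over control-bait
    ratio_count: int
    is_contaminant: bool = False
    is_reverse_hit: bool = False


@dataclass(frozen=True)
class EnrichmentRecord:
    protein_id: str
    fold_id: str
    fwd: float
    rev: float
    enrichment_value: float
    called: bool


@dataclass(frozen=True)
class ScreenDesign:
    n_folds: int
    control_bait: str = "COX17-3UTR"
    orientations: tuple[str, str] = ("forward", "reverse")
    pulldowns_per_orientation: int = 2

    @property
    def total_pulldowns(self) -> int:
        return self.n_folds * len(self.orientations) * self.pulldowns_per_orientation


@dataclass(frozen=True)
class PulsedSilacRecord:
    protein_id: str
    log2_hm: float
    flagged_up: bool


def parse_protein_groups(
    table: pd.DataFrame | str,
    orientation: str,
    fold_id: str = "",
    columns: dict[str, str] | None = None,
    min_ratio_count: int = 2,
) -> list[PulldownMeasurement]:
    """Parse a MaxQuant-style proteinGroups table into oriented measurements.

    Contaminant and reverse-database rows are removed, as are proteins
    quantified with fewer than ``min_ratio_count`` ratio counts. Ratios are
    log2-transformed; for the reverse orientation the label swap means the
    raw ratio points the other way, so it is negated to keep "positive =
    fold-bait enriched". Unparseable ratios drop the row (counted in a
    warning).
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward/reverse, got {orientation!r}")
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t")
    missing = [c for c in (cols["id"], cols["ratio"], cols["ratio_count"]) if c not in df.columns]
    if missing:
        raise KeyError(f"missing mandatory columns: {missing}")

    out: list[PulldownMeasurement] = []
    n_dropped = 0
    for _, row in df.iterrows():
        if _flag(row.get(cols["contaminant"])) or _flag(row.get(cols["reverse"])):
            continue
        try:
            count = int(row[cols["ratio_count"]])
        except (TypeError, ValueError):
            count = 0
        if count < min_ratio_count:
            continue
        try:
            ratio = float(row[cols["ratio"]])
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if not math.isfinite(ratio) or ratio <= 0:
            n_dropped += 1
            continue
        log2r = math.log2(ratio)
        if orientation == "reverse":
            log2r = -log2r
        out.append(
            PulldownMeasurement(
                protein_id=str(row[cols["id"]]),
                fold_id=fold_id,
                orientation=orientation,
                log2_ratio=log2r,
                ratio_count=count,
            )
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} rows with unparseable ratios", stacklevel=2)
    return out


def _flag(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return str(value).strip() in ("+", "1", "True", "true", "yes")


def enrichment_value(fwd: float, rev: float) -> float:
    """log2 of the Euclidean distance from (fwd, rev) to the origin.

    Undefined (NaN) at the origin itself.
    """
    if fwd == 0 and rev == 0:
        return float("nan")
    return math.log2(math.hypot(fwd, rev))


def pair_orientations(
    forward: list[PulldownMeasurement], reverse: list[PulldownMeasurement]
) -> pd.DataFrame:
    """Join the two orientations per protein; keeps only both-quantified rows.

    Returns columns protein_id, fwd, rev. Proteins present in a single
    orientation are listed in ``frame.attrs["single_orientation"]``.
    """
    f = {m.protein_id: m.log2_ratio for m in forward}
    r = {m.protein_id: m.log2_ratio for m in reverse}
    both = sorted(f.keys() & r.keys())
    df = pd.DataFrame(
        {"protein_id": both, "fwd": [f[p] for p in both], "rev": [r[p] for p in both]}
    )
    df.attrs["single_orientation"] = sorted(f.keys() ^ r.keys())
    return df


def call_interactors_stringent(
    pairs: pd.DataFrame, fold_id: str = "", cutoff: float = 1.0
) -> list[EnrichmentRecord]:
    """Stringent filter: oriented log2 ratio strictly above ``cutoff`` in BOTH
    the forward and the reverse experiment (cutoff 1 = two-fold enrichment)."""
    records = []
    for row in pairs.itertuples(index=False):
        called = (row.fwd > cutoff) and (row.rev > cutoff)
        records.append(
            EnrichmentRecord(
                protein_id=row.protein_id,
                fold_id=fold_id,
                fwd=float(row.fwd),
                rev=float(row.rev),
                enrichment_value=enrichment_value(row.fwd, row.rev),
                called=called,
            )
        )
    return records


def call_interactors_flexible(
    pairs: pd.DataFrame,
    puf3_point: tuple[float, float],
    fold_id: str = "",
) -> list[EnrichmentRecord]:
    """Flexible filter anchored on the Puf3 positive control.

    A candidate is called when it lies in the fold-enriched quadrant
    (fwd > 0 and rev > 0) and its distance to the origin exceeds Puf3's
    distance in the same experiment pair. The quadrant requirement prevents
    control-side (doubly negative) points from passing on distance alone.
    """
    if puf3_point is None:
        raise ValueError(
            "Puf3 control not quantified in both orientations; "
            "fall back to the stringent filter"
        )
    puf3_dist = math.hypot(*puf3_point)
    records = []
    for row in pairs.itertuples(index=False):
        dist = math.hypot(row.fwd, row.rev)
        called = row.fwd > 0 and row.rev > 0 and dist > puf3_dist
        records.append(
            EnrichmentRecord(
                protein_id=row.protein_id,
                fold_id=fold_id,
                fwd=float(row.fwd),
                rev=float(row.rev),
                enrichment_value=enrichment_value(row.fwd, row.rev),
                called=called,
            )
        )
    return records


def qc_control_binders(
    experiments: dict[str, pd.DataFrame],
    controls: tuple[str, ...] = CONTROL_BINDERS,
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Monitor repeat binders of the control bait across all experiments.

    A control protein passes an experiment when both of its oriented ratios
    are below ``-cutoff`` (i.e. enriched on the control side, where the Puf3
    control binds its sites on the control bait). Returns one row per control
    with its pass fraction, plus per-experiment Puf3 failures in
    ``frame.attrs["flagged_experiments"]``.
    """
    rows = []
    flagged: list[str] = []
    for ctrl in controls:
        n_seen = n_pass = 0
        for exp_id, pairs in experiments.items():
            hit = pairs.loc[pairs["protein_id"] == ctrl]
            if hit.empty:
                continue
            n_seen += 1
            ok = bool((hit["fwd"].iloc[0] < -cutoff) and (hit["rev"].iloc[0] < -cutoff))
            n_pass += ok
            if ctrl == "Puf3" and not ok:
                flagged.append(exp_id)
        rows.append(
            {
                "control": ctrl,
                "n_experiments": n_seen,
                "n_pass": n_pass,
                "pass_fraction": (n_pass / n_seen) if n_seen else float("nan"),
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["flagged_experiments"] = flagged
    return report


def plan_screen(n_folds: int, control_bait: str = "COX17-3UTR") -> ScreenDesign:
    """Label-switch screen design: each fold needs forward + reverse pull-downs
    of both the fold bait and the control bait (4 pull-downs per fold)."""
    if n_folds < 1:
        raise ValueError("need at least one fold")
    return ScreenDesign(n_folds=n_folds, control_bait=control_bait)


def pulsed_silac_compare(
    log2_hm: dict[str, float] | pd.Series,
) -> list[PulsedSilacRecord]:
    """Flag proteins synthesized faster in the knock-out (H) than wild-type (M).

    Uses the Tukey boxplot convention: the upper whisker is the largest
    observation at most Q3 + 1.5 x IQR above; values strictly beyond that
    fence are flagged as upregulated. A constant distribution yields no flags.
    """
    series = pd.Series(log2_hm, dtype=float)
    if len(series) < 5:
        raise ValueError("need at least 5 quantified proteins")
    q1, q3 = series.quantile([0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("degenerate (constant) ratio distribution", stacklevel=2)
    upper_fence = q3 + 1.5 * iqr
    return [
        PulsedSilacRecord(protein_id=str(p), log2_hm=float(v), flagged_up=bool(v > upper_fence))
        for p, v in series.items()
    ]


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "fold_id": r.fold_id,
                "fwd": r.fwd,
                "rev": r.rev,
                "enrichment_value": r.enrichment_value,
                "called": r.called,
            }
            for r in records
        ]
    )
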