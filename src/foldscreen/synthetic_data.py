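"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration and seed and returns
both the data (in the same shape the analysis modules read) and the planted
ground truth, so the whole pipeline can be exercised and scored end-to-end
without external downloads.

The screen generator emulates the label-swap pull-down design: a planted
binder is enriched on the fold bait in both orientations (oriented log2 ratio
centered on the effect size), background proteins scatter around zero, and a
Puf3-like positive control binds the control bait (negative oriented ratio)
in every experiment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from foldscreen.dms_structure import DmsProfile
from foldscreen.genetic_network import GiMatrix
from foldscreen.silac_screen import DEFAULT_COLUMNS

CONTROL_PROTEIN = "Puf3"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic label-swap screen."""

    n_proteins: int = 200
    n_folds: int = 20
    n_planted_per_fold: int = 5
    effect_size: float = 2.0  # oriented log2 enrichment of planted binders
    background_sd: float = 0.3  # log2 scatter of non-binders
    missing_rate: float = 0.1  # per-entry, per-orientation dropout
    control_binder_effect: float = 2.0  # Puf3-like control, control side
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_folds, self.n_planted_per_fold) < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


@dataclass
class ScreenTruth:
    planted_binders: dict[str, set[str]]  # fold_id -> protein ids
    effect_size: float
    background_sd: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_binders": {k: sorted(v) for k, v in self.planted_binders.items()},
            "effect_size": self.effect_size,
            "background_sd": self.background_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreenTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_binders={k: set(v) for k, v in payload["planted_binders"].items()},
            effect_size=payload["effect_size"],
            background_sd=payload["background_sd"],
            seed=payload["seed"],
        )


def simulate_screen(
    cfg: SimConfig,
) -> tuple[dict[str, dict[str, pd.DataFrame]], ScreenTruth]:
    """Generate forward/reverse MaxQuant-style ratio tables per fold.

    Returns ``tables[fold_id]["forward"|"reverse"]`` DataFrames with the
    default proteinGroups columns (linear H/L ratios; the reverse table's
    ratio is inverted so that parsing re-orients it), plus the truth object.
    A handful of decoy rows (contaminant flag, reverse-database flag, single
    ratio count) are included to exercise the upstream filters.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    folds = [f"fold{j:03d}" for j in range(cfg.n_folds)]
    truth: dict[str, set[str]] = {}
    tables: dict[str, dict[str, pd.DataFrame]] = {}
    for fold in folds:
        planted = set(
            rng.choice(proteins, size=cfg.n_planted_per_fold, replace=False)
        ) if cfg.n_planted_per_fold else set()
        truth[fold] = planted
        oriented = {
            "forward": _oriented_ratios(rng, proteins, planted, cfg),
            "reverse": _oriented_ratios(rng, proteins, planted, cfg),
        }
        tables[fold] = {}
        for orient in ("forward", "reverse"):
            rows = []
            for protein in proteins + [CONTROL_PROTEIN]:
                if protein == CONTROL_PROTEIN:
                    x = rng.normal(-cfg.control_binder_effect, cfg.background_sd)
                else:
                    x = oriented[orient][protein]
                if rng.random() < cfg.missing_rate:
                    continue
                raw = 2.0 ** (x if orient == "forward" else -x)
                rows.append(
                    {
                        DEFAULT_COLUMNS["id"]: protein,
                        DEFAULT_COLUMNS["ratio"]: raw,
                        DEFAULT_COLUMNS["ratio_count"]: int(rng.integers(2, 20)),
                        DEFAULT_COLUMNS["contaminant"]: "",
                        DEFAULT_COLUMNS["reverse"]: "",
                    }
                )
            # decoys the parser must drop
            rows.append(
                {
                    DEFAULT_COLUMNS["id"]: "KERATIN_CONT",
                    DEFAULT_COLUMNS["ratio"]: 8.0,
                    DEFAULT_COLUMNS["ratio_count"]: 10,
                    DEFAULT_COLUMNS["contaminant"]: "+",
                    DEFAULT_COLUMNS["reverse"]: "",
                }
            )
            rows.append(
                {
                    DEFAULT_COLUMNS["id"]: "REV__DECOY",
                    DEFAULT_COLUMNS["ratio"]: 8.0,
                    DEFAULT_COLUMNS["ratio_count"]: 10,
                    DEFAULT_COLUMNS["contaminant"]: "",
                    DEFAULT_COLUMNS["reverse"]: "+",
                }
            )
            rows.append(
                {
                    DEFAULT_COLUMNS["id"]: "ONECOUNT",
                    DEFAULT_COLUMNS["ratio"]: 8.0,
                    DEFAULT_COLUMNS["ratio_count"]: 1,
                    DEFAULT_COLUMNS["contaminant"]: "",
                    DEFAULT_COLUMNS["reverse"]: "",
                }
            )
            tables[fold][orient] = pd.DataFrame(rows)
    return tables, ScreenTruth(
        planted_binders=truth,
        effect_size=cfg.effect_size,
        background_sd=cfg.background_sd,
        seed=cfg.seed,
    )


def _oriented_ratios(rng, proteins, planted, cfg) -> dict[str, float]:
    out = {}
    for protein in proteins:
        mu = cfg.effect_size if protein in planted else 0.0
        out[protein] = rng.normal(mu, cfg.background_sd)
    return out


def evaluate_calls(
    truth: ScreenTruth,
    called: dict[str, set[str]],
    evaluable: dict[str, set[str]] | None = None,
) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of a call set vs truth.

    Sensitivity is computed over planted (protein, fold) pairs that were
    *evaluable* — quantified in both orientations — since the caller by
    contract never calls single-orientation proteins; missingness is an
    ascertainment limit, not a caller error. ``evaluable`` maps fold_id to
    the both-orientation protein set (None = all planted pairs evaluable).
    The control protein never counts as a false positive candidate.
    """
    tp = fp = fn = 0
    for fold, planted in truth.planted_binders.items():
        calls = called.get(fold, set())
        pool = evaluable.get(fold) if evaluable is not None else None
        planted_eval = planted if pool is None else planted & pool
        tp += len(calls & planted_eval)
        fp += len(calls - planted - {CONTROL_PROTEIN})
        fn += len(planted_eval - calls)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    fdp = fp / (tp + fp) if (tp + fp) else 0.0
    return {"sensitivity": sens, "fdp": fdp, "tp": tp, "fp": fp, "fn": fn}


def simulate_dms(
    region_len: int, structured: bool, seed: int, loop_fraction: float = 0.2
) -> DmsProfile:
    """Per-base three-condition DMS reactivities for one region.

    Structured regions concentrate reactivity on a minority of loop bases
    (stems near zero); unstructured regions have moderate, evenly spread
    reactivity. The in vivo and in vitro profiles share the same underlying
    structure with independent multiplicative noise; the denatured profile is
    uniformly highly reactive.
    """
    if region_len < 10:
        raise ValueError("region_len must be >= 10")
    rng = np.random.default_rng(seed)
    if structured:
        n_loop = max(1, int(round(loop_fraction * region_len)))
        loop = np.zeros(region_len, dtype=bool)
        loop[rng.choice(region_len, size=n_loop, replace=False)] = True
        latent = np.where(loop, rng.uniform(0.5, 1.0, region_len), rng.uniform(0.0, 0.03, region_len))
    else:
        latent = rng.uniform(0.3, 0.7, region_len)
    vivo = latent * rng.uniform(0.9, 1.1, region_len)
    vitro = latent * rng.uniform(0.9, 1.1, region_len)
    denatured = rng.uniform(0.8, 1.2, region_len)
    return DmsProfile(
        region_id=f"{'structured' if structured else 'unstructured'}_{seed}",
        vivo=vivo,
        vitro=vitro,
        denatured=denatured,
    )


def simulate_gi(
    genes: list[str],
    planted_blocks: list[list[str]],
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[GiMatrix, dict[str, int]]:
    """Gene x gene epsilon matrix with planted community blocks.

    Genes in a block share a latent interaction profile over all array genes
    plus independent Gaussian noise, so within-block profile correlations are
    high and between-block correlations are near zero. Returns the matrix and
    the true block label of each gene.
    """
    members = {g for block in planted_blocks for g in block}
    if members != set(genes):
        raise ValueError("planted blocks must partition the gene list")
    rng = np.random.default_rng(seed)
    n = len(genes)
    eps = np.empty((n, n))
    index = {g: i for i, g in enumerate(genes)}
    truth: dict[str, int] = {}
    for b, block in enumerate(planted_blocks):
        latent = rng.normal(0.0, 1.0, n)
        for g in block:
            truth[g] = b
            eps[index[g]] = latent + rng.normal(0.0, noise_sd, n)
    return GiMatrix(genes=list(genes), epsilon=eps), truth


def simulate_planted_partition_graph(
    block_sizes: list[int], p_in: float, p_out: float, seed: int
) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition random graph with named vertices and true labels."""
    rng = np.random.default_rng(seed)
    names: list[str] = []
    truth: dict[str, int] = {}
    for b, size in enumerate(block_sizes):
        for k in range(size):
            name = f"g{b}_{k:02d}"
            names.append(name)
            truth[name] = b
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = p_in if truth[names[i]] == truth[names[j]] else p_out
            if rng.random() < p:
                graph.add_edge(names[i], names[j])
    return graph, truth


RNA_BASES = np.array(list("ACGU"))


def simulate_transcripts(
    n_genes: int, motif_rate: float, seed: int, motif: str = "UGUAAAUA"
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, int]]]:
    """Transcripts with 5'UTR/CDS/3'UTR structure and planted motifs.

    Each region independently receives one planted canonical motif with
    probability ``motif_rate`` at a uniformly random offset. Returns the
    (gene, region, sequence) triples the motif scanner reads and the truth
    list of (gene, region, offset) plants.
    """
    if not 0 <= motif_rate <= 1:
        raise ValueError("motif_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    regions: list[tuple[str, str, str]] = []
    truth: list[tuple[str, str, int]] = []
    lengths = {"5UTR": (50, 150), "CDS": (300, 900), "3UTR": (100, 250)}
    for g in range(n_genes):
        gene = f"GENE{g:04d}"
        for region, (lo, hi) in lengths.items():
            length = int(rng.integers(lo, hi + 1))
            seq = list(rng.choice(RNA_BASES, size=length))
            if rng.random() < motif_rate:
                off = int(rng.integers(0, length - len(motif) + 1))
                seq[off : off + len(motif)] = list(motif)
                truth.append((gene, region, off))
            regions.append((gene, region, "".join(seq)))
    return regions, truth


def write_screen_tables(
    tables: dict[str, dict[str, pd.DataFrame]], outdir: str | Path
) -> None:
    """Export the per-fold forward/reverse tables as proteinGroups-style TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for fold, pair in tables.items():
        for orient, df in pair.items():
            df.to_csv(outdir / f"{fold}_{orient}.tsv", sep="\t", index=False)
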