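"""Fold catalog: coordinates, sequences, region classes and cloning primers.

A *fold* is a short mRNA region with evolutionarily conserved secondary
structure, used downstream as an affinity bait. This module resolves fold
coordinates against a genome, classifies each fold by transcript region
(5'UTR / CDS / 3'UTR), and designs the PCR amplification primers and the
T7/S1-aptamer-tagged bait template used to produce the RNA baits.

Coordinates are 0-based half-open throughout (BED convention); 1-based
inclusive tables can be converted on read with ``one_based=True``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

# Generic amplification primers used for bait production. The forward primer
# carries the T7 promoter at the 5' end; the reverse primer appends the S1
# minimal streptavidin aptamer at the 3' end of the amplicon.
T7_FORWARD_PRIMER = "CGTTAATACGACTCACTATAGGGATCGAACCCTT"
S1_REVERSE_PRIMER = (
    "CATGGCCCGGCCCGCGACTATCTTACGCACTTGCATGATTCTGGTCGGTCCCATGGATCCAAAAAAAGATCGAACCCTT"
)

_DNA_BASES = frozenset("ACGT")


class RegionClass(str, enum.Enum):
    """Transcript region a fold falls into."""

    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"
    MIXED = "MIXED"


#: Tie-break precedence when a fold overlaps two regions equally.
TIE_ORDER: tuple[RegionClass, ...] = (
    RegionClass.CDS,
    RegionClass.FIVE_UTR,
    RegionClass.THREE_UTR,
)


@dataclass(frozen=True)
class FoldRegion:
    """A conserved RNA fold with genomic coordinates and resolved sequence."""

    fold_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    gene: str
    sequence: str  # RNA alphabet, 5'->3' on the transcript strand
    region_class: RegionClass | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fold {self.fold_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"fold {self.fold_id}: strand must be '+' or '-'")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"fold {self.fold_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Per-gene genomic intervals of the three transcript regions.

    Interval lists are (start, end) 0-based half-open on the genome; they must
    not overlap each other within a gene.
    """

    gene: str
    strand: str
    five_utr: tuple[tuple[int, int], ...] = ()
    cds: tuple[tuple[int, int], ...] = ()
    three_utr: tuple[tuple[int, int], ...] = ()

    def intervals(self) -> Mapping[RegionClass, tuple[tuple[int, int], ...]]:
        return {
            RegionClass.FIVE_UTR: self.five_utr,
            RegionClass.CDS: self.cds,
            RegionClass.THREE_UTR: self.three_utr,
        }


@dataclass(frozen=True)
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    forward_tm: int
    reverse_tm: int


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def transcribe(dna: str) -> str:
    return dna.upper().replace("T", "U")


def load_fold_regions(
    coord_table: str | Path | pd.DataFrame,
    genome: str | Path | Fasta,
    *,
    one_based: bool = False,
) -> list[FoldRegion]:
    """Resolve fold coordinates to strand-aware RNA sequences.

    Parameters
    ----------
    coord_table
        BED6-like or headered TSV with columns fold_id, chrom, start, end,
        strand, gene (column order used for headerless BED: chrom, start, end,
        fold_id, score, strand). May also be a pre-parsed DataFrame.
    genome
        FASTA path or an open :class:`pyfaidx.Fasta`.
    one_based
        If True, input starts are 1-based inclusive and converted on read.

    Minus-strand folds are reverse-complemented so sequences always read
    5'->3' on the transcript; output is in the RNA alphabet.
    """
    df = _read_coord_table(coord_table)
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    folds: list[FoldRegion] = []
    for rec in df.itertuples(index=False):
        start = int(rec.start) - (1 if one_based else 0)
        end = int(rec.end)
        if rec.chrom not in fa:
            raise KeyError(f"fold {rec.fold_id}: chromosome {rec.chrom!r} not in genome")
        contig_len = len(fa[rec.chrom])
        if start < 0 or end > contig_len:
            raise ValueError(
                f"fold {rec.fold_id}: interval [{start},{end}) outside contig "
                f"{rec.chrom} of length {contig_len}"
            )
        dna = str(fa[rec.chrom][start:end]).upper()
        if rec.strand == "-":
            dna = reverse_complement(dna)
        region_class = None
        if "region_class" in df.columns and pd.notna(getattr(rec, "region_class", None)):
            region_class = RegionClass(str(rec.region_class))
        folds.append(
            FoldRegion(
                fold_id=str(rec.fold_id),
                chrom=str(rec.chrom),
                start=start,
                end=end,
                strand=str(rec.strand),
                gene=str(getattr(rec, "gene", "")),
                sequence=transcribe(dna),
                region_class=region_class,
            )
        )
    return folds


def _read_coord_table(coord_table: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(coord_table, pd.DataFrame):
        return coord_table
    path = Path(coord_table)
    with open(path) as fh:
        first = fh.readline()
    if first.lower().startswith(("fold_id", "#fold_id")):
        return pd.read_csv(path, sep="\t")
    # headerless BED6: chrom start end name score strand
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "fold_id", "score", "strand"],
    )
    bed["gene"] = bed["fold_id"].astype(str).str.split("|").str[0]
    return bed


def overlap_fractions(
    fold: FoldRegion, annotation: TranscriptAnnotation
) -> dict[RegionClass, float]:
    """Fraction of fold bases overlapping each transcript region.

    Fractions are relative to the fold length; they sum to 1 for a fold fully
    contained in the annotated transcript.
    """
    fracs: dict[RegionClass, float] = {}
    for cls, ivs in annotation.intervals().items():
        bases = sum(
            max(0, min(fold.end, e) - max(fold.start, s)) for s, e in ivs
        )
        fracs[cls] = bases / fold.length
    return fracs


def classify_region(
    fold: FoldRegion,
    annotation: TranscriptAnnotation,
    *,
    allow_mixed: bool = False,
) -> RegionClass:
    """Assign a fold the transcript region with maximal base overlap.

    Ties are broken by the fixed precedence CDS > 5'UTR > 3'UTR unless
    ``allow_mixed`` is set, in which case tied folds are labelled MIXED.
    Raises ``ValueError`` when the fold does not overlap the transcript.
    """
    fracs = overlap_fractions(fold, annotation)
    best = max(fracs.values())
    if best == 0:
        raise ValueError(
            f"fold {fold.fold_id} has zero overlap with transcript of {annotation.gene}"
        )
    winners = [cls for cls in TIE_ORDER if fracs[cls] == best]
    if len(winners) > 1 and allow_mixed:
        return RegionClass.MIXED
    return winners[0]


def wallace_tm(seq: str) -> int:
    """Wallace-rule melting temperature: 4·(#G + #C) + 2·(#A + #T), in °C."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = set(s) - _DNA_BASES
    if bad:
        raise ValueError(f"ambiguous bases in primer sequence: {sorted(bad)}")
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    return 4 * gc + 2 * at


def _shortest_prefix_above(template: str, tm_threshold: int) -> str:
    tm = 0
    for i, base in enumerate(template.upper()):
        if base not in _DNA_BASES:
            raise ValueError(f"ambiguous base {base!r} at position {i}")
        tm += 4 if base in "GC" else 2
        if tm > tm_threshold:
            return template[: i + 1]
    raise ValueError(
        f"melting temperature threshold {tm_threshold} °C unreachable; "
        f"maximal attainable Tm is {tm} °C"
    )


def design_amplification_primers(template: str, tm_threshold: int = 58) -> PrimerPair:
    """Design amplification primers by prefix extension until Tm exceeds threshold.

    The forward primer is the shortest prefix of the template whose Wallace Tm
    strictly exceeds ``tm_threshold``; the reverse primer is the analogous
    prefix of the reverse-complement strand.
    """
    fwd = _shortest_prefix_above(template, tm_threshold)
    rev = _shortest_prefix_above(reverse_complement(template), tm_threshold)
    return PrimerPair(
        forward_seq=fwd,
        reverse_seq=rev,
        forward_tm=wallace_tm(fwd),
        reverse_tm=wallace_tm(rev),
    )


def build_bait_template(fold_seq: str) -> str:
    """Assemble the DNA template for bait transcription.

    The template concatenates the generic T7-promoter forward tag, the fold
    insert, and the S1-aptamer tag (reverse complement of the generic reverse
    primer), mirroring the PCR product transcribed in vitro.
    """
    if not fold_seq:
        raise ValueError("empty insert")
    s = fold_seq.upper()
    bad = set(s) - _DNA_BASES
    if bad:
        raise ValueError(f"insert contains non-DNA characters: {sorted(bad)}")
    return T7_FORWARD_PRIMER + s + reverse_complement(S1_REVERSE_PRIMER)


def catalog_to_frame(folds: Iterable[FoldRegion]) -> pd.DataFrame:
    """Flatten a fold catalog to a tidy table (one row per fold)."""
    rows = [
        {
            "fold_id": f.fold_id,
            "chrom": f.chrom,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "gene": f.gene,
            "region_class": f.region_class.value if f.region_class else "",
            "length": f.length,
            "sequence": f.sequence,
        }
        for f in folds
    ]
    return pd.DataFrame(rows)
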