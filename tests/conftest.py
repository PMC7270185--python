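import numpy as np
import pytest

from foldscreen import silac_screen, synthetic_data


@pytest.fixture
def tiny_genome(tmp_path):
    """Two-contig FASTA with known sequence for coordinate extraction tests."""
    chr1 = "ACGTAAGGCCTTACGATCGATCGGATCCAAGGTTCCAACGTACGTAACC"
    chr2 = "TTTTGGGGCCCCAAAATATATATGCGCGCGCATTTAATTTAAGGGCCCA"
    path = tmp_path / "genome.fa"
    path.write_text(f">chrI\n{chr1}\n>chrII\n{chr2}\n")
    return path, {"chrI": chr1, "chrII": chr2}


def run_stringent_screen(tables, cutoff=1.0):
    """Parse, orient, pair and call every fold of a simulated screen.

    Returns (called sets, evaluable both-orientation sets) per fold.
    """
    called: dict[str, set[str]] = {}
    evaluable: dict[str, set[str]] = {}
    for fold, pair in tables.items():
        fwd = silac_screen.parse_protein_groups(pair["forward"], "forward", fold)
        rev = silac_screen.parse_protein_groups(pair["reverse"], "reverse", fold)
        pairs = silac_screen.pair_orientations(fwd, rev)
        evaluable[fold] = set(pairs["protein_id"])
        records = silac_screen.call_interactors_stringent(pairs, fold, cutoff)
        called[fold] = {r.protein_id for r in records if r.called}
    return called, evaluable


@pytest.fixture
def default_screen():
    cfg = synthetic_data.SimConfig(seed=42)
    tables, truth = synthetic_data.simulate_screen(cfg)
    return cfg, tables, truth
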