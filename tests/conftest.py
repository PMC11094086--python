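import numpy as np
import pandas as pd
import pytest

from splicetope import splice_events as se
from splicetope import synthetic_data as syn

# Independent codon-table oracle (standard genetic code), used to verify
# every translation the package performs. Kept separate from the package's
# Biopython-backed translation on purpose.
CODON_ORACLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(seq: str) -> str:
    """Translate to the first stop using the frozen codon dictionary."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_ORACLE[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


@pytest.fixture(scope="session")
def study():
    """Synthetic study: 5 genes, 3 planted RI + 2 planted SE neoepitopes."""
    return syn.make_synthetic_study(
        n_genes=5, n_ri_neoepitopes=3, n_se_neoepitopes=2,
        n_filler_events=20, seed=11,
    )


@pytest.fixture(scope="session")
def study_events(study):
    frames = [se.add_psi_columns(t) for t in study.tables.values()]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
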