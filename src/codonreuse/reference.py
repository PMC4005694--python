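"""Loader for the shipped reference codon-pair table.

The published Ser/Arg co-occurrence and expected counts for the
M. thermautotrophicus deltaH genome (NC_000916.1) ship with the package so
the deviation statistics can be exercised without downloading the genome.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_reference_pair_table() -> pd.DataFrame:
    """Ser4/Ser2/Arg4/Arg2 counts and expected counts as a long DataFrame.

    Columns: family, codon_i, codon_j, count, expected.
    """
    ref = resources.files("codonreuse").joinpath("data/mthermautotrophicus_ser_arg_pairs.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
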