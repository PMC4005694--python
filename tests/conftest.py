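"""Shared fixtures: genetic code, family partition, GenBank fixture builder."""

from __future__ import annotations

from pathlib import Path

import pytest

from codonreuse.codon_model import (
    default_isoacceptor_map,
    partition_families,
    standard_code,
)


@pytest.fixture(scope="session")
def code():
    return standard_code(11)


@pytest.fixture(scope="session")
def families(code):
    return {f.name: f for f in partition_families(code)}


@pytest.fixture(scope="session")
def iso_map():
    return default_isoacceptor_map()


def _genbank_text(seq: str, features: str, name: str = "TESTGENOME") -> str:
    """Minimal GenBank flat file around a raw sequence and feature lines."""
    origin_lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        origin_lines.append(f"{i + 1:>9} {blocks}")
    return (
        f"LOCUS       {name}          {len(seq)} bp    DNA     linear   BCT 01-JAN-2000\n"
        f"DEFINITION  synthetic test fixture.\n"
        f"ACCESSION   {name}\n"
        f"FEATURES             Location/Qualifiers\n"
        f"{features}"
        f"ORIGIN\n" + "\n".join(origin_lines) + "\n//\n"
    )


@pytest.fixture
def make_genbank(tmp_path: Path):
    """Write a handcrafted GenBank file; returns its path."""

    def _make(seq: str, features: str, fname: str = "fixture.gb") -> Path:
        path = tmp_path / fname
        path.write_text(_genbank_text(seq, features))
        return path

    return _make


@pytest.fixture
def two_gene_genbank(make_genbank) -> Path:
    # gene A plus-strand ATG TCA TAA; gene B genomic text TTATGACAT,
    # annotated complement -> mRNA-sense ATG TCA TAA after reverse-complement
    seq = "ATGTCATAA" + "TTATGACAT"
    features = """\
     CDS             1..9
                     /locus_tag="geneA"
     CDS             complement(10..18)
                     /locus_tag="geneB"
"""
    return make_genbank(seq, features)
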