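"""Genetic code, synonymous-family partition, and tRNA isoacceptor grouping.

A *synonymous family* is a block of codons for one amino acid.  Six-fold
degenerate amino acids (Leu, Ser, Arg) are split by degeneracy rules into a
four-codon quartet sharing the first two bases (e.g. Ser4 = UCN) and a
two-codon doublet (Ser2 = AGY); all other amino acids with degeneracy >= 2
form a single block (Ile3, Val4, ...).  Met, Trp and stops have no family.

*Co-tRNA groups* partition a family by decoding isoacceptor: codons read by
the same anticodon under wobble rules fall in one group.  Because decoding
depends on base modifications that cannot be inferred from sequence, the
isoacceptor inventory is configuration — a plain-text table shipped with a
default for Methanothermobacter thermautotrophicus and editable by the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from Bio.Data import CodonTable

STOP = "*"

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: amino-acid one-letter -> three-letter, used for family names (Ser4, Val4, ...)
AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}

_SUPPORTED_TABLES = {1, 11}


@dataclass(frozen=True)
class GeneticCode:
    table_id: int
    codon_to_aa: Dict[str, str]  # 64 codons -> amino-acid letter or STOP

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.codon_to_aa)}")

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == STOP


def standard_code(table_id: int = 11) -> GeneticCode:
    """NCBI translation table as a total 64-codon map (stops -> ``*``).

    Tables 1 (standard) and 11 (bacterial/archaeal/plastid) are supported;
    their codon-to-amino-acid maps are identical, so the family partition is
    the same either way.
    """
    if table_id not in _SUPPORTED_TABLES:
        raise ValueError(f"unsupported translation table {table_id}; supported: {sorted(_SUPPORTED_TABLES)}")
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(table_id=table_id, codon_to_aa=mapping)


@dataclass(frozen=True)
class SynonymousFamily:
    """A degeneracy block: name (e.g. Ser4), amino acid, ordered codons."""

    name: str
    amino_acid: str
    codons: Tuple[str, ...]
    degeneracy: int

    def __post_init__(self) -> None:
        if self.degeneracy != len(self.codons):
            raise ValueError(f"{self.name}: degeneracy {self.degeneracy} != {len(self.codons)} codons")

    def index(self, codon: str) -> int:
        return self.codons.index(codon)

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons


def partition_families(code: GeneticCode, split_sixfold: bool = True) -> List[SynonymousFamily]:
    """Partition the coding codons into synonymous families.

    With ``split_sixfold`` (default), each six-fold amino acid yields a
    quartet block (the four codons sharing a first-two-base prefix) and a
    doublet block, named ``<Aa>4`` / ``<Aa>2``.  Codons within a family are
    ordered alphabetically.
    """
    by_aa: Dict[str, List[str]] = {}
    for codon, aa in code.codon_to_aa.items():
        if aa == STOP:
            continue
        by_aa.setdefault(aa, []).append(codon)

    families: List[SynonymousFamily] = []
    for aa in sorted(by_aa):
        codons = sorted(by_aa[aa])
        if len(codons) < 2:
            continue  # Met, Trp
        if len(codons) == 6 and split_sixfold:
            prefixes: Dict[str, List[str]] = {}
            for c in codons:
                prefixes.setdefault(c[:2], []).append(c)
            quartet = next(v for v in prefixes.values() if len(v) == 4)
            doublet = sorted(c for c in codons if c not in quartet)
            families.append(SynonymousFamily(f"{AA3[aa]}4", aa, tuple(sorted(quartet)), 4))
            families.append(SynonymousFamily(f"{AA3[aa]}2", aa, tuple(doublet), 2))
        else:
            families.append(
                SynonymousFamily(f"{AA3[aa]}{len(codons)}", aa, tuple(codons), len(codons))
            )
    families.sort(key=lambda f: f.name)
    return families


@dataclass(frozen=True)
class Isoacceptor:
    anticodon: str  # 5'->3' DNA
    copy_number: int
    codons: Tuple[str, ...]  # codons this isoacceptor decodes


class IsoacceptorMap:
    """anticodon -> decoded codon set, with gene copy numbers."""

    def __init__(self, isoacceptors: Sequence[Isoacceptor]):
        self.by_anticodon: Dict[str, Isoacceptor] = {}
        for iso in isoacceptors:
            if iso.anticodon in self.by_anticodon:
                raise ValueError(f"duplicate anticodon {iso.anticodon}")
            self.by_anticodon[iso.anticodon] = iso

    def decoders_of(self, codon: str) -> List[Isoacceptor]:
        return [iso for iso in self.by_anticodon.values() if codon in iso.codons]

    def __len__(self) -> int:
        return len(self.by_anticodon)


def wobble_decodes(anticodon: str) -> Tuple[str, ...]:
    """Codons read by an anticodon under the default wobble rules.

    Positions 1-2 of the codon pair Watson-Crick with anticodon positions
    3-2 (antiparallel).  At the wobble position (anticodon base 1 vs codon
    base 3): G reads C/T, T reads A/G, C reads G, unmodified A reads T.
    Real decoding depends on base modifications, so this is a helper for
    building candidate configs, not ground truth.
    """
    anticodon = anticodon.upper()
    if len(anticodon) != 3 or set(anticodon) - set(_BASES):
        raise ValueError(f"bad anticodon {anticodon!r}")
    stem = _COMP[anticodon[2]] + _COMP[anticodon[1]]
    wobble = {"G": "CT", "T": "AG", "C": "G", "A": "T"}[anticodon[0]]
    return tuple(stem + b for b in wobble)


def cotrna_groups(family: SynonymousFamily, iso: IsoacceptorMap) -> List[Tuple[str, ...]]:
    """Partition a family's codons into groups decoded by the same tRNA.

    Each codon is assigned to a primary anticodon — the decoder whose wobble
    base is the exact Watson-Crick complement of the codon's third base when
    one exists, otherwise the alphabetically first decoder — and codons
    sharing a primary anticodon form one group.  With e.g. Arg2 read by both
    CCT and TCT this yields the singleton groups {AGG}, {AGA}; with a single
    G34 reader (Ser2, GCT) it yields one group {AGC, AGT}.
    """
    primary: Dict[str, str] = {}
    for codon in family.codons:
        decoders = sorted(iso.decoders_of(codon), key=lambda i: i.anticodon)
        if not decoders:
            raise ValueError(
                f"configuration error: no anticodon decodes {codon} ({family.name})"
            )
        exact = [i for i in decoders if i.anticodon[0] == _COMP[codon[2]]]
        primary[codon] = (exact[0] if exact else decoders[0]).anticodon

    groups: Dict[str, List[str]] = {}
    for codon, anti in primary.items():
        groups.setdefault(anti, []).append(codon)
    out = sorted(tuple(sorted(g)) for g in groups.values())
    covered = [c for g in out for c in g]
    assert sorted(covered) == sorted(family.codons), "groups must partition the family"
    return out


def load_isoacceptor_config(path: str | Path) -> IsoacceptorMap:
    """Load a plain-text isoacceptor table.

    One line per isoacceptor: ``anticodon<TAB>copy_number<TAB>codon,codon``.
    Lines starting with ``#`` and blank lines are ignored.
    """
    isos: List[Isoacceptor] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields, got {len(parts)}")
        anticodon, copies, codons = parts
        isos.append(
            Isoacceptor(
                anticodon=anticodon.upper(),
                copy_number=int(copies),
                codons=tuple(c.strip().upper() for c in codons.split(",") if c.strip()),
            )
        )
    return IsoacceptorMap(isos)


def default_isoacceptor_map() -> IsoacceptorMap:
    """The shipped isoacceptor inventory for M. thermautotrophicus.

    Ser and Arg follow the genome's annotated anticodons (two tRNA-Ser
    GGA gene copies, TGA and GCT; Arg GCG, TCG, CCT, TCT); the remaining
    families use a generic archaeal two-isoacceptor layout (G34 reading
    NNC/NNT, T34 reading NNA/NNG, with dedicated C34/one-codon readers
    where needed).  Users studying another genome should supply their own
    table via ``load_isoacceptor_config``.
    """
    ref = resources.files("codonreuse").joinpath("data/isoacceptors_mthermautotrophicus.tsv")
    with resources.as_file(ref) as path:
        return load_isoacceptor_config(path)
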