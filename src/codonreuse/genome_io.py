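"""Reading and validating coding sequences from GenBank flat files or FASTA.

Produces :class:`CDSRecord` objects: ordered codon lists in mRNA sense, with
ambiguous-base codons *masked* (kept in position, excluded from counting) so
that the occurrence order of the remaining codons is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Set

from Bio import SeqIO
from Bio.Seq import Seq

from codonreuse.codon_model import GeneticCode

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
# IUPAC nucleotide alphabet (ambiguity codes mask the containing codon)
_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass
class CDSRecord:
    """One coding sequence as an ordered codon list.

    ``masked_positions`` are codon indices containing non-ACGT bases; masked
    codons stay in place so downstream pairing sees the true occurrence order
    of the unmasked codons.
    """

    gene_id: str
    strand: str  # "+" or "-"
    codons: List[str]
    masked_positions: Set[int] = field(default_factory=set)
    source_coords: str = ""
    valid: bool = True
    reason: Optional[str] = None
    flags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for i in self.masked_positions:
            if not 0 <= i < len(self.codons):
                raise ValueError(
                    f"{self.gene_id}: masked position {i} outside codon range"
                )

    def unmasked_codons(self) -> List[str]:
        return [c for i, c in enumerate(self.codons) if i not in self.masked_positions]


def _split_codons(gene_id: str, seq: str) -> tuple[List[str], Set[int]]:
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(
            f"record {gene_id}: non-nucleotide characters {sorted(bad)!r}"
        )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    masked = {i for i, c in enumerate(codons) if set(c) - _DNA}
    return codons, masked


def _is_partial(feature) -> bool:
    loc = str(feature.location)
    return "<" in loc or ">" in loc


def read_genbank_cds(
    path: str | Path,
    include_partial: bool = False,
    include_pseudo: bool = False,
) -> List[CDSRecord]:
    """Extract CDS features from a GenBank flat file.

    Minus-strand and multi-segment (``join``) locations are resolved to the
    mRNA-sense nucleotide sequence before codon splitting.  Features whose
    resolved length is not a multiple of 3 are skipped with a warning, as are
    partial features (unless ``include_partial``) and ``pseudo``-qualified
    features (unless ``include_pseudo``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"cannot parse {path} as GenBank: {exc}") from exc
    if not seq_records:
        logger.warning("%s: no GenBank sequence entries found", path)
        return []

    out: List[CDSRecord] = []
    for rec in seq_records:
        n_cds = 0
        for feature in rec.features:
            if feature.type != "CDS":
                continue
            n_cds += 1
            quals = feature.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("protein_id", [None])[0]
                or f"{rec.id}_CDS{n_cds}"
            )
            if "pseudo" in quals and not include_pseudo:
                logger.warning("skipping %s: pseudo qualifier", gene_id)
                continue
            if _is_partial(feature) and not include_partial:
                logger.warning("skipping %s: partial location %s", gene_id, feature.location)
                continue
            try:
                seq = str(feature.extract(rec.seq))
            except Exception as exc:
                raise ValueError(
                    f"cannot resolve location of feature {gene_id} "
                    f"({feature.location}): {exc}"
                ) from exc
            if len(seq) % 3 != 0:
                logger.warning(
                    "skipping %s: length %d not a multiple of 3", gene_id, len(seq)
                )
                continue
            if not seq:
                logger.warning("skipping %s: empty sequence", gene_id)
                continue
            strand = "-" if (feature.location.strand or 1) < 0 else "+"
            codons, masked = _split_codons(gene_id, seq)
            out.append(
                CDSRecord(
                    gene_id=gene_id,
                    strand=strand,
                    codons=codons,
                    masked_positions=masked,
                    source_coords=f"{rec.id}:{feature.location}",
                )
            )
    return out


def read_fasta_cds(path: str | Path) -> List[CDSRecord]:
    """Read one CDS per FASTA record (header first token = gene id).

    Lowercase is accepted and upper-cased; sequences whose length is not a
    multiple of 3 are skipped with a warning; codons containing IUPAC
    ambiguity codes are masked.  Strand is recorded as "+" (records are
    assumed already in mRNA sense).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: List[CDSRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if len(seq) % 3 != 0:
            logger.warning("skipping %s: length %d not a multiple of 3", rec.id, len(seq))
            continue
        if not seq:
            logger.warning("skipping %s: empty sequence", rec.id)
            continue
        codons, masked = _split_codons(rec.id, seq)
        out.append(
            CDSRecord(
                gene_id=rec.id,
                strand="+",
                codons=codons,
                masked_positions=masked,
                source_coords=f"{path.name}:{rec.id}",
            )
        )
    return out


def write_fasta_cds(records: Iterable[CDSRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, 60-column wrapped, codons concatenated."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            seq = "".join(rec.codons)
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Minus-strand resolution used for GenBank ``complement`` locations."""
    return str(Seq(seq).reverse_complement())


def validate_and_trim(record: CDSRecord, code: GeneticCode) -> CDSRecord:
    """Trim the terminal stop codon and reject records with internal stops.

    Returns a new record.  Invalid records carry ``valid=False`` and a
    machine-readable ``reason``; a missing terminal stop is flagged
    (``no_terminal_stop``) but not fatal.  Masked codons are never
    interpreted as stops.
    """
    codons = list(record.codons)
    masked = set(record.masked_positions)
    flags = set(record.flags)

    if codons and (len(codons) - 1 not in masked) and code.is_stop(codons[-1]):
        codons = codons[:-1]
    else:
        flags.add("no_terminal_stop")

    if not codons:
        return replace(record, codons=codons, masked_positions=set(), flags=flags,
                       valid=False, reason="empty_after_trim")

    for i, c in enumerate(codons):
        if i in masked:
            continue
        if code.is_stop(c):
            logger.warning("%s: internal stop %s at codon %d", record.gene_id, c, i)
            return replace(record, codons=codons, masked_positions=masked,
                           flags=flags, valid=False, reason="internal_stop")

    masked = {i for i in masked if i < len(codons)}
    return replace(record, codons=codons, masked_positions=masked, flags=flags,
                   valid=True, reason=None)
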