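"""Variant annotation: substitution class, database membership, coding consequence.

Classifies each called SNV three ways:

* transition (purine<->purine, pyrimidine<->pyrimidine) vs transversion;
* known vs novel, by exact (chrom, pos, ref, alt) membership in one or more
  SNP database key sets (dbSNP-like, 1000G-like, ESP-like);
* coding consequence (silent / missense / nonsense) against a gene model,
  with HGVS-style cDNA (c.11C>T) and protein (p.Thr4Met) names.

Coordinates are 1-based genomic throughout the public surface; gene models
store their exon blocks as 0-based half-open intervals (BED convention) and
convert at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: database column order in the mock database TSVs
DB_COLUMNS = ("chrom", "pos", "ref", "alt")


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-nucleotide substitution as ``"Ti"`` or ``"Tv"``.

    A transition keeps the base chemistry (A<->G or C<->T); a transversion
    swaps purine for pyrimidine or vice versa. Of the 12 ordered substitution
    classes, 4 are transitions and 8 transversions, which is why a uniformly
    random error process has an expected Ti/Tv of 0.5.
    """
    ref, alt = ref.upper(), alt.upper()
    for b in (ref, alt):
        if b not in BASES:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    both_purine = ref in PURINES and alt in PURINES
    both_pyrimidine = ref in PYRIMIDINES and alt in PYRIMIDINES
    return "Ti" if (both_purine or both_pyrimidine) else "Tv"


def complement(base: str) -> str:
    return _COMPLEMENT[base.upper()]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A single-transcript coding gene model.

    ``cds`` is the coding-strand CDS sequence (starts at the ATG, length a
    multiple of 3). ``exons`` are the genomic blocks covering the CDS as
    0-based half-open intervals in ascending genomic order; for a minus-strand
    gene the CDS reads through the blocks in descending order, complemented.
    """

    name: str
    chrom: str
    strand: str
    cds: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.name}: CDS length {len(self.cds)} not a multiple of 3")
        span = sum(e - s for s, e in self.exons)
        if span != len(self.cds):
            raise ValueError(f"{self.name}: exon span {span} != CDS length {len(self.cds)}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.name}: empty exon block ({s}, {e})")

    # -- coordinate mapping --------------------------------------------------

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a 1-based genomic position to a 1-based CDS coordinate.

        Returns None when the position does not fall in any exon block.
        """
        p0 = pos - 1
        offset = 0
        blocks = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for s, e in blocks:
            if s <= p0 < e:
                within = (p0 - s) if self.strand == "+" else (e - 1 - p0)
                return offset + within + 1
            offset += e - s
        return None

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.genomic_to_cds(pos) is not None

    def cds_base(self, cds_pos: int) -> str:
        return self.cds[cds_pos - 1]

    def genomic_ref_base(self, pos: int) -> str:
        """Plus-strand genomic base at ``pos`` implied by the CDS sequence."""
        cds_pos = self.genomic_to_cds(pos)
        if cds_pos is None:
            raise ValueError(f"position {pos} outside CDS of {self.name}")
        b = self.cds_base(cds_pos)
        return b if self.strand == "+" else complement(b)

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())


@dataclass
class GenePanel:
    """An ordered collection of gene models with position lookup."""

    genes: dict[str, GeneModel] = field(default_factory=dict)

    def add(self, model: GeneModel) -> None:
        self.genes[model.name] = model

    def __getitem__(self, name: str) -> GeneModel:
        return self.genes[name]

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def find(self, chrom: str, pos: int) -> GeneModel | None:
        for model in self.genes.values():
            if model.contains(chrom, pos):
                return model
        return None

    # -- serialization (FASTA for CDS, TSV for coordinates) -------------------

    def write(self, fasta_path: str | Path, table_path: str | Path) -> None:
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        records = [SeqRecord(Seq(m.cds), id=m.name, description="") for m in self]
        SeqIO.write(records, str(fasta_path), "fasta")
        rows = [
            {
                "gene": m.name,
                "chrom": m.chrom,
                "strand": m.strand,
                "blocks": ",".join(f"{s}-{e}" for s, e in m.exons),
            }
            for m in self
        ]
        pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | Path, table_path: str | Path) -> "GenePanel":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        table = pd.read_csv(table_path, sep="\t", dtype=str)
        panel = cls()
        for row in table.itertuples(index=False):
            blocks = tuple(
                tuple(int(x) for x in chunk.split("-")) for chunk in row.blocks.split(",")
            )
            panel.add(
                GeneModel(
                    name=row.gene,
                    chrom=row.chrom,
                    strand=row.strand,
                    cds=seqs[row.gene],
                    exons=blocks,  # type: ignore[arg-type]
                )
            )
        return panel


# ---------------------------------------------------------------------------
# Database membership
# ---------------------------------------------------------------------------

VariantKey = tuple[str, int, str, str]


def load_database(path: str | Path) -> set[VariantKey]:
    """Read a variant-key database TSV (chrom, pos, ref, alt; no header).

    Malformed rows are skipped with a logged count rather than aborting the
    run; mock databases are external inputs.
    """
    keys: set[VariantKey] = set()
    skipped = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                skipped += 1
                continue
            chrom, pos, ref, alt = parts
            try:
                keys.add((chrom, int(pos), ref.upper(), alt.upper()))
            except ValueError:
                skipped += 1
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    return keys


def lookup_databases(
    key: VariantKey, databases: Mapping[str, set[VariantKey]]
) -> dict[str, bool]:
    """Exact-key membership flags per database, plus the ``known`` union."""
    flags = {name: key in keys for name, keys in databases.items()}
    flags["known"] = any(flags.values())
    return flags


# ---------------------------------------------------------------------------
# Coding consequence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Consequence:
    kind: str  # silent | missense | nonsense | noncoding
    cdna: str | None
    protein: str | None


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def annotate_consequence(
    chrom: str, pos: int, ref: str, alt: str, model: GeneModel
) -> Consequence:
    """Coding consequence of a genomic SNV against a gene model.

    ``ref``/``alt`` are plus-strand genomic bases; for minus-strand genes they
    are complemented into CDS space before codon lookup, so a variant and its
    reverse-complement representation annotate identically.
    """
    if chrom != model.chrom:
        raise ValueError(f"{chrom} does not match gene {model.name} on {model.chrom}")
    cds_pos = model.genomic_to_cds(pos)
    if cds_pos is None:
        return Consequence("noncoding", None, None)
    if model.strand == "+":
        cref, calt = ref.upper(), alt.upper()
    else:
        cref, calt = complement(ref), complement(alt)
    if model.cds_base(cds_pos) != cref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos} ({model.name}): "
            f"CDS has {model.cds_base(cds_pos)}, call says {cref}"
        )
    codon_index = (cds_pos - 1) // 3  # 0-based
    within = (cds_pos - 1) % 3
    codon = model.cds[codon_index * 3 : codon_index * 3 + 3]
    mutated = codon[:within] + calt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    cdna = f"c.{cds_pos}{cref}>{calt}"
    if aa_alt == aa_ref:
        return Consequence("silent", cdna, "p.=")
    prot = f"p.{_aa3(aa_ref)}{codon_index + 1}{_aa3(aa_alt)}"
    kind = "nonsense" if aa_alt == "*" else "missense"
    return Consequence(kind, cdna, prot)


# ---------------------------------------------------------------------------
# Whole-callset annotation
# ---------------------------------------------------------------------------

def annotate_calls(
    calls: pd.DataFrame,
    panel: GenePanel,
    databases: Mapping[str, Iterable[VariantKey]],
) -> pd.DataFrame:
    """Annotate a call table (chrom, pos, ref, alt columns required).

    Returns one row per call with substitution class, per-database flags, the
    known/novel verdict, and the coding consequence. Calls outside any gene
    model's CDS get consequence ``noncoding``.
    """
    db_sets = {name: set(keys) for name, keys in databases.items()}
    records = []
    for row in calls.itertuples(index=False):
        key: VariantKey = (str(row.chrom), int(row.pos), row.ref, row.alt)
        flags = lookup_databases(key, db_sets)
        model = panel.find(key[0], key[1])
        if model is None:
            csq = Consequence("noncoding", None, None)
            gene = getattr(row, "gene", None)
        else:
            csq = annotate_consequence(key[0], key[1], key[2], key[3], model)
            gene = model.name
        rec = {
            "site_id": getattr(row, "site_id", f"{key[0]}:{key[1]}"),
            "gene": gene,
            "titv": classify_substitution(row.ref, row.alt),
            "consequence": csq.kind,
            "cdna": csq.cdna,
            "protein": csq.protein,
        }
        rec.update(flags)
        records.append(rec)
    return pd.DataFrame(records)
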