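"""Per-individual, per-gene structural-variant burden from annotated VCFs.

The input contract is a multi-sample VCF (v4.2+) of structural variants in
which each record carries Ensembl gene identifiers in an INFO field.  Two
annotation styles are understood:

* a plain ``GENE`` INFO key holding one or more gene identifiers separated
  by ``|`` or ``,``;
* SnpEff / Ensembl-VEP style ``ANN`` entries, taking the gene-ID subfield
  (index 4, with index 3 as the symbol) of each comma-separated annotation.

By default both are tried in that order per record.  The tally counts, for
every sample and every annotated gene, the number of VCF records in which
the sample carries at least one alternate allele — one increment per
(record, sample, gene) regardless of allele copy number, so a homozygous
alternate genotype counts once.  Missing genotypes are non-carriers.

Coordinates stay in the 1-based VCF convention; annotations are trusted as
given (no interval arithmetic).  BND records participate like any other
record, with END falling back to POS.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = ["SVRecord", "GeneTally", "read_annotated_vcf", "is_carrier",
           "build_gene_tally", "write_tally", "read_tally"]

log = logging.getLogger(__name__)

_SV_TYPES = {"DEL", "DUP", "INS", "INV", "BND"}
_GENE_SEP = re.compile(r"[|,]")


@dataclass
class SVRecord:
    """One structural-variant call with its gene annotations and genotypes."""

    chrom: str
    pos: int                      # 1-based start
    end: int                      # 1-based inclusive end; == pos for BND / missing END
    sv_type: str                  # DEL/DUP/INS/INV/BND/other
    gene_ids: frozenset = frozenset()
    gene_symbols: dict = field(default_factory=dict)  # gene_id -> symbol where known
    genotypes: list = field(default_factory=list)     # aligned to the file's sample order

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"POS must be >= 1, got {self.pos}")
        if self.sv_type != "BND" and self.end < self.pos:
            raise ValidationError(f"END {self.end} < POS {self.pos} for non-BND record")


@dataclass
class GeneTally:
    """samples x genes matrix of SV counts."""

    samples: list
    genes: list            # sorted lexicographically
    counts: np.ndarray     # (n_samples, n_genes) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.samples), len(self.genes)):
            raise ValidationError("tally matrix shape does not match sample/gene lists")
        if np.any(self.counts < 0):
            raise ValidationError("tally counts must be non-negative")

    def __eq__(self, other):
        return (isinstance(other, GeneTally) and self.samples == other.samples
                and self.genes == other.genes and np.array_equal(self.counts, other.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.samples, name="sample"),
                            columns=self.genes)

    def gene_counts(self, gene: str) -> pd.Series:
        """Per-sample SV count for one gene; all-zero if the gene is absent."""
        if gene in self.genes:
            return self.to_frame()[gene]
        log.warning("gene %s not present in tally; counting 0 SVs for every sample", gene)
        return pd.Series(0, index=pd.Index(self.samples, name="sample"), name=gene)


def is_carrier(genotype: str) -> bool:
    """True iff the allele call contains at least one alternate allele.

    Missing calls ('.', './.', '.|.') are non-carriers.
    """
    if genotype is None:
        return False
    gt = genotype.split(":", 1)[0].strip()
    if gt in ("", "."):
        return False
    alleles = re.split(r"[/|]", gt)
    out = False
    for a in alleles:
        if a == ".":
            continue
        if not a.isdigit():
            raise FormatError(f"malformed genotype {genotype!r}")
        out = out or int(a) > 0
    return out


def _genes_from_info(info_get, annotation_keys):
    """Extract (gene_ids, symbols) trying each configured INFO key in order."""
    for key in annotation_keys:
        raw = info_get(key)
        if raw is None:
            continue
        if isinstance(raw, bytes):
            raw = raw.decode()
        raw = str(raw)
        if key.upper() == "ANN":
            ids, symbols = set(), {}
            for entry in raw.split(","):
                parts = entry.split("|")
                if len(parts) > 4 and parts[4]:
                    ids.add(parts[4])
                    if parts[3]:
                        symbols[parts[4]] = parts[3]
            if ids:
                return frozenset(ids), symbols
        else:
            ids = {g for g in _GENE_SEP.split(raw) if g}
            if ids:
                return frozenset(ids), {}
    return frozenset(), {}


def read_annotated_vcf(path, annotation_keys=("GENE", "ANN")):
    """Read a gene-annotated multi-sample SV VCF.

    Returns ``(records, samples, n_unannotated)`` where ``records`` is a list
    of SVRecord in file order, ``samples`` preserves the header order, and
    ``n_unannotated`` counts records that carried none of the annotation
    keys (these are retained with empty gene_ids).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FormatError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValidationError(f"VCF {path} has no sample columns; a multi-sample VCF is required")

    records = []
    n_unannotated = 0
    for v in vcf:
        gene_ids, symbols = _genes_from_info(v.INFO.get, annotation_keys)
        if not gene_ids:
            n_unannotated += 1
        svt = v.INFO.get("SVTYPE")
        svt = str(svt) if svt else "other"
        if svt not in _SV_TYPES:
            svt = "other" if svt != "other" else svt
        end = v.INFO.get("END")
        end = int(end) if end is not None else int(v.POS)
        if svt == "BND":
            end = int(v.POS)
        gts = _format_gts(v)
        records.append(SVRecord(chrom=v.CHROM, pos=int(v.POS), end=end, sv_type=svt,
                                gene_ids=gene_ids, gene_symbols=symbols, genotypes=gts))
    if n_unannotated:
        log.warning("%d of %d records carry no gene annotation under keys %s",
                    n_unannotated, len(records), list(annotation_keys))
    return records, samples, n_unannotated


def _format_gts(variant):
    """Genotype strings ('0/1', './.', ...) per sample from a cyvcf2 variant."""
    out = []
    for g in variant.genotypes:
        *alleles, phased = g
        sep = "|" if phased else "/"
        out.append(sep.join("." if a < 0 else str(a) for a in alleles))
    return out


def build_gene_tally(records, samples) -> GeneTally:
    """Tally carrier records per (sample, gene).

    counts[s, g] = #{records r : g in r.gene_ids and is_carrier(r.genotypes[s])}.
    Deterministic: genes are sorted lexicographically and record order is
    irrelevant.
    """
    genes = sorted({g for r in records for g in r.gene_ids})
    gene_idx = {g: j for j, g in enumerate(genes)}
    counts = np.zeros((len(samples), len(genes)), dtype=int)
    for r in records:
        if len(r.genotypes) != len(samples):
            raise ValidationError(
                f"record {r.chrom}:{r.pos} has {len(r.genotypes)} genotypes "
                f"for {len(samples)} samples")
        if not r.gene_ids:
            continue
        for si, gt in enumerate(r.genotypes):
            try:
                carrier = is_carrier(gt)
            except FormatError as exc:
                raise FormatError(f"{exc} (sample {samples[si]} at {r.chrom}:{r.pos})") from exc
            if carrier:
                for g in r.gene_ids:
                    counts[si, gene_idx[g]] += 1
    return GeneTally(samples=list(samples), genes=genes, counts=counts)


def write_tally(tally: GeneTally, path) -> None:
    """Write the tally as a TSV: header ``sample`` + sorted gene columns."""
    df = tally.to_frame()
    df = df[sorted(df.columns)]
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_tally(path) -> GeneTally:
    """Read a tally TSV back; rejects ragged rows, non-integers and negatives."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot read tally TSV {path}: {exc}") from exc
    mat = np.zeros(df.shape, dtype=int)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, val in enumerate(row):
            try:
                iv = int(val)
            except (TypeError, ValueError):
                raise FormatError(f"non-integer tally cell {val!r} at data row {i + 1}")
            if iv < 0:
                raise FormatError(f"negative tally count {iv} at data row {i + 1}")
            mat[i, j] = iv
    return GeneTally(samples=list(df.index), genes=list(df.columns), counts=mat)
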