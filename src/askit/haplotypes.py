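"""Build and index the two parental allele sequences of a gene locus.

A locus is described by a reference sequence (FASTA) plus exon/CDS
annotation (BED or GFF3), and the second strain by a table of fixed
variants (VCF).  Applying the variants yields a :class:`Haplotype` whose
coordinate map translates positions exactly between the strain sequence
and the reference, including across insertions and deletions.  All
internal coordinates are 0-based half-open; the 1-based conventions of
VCF and GFF are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Sentinel returned by coordinate maps for positions inside an indel
#: footprint (inserted bases have no reference position; deleted
#: reference bases have no haplotype position).
UNMAPPED = -1

_DNA = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class LocusError(ValueError):
    """Raised for invalid locus definitions (bad exons, REF mismatches...)."""


@dataclass(frozen=True)
class Exon:
    start: int
    end: int
    coding: bool = True
    frame: int = 0

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise LocusError(f"bad exon interval ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A single-gene locus: sequence plus ordered exon structure."""

    locus_id: str
    sequence: str
    exons: list[Exon]
    cds_strand: str = "+"

    def __post_init__(self):
        bad = set(self.sequence) - _DNA
        if bad:
            raise LocusError(f"non-DNA characters in sequence: {sorted(bad)}")
        if self.cds_strand not in "+-":
            raise LocusError(f"cds_strand must be + or -, got {self.cds_strand!r}")
        prev_end = -1
        for ex in self.exons:
            if ex.end > len(self.sequence):
                raise LocusError(
                    f"exon ({ex.start}, {ex.end}) outside sequence of "
                    f"length {len(self.sequence)}"
                )
            if ex.start < prev_end:
                raise LocusError(f"overlapping/unsorted exon ({ex.start}, {ex.end})")
            prev_end = ex.end

    @property
    def coding_exons(self) -> list[Exon]:
        return [e for e in self.exons if e.coding]

    @property
    def cds_length(self) -> int:
        return sum(e.length for e in self.coding_exons)

    def exon_index_at(self, pos: int) -> int | None:
        """Index (into ``exons``) of the exon containing ``pos``, else None."""
        for i, ex in enumerate(self.exons):
            if ex.start <= pos < ex.end:
                return i
        return None

    def cds_sequence(self) -> str:
        cds = "".join(self.sequence[e.start:e.end] for e in self.coding_exons)
        return reverse_complement(cds) if self.cds_strand == "-" else cds


@dataclass(frozen=True)
class Variant:
    """One fixed difference between strains, VCF-anchored representation.

    ``pos`` is 0-based on the reference.  SNP: len(ref)==len(alt)==1.
    INS: alt = ref anchor base + inserted sequence.  DEL: ref = anchor
    base + deleted span, alt = anchor base.
    """

    pos: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        if len(self.alt) > len(self.ref):
            return "INS"
        return "DEL"

    @property
    def end(self) -> int:
        """End (exclusive) of the reference footprint."""
        return self.pos + len(self.ref)

    @property
    def net_size(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class VariantTable:
    records: list[Variant]
    source: str = ""

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda v: v.pos)
        prev_end = -1
        for v in self.records:
            if v.pos < prev_end:
                raise LocusError(f"overlapping variants near position {v.pos}")
            prev_end = v.end

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate_against(self, gene: GeneModel) -> None:
        for v in self.records:
            observed = gene.sequence[v.pos:v.end]
            if observed != v.ref:
                raise LocusError(
                    f"REF mismatch at 1-based position {v.pos + 1}: variant says "
                    f"{v.ref!r}, sequence has {observed!r} (wrong reference build?)"
                )
            if "N" in observed:
                raise LocusError(
                    f"variant at 1-based position {v.pos + 1} overlaps N bases"
                )


class CoordMap:
    """Exact bidirectional position map between a haplotype and its reference.

    Positions inside indel footprints map to :data:`UNMAPPED`.
    """

    def __init__(self, hap_to_ref: np.ndarray, ref_to_hap: np.ndarray):
        self._h2r = hap_to_ref
        self._r2h = ref_to_hap

    def to_ref(self, hap_pos: int) -> int:
        return int(self._h2r[hap_pos])

    def to_hap(self, ref_pos: int) -> int:
        return int(self._r2h[ref_pos])

    def to_ref_array(self, start: int, end: int) -> np.ndarray:
        return self._h2r[start:end]

    def to_hap_array(self, start: int, end: int) -> np.ndarray:
        return self._r2h[start:end]

    def to_hap_nearest(self, ref_pos: int) -> int:
        """Haplotype position of ``ref_pos``, or of the next mapped base to
        its right (used to project interval boundaries across deletions)."""
        n = len(self._r2h)
        p = ref_pos
        while p < n and self._r2h[p] == UNMAPPED:
            p += 1
        if p == n:
            return len(self._h2r)
        return int(self._r2h[p])


@dataclass
class Haplotype:
    """A strain-specific allele sequence with its coordinate map."""

    strain: str
    sequence: str
    coord_map: CoordMap
    applied_variants: VariantTable

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# I/O


def _read_bed_exons(path: str, locus_id: str) -> tuple[list[tuple[int, int, bool]], str]:
    rows: list[tuple[int, int, bool]] = []
    strand = "+"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if f[0] != locus_id:
                continue
            rows.append((int(f[1]), int(f[2]), True))
            if len(f) >= 6 and f[5] in "+-":
                strand = f[5]
    return rows, strand


def _read_gff_exons(path: str, locus_id: str) -> tuple[list[tuple[int, int, bool]], str]:
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    strand = "+"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8 or f[0] != locus_id:
                continue
            ftype = f[2].lower()
            # GFF is 1-based closed -> 0-based half-open
            iv = (int(f[3]) - 1, int(f[4]))
            if ftype == "exon":
                exons.append(iv)
            elif ftype == "cds":
                cds.append(iv)
            else:
                continue
            if f[6] in "+-":
                strand = f[6]
    if not exons:
        exons = cds
    cds_set = set(cds)
    rows = [(s, e, (not cds) or ((s, e) in cds_set) or _overlaps_any(s, e, cds))
            for s, e in exons]
    return rows, strand


def _overlaps_any(s: int, e: int, ivs: Iterable[tuple[int, int]]) -> bool:
    return any(s < b and a < e for a, b in ivs)


def read_gene_model(fasta_path: str, annotation_path: str,
                    record_id: str | None = None) -> GeneModel:
    """Load a locus from FASTA + exon annotation (BED or GFF3).

    BED intervals are 0-based half-open and taken as coding exons; GFF3
    ``exon``/``CDS`` features are 1-based closed and converted.  The
    dialect is chosen by file extension (.gff/.gff3/.gtf -> GFF),
    falling back to BED.
    """
    records = {r.id: r for r in SeqIO.parse(fasta_path, "fasta")}
    if not records:
        raise LocusError(f"no FASTA records in {fasta_path}")
    if record_id is None:
        if len(records) > 1:
            raise LocusError(
                f"{fasta_path} has {len(records)} records; name one explicitly"
            )
        record_id = next(iter(records))
    if record_id not in records:
        raise LocusError(f"record {record_id!r} not found in {fasta_path}")
    seq = str(records[record_id].seq).upper()

    if annotation_path.lower().endswith((".gff", ".gff3", ".gtf")):
        rows, strand = _read_gff_exons(annotation_path, record_id)
    else:
        rows, strand = _read_bed_exons(annotation_path, record_id)
    rows.sort()
    exons, acc = [], 0
    for s, e, coding in rows:
        exons.append(Exon(s, e, coding, frame=acc % 3 if coding else 0))
        if coding:
            acc += e - s
    model = GeneModel(record_id, seq, exons, strand)
    if model.coding_exons and model.cds_length % 3 != 0:
        log.warning("CDS length %d of %s is not a multiple of 3",
                    model.cds_length, record_id)
    return model


def read_variants(vcf_path: str, gene: GeneModel,
                  split_multiallelic: bool = True,
                  allow_het: bool = False,
                  source: str = "") -> VariantTable:
    """Read strain variants from a VCF restricted to the gene locus.

    Records outside the locus are dropped (counted in the log); REF
    mismatches against the locus sequence are hard errors.  Non-fixed
    (heterozygous) strain calls are excluded unless ``allow_het``.
    """
    recs: list[Variant] = []
    dropped = 0
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            if rec.chrom != gene.locus_id or rec.pos - 1 >= len(gene.sequence):
                dropped += 1
                continue
            alts = rec.alts or ()
            if len(alts) > 1 and not split_multiallelic:
                raise LocusError(f"multi-allelic record at position {rec.pos}")
            if not allow_het and rec.samples:
                gts = {gt for s in rec.samples.values()
                       for gt in (s.get("GT") or ()) if gt is not None}
                if len(gts) > 1:
                    log.warning("excluding heterozygous call at %d", rec.pos)
                    continue
            for alt in alts:
                if alt is None or set(alt) - set("ACGT"):
                    raise LocusError(
                        f"symbolic/non-ACGT ALT {alt!r} at position {rec.pos}"
                    )
                recs.append(Variant(rec.pos - 1, rec.ref.upper(), alt.upper()))
    if dropped:
        log.info("dropped %d VCF records outside locus %s", dropped, gene.locus_id)
    table = VariantTable(recs, source=source)
    table.validate_against(gene)
    return table


# ---------------------------------------------------------------------------
# Haplotype construction


def build_haplotype(gene: GeneModel, variants: VariantTable,
                    strain: str) -> Haplotype:
    """Apply a variant table to the reference, producing the strain allele.

    Substitutions replace bases in place; insertions and deletions shift
    downstream coordinates.  The coordinate map is exact: inserted bases
    and deleted reference bases map to :data:`UNMAPPED`.
    """
    variants.validate_against(gene)
    ref = gene.sequence
    pieces: list[str] = []
    h2r: list[np.ndarray] = []
    r2h = np.full(len(ref), UNMAPPED, dtype=np.int64)
    cur = 0   # reference cursor
    hlen = 0  # haplotype length so far

    def copy_ref(upto: int):
        nonlocal cur, hlen
        n = upto - cur
        if n > 0:
            pieces.append(ref[cur:upto])
            h2r.append(np.arange(cur, upto, dtype=np.int64))
            r2h[cur:upto] = np.arange(hlen, hlen + n)
            hlen += n
        cur = upto

    for v in variants:
        copy_ref(v.pos)
        pieces.append(v.alt)
        vmap = np.full(len(v.alt), UNMAPPED, dtype=np.int64)
        n_shared = min(len(v.ref), len(v.alt))
        vmap[:n_shared] = np.arange(v.pos, v.pos + n_shared)
        r2h[v.pos:v.pos + n_shared] = np.arange(hlen, hlen + n_shared)
        h2r.append(vmap)
        hlen += len(v.alt)
        cur = v.end
    copy_ref(len(ref))

    hap_to_ref = (np.concatenate(h2r) if h2r
                  else np.empty(0, dtype=np.int64))
    return Haplotype(strain, "".join(pieces), CoordMap(hap_to_ref, r2h), variants)


# ---------------------------------------------------------------------------
# Variant confirmation against Sanger reads


@dataclass
class VariantStatus:
    variant: Variant
    status: str  # confirmed | contradicted | uncovered
    read_id: str | None = None


def confirm_variants(haplotype: Haplotype, gene: GeneModel,
                     confirmation_reads: Sequence,
                     ) -> list[VariantStatus]:
    """Check each applied variant against confirmation reads.

    A read confirming a variant must match the haplotype exactly across
    the variant footprint; a read matching the reference there instead
    contradicts it.  Variants covered by no read — or only by reads that
    fit both alleles equally — are ``uncovered``.  Reads may be Biopython
    SeqRecords or (id, sequence) pairs.
    """
    reads = []
    for r in confirmation_reads:
        if hasattr(r, "seq"):
            reads.append((r.id, str(r.seq).upper()))
        else:
            reads.append((r[0], str(r[1]).upper()))

    out: list[VariantStatus] = []
    for v in haplotype.applied_variants:
        hap_start = haplotype.coord_map.to_hap_nearest(v.pos)
        hap_end = hap_start + len(v.alt)
        status, rid = "uncovered", None
        for read_id, seq in reads:
            for strand_seq in (seq, reverse_complement(seq)):
                # locate the read on the ALT allele spanning the variant
                hit = haplotype.sequence.find(strand_seq)
                while hit != -1:
                    if hit <= hap_start and hit + len(strand_seq) >= hap_end:
                        status, rid = "confirmed", read_id
                        break
                    hit = haplotype.sequence.find(strand_seq, hit + 1)
                if status == "confirmed":
                    break
                # or on the REF allele spanning the variant footprint
                hit = gene.sequence.find(strand_seq)
                while hit != -1:
                    if hit <= v.pos and hit + len(strand_seq) >= v.end and v.ref != v.alt:
                        status, rid = "contradicted", read_id
                        break
                    hit = gene.sequence.find(strand_seq, hit + 1)
                if status == "contradicted":
                    break
            if status != "uncovered":
                break
        out.append(VariantStatus(v, status, rid))
    return out
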