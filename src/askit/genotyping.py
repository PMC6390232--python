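"""Founder genotyping for allele-specific CRISPR knockouts.

Founder (F0/F1) animals are screened by two complementary assays the
way fluorescent-PCR labs do it: capillary-electrophoresis fragment
lengths of FAM-labelled amplicons spanning each cut site, and Sanger
sequencing of TA-cloned PCR products.  Fragment peaks give each
animal's net indel size per amplicon; clone reads additionally carry
the inter-strain diagnostic SNPs, so every indel can be assigned to its
allele of origin.  Indels are classified for reading-frame consequence
(frameshift / in-frame / premature stop) and summarized per founder
cohort as editing efficiency and mistargeting counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq

from .haplotypes import (UNMAPPED, GeneModel, Haplotype, Variant,
                         reverse_complement)

log = logging.getLogger(__name__)

TARGET = "target"
NON_TARGET = "non_target"
AMBIGUOUS = "ambiguous"


class AssayError(ValueError):
    """Primer does not land uniquely on a haplotype."""


@dataclass(frozen=True)
class Indel:
    """Net indel: position on the allele of origin (None when only a
    fragment length is known), net size in bp, inserted sequence for
    insertions (empty for pure deletions, None when unsequenced)."""

    position: int | None
    net_size: int
    inserted: str | None = None


@dataclass
class GenotypeCall:
    sample_id: str
    allele_of_origin: str           # target | non_target | ambiguous
    indel: Indel | None
    frame_class: str | None         # frameshift | in_frame | premature_stop | wild_type
    evidence: str                   # fragment | clone_sequence
    assay_id: str | None = None
    low_confidence: bool = False
    no_call: bool = False
    rejected: bool = False
    notes: str = ""

    @property
    def is_orf_loss(self) -> bool:
        return self.frame_class in ("frameshift", "premature_stop")


@dataclass(frozen=True)
class FragmentPeak:
    sample_id: str
    assay_id: str
    size: float
    height: float

    def __post_init__(self):
        if self.size <= 0 or self.height <= 0:
            raise ValueError("peak size and height must be positive")


@dataclass
class AmpliconAssay:
    """One FAM-primer amplicon, located on both parental haplotypes."""

    assay_id: str
    forward_primer: str
    reverse_primer: str
    expected_length: dict[str, int]          # role -> bp, roles target/non_target
    region: dict[str, tuple[int, int]]       # role -> (start, end) on that haplotype


def _locate_unique(seq: str, primer: str, name: str) -> tuple[int, str]:
    """(start, strand) of the single occurrence of primer or its RC."""
    fwd = [i for i in _find_all(seq, primer)]
    rev = [i for i in _find_all(seq, reverse_complement(primer))]
    hits = [(i, "+") for i in fwd] + [(i, "-") for i in rev]
    if len(hits) != 1:
        raise AssayError(
            f"primer {name} ({primer}) has {len(hits)} matches; need exactly 1"
        )
    return hits[0]


def _find_all(seq: str, sub: str):
    i = seq.find(sub)
    while i != -1:
        yield i
        i = seq.find(sub, i + 1)


def predict_amplicons(assay_id: str, forward_primer: str, reverse_primer: str,
                      haplotypes: dict[str, Haplotype]) -> AmpliconAssay:
    """Locate a primer pair on both haplotypes and predict product sizes.

    Each primer (or its reverse complement) must occur exactly once per
    haplotype, on opposite strands; the expected length includes both
    primers.  A primer sitting on a strain SNP will match one allele
    only and is reported as an error (no mismatch tolerance).
    """
    expected, region = {}, {}
    for role, hap in haplotypes.items():
        f_start, f_strand = _locate_unique(hap.sequence, forward_primer,
                                           f"forward[{role}]")
        r_start, r_strand = _locate_unique(hap.sequence, reverse_primer,
                                           f"reverse[{role}]")
        if f_strand == r_strand:
            raise AssayError(
                f"primers of {assay_id} land on the same strand of {role}"
            )
        if f_strand == "-":
            f_start, r_start = r_start, f_start
            flen, rlen = len(reverse_primer), len(forward_primer)
        else:
            flen, rlen = len(forward_primer), len(reverse_primer)
        start, end = f_start, r_start + rlen
        if end <= start:
            raise AssayError(f"primers of {assay_id} face outward on {role}")
        expected[role] = end - start
        region[role] = (start, end)
    return AmpliconAssay(assay_id, forward_primer, reverse_primer,
                         expected, region)


# ---------------------------------------------------------------------------
# Fragment-length genotyping


def call_fragment_genotype(peaks: list[FragmentPeak], assay: AmpliconAssay,
                           tolerance_bp: float = 1.0,
                           min_rel_height: float = 0.10,
                           ) -> list[GenotypeCall]:
    """Genotype every sample from capillary-electrophoresis peaks.

    Peaks below ``min_rel_height`` of the tallest peak in the same
    sample/assay are treated as noise.  Each retained peak is matched to
    the nearest per-allele expected product length: within
    ``tolerance_bp`` it is a wild-type allele, otherwise an indel of net
    size round(observed - expected).  When the two alleles' expected
    lengths are closer than twice the tolerance they cannot be told
    apart by size, and the allele of origin is ``ambiguous``.  A sample
    with no retained peaks yields a single no-call (not an exception).
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    roles = sorted(assay.expected_length, key=lambda r: r != TARGET)
    sizes = [assay.expected_length[r] for r in roles]
    indistinct = abs(sizes[0] - sizes[-1]) < 2 * tolerance_bp

    calls: list[GenotypeCall] = []
    by_sample: dict[str, list[FragmentPeak]] = {}
    for p in peaks:
        if p.assay_id == assay.assay_id:
            by_sample.setdefault(p.sample_id, []).append(p)

    for sample, plist in sorted(by_sample.items()):
        tallest = max(p.height for p in plist)
        kept = [p for p in plist if p.height >= min_rel_height * tallest]
        if not kept:
            calls.append(GenotypeCall(sample, AMBIGUOUS, None, None,
                                      "fragment", assay.assay_id,
                                      no_call=True, notes="no peaks above threshold"))
            continue
        low_conf = len(kept) < len(roles)
        for p in sorted(kept, key=lambda q: q.size):
            dists = [abs(p.size - s) for s in sizes]
            best = min(range(len(roles)), key=lambda i: dists[i])
            allele = AMBIGUOUS if indistinct else roles[best]
            if dists[best] <= tolerance_bp:
                calls.append(GenotypeCall(p.sample_id, allele, None,
                                          "wild_type", "fragment",
                                          assay.assay_id,
                                          low_confidence=low_conf))
            else:
                net = round(p.size - sizes[best])
                frame = "frameshift" if net % 3 else "in_frame"
                calls.append(GenotypeCall(p.sample_id, allele,
                                          Indel(None, net), frame,
                                          "fragment", assay.assay_id,
                                          low_confidence=low_conf))
    return calls


def read_peaks(path: str) -> list[FragmentPeak]:
    """Read a peak table TSV with columns sample_id, assay_id, size, height."""
    df = pd.read_csv(path, sep="\t")
    return [FragmentPeak(str(r.sample_id), str(r.assay_id),
                         float(r.size), float(r.height))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Clone-sequence genotyping

#: Affine gap scoring, open >> extend, so one contiguous indel is
#: preferred over scattered gaps.
def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -10
    a.extend_gap_score = -0.5
    return a


def _alignment_gaps(alignment) -> list[tuple[int, int, str]]:
    """Gap events as (reference_position, net_size, inserted_seq)."""
    tb, qb = alignment.aligned
    query = str(alignment.query)
    events = []
    for i in range(len(tb) - 1):
        t_gap = int(tb[i + 1][0] - tb[i][1])
        q_gap = int(qb[i + 1][0] - qb[i][1])
        if t_gap:  # deletion in the clone
            events.append((int(tb[i][1]), -t_gap, ""))
        if q_gap:  # insertion in the clone
            ins = query[int(qb[i][1]):int(qb[i + 1][0])]
            events.append((int(tb[i][1]), q_gap, ins))
    return events


def _identity(alignment) -> float:
    c = alignment.counts()
    total = c.identities + c.mismatches + c.gaps
    return c.identities / total if total else 0.0


def diagnostic_snps(assay: AmpliconAssay, target_hap: Haplotype,
                    other_hap: Haplotype) -> list[Variant]:
    """Applied SNPs of the target haplotype lying inside the amplicon."""
    lo, hi = assay.region[TARGET]
    out = []
    for v in target_hap.applied_variants:
        if v.kind != "SNP":
            continue
        p = target_hap.coord_map.to_hap(v.pos)
        if p != UNMAPPED and lo <= p < hi:
            out.append(v)
    return out


def project_cut_sites(cut_sites: list[int], target_hap: Haplotype,
                      other_hap: Haplotype) -> list[int]:
    """Target-haplotype cut positions projected onto the other allele."""
    out = []
    for c in cut_sites:
        r = target_hap.coord_map.to_ref(c)
        if r != UNMAPPED:
            out.append(other_hap.coord_map.to_hap_nearest(r))
    return out


def assign_clone(clone_seq: str, sample_id: str, assay: AmpliconAssay,
                 target_hap: Haplotype, other_hap: Haplotype,
                 cut_sites: list[int], gene: GeneModel,
                 identity_min: float = 0.90,
                 attribution_window: int = 10) -> GenotypeCall:
    """Assign a Sanger clone to its allele of origin and call its indel.

    The allele is decided by majority vote over the diagnostic
    inter-strain SNPs the clone covers; the indel comes from a global
    affine-gap alignment of the clone against its assigned allele's
    amplicon, and is attributed to editing only if it falls within
    ``attribution_window`` bp of a guide cut site (Cas9 cuts bluntly
    3 bp 5' of the PAM).  Clones below ``identity_min`` alignment
    identity are rejected as cloning/sequencing artifacts.
    """
    clone_seq = clone_seq.upper()
    diags = diagnostic_snps(assay, target_hap, other_hap)
    haps = {TARGET: target_hap, NON_TARGET: other_hap}
    amplicons = {role: haps[role].sequence[slice(*assay.region[role])]
                 for role in haps}
    aligner = _aligner()
    alns = {}
    for role, amp in amplicons.items():
        best = max((aligner.align(amp, s)[0]
                    for s in (clone_seq, reverse_complement(clone_seq))),
                   key=lambda a: a.score)
        alns[role] = best

    votes = {TARGET: 0, NON_TARGET: 0}
    lo_t = assay.region[TARGET][0]
    aln_t = alns[TARGET]
    for v in diags:
        p_t = target_hap.coord_map.to_hap(v.pos) - lo_t
        base = _query_base_at(aln_t, p_t)
        if base == v.alt:
            votes[TARGET] += 1
        elif base == v.ref:
            votes[NON_TARGET] += 1
    if votes[TARGET] == votes[NON_TARGET]:
        return GenotypeCall(sample_id, AMBIGUOUS, None, None,
                            "clone_sequence", assay.assay_id,
                            notes=f"diagnostic votes tied {votes[TARGET]}:"
                                  f"{votes[NON_TARGET]}")
    role = TARGET if votes[TARGET] > votes[NON_TARGET] else NON_TARGET
    aln = alns[role]
    if _identity(aln) < identity_min:
        return GenotypeCall(sample_id, role, None, None, "clone_sequence",
                            assay.assay_id, rejected=True,
                            notes=f"alignment identity {_identity(aln):.2f} "
                                  f"below {identity_min}")

    lo = assay.region[role][0]
    cuts = cut_sites if role == TARGET else project_cut_sites(
        cut_sites, target_hap, other_hap)
    cuts_local = [c - lo for c in cuts]
    attributed = [(p, n, ins) for p, n, ins in _alignment_gaps(aln)
                  if any(abs(p - c) <= attribution_window for c in cuts_local)]
    if not attributed:
        return GenotypeCall(sample_id, role, None, "wild_type",
                            "clone_sequence", assay.assay_id)
    net = sum(n for _, n, _ in attributed)
    pos = lo + attributed[0][0]
    ins = "".join(s for _, n, s in attributed if n > 0) or ("" if net < 0 else None)
    indel = Indel(pos, net, ins)
    frame = classify_frame(indel, gene, haps[role])
    return GenotypeCall(sample_id, role, indel, frame, "clone_sequence",
                        assay.assay_id)


def _query_base_at(alignment, target_pos: int) -> str | None:
    """Clone base aligned to a given amplicon position, if any."""
    tb, qb = alignment.aligned
    query = str(alignment.query)
    for (ts, te), (qs, qe) in zip(tb, qb):
        if ts <= target_pos < te:
            return query[qs + (target_pos - ts)]
    return None


# ---------------------------------------------------------------------------
# Reading-frame classification


def _cds_segments(gene: GeneModel, hap: Haplotype) -> list[tuple[int, int]]:
    """Coding-exon spans projected onto the haplotype."""
    segs = []
    for ex in gene.coding_exons:
        s = hap.coord_map.to_hap_nearest(ex.start)
        e = hap.coord_map.to_hap_nearest(ex.end)
        segs.append((s, e))
    return segs


def classify_frame(indel: Indel | None, gene: GeneModel,
                   hap: Haplotype) -> str:
    """Reading-frame consequence of an indel on its allele of origin.

    A net size not divisible by 3 is a frameshift.  In-frame indels are
    checked by translating the edited CDS: a stop codon arising before
    50% of the protein length is a premature stop (ORF loss); otherwise
    the allele keeps an intact frame.  Indels entirely outside coding
    exons are frame-neutral and reported wild_type (flagged in the log).
    An indel of known size but unknown position is classified on size
    alone.
    """
    if indel is None or indel.net_size == 0:
        return "wild_type"
    if indel.position is None:
        # size known, position/sequence not (fragment evidence): classify
        # on size alone; a multiple of 3 cannot show a premature stop
        return "frameshift" if indel.net_size % 3 else "in_frame"

    segs = _cds_segments(gene, hap)
    cds_pos, offset = None, 0
    for s, e in segs:
        if s <= indel.position < e:
            cds_pos = offset + (indel.position - s)
            break
        offset += e - s
    if cds_pos is None:
        log.info("indel at %d is intronic; frame-neutral", indel.position)
        return "wild_type"
    if indel.net_size % 3 != 0:
        return "frameshift"

    cds = "".join(hap.sequence[s:e] for s, e in segs)
    if indel.net_size < 0:
        edited = cds[:cds_pos] + cds[cds_pos - indel.net_size:]
    else:
        ins = indel.inserted if indel.inserted is not None else "N" * indel.net_size
        edited = cds[:cds_pos] + ins + cds[cds_pos:]
    if gene.cds_strand == "-":
        edited = reverse_complement(edited)
        cds = reverse_complement(cds)
    prot_len = len(cds) // 3
    protein = str(Seq(edited[: 3 * (len(edited) // 3)]).translate())
    stop = protein.find("*")
    if stop != -1 and stop < 0.5 * prot_len:
        return "premature_stop"
    return "in_frame"


# ---------------------------------------------------------------------------
# Founder summary


@dataclass
class FounderSummary:
    n_newborns: int
    n_indel_carriers: int
    n_orf_loss: int
    n_mistargeted: int

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.n_orf_loss / self.n_newborns

    def __post_init__(self):
        for c in (self.n_indel_carriers, self.n_orf_loss, self.n_mistargeted):
            if not 0 <= c <= self.n_newborns:
                raise ValueError("counts must lie in [0, n_newborns]")


def summarize_founders(calls: list[GenotypeCall],
                       n_newborns: int) -> FounderSummary:
    """Per-cohort editing efficiency and mistargeting.

    An animal is an indel carrier if any of its calls reports an indel;
    an ORF-loss carrier if at least one call is a target-allele
    frameshift or premature stop; mistargeted if at least one call is a
    non-target-allele indel (animals are counted, not clones).
    Efficiency is 100 x ORF-loss carriers / newborns.
    """
    samples: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        if not (c.no_call or c.rejected):
            samples.setdefault(c.sample_id, []).append(c)
    if len(samples) > n_newborns:
        raise ValueError(
            f"{len(samples)} genotyped samples exceed n_newborns={n_newborns}"
        )
    carriers = orf_loss = mistargeted = 0
    for sample, cs in samples.items():
        has_indel = any(c.indel is not None for c in cs)
        carriers += has_indel
        orf_loss += any(c.indel is not None and c.allele_of_origin == TARGET
                        and c.is_orf_loss for c in cs)
        mistargeted += any(c.indel is not None
                           and c.allele_of_origin == NON_TARGET for c in cs)
    return FounderSummary(n_newborns, carriers, orf_loss, mistargeted)


def read_clones(path: str) -> list[tuple[str, str, str, str]]:
    """Read a clones FASTA with ``sample|assay|clone_n`` headers.

    Returns (sample_id, assay_id, clone_id, sequence) tuples.
    """
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(f"clone header {rec.id!r} is not sample|assay|clone")
        out.append((parts[0], parts[1], parts[2], str(rec.seq).upper()))
    return out
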