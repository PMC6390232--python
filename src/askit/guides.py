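"""Allele-specific Cas9 guide design from strain-divergent PAM sites.

Cas9 requires a protospacer-adjacent motif (NGG for SpCas9) immediately
3' of the 20-nt protospacer; without it, cleavage is undetectable.  In
an F1 hybrid between two diverged strains, a SNP that creates a PAM on
one haplotype but not the other makes a guide that can only cut that
allele.  This module scans both haplotypes for protospacer+PAM windows,
classifies each site's allele specificity by comparing the homologous
window on the other allele, applies basic guide-quality filters, and
selects a two-guide pair in distinct coding exons to delete or disrupt
the open reading frame of the targeted allele only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .haplotypes import (UNMAPPED, GeneModel, Haplotype, reverse_complement)

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class Specificity(Enum):
    TARGET_ONLY_PAM = "TARGET_ONLY_PAM"
    PROTOSPACER_VARIANT = "PROTOSPACER_VARIANT"
    SHARED = "SHARED"
    UNMAPPABLE = "UNMAPPABLE"


@dataclass(frozen=True)
class PamSpec:
    """PAM motif description (3' of the protospacer, SpCas9 geometry)."""

    motif: str = "NGG"
    guide_length: int = 20

    def __post_init__(self):
        if not self.motif or set(self.motif) - set(IUPAC):
            raise ValueError(f"motif {self.motif!r} is not IUPAC DNA")
        if self.guide_length < 1:
            raise ValueError("guide_length must be positive")

    @property
    def window(self) -> int:
        return self.guide_length + len(self.motif)

    def matches(self, seq: str) -> bool:
        """True iff ``seq`` matches the motif.  An N in the *sequence*
        matches nothing (ambiguous bases cannot guarantee a PAM)."""
        if len(seq) != len(self.motif):
            return False
        return all(b in IUPAC[m] for b, m in zip(seq, self.motif))


@dataclass
class ProtospacerSite:
    """One protospacer+PAM occurrence on a haplotype.

    ``start``/``end`` span the full window (protospacer plus PAM) in
    haplotype forward coordinates; ``protospacer`` and ``pam`` are given
    5'->3' in guide orientation regardless of strand.
    """

    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    exon_index: int | None = None
    specificity: Specificity | None = None
    diagnostic_variants: list[int] = field(default_factory=list)

    @property
    def gc_fraction(self) -> float:
        p = self.protospacer
        return (p.count("G") + p.count("C")) / len(p)

    def cut_position(self) -> int:
        """Expected blunt-cut position on the haplotype (between the 3rd
        and 4th protospacer base counting from the PAM)."""
        if self.strand == "+":
            return self.end - len(self.pam) - 3
        return self.start + len(self.pam) + 3


def scan_protospacers(haplotype: Haplotype, pam_spec: PamSpec = PamSpec(),
                      region: tuple[int, int] | None = None,
                      ) -> list[ProtospacerSite]:
    """Every protospacer+PAM window on both strands of ``region``.

    A region shorter than the window yields an empty list.  Windows
    containing N never match (N matches no motif letter).
    """
    seq = haplotype.sequence
    lo, hi = region if region is not None else (0, len(seq))
    if not (0 <= lo <= hi <= len(seq)):
        raise ValueError(f"region ({lo}, {hi}) outside haplotype")
    w, g = pam_spec.window, pam_spec.guide_length
    sites: list[ProtospacerSite] = []
    for s in range(lo, hi - w + 1):
        win = seq[s:s + w]
        if pam_spec.matches(win[g:]):
            sites.append(ProtospacerSite(s, s + w, "+", win[:g], win[g:]))
        rc = reverse_complement(win)
        if pam_spec.matches(rc[g:]):
            sites.append(ProtospacerSite(s, s + w, "-", rc[:g], rc[g:]))
    return sites


def _homologous_window(site: ProtospacerSite, target: Haplotype,
                       other: Haplotype) -> tuple[str, list[int]] | None:
    """Project the site's window onto the other haplotype.

    Returns (other-allele window sequence, diagnostic target-haplotype
    positions where the alleles differ), or None when the window crosses
    an indel or falls off the other allele.
    """
    refpos = target.coord_map.to_ref_array(site.start, site.end)
    if (refpos == UNMAPPED).any():
        return None
    if not (np.diff(refpos) == 1).all():
        return None
    other_pos = other.coord_map.to_hap_array(int(refpos[0]), int(refpos[-1]) + 1)
    if (other_pos == UNMAPPED).any() or not (np.diff(other_pos) == 1).all():
        return None
    o0, o1 = int(other_pos[0]), int(other_pos[-1]) + 1
    window = other.sequence[o0:o1]
    tgt_window = target.sequence[site.start:site.end]
    diags = [site.start + i for i, (a, b) in enumerate(zip(tgt_window, window))
             if a != b]
    return window, diags


def classify_specificity(site: ProtospacerSite, target_hap: Haplotype,
                         other_hap: Haplotype,
                         pam_spec: PamSpec = PamSpec()) -> Specificity:
    """Assign the allele-specificity class of a site found on the target.

    TARGET_ONLY_PAM: the homologous window on the other allele fails the
    PAM motif — a guide here can only cut the target allele.
    PROTOSPACER_VARIANT: both alleles carry the PAM but the protospacers
    differ.  SHARED: the full window is identical.  Sites whose window
    crosses an indel are UNMAPPABLE and excluded from design.
    """
    proj = _homologous_window(site, target_hap, other_hap)
    if proj is None:
        site.specificity = Specificity.UNMAPPABLE
        return site.specificity
    window, diags = proj
    g = pam_spec.guide_length
    if site.strand == "-":
        window_g = reverse_complement(window)
    else:
        window_g = window
    other_pam = window_g[g:]
    if not pam_spec.matches(other_pam):
        cls = Specificity.TARGET_ONLY_PAM
    elif window_g[:g] != site.protospacer:
        cls = Specificity.PROTOSPACER_VARIANT
    else:
        cls = Specificity.SHARED
    site.specificity = cls
    site.diagnostic_variants = diags
    return cls


@dataclass
class FilterRules:
    gc_min: float = 0.25
    gc_max: float = 0.75
    forbidden_homopolymer: str = "TTTT"
    require_coding_exon: bool = True


def annotate_exons(sites: list[ProtospacerSite], haplotype: Haplotype,
                   gene: GeneModel) -> None:
    """Set each site's exon index from the reference projection of its
    protospacer midpoint (None for intronic/unmappable sites)."""
    for s in sites:
        mid = (s.start + s.end) // 2
        refpos = haplotype.coord_map.to_ref(mid)
        s.exon_index = None if refpos == UNMAPPED else gene.exon_index_at(refpos)


def filter_guides(sites: list[ProtospacerSite], gene: GeneModel,
                  haplotype: Haplotype,
                  rules: FilterRules = FilterRules(),
                  ) -> list[ProtospacerSite]:
    """Order-preserving quality filter; each rejection is logged."""
    annotate_exons(sites, haplotype, gene)
    kept = []
    for s in sites:
        gc = s.gc_fraction
        if not (rules.gc_min <= gc <= rules.gc_max):
            log.info("reject %d%s: GC %.0f%% outside bounds", s.start, s.strand,
                     100 * gc)
            continue
        if rules.forbidden_homopolymer and rules.forbidden_homopolymer in s.protospacer:
            log.info("reject %d%s: contains %s", s.start, s.strand,
                     rules.forbidden_homopolymer)
            continue
        if rules.require_coding_exon:
            if s.exon_index is None or not gene.exons[s.exon_index].coding:
                log.info("reject %d%s: not in a coding exon", s.start, s.strand)
                continue
        kept.append(s)
    return kept


@dataclass
class GuidePair:
    site_a: ProtospacerSite
    site_b: ProtospacerSite
    expected_deletion_span: tuple[int, int]
    rationale: str


@dataclass
class NoPairResult:
    """Design infeasible: fewer than two qualifying sites in distinct
    coding exons.  ``best_singles`` lists the qualifying sites found."""

    best_singles: list[ProtospacerSite]
    reason: str


def select_guide_pair(filtered_sites: list[ProtospacerSite], gene: GeneModel,
                      allow_protospacer_variant: bool = False,
                      ) -> GuidePair | NoPairResult:
    """Deterministic two-guide choice maximizing the deletion span.

    Policy: among allele-specific sites (TARGET_ONLY_PAM by default),
    take the 5'-most site in the earliest coding exon, then the farthest
    downstream site in a different exon; ties break to the 5'-most
    coordinate.
    """
    ok = {Specificity.TARGET_ONLY_PAM}
    if allow_protospacer_variant:
        ok.add(Specificity.PROTOSPACER_VARIANT)
    cands = [s for s in filtered_sites
             if s.specificity in ok and s.exon_index is not None]
    exons = {s.exon_index for s in cands}
    if len(cands) < 2 or len(exons) < 2:
        return NoPairResult(
            best_singles=sorted(cands, key=lambda s: s.start),
            reason="no allele-specific pair: need >=2 qualifying sites in "
                   ">=2 distinct coding exons",
        )
    first = min(cands, key=lambda s: (s.exon_index, s.start))
    rest = [s for s in cands if s.exon_index != first.exon_index]
    second = max(rest, key=lambda s: s.start)  # farthest downstream; ties keep 5'-most listed
    span = (min(first.cut_position(), second.cut_position()),
            max(first.cut_position(), second.cut_position()))
    return GuidePair(
        first, second, span,
        rationale=f"exon {first.exon_index} + exon {second.exon_index}, "
                  f"expected deletion {span[1] - span[0]} bp",
    )


def count_offtargets(protospacer: str, background_sequence: str,
                     max_mismatches: int = 3,
                     pam_spec: PamSpec = PamSpec()) -> int:
    """Hamming-distance off-target count over both strands.

    Counts every window of the background with a motif-matching PAM
    whose protospacer is within ``max_mismatches`` of the guide; the
    on-target site itself is included when present.
    """
    g = len(protospacer)
    count = 0
    for seq in (background_sequence, reverse_complement(background_sequence)):
        n = len(seq)
        for s in range(0, n - g - len(pam_spec.motif) + 1):
            if not pam_spec.matches(seq[s + g:s + g + len(pam_spec.motif)]):
                continue
            mism = sum(a != b for a, b in zip(protospacer, seq[s:s + g]))
            if mism <= max_mismatches:
                count += 1
    return count


def sites_table(sites: list[ProtospacerSite]) -> pd.DataFrame:
    """Tabular view of scanned sites (for the TSV report)."""
    return pd.DataFrame([{
        "start": s.start, "end": s.end, "strand": s.strand,
        "protospacer": s.protospacer, "pam": s.pam,
        "exon_index": s.exon_index,
        "specificity": s.specificity.value if s.specificity else None,
        "gc_percent": round(100 * s.gc_fraction, 1),
        "cut_position": s.cut_position(),
    } for s in sites])
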