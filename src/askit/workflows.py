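"""End-to-end convenience pipelines tying the modules together.

These are thin orchestration functions used by the CLI and by scripted
analyses: locus -> haplotype pair -> guide design, and editing readouts
-> genotype calls -> founder summary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotyping import (NON_TARGET, TARGET, FounderSummary, GenotypeCall,
                         assign_clone, call_fragment_genotype,
                         summarize_founders)
from .guides import (FilterRules, GuidePair, NoPairResult, PamSpec,
                     ProtospacerSite, classify_specificity, filter_guides,
                     scan_protospacers)
from .haplotypes import GeneModel, Haplotype, VariantTable, build_haplotype
from .simulate import EditingSim


def build_haplotype_pair(gene: GeneModel, variants: VariantTable,
                         target_strain: str = "donor",
                         reference_strain: str = "reference",
                         ) -> tuple[Haplotype, Haplotype]:
    """(target, other) haplotypes: the donor allele carries the variants,
    the other allele is the reference itself (identity coordinate map)."""
    target = build_haplotype(gene, variants, target_strain)
    other = build_haplotype(gene, VariantTable([], source=reference_strain),
                            reference_strain)
    return target, other


@dataclass
class DesignResult:
    target: Haplotype
    other: Haplotype
    sites: list[ProtospacerSite]        # all scanned+classified sites
    filtered: list[ProtospacerSite]     # after quality filters
    pair: GuidePair | NoPairResult


def design_guides(gene: GeneModel, variants: VariantTable,
                  pam_spec: PamSpec = PamSpec(),
                  rules: FilterRules = FilterRules(),
                  target_strain: str = "donor",
                  allow_protospacer_variant: bool = False) -> DesignResult:
    """Full allele-specific design: scan the donor haplotype, classify
    every site against the other allele, filter, and select the pair."""
    from .guides import select_guide_pair

    target, other = build_haplotype_pair(gene, variants, target_strain)
    sites = scan_protospacers(target, pam_spec)
    for s in sites:
        classify_specificity(s, target, other, pam_spec)
    filtered = filter_guides(sites, gene, target, rules)
    pair = select_guide_pair(filtered, gene,
                             allow_protospacer_variant=allow_protospacer_variant)
    return DesignResult(target, other, sites, filtered, pair)


def genotype_founders(sim: EditingSim, gene: GeneModel, target: Haplotype,
                      other: Haplotype, n_newborns: int,
                      evidence: str = "clone_sequence",
                      ) -> tuple[list[GenotypeCall], FounderSummary]:
    """Run the genotyping pipeline over simulated (or file-loaded)
    editing readouts and summarize the founder cohort.

    ``evidence`` selects the assay: ``clone_sequence`` assigns each
    Sanger clone to its allele of origin (required to score
    mistargeting when both alleles amplify at the same length);
    ``fragment`` uses peak sizes only.
    """
    calls: list[GenotypeCall] = []
    if evidence == "fragment":
        for assay in sim.assays:
            calls.extend(call_fragment_genotype(sim.peaks, assay))
    elif evidence == "clone_sequence":
        by_assay = {a.assay_id: a for a in sim.assays}
        for sample, assay_id, _clone, seq in sim.clones:
            assay = by_assay[assay_id]
            calls.append(assign_clone(seq, sample, assay, target, other,
                                      [sim.cut_sites[assay_id]], gene))
    else:
        raise ValueError(f"unknown evidence type {evidence!r}")
    return calls, summarize_founders(calls, n_newborns)
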