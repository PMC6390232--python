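"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the experimental structure end to end:

* :func:`make_strain_pair` — a two-strain gene locus: a random reference
  haplotype plus a variant table with background SNPs at a configurable
  per-bp rate, optional strain indel, and *planted* PAM-gain SNPs that
  provably create an NGG on the alternate (donor) haplotype where the
  reference fails the motif.
* :func:`simulate_backcross` — an N2 backcross panel: one recombinant F1
  gamete per chromosome per individual (Haldane probabilities, no
  interference) and a binary phenotype driven by a single dominant donor
  locus with configurable penetrance and phenocopy rate.
* :func:`simulate_editing` — founder editing outcomes: each allele of
  each embryo is cut per-guide with its configured probability, receives
  an indel at the cut site (3 bp 5' of the PAM), and is read out both as
  fluorescent-PCR peak sizes (with Gaussian sizing noise) and as TA-clone
  Sanger reads.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genotyping import (NON_TARGET, TARGET, AmpliconAssay, FragmentPeak,
                         predict_amplicons)
from .guides import PamSpec, ProtospacerSite
from .haplotypes import (Exon, GeneModel, Haplotype, Variant, VariantTable,
                         build_haplotype, reverse_complement)
from .linkage import GeneticMap, Marker, N2Panel, haldane_r

_BASES = np.array(list("ACGT"))


def _default_indel_sizes() -> dict[int, float]:
    # small deletions dominate real Cas9 NHEJ outcomes
    w = {s: 6.0 / abs(s) for s in range(-12, 0)}
    w.update({s: 1.5 / s for s in range(1, 7)})
    z = sum(w.values())
    return {s: v / z for s, v in w.items()}


@dataclass
class SimConfig:
    """Study conditions for all three generators (defaults mirror the
    validated experiment: 559 N2 mice, full penetrance, 10 injected-
    embryo newborns, 80% per-allele cutting, zero non-target cutting)."""

    seed: int = 0
    # locus
    locus_length: int = 8000
    n_exons: int = 19
    exon_length: int = 150
    snp_rate: float = 0.006
    planted_pam_gain_snps: list[tuple[int, int]] = field(
        default_factory=lambda: [(4, 1), (11, 1)])
    planted_strain_indel: tuple[int, int] | None = None
    # backcross
    n_individuals: int = 559
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    # editing
    n_embryos: int = 10
    p_edit_target: float = 0.8
    p_edit_nontarget: float = 0.0
    indel_size_distribution: dict[int, float] = field(
        default_factory=_default_indel_sizes)
    peak_noise_sd: float = 0.3
    n_clones: int = 10

    def __post_init__(self):
        for p in (self.penetrance, self.phenocopy_rate,
                  self.p_edit_target, self.p_edit_nontarget):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.snp_rate < 0 or self.peak_noise_sd < 0:
            raise ValueError("rates must be >= 0")
        if 0 in self.indel_size_distribution:
            raise ValueError("indel size 0 is not an indel")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted PAM-gain SNP."""

    exon_index: int
    window_start_ref: int      # reference coordinate of protospacer start
    snp_pos_ref: int           # reference coordinate of the PAM-gain SNP
    protospacer: str
    strand: str = "+"


@dataclass
class StrainPairTruth:
    planted_sites: list[PlantedSite]
    strain_indel: tuple[int, int] | None = None


def _random_protospacer(rng: np.random.Generator, length: int = 20) -> str:
    """Random protospacer passing the default quality filters
    (GC 25-75%, no TTTT run)."""
    while True:
        p = "".join(rng.choice(_BASES, size=length))
        gc = (p.count("G") + p.count("C")) / length
        if 0.3 <= gc <= 0.7 and "TTTT" not in p:
            return p


def make_strain_pair(config: SimConfig,
                     ) -> tuple[GeneModel, VariantTable, StrainPairTruth]:
    """Generate a reference locus and the donor-strain variant table.

    Each planted PAM-gain SNP rewrites a 23-nt exonic window so the
    reference PAM triplet reads NGA (failing NGG) and the SNP turns it
    into NGG on the donor haplotype; the planted window is shielded from
    background SNPs so the site is provably target-only.
    """
    rng = np.random.default_rng(config.seed)
    L = config.locus_length
    seq = rng.choice(_BASES, size=L)

    # evenly spaced exons, CDS length forced to a multiple of 3
    total_exonic = config.n_exons * config.exon_length
    if total_exonic >= L:
        raise ValueError("locus too short for requested exons")
    gap = (L - total_exonic) // (config.n_exons + 1)
    exons = []
    cursor = gap
    for i in range(config.n_exons):
        end = cursor + config.exon_length
        if i == config.n_exons - 1:
            end -= (config.n_exons * config.exon_length) % 3
        exons.append((cursor, end))
        cursor = end + gap

    window = 23  # 20-nt protospacer + NGG
    planted: list[PlantedSite] = []
    variants: list[Variant] = []
    shielded: list[tuple[int, int]] = []
    for exon_index, count in config.planted_pam_gain_snps:
        s, e = exons[exon_index]
        if e - s < count * (window + 2):
            raise ValueError(
                f"exon {exon_index} too short for {count} PAM-gain SNPs")
        for k in range(count):
            ws = s + 1 + k * (window + 2)
            proto = _random_protospacer(rng)
            seq[ws:ws + 20] = list(proto)
            pam_n = rng.choice(_BASES)
            seq[ws + 20:ws + 23] = [pam_n, "G", "A"]
            snp_pos = ws + 22
            variants.append(Variant(snp_pos, "A", "G"))
            planted.append(PlantedSite(exon_index, ws, snp_pos, proto))
            shielded.append((ws - 1, ws + window + 1))

    indel = config.planted_strain_indel
    if indel is not None:
        pos, size = indel
        if size < 0:
            ref_allele = "".join(seq[pos:pos + 1 - size])
            variants.append(Variant(pos, ref_allele, ref_allele[0]))
            shielded.append((pos, pos + 1 - size))
        else:
            ins = "".join(rng.choice(_BASES, size=size))
            variants.append(Variant(pos, str(seq[pos]), str(seq[pos]) + ins))
            shielded.append((pos, pos + 1))

    occupied = np.zeros(L, dtype=bool)
    for a, b in shielded:
        occupied[a:b] = True
    bg = np.flatnonzero((rng.random(L) < config.snp_rate) & ~occupied)
    for p in bg:
        ref_b = str(seq[p])
        alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
        variants.append(Variant(int(p), ref_b, alt_b))

    gene = GeneModel("locus", "".join(seq),
                     [Exon(s, e, True) for s, e in exons])
    table = VariantTable(variants, source="donor")
    table.validate_against(gene)
    return gene, table, StrainPairTruth(planted, indel)


# ---------------------------------------------------------------------------
# Backcross panels


def default_genome_map(n_chromosomes: int = 19, n_markers: int = 5,
                       spacing_cM: float = 20.0) -> GeneticMap:
    """An evenly spaced marker map over the autosomes."""
    return GeneticMap({
        str(c): {f"D{c}M{j + 1}": j * spacing_cM for j in range(n_markers)}
        for c in range(1, n_chromosomes + 1)
    })


def simulate_backcross(gmap: GeneticMap, causal_position: tuple[str, float],
                       config: SimConfig,
                       seed: int | None = None) -> N2Panel:
    """Simulate an N2 panel with a single dominant causal locus.

    Each individual receives one recombinant F1 gamete per chromosome
    (independent Haldane recombination per marker interval); phenotype
    is Bernoulli(penetrance) for causal-locus heterozygotes and
    Bernoulli(phenocopy_rate) for recurrent homozygotes.
    """
    chrom_c, pos_c = str(causal_position[0]), float(causal_position[1])
    if chrom_c not in gmap.positions:
        raise ValueError(f"causal chromosome {chrom_c!r} not on the map")
    cpos = gmap.chrom_positions(chrom_c)
    if not (cpos.min() <= pos_c <= cpos.max()):
        raise ValueError(f"causal position {pos_c} cM is off the {chrom_c} map")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_individuals
    markers: list[Marker] = []
    columns: list[np.ndarray] = []
    causal_geno = None
    for chrom, posdict in gmap.positions.items():
        ids = list(posdict)
        pos = np.array([posdict[i] for i in ids])
        loci = list(pos)
        if chrom == chrom_c:
            loci.append(pos_c)
        loci_sorted = np.unique(np.array(loci))
        g = np.empty((n, len(loci_sorted)), dtype=np.int8)
        g[:, 0] = rng.integers(0, 2, size=n)
        r = haldane_r(np.diff(loci_sorted))
        for k, rk in enumerate(r):
            flip = rng.random(n) < rk
            g[:, k + 1] = g[:, k] ^ flip
        col_of = {p: k for k, p in enumerate(loci_sorted)}
        if chrom == chrom_c:
            causal_geno = g[:, col_of[pos_c]]
        for mid, p in zip(ids, pos):
            markers.append(Marker(mid, chrom, float(p)))
            columns.append(g[:, col_of[p]])
    het = causal_geno.astype(bool)
    pheno = np.where(het, rng.random(n) < config.penetrance,
                     rng.random(n) < config.phenocopy_rate).astype(np.int8)
    return N2Panel(markers, np.column_stack(columns), pheno)


# ---------------------------------------------------------------------------
# Editing outcomes


@dataclass
class EmbryoTruth:
    sample_id: str
    # assay_id -> role -> net indel size (0 = uncut)
    edits: dict[str, dict[str, int]]

    @property
    def is_carrier(self) -> bool:
        return any(s != 0 for a in self.edits.values() for s in a.values())

    @property
    def mistargeted(self) -> bool:
        return any(a[NON_TARGET] != 0 for a in self.edits.values())


@dataclass
class EditingSim:
    assays: list[AmpliconAssay]
    cut_sites: dict[str, int]                 # assay_id -> target-hap cut pos
    peaks: list[FragmentPeak]
    clones: list[tuple[str, str, str, str]]   # sample, assay, clone, sequence
    truth: list[EmbryoTruth]


def design_assay(assay_id: str, gene: GeneModel, target_hap: Haplotype,
                 other_hap: Haplotype, cut_site_target: int,
                 flank: int = 80, primer_len: int = 20) -> AmpliconAssay:
    """Place a FAM-primer pair around a cut site, on variant-free windows
    so both alleles amplify, and predict per-allele product sizes."""
    ref_c = target_hap.coord_map.to_ref(cut_site_target)
    var_spans = [(v.pos, v.end) for v in target_hap.applied_variants]

    def clean(a: int, b: int) -> bool:
        return not any(s < b and a < e for s, e in var_spans)

    def pick(start: int, step: int) -> str:
        for off in range(0, 200, 5):
            a = start - step * off
            b = a + primer_len
            if 0 <= a and b <= len(gene.sequence) and clean(a, b):
                return gene.sequence[a:b]
        raise ValueError(f"no variant-free primer window near {start}")

    fwd = pick(ref_c - flank - primer_len, 1)
    rev = reverse_complement(pick(ref_c + flank, -1))
    return predict_amplicons(assay_id, fwd, rev,
                             {TARGET: target_hap, NON_TARGET: other_hap})


def simulate_editing(gene: GeneModel, target_hap: Haplotype,
                     other_hap: Haplotype,
                     guide_sites: list[ProtospacerSite],
                     config: SimConfig,
                     seed: int | None = None) -> EditingSim:
    """Simulate founder editing, fragment peaks, and TA-clone reads.

    Per embryo, each allele x guide is cut with its configured
    probability; cut alleles receive one indel from the size
    distribution at the cut site.  Peaks are per-allele amplicon
    lengths with Gaussian sizing noise; clones sample the two alleles
    evenly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = np.array(sorted(config.indel_size_distribution))
    probs = np.array([config.indel_size_distribution[s] for s in sizes])
    probs = probs / probs.sum()

    assays, cut_sites = [], {}
    for i, site in enumerate(guide_sites):
        aid = f"amp{i + 1}"
        cut = site.cut_position()
        assays.append(design_assay(aid, gene, target_hap, other_hap, cut))
        cut_sites[aid] = cut

    haps = {TARGET: target_hap, NON_TARGET: other_hap}
    p_cut = {TARGET: config.p_edit_target, NON_TARGET: config.p_edit_nontarget}

    peaks: list[FragmentPeak] = []
    clones: list[tuple[str, str, str, str]] = []
    truth: list[EmbryoTruth] = []
    for e in range(config.n_embryos):
        sample = f"F1-{e + 1:03d}"
        edits: dict[str, dict[str, int]] = {}
        for assay in assays:
            cut_t = cut_sites[assay.assay_id]
            edits[assay.assay_id] = {}
            seqs = {}
            for role, hap in haps.items():
                lo, hi = assay.region[role]
                amp = hap.sequence[lo:hi]
                if role == TARGET:
                    cut_local = cut_t - lo
                else:
                    r = target_hap.coord_map.to_ref(cut_t)
                    cut_local = other_hap.coord_map.to_hap_nearest(r) - lo
                net = 0
                if rng.random() < p_cut[role]:
                    net = int(rng.choice(sizes, p=probs))
                    if net < 0:
                        a = cut_local + net // 2
                        amp = amp[:a] + amp[a - net:]
                    else:
                        ins = "".join(rng.choice(_BASES, size=net))
                        amp = amp[:cut_local] + ins + amp[cut_local:]
                edits[assay.assay_id][role] = net
                seqs[role] = amp
                peaks.append(FragmentPeak(
                    sample, assay.assay_id,
                    size=len(amp) + float(rng.normal(0, config.peak_noise_sd))
                    if config.peak_noise_sd else float(len(amp)),
                    height=float(rng.uniform(800, 1200))))
            for k in range(config.n_clones):
                role = TARGET if rng.random() < 0.5 else NON_TARGET
                clones.append((sample, assay.assay_id, f"clone{k + 1}",
                               seqs[role]))
        truth.append(EmbryoTruth(sample, edits))
    return EditingSim(assays, cut_sites, peaks, clones, truth)


# ---------------------------------------------------------------------------
# File emission (the exact dialects the other modules consume)


def write_fasta(gene: GeneModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{gene.locus_id}\n")
        for i in range(0, len(gene.sequence), 70):
            fh.write(gene.sequence[i:i + 70] + "\n")


def write_bed(gene: GeneModel, path: str) -> None:
    with open(path, "w") as fh:
        for ex in gene.exons:
            fh.write(f"{gene.locus_id}\t{ex.start}\t{ex.end}\texon\t0\t"
                     f"{gene.cds_strand}\n")


def write_vcf(table: VariantTable, gene: GeneModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gene.locus_id},length={len(gene.sequence)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in table:
            fh.write(f"{gene.locus_id}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\n")


def write_peaks(peaks: list[FragmentPeak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tassay_id\tsize\theight\n")
        for p in peaks:
            fh.write(f"{p.sample_id}\t{p.assay_id}\t{p.size:.2f}"
                     f"\t{p.height:.1f}\n")


def write_clones(clones: list[tuple[str, str, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for sample, assay, clone, seq in clones:
            fh.write(f">{sample}|{assay}|{clone}\n{seq}\n")


def write_truth(truth: list[EmbryoTruth], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([{"sample_id": t.sample_id, "edits": t.edits}
                   for t in truth], fh, indent=1)
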