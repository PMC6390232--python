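"""Dominant binary-trait linkage mapping in an N2 backcross.

In an N2 design (F1 x recurrent parent), every autosomal locus is
either heterozygous (one donor allele) or homozygous recurrent, each
with probability 1/2, so a fully penetrant dominant donor allele
segregates 1:1.  The mapping model scores each genome position by the
binomial likelihood of the binary phenotype under two penetrance
parameters — p1 = P(phenotype | heterozygous), p0 = P(phenotype |
homozygous recurrent) — with the latent genotype at positions between
markers handled by EM over flanking-marker probabilities (Haldane map
function, no interference).  The LOD score is the log10 ratio of that
maximized likelihood to a single-probability null.  Genome-wide
significance comes from permuting phenotype labels and taking the
empirical quantile of the permuted maximum LOD.  Recombinant
individuals inside the mapped interval then tighten the localization:
under full dominance, phenotypic mice must carry the donor allele at
the causal position and non-phenotypic mice must not, so each
recombinant's genotypes restrict where the causal gene can lie.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

log = logging.getLogger(__name__)

MISSING = -1
_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Map functions (Haldane, no interference)


def haldane_d(r: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction -> map distance in cM: d = -50 ln(1 - 2r)."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


def haldane_r(d: float | np.ndarray) -> float | np.ndarray:
    """Map distance in cM -> recombination fraction: r = (1 - e^(-d/50))/2."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d, dtype=float) / 50.0))


# ---------------------------------------------------------------------------
# Panel container and I/O


@dataclass(frozen=True)
class Marker:
    marker_id: str
    chromosome: str
    position_cM: float


@dataclass
class N2Panel:
    """Marker genotype matrix plus binary phenotype for backcross progeny.

    Genotype codes: 0 = homozygous recurrent, 1 = heterozygous,
    -1 = missing (the design admits no donor homozygotes).
    """

    markers: list[Marker]
    genotypes: np.ndarray   # (n_individuals, n_markers) int8
    phenotype: np.ndarray   # (n_individuals,) 0/1
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if m != len(self.markers):
            raise ValueError("genotype matrix width != number of markers")
        if len(self.phenotype) != n:
            raise ValueError("phenotype length != number of individuals")
        if not self.individual_ids:
            self.individual_ids = [f"N2-{i + 1}" for i in range(n)]
        bad = set(np.unique(self.genotypes)) - {0, 1, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        if set(np.unique(self.phenotype)) - {0, 1}:
            raise ValueError("phenotype must be binary 0/1")
        for chrom in self.chromosomes:
            pos = [m_.position_cM for m_ in self.markers
                   if m_.chromosome == chrom]
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"markers on {chrom} not sorted by position")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.chromosome)
        return list(seen)

    def marker_index(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m.marker_id == marker_id:
                return i
        raise KeyError(f"marker {marker_id!r} not in panel")

    def chromosome_slice(self, chrom: str) -> list[int]:
        return [i for i, m in enumerate(self.markers) if m.chromosome == chrom]


_CODE = {"A": 0, "H": 1, "-": MISSING}
_CODE_INV = {v: k for k, v in _CODE.items()}


def read_panel(path: str) -> N2Panel:
    """Read a panel TSV: header ``id  phenotype  marker:chrom:cM ...``;
    one row per individual with genotype codes A (hom-recurrent),
    H (het), - (missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    markers = []
    for col in df.columns[2:]:
        mid, chrom, pos = col.rsplit(":", 2)
        markers.append(Marker(mid, chrom, float(pos)))
    geno = np.array([[_CODE[v] for v in df[c]] for c in df.columns[2:]],
                    dtype=np.int8).T
    return N2Panel(markers, geno, df.iloc[:, 1].astype(int).to_numpy(),
                   list(df.iloc[:, 0]))


def write_panel(panel: N2Panel, path: str) -> None:
    cols = {"id": panel.individual_ids,
            "phenotype": panel.phenotype.astype(int)}
    for j, m in enumerate(panel.markers):
        cols[f"{m.marker_id}:{m.chromosome}:{m.position_cM:g}"] = [
            _CODE_INV[int(g)] for g in panel.genotypes[:, j]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segregation test


def test_segregation(n_phenotypic: int, n_total: int
                     ) -> tuple[float, float, float]:
    """Chi-square goodness of fit of phenotype counts against 1:1.

    Returns (chi_square, p_value, phenotypic fraction); 1 df.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_phenotypic <= n_total:
        raise ValueError("n_phenotypic must lie in [0, n_total]")
    e = n_total / 2.0
    chi2 = (n_phenotypic - e) ** 2 / e + ((n_total - n_phenotypic) - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, n_phenotypic / n_total


# ---------------------------------------------------------------------------
# Genetic map estimation


@dataclass
class GeneticMap:
    """Per-chromosome marker positions in cM (Haldane map function)."""

    positions: dict[str, dict[str, float]]  # chrom -> marker_id -> cM
    map_function: str = "haldane"

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return np.array(list(self.positions[chrom].values()))


def estimate_map(panel: N2Panel, r_cap: float = 0.49) -> GeneticMap:
    """Estimate a genetic map from adjacent-marker recombination fractions.

    For each adjacent pair, r-hat = recombinant pairs / informative pairs
    (individuals genotyped at both), converted to cM with the Haldane
    function; r-hat is capped at ``r_cap`` (with a warning) because the
    map distance diverges at r = 1/2.
    """
    positions: dict[str, dict[str, float]] = {}
    for chrom in panel.chromosomes:
        idx = panel.chromosome_slice(chrom)
        for j in idx:
            if (panel.genotypes[:, j] == MISSING).all():
                raise ValueError(
                    f"marker {panel.markers[j].marker_id} has no genotypes")
        pos: dict[str, float] = {panel.markers[idx[0]].marker_id: 0.0}
        acc = 0.0
        for a, b in zip(idx, idx[1:]):
            ga, gb = panel.genotypes[:, a], panel.genotypes[:, b]
            inf = (ga != MISSING) & (gb != MISSING)
            if not inf.any():
                raise ValueError(
                    f"no informative pairs between "
                    f"{panel.markers[a].marker_id} and {panel.markers[b].marker_id}")
            r = float(np.mean(ga[inf] != gb[inf]))
            if r > r_cap:
                log.warning("r-hat %.3f between %s and %s capped at %.2f "
                            "(markers look unlinked)", r,
                            panel.markers[a].marker_id,
                            panel.markers[b].marker_id, r_cap)
                r = r_cap
            acc += float(haldane_d(r))
            pos[panel.markers[b].marker_id] = acc
        positions[chrom] = pos
    return GeneticMap(positions)


def map_from_panel_positions(panel: N2Panel) -> GeneticMap:
    """Take the marker positions annotated in the panel as the map."""
    positions: dict[str, dict[str, float]] = {}
    for m in panel.markers:
        positions.setdefault(m.chromosome, {})[m.marker_id] = m.position_cM
    return GeneticMap(positions)


# ---------------------------------------------------------------------------
# Interval mapping (two-penetrance binomial model, EM over latent genotype)


def _het_prior(panel: N2Panel, gmap: GeneticMap, chrom: str,
               grid: np.ndarray) -> np.ndarray:
    """P(heterozygous at each grid position | flanking marker genotypes).

    Missing flanks are marginalized by conditioning on the nearest
    informative marker on each side; individuals with no informative
    marker on the chromosome get the population prior 1/2.
    """
    idx = panel.chromosome_slice(chrom)
    mpos = np.array([gmap.positions[chrom][panel.markers[j].marker_id]
                     for j in idx])
    G = panel.genotypes[:, idx]
    n = G.shape[0]
    prior = np.full((len(grid), n), 0.5)
    for i in range(n):
        inf = np.flatnonzero(G[i] != MISSING)
        if inf.size == 0:
            continue
        p_inf = mpos[inf]
        g_inf = G[i, inf].astype(float)
        right_idx = np.searchsorted(p_inf, grid, side="left")
        left_idx = np.searchsorted(p_inf, grid, side="right") - 1
        has_l = left_idx >= 0
        has_r = right_idx < inf.size
        # left-flank-only term P(x=1 | gL)
        li = np.clip(left_idx, 0, inf.size - 1)
        rl = haldane_r(grid - p_inf[li])
        pl = np.where(g_inf[li] == 1, 1 - rl, rl)
        # right-flank likelihood P(gR | x)
        ri = np.clip(right_idx, 0, inf.size - 1)
        rr = haldane_r(p_inf[ri] - grid)
        pr1 = np.where(g_inf[ri] == 1, 1 - rr, rr)      # P(gR | x=1)
        pr0 = np.where(g_inf[ri] == 1, rr, 1 - rr)      # P(gR | x=0)
        num = np.where(has_l, pl, 0.5) * np.where(has_r, pr1, 1.0)
        den = num + np.where(has_l, 1 - pl, 0.5) * np.where(has_r, pr0, 1.0)
        prior[:, i] = num / den
    return prior


def _em_lod(prior: np.ndarray, y: np.ndarray,
            max_iter: int = 200, tol: float = 1e-10,
            starts: tuple[tuple[float, float], ...] = ((0.8, 0.2), (0.2, 0.8)),
            ) -> np.ndarray:
    """Vectorized EM for the two-penetrance model.

    prior: (G, n) P(het) per grid position x individual; y: (n,) or
    (B, n) phenotype vectors.  Returns LOD of shape (G,) or (B, G).
    The null (single overall probability) is a boundary point of the
    alternative, so LOD is clipped at 0.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = y[None, :] if single else y                      # (B, n)
    B, n = Y.shape
    G = prior.shape[0]
    pr = prior[None, :, :]                               # (1, G, n)
    Yb = Y[:, None, :]                                   # (B, 1, n)

    k = Y.sum(axis=1)
    pbar = k / n
    ll0 = xlogy(k, pbar) + xlogy(n - k, 1 - pbar)        # (B,)

    best_ll = np.full((B, G), -np.inf)
    for p1_0, p0_0 in starts:
        p1 = np.full((B, G), p1_0)
        p0 = np.full((B, G), p0_0)
        prev = np.full((B, G), -np.inf)
        for _ in range(max_iter):
            f1 = Yb * p1[..., None] + (1 - Yb) * (1 - p1[..., None])
            f0 = Yb * p0[..., None] + (1 - Yb) * (1 - p0[..., None])
            a = pr * f1
            den = a + (1 - pr) * f0                      # (B, G, n)
            ll = np.log(np.maximum(den, 1e-300)).sum(axis=2)
            w = a / np.maximum(den, 1e-300)
            sw = w.sum(axis=2)
            swy = (w * Yb).sum(axis=2)
            cw = n - sw
            cwy = k[:, None] - swy
            p1 = np.where(sw > 0, swy / np.maximum(sw, 1e-300),
                          pbar[:, None])
            p0 = np.where(cw > 0, cwy / np.maximum(cw, 1e-300),
                          pbar[:, None])
            if np.max(np.abs(ll - prev)) < tol:
                prev = ll
                break
            prev = ll
        best_ll = np.maximum(best_ll, prev)

    lod = np.maximum((best_ll - ll0[:, None]) / _LN10, 0.0)
    return lod[0] if single else lod


@dataclass
class LODCurve:
    grid: pd.DataFrame                    # chromosome, position_cM, lod
    peak: tuple[str, float, float]        # (chromosome, position, LOD)
    threshold: float | None = None

    @property
    def max_lod(self) -> float:
        return self.peak[2]


def _scan_grid(gmap: GeneticMap, chrom: str, step_cM: float) -> np.ndarray:
    pos = gmap.chrom_positions(chrom)
    lo, hi = float(pos.min()), float(pos.max())
    grid = np.unique(np.concatenate([pos, np.arange(lo, hi + 1e-9, step_cM)]))
    return grid


def interval_scan(panel: N2Panel, gmap: GeneticMap, step_cM: float = 1.0,
                  em_max_iter: int = 200, em_tol: float = 1e-10,
                  ) -> LODCurve:
    """Genome scan of the binary trait by EM interval mapping.

    At every grid position (markers plus ``step_cM`` pseudomarkers) the
    two-penetrance likelihood is maximized by EM over the latent
    genotype and compared with the single-probability null; LOD =
    log10 of that ratio.  A monomorphic phenotype gives LOD 0
    everywhere (with a warning).
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    y = panel.phenotype.astype(float)
    if len(np.unique(y)) < 2:
        log.warning("monomorphic phenotype: LOD is identically 0")
    rows = []
    peak = (None, 0.0, -1.0)
    for chrom in panel.chromosomes:
        grid = _scan_grid(gmap, chrom, step_cM)
        prior = _het_prior(panel, gmap, chrom, grid)
        lod = _em_lod(prior, y, max_iter=em_max_iter, tol=em_tol)
        for x, l in zip(grid, lod):
            rows.append((chrom, float(x), float(l)))
        j = int(np.argmax(lod))
        if lod[j] > peak[2]:
            peak = (chrom, float(grid[j]), float(lod[j]))
    df = pd.DataFrame(rows, columns=["chromosome", "position_cM", "lod"])
    return LODCurve(df, peak)


def permutation_threshold(panel: N2Panel, gmap: GeneticMap,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, step_cM: float = 1.0,
                          em_max_iter: int = 60, em_tol: float = 1e-6,
                          batch: int = 50) -> float:
    """Genome-wide LOD significance threshold by phenotype permutation.

    Phenotype labels are shuffled ``n_perm`` times with a seeded
    generator; the (1 - alpha) empirical (right-continuous) quantile of
    the permuted genome-wide maximum LOD is returned.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    y = panel.phenotype.astype(float)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])

    priors = [(_het_prior(panel, gmap, chrom, _scan_grid(gmap, chrom, step_cM)))
              for chrom in panel.chromosomes]
    maxima = np.zeros(n_perm)
    for b0 in range(0, n_perm, batch):
        Yb = perms[b0:b0 + batch]
        mx = np.full(Yb.shape[0], -np.inf)
        for prior in priors:
            lod = _em_lod(prior, Yb, max_iter=em_max_iter, tol=em_tol)
            mx = np.maximum(mx, lod.max(axis=1))
        maxima[b0:b0 + len(mx)] = mx
    order = np.sort(maxima)
    kth = max(int(np.ceil((1 - alpha) * n_perm)), 1)
    return float(order[kth - 1])


# ---------------------------------------------------------------------------
# Recombinant screening and fine mapping


def find_recombinants(panel: N2Panel, left_marker: str,
                      right_marker: str) -> list[str]:
    """Individuals with a crossover between two markers (discordant
    genotypes); individuals missing at either marker are excluded and
    counted in the log."""
    li, ri = panel.marker_index(left_marker), panel.marker_index(right_marker)
    ml, mr = panel.markers[li], panel.markers[ri]
    if ml.chromosome != mr.chromosome:
        raise ValueError(f"{left_marker} and {right_marker} are on "
                         f"different chromosomes")
    if ml.position_cM > mr.position_cM:
        raise ValueError(f"{left_marker} is not left of {right_marker}")
    gl, gr = panel.genotypes[:, li], panel.genotypes[:, ri]
    ok = (gl != MISSING) & (gr != MISSING)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("excluded %d individuals missing at %s or %s",
                 n_excluded, left_marker, right_marker)
    rec = ok & (gl != gr)
    return [panel.individual_ids[i] for i in np.flatnonzero(rec)]


@dataclass
class Candidate:
    gene: str
    expression: float | None
    unknown_expression: bool = False


@dataclass
class IntervalResult:
    left_marker: str | None
    right_marker: str | None
    left_cM: float | None
    right_cM: float | None
    supporting_recombinants: list[str]
    inconsistent_individuals: list[str]
    consistent: bool
    genes_in_interval: list[str] = field(default_factory=list)
    candidates: list[Candidate] = field(default_factory=list)


def minimal_interval(panel: N2Panel, chromosome: str,
                     candidate_region: tuple[float, float],
                     exclude_inconsistent: bool = False) -> IntervalResult:
    """Tightest flanking-marker interval consistent with every informative
    individual, assuming a fully dominant donor allele.

    Phenotypic individuals must be heterozygous at the causal position
    and non-phenotypic ones homozygous recurrent, so each individual
    permits the set of region markers where its genotype matches that
    requirement; the causal position lies in the intersection of the
    permitted sets, extended into the adjacent inter-marker intervals.
    Individuals contradicting every position (phenocopies or genotyping
    errors) make the intersection empty: they are reported, and excluded
    from a recomputation only when ``exclude_inconsistent`` is set.
    """
    lo, hi = candidate_region
    idx = [j for j in panel.chromosome_slice(chromosome)
           if lo <= panel.markers[j].position_cM <= hi]
    if len(idx) < 2:
        raise ValueError("candidate region covers fewer than 2 markers")
    mk = [panel.markers[j] for j in idx]
    G = panel.genotypes[:, idx]
    y = panel.phenotype

    permitted = (G == y[:, None]) | (G == MISSING)     # (n, K)
    informative = (G != MISSING).any(axis=1)

    def solve(mask: np.ndarray):
        inter = permitted[mask].all(axis=0) if mask.any() else \
            np.ones(len(idx), dtype=bool)
        return inter

    inter = solve(informative)
    inconsistent: list[str] = []
    if not inter.any():
        # individuals not permitting the consensus (most-permitted) marker
        counts = permitted[informative].sum(axis=0)
        consensus = int(np.argmax(counts))
        bad = informative & ~permitted[:, consensus]
        inconsistent = [panel.individual_ids[i] for i in np.flatnonzero(bad)]
        if not exclude_inconsistent:
            return IntervalResult(None, None, None, None, [],
                                  inconsistent, consistent=False)
        keep = informative & permitted[:, consensus]
        inter = solve(keep)
        if not inter.any():
            return IntervalResult(None, None, None, None, [],
                                  inconsistent, consistent=False)

    lm = int(np.argmax(inter))
    rm = len(inter) - 1 - int(np.argmax(inter[::-1]))
    left = mk[lm - 1] if lm > 0 else mk[0]
    right = mk[rm + 1] if rm < len(inter) - 1 else mk[-1]
    recs = [panel.individual_ids[i] for i in np.flatnonzero(
        informative & (~permitted).any(axis=1))]
    return IntervalResult(left.marker_id, right.marker_id,
                          left.position_cM, right.position_cM,
                          supporting_recombinants=recs,
                          inconsistent_individuals=inconsistent,
                          consistent=not inconsistent)


def filter_candidates(genes_in_interval: list[str],
                      expression_table: dict[str, float],
                      threshold: float) -> list[Candidate]:
    """Keep genes expressed at or above ``threshold`` in the relevant cell
    type; genes absent from the table are retained with an
    unknown-expression flag (conservative), order preserved."""
    out = []
    for g in genes_in_interval:
        if g not in expression_table:
            out.append(Candidate(g, None, unknown_expression=True))
        elif expression_table[g] >= threshold:
            out.append(Candidate(g, expression_table[g]))
    return out
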