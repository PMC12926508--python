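"""Synthetic mutation-accumulation experiment generator.

Generates a complete fake study with a known ground truth: a reference
genome with gene models, a heterozygous diploid ancestor, MA lines evolved
by planting de novo SNMs, small indels, and loss-of-heterozygosity tracts
(gene conversion or hemizygous deletion), noisy per-site evidence (depth,
allele counts, GATK-style quality annotations), and population
allele-frequency tables.  The truth table is the recovery oracle for the
calling pipeline.

Defaults mirror the eight-line *Daphnia obtusa* MA experiment: eight lines
at ~480-510 generations, ancestral heterozygosity 0.57% of sites, an SNM
rate of 2.23e-9 and indel rate of 2.75e-10 per site per generation, the
observed six-type substitution spectrum, a per-het-site LOH rate of
2.93e-5 with one event in six a hemizygous deletion, and ~79x sequencing
depth.  Genome size is scaled down (12 x 1 Mb chromosomes by default) so
the whole pipeline runs at desk scale.

A single seed governs all draws; per-stage child seeds are derived from it
so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import study
from .reference import (BASE_CODE, BASES, COMPLEMENT_CODE, GeneModel,
                        ReferenceBundle, decode_seq)
from .variants import (DepthTracks, HET, HOM_ALT, HOM_REF, SiteTable)

# six-type weights are *conditional* substitution rates (per source-base
# class): they set both where mutations land (GC vs AT sites) and which
# substitution occurs there.  Defaults are the study's conditional rates.
_DEFAULT_SPECTRUM = {t: r * 1e10 for t, r in study.SIX_TYPE_RATES.items()}
_DEFAULT_OVERLAP = {"nonsynonymous": 0.22, "synonymous": 0.20, "UTR": 0.25,
                    "intron": 0.32, "intergenic": 0.36}

ARTIFACT_CLASSES = ("fs", "mq_rank_sum", "read_pos_rank_sum",
                    "allele_fraction", "min_alt_reads", "near_indel",
                    "multiallelic")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic MA experiment (defaults: study conditions,
    genome scaled down to 12 x 1 Mb)."""

    seed: int = 0
    n_chromosomes: int = 12
    chromosome_length: int = 1_000_000
    gc_content: float = study.GENOME_GC
    gene_density: float = 118.0           # genes per Mb
    n_lines: int = 8
    generations_per_line: tuple = tuple(study.GENERATIONS.values())
    het_density: float = study.ANCESTRAL_HET_FRACTION
    snm_rate: float = 2.23e-9             # per site per generation
    indel_rate: float = 2.75e-10
    spectrum: dict = field(default_factory=lambda: dict(_DEFAULT_SPECTRUM))
    loh_rate_per_het_site: float = 2.93e-5
    deletion_fraction: float = 8 / 48
    tract_length_dist: tuple = ("lognormal",
                                {"mean_log": np.log(60_000.0), "sigma_log": 1.4,
                                 "min": 1000, "max": 2_500_000})
    conversion_gc_bias: float = 0.5       # 0.5 = unbiased transmission
    mean_depth: float = 79.0
    depth_overdispersion: float = 0.5     # var = mean * (1 + od)
    genotyping_error: float = 0.0
    # gene-structure knobs
    gene_codons_range: tuple = (300, 1100)
    utr5_length: int = 150
    utr3_length: int = 200
    n_introns: int = 4
    intron_length_range: tuple = (400, 800)
    # evidence annotations
    fs_scale: float = 8.0
    rank_sum_sd: float = 2.0
    # population-frequency table
    pop_site_fraction: float = 0.01
    pop_snm_overlap: dict = field(default_factory=lambda: dict(_DEFAULT_OVERLAP))

    def __post_init__(self):
        for name in ("gc_content", "het_density", "deletion_fraction",
                     "genotyping_error", "conversion_gc_bias"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("snm_rate", "indel_rate", "loh_rate_per_het_site",
                     "gene_density", "mean_depth", "depth_overdispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_chromosomes", "chromosome_length", "n_lines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        w = np.array([self.spectrum[t] for t in
                      ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("spectrum weights must be nonnegative with positive sum")
        if len(self.generations_per_line) != self.n_lines:
            raise ValueError("generations_per_line must have n_lines entries")
        if any(g < 1 for g in self.generations_per_line):
            raise ValueError("generation counts must be >= 1")

    @property
    def line_names(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_lines)]

    @property
    def generations(self) -> dict[str, float]:
        return dict(zip(self.line_names, self.generations_per_line))

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chromosome_length


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class PlantedLoh:
    line: str
    chrom: str
    start: int
    end: int
    mechanism: str                 # conversion / deletion
    site_positions: np.ndarray     # ancestral het sites inside the tract
    resolved: np.ndarray           # retained base codes per site


@dataclass
class TruthTable:
    planted_snms: list[tuple]      # (line, chrom, pos, ref, alt)
    planted_indels: list[tuple]    # (line, chrom, pos, ref, alt)
    planted_loh: list[PlantedLoh]

    def snm_set(self) -> set:
        return {(l, c, p) for l, c, p, *_ in self.planted_snms}

    def indel_set(self) -> set:
        return {(l, c, p) for l, c, p, *_ in self.planted_indels}

    def write_tsv(self, outdir) -> None:
        import pandas as pd
        from pathlib import Path
        outdir = Path(outdir)
        pd.DataFrame(self.planted_snms,
                     columns=["line", "chrom", "pos", "ref", "alt"]) \
            .to_csv(outdir / "truth_snms.tsv", sep="\t", index=False)
        pd.DataFrame(self.planted_indels,
                     columns=["line", "chrom", "pos", "ref", "alt"]) \
            .to_csv(outdir / "truth_indels.tsv", sep="\t", index=False)
        rows = []
        for t in self.planted_loh:
            rows.append({"line": t.line, "chrom": t.chrom, "start": t.start,
                         "end": t.end, "mechanism": t.mechanism,
                         "n_sites": len(t.site_positions)})
        pd.DataFrame(rows).to_csv(outdir / "truth_loh.tsv", sep="\t", index=False)


@dataclass
class AncestralGenotypes:
    """Ancestral heterozygous SNV sites: ref on one haplotype, alt on the
    other; all remaining sites are homozygous reference."""

    het: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos, alt codes)

    @property
    def n_het(self) -> int:
        return sum(len(p) for p, _ in self.het.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self.het[chrom][0]


@dataclass
class LineEvents:
    line: str
    snms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    indels: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    loh: list[PlantedLoh] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Stage 1: reference
# ---------------------------------------------------------------------------

def generate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> ReferenceBundle:
    """Random reference with target GC and placed gene models."""
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(5)[0])
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    genes: list[GeneModel] = []
    min_span = (config.utr5_length + config.utr3_length +
                3 * (config.gene_codons_range[0] + 2) +
                config.n_introns * config.intron_length_range[0])
    if config.gene_density > 0 and config.chromosome_length < min_span + 2:
        raise ValueError(
            f"chromosome_length {config.chromosome_length} is too short to "
            f"place one gene (minimum span {min_span} bp)")
    base_cdf = np.cumsum(base_p)
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        L = config.chromosome_length
        seq = np.searchsorted(base_cdf, rng.random(L)).astype(np.uint8)
        if config.gene_density > 0:
            genes.extend(_place_genes(name, seq, config, rng))
        seqs[name] = seq
    return ReferenceBundle(sequences=seqs, genes=genes)


def _place_genes(chrom: str, seq: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> list[GeneModel]:
    L = len(seq)
    mean_codons = np.mean(config.gene_codons_range)
    mean_span = (config.utr5_length + config.utr3_length + 3 * (mean_codons + 2)
                 + config.n_introns * np.mean(config.intron_length_range))
    n_target = config.gene_density * L / 1e6
    mean_gap = max(L / max(n_target, 1e-9) - mean_span, 50.0)
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genes = []
    pos = 1 + int(rng.exponential(mean_gap / 2))
    gi = 0
    while True:
        n_codons = int(rng.integers(*config.gene_codons_range))
        intron_lens = rng.integers(*config.intron_length_range,
                                   size=config.n_introns)
        cds_len = 3 * (n_codons + 2)  # incl. start and stop codons
        span = config.utr5_length + cds_len + int(intron_lens.sum()) + \
            config.utr3_length
        if pos + span - 1 > L:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        gi += 1
        gene = _build_gene(f"{chrom}_g{gi}", chrom, strand, pos, n_codons,
                           intron_lens, config, seq, base_p, rng)
        genes.append(gene)
        pos += span + int(rng.exponential(mean_gap))
    return genes


def _build_gene(gene_id, chrom, strand, start, n_codons, intron_lens, config,
                seq, base_p, rng) -> GeneModel:
    """Lay out utr5 - CDS (split by introns) - utr3 left to right on the
    genome and write a valid ORF into the sequence."""
    cds_len = 3 * (n_codons + 2)
    # split CDS into n_introns+1 exon chunks
    n_chunks = len(intron_lens) + 1
    cuts = np.sort(rng.choice(np.arange(3, cds_len - 3), size=n_chunks - 1,
                              replace=False)) if n_chunks > 1 else np.array([], int)
    chunk_lens = np.diff(np.concatenate([[0], cuts, [cds_len]])).astype(int)
    p = start
    utr_a = (p, p + config.utr5_length - 1)
    p += config.utr5_length
    cds_segs = []
    for k, cl in enumerate(chunk_lens):
        cds_segs.append((p, p + cl - 1))
        p += cl
        if k < len(intron_lens):
            p += int(intron_lens[k])
    utr_b = (p, p + config.utr3_length - 1)

    # coding sequence: ATG + random non-stop codons + stop
    stops = {"TAA", "TAG", "TGA"}
    stop_idx = [BASE_CODE[c[0]] * 16 + BASE_CODE[c[1]] * 4 + BASE_CODE[c[2]]
                for c in stops]
    body = rng.choice(4, size=3 * n_codons, p=base_p).astype(np.uint8)
    cidx = body.reshape(-1, 3)
    ids = cidx[:, 0] * 16 + cidx[:, 1] * 4 + cidx[:, 2]
    bad = np.isin(ids, stop_idx)
    while bad.any():
        cidx[bad] = rng.choice(4, size=(int(bad.sum()), 3), p=base_p)
        ids = cidx[:, 0] * 16 + cidx[:, 1] * 4 + cidx[:, 2]
        bad = np.isin(ids, stop_idx)
    stop_codon = [list(map(BASE_CODE.get, s)) for s in sorted(stops)][
        int(rng.integers(3))]
    coding = np.concatenate([
        np.array([BASE_CODE["A"], BASE_CODE["T"], BASE_CODE["G"]], dtype=np.uint8),
        cidx.reshape(-1).astype(np.uint8),
        np.array(stop_codon, dtype=np.uint8)])
    positions = np.concatenate([np.arange(s, e + 1) for s, e in cds_segs])
    if strand == "+":
        seq[positions - 1] = coding
        utr5, utr3 = [utr_a], [utr_b]
    else:
        seq[positions - 1] = COMPLEMENT_CODE[coding[::-1]]
        utr5, utr3 = [utr_b], [utr_a]
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     cds=cds_segs, utr5=utr5, utr3=utr3)


# ---------------------------------------------------------------------------
# Stage 2: ancestor
# ---------------------------------------------------------------------------

def simulate_ancestor(config: SimulationConfig, ref: ReferenceBundle,
                      rng: np.random.Generator | None = None) -> AncestralGenotypes:
    """Heterozygous sites as Bernoulli(het_density) per base; the alternate
    allele drawn uniformly from the three non-reference bases."""
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(5)[1])
    het = {}
    for chrom, seq in ref.sequences.items():
        hit = rng.random(len(seq)) < config.het_density
        pos = np.flatnonzero(hit) + 1
        alt = ((seq[pos - 1].astype(np.int64) +
                rng.integers(1, 4, size=len(pos))) % 4).astype(np.uint8)
        het[chrom] = (pos.astype(np.int64), alt)
    return AncestralGenotypes(het=het)


# ---------------------------------------------------------------------------
# Stage 3: MA-line evolution
# ---------------------------------------------------------------------------

def _spectrum_alt_probs(spectrum: dict) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per reference-base code: (candidate alt codes, probabilities)."""
    from .rates import collapse_substitution
    out = {}
    for b in BASES:
        alts = [a for a in BASES if a != b]
        w = np.array([spectrum[collapse_substitution(b, a)] for a in alts],
                     dtype=float)
        out[BASE_CODE[b]] = (np.array([BASE_CODE[a] for a in alts]), w / w.sum())
    return out


def _spectrum_site_accept(spectrum: dict) -> np.ndarray:
    """Relative per-site mutability by base code (conditional-rate sums),
    scaled so the most mutable class has acceptance probability 1."""
    from .rates import collapse_substitution
    w = np.zeros(4)
    for b in BASES:
        w[BASE_CODE[b]] = sum(spectrum[collapse_substitution(b, a)]
                              for a in BASES if a != b)
    return w / w.max()


def _draw_tract_length(dist: tuple, rng: np.random.Generator) -> int:
    name, p = dist
    if name == "lognormal":
        v = rng.lognormal(p["mean_log"], p["sigma_log"])
        return int(np.clip(v, p["min"], p["max"]))
    if name == "fixed":
        return int(p["length"])
    raise ValueError(f"unknown tract length distribution {name!r}")


def evolve_ma_lines(ancestor: AncestralGenotypes, ref: ReferenceBundle,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, LineEvents], TruthTable]:
    """Plant SNMs, indels, and LOH tracts independently per line.

    Per line the SNM count is Poisson with mean snm_rate * 2 * genome *
    generations; LOH converts contiguous runs of ancestral het sites to one
    resolved allele (conversion) or marks the tract hemizygous (deletion)
    at an expected per-het-site rate of loh_rate * generations.  Planted
    event positions are globally unique (no parallel mutations), never on
    ancestral het sites, and SNMs/indels are kept out of deleted tracts of
    their own line.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(5)[2])
    chroms = ref.chrom_names
    lengths = np.array([ref.chrom_length(c) for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    L_total = int(lengths.sum())
    occupied = {(c, int(p)) for c in chroms for p in ancestor.positions(c)}
    alt_probs = _spectrum_alt_probs(config.spectrum)
    site_accept = _spectrum_site_accept(config.spectrum)
    strong = (BASE_CODE["G"], BASE_CODE["C"])

    # expected het sites per tract for event-count calibration
    if config.loh_rate_per_het_site > 0 and config.het_density > 0:
        mean_len = float(np.mean([_draw_tract_length(config.tract_length_dist, rng)
                                  for _ in range(500)]))
        sites_per_tract = max(mean_len * config.het_density, 1.0)
    else:
        sites_per_tract = 1.0

    events: dict[str, LineEvents] = {}
    truth = TruthTable(planted_snms=[], planted_indels=[], planted_loh=[])
    for line, g in config.generations.items():
        ev = LineEvents(line=line,
                        snms={c: (np.array([], dtype=np.int64),
                                  np.array([], dtype=np.uint8)) for c in chroms},
                        indels={c: [] for c in chroms})
        # --- LOH tracts ---
        n_het = ancestor.n_het
        target_sites = config.loh_rate_per_het_site * g * n_het
        n_events = rng.poisson(target_sites / sites_per_tract) if target_sites > 0 else 0
        line_tracts: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        for _ in range(n_events):
            for _try in range(80):
                c = chroms[int(rng.choice(len(chroms), p=chrom_p))]
                tl = _draw_tract_length(config.tract_length_dist, rng)
                Lc = ref.chrom_length(c)
                if tl >= Lc:
                    tl = Lc - 2
                s = int(rng.integers(1, Lc - tl + 1))
                e = s + tl - 1
                if any(not (e < a or s > b) for a, b in line_tracts[c]):
                    continue
                hp, ha = ancestor.het[c]
                i0, i1 = np.searchsorted(hp, [s, e + 1])
                if i1 - i0 < 1:
                    continue  # must overlap at least one ancestral het site
                site_pos = hp[i0:i1]
                site_alt = ha[i0:i1]
                site_ref = ref.sequences[c][site_pos - 1]
                mech = "deletion" if rng.random() < config.deletion_fraction \
                    else "conversion"
                pick_alt = rng.random(len(site_pos)) < 0.5
                if mech == "conversion" and config.conversion_gc_bias != 0.5:
                    sw = (np.isin(site_ref, strong) != np.isin(site_alt, strong))
                    gc_is_alt = np.isin(site_alt, strong)
                    biased = rng.random(len(site_pos)) < config.conversion_gc_bias
                    pick_alt = np.where(sw, np.where(gc_is_alt, biased, ~biased),
                                        pick_alt)
                resolved = np.where(pick_alt, site_alt, site_ref).astype(np.uint8)
                tract = PlantedLoh(line=line, chrom=c, start=s, end=e,
                                   mechanism=mech, site_positions=site_pos.copy(),
                                   resolved=resolved)
                ev.loh.append(tract)
                truth.planted_loh.append(tract)
                line_tracts[c].append((s, e))
                break
        deleted = {c: [(s, e) for s, e in line_tracts[c]
                       if any(t.mechanism == "deletion" and t.chrom == c and
                              t.start == s for t in ev.loh)]
                   for c in chroms}

        # --- SNMs ---
        n_snm = rng.poisson(config.snm_rate * 2 * L_total * g)
        placed = _place_point_events(n_snm, chroms, chrom_p, ref, occupied,
                                     deleted, rng, accept=site_accept)
        for c, pos_list in placed.items():
            if not pos_list:
                continue
            pos = np.array(sorted(pos_list), dtype=np.int64)
            refc = ref.sequences[c][pos - 1]
            alt = np.empty(len(pos), dtype=np.uint8)
            for code in range(4):
                m = refc == code
                if m.any():
                    cand, p = alt_probs[code]
                    alt[m] = rng.choice(cand, size=int(m.sum()), p=p)
            ev.snms[c] = (pos, alt)
            for p_, r_, a_ in zip(pos, refc, alt):
                truth.planted_snms.append(
                    (line, c, int(p_), BASES[r_], BASES[a_]))

        # --- indels (length <= 5) ---
        n_ind = rng.poisson(config.indel_rate * 2 * L_total * g)
        placed = _place_point_events(n_ind, chroms, chrom_p, ref, occupied,
                                     deleted, rng, margin=6)
        len_w = np.array([0.45, 0.25, 0.15, 0.10, 0.05])
        for c, pos_list in placed.items():
            for p_ in sorted(pos_list):
                length = int(rng.choice([1, 2, 3, 4, 5], p=len_w))
                anchor = BASES[ref.sequences[c][p_ - 1]]
                if rng.random() < 0.6 and p_ + length <= ref.chrom_length(c):
                    ref_a = anchor + decode_seq(ref.sequences[c][p_:p_ + length])
                    alt_a = anchor
                else:
                    ins = decode_seq(rng.choice(4, size=length).astype(np.uint8))
                    ref_a, alt_a = anchor, anchor + ins
                ev.indels[c].append((p_, ref_a, alt_a))
                truth.planted_indels.append((line, c, p_, ref_a, alt_a))
        events[line] = ev
    return events, truth


def _place_point_events(n: int, chroms, chrom_p, ref, occupied, deleted, rng,
                        margin: int = 2, accept=None) -> dict[str, list[int]]:
    """Sample n globally unoccupied positions, outside deleted tracts of the
    focal line and away from chromosome edges.

    ``accept`` optionally weights per-site mutability by reference base code
    (rejection sampling), so mutation density differs between GC and AT
    sites as conditional spectra demand.
    """
    placed = {c: [] for c in chroms}
    attempts = 0
    while n > 0 and attempts < 400:
        attempts += 1
        which = rng.choice(len(chroms), size=n, p=chrom_p)
        for ci, c in enumerate(chroms):
            k = int((which == ci).sum())
            if k == 0:
                continue
            Lc = ref.chrom_length(c)
            cand = rng.integers(1 + margin, Lc - margin, size=k)
            if accept is not None:
                keep = rng.random(k) < accept[ref.sequences[c][cand - 1]]
                cand = cand[keep]
            for p in cand:
                p = int(p)
                if (c, p) in occupied:
                    continue
                if any(s <= p <= e for s, e in deleted.get(c, [])):
                    continue
                occupied.add((c, p))
                placed[c].append(p)
                n -= 1
    return placed


# ---------------------------------------------------------------------------
# Stage 4: evidence emission
# ---------------------------------------------------------------------------

_DEPTH_CDF_CACHE: dict = {}
_LUT_BITS = 16


def _depth_draw(rng, mean, overdispersion, size):
    """Negative-binomial (or Poisson) depth via exact inverse-CDF lookup.

    var = mean * (1 + overdispersion); overdispersion -> 0 is the Poisson
    limit.  A uint32 uniform draw is mapped through the tabulated CDF: a
    coarse lookup on the high bits resolves ~99% of draws directly, the
    rest (bins straddling a CDF step) fall back to binary search, so
    whole-chromosome draws are fast with the distribution quantised only
    at the 2^-32 level.
    """
    from scipy import stats as _st
    key = (float(mean), float(overdispersion))
    if key not in _DEPTH_CDF_CACHE:
        if overdispersion <= 0:
            dist = _st.poisson(mean)
        else:
            dist = _st.nbinom(mean / overdispersion, 1.0 / (1.0 + overdispersion))
        kmax = int(dist.ppf(1.0 - 1e-12)) + 1
        cdf = dist.cdf(np.arange(kmax))
        bound = np.ceil(cdf * 2.0 ** 32).astype(np.uint64)
        shift = 32 - _LUT_BITS
        edges = (np.arange(1 << _LUT_BITS, dtype=np.uint64) << shift)
        lut_val = np.searchsorted(bound, edges, side="right").astype(np.int32)
        hi = np.searchsorted(bound, edges + ((1 << shift) - 1),
                             side="right").astype(np.int32)
        _DEPTH_CDF_CACHE[key] = (bound, lut_val, lut_val == hi)
    bound, lut_val, lut_same = _DEPTH_CDF_CACHE[key]
    u = rng.integers(0, 2 ** 32, size=size, dtype=np.uint32)
    b = (u >> (32 - _LUT_BITS)).astype(np.int64)
    out = lut_val[b]
    mixed = ~lut_same[b]
    if mixed.any():
        out[mixed] = np.searchsorted(bound, u[mixed].astype(np.uint64),
                                     side="right")
    return out.astype(np.int32, copy=False)


def emit_evidence(line_events: dict[str, LineEvents],
                  ancestor: AncestralGenotypes, ref: ReferenceBundle,
                  config: SimulationConfig,
                  rng: np.random.Generator | None = None,
                  artifacts: dict[str, int] | None = None
                  ) -> tuple[SiteTable, DepthTracks, list[tuple]]:
    """Emit multi-sample variant records and per-line depth tracks.

    Depth is negative-binomial around ``mean_depth``; deleted tracts emit
    binomially-thinned (~half) depth in the carrier line.  Allele depths at
    het sites are Binomial(DP, 0.5).  FS / rank-sum annotations are drawn
    from null distributions; ``artifacts`` optionally injects labelled
    artifact sites that the filter stack must remove (returned as the third
    element: a list of (chrom, pos, class)).
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(5)[3])
    lines = list(line_events)
    chroms = ref.chrom_names

    # --- depth tracks ---
    depth = {line: {} for line in lines}
    for line in lines:
        for c in chroms:
            arr = _depth_draw(rng, config.mean_depth,
                              config.depth_overdispersion, ref.chrom_length(c))
            for t in line_events[line].loh:
                if t.mechanism == "deletion" and t.chrom == c:
                    seg = arr[t.start - 1:t.end]
                    arr[t.start - 1:t.end] = rng.binomial(seg, 0.5)
            depth[line][c] = arr
    tracks = DepthTracks(samples=lines, depth=depth)

    # --- assemble sites per chromosome ---
    occupied = {(c, int(p)) for c in chroms for p in ancestor.positions(c)}
    for ev in line_events.values():
        for c in chroms:
            occupied.update((c, int(p)) for p in ev.snms[c][0])
            occupied.update((c, p) for p, _, _ in ev.indels[c])
    art_rows, art_truth = _build_artifacts(artifacts, ref, config, occupied,
                                           lines, rng)

    chrom_col, pos_col, ref_col, alts_col = [], [], [], []
    gt_rows, extra = [], []
    for c in chroms:
        rows = {}
        hp, ha = ancestor.het[c]
        seq = ref.sequences[c]
        for p, a in zip(hp, ha):
            rows[int(p)] = ("anc", BASES[seq[p - 1]], (BASES[a],), None)
        for line in lines:
            pos, alt = line_events[line].snms[c]
            for p, a in zip(pos, alt):
                rows[int(p)] = ("snm", BASES[seq[p - 1]], (BASES[a],), line)
            for p, r_a, a_a in line_events[line].indels[c]:
                rows[int(p)] = ("indel", r_a, (a_a,), line)
        for (ac, ap, aref, aalts, acls, aline) in art_rows:
            if ac == c:
                rows[ap] = (f"art:{acls}", aref, aalts, aline)
        positions = sorted(rows)
        for p in positions:
            kind, r_a, alts_a, carrier = rows[p]
            chrom_col.append(c)
            pos_col.append(p)
            ref_col.append(r_a)
            alts_col.append(tuple(alts_a))
            extra.append((c, p, kind, carrier))

    n_sites = len(pos_col)
    n_lines = len(lines)
    gt = np.zeros((n_sites, n_lines), dtype=np.int8)
    pos_arr = np.array(pos_col, dtype=np.int64)
    chrom_arr = np.array(chrom_col, dtype=object)

    # genotypes
    row_of = {(c, p): i for i, (c, p) in enumerate(zip(chrom_col, pos_col))}
    for i, (c, p, kind, carrier) in enumerate(extra):
        if kind == "anc":
            gt[i, :] = HET
        elif kind in ("snm", "indel") or kind.startswith("art:"):
            gt[i, :] = HOM_REF
            if carrier is not None:
                gt[i, lines.index(carrier)] = HET
    # LOH overrides at ancestral het sites
    for j, line in enumerate(lines):
        for t in line_events[line].loh:
            seq = ref.sequences[t.chrom]
            for p, res in zip(t.site_positions, t.resolved):
                i = row_of[(t.chrom, int(p))]
                ref_code = seq[p - 1]
                gt[i, j] = HOM_REF if res == ref_code else HOM_ALT

    # depth + allele depths
    dp = np.empty((n_sites, n_lines), dtype=np.int32)
    for j, line in enumerate(lines):
        for c in chroms:
            m = chrom_arr == c
            dp[m, j] = depth[line][c][pos_arr[m] - 1]

    if config.genotyping_error > 0:
        flip = rng.random(gt.shape) < config.genotyping_error
        was_het = gt == HET
        gt = np.where(flip & was_het,
                      np.where(rng.random(gt.shape) < 0.5, HOM_REF, HOM_ALT), gt)
        gt = np.where(flip & ~was_het, HET, gt).astype(np.int8)

    ad_ref = np.where(gt == HOM_REF, dp, 0).astype(np.int32)
    ad_alt = np.where(gt == HOM_ALT, dp, 0).astype(np.int32)
    het_mask = gt == HET
    alt_reads = rng.binomial(dp[het_mask], 0.5)
    ad_alt[het_mask] = alt_reads
    ad_ref[het_mask] = dp[het_mask] - alt_reads

    # null FS is exponential truncated below the filter threshold, so any
    # FS > 60 comes only from injected artifacts
    u = rng.random(n_sites)
    fs = -config.fs_scale * np.log1p(-u * (1.0 - np.exp(-60.0 / config.fs_scale)))
    mqrs = rng.normal(0.0, config.rank_sum_sd, size=n_sites)
    rprs = rng.normal(0.0, config.rank_sum_sd, size=n_sites)

    # overwrite evidence at artifact rows
    for (ac, ap, aref, aalts, acls, aline) in art_rows:
        i = row_of[(ac, ap)]
        j = lines.index(aline)
        if acls == "fs":
            fs[i] = 80.0
        elif acls == "mq_rank_sum":
            mqrs[i] = -20.0
        elif acls == "read_pos_rank_sum":
            rprs[i] = -10.0
        elif acls == "allele_fraction":
            ad_alt[i, j] = max(int(round(0.1 * dp[i, j])), 1)
            ad_ref[i, j] = dp[i, j] - ad_alt[i, j]
        elif acls == "min_alt_reads":
            dp[i, j] = 20
            ad_alt[i, j] = 4
            ad_ref[i, j] = 16

    table = SiteTable(
        chrom=chrom_arr, pos=pos_arr,
        ref=np.array(ref_col, dtype=object), alts=alts_col,
        gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, dp=dp,
        fs=fs, mq_rank_sum=mqrs, read_pos_rank_sum=rprs, samples=lines)
    return table, tracks, art_truth


def _build_artifacts(artifacts, ref, config, occupied, lines, rng):
    """Construct artifact rows: (chrom, pos, ref, alts, class, line)."""
    rows, truth = [], []
    if not artifacts:
        return rows, truth
    chroms = ref.chrom_names
    taken = set(occupied)

    def fresh_pos(margin=30):
        for _ in range(1000):
            c = chroms[int(rng.integers(len(chroms)))]
            p = int(rng.integers(1 + margin, ref.chrom_length(c) - margin))
            if all((c, q) not in taken for q in range(p - margin, p + margin + 1)):
                taken.add((c, p))
                return c, p
        raise RuntimeError("could not place artifact site")

    for cls, count in artifacts.items():
        if cls not in ARTIFACT_CLASSES:
            raise ValueError(f"unknown artifact class {cls!r}")
        for _ in range(count):
            c, p = fresh_pos()
            line = lines[int(rng.integers(len(lines)))]
            base = BASES[ref.sequences[c][p - 1]]
            alt = BASES[(BASE_CODE[base] + 1) % 4]
            if cls == "multiallelic":
                alt2 = BASES[(BASE_CODE[base] + 2) % 4]
                rows.append((c, p, base, (alt, alt2), cls, line))
            elif cls == "near_indel":
                anchor = base
                ref_a = anchor + decode_seq(ref.sequences[c][p:p + 2])
                rows.append((c, p, ref_a, (anchor,), cls, line))
                q = p + 10
                taken.add((c, q))
                qbase = BASES[ref.sequences[c][q - 1]]
                qalt = BASES[(BASE_CODE[qbase] + 1) % 4]
                rows.append((c, q, qbase, (qalt,), cls, line))
                truth.append((c, q, cls))
                continue
            else:
                rows.append((c, p, base, (alt,), cls, line))
            truth.append((c, p, cls))
    return rows, truth


# ---------------------------------------------------------------------------
# Stage 5: population frequencies
# ---------------------------------------------------------------------------

def simulate_population_frequencies(ref: ReferenceBundle,
                                    config: SimulationConfig,
                                    truth: TruthTable,
                                    rng: np.random.Generator | None = None):
    """Background segregating sites plus a compartment-dependent subset of
    planted SNMs seeded at MAF > 0.02 (so overlap recovery is testable)."""
    import pandas as pd
    from .popgen import PopulationFrequencies
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(5)[4])
    planted = {(c, p) for _, c, p, *_ in truth.planted_snms}
    rows = []
    pmin, pmax = 0.005, 0.5
    for c in ref.chrom_names:
        Lc = ref.chrom_length(c)
        n_bg = rng.poisson(config.pop_site_fraction * Lc)
        pos = rng.integers(1, Lc + 1, size=n_bg)
        for p in np.unique(pos):
            if (c, int(p)) in planted:
                continue
            maf = pmin * (pmax / pmin) ** rng.random()
            major = BASES[ref.sequences[c][p - 1]]
            minor = BASES[(BASE_CODE[major] + int(rng.integers(1, 4))) % 4]
            rows.append((c, int(p), major, minor, maf))
    overlap = config.pop_snm_overlap
    for line, c, p, ref_a, alt_a in truth.planted_snms:
        comp = ref.compartment(c, p)
        frac = overlap[comp] if isinstance(overlap, dict) else float(overlap)
        if rng.random() < frac:
            maf = float(rng.uniform(0.03, 0.3))
            rows.append((c, p, ref_a, alt_a, maf))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "major", "minor", "maf"])
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return PopulationFrequencies(table=df)


# ---------------------------------------------------------------------------
# Whole-experiment convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    ref: ReferenceBundle
    ancestor: AncestralGenotypes
    line_events: dict[str, LineEvents]
    truth: TruthTable
    sites: SiteTable
    depth: DepthTracks
    pop_freqs: object | None = None
    artifact_truth: list = field(default_factory=list)


def simulate_experiment(config: SimulationConfig,
                        artifacts: dict[str, int] | None = None,
                        with_population: bool = False) -> SimulatedExperiment:
    """Run every generator stage with per-stage seeds derived from
    ``config.seed``."""
    children = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in children]
    ref = generate_reference(config, rngs[0])
    ancestor = simulate_ancestor(config, ref, rngs[1])
    line_events, truth = evolve_ma_lines(ancestor, ref, config, rngs[2])
    sites, depth, art = emit_evidence(line_events, ancestor, ref, config,
                                      rngs[3], artifacts=artifacts)
    pop = simulate_population_frequencies(ref, config, truth, rngs[4]) \
        if with_population else None
    return SimulatedExperiment(config=config, ref=ref, ancestor=ancestor,
                               line_events=line_events, truth=truth,
                               sites=sites, depth=depth, pop_freqs=pop,
                               artifact_truth=art)


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Persist an experiment as plain-text standard formats."""
    from pathlib import Path
    from .reference import write_fasta, write_gff3
    from .variants import write_variants
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(exp.ref, outdir / "reference.fa")
    write_gff3(exp.ref, outdir / "annotation.gff3")
    contigs = {c: exp.ref.chrom_length(c) for c in exp.ref.chrom_names}
    write_variants(exp.sites, outdir / "variants.vcf", contigs)
    exp.depth.write_tsv(outdir / "depth.tsv")
    exp.truth.write_tsv(outdir)
    if exp.pop_freqs is not None:
        exp.pop_freqs.write_tsv(outdir / "population_frequencies.tsv")
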