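"""Loss-of-heterozygosity (LOH) tract detection and mechanism classification.

Over the ordered ancestral heterozygous sites of each line, a two-state
hidden Markov model {RETAINED, LOH} is Viterbi-decoded: in the RETAINED
state the line still reads heterozygous (up to a miscall rate), in the LOH
state it reads homozygous.  Decoded LOH runs become tracts if their minimum
span (first to last homozygous-converted site) exceeds a length threshold,
they contain enough converted sites, and the same sites remain
heterozygous in the non-focal lines (ruling out shared artifacts).

Each tract carries two span definitions: the *minimum* span is the distance
between the first and last converted sites; the *maximum* span extends to
just inside the nearest flanking sites that are still heterozygous.

Mechanism is classified from standardized coverage (site depth divided by
the line's mean callable-site depth): a hemizygous deletion removes one
chromosomal copy and therefore shows about half coverage in the carrier
while the other lines stay near full coverage; gene conversion is
copy-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .calls import AncestralState
from .variants import HET, HOM_REF, MISSING, CallableMask, DepthTracks, SiteTable


@dataclass
class HmmParams:
    """Two-state LOH HMM and tract-acceptance parameters.

    Transition probabilities are per observed heterozygous site.  The
    background requirement demands that at least ``background_het_fraction``
    of a tract's converted sites remain heterozygous in every non-focal
    line.
    """

    p_loh_entry: float = 1e-6
    p_loh_exit: float = 1e-3
    het_miscall_rate: float = 0.01
    hom_miscall_rate: float = 0.01
    min_tract_span: int = 1000
    min_tract_sites: int = 3
    background_het_fraction: float = 0.9

    def __post_init__(self):
        for name in ("p_loh_entry", "p_loh_exit", "het_miscall_rate",
                     "hom_miscall_rate"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1)")
        if self.min_tract_span <= 0:
            raise ValueError("min_tract_span must be positive")


@dataclass
class LohTract:
    line: str
    chrom: str
    min_span: tuple[int, int]   # first, last converted-site positions
    max_span: tuple[int, int]   # up to (not including) flanking het sites
    n_sites: int                # converted ancestral het sites
    mechanism: str = "unclassified"  # conversion / deletion / unclassified
    site_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    site_ref: list[str] = field(default_factory=list)
    site_alt: list[str] = field(default_factory=list)
    resolved_alleles: list[str] = field(default_factory=list)

    @property
    def min_length(self) -> int:
        return self.min_span[1] - self.min_span[0]

    @property
    def max_length(self) -> int:
        return self.max_span[1] - self.max_span[0]


def _viterbi_loh(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    """Viterbi path over obs (1 het, 0 hom, -1 missing); True = LOH state."""
    n = len(obs)
    log = np.log
    t_rr = log(1 - params.p_loh_entry)
    t_rl = log(params.p_loh_entry)
    t_ll = log(1 - params.p_loh_exit)
    t_lr = log(params.p_loh_exit)
    # emission log-probs [state][obs] for obs het / hom
    e_r = {1: log(1 - params.hom_miscall_rate), 0: log(params.hom_miscall_rate)}
    e_l = {1: log(params.het_miscall_rate), 0: log(1 - params.het_miscall_rate)}
    back = np.zeros((n, 2), dtype=np.uint8)
    vr, vl = log(1 - params.p_loh_entry), log(params.p_loh_entry)
    o = int(obs[0])
    if o >= 0:
        vr += e_r[o]
        vl += e_l[o]
    for i in range(1, n):
        nr_from_r = vr + t_rr
        nr_from_l = vl + t_lr
        nl_from_r = vr + t_rl
        nl_from_l = vl + t_ll
        if nr_from_r >= nr_from_l:
            nvr, back[i, 0] = nr_from_r, 0
        else:
            nvr, back[i, 0] = nr_from_l, 1
        if nl_from_l >= nl_from_r:
            nvl, back[i, 1] = nl_from_l, 1
        else:
            nvl, back[i, 1] = nl_from_r, 0
        o = int(obs[i])
        if o >= 0:
            nvr += e_r[o]
            nvl += e_l[o]
        vr, vl = nvr, nvl
    path = np.zeros(n, dtype=bool)
    state = 1 if vl > vr else 0
    for i in range(n - 1, -1, -1):
        path[i] = bool(state)
        state = int(back[i, state])
    return path


def detect_loh_tracts(table: SiteTable, ancestral: AncestralState,
                      params: HmmParams | None = None,
                      chrom_lengths: dict[str, int] | None = None
                      ) -> list[LohTract]:
    """Detect per-line LOH tracts over ancestral heterozygous SNV sites."""
    params = params or HmmParams()
    is_snv = np.array([len(r) == 1 and len(alts) == 1 and len(alts[0]) == 1
                       for r, alts in zip(table.ref, table.alts)])
    anc_het = (ancestral.genotype == HET) & is_snv
    tracts: list[LohTract] = []
    if not anc_het.any():
        return tracts
    for chrom in pd.unique(table.chrom.astype(str)):
        sel = np.flatnonzero((table.chrom == chrom) & anc_het)
        if len(sel) == 0:
            continue
        pos = table.pos[sel]
        gt = table.gt[sel]  # (n_sites, n_lines)
        obs_all = np.where(gt == MISSING, -1, np.where(gt == HET, 1, 0)).astype(np.int8)
        chrom_len = chrom_lengths[chrom] if chrom_lengths else int(pos[-1]) + 1
        for j, line in enumerate(table.samples):
            obs = obs_all[:, j]
            if not (obs == 0).any():
                continue
            path = _viterbi_loh(obs, params)
            tracts.extend(_runs_to_tracts(
                path, obs, obs_all, j, pos, sel, table, chrom, chrom_len, params))
    tracts.sort(key=lambda t: (t.chrom, t.min_span[0], t.line))
    return tracts


def _runs_to_tracts(path, obs, obs_all, j, pos, sel, table, chrom, chrom_len,
                    params) -> list[LohTract]:
    out = []
    n = len(path)
    i = 0
    while i < n:
        if not path[i]:
            i += 1
            continue
        k = i
        while k < n and path[k]:
            k += 1
        run = np.arange(i, k)
        i = k
        conv = run[obs[run] == 0]  # converted (hom-observed) sites
        if len(conv) == 0:
            continue
        first, last = int(pos[conv[0]]), int(pos[conv[-1]])
        if len(conv) < params.min_tract_sites or (last - first) <= params.min_tract_span:
            continue
        # background: converted sites must stay het in every other line
        ok = True
        for other in range(obs_all.shape[1]):
            if other == j:
                continue
            o = obs_all[conv, other]
            known = o >= 0
            if known.sum() == 0 or (o[known] == 1).mean() < params.background_het_fraction:
                ok = False
                break
        if not ok:
            continue
        lo = int(pos[conv[0] - 1]) + 1 if conv[0] > 0 else 1
        hi = int(pos[conv[-1] + 1]) - 1 if conv[-1] < n - 1 else chrom_len
        rows = sel[conv]
        resolved = []
        refs, alts = [], []
        for r in rows:
            refs.append(str(table.ref[r]))
            alts.append(str(table.alts[r][0]))
            g = table.gt[r, j]
            resolved.append(refs[-1] if g == HOM_REF else alts[-1])
        out.append(LohTract(
            line=table.samples[j], chrom=chrom, min_span=(first, last),
            max_span=(lo, hi), n_sites=len(conv),
            site_positions=pos[conv].copy(), site_ref=refs, site_alt=alts,
            resolved_alleles=resolved))
    return out


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def loh_rate(n_converted_sites: int, g: float, n_het: float) -> float:
    """Per-heterozygous-site LOH rate: x / (g * n)."""
    if g <= 0 or n_het <= 0:
        raise ValueError("generations and ancestral het count must be positive")
    return n_converted_sites / (g * n_het)


def experiment_loh_rate(tracts: list[LohTract], generations: dict[str, float],
                        n_het_per_line: dict[str, float]) -> tuple[pd.DataFrame, float]:
    """Per-line LOH rates and their unweighted mean (lines with zero events
    contribute rate 0)."""
    rows = []
    for line in generations:
        x = sum(t.n_sites for t in tracts if t.line == line)
        events = sum(1 for t in tracts if t.line == line)
        mu = loh_rate(x, generations[line], n_het_per_line[line]) if x else 0.0
        lengths = [t.min_length for t in tracts if t.line == line]
        sites = [t.n_sites for t in tracts if t.line == line]
        rows.append({"line": line, "events": events, "x_sites": x,
                     "mean_length": float(np.mean(lengths)) if lengths else np.nan,
                     "mean_sites": float(np.mean(sites)) if sites else np.nan,
                     "mu": mu})
    df = pd.DataFrame(rows)
    return df, float(df["mu"].mean())


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------

def classify_mechanism(tract: LohTract, depth: DepthTracks, mask: CallableMask,
                       flank: int = 50_000, deletion_max: float = 0.70,
                       background_min: float = 0.80,
                       line_mean_depth: dict[str, float] | None = None) -> str:
    """Classify a tract as heterozygous deletion or gene conversion.

    Standardized coverage = mean depth over the tract region divided by the
    line's mean depth across callable sites.  Deletion requires focal
    standardized coverage <= ``deletion_max`` relative to both flanks and
    the genome-wide mean, with every other line >= ``background_min`` on
    the same region; anything else is conversion.  Tracts with depth
    missing (zero) over more than half the region are left unclassified.
    """
    if line_mean_depth is None:
        line_mean_depth = mean_callable_depth(depth, mask)
    chrom = tract.chrom
    lo, hi = tract.min_span
    arr = depth.depth[tract.line][chrom]
    region = arr[lo - 1:hi]
    if (region == 0).mean() > 0.5:
        tract.mechanism = "unclassified"
        return tract.mechanism
    n = len(arr)
    left = arr[max(0, lo - 1 - flank):lo - 1]
    right = arr[hi:min(n, hi + flank)]
    flanks = np.concatenate([left, right]) if (len(left) + len(right)) else np.array([1.0])

    def standardized(a, line):
        return float(np.mean(a)) / line_mean_depth[line]

    focal = standardized(region, tract.line)
    focal_flank = standardized(flanks, tract.line)
    is_del = (focal <= deletion_max * focal_flank) and (focal <= deletion_max)
    if is_del:
        for line in depth.samples:
            if line == tract.line:
                continue
            o_arr = depth.depth[line][chrom]
            o_region = standardized(o_arr[lo - 1:hi], line)
            o_left = o_arr[max(0, lo - 1 - flank):lo - 1]
            o_right = o_arr[hi:min(len(o_arr), hi + flank)]
            o_fl = np.concatenate([o_left, o_right]) if (len(o_left) + len(o_right)) \
                else np.array([1.0])
            o_flank = standardized(o_fl, line)
            if o_region < background_min or o_region < background_min * o_flank:
                is_del = False
                break
    tract.mechanism = "deletion" if is_del else "conversion"
    return tract.mechanism


def mean_callable_depth(depth: DepthTracks, mask: CallableMask) -> dict[str, float]:
    out = {}
    for line in depth.samples:
        tot = n = 0
        for chrom, arr in depth.depth[line].items():
            m = mask.masks[line][chrom]
            tot += int(arr[m].sum())
            n += int(m.sum())
        out[line] = tot / n if n else np.nan
    return out


def classify_all(tracts: list[LohTract], depth: DepthTracks, mask: CallableMask,
                 flank: int = 50_000) -> list[LohTract]:
    means = mean_callable_depth(depth, mask)
    for t in tracts:
        classify_mechanism(t, depth, mask, flank=flank, line_mean_depth=means)
    return tracts


# ---------------------------------------------------------------------------
# GC-biased gene conversion
# ---------------------------------------------------------------------------

def gc_conversion_bias(tracts: list[LohTract]) -> tuple[float, float]:
    """Fraction of strong/weak conversion sites resolved to the G/C allele,
    with an exact two-sided binomial test against 0.5.

    Only sites whose two ancestral alleles pair one G/C with one A/T are
    eligible; conversion tracts only.
    """
    n_gc = n_total = 0
    for t in tracts:
        if t.mechanism != "conversion":
            continue
        for ref, alt, res in zip(t.site_ref, t.site_alt, t.resolved_alleles):
            strong = {"G", "C"}
            if (ref in strong) == (alt in strong):
                continue  # G/C<->G/C or A/T<->A/T: uninformative
            n_total += 1
            if res in strong:
                n_gc += 1
    if n_total == 0:
        raise ValueError("no eligible strong/weak conversion sites")
    p = binomtest(n_gc, n_total, 0.5, alternative="two-sided").pvalue
    return n_gc / n_total, float(p)


def tracts_to_frame(tracts: list[LohTract]) -> pd.DataFrame:
    return pd.DataFrame([{
        "line": t.line, "chrom": t.chrom,
        "min_start": t.min_span[0], "min_end": t.min_span[1],
        "max_start": t.max_span[0], "max_end": t.max_span[1],
        "n_sites": t.n_sites, "mechanism": t.mechanism} for t in tracts])


def write_bed(tracts: list[LohTract], path) -> None:
    """Write tracts as BED (0-based half-open; both span definitions)."""
    with open(path, "w") as fh:
        for t in tracts:
            name = f"{t.line}|{t.mechanism}|sites={t.n_sites}"
            fh.write(f"{t.chrom}\t{t.min_span[0] - 1}\t{t.min_span[1]}\t"
                     f"{name}|min\n")
            fh.write(f"{t.chrom}\t{t.max_span[0] - 1}\t{t.max_span[1]}\t"
                     f"{name}|max\n")
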