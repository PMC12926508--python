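"""Mutation-rate estimation, spectra, and derived population statistics.

Per-line rates follow the standard mutation-accumulation estimator

    mu = x / (g * 2n)

with x accepted mutations, g generations, and n callable sites (the factor
2 accounts for diploidy: events are recovered as heterozygotes).  The
experiment-wide rate is the unweighted mean of per-line rates with a
normal-approximation confidence interval (mean +/- z * SD / sqrt(L)).

The six-type conditional spectrum normalises each strand-collapsed
substitution class by the callable content of its source base pair summed
over lines, i.e. rate(C:G>T:A) = count / (2 * sum_l g_l * n_l(GC)).  From
these conditional rates the AT->GC flux u and GC->AT flux v give the
equilibrium GC content u/(u+v) expected under mutation pressure alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import IMPACTS, MutationCall, annotate_impact
from .reference import BASES, COMPARTMENTS, ReferenceBundle
from .variants import CallableMask

# strand-collapsed substitution classes, pyrimidine-centred (COSMIC order)
SIX_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = ("C>T", "T>C")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def collapse_substitution(ref: str, alt: str) -> str:
    """Collapse a substitution to its pyrimidine-centred class."""
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def context_labels() -> list[str]:
    """The 96 trinucleotide-context labels in canonical (COSMIC) order."""
    return [f"{l}[{t}]{r}" for t in SIX_TYPES for l in BASES for r in BASES]


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def per_line_rate(x: int, g: float, n: float, ploidy: int = 2) -> float:
    """mu = x / (g * ploidy * n)."""
    if g <= 0 or n <= 0:
        raise ValueError("generations and callable sites must be positive")
    return x / (g * ploidy * n)


def pooled_rate_ci(rates, confidence: float = 0.95, method: str = "t"
                   ) -> tuple[float, float, float]:
    """Mean of per-line rates with CI = mean +/- q * SD / sqrt(L).

    ``method="t"`` (default) takes q from the Student t distribution with
    L-1 degrees of freedom, which gives nominal coverage for the small line
    counts typical of MA experiments (a 1.96-SE interval over 8 lines
    covers only ~91% of the time).  ``method="normal"`` uses the plain
    z quantile (q = 1.96 at 95%) -- the arithmetic that reproduces the
    published interval bounds from the per-line tables.
    """
    r = np.asarray(rates, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least two per-line rates")
    mean = float(r.mean())
    se = float(r.std(ddof=1) / np.sqrt(len(r)))
    if method == "t":
        q = float(stats.t.ppf(0.5 + confidence / 2, df=len(r) - 1))
    elif method == "normal":
        q = float(stats.norm.ppf(0.5 + confidence / 2))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return mean, mean - q * se, mean + q * se


@dataclass
class RateEstimate:
    per_line: pd.DataFrame  # line, x, g, n, mu
    pooled_mean: float
    ci_low: float
    ci_high: float


def rate_table(calls: list[MutationCall], mask: CallableMask,
               generations: dict[str, float],
               event_classes: tuple[str, ...] = ("SNM",),
               confidence: float = 0.95) -> RateEstimate:
    """Per-line mutation counts, callable sites, and rates; pooled CI."""
    lines = mask.samples
    n_callable = mask.n_callable
    counts = {s: 0 for s in lines}
    for c in calls:
        if c.event_class in event_classes:
            counts[c.line] += 1
    rows = []
    for s in lines:
        mu = per_line_rate(counts[s], generations[s], n_callable[s])
        rows.append({"line": s, "x": counts[s], "g": generations[s],
                     "n": n_callable[s], "mu": mu})
    df = pd.DataFrame(rows)
    mean, lo, hi = pooled_rate_ci(df["mu"], confidence)
    return RateEstimate(per_line=df, pooled_mean=mean, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumTable:
    counts: dict[str, int]            # six-type counts
    rates: dict[str, float]           # six-type conditional rates
    ts_tv: float
    u: float                          # AT -> GC per-site flux
    v: float                          # GC -> AT per-site flux
    gc_equilibrium: float
    context_counts: pd.Series | None = None  # 96-vector
    n_edge_dropped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_counts_and_rates(cls, counts: dict[str, float],
                              rates: dict[str, float]) -> "SpectrumTable":
        """Build a spectrum summary from externally supplied six-type
        counts and conditional rates (e.g. a published table)."""
        ts = sum(counts[t] for t in TRANSITIONS)
        tv = sum(counts[t] for t in SIX_TYPES if t not in TRANSITIONS)
        u = rates["T>C"] + rates["T>G"]
        v = rates["C>T"] + rates["C>A"]
        return cls(counts=dict(counts), rates=dict(rates),
                   ts_tv=ts / tv if tv else np.inf, u=u, v=v,
                   gc_equilibrium=equilibrium_gc(u, v))


def equilibrium_gc(u: float, v: float) -> float:
    """Equilibrium GC fraction u/(u+v) under mutation pressure alone."""
    if u < 0 or v < 0:
        raise ValueError("rates must be nonnegative")
    if u + v == 0:
        raise ValueError("u + v must be positive")
    return u / (u + v)


def _gc_at_callable(mask: CallableMask, ref: ReferenceBundle) -> dict[str, tuple[int, int]]:
    """Per line: (callable GC sites, callable AT sites)."""
    gc_masks = {c: (s == 1) | (s == 2) for c, s in ref.sequences.items()}
    out = {}
    for line in mask.samples:
        gc = at = 0
        for c, m in mask.masks[line].items():
            n_gc = int((m & gc_masks[c]).sum())
            gc += n_gc
            at += int(m.sum()) - n_gc
        out[line] = (gc, at)
    return out


def six_type_spectrum(calls: list[MutationCall], mask: CallableMask,
                      ref: ReferenceBundle, generations: dict[str, float]
                      ) -> SpectrumTable:
    """Strand-collapsed six-class counts and conditional rates.

    Conditional rate = class count / (2 * sum over lines of generations x
    callable sites whose reference base matches the class source pair).
    """
    counts = {t: 0 for t in SIX_TYPES}
    for c in calls:
        if c.event_class == "SNM":
            counts[collapse_substitution(c.ref_allele, c.alt_allele)] += 1
    exposure = _gc_at_callable(mask, ref)
    denom_gc = 2.0 * sum(generations[s] * exposure[s][0] for s in mask.samples)
    denom_at = 2.0 * sum(generations[s] * exposure[s][1] for s in mask.samples)
    rates = {}
    for t in SIX_TYPES:
        denom = denom_gc if t.startswith("C") else denom_at
        rates[t] = counts[t] / denom if denom else np.nan
    spec = SpectrumTable.from_counts_and_rates(counts, rates)
    spec.context_counts, spec.n_edge_dropped = trinucleotide_spectrum(calls, ref)
    return spec


def trinucleotide_spectrum(calls: list[MutationCall], ref: ReferenceBundle
                           ) -> tuple[pd.Series, int]:
    """96-context counts (pyrimidine-centred); edge-of-chromosome calls
    lacking a flanking base are dropped with a tally."""
    labels = context_labels()
    counts = pd.Series(0, index=labels, dtype=int)
    dropped = 0
    for c in calls:
        if c.event_class != "SNM":
            continue
        ctx = c.trinucleotide_context or ref.trinucleotide_context(
            c.chrom, c.position, c.alt_allele)
        if ctx is None:
            dropped += 1
        else:
            counts[ctx] += 1
    return counts, dropped


# ---------------------------------------------------------------------------
# Compartment and chromosome distribution
# ---------------------------------------------------------------------------

def _pairwise_chi2(x1: int, e1: float, x2: int, e2: float) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) comparing two
    counts against expectations proportional to their exposures."""
    total = x1 + x2
    if total == 0:
        return 0.0, 1.0
    exp1 = total * e1 / (e1 + e2)
    exp2 = total * e2 / (e1 + e2)
    chi2 = (x1 - exp1) ** 2 / exp1 + (x2 - exp2) ** 2 / exp2
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def compartment_rates(calls: list[MutationCall], mask: CallableMask,
                      ref: ReferenceBundle, generations: dict[str, float]
                      ) -> tuple[pd.DataFrame, dict]:
    """Per-compartment counts, exposures, densities, and pairwise chi-square
    tests (expected counts proportional to callable bases per compartment)."""
    import warnings as _w
    counts = {name: 0 for name in COMPARTMENTS}
    for c in calls:
        if c.event_class == "SNM" and c.compartment:
            counts[c.compartment] += 1
    exposure = {name: 0.0 for name in COMPARTMENTS}
    for line in mask.samples:
        g = generations[line]
        for chrom, m in mask.masks[line].items():
            comp = ref.compartments[chrom]
            bc = np.bincount(comp[m], minlength=len(COMPARTMENTS))
            for k, name in enumerate(COMPARTMENTS):
                exposure[name] += 2.0 * g * int(bc[k])
    names = []
    for name in COMPARTMENTS:
        if exposure[name] == 0:
            _w.warn(f"compartment {name} has zero callable exposure; excluded")
        else:
            names.append(name)
    df = pd.DataFrame({
        "compartment": names,
        "count": [counts[n] for n in names],
        "exposure": [exposure[n] for n in names]})
    df["density"] = df["count"] / df["exposure"]
    tests = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            tests[(a, b)] = _pairwise_chi2(counts[a], exposure[a],
                                           counts[b], exposure[b])
    return df, tests


def chromosome_uniformity(calls: list[MutationCall], mask: CallableMask
                          ) -> tuple[float, int, float]:
    """Chi-square test of SNM counts against callable-site proportions per
    chromosome.  Returns (chi2, df, p)."""
    chroms = list(next(iter(mask.masks.values())))
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes")
    counts = {c: 0 for c in chroms}
    for c in calls:
        if c.event_class == "SNM":
            counts[c.chrom] += 1
    exposure = {c: 0.0 for c in chroms}
    for line in mask.samples:
        for chrom, m in mask.masks[line].items():
            exposure[chrom] += int(m.sum())
    obs = np.array([counts[c] for c in chroms], dtype=float)
    e = np.array([exposure[c] for c in chroms], dtype=float)
    f_exp = obs.sum() * e / e.sum()
    chi2, p = stats.chisquare(obs, f_exp)
    return float(chi2), len(chroms) - 1, float(p)


# ---------------------------------------------------------------------------
# Selection correction, neutral impact expectation, Ne
# ---------------------------------------------------------------------------

@dataclass
class CorrectionModel:
    target_fraction: float
    deficit: float
    raw_rate: float

    @property
    def corrected_rate(self) -> float:
        return corrected_rate(self.raw_rate, self.target_fraction, self.deficit)


def corrected_rate(raw: float, target_fraction: float, deficit: float) -> float:
    """Selection-corrected rate: the depleted class (a fraction
    ``target_fraction`` of the genome) is scaled up by its fractional
    under-observation ``deficit``::

        corrected = target_fraction * (1 + deficit) * raw
                    + (1 - target_fraction) * raw
    """
    if not (0 <= target_fraction <= 1):
        raise ValueError("target_fraction must be in [0,1]")
    return target_fraction * (1 + deficit) * raw + (1 - target_fraction) * raw


def estimate_deficit(observed_rate_target: float,
                     observed_rate_reference: float) -> float:
    """Fractional under-observation: 1 - target/reference."""
    if observed_rate_reference <= 0:
        raise ValueError("reference rate must be positive")
    return 1.0 - observed_rate_target / observed_rate_reference


def effective_population_size(pi_s: float, mu: float) -> float:
    """N_e = pi_s / (4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return pi_s / (4.0 * mu)


def neutral_impact_simulation(n_snm: int, spectrum: dict[str, float],
                              ref: ReferenceBundle, reps: int = 1000,
                              seed=None, mask: CallableMask | None = None
                              ) -> pd.DataFrame:
    """Neutral expectation of impact-category proportions.

    Each replicate places ``n_snm`` SNMs uniformly over callable sites
    (whole genome when no mask), draws the substitution type from the
    six-class ``spectrum`` conditioned on the reference base (so the
    realised Ts/Tv matches the spectrum in expectation), annotates with the
    minimal impact classifier, and tallies category proportions.  Returns
    mean and SD per category over replicates.
    """
    rng = np.random.default_rng(seed)
    chroms = ref.chrom_names
    pools = {}
    for c in chroms:
        if mask is not None:
            m = np.ones(ref.chrom_length(c), dtype=bool)
            for line in mask.samples:
                m &= mask.masks[line][c]
            pools[c] = np.flatnonzero(m) + 1
        else:
            pools[c] = None  # uniform over whole chromosome
    lengths = np.array([len(pools[c]) if pools[c] is not None
                        else ref.chrom_length(c) for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    # per-base alt-draw distributions from the six-type weights
    # pyrimidine classes map to each base via strand collapse
    alt_w = {}
    for b in BASES:
        ws = []
        for a in BASES:
            if a == b:
                continue
            ws.append(spectrum[collapse_substitution(b, a)])
        ws = np.asarray(ws, dtype=float)
        alt_w[b] = ws / ws.sum()
    alt_bases = {b: [a for a in BASES if a != b] for b in BASES}

    props = np.zeros((reps, len(IMPACTS)))
    impact_idx = {n: i for i, n in enumerate(IMPACTS)}
    cache: dict[tuple[str, int, str], str] = {}
    for r in range(reps):
        which = rng.choice(len(chroms), size=n_snm, p=chrom_p)
        tally = np.zeros(len(IMPACTS))
        for ci in range(len(chroms)):
            k = int((which == ci).sum())
            if k == 0:
                continue
            c = chroms[ci]
            if pools[c] is not None:
                positions = rng.choice(pools[c], size=k)
            else:
                positions = rng.integers(1, ref.chrom_length(c) + 1, size=k)
            for p in positions:
                b = ref.base(c, int(p))
                alt = rng.choice(alt_bases[b], p=alt_w[b])
                key = (c, int(p), alt)
                if key not in cache:
                    call = MutationCall(line="sim", chrom=c, position=int(p),
                                        ref_allele=b, alt_allele=alt,
                                        event_class="SNM")
                    cache[key] = annotate_impact(call, ref)
                tally[impact_idx[cache[key]]] += 1
        props[r] = tally / n_snm
    return pd.DataFrame({"impact": IMPACTS, "mean": props.mean(axis=0),
                         "sd": props.std(axis=0, ddof=1)}).set_index("impact")


def observed_impact_proportions(calls: list[MutationCall]) -> pd.Series:
    snms = [c for c in calls if c.event_class == "SNM" and c.impact]
    s = pd.Series(0.0, index=list(IMPACTS))
    for c in snms:
        s[c.impact] += 1
    return s / max(len(snms), 1)
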