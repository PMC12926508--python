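"""Hard-filter stack turning raw variant records into high-confidence
genotypes.

The stack mirrors a standard GATK-style short-variant curation for
mutation-accumulation data: proximity to indels, multi-allelic exclusion,
depth bounds, strand-bias (FS), mapping-quality and read-position rank-sum
cuts, and for heterozygous genotypes an allele-balance screen (minor-read
fraction, minimum alternate reads, and an exact binomial test against the
expected 1:1 allele ratio).

Site-level rules (indel proximity, multi-allelic, FS, rank sums) drop the
site for every line; per-line rules (depth, heterozygous evidence) demote
only the failing genotype to missing.  The surviving set is independent of
rule order; the removal tallies attribute each loss to the first failing
rule in the order above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .variants import HET, MISSING, SiteTable

SITE_RULES = ("near_indel", "multiallelic", "fs", "mq_rank_sum", "read_pos_rank_sum")
LINE_RULES = ("depth", "het_allele_fraction", "het_min_alt_reads", "het_balance")


@dataclass
class FilterConfig:
    """Thresholds for the hard-filter stack.

    The allele-balance binomial test is applied as a hard cut at
    ``balance_alpha``.  The default is deliberately stringent (1e-3): at
    typical 80x depth an exact 1:1 test at alpha=0.05 would discard ~4-5%
    of genuine heterozygotes and bias mutation counts downward by the same
    amount, while genuinely artifactual imbalance (e.g. 90:10 read ratios)
    sits many orders of magnitude below either cut.
    """

    indel_proximity_window: int = 20
    drop_multiallelic: bool = True
    het_min_allele_fraction: float = 0.2
    min_depth: int = 20
    max_depth: int = 300
    max_fs: float = 60.0
    min_mq_rank_sum: float = -12.5
    min_read_pos_rank_sum: float = -8.0
    balance_alpha: float = 1e-3
    min_alt_reads: int = 5

    def __post_init__(self):
        if not (0 < self.balance_alpha < 1):
            raise ValueError("balance_alpha must be in (0,1)")
        for name in ("max_fs", "min_mq_rank_sum", "min_read_pos_rank_sum",
                     "het_min_allele_fraction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class FilterReport:
    """Removal tallies (first failing rule) and survivor counts."""

    n_input_sites: int = 0
    removed_sites: dict = field(default_factory=dict)      # site rule -> count
    removed_genotypes: dict = field(default_factory=dict)  # line rule -> count
    surviving_het_per_line: dict = field(default_factory=dict)
    surviving_hom_per_line: dict = field(default_factory=dict)
    n_surviving_sites: int = 0

    def to_frame(self):
        import pandas as pd
        rows = [{"rule": k, "scope": "site", "removed": v}
                for k, v in self.removed_sites.items()]
        rows += [{"rule": k, "scope": "genotype", "removed": v}
                 for k, v in self.removed_genotypes.items()]
        return pd.DataFrame(rows)


def binomial_balance_test(ref_reads, alt_reads):
    """Exact two-sided binomial p-value for allele balance against 0.5.

    Implements the minimum-likelihood two-sided test (sum of probabilities of
    all outcomes no more likely than the observed one), which for the
    symmetric p0=0.5 null reduces to ``min(1, 2*P(X <= min(k, n-k)))``.
    Accepts scalars or arrays.
    """
    r = np.asarray(ref_reads)
    a = np.asarray(alt_reads)
    n = r + a
    if np.any(n < 1):
        raise ValueError("ref_reads + alt_reads must be >= 1")
    m = np.minimum(r, a)
    p = np.minimum(1.0, 2.0 * binom.cdf(m, n, 0.5))
    if np.isscalar(ref_reads) and np.isscalar(alt_reads):
        return float(p)
    return p


def apply_site_filters(table: SiteTable, mask=None,
                       config: FilterConfig | None = None
                       ) -> tuple[SiteTable, FilterReport]:
    """Apply the full hard-filter stack to a sorted SiteTable.

    ``mask`` (a :class:`~malines.variants.CallableMask`) is accepted for
    interface symmetry; the per-line DP field already carries the same depth
    information, so the depth rule operates on DP directly.
    """
    cfg = config or FilterConfig()
    if not table.is_sorted():
        raise ValueError("input records must be sorted by chromosome, position")
    report = FilterReport(n_input_sites=table.n_sites)
    n_sites, n_lines = table.n_sites, table.n_lines

    # --- site-level rules -------------------------------------------------
    removed = np.zeros(n_sites, dtype=bool)

    near = _near_indel(table, cfg.indel_proximity_window)
    report.removed_sites["near_indel"] = int(near.sum())
    removed |= near

    if cfg.drop_multiallelic:
        multi = table.multiallelic & ~removed
        report.removed_sites["multiallelic"] = int(multi.sum())
        removed |= multi

    with np.errstate(invalid="ignore"):
        fs_fail = (table.fs > cfg.max_fs) & ~removed
        report.removed_sites["fs"] = int(fs_fail.sum())
        removed |= fs_fail

        mq_fail = (table.mq_rank_sum < cfg.min_mq_rank_sum) & ~removed
        report.removed_sites["mq_rank_sum"] = int(mq_fail.sum())
        removed |= mq_fail

        rp_fail = (table.read_pos_rank_sum < cfg.min_read_pos_rank_sum) & ~removed
        report.removed_sites["read_pos_rank_sum"] = int(rp_fail.sum())
        removed |= rp_fail

    out = table.subset(~removed)

    # --- per-line rules ---------------------------------------------------
    gt = out.gt.copy()
    present = gt != MISSING
    demoted = np.zeros_like(present)

    depth_fail = present & ((out.dp < cfg.min_depth) | (out.dp > cfg.max_depth))
    report.removed_genotypes["depth"] = int(depth_fail.sum())
    demoted |= depth_fail

    het = (gt == HET) & ~demoted
    with np.errstate(divide="ignore", invalid="ignore"):
        total = out.ad_ref + out.ad_alt
        frac = np.where(total > 0, out.ad_alt / np.maximum(total, 1), 0.0)
    lo, hi = cfg.het_min_allele_fraction, 1.0 - cfg.het_min_allele_fraction
    frac_fail = het & ((frac < lo) | (frac > hi))
    report.removed_genotypes["het_allele_fraction"] = int(frac_fail.sum())
    demoted |= frac_fail

    alt_fail = het & ~demoted & (out.ad_alt < cfg.min_alt_reads)
    report.removed_genotypes["het_min_alt_reads"] = int(alt_fail.sum())
    demoted |= alt_fail

    bal_candidates = het & ~demoted & (total >= 1)
    if bal_candidates.any():
        idx = np.flatnonzero(bal_candidates.ravel())
        p = binomial_balance_test(out.ad_ref.ravel()[idx], out.ad_alt.ravel()[idx])
        bal_fail = np.zeros(bal_candidates.size, dtype=bool)
        bal_fail[idx] = p < cfg.balance_alpha
        bal_fail = bal_fail.reshape(bal_candidates.shape)
    else:
        bal_fail = np.zeros_like(bal_candidates)
    report.removed_genotypes["het_balance"] = int(bal_fail.sum())
    demoted |= bal_fail

    gt[demoted] = MISSING
    out.gt = gt

    report.surviving_het_per_line = {
        s: int((gt[:, j] == HET).sum()) for j, s in enumerate(out.samples)}
    if mask is not None:
        # homozygous survivors = callable sites minus surviving non-hom rows
        for j, s in enumerate(out.samples):
            non_hom = int(((gt[:, j] == HET) | (gt[:, j] == MISSING)).sum())
            report.surviving_hom_per_line[s] = mask.n_callable[s] - non_hom
    report.n_surviving_sites = out.n_sites
    return out, report


def _near_indel(table: SiteTable, window: int) -> np.ndarray:
    """Sites within ``window`` bp of another indel record."""
    fail = np.zeros(table.n_sites, dtype=bool)
    is_indel = table.is_indel
    for chrom in np.unique(table.chrom.astype(str)):
        sel = np.flatnonzero(table.chrom == chrom)
        ipos = table.pos[sel][is_indel[sel]]
        if len(ipos) == 0:
            continue
        pos = table.pos[sel]
        left = np.searchsorted(ipos, pos - window, side="left")
        right = np.searchsorted(ipos, pos + window, side="right")
        n_near = right - left
        # an indel is always within the window of itself; require another
        self_hit = is_indel[sel].astype(int)
        fail[sel] = (n_near - self_hit) > 0
    return fail
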