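"""Comparison of MA-derived mutations with standing variation.

Per-site nucleotide diversity is pi = 2p(1-p) for minor-allele frequency p.
Gene-level pi_N/pi_S uses Nei-Gojobori-style fractional site counting: each
coding position contributes a synonymous site weight equal to the fraction
of its three possible substitutions that are silent.

The SNM/SNP overlap asks, per genomic compartment, what fraction of de novo
mutations from the MA experiment segregate in a natural population above a
minor-allele-frequency threshold (allele identity required by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import MutationCall
from .reference import (CODON_AA, COMPARTMENTS, GeneModel, ReferenceBundle,
                        SYN_FRACTION, codon_index)


@dataclass
class PopulationFrequencies:
    """Per-site minor-allele frequencies for one population."""

    table: pd.DataFrame  # chrom, pos, major, minor, maf

    def __post_init__(self):
        t = self.table
        if (t["maf"] > 0.5).any() or (t["maf"] < 0).any():
            raise ValueError("minor-allele frequencies must lie in [0, 0.5]")
        self._index = {(c, int(p)): (maj, mnr, float(f))
                       for c, p, maj, mnr, f in zip(t["chrom"], t["pos"],
                                                    t["major"], t["minor"], t["maf"])}

    def lookup(self, chrom: str, pos: int):
        return self._index.get((chrom, pos))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PopulationFrequencies":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def site_pi(p: float):
    """Per-site diversity 2p(1-p); p is the minor-allele frequency."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 0.5)):
        raise ValueError("minor-allele frequency must be in [0, 0.5]")
    out = 2.0 * arr * (1.0 - arr)
    return float(out) if np.isscalar(p) else out


def count_syn_nonsyn_sites(gene: GeneModel, ref: ReferenceBundle
                           ) -> tuple[float, float] | None:
    """Fractional synonymous / nonsynonymous site counts for one gene.

    Per coding position the synonymous weight is the fraction of the three
    possible substitutions that leave the protein unchanged; weights sum to
    the CDS length.  Genes with an internal stop codon are skipped with a
    warning (returns None).
    """
    cds = ref.spliced_cds(gene)
    if len(cds) % 3 != 0:
        warnings.warn(f"gene {gene.gene_id}: CDS not divisible by 3; skipped")
        return None
    cidx = codon_index(cds)
    aas = CODON_AA[cidx]
    if (aas[:-1] == "*").any():
        warnings.warn(f"gene {gene.gene_id}: internal stop codon; skipped")
        return None
    syn = float(SYN_FRACTION[np.repeat(cidx, 3), np.tile([0, 1, 2], len(cidx))].sum())
    return syn, len(cds) - syn


def gene_pi_ratio(gene: GeneModel, freqs: PopulationFrequencies,
                  ref: ReferenceBundle) -> tuple[float, float, float | None]:
    """(pi_N, pi_S, pi_N/pi_S) for one gene.

    Polymorphic coding sites are classified by whether the major->minor
    substitution is silent, assuming the major allele matches the
    reference.  The ratio is None when pi_S is zero.
    """
    counts = count_syn_nonsyn_sites(gene, ref)
    if counts is None:
        raise ValueError(f"gene {gene.gene_id} has an invalid CDS")
    n_syn, n_nonsyn = counts
    cds = ref.spliced_cds(gene)
    pi_n = pi_s = 0.0
    for pos in gene.cds_genomic_positions():
        hit = freqs.lookup(gene.chrom, int(pos))
        if hit is None:
            continue
        _major, minor, maf = hit
        if minor not in "ACGT" or maf <= 0:
            continue
        call = MutationCall(line="pop", chrom=gene.chrom, position=int(pos),
                            ref_allele=ref.base(gene.chrom, int(pos)),
                            alt_allele=minor, event_class="SNM")
        from .calls import annotate_impact
        impact = annotate_impact(call, ref)
        if impact == "LOW":
            pi_s += site_pi(maf)
        else:
            pi_n += site_pi(maf)
    pi_n = pi_n / n_nonsyn if n_nonsyn else 0.0
    pi_s = pi_s / n_syn if n_syn else 0.0
    ratio = pi_n / pi_s if pi_s > 0 else None
    return pi_n, pi_s, ratio


def snm_overlap(calls: list[MutationCall], freqs: PopulationFrequencies,
                maf_min: float = 0.02, require_allele: bool = True
                ) -> pd.DataFrame:
    """Fraction of SNMs segregating in the population, per compartment.

    An SNM counts as present iff a population site exists at the same
    position with minor-allele frequency strictly above ``maf_min`` and
    (by default) the minor allele matching the SNM's alternate allele.
    """
    rows = {name: [0, 0] for name in COMPARTMENTS}  # [present, total]
    overall = [0, 0]
    for c in calls:
        if c.event_class != "SNM":
            continue
        comp = c.compartment or "intergenic"
        hit = freqs.lookup(c.chrom, c.position)
        present = (hit is not None and hit[2] > maf_min and
                   (not require_allele or hit[1] == c.alt_allele))
        rows[comp][1] += 1
        overall[1] += 1
        if present:
            rows[comp][0] += 1
            overall[0] += 1
    out = []
    for name in COMPARTMENTS:
        present, total = rows[name]
        out.append({"compartment": name, "n_snm": total, "n_present": present,
                    "overlap": present / total if total else np.nan})
    out.append({"compartment": "overall", "n_snm": overall[1],
                "n_present": overall[0],
                "overlap": overall[0] / overall[1] if overall[1] else np.nan})
    return pd.DataFrame(out)
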