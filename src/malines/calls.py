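"""De novo mutation calling by cross-line consensus.

In a mutation-accumulation design all lines descend from one ancestor, so
the ancestral genotype at a polymorphic site can be read off as the genotype
shared by nearly all lines.  A de novo event is a site where exactly one
line deviates from that consensus, the deviation is homozygote ->
heterozygote, the site is callable in every line, and no non-mutant line
carries even a single read of the novel allele.

Calls are annotated with their trinucleotide context (pyrimidine-centred),
genomic compartment, and a minimal SnpEff-style impact class derived from
strand-aware codon reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import (BASE_CODE, CODON_AA, COMPLEMENT_CODE,
                        ReferenceBundle, codon_index)
from .variants import HET, HOM_ALT, HOM_REF, MISSING, CallableMask, SiteTable

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass
class AncestralState:
    """Consensus ancestral genotype per site of a (filtered) SiteTable."""

    genotype: np.ndarray  # int8 per site; MISSING = uncallable
    support: np.ndarray   # number of lines agreeing

    def callable_sites(self) -> np.ndarray:
        return self.genotype != MISSING


@dataclass
class MutationCall:
    line: str
    chrom: str
    position: int
    ref_allele: str
    alt_allele: str
    event_class: str  # 'SNM', 'insertion', 'deletion'
    trinucleotide_context: str | None = None
    compartment: str | None = None
    impact: str | None = None
    mnm_group: str | None = None

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))


def infer_ancestral(table: SiteTable, min_consensus: int | None = None) -> AncestralState:
    """Ancestral genotype = genotype shared by >= ``min_consensus`` lines.

    Default consensus is ``n_lines - 1`` (one line may carry the de novo
    event).  Sites with any missing genotype are left uncallable
    (conservative), as are sites without sufficient agreement.
    """
    n_lines = table.n_lines
    if n_lines < 3:
        raise ValueError("consensus undefined with fewer than 3 lines")
    if min_consensus is None:
        min_consensus = n_lines - 1
    gt = table.gt
    counts = np.stack([(gt == g).sum(axis=1) for g in (HOM_REF, HET, HOM_ALT)], axis=1)
    complete = (gt != MISSING).all(axis=1)
    best = counts.argmax(axis=1)
    support = counts.max(axis=1)
    anc = np.where(complete & (support >= min_consensus), best, MISSING)
    return AncestralState(genotype=anc.astype(np.int8), support=support)


def call_mutations(table: SiteTable, ancestral: AncestralState,
                   mask: CallableMask | None = None,
                   ref: ReferenceBundle | None = None,
                   indel_window: int = 20,
                   max_indel_length: int = 5) -> list[MutationCall]:
    """Accept de novo events: unique Hom -> Het changes.

    A call is accepted iff exactly one line deviates from the ancestral
    homozygous genotype, the deviant genotype is heterozygous, the site is
    callable in all lines, no other line has any read supporting the novel
    allele, and the site is at least ``indel_window`` bp from any indel
    record in the table.
    """
    gt = table.gt
    anc = ancestral.genotype
    hom_anc = (anc == HOM_REF) | (anc == HOM_ALT)
    deviant = gt != anc[:, None]
    n_dev = deviant.sum(axis=1)
    complete = (gt != MISSING).all(axis=1)
    cand = hom_anc & (n_dev == 1) & complete
    if not cand.any():
        return []
    cand_idx = np.flatnonzero(cand)
    dev_line = deviant[cand_idx].argmax(axis=1)

    # deviant genotype must be het
    keep = gt[cand_idx, dev_line] == HET
    cand_idx, dev_line = cand_idx[keep], dev_line[keep]

    # no reads of the novel allele in any other line
    novel_is_alt = anc[cand_idx] == HOM_REF
    novel_reads = np.where(novel_is_alt[:, None], table.ad_alt[cand_idx],
                           table.ad_ref[cand_idx])
    other = np.ones_like(novel_reads, dtype=bool)
    other[np.arange(len(cand_idx)), dev_line] = False
    keep = (novel_reads * other).sum(axis=1) == 0
    cand_idx, dev_line, novel_is_alt = cand_idx[keep], dev_line[keep], novel_is_alt[keep]

    # callable in every line
    if mask is not None:
        keep = np.ones(len(cand_idx), dtype=bool)
        for chrom in np.unique(table.chrom[cand_idx].astype(str)):
            sub = table.chrom[cand_idx] == chrom
            keep[sub] = mask.callable_all_lines(chrom, table.pos[cand_idx][sub])
        cand_idx, dev_line, novel_is_alt = (cand_idx[keep], dev_line[keep],
                                            novel_is_alt[keep])

    # distance from any indel record
    keep = ~_near_any_indel(table, cand_idx, indel_window)
    cand_idx, dev_line, novel_is_alt = cand_idx[keep], dev_line[keep], novel_is_alt[keep]

    calls: list[MutationCall] = []
    for i, j, alt_is_novel in zip(cand_idx, dev_line, novel_is_alt):
        ref_allele = str(table.ref[i])
        alt_allele = str(table.alts[i][0])
        if not alt_is_novel:
            # ancestor was hom-alt; the novel allele is the reference base
            ref_allele, alt_allele = alt_allele, ref_allele
        if len(ref_allele) == 1 and len(alt_allele) == 1:
            event_class = "SNM"
        elif len(alt_allele) > len(ref_allele):
            event_class = "insertion"
        else:
            event_class = "deletion"
        call = MutationCall(
            line=table.samples[int(j)], chrom=str(table.chrom[i]),
            position=int(table.pos[i]), ref_allele=ref_allele,
            alt_allele=alt_allele, event_class=event_class)
        if event_class != "SNM" and call.indel_length > max_indel_length:
            continue
        if ref is not None:
            call.compartment = ref.compartment(call.chrom, call.position)
            if event_class == "SNM":
                call.trinucleotide_context = ref.trinucleotide_context(
                    call.chrom, call.position, call.alt_allele)
                call.impact = annotate_impact(call, ref)
        calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.position, c.line))
    return calls


def _near_any_indel(table: SiteTable, idx: np.ndarray, window: int) -> np.ndarray:
    is_indel = table.is_indel
    near = np.zeros(len(idx), dtype=bool)
    for chrom in np.unique(table.chrom[idx].astype(str)):
        all_sel = table.chrom == chrom
        ipos = table.pos[all_sel & is_indel]
        sub = np.flatnonzero(table.chrom[idx] == chrom)
        if len(ipos) == 0 or len(sub) == 0:
            continue
        pos = table.pos[idx[sub]]
        left = np.searchsorted(ipos, pos - window, side="left")
        right = np.searchsorted(ipos, pos + window, side="right")
        n_near = right - left
        self_hit = is_indel[idx[sub]].astype(int)
        near[sub] = (n_near - self_hit) > 0
    return near


def group_mnms(calls: list[MutationCall], window: int = 50) -> list[MutationCall]:
    """Chain same-line SNMs with consecutive gaps <= ``window`` into MNM groups.

    Groups of >= 2 members get an ``mnm_group`` id; members remain ordinary
    SNMs in all totals.  Returns the same call objects (mutated in place).
    """
    snms = [c for c in calls if c.event_class == "SNM"]
    snms.sort(key=lambda c: (c.line, c.chrom, c.position))
    group_no = 0
    chain: list[MutationCall] = []

    def flush():
        nonlocal group_no
        if len(chain) >= 2:
            group_no += 1
            gid = f"mnm{group_no}"
            for c in chain:
                c.mnm_group = gid

    for c in snms:
        if chain and c.line == chain[-1].line and c.chrom == chain[-1].chrom \
                and c.position - chain[-1].position <= window:
            chain.append(c)
        else:
            flush()
            chain = [c]
    flush()
    return calls


def count_mnm(calls: list[MutationCall]) -> tuple[int, int]:
    """(number of MNM groups, number of member mutations)."""
    groups = {c.mnm_group for c in calls if c.mnm_group}
    members = sum(1 for c in calls if c.mnm_group)
    return len(groups), members


def annotate_impact(call: MutationCall, ref: ReferenceBundle) -> str:
    """Minimal SnpEff-style impact for an SNM.

    Coding changes are classified by strand-aware codon reconstruction:
    stop-gained / stop-lost / start-lost -> HIGH, amino-acid change ->
    MODERATE, silent -> LOW; non-coding positions -> MODIFIER.  Splice-site
    effects are not modelled.
    """
    if call.position < 1 or call.position > ref.chrom_length(call.chrom):
        raise ValueError(f"position {call.chrom}:{call.position} outside reference")
    gene = ref.coding_gene_at(call.chrom, call.position)
    if gene is None:
        return "MODIFIER"
    cds = ref.spliced_cds(gene)
    if len(cds) % 3 != 0:
        return "MODIFIER"
    k = gene.cds_offset_of(call.position)
    codon_i, off = divmod(k, 3)
    codon = cds[codon_i * 3:codon_i * 3 + 3].copy()
    alt_code = BASE_CODE[call.alt_allele]
    if gene.strand == "-":
        alt_code = int(COMPLEMENT_CODE[alt_code])
    codon_new = codon.copy()
    codon_new[off] = alt_code
    old_aa = CODON_AA[codon_index(codon)[0]]
    new_aa = CODON_AA[codon_index(codon_new)[0]]
    if old_aa == "*" and new_aa != "*":
        return "HIGH"   # stop-lost
    if new_aa == "*" and old_aa != "*":
        return "HIGH"   # stop-gained
    if codon_i == 0 and old_aa == "M" and new_aa != "M":
        return "HIGH"   # start-lost
    if old_aa != new_aa:
        return "MODERATE"
    return "LOW"


def calls_to_frame(calls: list[MutationCall]):
    """Annotated TSV-ready DataFrame of calls."""
    import pandas as pd
    return pd.DataFrame([{
        "line": c.line, "chrom": c.chrom, "pos": c.position,
        "ref": c.ref_allele, "alt": c.alt_allele, "class": c.event_class,
        "context": c.trinucleotide_context, "compartment": c.compartment,
        "impact": c.impact, "mnm_group": c.mnm_group} for c in calls])
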