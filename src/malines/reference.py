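"""Reference genome containers: chromosome sequences, gene models, and the
per-base functional compartment map.

Sequences are held as numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3) so that
whole-genome operations (GC masks, callable-site intersections, context
lookups) stay vectorised.  Every base of the genome is assigned exactly one
compartment label:

* ``intergenic`` -- outside any annotated gene
* ``intron``     -- inside a gene but not in an exon
* ``UTR``        -- annotated untranslated exonic sequence
* ``synonymous`` -- CDS base where most possible substitutions are silent
* ``nonsynonymous`` -- CDS base where most possible substitutions change the
  protein

The synonymous/nonsynonymous split of CDS bases uses a majority rule on the
fraction of the three possible substitutions that are silent (a per-base
collapse of Nei-Gojobori fractional site counting; the fractional weights
themselves are used for diversity denominators in :mod:`malines.popgen`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)

# compartment label codes
INTERGENIC, INTRON, UTR, SYNONYMOUS, NONSYNONYMOUS = range(5)
COMPARTMENTS = ("intergenic", "intron", "UTR", "synonymous", "nonsynonymous")


def encode_seq(s: str) -> np.ndarray:
    """Encode an ACGT string to uint8 codes."""
    arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for b, c in BASE_CODE.items():
        out[arr == ord(b)] = c
    if (out == 255).any():
        # non-ACGT characters (e.g. N) are coded as A; rare and harmless for
        # the synthetic genomes this package works on, but flagged.
        n_bad = int((out == 255).sum())
        warnings.warn(f"{n_bad} non-ACGT bases coded as A")
        out[out == 255] = 0
    return out


def decode_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Codon machinery (standard genetic code, from Biopython)
# ---------------------------------------------------------------------------

def _build_codon_tables():
    table = CodonTable.unambiguous_dna_by_id[1]
    aa = np.empty(64, dtype="<U1")
    for i0, b0 in enumerate(BASES):
        for i1, b1 in enumerate(BASES):
            for i2, b2 in enumerate(BASES):
                codon = b0 + b1 + b2
                idx = i0 * 16 + i1 * 4 + i2
                aa[idx] = "*" if codon in table.stop_codons else table.forward_table[codon]
    syn_frac = np.zeros((64, 3))
    for idx in range(64):
        c = [idx // 16, (idx // 4) % 4, idx % 4]
        for pos in range(3):
            silent = 0
            for alt in range(4):
                if alt == c[pos]:
                    continue
                c2 = list(c)
                c2[pos] = alt
                if aa[c2[0] * 16 + c2[1] * 4 + c2[2]] == aa[idx]:
                    silent += 1
            syn_frac[idx, pos] = silent / 3.0
    return aa, syn_frac


CODON_AA, SYN_FRACTION = _build_codon_tables()
START_CODON_IDX = BASE_CODE["A"] * 16 + BASE_CODE["T"] * 4 + BASE_CODE["G"]


def codon_index(codes: np.ndarray) -> np.ndarray:
    """Codon index array from a (3k,) array of base codes."""
    c = codes.reshape(-1, 3).astype(np.int64)
    return c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene: CDS and UTR segments in genomic order.

    Coordinates are 1-based inclusive (GFF3 convention).  ``cds`` segments are
    sorted by genomic start; for minus-strand genes the spliced CDS is read
    from the last segment backwards, reverse-complemented.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        segs = self.cds + self.utr5 + self.utr3
        return min(s for s, _ in segs)

    @property
    def end(self) -> int:
        segs = self.cds + self.utr5 + self.utr3
        return max(e for _, e in segs)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_genomic_positions(self) -> np.ndarray:
        """1-based genomic positions of CDS bases, in genomic order."""
        return np.concatenate([np.arange(s, e + 1) for s, e in self.cds])

    def spliced_cds(self, seq_codes: np.ndarray) -> np.ndarray:
        """Spliced CDS base codes in translation (5'->3' mRNA) order."""
        pos = self.cds_genomic_positions()
        codes = seq_codes[pos - 1]
        if self.strand == "-":
            codes = COMPLEMENT_CODE[codes[::-1]]
        return codes

    def cds_offset_of(self, position: int) -> int:
        """0-based offset within the spliced CDS of a genomic position."""
        off = 0
        found = -1
        for s, e in self.cds:
            if s <= position <= e:
                found = off + (position - s)
                break
            off += e - s + 1
        if found < 0:
            raise ValueError(f"position {position} not in CDS of {self.gene_id}")
        if self.strand == "-":
            found = self.cds_length - 1 - found
        return found


# ---------------------------------------------------------------------------
# Reference bundle
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    """Chromosome sequences + gene models + derived compartment map."""

    sequences: dict[str, np.ndarray]
    genes: list[GeneModel]
    compartments: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.compartments:
            self.compartments = build_compartment_map(self.sequences, self.genes)
        self._cds_index = None
        self._cds_cache: dict[str, np.ndarray] = {}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def gc_content(self, chrom: str | None = None) -> float:
        if chrom is not None:
            s = self.sequences[chrom]
            return float(((s == 1) | (s == 2)).mean())
        n = sum(int(((s == 1) | (s == 2)).sum()) for s in self.sequences.values())
        return n / self.genome_length

    def base(self, chrom: str, position: int) -> str:
        return BASES[self.sequences[chrom][position - 1]]

    def compartment(self, chrom: str, position: int) -> str:
        return COMPARTMENTS[self.compartments[chrom][position - 1]]

    def trinucleotide_context(self, chrom: str, position: int, alt: str) -> str | None:
        """Pyrimidine-centred context label like ``"T[C>T]A"``.

        Returns None for positions at chromosome edges (no flanking base).
        """
        seq = self.sequences[chrom]
        if position < 2 or position > len(seq) - 1:
            return None
        left, mid, right = seq[position - 2], seq[position - 1], seq[position]
        a = BASE_CODE[alt]
        if BASES[mid] in "AG":  # collapse to the pyrimidine strand
            left, mid, right = (COMPLEMENT_CODE[right], COMPLEMENT_CODE[mid],
                                COMPLEMENT_CODE[left])
            a = int(COMPLEMENT_CODE[a])
        return f"{BASES[left]}[{BASES[mid]}>{BASES[a]}]{BASES[right]}"

    # -- CDS interval index ------------------------------------------------

    def _build_cds_index(self):
        idx = {}
        for c in self.chrom_names:
            starts, ends, gi = [], [], []
            for g_i, g in enumerate(self.genes):
                if g.chrom != c:
                    continue
                for s, e in g.cds:
                    starts.append(s)
                    ends.append(e)
                    gi.append(g_i)
            order = np.argsort(starts) if starts else np.array([], dtype=int)
            idx[c] = (np.asarray(starts)[order] if starts else np.array([], dtype=int),
                      np.asarray(ends)[order] if starts else np.array([], dtype=int),
                      np.asarray(gi)[order] if starts else np.array([], dtype=int))
        self._cds_index = idx

    def coding_gene_at(self, chrom: str, position: int) -> GeneModel | None:
        """The gene whose CDS contains ``position``, or None."""
        if self._cds_index is None:
            self._build_cds_index()
        starts, ends, gi = self._cds_index[chrom]
        if len(starts) == 0:
            return None
        k = np.searchsorted(starts, position, side="right") - 1
        if k >= 0 and ends[k] >= position:
            return self.genes[int(gi[k])]
        return None

    def spliced_cds(self, gene: GeneModel) -> np.ndarray:
        if gene.gene_id not in self._cds_cache:
            self._cds_cache[gene.gene_id] = gene.spliced_cds(self.sequences[gene.chrom])
        return self._cds_cache[gene.gene_id]


# ---------------------------------------------------------------------------
# Compartment map construction
# ---------------------------------------------------------------------------

def build_compartment_map(sequences: dict[str, np.ndarray],
                          genes: list[GeneModel]) -> dict[str, np.ndarray]:
    """Label every base with exactly one compartment.

    Genes whose CDS length is not a multiple of three are excluded from the
    coding labels (their bases fall back to intron) with a warning.
    """
    comp = {c: np.zeros(len(s), dtype=np.uint8) for c, s in sequences.items()}
    for g in genes:
        arr = comp[g.chrom]
        arr[g.start - 1:g.end] = INTRON
        for s, e in g.utr5 + g.utr3:
            arr[s - 1:e] = UTR
        if g.cds_length % 3 != 0:
            warnings.warn(
                f"gene {g.gene_id}: CDS length {g.cds_length} not divisible by 3; "
                "excluded from coding compartments")
            continue
        codes = g.spliced_cds(sequences[g.chrom])
        cidx = codon_index(codes)
        frac = SYN_FRACTION[np.repeat(cidx, 3), np.tile([0, 1, 2], len(cidx))]
        labels = np.where(frac >= 0.5, SYNONYMOUS, NONSYNONYMOUS).astype(np.uint8)
        if g.strand == "-":
            labels = labels[::-1]
        pos = g.cds_genomic_positions()
        arr[pos - 1] = labels
    return comp


# ---------------------------------------------------------------------------
# FASTA / GFF3 round trip
# ---------------------------------------------------------------------------

def write_fasta(bundle_or_seqs, path) -> None:
    seqs = bundle_or_seqs.sequences if isinstance(bundle_or_seqs, ReferenceBundle) \
        else bundle_or_seqs
    records = [SeqRecord(Seq(decode_seq(codes)), id=name, description="")
               for name, codes in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(bundle: ReferenceBundle, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in bundle.chrom_names:
            fh.write(f"##sequence-region {name} 1 {bundle.chrom_length(name)}\n")
        for g in sorted(bundle.genes, key=lambda g: (g.chrom, g.start)):
            rid = g.gene_id
            row = [g.chrom, "malines", "gene", str(g.start), str(g.end), ".",
                   g.strand, ".", f"ID={rid}"]
            fh.write("\t".join(row) + "\n")
            mrna = f"{rid}.t1"
            fh.write("\t".join([g.chrom, "malines", "mRNA", str(g.start),
                                str(g.end), ".", g.strand, ".",
                                f"ID={mrna};Parent={rid}"]) + "\n")
            for s, e in g.utr5:
                fh.write("\t".join([g.chrom, "malines", "five_prime_UTR", str(s),
                                    str(e), ".", g.strand, ".",
                                    f"Parent={mrna}"]) + "\n")
            # CDS phase: bases to skip to reach the next codon start
            segs = g.cds if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            phases = {}
            for s, e in segs:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s + 1
            for s, e in g.cds:
                fh.write("\t".join([g.chrom, "malines", "CDS", str(s), str(e),
                                    ".", g.strand, str(phases[(s, e)]),
                                    f"Parent={mrna}"]) + "\n")
            for s, e in g.utr3:
                fh.write("\t".join([g.chrom, "malines", "three_prime_UTR", str(s),
                                    str(e), ".", g.strand, ".",
                                    f"Parent={mrna}"]) + "\n")


def read_reference(fasta_path, gff3_path) -> ReferenceBundle:
    """Load FASTA + GFF3 into a :class:`ReferenceBundle`.

    The compartment map is rebuilt from the annotation; genes with a CDS
    length not divisible by three are excluded from coding labels (warning).
    """
    import gffutils

    seqs = {rec.id: encode_seq(str(rec.seq))
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for gene in db.features_of_type("gene"):
        cds, u5, u3 = [], [], []
        for f in db.children(gene, featuretype="CDS"):
            cds.append((f.start, f.end))
        for f in db.children(gene, featuretype="five_prime_UTR"):
            u5.append((f.start, f.end))
        for f in db.children(gene, featuretype="three_prime_UTR"):
            u3.append((f.start, f.end))
        if not cds:
            continue
        genes.append(GeneModel(gene_id=gene.id, chrom=gene.seqid,
                               strand=gene.strand, cds=sorted(cds),
                               utr5=sorted(u5), utr3=sorted(u3)))
    return ReferenceBundle(sequences=seqs, genes=genes)
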