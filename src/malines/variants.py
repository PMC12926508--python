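"""Multi-sample variant sites, depth tracks, and callable-site masks.

The in-memory workhorse is :class:`SiteTable`, a columnar container holding
one row per variant site with per-line genotypes, allele depths, total depth
and the site-level quality annotations consumed by the hard filters (FS,
MQRankSum, ReadPosRankSum).  VCF v4.2 round-trips go through pysam.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention); depth
tracks are 1-based as well.  Indels are stored VCF-style with an anchored
REF/ALT pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

# genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class SiteRecord:
    """A single multi-sample variant site (row view of a SiteTable)."""

    chrom: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: np.ndarray        # (n_lines,) int8
    allele_depths: np.ndarray    # (n_lines, 2) ref/alt read counts
    total_depth: np.ndarray      # (n_lines,)
    fs: float
    mq_rank_sum: float
    read_pos_rank_sum: float

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref_allele) for a in self.alt_alleles)

    @property
    def multiallelic(self) -> bool:
        return len(self.alt_alleles) > 1


@dataclass
class SiteTable:
    """Columnar multi-sample variant table, sorted by (chromosome, position)."""

    chrom: np.ndarray            # object, per site
    pos: np.ndarray              # int64, 1-based
    ref: np.ndarray              # object (allele strings)
    alts: list[tuple[str, ...]]  # per site, >=1 alt
    gt: np.ndarray               # (n_sites, n_lines) int8
    ad_ref: np.ndarray           # (n_sites, n_lines) int32
    ad_alt: np.ndarray           # reads supporting the first alt
    dp: np.ndarray               # (n_sites, n_lines) int32
    fs: np.ndarray               # float, nan = absent
    mq_rank_sum: np.ndarray
    read_pos_rank_sum: np.ndarray
    samples: list[str]
    parse_errors: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_lines(self) -> int:
        return len(self.samples)

    @property
    def is_indel(self) -> np.ndarray:
        return np.array([any(len(a) != len(r) for a in alts)
                         for r, alts in zip(self.ref, self.alts)])

    @property
    def multiallelic(self) -> np.ndarray:
        return np.array([len(a) > 1 for a in self.alts])

    def is_sorted(self) -> bool:
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and (np.diff(p) <= 0).any():
                return False
        return True

    def subset(self, keep: np.ndarray) -> "SiteTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SiteTable(
            chrom=self.chrom[keep], pos=self.pos[keep], ref=self.ref[keep],
            alts=[self.alts[i] for i in keep], gt=self.gt[keep],
            ad_ref=self.ad_ref[keep], ad_alt=self.ad_alt[keep],
            dp=self.dp[keep], fs=self.fs[keep],
            mq_rank_sum=self.mq_rank_sum[keep],
            read_pos_rank_sum=self.read_pos_rank_sum[keep],
            samples=list(self.samples))

    def record(self, i: int) -> SiteRecord:
        return SiteRecord(
            chrom=str(self.chrom[i]), position=int(self.pos[i]),
            ref_allele=str(self.ref[i]), alt_alleles=tuple(self.alts[i]),
            genotypes=self.gt[i], allele_depths=np.stack(
                [self.ad_ref[i], self.ad_alt[i]], axis=1),
            total_depth=self.dp[i], fs=float(self.fs[i]),
            mq_rank_sum=float(self.mq_rank_sum[i]),
            read_pos_rank_sum=float(self.read_pos_rank_sum[i]))

    def records(self):
        for i in range(self.n_sites):
            yield self.record(i)


# ---------------------------------------------------------------------------
# VCF round trip (pysam)
# ---------------------------------------------------------------------------

def write_variants(table: SiteTable, path, contig_lengths: dict[str, int]) -> None:
    """Write a SiteTable as an uncompressed multi-sample VCF v4.2."""
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.add_meta("INFO", items=[("ID", "FS"), ("Number", "1"), ("Type", "Float"),
                                   ("Description", "Phred-scaled strand-bias Fisher test")])
    header.add_meta("INFO", items=[("ID", "MQRankSum"), ("Number", "1"), ("Type", "Float"),
                                   ("Description", "Mapping-quality rank-sum z")])
    header.add_meta("INFO", items=[("ID", "ReadPosRankSum"), ("Number", "1"), ("Type", "Float"),
                                   ("Description", "Read-position rank-sum z")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                                     ("Description", "Allele depths")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Total depth")])
    for s in table.samples:
        header.add_sample(s)
    gt_map = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(table.n_sites):
            rec = vcf.new_record(
                contig=str(table.chrom[i]), start=int(table.pos[i]) - 1,
                alleles=(str(table.ref[i]), *table.alts[i]))
            if np.isfinite(table.fs[i]):
                rec.info["FS"] = float(table.fs[i])
            if np.isfinite(table.mq_rank_sum[i]):
                rec.info["MQRankSum"] = float(table.mq_rank_sum[i])
            if np.isfinite(table.read_pos_rank_sum[i]):
                rec.info["ReadPosRankSum"] = float(table.read_pos_rank_sum[i])
            n_alleles = 1 + len(table.alts[i])
            for j, s in enumerate(table.samples):
                g = int(table.gt[i, j])
                rec.samples[s]["GT"] = gt_map[g]
                ad = [0] * n_alleles
                ad[0] = int(table.ad_ref[i, j])
                ad[1] = int(table.ad_alt[i, j])
                rec.samples[s]["AD"] = tuple(ad)
                rec.samples[s]["DP"] = int(table.dp[i, j])
            vcf.write(rec)


def _info_or_nan(rec, key):
    try:
        v = rec.info.get(key, np.nan)
        return np.nan if v is None else float(v)
    except (KeyError, ValueError):
        return np.nan  # annotation not declared in this header


def read_variants(path) -> SiteTable:
    """Read a multi-sample VCF into a SiteTable.

    Records whose allele depths sum to more than DP in any sample are
    rejected; the offending row numbers are listed in ``.parse_errors``.
    Missing annotations surface as NaN, never as zero.
    """
    chrom, pos, ref, alts = [], [], [], []
    gt, ad_ref, ad_alt, dp = [], [], [], []
    fs, mqrs, rprs = [], [], []
    errors = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for row_no, rec in enumerate(vcf, start=1):
            try:
                row_gt, row_adr, row_ada, row_dp = [], [], [], []
                for s in samples:
                    smp = rec.samples[s]
                    g = smp.get("GT")
                    if g is None or g[0] is None:
                        code = MISSING
                    elif g[0] == 0 and g[1] == 0:
                        code = HOM_REF
                    elif g[0] != g[1]:
                        code = HET
                    else:
                        code = HOM_ALT
                    ad = smp.get("AD") or (0, 0)
                    d = smp.get("DP")
                    d = 0 if d is None else int(d)
                    ad0 = int(ad[0] or 0)
                    ad1 = int(ad[1] or 0) if len(ad) > 1 else 0
                    if ad0 + ad1 > d:
                        raise ValueError(
                            f"row {row_no} ({rec.chrom}:{rec.pos}): AD sum "
                            f"{ad0 + ad1} exceeds DP {d} in sample {s}")
                    row_gt.append(code)
                    row_adr.append(ad0)
                    row_ada.append(ad1)
                    row_dp.append(d)
            except ValueError as exc:
                errors.append(str(exc))
                continue
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alts.append(tuple(rec.alts or ()))
            gt.append(row_gt)
            ad_ref.append(row_adr)
            ad_alt.append(row_ada)
            dp.append(row_dp)
            fs.append(_info_or_nan(rec, "FS"))
            mqrs.append(_info_or_nan(rec, "MQRankSum"))
            rprs.append(_info_or_nan(rec, "ReadPosRankSum"))
    n = len(pos)
    table = SiteTable(
        chrom=np.array(chrom, dtype=object), pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object), alts=alts,
        gt=np.array(gt, dtype=np.int8).reshape(n, len(samples)),
        ad_ref=np.array(ad_ref, dtype=np.int32).reshape(n, len(samples)),
        ad_alt=np.array(ad_alt, dtype=np.int32).reshape(n, len(samples)),
        dp=np.array(dp, dtype=np.int32).reshape(n, len(samples)),
        fs=np.array(fs, dtype=float), mq_rank_sum=np.array(mqrs, dtype=float),
        read_pos_rank_sum=np.array(rprs, dtype=float),
        samples=samples, parse_errors=errors)
    return table


# ---------------------------------------------------------------------------
# Depth tracks and callable mask
# ---------------------------------------------------------------------------

@dataclass
class DepthTracks:
    """Per-line, per-chromosome read-depth arrays (index 0 = position 1)."""

    samples: list[str]
    depth: dict[str, dict[str, np.ndarray]]  # line -> chrom -> int32 array

    def chrom_names(self) -> list[str]:
        return list(next(iter(self.depth.values())))

    def at(self, line: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self.depth[line][chrom][np.asarray(positions) - 1]

    def write_tsv(self, path) -> None:
        frames = []
        for chrom in self.chrom_names():
            n = len(self.depth[self.samples[0]][chrom])
            df = pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n + 1)})
            for s in self.samples:
                df[s] = self.depth[s][chrom]
            frames.append(df)
        pd.concat(frames).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "DepthTracks":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("chrom", "pos")]
        depth = {s: {} for s in samples}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            n = int(sub["pos"].max())
            for s in samples:
                arr = np.zeros(n, dtype=np.int32)
                arr[sub["pos"].to_numpy() - 1] = sub[s].to_numpy()
                depth[s][str(chrom)] = arr
        return cls(samples=samples, depth=depth)


@dataclass
class CallableMask:
    """Per-line boolean masks of positions passing the depth bounds."""

    samples: list[str]
    masks: dict[str, dict[str, np.ndarray]]  # line -> chrom -> bool array
    min_depth: int
    max_depth: int

    @property
    def n_callable(self) -> dict[str, int]:
        return {s: sum(int(m.sum()) for m in chroms.values())
                for s, chroms in self.masks.items()}

    def is_callable(self, line: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self.masks[line][chrom][np.asarray(positions) - 1]

    def callable_all_lines(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        out = np.ones(len(positions), dtype=bool)
        for s in self.samples:
            out &= self.is_callable(s, chrom, positions)
        return out


def build_callable_mask(depth: DepthTracks, min_depth: int = 20,
                        max_depth: int = 300) -> CallableMask:
    """Sites with ``min_depth <= depth <= max_depth`` (inclusive bounds)."""
    masks = {s: {c: (arr >= min_depth) & (arr <= max_depth)
                 for c, arr in chroms.items()}
             for s, chroms in depth.depth.items()}
    return CallableMask(samples=list(depth.samples), masks=masks,
                        min_depth=min_depth, max_depth=max_depth)
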