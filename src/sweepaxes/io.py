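"""Domain containers and file formats shared by every scan stage.

Conventions
-----------
* Genomic coordinates are **1-based inclusive** everywhere inside the
  package (the VCF convention).  BED input/output converts at the boundary.
* Haplotype alleles are coded ``0`` = ancestral, ``1`` = derived whenever the
  ancestral state of a SNP is known.  SNPs whose ancestral allele could not
  be assigned are kept with REF-based 0/1 coding and flagged missing in
  :attr:`SnpMap.ancestral` (``"."``); polarized statistics skip them.
* Missing per-SNP scores are ``NaN`` in memory and ``NA`` on disk.

The haplotype-table dialect written by :func:`write_hap_table` is plain TSV:
``##snp`` comment lines carrying the SNP map (id, chrom, bp, cM, ancestral),
one header row of SNP ids, then one row per haplotype:
``population <TAB> hap_id <TAB> allele <TAB> allele ...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

MISSING_ANCESTRAL = "."

#: orientation of a score track: which tail of the distribution is evidence
#: of selection (drives the log transform and the outlier direction).
HIGH_IS_EVIDENCE = "high_is_evidence"
LOW_IS_EVIDENCE = "low_is_evidence"
ABS_IS_EVIDENCE = "abs_is_evidence"
ORIENTATIONS = (HIGH_IS_EVIDENCE, LOW_IS_EVIDENCE, ABS_IS_EVIDENCE)


class FormatError(ValueError):
    """An input file violates the documented dialect or an invariant."""


@dataclass
class SnpMap:
    """Per-SNP coordinates: chromosome, physical (bp) and genetic (cM)
    position, identifier and ancestral-allele symbol (``"."`` = unknown).

    SNPs are sorted by (chrom, pos_bp) with strictly increasing bp and
    non-decreasing cM within each chromosome; chromosomes are contiguous
    blocks in input order.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray
    snp_id: np.ndarray
    ancestral: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=np.float64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.ancestral = np.asarray(self.ancestral, dtype=object)
        n = len(self.pos_bp)
        for name in ("chrom", "pos_cm", "snp_id", "ancestral"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpMap field {name!r} has wrong length")
        self._validate_order()

    def _validate_order(self):
        for c, (lo, hi) in self.chrom_blocks().items():
            bp = self.pos_bp[lo:hi]
            if np.any(np.diff(bp) <= 0):
                raise FormatError(f"pos_bp not strictly increasing on chromosome {c!r}")
            cm = self.pos_cm[lo:hi]
            if np.any(np.diff(cm) < -1e-12):
                raise FormatError(f"pos_cm decreasing on chromosome {c!r}")

    def __len__(self) -> int:
        return len(self.pos_bp)

    def chrom_blocks(self) -> dict:
        """Mapping chromosome -> (start, stop) index slice, in file order."""
        blocks = {}
        if len(self) == 0:
            return blocks
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chrom[i] != self.chrom[start]:
                c = self.chrom[start]
                if c in blocks:
                    raise FormatError(f"chromosome {c!r} is not a contiguous block")
                blocks[c] = (start, i)
                start = i
        return blocks

    @property
    def ancestral_known(self) -> np.ndarray:
        return np.asarray([a != MISSING_ANCESTRAL for a in self.ancestral], dtype=bool)

    def take(self, idx) -> "SnpMap":
        return SnpMap(self.chrom[idx], self.pos_bp[idx], self.pos_cm[idx],
                      self.snp_id[idx], self.ancestral[idx])


@dataclass
class HaplotypeSet:
    """Binary phased haplotype matrix: rows = haplotypes, columns = SNPs."""

    alleles: np.ndarray
    pop_of_hap: np.ndarray
    snp_map: SnpMap
    hap_id: np.ndarray = None

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.pop_of_hap = np.asarray(self.pop_of_hap, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != len(self.snp_map):
            raise ValueError("column count does not match the SNP map")
        if self.alleles.shape[0] != len(self.pop_of_hap):
            raise ValueError("one population label per haplotype row required")
        if self.alleles.size and self.alleles.max() > 1:
            raise FormatError("alleles must be strictly 0/1")
        if self.hap_id is None:
            self.hap_id = np.asarray(
                [f"hap{i}" for i in range(self.alleles.shape[0])], dtype=object)
        for p in self.populations:
            if np.count_nonzero(self.pop_of_hap == p) % 2:
                raise FormatError(
                    f"population {p!r} has an odd number of haplotypes "
                    "(phased diploids expected)")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list:
        seen, out = set(), []
        for p in self.pop_of_hap:
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out

    def pop_rows(self, population) -> np.ndarray:
        rows = np.flatnonzero(self.pop_of_hap == population)
        if rows.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return rows

    def pop_alleles(self, population) -> np.ndarray:
        return self.alleles[self.pop_rows(population)]

    def take_snps(self, idx) -> "HaplotypeSet":
        return HaplotypeSet(self.alleles[:, idx], self.pop_of_hap,
                            self.snp_map.take(idx), self.hap_id)


@dataclass
class ScoreTrack:
    """Per-SNP values of one test in one population, aligned to a SnpMap."""

    test_name: str
    population: str
    values: np.ndarray
    orientation: str
    snp_map: SnpMap

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"undeclared orientation {self.orientation!r}; "
                             f"expected one of {ORIENTATIONS}")
        if len(self.values) != len(self.snp_map):
            raise ValueError("values length does not match the SNP map")

    @property
    def mask(self) -> np.ndarray:
        """True where a value is present."""
        return ~np.isnan(self.values)


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive, sorted by (chrom, start)."""

    chrom: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray
    gene_id: np.ndarray
    gene_name: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start_bp = np.asarray(self.start_bp, dtype=np.int64)
        self.end_bp = np.asarray(self.end_bp, dtype=np.int64)
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.gene_name = np.asarray(self.gene_name, dtype=object)
        if np.any(self.start_bp > self.end_bp):
            raise FormatError("gene with start_bp > end_bp")

    def __len__(self):
        return len(self.gene_id)


# ---------------------------------------------------------------------------
# phased VCF

def read_phased_vcf(path, ancestral_source=None) -> tuple:
    """Read biallelic, fully phased SNPs from a VCF into a HaplotypeSet.

    ``ancestral_source`` may be ``"AA"`` (default: use the INFO/AA tag), a
    mapping ``snp_id or (chrom, pos) -> allele``, or a path to a two-column
    TSV ``snp_id <TAB> allele``.  SNPs whose ancestral allele matches ALT get
    their 0/1 coding flipped so 0 is always ancestral; an ancestral allele
    matching neither REF nor ALT drops the SNP (count logged).  Unphased or
    multiallelic records raise :class:`FormatError`.

    Population labels default to ``"pop"`` for all samples; assign
    ``pop_of_hap`` afterwards or use a pop-map in the CLI layer.
    """
    from cyvcf2 import VCF

    side = None
    if isinstance(ancestral_source, (str, Path)) and str(ancestral_source) != "AA":
        side = {}
        with open(ancestral_source) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                key, allele = line.split()[:2]
                side[key] = allele
    elif isinstance(ancestral_source, dict):
        side = ancestral_source

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, chroms, pos, ids, anc = [], [], [], [], []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        gts = rec.genotypes  # [a0, a1, phased]
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, g in enumerate(gts):
            if len(g) < 3 or not g[2]:
                raise FormatError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS}")
            if g[0] < 0 or g[1] < 0:
                raise FormatError(
                    f"missing genotype for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS}")
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if side is not None:
            aa = side.get(snp_id) or side.get((rec.CHROM, rec.POS))
        else:
            aa = rec.INFO.get("AA")
        ref, alt = rec.REF, rec.ALT[0]
        if aa is None or aa == MISSING_ANCESTRAL:
            aa = MISSING_ANCESTRAL  # keep REF-based coding, flagged missing
        elif aa == ref:
            pass
        elif aa == alt:
            col = (1 - col).astype(np.uint8)
        else:
            n_dropped += 1
            continue
        cols.append(col)
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ids.append(snp_id)
        anc.append(aa)
    if n_dropped:
        log.warning("dropped %d SNPs whose ancestral allele matched neither "
                    "REF nor ALT", n_dropped)
    if not cols:
        raise FormatError(f"no usable SNPs in {path}")
    alleles = np.column_stack(cols)
    snp_map = SnpMap(chroms, pos, np.zeros(len(pos)), ids, anc)
    hap_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    haps = HaplotypeSet(alleles, ["pop"] * alleles.shape[0], snp_map,
                        np.asarray(hap_ids, dtype=object))
    return haps, snp_map


def write_phased_vcf(path, haps: HaplotypeSet) -> None:
    """Write a HaplotypeSet as a minimal phased VCF with INFO/AA tags.

    Alleles are emitted as REF=ancestral ("A"), ALT=derived ("T") for
    polarized SNPs, which round-trips the 0/1 coding exactly.
    """
    m = haps.snp_map
    samples = [f"{haps.pop_of_hap[i]}_d{i // 2}" for i in range(0, haps.n_hap, 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(len(m)):
            info = "." if m.ancestral[j] == MISSING_ANCESTRAL else "AA=A"
            gts = "\t".join(
                f"{haps.alleles[i, j]}|{haps.alleles[i + 1, j]}"
                for i in range(0, haps.n_hap, 2))
            fh.write(f"{m.chrom[j]}\t{m.pos_bp[j]}\t{m.snp_id[j]}\tA\tT\t.\t.\t"
                     f"{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# haplotype table

def write_hap_table(path, haps: HaplotypeSet) -> None:
    m = haps.snp_map
    with open(path, "w") as fh:
        for j in range(len(m)):
            fh.write(f"##snp\t{m.snp_id[j]}\t{m.chrom[j]}\t{m.pos_bp[j]}\t"
                     f"{m.pos_cm[j]:.10g}\t{m.ancestral[j]}\n")
        fh.write("population\thap_id\t" + "\t".join(m.snp_id) + "\n")
        for i in range(haps.n_hap):
            row = "\t".join(str(a) for a in haps.alleles[i])
            fh.write(f"{haps.pop_of_hap[i]}\t{haps.hap_id[i]}\t{row}\n")


def read_hap_table(path) -> tuple:
    """Inverse of :func:`write_hap_table`; rejects ragged or non-binary rows."""
    ids, chroms, pos, cm, anc = [], [], [], [], []
    rows, pops, hids = [], [], []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##snp\t"):
                _, sid, c, bp, g, a = line.split("\t")
                ids.append(sid); chroms.append(c); pos.append(int(bp))
                cm.append(float(g)); anc.append(a)
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if len(header) < 3:
                    raise FormatError("hap table header too short")
                if not ids:  # header-only dialect: synthesize a map
                    ids = header[2:]
                    chroms = ["1"] * len(ids)
                    pos = list(range(1, len(ids) + 1))
                    cm = [0.0] * len(ids)
                    anc = [MISSING_ANCESTRAL] * len(ids)
                continue
            if len(parts) != len(ids) + 2:
                raise FormatError(f"ragged row at line {lineno} of {path}")
            pops.append(parts[0]); hids.append(parts[1])
            try:
                vals = [int(t) for t in parts[2:]]
            except ValueError:
                raise FormatError(f"non-integer allele at line {lineno}") from None
            for col, v in enumerate(vals):
                if v not in (0, 1):
                    raise FormatError(
                        f"non-binary allele {v} at line {lineno}, column {col}")
            rows.append(vals)
    if not rows:
        raise FormatError(f"no haplotypes in {path}")
    snp_map = SnpMap(chroms, pos, cm, ids, anc)
    haps = HaplotypeSet(np.asarray(rows, dtype=np.uint8), pops, snp_map,
                        np.asarray(hids, dtype=object))
    return haps, snp_map


# ---------------------------------------------------------------------------
# genetic map

def read_genetic_map(path, snp_map: SnpMap) -> SnpMap:
    """Interpolate cM positions onto the SNP map from a 3-column
    ``chrom bp cM`` table (linear between points, terminal-rate
    extrapolation beyond the ends).  Returns a new SnpMap."""
    pts = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            c, bp, g = line.split()[:3]
            pts.setdefault(c, []).append((int(bp), float(g)))
    new_cm = np.array(snp_map.pos_cm, copy=True)
    for c, (lo, hi) in snp_map.chrom_blocks().items():
        if c not in pts:
            raise FormatError(f"chromosome {c!r} absent from genetic map")
        p = sorted(pts[c])
        xs = np.asarray([q[0] for q in p], dtype=float)
        ys = np.asarray([q[1] for q in p], dtype=float)
        bp = snp_map.pos_bp[lo:hi].astype(float)
        cm = np.interp(bp, xs, ys)
        if len(xs) >= 2:  # linear extrapolation at the terminal rates
            r0 = (ys[1] - ys[0]) / (xs[1] - xs[0])
            r1 = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            left = bp < xs[0]
            right = bp > xs[-1]
            cm[left] = ys[0] + (bp[left] - xs[0]) * r0
            cm[right] = ys[-1] + (bp[right] - xs[-1]) * r1
        new_cm[lo:hi] = cm
    out = replace(snp_map, pos_cm=new_cm)
    return out


# ---------------------------------------------------------------------------
# gene annotation

def read_gene_annotation(path, format) -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open) or GFF3 ("gene"
    features only), convert to 1-based inclusive, sort and deduplicate."""
    if format == "BED":
        recs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                c, s, e = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"{c}:{s}-{e}"
                if e <= s:
                    log.warning("zero-length BED interval at line %d skipped", lineno)
                    continue
                recs.append((c, s + 1, e, name, name))
    elif format == "GFF3":
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique")
        recs = []
        for g in db.features_of_type("gene"):
            gid = g.id or f"{g.seqid}:{g.start}-{g.end}"
            name = (g.attributes.get("Name") or [gid])[0]
            recs.append((g.seqid, int(g.start), int(g.end), gid, name))
    else:
        raise FormatError(f"unknown gene-annotation format {format!r}")
    # dedupe by gene_id, then sort
    seen = {}
    for r in recs:
        seen.setdefault(r[3], r)
    recs = sorted(seen.values(), key=lambda r: (str(r[0]), r[1]))
    if not recs:
        return GeneAnnotation(np.empty(0, object), np.empty(0, np.int64),
                              np.empty(0, np.int64), np.empty(0, object),
                              np.empty(0, object))
    cols = list(zip(*recs))
    return GeneAnnotation(*[np.asarray(c, dtype=object if i in (0, 3, 4) else np.int64)
                            for i, c in enumerate(cols)])


# ---------------------------------------------------------------------------
# score tracks

def write_score_track(path, track: ScoreTrack) -> None:
    m = track.snp_map
    with open(path, "w") as fh:
        fh.write(f"##test_name={track.test_name}\n")
        fh.write(f"##population={track.population}\n")
        fh.write(f"##orientation={track.orientation}\n")
        fh.write("chrom\tpos_bp\tsnp_id\tvalue\n")
        for j in range(len(m)):
            v = track.values[j]
            sv = "NA" if np.isnan(v) else f"{v:.10g}"
            fh.write(f"{m.chrom[j]}\t{m.pos_bp[j]}\t{m.snp_id[j]}\t{sv}\n")


def snp_map_from_score_track(path) -> SnpMap:
    """Minimal SnpMap (no cM, unknown ancestral) from a score-track TSV —
    enough to align a batch of track files that share one SNP grid."""
    chroms, pos, ids = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("##") or line.startswith("chrom\t"):
                continue
            c, bp, sid, _v = line.split("\t")
            chroms.append(c)
            pos.append(int(bp))
            ids.append(sid)
    return SnpMap(chroms, pos, np.zeros(len(pos)), ids,
                  [MISSING_ANCESTRAL] * len(pos))


def read_score_track(path, snp_map: SnpMap) -> ScoreTrack:
    """Read a per-SNP score TSV aligned to ``snp_map``.

    Positions absent from the map are an error (orphan count reported);
    map positions absent from the file are NaN.  A missing orientation
    header defaults to ``high_is_evidence`` with a logged warning — this is
    also the import path for externally computed tracks (e.g. SelEstim
    selection coefficients or XP-CLR composite-likelihood scores).
    """
    meta = {"test_name": Path(path).stem, "population": "all"}
    index = {(snp_map.chrom[j], int(snp_map.pos_bp[j])): j
             for j in range(len(snp_map))}
    values = np.full(len(snp_map), np.nan)
    orphans = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                k, _, v = line[2:].partition("=")
                meta[k] = v
                continue
            if line.startswith("chrom\t"):
                continue
            c, bp, _sid, v = line.split("\t")
            j = index.get((c, int(bp)))
            if j is None:
                orphans += 1
                continue
            values[j] = np.nan if v == "NA" else float(v)
    if orphans:
        raise FormatError(f"{orphans} positions in {path} absent from the SNP map")
    if "orientation" not in meta:
        log.warning("no orientation header in %s; defaulting to %s",
                    path, HIGH_IS_EVIDENCE)
        meta["orientation"] = HIGH_IS_EVIDENCE
    return ScoreTrack(meta["test_name"], meta["population"], values,
                      meta["orientation"], snp_map)
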