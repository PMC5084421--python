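"""End-to-end orchestration: simulate/load -> scan -> summarize -> regions.

One YAML (or dict) config drives every stage; outputs land in an output
directory together with a JSON manifest of SHA-256 checksums, so a rerun
with identical config and inputs is verifiably identical.  A single
top-level seed deterministically derives all stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import yaml

from . import axes, diff, haplen, regions as reg, sfs
from .simulate import (preset_neutral, preset_seven_pops, preset_sweep,
                       simulate)
from .io import (HaplotypeSet, read_gene_annotation, read_genetic_map,
                 read_hap_table, read_phased_vcf, read_score_track,
                 write_hap_table, write_score_track)

log = logging.getLogger(__name__)

INTERNAL_TESTS = ("TajimaD", "FayWuH", "FuLiD", "IHS", "NSL", "H12",
                  "FST", "XPEHH", "VarLD")
TEST_FAMILIES = {
    "sfs": ["TajimaD", "FayWuH", "FuLiD"],
    "haplotype_length": ["IHS", "NSL"],
    "differentiation": ["FST", "XPEHH", "VarLD", "H12", "Selestim", "XPCLR"],
}


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    preset: str = None                   # "neutral" | "sweep" | "seven_pops"
    vcf: str = None
    hap_table: str = None
    pop_map: str = None                  # sample -> population TSV (VCF input)
    genetic_map: str = None
    ancestral: str = None                # side TSV for VCF ancestral alleles
    tests: tuple = INTERNAL_TESTS
    external_tracks: tuple = ()
    window: int = 100
    step: int = 1
    transform: str = "log1p"
    n_factors: int = 3
    q_strict: float = 0.001
    min_snps: int = 25
    bin_bp: int = 1_000_000
    q_relaxed: float = 0.05
    gene_annotation: str = None
    gene_annotation_format: str = "BED"
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self):
        sources = [s for s in (self.preset, self.vcf, self.hap_table) if s]
        if len(sources) != 1:
            raise ValueError("exactly one of preset/vcf/hap_table required")
        n_tests = len(self.tests) + len(self.external_tracks)
        if n_tests < 3:
            raise ValueError("factor analysis needs at least 3 tests")
        for p in list(self.external_tracks) + [self.vcf, self.hap_table,
                                               self.pop_map, self.genetic_map,
                                               self.ancestral,
                                               self.gene_annotation]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input missing: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig, out: Path):
    if config.preset:
        maker = {"neutral": preset_neutral, "sweep": preset_sweep,
                 "seven_pops": preset_seven_pops}[config.preset]
        cfg = maker(seed=config.seed)
        for k, v in config.sim_overrides.items():
            setattr(cfg, k, v)
        haps, snp_map, truth = simulate(cfg)
        write_hap_table(out / "simulated_haplotypes.tsv", haps)
        with open(out / "sim_truth.tsv", "w") as fh:
            fh.write("population\tsnp_id\tpos_bp\ts\tfinal_freq\tattempts\tlost\n")
            for sw in truth.sweeps:
                fh.write(f"{sw.population}\t{sw.snp_id}\t{sw.pos_bp}\t{sw.s}\t"
                         f"{sw.final_freq:.6g}\t{sw.attempts}\t{sw.lost}\n")
        return haps, snp_map, truth
    if config.vcf:
        haps, snp_map = read_phased_vcf(config.vcf, config.ancestral or "AA")
        if config.pop_map:
            pops = {}
            with open(config.pop_map) as fh:
                for line in fh:
                    if line.strip() and not line.startswith("#"):
                        s, p = line.split()[:2]
                        pops[s] = p
            labels = [pops.get(h.rsplit("_", 1)[0], "pop") for h in haps.hap_id]
            haps = HaplotypeSet(haps.alleles, labels, snp_map, haps.hap_id)
    else:
        haps, snp_map = read_hap_table(config.hap_table)
    if config.genetic_map:
        snp_map = read_genetic_map(config.genetic_map, snp_map)
        haps = HaplotypeSet(haps.alleles, haps.pop_of_hap, snp_map, haps.hap_id)
    return haps, snp_map, None


def compute_tracks(haps: HaplotypeSet, tests=INTERNAL_TESTS, window: int = 100,
                   step: int = 1) -> list:
    """Run the selected internal scans for every population."""
    tests = set(tests)
    tracks = []
    pops = haps.populations
    if tests & {"TajimaD", "FayWuH", "FuLiD"}:
        for p in pops:
            got = sfs.sliding_sfs_tracks(haps, p, window, step)
            tracks.extend(t for name, t in got.items() if name in tests)
    for p in pops:
        if "IHS" in tests:
            tracks.append(haplen.ihs_track(haps, p))
        if "NSL" in tests:
            tracks.append(haplen.nsl_track(haps, p))
        if "H12" in tests:
            tracks.append(haplen.h12_track(haps, p, window, step))
    if "FST" in tests:
        tracks.extend(diff.fst_tracks(haps, window=window, step=step).values())
    if "XPEHH" in tests:
        tracks.extend(haplen.xpehh_tracks(haps).values())
    if "VarLD" in tests:
        tracks.extend(diff.varld_tracks(haps, window=window, step=step).values())
    return tracks


def write_factor_model_tsv(path, model: axes.FactorModel) -> None:
    """Weights with loadings in parentheses plus % variance, one test per
    row — the factor-analysis summary table layout."""
    k = model.loadings.shape[1]
    with open(path, "w") as fh:
        head = "\t".join(f"axis{a + 1}" for a in range(k))
        fh.write(f"test\t{head}\tpct_variance\n")
        for i, name in enumerate(model.test_names):
            cells = "\t".join(
                f"{model.weights[i, a]:.2f} ({model.loadings[i, a]:.2f})"
                for a in range(k))
            fh.write(f"{name}\t{cells}\t{100 * model.communalities[i]:.0f}\n")
        tail = "\t".join(f"{100 * e:.0f}" for e in model.explained)
        fh.write(f"%variance_per_axis\t{tail}\t"
                 f"{100 * model.explained.sum():.0f}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    (out / "axes").mkdir(exist_ok=True)
    (out / "regions").mkdir(exist_ok=True)

    haps, snp_map, truth = _load_inputs(config, out)
    tracks = compute_tracks(haps, config.tests, config.window, config.step)
    for t in tracks:
        write_score_track(out / "tracks" / f"{t.test_name}_{t.population}.tsv", t)
    for p in config.external_tracks:
        tracks.append(read_score_track(p, snp_map))

    matrix = axes.build_score_matrix(tracks, config.transform)
    corr, order = axes.correlation_matrix(matrix)
    with open(out / "axes" / "correlations.tsv", "w") as fh:
        fh.write("test\t" + "\t".join(matrix.test_names) + "\n")
        for i, name in enumerate(matrix.test_names):
            fh.write(name + "\t" + "\t".join(f"{v:.4f}" for v in corr[i]) + "\n")
    model = axes.factor_analysis(corr, config.n_factors, matrix.test_names)
    write_factor_model_tsv(out / "axes" / "factor_model.tsv", model)
    axis_tracks = axes.axis_score_tracks(matrix, model, snp_map)
    for (a, p), t in axis_tracks.items():
        write_score_track(out / "axes" / f"axis{a}_{p}.tsv", t)

    all_regions = []
    for (a, p), t in sorted(axis_tracks.items(), key=lambda kv: (kv[0][0],
                                                                 str(kv[0][1]))):
        all_regions += reg.call_strict_regions(t, a, p, config.q_strict,
                                               config.min_snps, config.bin_bp)
        all_regions += reg.call_relaxed_regions(t, a, p, config.q_relaxed,
                                                config.bin_bp)
    reg.write_regions_tsv(out / "regions" / "regions.tsv", all_regions)
    reg.write_regions_bed(out / "regions" / "regions.bed", all_regions)
    if config.gene_annotation:
        ann = read_gene_annotation(config.gene_annotation,
                                   config.gene_annotation_format)
        strict = [r for r in all_regions if r.rule.startswith("strict")]
        _, universe = reg.overlap_genes(strict, ann)
        with open(out / "regions" / "candidate_genes.txt", "w") as fh:
            fh.write("".join(g + "\n" for g in universe))

    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in vars(config).items()},
                "artifacts": {}}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
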