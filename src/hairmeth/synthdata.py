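"""Seeded generator for every input the pipeline consumes, with ground truth.

The generator emulates the statistical structure of a two-stage skin
methylome comparison: 3 replicates per stage ("anagen", "telogen"),
CpG-depleted background sequence with CpG-rich islands, high CG methylation
in gene bodies and low in promoters, a hypomethylation dip around
transcription start sites, low CHG/CHH methylation slightly elevated at
islands and shores, a small global telogen CG hypermethylation offset,
planted DMRs of known location/effect/direction, an unmethylated
lambda-phage spike-in contig for conversion-rate estimation, and an
expression results table with planted DEGs, a subset co-located with
planted DMRs.

Everything is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import GeneModel, GenomicInterval, cgi_shores
from .methcore import ANAGEN, TELOGEN, MethylomeMatrix, genome_cytosines

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    include_lambda: bool = True
    lambda_name: str = "lambda"
    lambda_length: int = 48_502

    # sequence composition
    gc_content: float = 0.42
    cpg_suppression: float = 0.85   # fraction of background CpGs mutated away
    cgi_gc: float = 0.60
    n_genes: int = 80
    gene_length: tuple[int, int] = (3000, 8000)
    exons_per_gene: tuple[int, int] = (2, 5)
    n_cgis: int = 60
    cgi_length: tuple[int, int] = (500, 1500)
    n_repeats: int = 100
    repeat_length: tuple[int, int] = (200, 1000)

    # methylation structure (expected levels)
    level_cg_body: float = 0.75
    level_cg_intergenic: float = 0.70
    level_cg_promoter: float = 0.15
    level_cg_cgi: float = 0.10
    level_chg: float = 0.02
    level_chh: float = 0.01
    shore_hh_elevation: float = 0.03
    telogen_cg_offset: float = 0.03
    tss_dip_depth: float = 0.12
    tss_dip_sigma: float = 400.0

    # planted DMRs
    n_dmrs: int = 20
    dmr_width: tuple[int, int] = (1000, 3000)
    dmr_delta: float = 0.3
    dmr_min_cg_sites: int = 5

    # sequencing model
    mean_depth: float = 20.0
    depth_dispersion: float = 10.0
    wobble_concentration: float = 300.0
    conversion_error: float = 0.005
    n_replicates: int = 3
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH")

    # expression
    n_degs: int = 20
    n_overlap_genes: int = 5

    def validate(self) -> None:
        if self.n_overlap_genes > self.n_degs:
            raise ValueError("n_overlap_genes cannot exceed n_degs")
        if self.n_degs > self.n_genes:
            raise ValueError("more planted DEGs than genes")
        if self.gene_length[1] + 6000 > min(self.chrom_lengths.values(),
                                            default=10**9):
            raise ValueError("genes too long for the chromosomes")
        if not 0 < self.conversion_error < 1:
            raise ValueError("conversion_error must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """What was planted, for recovery scoring."""

    dmrs: list[dict]                 # chrom, start, end, direction, delta
    deg_ids: list[str]
    overlap_gene_ids: list[str]
    conversion_error: float
    expected_anagen: np.ndarray = field(repr=False, default=None)
    expected_telogen: np.ndarray = field(repr=False, default=None)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    seqs: dict[str, str]
    genes: list[GeneModel]
    cgis: list[GenomicInterval]
    repeats: list[GenomicInterval]
    matrix: MethylomeMatrix
    expression: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_sequence(length: int, gc: float, rng: np.random.Generator
                     ) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _block_intervals(chrom_lengths: dict[str, int], n: int,
                     length_range: tuple[int, int], margin: int,
                     rng: np.random.Generator) -> list[GenomicInterval]:
    """Place n non-overlapping intervals by splitting the genome into equal
    blocks (one interval per block), which guarantees non-overlap."""
    total = sum(chrom_lengths.values())
    out = []
    counts = {c: max(0, round(n * L / total)) for c, L in
              chrom_lengths.items()}
    # adjust rounding so exactly n intervals are placed
    chroms = list(chrom_lengths)
    while sum(counts.values()) < n:
        counts[chroms[len(out) % len(chroms)]] += 1
    while sum(counts.values()) > n:
        c = max(counts, key=counts.get)
        counts[c] -= 1
    for chrom, L in chrom_lengths.items():
        k = counts[chrom]
        if k == 0:
            continue
        block = L // k
        for b in range(k):
            lo = b * block + margin
            hi = (b + 1) * block - margin
            width = int(rng.integers(length_range[0],
                                     min(length_range[1], hi - lo - 1) + 1))
            start = int(rng.integers(lo, hi - width))
            out.append(GenomicInterval(chrom, start, start + width))
    return out


def make_genome(config: SimulationConfig
                ) -> tuple[dict[str, str], list[GeneModel],
                           list[GenomicInterval], list[GenomicInterval]]:
    """Build the reference: sequences, gene models, CGIs and repeats.

    Background sequence is CpG-depleted (a fraction of CG dinucleotides is
    mutated away) while CpG islands keep their G+C-rich composition intact,
    so CpG o/e is high inside islands and low outside.  Genes are
    non-overlapping with clear margins; the lambda spike-in contig is an
    ordinary 50% GC sequence that the methylome simulator leaves
    unmethylated by construction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    cgis = _block_intervals(config.chrom_lengths, config.n_cgis,
                            config.cgi_length, margin=200, rng=rng)
    genes_iv = _block_intervals(config.chrom_lengths, config.n_genes,
                                config.gene_length, margin=3000, rng=rng)
    repeats = [GenomicInterval(iv.chrom, iv.start, iv.end, ".", "repeat")
               for iv in _block_intervals(config.chrom_lengths,
                                          config.n_repeats,
                                          config.repeat_length, margin=50,
                                          rng=rng)]

    seqs: dict[str, str] = {}
    for chrom, L in config.chrom_lengths.items():
        arr = _random_sequence(L, config.gc_content, rng)
        in_cgi = np.zeros(L, dtype=bool)
        for iv in cgis:
            if iv.chrom == chrom:
                arr[iv.start:iv.end] = _random_sequence(
                    len(iv), config.cgi_gc, rng)
                in_cgi[iv.start:iv.end] = True
        # deplete background CpGs: mutate the G of a CG pair to A
        cg = np.flatnonzero((arr[:-1] == 1) & (arr[1:] == 2)
                            & ~in_cgi[:-1])
        hit = cg[rng.random(len(cg)) < config.cpg_suppression]
        arr[hit + 1] = 0
        seqs[chrom] = _BASES[arr].tobytes().decode("ascii")
    if config.include_lambda:
        arr = _random_sequence(config.lambda_length, 0.5, rng)
        seqs[config.lambda_name] = _BASES[arr].tobytes().decode("ascii")

    genes = []
    for i, iv in enumerate(genes_iv):
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(config.exons_per_gene[0],
                             config.exons_per_gene[1] + 1))
        cuts = np.sort(rng.choice(np.arange(iv.start + 50, iv.end - 50),
                                  size=2 * k - 2, replace=False))
        bounds = [iv.start, *cuts.tolist(), iv.end]
        exons = [(bounds[j], bounds[j + 1])
                 for j in range(0, 2 * k - 1, 2)]
        genes.append(GeneModel(f"gene{i:04d}", iv.chrom, strand,
                               iv.start, iv.end, exons))
    return seqs, genes, cgis, repeats


# ---------------------------------------------------------------------------
# Planted DMRs
# ---------------------------------------------------------------------------

def _cg_site_positions(seq: str) -> np.ndarray:
    """Sorted positions of CG-context cytosines on both strands."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    cg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
    return np.sort(np.concatenate([cg, cg + 1]))


def _plant_dmrs(config: SimulationConfig, seqs: dict[str, str],
                genes: list[GeneModel], overlap_genes: list[GeneModel],
                deg_gene_ids: set[str],
                rng: np.random.Generator) -> list[dict]:
    """Choose planted DMR intervals: one inside each overlap gene, the rest
    scattered away from DEG genes; every interval holds enough CG sites."""
    cg_pos = {c: _cg_site_positions(s) for c, s in seqs.items()
              if c in config.chrom_lengths}

    def n_sites(chrom, start, end):
        p = cg_pos[chrom]
        i0, i1 = np.searchsorted(p, [start, end])
        return i1 - i0

    planted: list[dict] = []

    def ok(chrom, start, end):
        if n_sites(chrom, start, end) < config.dmr_min_cg_sites:
            return False
        for d in planted:
            if d["chrom"] == chrom and start < d["end"] + 500 \
                    and d["start"] - 500 < end:
                return False
        return True

    direction = "hyper"
    for g in overlap_genes:
        width = min(int(rng.integers(*config.dmr_width)),
                    (g.end - g.start) - 200)
        for _ in range(50):
            start = int(rng.integers(g.start + 100, g.end - 100 - width))
            if ok(g.chrom, start, start + width):
                break
        planted.append({"chrom": g.chrom, "start": start,
                        "end": start + width, "direction": direction,
                        "delta": config.dmr_delta, "gene_id": g.gene_id})
        direction = "hypo" if direction == "hyper" else "hyper"

    n_rest = config.n_dmrs - len(overlap_genes)
    if n_rest > 0:
        forbidden = [(g.chrom, g.start - 2500, g.end + 2500)
                     for g in genes if g.gene_id in deg_gene_ids]
        blocks = _block_intervals(config.chrom_lengths, n_rest,
                                  (config.dmr_width[1] + 200,
                                   config.dmr_width[1] + 201),
                                  margin=2000, rng=rng)
        for block in blocks:
            width = int(rng.integers(*config.dmr_width))
            placed = False
            for _ in range(50):
                start = int(rng.integers(block.start,
                                         max(block.start + 1,
                                             block.end - width)))
                end = start + width
                if any(c == block.chrom and start < fe and fs < end
                       for c, fs, fe in forbidden):
                    continue
                if ok(block.chrom, start, end):
                    planted.append({"chrom": block.chrom, "start": start,
                                    "end": end, "direction": direction,
                                    "delta": config.dmr_delta,
                                    "gene_id": None})
                    direction = ("hypo" if direction == "hyper"
                                 else "hyper")
                    placed = True
                    break
            if not placed:
                continue
    return planted


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(config: SimulationConfig,
                       seqs: dict[str, str],
                       genes: list[GeneModel],
                       cgis: list[GenomicInterval],
                       planted: list[dict],
                       ) -> tuple[MethylomeMatrix, np.ndarray, np.ndarray]:
    """Draw per-sample counts around the configured expected levels.

    Per site: expected level from context and genomic feature (body,
    promoter, island, TSS dip, shore elevation), a telogen CG offset, and
    the planted DMR effects (realized as an explicit per-group level pair
    centred on the clamped local baseline, so the between-group difference
    is exactly delta).  Per sample: coverage is negative-binomial around the
    mean depth; the replicate's level wobbles around the expected level with
    a beta distribution; methylated counts are binomial with the
    conversion-error leak added to the unmethylated fraction.  The lambda
    contig is unmethylated everywhere.

    Returns (matrix, expected_anagen, expected_telogen).
    """
    rng = np.random.default_rng([config.seed, 2])
    frames, exp_a_parts, exp_t_parts = [], [], []
    for chrom, seq in seqs.items():
        sites = genome_cytosines(seq, chrom)
        sites = sites[sites["context"].isin(config.contexts)]
        sites = sites.reset_index(drop=True)
        pos = sites["pos"].to_numpy()
        ctx = sites["context"].to_numpy()
        n = len(sites)
        if chrom == config.lambda_name:
            ea = et = np.zeros(n)
        else:
            L = len(seq)
            paint = np.full(L, config.level_cg_intergenic)
            hh_lift = np.zeros(L, dtype=bool)
            for g in genes:
                if g.chrom != chrom:
                    continue
                paint[g.start:g.end] = config.level_cg_body
            for g in genes:
                if g.chrom != chrom:
                    continue
                p = g.promoter(2000)
                paint[p.start:min(L, p.end)] = config.level_cg_promoter
            for c in cgis:
                if c.chrom == chrom:
                    paint[c.start:c.end] = config.level_cg_cgi
                    hh_lift[c.start:c.end] = True
            for s in cgi_shores([c for c in cgis if c.chrom == chrom]):
                hh_lift[s.start:min(L, s.end)] = True
            # hypomethylation dip around every TSS
            dip = np.zeros(L)
            w = int(3 * config.tss_dip_sigma)
            for g in genes:
                if g.chrom != chrom:
                    continue
                t = g.tss
                lo, hi = max(0, t - w), min(L, t + w + 1)
                d = np.arange(lo, hi) - t
                dep = config.tss_dip_depth * np.exp(
                    -0.5 * (d / config.tss_dip_sigma) ** 2)
                dip[lo:hi] = np.maximum(dip[lo:hi], dep)
            base = np.empty(n)
            is_cg = ctx == "CG"
            base[is_cg] = np.clip(paint[pos[is_cg]] - dip[pos[is_cg]],
                                  0.01, 0.99)
            base[ctx == "CHG"] = config.level_chg
            base[ctx == "CHH"] = config.level_chh
            hh = ~is_cg & hh_lift[pos]
            base[hh] += config.shore_hh_elevation
            ea = base.copy()
            et = base.copy()
            et[is_cg] = np.clip(et[is_cg] + config.telogen_cg_offset,
                                0.0, 1.0)
            # planted DMRs override both group levels on CG sites
            half = config.dmr_delta / 2
            for d in planted:
                if d["chrom"] != chrom:
                    continue
                in_dmr = is_cg & (pos >= d["start"]) & (pos < d["end"])
                center = np.clip(base[in_dmr], 0.02 + half, 0.98 - half)
                if d["direction"] == "hyper":
                    ea[in_dmr] = center - half
                    et[in_dmr] = center + half
                else:
                    ea[in_dmr] = center + half
                    et[in_dmr] = center - half
        frames.append(sites)
        exp_a_parts.append(ea)
        exp_t_parts.append(et)

    sites = pd.concat(frames, ignore_index=True)
    exp_a = np.concatenate(exp_a_parts)
    exp_t = np.concatenate(exp_t_parts)

    n = len(sites)
    samples, groups = [], {}
    meth = np.empty((n, 2 * config.n_replicates), dtype=np.int64)
    total = np.empty_like(meth)
    r = config.depth_dispersion
    p_nb = r / (r + config.mean_depth)
    col = 0
    for group, expected in ((ANAGEN, exp_a), (TELOGEN, exp_t)):
        for rep in range(1, config.n_replicates + 1):
            name = f"{group}_{rep}"
            samples.append(name)
            groups[name] = group
            depth = rng.negative_binomial(r, p_nb, size=n)
            p_rep = expected.copy()
            inner = (expected > 0) & (expected < 1)
            k = config.wobble_concentration
            p_rep[inner] = rng.beta(k * expected[inner],
                                    k * (1 - expected[inner]))
            p_obs = p_rep + (1 - p_rep) * config.conversion_error
            meth[:, col] = rng.binomial(depth, p_obs)
            total[:, col] = depth
            col += 1
    matrix = MethylomeMatrix(sites, meth, total, samples, groups)
    return matrix, exp_a, exp_t


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(genes: list[GeneModel], deg_ids: list[str],
                        config: SimulationConfig) -> pd.DataFrame:
    """Expression results table with planted DEGs.

    Planted DEGs draw |log_fc| in (1.5, 3) and q in (0, 0.05]; every other
    gene draws log_fc ~ N(0, 0.3) and q in (0.05, 1], so it can never pass
    the DEG filter.
    """
    if len(deg_ids) > len(genes):
        raise ValueError("more planted DEGs than genes")
    rng = np.random.default_rng([config.seed, 3])
    deg = set(deg_ids)
    rows = []
    for g in genes:
        if g.gene_id in deg:
            lfc = float(rng.uniform(1.5, 3.0) * rng.choice([-1, 1]))
            q = float(rng.uniform(0.001, 0.05))
        else:
            lfc = float(rng.normal(0, 0.3))
            q = float(rng.uniform(0.0500001, 1.0))
        rows.append((g.gene_id, lfc, q))
    return pd.DataFrame(rows, columns=["gene_id", "log_fc", "q_value"])


# ---------------------------------------------------------------------------
# Bundled generation, presets, scoring, writing
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the complete input bundle plus ground truth."""
    seqs, genes, cgis, repeats = make_genome(config)
    rng = np.random.default_rng([config.seed, 4])
    if config.n_degs and genes:
        chosen = rng.choice(len(genes), size=config.n_degs, replace=False)
        deg_ids = [genes[i].gene_id for i in chosen]
    else:
        deg_ids = []
    overlap_genes = [g for g in genes
                     if g.gene_id in deg_ids[:config.n_overlap_genes]]
    planted = _plant_dmrs(config, seqs, genes, overlap_genes,
                          set(deg_ids), rng)
    matrix, exp_a, exp_t = simulate_methylome(config, seqs, genes, cgis,
                                              planted)
    expression = simulate_expression(genes, deg_ids, config)
    truth = SyntheticTruth(
        dmrs=planted, deg_ids=deg_ids,
        overlap_gene_ids=[g.gene_id for g in overlap_genes],
        conversion_error=config.conversion_error,
        expected_anagen=exp_a, expected_telogen=exp_t)
    return SyntheticDataset(config, seqs, genes, cgis, repeats, matrix,
                            expression, truth)


def preset_config(name: str, seed: int) -> SimulationConfig:
    """The three study presets.

    * ``small`` — the default conditions: 2 x 1 Mb chromosomes plus the
      lambda spike-in, all contexts, 20 planted DMRs, 20 planted DEGs of
      which 5 genes also carry a planted DMR.
    * ``null`` — 1 Mb, CG only, identical generative parameters for both
      groups (no offset, no planted DMRs), for false-positive calibration.
    * ``recovery`` — 2 x 1 Mb, CG only, 50 planted DMRs of width 1-3 kb and
      effect 0.3, for sensitivity/precision measurement.
    """
    if name == "small":
        return SimulationConfig(seed=seed)
    if name == "null":
        return SimulationConfig(
            seed=seed, chrom_lengths={"chr1": 1_000_000},
            include_lambda=False, contexts=("CG",), n_dmrs=0,
            telogen_cg_offset=0.0, n_degs=0, n_overlap_genes=0,
            n_genes=40, n_cgis=30, n_repeats=50)
    if name == "recovery":
        return SimulationConfig(
            seed=seed, include_lambda=False, contexts=("CG",), n_dmrs=50,
            dmr_width=(1000, 3000), dmr_delta=0.3, n_degs=0,
            n_overlap_genes=0)
    raise ValueError(f"unknown preset {name!r}")


def score_dmr_recovery(called, truth: SyntheticTruth) -> dict[str, float]:
    """Recovery metrics of called DMRs against the planted truth.

    Sensitivity: fraction of planted DMRs overlapped by >= 1 called DMR.
    Base precision: fraction of called bases inside planted intervals.
    Direction agreement: fraction of truth-overlapping called DMRs whose
    direction matches the planted one.
    """
    truth_iv = [(d["chrom"], d["start"], d["end"], d["direction"])
                for d in truth.dmrs]
    hit = [False] * len(truth_iv)
    called_bases = correct_bases = 0
    n_overlapping = n_direction_ok = 0
    for d in called:
        called_bases += d.end - d.start
        for i, (c, s, e, direc) in enumerate(truth_iv):
            if c == d.chrom and d.start < e and s < d.end:
                hit[i] = True
                correct_bases += min(d.end, e) - max(d.start, s)
                if direc == d.direction:
                    n_direction_ok += 1
                n_overlapping += 1
    return {
        "sensitivity": (sum(hit) / len(hit)) if hit else float("nan"),
        "base_precision": (correct_bases / called_bases
                           if called_bases else float("nan")),
        "direction_agreement": (n_direction_ok / n_overlapping
                                if n_overlapping else float("nan")),
        "n_called": float(len(called)),
        "n_planted": float(len(truth_iv)),
    }


def write_bundle(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the full input bundle as plain-text files plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(dataset.seqs, outdir / "genome.fa")
    io_formats.write_gene_models(dataset.genes, outdir / "genes.gtf")
    io_formats.write_intervals(dataset.cgis, outdir / "cgi.bed")
    io_formats.write_intervals(dataset.repeats, outdir / "repeats.bed")
    m = dataset.matrix
    for j, name in enumerate(m.samples):
        df = m.sites.copy()
        df["meth_count"] = m.meth[:, j]
        df["total_count"] = m.total[:, j]
        covered = df["total_count"] > 0
        io_formats.write_site_table(df[covered], outdir / f"{name}.meth.tsv")
    io_formats.write_expression_table(dataset.expression,
                                      outdir / "expression.tsv")
    truth = {
        "dmrs": dataset.truth.dmrs,
        "deg_ids": dataset.truth.deg_ids,
        "overlap_gene_ids": dataset.truth.overlap_gene_ids,
        "conversion_error": dataset.truth.conversion_error,
        "groups": dataset.matrix.groups,
        "config": {k: v for k, v in
                   dataclasses.asdict(dataset.config).items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
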