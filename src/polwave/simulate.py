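"""Ground-truth simulator for the experiments the pipeline analyses.

Three data modalities are emulated, all with truth tables written alongside:

* cytoplasmic long-read 3' ends — per gene, each read picks one annotated
  cleavage site (PAS) multinomially from a condition-specific usage vector
  and its 3' terminus is jittered with rounded Gaussian noise;
* DRB/TT-seq nascent coverage — after release from DRB inhibition, Pol II
  advances at a gene-specific velocity v (kb/min); the expected labeled-RNA
  coverage at distance x from the TSS at release time t is

      background + body * 1[0 <= x <= v*(t - t0)]
                 + amplitude * exp(-(x - v*(t - t0))**2 / (2 * width**2))

  with Poisson-distributed observed bin counts;
* ChIP-style coverage — Poisson background with multiplicative TSS-window
  and gene-body enrichment, plus a matched pure-background input track.

Randomness: one numpy Generator per (operation, condition, replicate),
derived from the single master seed, so partial re-runs are reproducible and
a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ConfigError
from .coverage import CoverageTrack
from . import io as pio

__all__ = [
    "SimulationConfig",
    "apa_usage_matrix",
    "make_genome",
    "make_pas",
    "simulate_reads",
    "simulate_ttseq",
    "simulate_chip",
    "wave_expectation",
    "write_dataset",
]

# operation codes for RNG stream derivation
_OP_GENOME, _OP_READS, _OP_TTSEQ, _OP_CHIP = 1, 3, 4, 5


def _cond_code(condition: str) -> int:
    return zlib.crc32(condition.encode()) & 0x7FFFFFFF


def apa_usage_matrix(
    n_genes: int,
    n_pas: int = 2,
    proximal_control: float = 0.3,
    proximal_case: float = 0.6,
    shifted_fraction: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-condition PAS usage matrices for the two-condition shift design.

    The first ``shifted_fraction`` of genes moves its proximal usage from
    ``proximal_control`` to ``proximal_case`` in the case condition; the rest
    keep control usage.  With >2 PAS the non-proximal mass is split evenly
    over the remaining sites, keeping the most TSS-distal site dominant among
    them irrelevant to the proximal fraction.
    """
    if n_pas < 2:
        raise ConfigError("n_pas must be >= 2")

    def vec(p: float) -> np.ndarray:
        v = np.full(n_pas, (1.0 - p) / (n_pas - 1))
        v[0] = p
        return v

    control = np.tile(vec(proximal_control), (n_genes, 1))
    case = control.copy()
    n_shift = int(round(n_genes * shifted_fraction))
    case[:n_shift] = vec(proximal_case)
    return {"control": control, "case": case}


@dataclass
class SimulationConfig:
    """Design constants of the emulated experiments.

    Defaults mirror the study design: two conditions x three replicates,
    200 reads per gene, 2 PAS per gene with a 0.3 -> 0.6 proximal-usage shift
    in half the genes, 10-bp 3'-end noise, DRB-release times 10/20/30/40 min
    with a 10-min labeling window, and 60-300 kb non-overlapping genes.
    """

    n_genes: int = 60
    gene_length_range: tuple[int, int] = (60_000, 300_000)
    intergenic_gap: int = 10_000
    n_pas_per_gene: int = 2
    pas_spacing: int = 5_000
    usage_by_condition: dict[str, np.ndarray] | None = None
    reads_per_gene: int = 200
    poisson_depth: bool = False
    end_noise_sd: float = 10.0
    velocities: np.ndarray | dict[str, np.ndarray] | None = None
    expression_scale: np.ndarray | None = None  # per-gene wave amplitude multiplier
    release_times: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    label_duration: float = 10.0
    wave_offset: float = 0.0  # t0 in minutes; rate regression is offset-invariant
    wave_width: float = 2_000.0  # bp; Gaussian front breadth from the label window
    bin_size: int = 200
    body_level: float = 15.0
    background_level: float = 2.0
    front_amplitude: float = 30.0
    chip_bin: int = 50
    chip_background: float = 2.0
    tss_enrichment: float = 10.0
    body_enrichment: float = 3.0
    tss_window: int = 1_000
    seed: int = 0
    chrom_name: str = "chrS"

    replicates: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if self.usage_by_condition is None:
            self.usage_by_condition = apa_usage_matrix(
                self.n_genes, self.n_pas_per_gene
            )
        if self.velocities is None:
            # lognormal-ish spread around ~2 kb/min in control, 2.1x slower in case
            rng = np.random.default_rng([self.seed, 99])
            v = np.exp(rng.normal(np.log(2.0), 0.25, self.n_genes))
            self.velocities = {"control": v, "case": v / 2.1}
        self.validate()

    # ------------------------------------------------------------ checks

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError("gene_length_range must satisfy 0 < min <= max")
        if self.n_pas_per_gene < 2:
            raise ConfigError("n_pas_per_gene must be >= 2")
        if lo < 2 * self.pas_spacing:
            raise ConfigError("gene_length_range min must be >= 2*pas_spacing")
        if self.n_pas_per_gene * self.pas_spacing > lo:
            raise ConfigError("pas_spacing * n_pas exceeds the shortest gene")
        for cond, mat in self.usage_by_condition.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (self.n_genes, self.n_pas_per_gene):
                raise ConfigError(
                    f"usage matrix for {cond!r} must be n_genes x n_pas"
                )
            if (mat < 0).any() or (mat > 1).any():
                raise ConfigError(f"usage probabilities for {cond!r} outside [0,1]")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError(f"usage rows for {cond!r} must sum to 1")
            self.usage_by_condition[cond] = mat
        times = np.asarray(self.release_times, dtype=float)
        if times.size == 0 or (np.diff(times) <= 0).any():
            raise ConfigError("release_times must be nonempty, strictly increasing")
        if self.expression_scale is not None:
            es = np.asarray(self.expression_scale, float)
            if es.shape != (self.n_genes,) or (es < 0).any():
                raise ConfigError("expression_scale must be one nonneg value per gene")
            self.expression_scale = es
        for v in self._velocity_map().values():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.n_genes,):
                raise ConfigError("velocities must have one value per gene")
            if (v < 0).any():
                raise ConfigError("negative velocity")
        if self.tss_enrichment < 1 or self.body_enrichment < 1:
            raise ConfigError("enrichment factors must be >= 1")

    def _velocity_map(self) -> dict[str, np.ndarray]:
        if isinstance(self.velocities, dict):
            return {k: np.asarray(v, float) for k, v in self.velocities.items()}
        v = np.asarray(self.velocities, float)
        return {c: v for c in self.usage_by_condition}

    def velocity(self, condition: str) -> np.ndarray:
        vmap = self._velocity_map()
        if condition not in vmap:
            raise ConfigError(f"no velocities for condition {condition!r}")
        return vmap[condition]

    def rng(self, op: int, condition: str = "", replicate: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            [int(self.seed), op, _cond_code(condition), int(replicate)]
        )


# ----------------------------------------------------------------- genome


def make_genome(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Lay out non-overlapping genes of random length on one chromosome.

    Genes alternate strand, are separated by ``intergenic_gap`` and flanked
    by one gap at each chromosome end.  Returns a BED6-style gene table
    (name = gene id, score column reused as gene index) and chrom sizes.
    """
    rng = config.rng(_OP_GENOME)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    rows = []
    cursor = config.intergenic_gap
    for i, length in enumerate(lengths):
        strand = "+" if i % 2 == 0 else "-"
        rows.append(
            (config.chrom_name, cursor, cursor + int(length), f"g{i:04d}", "0", strand)
        )
        cursor += int(length) + config.intergenic_gap
    genes = pd.DataFrame(rows, columns=pio.BED6_COLUMNS)
    sizes = {config.chrom_name: int(cursor)}
    return genes, sizes


def gene_tss(genes: pd.DataFrame) -> np.ndarray:
    """Genomic TSS coordinate per gene (start on +, end-1 on -)."""
    return np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)


def make_pas(genes: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Annotate ``n_pas_per_gene`` cleavage sites per gene.

    Sites are ranked 1..n by transcriptional distance from the TSS
    (strand-aware); the most TSS-distal site sits at the 3' gene end and is
    flagged distal.  Columns: chrom, pos, gene_id, rank, is_distal, strand.
    """
    if config.n_pas_per_gene < 2:
        raise ConfigError("n_pas_per_gene must be >= 2")
    n = config.n_pas_per_gene
    rows = []
    for g in genes.itertuples(index=False):
        length = g.end - g.start
        if n * config.pas_spacing > length:
            raise ConfigError(
                f"{g.name}: pas_spacing*n_pas ({n * config.pas_spacing}) "
                f"exceeds gene length ({length})"
            )
        # transcriptional offsets from TSS; distal at the 3' end
        offsets = [length - 1 - (n - 1 - k) * config.pas_spacing for k in range(n)]
        for rank, off in enumerate(offsets, start=1):
            pos = g.start + off if g.strand == "+" else g.end - 1 - off
            rows.append(
                (g.chrom, int(pos), g.name, rank, rank == n, g.strand)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "gene_id", "rank", "is_distal", "strand"]
    )


def pas_to_bed(pas: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of a PAS table (name=geneID:rank, score=1 for distal)."""
    return pd.DataFrame(
        {
            "chrom": pas["chrom"],
            "start": pas["pos"],
            "end": pas["pos"] + 1,
            "name": pas["gene_id"] + ":" + pas["rank"].astype(str),
            "score": pas["is_distal"].astype(int).astype(str),
            "strand": pas["strand"],
        }
    )


def pas_from_bed(bed: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`pas_to_bed`."""
    name = bed["name"].str.rsplit(":", n=1, expand=True)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "pos": bed["start"].astype(int),
            "gene_id": name[0],
            "rank": name[1].astype(int),
            "is_distal": bed["score"].astype(int).astype(bool),
            "strand": bed["strand"],
        }
    )


# ------------------------------------------------------------------ reads


def simulate_reads(
    genes: pd.DataFrame,
    pas: pd.DataFrame,
    config: SimulationConfig,
    condition: str,
    replicate: int = 1,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw long-read 3' ends for one (condition, replicate) library.

    Returns ``(ends, spans, truth)``: single-base 3'-end BED6 records, the
    matching full-length TSS->3' spans, and the per-gene truth table
    (true proximal fraction, read count).
    """
    if condition not in config.usage_by_condition:
        raise ConfigError(f"unknown condition {condition!r}")
    usage = config.usage_by_condition[condition]
    rng = config.rng(_OP_READS, condition, replicate)
    tss = gene_tss(genes)
    end_rows, span_rows, truth_rows = [], [], []
    for gi, g in enumerate(genes.itertuples(index=False)):
        n_reads = (
            int(rng.poisson(config.reads_per_gene))
            if config.poisson_depth
            else config.reads_per_gene
        )
        gene_pas = pas[pas["gene_id"] == g.name].sort_values("rank")
        positions = gene_pas["pos"].to_numpy()
        choice = rng.choice(len(positions), size=n_reads, p=usage[gi])
        noise = np.round(rng.normal(0.0, config.end_noise_sd, size=n_reads)).astype(int)
        pos3 = positions[choice] + noise
        if chrom_sizes:
            pos3 = np.clip(pos3, 0, chrom_sizes[g.chrom] - 1)
        for ri, p3 in enumerate(pos3):
            rid = f"{g.name}|{condition}|r{replicate}|{ri}"
            end_rows.append((g.chrom, int(p3), int(p3) + 1, rid, "0", g.strand))
            lo, hi = (tss[gi], p3 + 1) if g.strand == "+" else (p3, tss[gi] + 1)
            span_rows.append((g.chrom, int(min(lo, hi)), int(max(lo, hi)), rid, "0", g.strand))
        truth_rows.append((g.name, float(usage[gi][0]), n_reads))
    ends = pd.DataFrame(end_rows, columns=pio.BED6_COLUMNS)
    spans = pd.DataFrame(span_rows, columns=pio.BED6_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "true_proximal_fraction", "n_reads"]
    )
    return ends, spans, truth


# ------------------------------------------------------------------ TT-seq


def wave_expectation(
    x: np.ndarray, velocity_kb_min: float, time_min: float, config: SimulationConfig
) -> np.ndarray:
    """Expected nascent coverage at distance ``x`` (bp) from the TSS."""
    front = velocity_kb_min * 1000.0 * (time_min - config.wave_offset)
    body = config.body_level * ((x >= 0) & (x <= front))
    gauss = config.front_amplitude * np.exp(
        -((x - front) ** 2) / (2.0 * config.wave_width**2)
    )
    return config.background_level + body + gauss


def simulate_ttseq(
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: SimulationConfig,
    condition: str = "control",
    noiseless: bool = False,
) -> dict[float, dict[str, CoverageTrack]]:
    """Simulate strand-specific nascent coverage per DRB-release time.

    Returns ``{time: {'+': track, '-': track}}``; bin values are expected
    coverage (noiseless) or Poisson draws around it.  Coverage from each gene
    is laid down over the whole chromosome grid at ``config.bin_size``,
    indexed by transcriptional distance from its TSS.
    """
    velocities = config.velocity(condition)
    rng = config.rng(_OP_TTSEQ, condition)
    tss = gene_tss(genes)
    out: dict[float, dict[str, CoverageTrack]] = {}
    bs = config.bin_size
    grids = {
        chrom: (np.arange(int(np.ceil(size / bs))) * bs + bs / 2.0)
        for chrom, size in chrom_sizes.items()
    }
    for t in config.release_times:
        dense = {
            s: {c: np.zeros(len(g)) for c, g in grids.items()} for s in "+-"
        }
        for gi, g in enumerate(genes.itertuples(index=False)):
            centers = grids[g.chrom]
            x = centers - tss[gi] if g.strand == "+" else tss[gi] - centers
            # restrict to the gene's forward neighborhood to keep waves local
            mask = (x >= -2 * bs) & (x <= 200_000)
            expect = np.zeros_like(centers)
            expect[mask] = wave_expectation(x[mask], velocities[gi], t, config)
            expect[mask] -= config.background_level  # background added once below
            if config.expression_scale is not None:
                expect[mask] *= config.expression_scale[gi]
            dense[g.strand][g.chrom] += expect
        for s in "+-":
            for chrom in dense[s]:
                dense[s][chrom] += config.background_level
                if not noiseless:
                    dense[s][chrom] = rng.poisson(dense[s][chrom]).astype(float)
        out[t] = {s: CoverageTrack.from_dense(dense[s], bs) for s in "+-"}
    return out


# -------------------------------------------------------------------- ChIP


def simulate_chip(
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: SimulationConfig,
    condition: str = "control",
    tss_enrichment: float | None = None,
    body_enrichment: float | None = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Poisson ChIP track with TSS/body enrichment plus a matched input.

    Bin values are Poisson counts at ``chip_background`` per ``chip_bin``,
    multiplied (in expectation) by the enrichment inside TSS windows
    (TSS +/- tss_window) and gene bodies.  The input track is pure background.
    """
    tssf = config.tss_enrichment if tss_enrichment is None else tss_enrichment
    bodyf = config.body_enrichment if body_enrichment is None else body_enrichment
    if tssf < 1 or bodyf < 1:
        raise ConfigError("enrichment factors must be >= 1")
    rng = config.rng(_OP_CHIP, condition)
    bs = config.chip_bin
    tss = gene_tss(genes)
    chip_dense, input_dense = {}, {}
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / bs))
        lam = np.full(n_bins, config.chip_background)
        centers = np.arange(n_bins) * bs + bs / 2.0
        sel = genes["chrom"] == chrom
        for gi, g in zip(np.flatnonzero(sel.to_numpy()), genes[sel].itertuples(index=False)):
            in_body = (centers >= g.start) & (centers < g.end)
            lam[in_body] *= bodyf
            # TSS windows get tss_enrichment over background, overriding body factor
            in_tss = np.abs(centers - (tss[gi] + 0.5)) <= config.tss_window
            lam[in_tss] = config.chip_background * tssf
        chip_dense[chrom] = rng.poisson(lam).astype(float)
        input_dense[chrom] = rng.poisson(
            np.full(n_bins, config.chip_background)
        ).astype(float)
    return (
        CoverageTrack.from_dense(chip_dense, bs),
        CoverageTrack.from_dense(input_dense, bs),
    )


# ----------------------------------------------------------------- dataset


def write_dataset(out_dir, config: SimulationConfig) -> dict[str, Path]:
    """Simulate the full experiment set and write every artifact as text.

    Writes genes.bed/genes.gtf, pas.bed, chrom.sizes, per condition x
    replicate 3'-end and full-length read BEDs, stranded TT-seq bedGraphs per
    release time, ChIP + input bedGraphs, and truth.tsv.  Returns the path
    map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    genes, sizes = make_genome(config)
    pas = make_pas(genes, config)
    paths["genes.bed"] = out / "genes.bed"
    pio.write_bed6(genes, paths["genes.bed"])
    paths["genes.gtf"] = out / "genes.gtf"
    pio.write_gtf_genes(genes, paths["genes.gtf"])
    paths["pas.bed"] = out / "pas.bed"
    pio.write_bed6(pas_to_bed(pas), paths["pas.bed"])
    paths["chrom.sizes"] = out / "chrom.sizes"
    pio.write_chrom_sizes(sizes, paths["chrom.sizes"])

    truth_frames = []
    for cond in sorted(config.usage_by_condition):
        for rep in config.replicates:
            ends, spans, truth = simulate_reads(genes, pas, config, cond, rep, sizes)
            k_e = f"reads_3prime_{cond}_rep{rep}.bed"
            k_s = f"reads_full_{cond}_rep{rep}.bed"
            paths[k_e] = out / k_e
            paths[k_s] = out / k_s
            pio.write_bed6(ends, paths[k_e])
            pio.write_bed6(spans, paths[k_s])
            truth = truth.assign(condition=cond, replicate=rep)
            truth_frames.append(truth)
        tracks = simulate_ttseq(genes, sizes, config, cond)
        for t, by_strand in tracks.items():
            for strand, tag in (("+", "plus"), ("-", "minus")):
                k = f"ttseq_{cond}_t{int(t)}_{tag}.bedgraph"
                paths[k] = out / k
                by_strand[strand].to_bedgraph(paths[k])
        chip, inp = simulate_chip(genes, sizes, config, cond)
        for k, tr in ((f"chip_{cond}.bedgraph", chip), (f"input_{cond}.bedgraph", inp)):
            paths[k] = out / k
            tr.to_bedgraph(paths[k])

    truth = pd.concat(truth_frames, ignore_index=True)
    vmap = config._velocity_map()
    vel = pd.DataFrame(
        {
            "gene_id": genes["name"],
            **{f"velocity_{c}_kb_min": vmap[c] for c in sorted(vmap)},
            "expression_scale": (
                config.expression_scale
                if config.expression_scale is not None
                else np.ones(config.n_genes)
            ),
        }
    )
    truth = truth.merge(vel, on="gene_id")
    paths["truth.tsv"] = out / "truth.tsv"
    pio.write_tsv(
        truth,
        paths["truth.tsv"],
        comments=[
            "per-library simulation ground truth",
            "true_proximal_fraction: multinomial probability of the rank-1 PAS",
            "velocity_*_kb_min: Pol II elongation velocity (kb/min)",
        ],
    )
    return paths
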