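"""End-to-end orchestration: simulate -> apa -> elongation -> chip -> manifest.

Each stage reads only files written by earlier stages, so any stage can be
re-run independently from on-disk inputs.  A manifest records the package
version, the full parameter set and the sha256 of every output, which makes
"same seed => identical run" checkable by hash comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__, apa, chip, elongation as elo
from . import io as pio
from .config import RunConfig
from .coverage import CoverageTrack
from .simulate import pas_from_bed, write_dataset

log = logging.getLogger("polwave")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_apa_stage(cfg: RunConfig, data_dir: Path, out_dir: Path) -> dict[str, Path]:
    """Classify genes from simulated 3'-end libraries; write usage/class/venn/expression tables."""
    out_dir.mkdir(parents=True, exist_ok=True)
    pas = pas_from_bed(pio.read_bed6(data_dir / "pas.bed"))
    sim = cfg.sim_config()
    paths: dict[str, Path] = {}
    usage_frames, classifications = [], []
    for rep in sim.replicates:
        summaries = {}
        for cond in ("control", "case"):
            ends = pio.read_bed6(data_dir / f"reads_3prime_{cond}_rep{rep}.bed")
            counts, n_un = apa.pas_usage_table(
                ends, pas, f"{cond}_rep{rep}", window=cfg.pas_window
            )
            usage_frames.append(counts)
            summary = apa.usage_summary(counts, cfg.proximal_policy)
            summaries[cond] = summary
            log.info("apa: %s_rep%d, %d ends unassigned", cond, rep, n_un)
        classifications.append(
            apa.classify_genes(
                summaries["case"], summaries["control"],
                tau=cfg.tau, min_pas=cfg.min_pas,
                min_distal_reads=cfg.min_distal_reads,
            ).assign(replicate=rep)
        )
    paths["usage.tsv"] = out_dir / "usage.tsv"
    pio.write_tsv(pd.concat(usage_frames, ignore_index=True), paths["usage.tsv"],
                  comments=["3'-end counts per PAS rank per library"])
    paths["classification.tsv"] = out_dir / "classification.tsv"
    pio.write_tsv(pd.concat(classifications, ignore_index=True),
                  paths["classification.tsv"],
                  comments=[f"fold = ratio_case/ratio_control, tau={cfg.tau}"])
    consensus = apa.intersect_replicates(classifications)
    venn_rows = [("consensus_dependent", len(consensus["consensus_dependent"])),
                 ("consensus_distal", len(consensus["consensus_distal"])),
                 ("consensus_independent", len(consensus["consensus_independent"]))]
    venn_rows += sorted(consensus["venn_proximal_dependent"].items())
    paths["venn.tsv"] = out_dir / "venn.tsv"
    pio.write_tsv(pd.DataFrame(venn_rows, columns=["region", "n_genes"]),
                  paths["venn.tsv"],
                  comments=["replicate-intersection summary; venn keys are membership patterns"])
    # expression screen on replicate-1 full-length reads
    def counts_for(cond: str) -> pd.Series:
        spans = pio.read_bed6(data_dir / f"reads_full_{cond}_rep1.bed")
        gene = spans["name"].str.split("|", n=1).str[0]
        return gene.value_counts().sort_index()

    expr = apa.expression_fold_change(counts_for("case"), counts_for("control"),
                                      fold=cfg.expression_fold)
    paths["expression.tsv"] = out_dir / "expression.tsv"
    pio.write_tsv(expr, paths["expression.tsv"],
                  comments=["rpm = full-length reads per million library reads",
                            f"reduced: control_rpm/case_rpm > {cfg.expression_fold}"])
    # stash consensus gene lists for the elongation group comparison
    for key in ("consensus_dependent", "consensus_independent"):
        paths[f"{key}.txt"] = out_dir / f"{key}.txt"
        with open(paths[f"{key}.txt"], "w") as fh:
            for g in sorted(consensus[key]):
                fh.write(g + "\n")
    return paths


def run_elongation_stage(cfg: RunConfig, data_dir: Path, out_dir: Path,
                         apa_dir: Path | None = None) -> dict[str, Path]:
    """Call wave peaks and estimate rates per condition; compare gene classes."""
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim_config()
    genes = pio.read_bed6(data_dir / "genes.bed")
    sizes = pio.read_chrom_sizes(data_dir / "chrom.sizes")
    intervals = elo.build_gene_intervals(
        genes, sizes, cfg.min_gene_width, cfg.max_gene_width,
        cfg.window_upstream, cfg.window_downstream,
    )
    paths: dict[str, Path] = {}
    rate_frames, peak_frames, meta_rows = [], [], []
    for cond in sorted(sim.usage_by_condition):
        matrices, gene_ids, x_kb = {}, None, None
        profiles = {}
        for t in sim.release_times:
            tracks = {
                "+": CoverageTrack.from_bedgraph(
                    data_dir / f"ttseq_{cond}_t{int(t)}_plus.bedgraph"),
                "-": CoverageTrack.from_bedgraph(
                    data_dir / f"ttseq_{cond}_t{int(t)}_minus.bedgraph"),
            }
            m, gene_ids, x_kb = elo.coverage_matrix(tracks, intervals, cfg.bin_size)
            matrices[t] = m
            raw, smoothed = elo.metagene_profile(m, x_kb)
            profiles[t] = smoothed
            peak, _ = elo.call_wave_peak(x_kb, raw)
            meta_rows.append((cond, t, peak))
        if cfg.make_plots:
            from . import plots

            # QC figure only: deliberately kept out of the hash manifest
            plots.plot_wave_profiles(
                x_kb, profiles, out_dir / f"profiles_{cond}.png",
                title=f"metagene wave, {cond}",
            )
        peaks = elo.gene_wave_peaks(
            matrices, gene_ids, x_kb, cfg.bin_size, cfg.min_rpm,
            cfg.min_first_peak_kb,
        )
        peak_frames.append(peaks.assign(condition=cond))
        rates = elo.estimate_gene_rates(peaks)
        rate_frames.append(rates.assign(condition=cond))
    paths["peaks.tsv"] = out_dir / "peaks.tsv"
    pio.write_tsv(pd.concat(peak_frames, ignore_index=True), paths["peaks.tsv"],
                  comments=["wave peak positions, kb downstream of the TSS"])
    rates = pd.concat(rate_frames, ignore_index=True)
    paths["rates.tsv"] = out_dir / "rates.tsv"
    pio.write_tsv(rates, paths["rates.tsv"],
                  comments=["per-gene elongation rate, kb/min (OLS slope)"])
    meta = pd.DataFrame(meta_rows, columns=["condition", "time_min", "metagene_peak_kb"])
    rows = []
    for cond, grp in meta.groupby("condition", sort=True):
        est = elo.elongation_rate(grp["time_min"], grp["metagene_peak_kb"])
        rows.append((cond, est.slope_kb_min, est.intercept_kb, est.r_squared))
    paths["metagene_rates.tsv"] = out_dir / "metagene_rates.tsv"
    pio.write_tsv(pd.DataFrame(rows, columns=["condition", "rate_kb_min",
                                              "intercept_kb", "r_squared"]),
                  paths["metagene_rates.tsv"],
                  comments=["metagene elongation rate per condition, kb/min"])
    # group comparison: consensus-dependent vs consensus-independent genes (control rates)
    if apa_dir is not None:
        ctrl = rates[rates["condition"] == "control"].set_index("gene_id")
        groups = {}
        for key in ("consensus_dependent", "consensus_independent"):
            f = apa_dir / f"{key}.txt"
            ids = [l.strip() for l in open(f)] if f.exists() else []
            groups[key] = ctrl.loc[ctrl.index.intersection(ids), "rate_kb_min"]
        if all(len(v) >= 2 for v in groups.values()):
            cmp = elo.compare_rate_groups(groups["consensus_dependent"],
                                          groups["consensus_independent"])
            paths["group_comparison.tsv"] = out_dir / "group_comparison.tsv"
            pio.write_tsv(pd.DataFrame([cmp]), paths["group_comparison.tsv"],
                          comments=["a=consensus_dependent, b=consensus_independent",
                                    "fold_b_over_a on mean rates; Welch two-sided t"])
    return paths


def run_chip_stage(cfg: RunConfig, data_dir: Path, out_dir: Path) -> dict[str, Path]:
    """Metaplots and Poisson peak calls for the ChIP tracks, plus the condition comparison."""
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = pio.read_bed6(data_dir / "genes.bed")
    sizes = pio.read_chrom_sizes(data_dir / "chrom.sizes")
    tracks = {c: CoverageTrack.from_bedgraph(data_dir / f"chip_{c}.bedgraph")
              for c in ("control", "case")}
    inp = CoverageTrack.from_bedgraph(data_dir / "input_control.bedgraph")
    paths: dict[str, Path] = {}
    spec = chip.MetaplotSpec()
    profs = {}
    for cond, tr in tracks.items():
        prof, layout = chip.metaplot(tr, genes, spec)
        profs[cond] = prof
    prof_in, _ = chip.metaplot(inp, genes, spec)
    meta = pd.DataFrame({"bin": range(len(prof_in)),
                         "control_rpm": profs["control"],
                         "case_rpm": profs["case"],
                         "input_rpm": prof_in})
    paths["metaplot.tsv"] = out_dir / "metaplot.tsv"
    pio.write_tsv(meta, paths["metaplot.tsv"],
                  comments=["anchored metagene profile, rpm per 50-bp (flanks) / scaled (body) bin"])
    peaks = chip.call_peaks(tracks["control"], sizes, inp,
                            cfg.peak_window, cfg.peak_step, cfg.p_cutoff,
                            genes, cfg.tss_window)
    paths["peaks.bed"] = out_dir / "peaks.bed"
    with open(paths["peaks.bed"], "w") as fh:
        for pk in peaks.itertuples(index=False):
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.annotation}\t0\t.\t"
                     f"{pk.p_value:.3g}\t{pk.density_rpm:.6g}\t{pk.background_lam:.6g}\n")
    comparison = chip.compare_peak_intensity(peaks, tracks["case"], tracks["control"])
    paths["peak_comparison.tsv"] = out_dir / "peak_comparison.tsv"
    pio.write_tsv(comparison, paths["peak_comparison.tsv"],
                  comments=["rpm peak densities per annotation class; paired t on log densities"])
    return paths


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage from a config; returns the output directory.

    Outputs land in ``<out_dir>/{data,apa,elongation,chip}`` plus
    ``manifest.json``; a stage failure aborts with the stage name while
    earlier outputs stay on disk.
    """
    cfg.validate()
    defaults = asdict(RunConfig())
    for key, value in asdict(cfg).items():
        if value != defaults.get(key):
            log.info("parameter %s = %r (non-default)", key, value)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim_config()
    all_paths: dict[str, Path] = {}
    stages = [
        ("simulate", lambda: write_dataset(out / "data", sim)),
        ("apa", lambda: run_apa_stage(cfg, out / "data", out / "apa")),
        ("elongation", lambda: run_elongation_stage(cfg, out / "data",
                                                    out / "elongation", out / "apa")),
        ("chip", lambda: run_chip_stage(cfg, out / "data", out / "chip")),
    ]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            all_paths.update({f"{name}/{k}": Path(v) for k, v in fn().items()})
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "outputs": {k: _sha256(p) for k, p in sorted(all_paths.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
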