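"""ChIP-style metagene profiles and sliding-window Poisson peak calling.

The metaplot averages depth-normalized coverage over a gene set in anchored
coordinates: fixed-resolution 50-bp bins in the flanks (1 kb before the TSS,
3 kb after the polyA site) and a length-scaled gene body resampled to a
common bin count.  Peak calling is a deliberately simple stand-in for a
full MACS-style caller: each sliding window is tested one-sided against a
Poisson expectation taken from a depth-scaled input track (or the
genome-wide background when no input is available), significant windows are
merged, and merged peaks are annotated TSS / gene_body / intergenic.  The
quoted raw p cutoff (1e-5) is applied per window with no multiplicity
correction, mirroring the original analysis convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .simulate import gene_tss

__all__ = ["MetaplotSpec", "metaplot", "call_peaks", "peak_density",
           "compare_peak_intensity"]


@dataclass
class MetaplotSpec:
    bin: int = 50               # bp, flank resolution
    upstream: int = 1_000       # bp before the TSS
    downstream: int = 3_000     # bp after the polyA site
    body_bins: int = 100        # length-normalized gene-body bins


def _chunk_means(values: np.ndarray, n_out: int) -> np.ndarray:
    """Average ``values`` into ``n_out`` near-equal contiguous chunks."""
    edges = np.linspace(0, len(values), n_out + 1).round().astype(int)
    sums = np.add.reduceat(values, edges[:-1])
    widths = np.diff(edges)
    # guard empty chunks (len(values) < n_out): reuse neighbor value
    widths = np.maximum(widths, 1)
    return sums / widths


def metaplot(
    track: CoverageTrack, genes: pd.DataFrame, spec: MetaplotSpec = MetaplotSpec()
) -> tuple[np.ndarray, dict]:
    """Mean rpm metagene profile over ``genes`` (strand-flipped, anchored).

    Returns ``(profile, layout)`` where layout gives the index ranges of the
    upstream-flank, body and downstream-flank segments.  Genes shorter than
    one body bin per flank bin are dropped with a warning; an empty usable
    gene set is an error.
    """
    total = track.total()
    if total <= 0:
        raise ValueError("track has zero depth")
    n_up = spec.upstream // spec.bin
    n_down = spec.downstream // spec.bin
    rows = []
    for g in genes.itertuples(index=False):
        length = g.end - g.start
        if length < spec.bin * 2:
            warnings.warn(f"{g.name}: gene shorter than flanks, dropped", stacklevel=2)
            continue
        if g.strand == "+":
            up = track.window_means(g.chrom, g.start - spec.upstream, g.start, spec.bin)
            down = track.window_means(g.chrom, g.end, g.end + spec.downstream, spec.bin)
        else:
            up = track.window_means(g.chrom, g.end, g.end + spec.upstream, spec.bin)[::-1]
            down = track.window_means(
                g.chrom, g.start - spec.downstream, g.start, spec.bin
            )[::-1]
        body_len = (length // spec.bin) * spec.bin
        start = g.start if g.strand == "+" else g.end - body_len
        body = track.window_means(g.chrom, start, start + body_len, spec.bin)
        if g.strand == "-":
            body = body[::-1]
        body = _chunk_means(body, spec.body_bins)
        rows.append(np.concatenate([up, body, down]))
    if not rows:
        raise ValueError("no usable genes in the metaplot gene set")
    profile = np.vstack(rows).mean(axis=0) * 1e6 / total
    layout = {
        "upstream": (0, n_up),
        "body": (n_up, n_up + spec.body_bins),
        "downstream": (n_up + spec.body_bins, n_up + spec.body_bins + n_down),
    }
    return profile, layout


# ------------------------------------------------------------------- peaks


def call_peaks(
    track: CoverageTrack,
    chrom_sizes: dict[str, int],
    input_track: CoverageTrack | None = None,
    window: int = 500,
    step: int = 100,
    p_cutoff: float = 1e-5,
    genes: pd.DataFrame | None = None,
    tss_window: int = 1_000,
    local_background: int = 5_000,
) -> pd.DataFrame:
    """Sliding-window one-sided Poisson enrichment test, merged into peaks.

    Track values are read as counts per bedGraph interval (the simulator
    emits one count value per bin); window counts sum them, so a window over
    pure Poisson background is itself Poisson.  The null expectation per
    window is the depth-scaled input density averaged over a centered
    ``local_background`` region (wider than the window, to damp input shot
    noise), or the genome-wide mean when ``input_track`` is missing or
    empty.  Windows with
    P(X >= observed) <= p_cutoff are merged when they overlap or abut.
    Peaks carry the minimum window p, the background expectation, the rpm
    density (window-count x 1e6 / depth / length) and, when ``genes`` is
    given, a TSS/gene_body/intergenic annotation (TSS wins on overlap with
    TSS +/- tss_window).
    """
    if window < step:
        raise ValueError("window must be >= step")
    depth = track.total_count()
    use_input = input_track is not None and input_track.total_count() > 0
    if input_track is not None and not use_input:
        warnings.warn("input track has zero depth; using global background",
                      stacklevel=2)
    if use_input:
        input_depth = input_track.total_count()
        scale = depth / input_depth
    genome = sum(chrom_sizes.values())
    global_lam = depth / genome * window if genome else 0.0
    win_per = window // step
    peaks = []
    for chrom, size in chrom_sizes.items():
        steps = track.binned_counts(chrom, size, step)
        kernel = np.ones(win_per)
        counts = np.convolve(steps, kernel)[win_per - 1 : len(steps)]
        if use_input:
            isteps = input_track.binned_counts(chrom, size, step)
            loc_per = max(local_background // step, win_per)
            loc_kernel = np.ones(loc_per)
            # centered local sums, edge-normalized to per-step density
            loc = np.convolve(isteps, loc_kernel, mode="same")
            norm = np.convolve(np.ones_like(isteps), loc_kernel, mode="same")
            density = loc / norm  # input count per step bin, locally averaged
            # align local density with window start positions
            centers = np.minimum(
                np.arange(len(steps) - win_per + 1) + win_per // 2, len(steps) - 1
            )
            lam = np.maximum(density[centers] * win_per * scale, 1e-12)
        else:
            lam = np.full_like(counts, max(global_lam, 1e-12))
        pvals = stats.poisson.sf(np.ceil(counts - 1e-9) - 1, lam)
        sig = np.flatnonzero(pvals <= p_cutoff)
        if len(sig) == 0:
            continue
        # merge windows that overlap or abut
        run_start = sig[0]
        prev = sig[0]
        runs = []
        for i in sig[1:]:
            if (i - prev) * step <= window:
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            start = int(a * step)
            end = int(min(b * step + window, size))
            cnt = track.window_count(chrom, start, end)
            sel = slice(a, b + 1)
            peaks.append(
                (
                    chrom, start, end, cnt,
                    float(lam[a : b + 1].mean()),
                    float(pvals[sel].min()),
                    cnt * 1e6 / depth / (end - start),
                )
            )
    out = pd.DataFrame(
        peaks,
        columns=["chrom", "start", "end", "count", "background_lam",
                 "p_value", "density_rpm"],
    )
    out["annotation"] = "intergenic"
    if genes is not None and len(out):
        tss = gene_tss(genes)
        for i, pk in out.iterrows():
            g_sel = genes["chrom"] == pk["chrom"]
            gs = genes[g_sel]
            ts = tss[g_sel.to_numpy()]
            if np.any((pk["start"] <= ts + tss_window) & (pk["end"] > ts - tss_window)):
                out.at[i, "annotation"] = "TSS"
            elif np.any((pk["start"] < gs["end"]) & (pk["end"] > gs["start"])):
                out.at[i, "annotation"] = "gene_body"
    return out


def peak_density(
    peaks: pd.DataFrame, track: CoverageTrack, depth: float | None = None
) -> np.ndarray:
    """rpm density of each peak region evaluated in ``track``.

    ``depth`` defaults to the track's own total count; pass an explicit
    library size when the track is a partial view of a larger library.
    """
    if depth is None:
        depth = track.total_count()
    if depth <= 0:
        raise ValueError("track has zero depth")
    dens = np.array(
        [
            track.window_count(pk.chrom, pk.start, pk.end) / (pk.end - pk.start)
            for pk in peaks.itertuples(index=False)
        ]
    )
    return dens * 1e6 / depth


def compare_peak_intensity(
    peaks: pd.DataFrame,
    track_case: CoverageTrack,
    track_control: CoverageTrack,
    depth_case: float | None = None,
    depth_control: float | None = None,
) -> pd.DataFrame:
    """Per-annotation-class case/control intensity fold with paired t-test.

    The same peak regions are evaluated in both tracks (rpm densities);
    fold is the ratio of class means and the paired two-sided t-test runs on
    per-peak log densities (peaks with a zero density in either track are
    excluded from the test but kept in the means).  Empty classes are
    skipped.
    """
    case = peak_density(peaks, track_case, depth_case)
    ctrl = peak_density(peaks, track_control, depth_control)
    rows = []
    for ann, grp in peaks.groupby("annotation", sort=True):
        idx = grp.index.to_numpy()
        c, k = case[idx], ctrl[idx]
        if len(idx) == 0 or k.mean() == 0:
            continue
        ok = (c > 0) & (k > 0)
        if ok.sum() >= 2 and not np.allclose(np.log(c[ok]), np.log(k[ok])):
            p = float(stats.ttest_rel(np.log(c[ok]), np.log(k[ok])).pvalue)
        else:
            p = 1.0
        rows.append((ann, len(idx), float(c.mean()), float(k.mean()),
                     float(c.mean() / k.mean()), p))
    return pd.DataFrame(
        rows,
        columns=["annotation", "n_peaks", "mean_case_rpm", "mean_control_rpm",
                 "fold_case_over_control", "p_value"],
    )
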