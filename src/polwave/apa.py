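"""Alternative-polyadenylation (APA) analysis from long-read 3' ends.

The procedure: reads are reduced to their 3'-terminal base, each terminus is
assigned to the nearest annotated same-strand cleavage site (PAS) within a
window, per-gene proximal/distal usage ratios r = proximal/distal are formed
for each library, and genes are classified between conditions by the fold
change f = r_case / r_control against a threshold tau (default 1.5):
f >= tau -> proximal_dependent, f <= 1/tau -> distal_dependent, otherwise
independent.  Replicate classifications are intersected to form consensus
dependent/independent sets, and full-length read counts screen for genes
whose cytoplasmic level drops between conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = ("proximal_dependent", "distal_dependent", "independent", "untestable")

__all__ = [
    "trim_to_3prime",
    "extract_three_prime_ends",
    "extract_three_prime_ends_bam",
    "assign_to_pas",
    "pas_usage_table",
    "usage_summary",
    "select_testable",
    "classify_fold",
    "classify_genes",
    "intersect_replicates",
    "expression_fold_change",
]


# ------------------------------------------------------------ read handling


def trim_to_3prime(records, keep_last: int = 200):
    """Yield FASTQ records trimmed to their last ``keep_last`` bases.

    Reads shorter than the window pass through unchanged; ids and qualities
    are preserved.  Operates on Biopython SeqRecords (see io.read_fastq).
    """
    if keep_last < 1:
        raise ValueError("keep_last must be >= 1")
    for rec in records:
        yield rec[-keep_last:] if len(rec) > keep_last else rec


def extract_three_prime_ends(spans: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Reduce aligned spans (BED6) to single-base 3' termini.

    + strand -> pos = end - 1; - strand -> pos = start.  Records with
    strand '.' are skipped; the count of skipped records is returned.
    """
    known = spans["strand"].isin(["+", "-"])
    n_skipped = int((~known).sum())
    s = spans[known]
    pos = np.where(s["strand"] == "+", s["end"] - 1, s["start"])
    ends = pd.DataFrame(
        {
            "chrom": s["chrom"].to_numpy(),
            "start": pos,
            "end": pos + 1,
            "name": s["name"].to_numpy(),
            "score": s["score"].to_numpy(),
            "strand": s["strand"].to_numpy(),
        }
    )
    return ends.reset_index(drop=True), n_skipped


def extract_three_prime_ends_bam(path) -> tuple[pd.DataFrame, int]:
    """3' termini from a BAM/SAM file; secondary/supplementary reads dropped."""
    import pysam

    rows = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                n_skipped += 1
                continue
            if aln.is_reverse:
                pos = aln.reference_start
                strand = "-"
            else:
                pos = aln.reference_end - 1
                strand = "+"
            rows.append(
                (aln.reference_name, pos, pos + 1, aln.query_name, "0", strand)
            )
    from .io import BED6_COLUMNS

    return pd.DataFrame(rows, columns=BED6_COLUMNS), n_skipped


# --------------------------------------------------------------- assignment


def assign_to_pas(ends: pd.DataFrame, pas: pd.DataFrame, window: int = 50) -> np.ndarray:
    """Assign each 3' end to the nearest same-strand PAS within ``window`` bp.

    Returns an integer array: row index into ``pas`` for assigned ends,
    -1 for unassigned.  Distance ties are broken toward the more TSS-distal
    site, i.e. downstream in the direction of transcription (larger genomic
    coordinate on +, smaller on -), which biases against proximal calls.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    result = np.full(len(ends), -1, dtype=np.int64)
    pas = pas.reset_index(drop=True)
    for (chrom, strand), grp in pas.groupby(["chrom", "strand"], sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        pos_sorted = grp["pos"].to_numpy()[order]
        idx_sorted = grp.index.to_numpy()[order]
        sel = (ends["chrom"] == chrom) & (ends["strand"] == strand)
        if not sel.any():
            continue
        epos = ends.loc[sel, "start"].to_numpy()
        right = np.searchsorted(pos_sorted, epos, side="left")
        left = right - 1
        d_left = np.where(left >= 0, epos - pos_sorted[np.clip(left, 0, None)], np.iinfo(np.int64).max)
        d_right = np.where(
            right < len(pos_sorted),
            pos_sorted[np.clip(right, None, len(pos_sorted) - 1)] - epos,
            np.iinfo(np.int64).max,
        )
        # tie-break distal-ward: + strand prefers the larger coordinate
        if strand == "+":
            use_right = d_right <= d_left
        else:
            use_right = d_right < d_left
        chosen = np.where(use_right, np.clip(right, None, len(pos_sorted) - 1), np.clip(left, 0, None))
        dist = np.where(use_right, d_right, d_left)
        assigned = np.where(dist <= window, idx_sorted[chosen], -1)
        result[np.flatnonzero(sel.to_numpy())] = assigned
    return result


def pas_usage_table(
    ends: pd.DataFrame, pas: pd.DataFrame, sample_id: str, window: int = 50
) -> tuple[pd.DataFrame, int]:
    """Count assigned 3' ends per (gene, PAS rank) for one library.

    Returns ``(counts, n_unassigned)`` with one row per PAS (gene_id, rank,
    is_distal, count, sample_id); conservation holds:
    counts.sum() + n_unassigned == len(ends).
    """
    assignment = assign_to_pas(ends, pas, window)
    n_unassigned = int((assignment == -1).sum())
    counted = pd.Series(assignment[assignment >= 0]).value_counts()
    counts = pas.reset_index(drop=True)[["gene_id", "rank", "is_distal"]].copy()
    counts["count"] = counts.index.map(counted).fillna(0).astype(int)
    counts["sample_id"] = sample_id
    return counts, n_unassigned


# ------------------------------------------------------------ ratio/classes


def usage_summary(counts: pd.DataFrame, proximal_policy: str = "sum_upstream") -> pd.DataFrame:
    """Per-gene proximal/distal counts and ratio for one library.

    ``proximal_policy`` selects the proximal count from the non-distal sites:
    'sum_upstream' (default) sums all of them, 'most_proximal' takes rank 1,
    'max_upstream' takes their maximum.  The ratio column is NaN where the
    distal count is zero.
    """
    if proximal_policy not in ("sum_upstream", "most_proximal", "max_upstream"):
        raise ValueError(f"unknown proximal_policy {proximal_policy!r}")
    rows = []
    for gene_id, grp in counts.groupby("gene_id", sort=True):
        distal = int(grp.loc[grp["is_distal"], "count"].sum())
        upstream = grp.loc[~grp["is_distal"], "count"]
        if proximal_policy == "sum_upstream":
            proximal = int(upstream.sum())
        elif proximal_policy == "most_proximal":
            proximal = int(grp.loc[grp["rank"] == 1, "count"].sum())
        else:
            proximal = int(upstream.max()) if len(upstream) else 0
        ratio = proximal / distal if distal > 0 else np.nan
        rows.append((gene_id, len(grp), proximal, distal, ratio))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_pas", "proximal_count", "distal_count", "ratio"]
    )


def select_testable(
    summary: pd.DataFrame, min_pas: int = 2, min_distal_reads: int = 5
) -> pd.DataFrame:
    """Flag genes testable in a library: enough PAS and enough distal reads."""
    out = summary.copy()
    out["testable"] = (out["n_pas"] >= min_pas) & (out["distal_count"] >= min_distal_reads)
    return out


def classify_fold(r_case: float, r_control: float, tau: float = 1.5) -> tuple[float, str]:
    """Fold change f = r_case/r_control and its category.

    Conventions for zero denominators: both ratios zero -> independent;
    control zero with case positive -> proximal_dependent (fold inf).
    """
    if r_control == 0:
        if r_case == 0:
            return 1.0, "independent"
        return float("inf"), "proximal_dependent"
    f = r_case / r_control
    if f >= tau:
        return f, "proximal_dependent"
    if f <= 1.0 / tau:
        return f, "distal_dependent"
    return f, "independent"


def classify_genes(
    summary_case: pd.DataFrame,
    summary_control: pd.DataFrame,
    tau: float = 1.5,
    min_pas: int = 2,
    min_distal_reads: int = 5,
) -> pd.DataFrame:
    """Per-gene category for one case-vs-control replicate pair.

    A gene is testable for the comparison only if testable in both
    libraries; untestable genes are categorized 'untestable' with NaN fold.
    """
    case = select_testable(summary_case, min_pas, min_distal_reads).set_index("gene_id")
    ctrl = select_testable(summary_control, min_pas, min_distal_reads).set_index("gene_id")
    genes = case.index.union(ctrl.index)
    rows = []
    for g in genes:
        ok = (
            g in case.index
            and g in ctrl.index
            and bool(case.at[g, "testable"])
            and bool(ctrl.at[g, "testable"])
        )
        if not ok:
            rows.append((g, np.nan, np.nan, np.nan, "untestable"))
            continue
        r_case, r_ctrl = float(case.at[g, "ratio"]), float(ctrl.at[g, "ratio"])
        fold, cat = classify_fold(r_case, r_ctrl, tau)
        rows.append((g, r_case, r_ctrl, fold, cat))
    return pd.DataFrame(
        rows, columns=["gene_id", "ratio_case", "ratio_control", "fold", "category"]
    )


def intersect_replicates(classifications: list[pd.DataFrame]) -> dict:
    """Consensus sets over replicate classifications, plus Venn counts.

    consensus_dependent: proximal_dependent in every replicate;
    consensus_distal: distal_dependent in every replicate;
    consensus_independent: independent (hence testable) in every replicate.
    Venn region counts are reported for the per-replicate
    proximal-dependent sets, keyed by membership pattern e.g. '110'.
    """
    if not classifications:
        raise ValueError("need at least one replicate classification")
    per_rep = [
        {
            cat: set(df.loc[df["category"] == cat, "gene_id"])
            for cat in CATEGORIES
        }
        for df in classifications
    ]
    consensus_dep = set.intersection(*[r["proximal_dependent"] for r in per_rep])
    consensus_distal = set.intersection(*[r["distal_dependent"] for r in per_rep])
    consensus_ind = set.intersection(*[r["independent"] for r in per_rep])
    dep_sets = [r["proximal_dependent"] for r in per_rep]
    universe = set.union(*dep_sets) if dep_sets else set()
    venn: dict[str, int] = {}
    for g in universe:
        key = "".join("1" if g in s else "0" for s in dep_sets)
        venn[key] = venn.get(key, 0) + 1
    return {
        "consensus_dependent": consensus_dep,
        "consensus_distal": consensus_distal,
        "consensus_independent": consensus_ind,
        "venn_proximal_dependent": venn,
    }


# ------------------------------------------------------------- expression


def expression_fold_change(
    case_counts: pd.Series, control_counts: pd.Series, fold: float = 1.5
) -> pd.DataFrame:
    """Screen genes for reduced cytoplasmic level in the case condition.

    Counts are full-length read counts per gene; levels are rpm-normalized
    by each library's total.  A gene is flagged when
    control_rpm / case_rpm > fold.  Zero case rpm with positive control rpm
    reports an infinite fold and is flagged.  Sorted by fold, descending.
    """
    case_lib = float(case_counts.sum())
    ctrl_lib = float(control_counts.sum())
    if case_lib <= 0 or ctrl_lib <= 0:
        raise ValueError("library sizes must be > 0")
    genes = case_counts.index.union(control_counts.index)
    case_rpm = case_counts.reindex(genes, fill_value=0) * 1e6 / case_lib
    ctrl_rpm = control_counts.reindex(genes, fill_value=0) * 1e6 / ctrl_lib
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            case_rpm > 0,
            ctrl_rpm / case_rpm,
            np.where(ctrl_rpm > 0, np.inf, 1.0),
        )
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "case_rpm": case_rpm.to_numpy(),
            "control_rpm": ctrl_rpm.to_numpy(),
            "fold": f,
            "reduced": f > fold,
        }
    )
    return out.sort_values("fold", ascending=False, kind="stable").reset_index(drop=True)
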