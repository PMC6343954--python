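"""Downstream analytics: tau specificity, enrichment, TSS proximity,
neighbour correlation and antisense fold-change concordance.

The tau index of a per-tissue mean-expression profile x_1..x_N is

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

0 for ubiquitous expression, 1 for single-tissue expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import TranscriptCandidate

TAU_CUTOFF = 0.8
MIN_MEAN_LOG2 = 3.0
DE_ALPHA = 0.05


def tau(profile: Sequence[float]) -> float:
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau needs a 1-d profile of >= 2 tissues")
    if (x < 0).any():
        raise ValueError("tau is undefined for negative expression")
    m = x.max()
    if m == 0:
        raise ValueError("tau is undefined for an all-zero profile")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def subtype_profiles(
    matrix: pd.DataFrame, sample_group: Mapping[str, str], log2: bool = True
) -> pd.DataFrame:
    """Per-feature, per-group expression profile.

    With ``log2`` (the default) the profile value for group g is
    log2(mean count over g's samples + 1); raw group means otherwise.
    """
    groups = sorted(set(sample_group.values()))
    cols = {}
    for g in groups:
        samples = [s for s in matrix.columns if sample_group.get(s) == g]
        if not samples:
            raise ValueError(f"group {g!r} has no samples in the matrix")
        m = matrix[samples].mean(axis=1)
        cols[g] = np.log2(m + 1.0) if log2 else m
    return pd.DataFrame(cols)


def subtype_specific(
    matrix: pd.DataFrame,
    sample_group: Mapping[str, str],
    tau_cutoff: float = TAU_CUTOFF,
    min_mean_log2: float = MIN_MEAN_LOG2,
) -> pd.DataFrame:
    """Features with tau > 0.8 and best-group mean log2 expression > 3.

    Returns a frame indexed by feature with columns tau, best_group,
    best_mean_log2 and specific (bool).
    """
    prof = subtype_profiles(matrix, sample_group, log2=True)
    if prof.shape[1] < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for fid, row in prof.iterrows():
        vals = row.values.astype(float)
        if vals.max() <= 0:
            t = np.nan
            specific = False
        else:
            t = tau(vals)
            specific = (t > tau_cutoff) and (vals.max() > min_mean_log2)
        rows.append(
            {
                "feature": fid,
                "tau": t,
                "best_group": row.idxmax(),
                "best_mean_log2": float(vals.max()),
                "specific": bool(specific),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def enrichment_2x2(
    k_specific_a: int, n_a: int, k_specific_b: int, n_b: int
) -> tuple[float, float]:
    """Fisher exact test of specificity enrichment between two feature sets.

    Table rows are (specific, not specific) for classes a and b. Returns
    (odds ratio, two-sided p); the odds ratio uses the Haldane 0.5
    correction when any cell is zero.
    """
    a, b = k_specific_a, n_a - k_specific_a
    c, d = k_specific_b, n_b - k_specific_b
    if min(a, b, c, d) < 0 or n_a <= 0 or n_b <= 0:
        raise ValueError("degenerate 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return float(orr), float(p)


# ---------------------------------------------------------------------------
# TSS proximity


@dataclass
class TssSummary:
    fraction_within_window: float
    median_distance: float
    mean_distance_trimmed: float
    n_candidates: int
    distances_trimmed: list[float]


def five_prime_end(candidate: TranscriptCandidate) -> int:
    """Genomic position of the transcript 5' end (0-based)."""
    return candidate.exons[0].start if candidate.strand == "+" else candidate.exons[-1].end - 1


def tss_proximity(
    candidates: Sequence[TranscriptCandidate],
    tss: pd.DataFrame,
    window: int = 100,
) -> tuple[pd.DataFrame, TssSummary]:
    """Signed distance from each candidate 5' end to its nearest same-strand TSS.

    Distance is strand-oriented: negative when the TSS lies upstream of the
    transcript start. The summary reports the fraction of candidates with a
    TSS within ``window`` bp, the median distance, and mean/distances after
    removing outliers beyond 1.5x the interquartile range.
    """
    recs = []
    for c in candidates:
        sub = tss[(tss["chrom"] == c.chrom) & (tss["strand"] == c.strand)]
        if sub.empty:
            continue
        p5 = five_prime_end(c)
        pos = sub["start"].values
        i = int(np.abs(pos - p5).argmin())
        t = int(pos[i])
        d = (t - p5) if c.strand == "+" else (p5 - t)
        recs.append({"id": c.id, "tss_pos": t, "distance": d})
    df = pd.DataFrame(recs, columns=["id", "tss_pos", "distance"])
    if df.empty:
        return df, TssSummary(0.0, float("nan"), float("nan"), 0, [])
    dist = df["distance"].astype(float)
    frac = float((dist.abs() <= window).mean())
    q1, q3 = np.percentile(dist, [25, 75])
    iqr = q3 - q1
    trimmed = dist[(dist >= q1 - 1.5 * iqr) & (dist <= q3 + 1.5 * iqr)]
    return df, TssSummary(
        fraction_within_window=frac,
        median_distance=float(dist.median()),
        mean_distance_trimmed=float(trimmed.mean()),
        n_candidates=len(df),
        distances_trimmed=[float(v) for v in trimmed],
    )


# ---------------------------------------------------------------------------
# neighbour correlation


def neighbor_correlation(
    pairs: Sequence[tuple[str, str, int]],
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """Expression correlation of intergenic candidates with their neighbours.

    ``pairs`` holds (candidate id, neighbour gene id, distance bp). The
    per-pair statistic is Pearson correlation of log2(x+1) expression across
    samples; the distance-vs-correlation association is Spearman's rho over
    pairs. Returns (per-pair frame, spearman rho, spearman p).
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    rows = []
    for cid, gid, dist in pairs:
        if cid not in matrix.index or gid not in matrix.index:
            continue
        x = np.log2(matrix.loc[cid].values.astype(float) + 1)
        y = np.log2(matrix.loc[gid].values.astype(float) + 1)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r, _ = stats.pearsonr(x, y)
        rows.append({"id": cid, "neighbor": gid, "distance": dist, "correlation": r})
    df = pd.DataFrame(rows, columns=["id", "neighbor", "distance", "correlation"])
    if len(df) < 3:
        return df, float("nan"), float("nan")
    rho, p = stats.spearmanr(df["distance"], df["correlation"])
    return df, float(rho), float(p)


# ---------------------------------------------------------------------------
# antisense concordance


def antisense_concordance(
    pairs: Sequence[tuple[str, str]],
    de: pd.DataFrame,
    alpha: float = DE_ALPHA,
) -> tuple[float, pd.DataFrame]:
    """Fraction of antisense lncRNA / sense gene pairs with opposite log2FC.

    ``de`` is indexed by feature with columns log2fc and padj. A pair is
    opposite when the product of the two fold changes is negative (zero fold
    change counts as non-opposite). Also returns the pairs where both
    members are significant (padj < alpha) with opposite signs.
    """
    n = 0
    opp = 0
    sig_rows = []
    for lnc, gene in pairs:
        if lnc not in de.index or gene not in de.index:
            continue
        lf, gf = float(de.loc[lnc, "log2fc"]), float(de.loc[gene, "log2fc"])
        n += 1
        if lf * gf < 0:
            opp += 1
            if de.loc[lnc, "padj"] < alpha and de.loc[gene, "padj"] < alpha:
                sig_rows.append(
                    {
                        "lncRNA": lnc,
                        "sense_gene": gene,
                        "lnc_log2fc": lf,
                        "gene_log2fc": gf,
                    }
                )
    frac = opp / n if n else float("nan")
    return frac, pd.DataFrame(
        sig_rows, columns=["lncRNA", "sense_gene", "lnc_log2fc", "gene_log2fc"]
    )
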