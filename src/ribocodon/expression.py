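"""ORF-windowed expression, RPKM, fold changes and gene-set enrichment.

Gene expression uses an unsplit pool of 5'-end counts over the ORF window
running from 12 nt upstream of the start codon to 14 nt upstream of the stop
codon, with the first 8 codons excluded (the head exclusion dominates the
upstream pad, so the default window is [12, L - 14) where L is the first nt
of the stop codon).  RPKM is reads per kilobase of ORF window per million
ORF-assigned reads.  Enrichment of a gene set among changed genes uses the
upper-tail hypergeometric test; distribution shifts of a target set use the
two-sample K-S test against the rest of the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .footprints import PooledFiveprimeTrack
from .reference import OrfModel

log = logging.getLogger(__name__)


@dataclass
class ExpressionConfig:
    upstream_pad: int = 12
    stop_pad: int = 14
    head_exclusion_codons: int = 8
    use_unsplit_pool: bool = True

    def __post_init__(self) -> None:
        if self.upstream_pad < 0 or self.stop_pad < 0:
            raise ValueError("pads must be >= 0")


@dataclass(frozen=True)
class EnrichmentResult:
    overlap_count: int
    set_sizes: tuple[int, int]
    background_size: int
    hypergeometric_p: float


def orf_window_count(
    track: PooledFiveprimeTrack,
    orf: OrfModel,
    config: ExpressionConfig | None = None,
) -> tuple[int | None, int]:
    """(window_reads, window_length) for one ORF; reads is None when the
    window is empty (tiny ORF, flagged and excluded from library totals)."""
    cfg = config or ExpressionConfig()
    L_stop = len(orf.coding_seq) - 3  # first nt of the stop codon
    start = max(3 * cfg.head_exclusion_codons - cfg.upstream_pad, -cfg.upstream_pad)
    end = L_stop - cfg.stop_pad
    if end <= start:
        return None, 0
    layer = track.unsplit_array if cfg.use_unsplit_pool else track.shifted_array
    arr = layer(orf.orf_id)
    reads = int(arr[start + track.upstream : end + track.upstream].sum())
    return reads, end - start


def rpkm_table(
    track: PooledFiveprimeTrack,
    orfs: dict[str, OrfModel],
    config: ExpressionConfig | None = None,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Windowed counts and RPKM for every ORF.

    rpkm = window_reads / (window_length/1000) / (library_orf_reads/1e6),
    where library_orf_reads sums window reads over non-flagged ORFs.
    """
    cfg = config or ExpressionConfig()
    rows = []
    for orf_id, orf in orfs.items():
        reads, length = orf_window_count(track, orf, cfg)
        rows.append(
            {"orf_id": orf_id, "window_reads": reads, "window_length_nt": length,
             "flagged": reads is None}
        )
    df = pd.DataFrame(rows)
    total = df.loc[~df["flagged"], "window_reads"].sum()
    if total == 0:
        raise ValueError("zero ORF-assigned reads in library")
    df["rpkm"] = np.where(
        df["flagged"],
        np.nan,
        df["window_reads"].astype(float)
        / (df["window_length_nt"] / 1000.0)
        / (total / 1e6),
    )
    df["sample_id"] = sample_id
    return df


def fold_change_table(
    records_mut: list[pd.DataFrame],
    records_wt: list[pd.DataFrame],
    min_window_reads: int = 1,
) -> pd.DataFrame:
    """Per-gene log2 fold change, averaged over paired replicates.

    Replicates are paired positionally (mut[i] vs wt[i]); genes failing the
    minimum-expression filter in any sample are dropped and counted in the
    ``n_dropped`` attribute of the returned frame.
    """
    if len(records_mut) != len(records_wt) or not records_mut:
        raise ValueError("need equal, nonzero numbers of mutant and WT replicates")
    per_rep = []
    dropped: set[str] = set()
    for i, (m, w) in enumerate(zip(records_mut, records_wt)):
        mm = m.loc[~m["flagged"], ["orf_id", "window_reads", "rpkm"]]
        ww = w.loc[~w["flagged"], ["orf_id", "window_reads", "rpkm"]]
        j = mm.merge(ww, on="orf_id", suffixes=("_mut", "_wt"))
        if len(j) == 0:
            raise ValueError("no overlapping genes between conditions")
        bad = (
            (j["window_reads_mut"] < min_window_reads)
            | (j["window_reads_wt"] < min_window_reads)
            | (j["rpkm_mut"] <= 0)
            | (j["rpkm_wt"] <= 0)
        )
        dropped |= set(j.loc[bad, "orf_id"])
        j = j[~bad]
        per_rep.append(
            j.assign(log2_fc=np.log2(j["rpkm_mut"] / j["rpkm_wt"]))[["orf_id", "log2_fc"]]
            .rename(columns={"log2_fc": f"log2_fc_{i}"})
        )
    out = per_rep[0]
    for rep in per_rep[1:]:
        out = out.merge(rep, on="orf_id", how="inner")
    out = out[~out["orf_id"].isin(dropped)].copy()
    fc_cols = [c for c in out.columns if c.startswith("log2_fc_")]
    out["log2_fc"] = out[fc_cols].mean(axis=1)
    out["n_replicates"] = len(fc_cols)
    out.attrs["n_dropped"] = len(dropped)
    return out[["orf_id", "log2_fc", "n_replicates"] + fc_cols]


def hypergeometric_overlap(set_a: set, set_b: set, background: set) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= overlap) for two gene sets drawn from
    a common background (the genes with confident expression everywhere)."""
    a, b, bg = set(set_a), set(set_b), set(background)
    offenders = (a | b) - bg
    if offenders:
        raise ValueError(
            "sets not contained in background: " + ", ".join(sorted(map(str, offenders))[:10])
        )
    k = len(a & b)
    N, K, n = len(bg), len(a), len(b)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k, (K, n), N, min(p, 1.0))


def target_set_ks(fold_changes: pd.DataFrame, target_set: set) -> dict:
    """K-S comparison of a target set's fold changes against all other genes,
    with per-group median fold changes (linear scale)."""
    genes = fold_changes["orf_id"]
    is_target = genes.isin(target_set)
    if is_target.all() or not is_target.any():
        raise ValueError("target set and its complement must both be nonempty")
    t = fold_changes.loc[is_target, "log2_fc"].to_numpy()
    rest = fold_changes.loc[~is_target, "log2_fc"].to_numpy()
    res = stats.ks_2samp(t, rest, alternative="two-sided", method="auto")
    return {
        "D_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_targets": len(t),
        "n_rest": len(rest),
        "median_fold_targets": float(2 ** np.median(t)),
        "median_fold_rest": float(2 ** np.median(rest)),
    }


def riboseq_rnaseq_correlation(fc_ribo: pd.DataFrame, fc_rna: pd.DataFrame) -> dict:
    """Pearson r between footprint and transcript log2 fold changes over
    matched genes, plus the matched scatter table."""
    j = fc_ribo[["orf_id", "log2_fc"]].merge(
        fc_rna[["orf_id", "log2_fc"]], on="orf_id", suffixes=("_ribo", "_rna")
    )
    if len(j) < 3:
        raise ValueError("fewer than 3 matched genes")
    r, p = stats.pearsonr(j["log2_fc_ribo"], j["log2_fc_rna"])
    return {"r": float(r), "p_value": float(p), "n": len(j), "table": j}
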