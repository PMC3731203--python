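"""Single-codon occupancy and genome-wide distribution comparison.

The occupancy of one codon instance in one ribosomal site is the in-frame
5'-end count at that site's position divided by the mean in-frame read
density of the parent gene.  Only in-frame reads (frame-shifted 5' ends a
multiple of 3 from the site's first nt) count; the first 4 codons and codons
with no in-frame reads are excluded from both numerator records and the
denominator's codon count.  Genome-wide per-codon distributions are compared
between strains with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codons import SENSE_CODONS, SITE_FIVEPRIME_OFFSET, SITES
from .footprints import PooledFiveprimeTrack
from .reference import OrfModel

log = logging.getLogger(__name__)

#: exact K-S p-values are used at or below this per-sample size
KS_EXACT_MAX_N = 10


@dataclass
class OccupancyConfig:
    head_exclusion_codons: int = 4
    min_inframe_reads_per_codon: int = 1
    sites: tuple[str, ...] = SITES

    def __post_init__(self) -> None:
        if self.head_exclusion_codons < 0:
            raise ValueError("head_exclusion_codons must be >= 0")
        if any(s not in SITES for s in self.sites):
            raise ValueError("unknown ribosomal site in config")


@dataclass(frozen=True)
class KSResult:
    codon: str
    site: str
    D_statistic: float
    p_value: float
    n_condition1: int
    n_condition2: int


RECORD_COLUMNS = [
    "orf_id", "codon_index", "codon", "site", "occupancy", "numerator_reads",
    "gene_mean_density",
]


def single_codon_occupancy(
    track: PooledFiveprimeTrack,
    orf: OrfModel,
    config: OccupancyConfig | None = None,
) -> pd.DataFrame:
    """Occupancy records for every included codon of one ORF, all config sites.

    A frame-shifted in-frame 5' end at position p is attributed to its A-site
    codon (index (p + 15) / 3) for density purposes, so numerator and
    denominator share one site frame and uniform coverage gives occupancy 1.
    """
    cfg = config or OccupancyConfig()
    arr = track.shifted_array(orf.orf_id)
    base = track.upstream
    n = orf.n_codons
    k = np.arange(n)
    a_counts = arr[3 * k - SITE_FIVEPRIME_OFFSET["A"] + base]
    included = (k >= cfg.head_exclusion_codons) & (
        a_counts >= cfg.min_inframe_reads_per_codon
    )
    n_inc = int(included.sum())
    if n_inc == 0:
        log.info("%s: no included codons; no occupancy records", orf.orf_id)
        return pd.DataFrame(columns=RECORD_COLUMNS)
    mean_density = a_counts[included].sum() / n_inc

    frames = []
    codon_arr = orf.codon_array
    for site in cfg.sites:
        pos = 3 * k - SITE_FIVEPRIME_OFFSET[site] + base
        valid = (pos >= 0) & (pos < len(arr))
        num = np.where(valid, arr[np.clip(pos, 0, len(arr) - 1)], 0)
        emit = included & (num >= cfg.min_inframe_reads_per_codon)
        ke = k[emit]
        frames.append(
            pd.DataFrame(
                {
                    "orf_id": orf.orf_id,
                    "codon_index": ke,
                    "codon": codon_arr[ke],
                    "site": site,
                    "occupancy": num[emit] / mean_density,
                    "numerator_reads": num[emit],
                    "gene_mean_density": mean_density,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def occupancy_table(
    track: PooledFiveprimeTrack,
    orfs: dict[str, OrfModel],
    config: OccupancyConfig | None = None,
) -> pd.DataFrame:
    """Genome-wide occupancy records (all ORFs, all configured sites)."""
    frames = [single_codon_occupancy(track, orf, config) for orf in orfs.values()]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def pool_replicates(
    track_a: PooledFiveprimeTrack, track_b: PooledFiveprimeTrack
) -> PooledFiveprimeTrack:
    """Positionwise count sum of two replicate tracks (before any occupancy
    computation); references must match."""
    return track_a.add(track_b)


def ks_compare(
    occupancies_mut, occupancies_wt, codon: str = "", site: str = ""
) -> KSResult:
    """Two-sample two-sided K-S test between occupancy distributions.

    Exact p by enumeration for min(n1, n2) <= 10, asymptotic otherwise.
    """
    x = np.asarray(occupancies_mut, dtype=float)
    y = np.asarray(occupancies_wt, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"empty occupancy sample for codon {codon!r} site {site!r}")
    method = "exact" if min(len(x), len(y)) <= KS_EXACT_MAX_N else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return KSResult(codon, site, float(res.statistic), float(res.pvalue), len(x), len(y))


def ks_heatmap(
    occ_mut: pd.DataFrame,
    occ_wt: pd.DataFrame,
    codons: tuple[str, ...] = SENSE_CODONS,
    sites: tuple[str, ...] = SITES,
) -> pd.DataFrame:
    """K-S grid over codons x sites; p-values reported raw (no correction),
    with a log10 column for display."""
    gm = {k: v["occupancy"].to_numpy() for k, v in occ_mut.groupby(["codon", "site"])}
    gw = {k: v["occupancy"].to_numpy() for k, v in occ_wt.groupby(["codon", "site"])}
    rows = []
    for codon in codons:
        for site in sites:
            x = gm.get((codon, site))
            y = gw.get((codon, site))
            if x is None or y is None or len(x) == 0 or len(y) == 0:
                rows.append(
                    {"codon": codon, "site": site, "D": np.nan, "p_value": np.nan,
                     "log10_p": np.nan, "n_mut": 0 if x is None else len(x),
                     "n_wt": 0 if y is None else len(y)}
                )
                continue
            r = ks_compare(x, y, codon, site)
            rows.append(
                {"codon": codon, "site": site, "D": r.D_statistic, "p_value": r.p_value,
                 "log10_p": np.log10(r.p_value) if r.p_value > 0 else -np.inf,
                 "n_mut": r.n_condition1, "n_wt": r.n_condition2}
            )
    return pd.DataFrame(rows)


def fold_change_vs_coverage(
    occ_mut: pd.DataFrame,
    occ_wt: pd.DataFrame,
    codon_sets: dict[str, set[str]] | None = None,
    bin_width_log2: float = 0.2,
    min_reads: int = 32,
    reads_min_mode: str = "each",
) -> dict:
    """Per-instance occupancy fold changes with read-coverage binning.

    Instances are matched by (orf_id, codon_index, site) across conditions;
    both occupancies must be positive.  Coverage is the WT numerator read
    count on a log2 scale, binned half-open with the given width; per-set
    binned means are reported ("Other" pools all non-listed codons when
    ``codon_sets`` defaults to the VAA codons).  ``max_fold_filtered`` is the
    largest fold change among instances meeting ``min_reads`` under
    ``reads_min_mode`` ("each": both conditions; "combined": summed).
    """
    if reads_min_mode not in ("each", "combined"):
        raise ValueError("reads_min_mode must be 'each' or 'combined'")
    keys = ["orf_id", "codon_index", "site"]
    m = occ_mut[keys + ["codon", "occupancy", "numerator_reads"]].rename(
        columns={"occupancy": "occ_mut", "numerator_reads": "reads_mut"}
    )
    w = occ_wt[keys + ["occupancy", "numerator_reads"]].rename(
        columns={"occupancy": "occ_wt", "numerator_reads": "reads_wt"}
    )
    df = m.merge(w, on=keys, how="inner")
    df = df[(df["occ_mut"] > 0) & (df["occ_wt"] > 0)].copy()
    flagged_empty = len(df) == 0
    if flagged_empty:
        log.warning("fold_change_vs_coverage: no matched instances")
    df["fold_change"] = df["occ_mut"] / df["occ_wt"]
    df["log2_coverage"] = np.log2(df["reads_wt"].astype(float))
    df["bin"] = np.floor(df["log2_coverage"] / bin_width_log2).astype(int)
    df["bin_left"] = df["bin"] * bin_width_log2

    if codon_sets is None:
        vaa = {"AAA", "CAA", "GAA"}
        codon_sets = {c: {c} for c in sorted(vaa)}
        codon_sets["Other"] = set(SENSE_CODONS) - vaa
    binned_rows = []
    for name, cods in codon_sets.items():
        sub = df[df["codon"].isin(cods)]
        for (b, left), grp in sub.groupby(["bin", "bin_left"]):
            binned_rows.append(
                {"set": name, "bin": b, "bin_left_log2": left,
                 "mean_fold_change": grp["fold_change"].mean(), "n": len(grp)}
            )
    binned = pd.DataFrame(
        binned_rows, columns=["set", "bin", "bin_left_log2", "mean_fold_change", "n"]
    )

    if reads_min_mode == "each":
        ok = (df["reads_mut"] >= min_reads) & (df["reads_wt"] >= min_reads)
    else:
        ok = (df["reads_mut"] + df["reads_wt"]) >= min_reads
    max_fold = float(df.loc[ok, "fold_change"].max()) if ok.any() else np.nan

    return {
        "instances": df,
        "binned": binned,
        "max_fold_filtered": max_fold,
        "metadata": {
            "bin_width_log2": bin_width_log2,
            "min_reads": min_reads,
            "reads_min_mode": reads_min_mode,
            "empty": flagged_empty,
        },
    }
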