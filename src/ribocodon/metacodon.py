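"""Metacodon profiles and bulk codon occupancy.

For every in-frame instance of a codon (first nt at ORF-relative c), the
frame-shifted 5'-end counts over the 21 positions [c-21, c) are summed; the
21-nt offset is the 28-mer P-site offset (12 nt) plus the distance from the
P site to the first window position.  Window peaks map to ribosomal sites as
{0: -2, 3: -1, 6: A, 9: P, 12: E, 15: +1, 18: +2}.  Codon identity is not
expected to affect dwell in the outer sites (+/-1, +/-2), so the profile is
normalized to the mean of those four peak heights; the normalized peak
heights are the bulk codon occupancies, a proxy for relative ribosome dwell
time in each site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codons import (
    AA_OF_CODON,
    AMINO_ACIDS,
    OUTER_SITE_INDICES,
    SENSE_CODONS,
    SITE_WINDOW_INDEX,
    SITES,
)
from .footprints import PooledFiveprimeTrack
from .reference import OrfModel

log = logging.getLogger(__name__)

WINDOW_NT = 21  # single-codon window; pair metaplots extend it by one codon

#: instances closer than this to either ORF end are excluded so the full
#: window (and the +/-2-site codons) lie in covered track space
EDGE_EXCLUSION_CODONS = 7


@dataclass
class MetacodonProfile:
    codon: str
    raw: np.ndarray  # 21 (or 24 for pairs) counts, window index i <-> position c - 21 + i
    normalized: np.ndarray | None
    n_instances: int
    outer_indices: tuple[int, ...] = OUTER_SITE_INDICES
    site_index_map: dict[str, int] = field(default_factory=lambda: dict(SITE_WINDOW_INDEX))
    error: str | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(len(self.raw))
        return pd.DataFrame(
            {
                "codon": self.codon,
                "window_index": idx,
                "raw": self.raw,
                "normalized": self.normalized if self.normalized is not None else np.nan,
            }
        )


def _window_sum(
    positions_by_orf: dict[str, np.ndarray],
    track: PooledFiveprimeTrack,
    width: int,
) -> tuple[np.ndarray, int]:
    raw = np.zeros(width, dtype=np.int64)
    n = 0
    offs = np.arange(-WINDOW_NT, -WINDOW_NT + width)
    for orf_id, cpos in positions_by_orf.items():
        if len(cpos) == 0:
            continue
        arr = track.shifted_array(orf_id)
        idx = cpos[:, None] + offs[None, :] + track.upstream
        raw += arr[idx].sum(axis=0)
        n += len(cpos)
    return raw, n


def _normalize(raw: np.ndarray, outer: tuple[int, ...]) -> tuple[np.ndarray | None, str | None]:
    denom = raw[list(outer)].mean()
    if denom == 0:
        return None, "zero outer-peak mean; profile cannot be normalized"
    return raw / denom, None


def _eligible_positions(
    orfs: dict[str, OrfModel],
    match: "callable",
    edge_exclusion: int,
    extra_codons: int = 0,
) -> dict[str, np.ndarray]:
    """First-nt positions of instances whose window stays inside the track."""
    out = {}
    for orf_id, orf in orfs.items():
        n = orf.n_codons
        lo, hi = edge_exclusion, n - edge_exclusion - extra_codons
        if hi <= lo:
            out[orf_id] = np.empty(0, dtype=np.int64)
            continue
        idx = match(orf)
        idx = idx[(idx >= lo) & (idx < hi)]
        out[orf_id] = 3 * idx
    return out


def compute_metacodon(
    codon: str,
    track: PooledFiveprimeTrack,
    orfs: dict[str, OrfModel],
    edge_exclusion: int = EDGE_EXCLUSION_CODONS,
) -> MetacodonProfile:
    """Raw and normalized 21-position metacodon vectors for one codon."""
    if codon not in SENSE_CODONS:
        raise ValueError(f"not a sense codon: {codon!r}")
    pos = _eligible_positions(
        orfs, lambda o: np.flatnonzero(o.codon_array == codon), edge_exclusion
    )
    raw, n = _window_sum(pos, track, WINDOW_NT)
    normalized, err = _normalize(raw, OUTER_SITE_INDICES)
    if err:
        log.warning("metacodon %s: %s", codon, err)
    return MetacodonProfile(codon, raw, normalized, n, error=err)


def bulk_occupancy(profile: MetacodonProfile) -> dict[str, float]:
    """Normalized peak height per ribosomal site (missing when unnormalizable)."""
    if profile.normalized is None:
        return {s: np.nan for s in SITES}
    return {s: float(profile.normalized[i]) for s, i in profile.site_index_map.items()}


def assemble_bulk_table(
    track: PooledFiveprimeTrack,
    orfs: dict[str, OrfModel],
    sample_id: str = "sample",
    codons: tuple[str, ...] = SENSE_CODONS,
    edge_exclusion: int = EDGE_EXCLUSION_CODONS,
) -> pd.DataFrame:
    """Long-format bulk occupancy: one row per (codon, site)."""
    rows = []
    for codon in codons:
        prof = compute_metacodon(codon, track, orfs, edge_exclusion)
        heights = bulk_occupancy(prof)
        for site in SITES:
            rows.append(
                {
                    "sample_id": sample_id,
                    "codon": codon,
                    "site": site,
                    "height": heights[site],
                    "raw_peak": int(prof.raw[prof.site_index_map[site]]),
                    "n_instances": prof.n_instances,
                }
            )
    return pd.DataFrame(rows)


def occupancy_change(mutant_table: pd.DataFrame, wt_table: pd.DataFrame) -> pd.DataFrame:
    """Per (codon, site) mutant/WT bulk-occupancy ratio and log2 ratio.

    Both tables must come from identically processed samples.  Zero or
    missing WT heights yield NaN ratios, flagged in the ``undefined`` column.
    """
    m = mutant_table[["codon", "site", "height"]].rename(columns={"height": "height_mut"})
    w = wt_table[["codon", "site", "height"]].rename(columns={"height": "height_wt"})
    df = m.merge(w, on=["codon", "site"], how="outer")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = df["height_mut"] / df["height_wt"]
        df.loc[df["height_wt"] == 0, "ratio"] = np.nan
        df["log2_ratio"] = np.log2(df["ratio"])
    df["undefined"] = ~np.isfinite(df["ratio"])
    return df


def pair_metaplot(
    amino_acid_pair: str,
    track: PooledFiveprimeTrack,
    orfs: dict[str, OrfModel],
    edge_exclusion: int = EDGE_EXCLUSION_CODONS,
) -> MetacodonProfile:
    """Metaplot over adjacent codon pairs encoding an amino-acid pair.

    The window origin is the first nucleotide of the first codon of the
    pair; the window is extended by one codon (24 positions) so both codons'
    site peaks are covered.  With the first codon in the P site (index 9)
    the second codon sits in the A site simultaneously.
    """
    pair = amino_acid_pair.upper()
    if len(pair) != 2 or any(a not in AMINO_ACIDS for a in pair):
        raise ValueError(f"not a valid amino-acid pair: {amino_acid_pair!r}")
    a1, a2 = pair

    def match(orf: OrfModel) -> np.ndarray:
        aas = np.array([AA_OF_CODON.get(c, "*") for c in orf.codons], dtype=object)
        first = aas[:-1]
        second = aas[1:]
        return np.flatnonzero((first == a1) & (second == a2))

    pos = _eligible_positions(orfs, match, edge_exclusion, extra_codons=1)
    width = WINDOW_NT + 3
    raw, n = _window_sum(pos, track, width)
    outer = (0, 3, 18, 21)  # -2/-1 of the first codon, +1/+2 of the second
    normalized, err = _normalize(raw, outer)
    if n == 0:
        err = err or "no instances of the pair"
        log.warning("pair metaplot %s: empty", pair)
    site_map = {s: i for s, i in SITE_WINDOW_INDEX.items()}  # peaks of the 1st codon
    prof = MetacodonProfile(pair, raw, normalized, n, outer_indices=outer, error=err)
    prof.site_index_map = site_map
    return prof


def correlate_with_metric(
    bulk_table: pd.DataFrame,
    per_codon_metric: dict[str, float] | pd.Series,
    min_codons: int = 50,
) -> pd.DataFrame:
    """Spearman rank correlation of bulk occupancy vs a per-codon metric,
    per ribosomal site (e.g. occupancy vs tAI)."""
    metric = pd.Series(per_codon_metric, dtype=float)
    if metric.notna().sum() < min_codons:
        raise ValueError(f"metric covers fewer than {min_codons} codons")
    rows = []
    for site, grp in bulk_table.groupby("site", sort=False):
        merged = grp.set_index("codon")["height"].to_frame().join(metric.rename("metric"))
        merged = merged.dropna()
        n = len(merged)
        if n < 3 or merged["metric"].nunique() == 1:
            rows.append({"site": site, "rho": np.nan, "p_value": np.nan, "n": n, "undefined": True})
            continue
        rho, p = stats.spearmanr(merged["height"], merged["metric"])
        rows.append({"site": site, "rho": rho, "p_value": p, "n": n, "undefined": False})
    return pd.DataFrame(rows)
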